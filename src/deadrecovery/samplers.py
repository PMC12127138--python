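"""Bayesian fitting for every model family.

State-space models are fitted by alternating (a) systematic single-site
Gibbs sweeps over the latent states (compiled kernels in
:mod:`deadrecovery._kernels`) with (b) conjugate Beta draws for the
parameters: under Uniform(0,1) = Beta(1,1) priors every parameter is a
Bernoulli/categorical success probability whose full conditional given the
latent states is Beta(1 + successes, 1 + failures).

The classical multistate model is *intentionally* updated one latent site
at a time: its deterministic two-step transition (recently dead -> long
dead) gives many single-site moves zero-support full conditionals, so the
sampler cannot leave large parts of its initialization.  This documented
failure mode is preserved, not repaired.

Marginalized and multinomial models carry no latent states and are fitted
by adaptive random-walk Metropolis on logit-transformed parameters, with
step sizes adapted only during burn-in.

Convergence is judged by the rank-normalized split-chain R-hat (threshold
1.1) and effective sample sizes from ``arviz``; the efficiency metric is
the minimum-over-parameters ESS per second of sampling time.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Optional, Sequence, Tuple, Union

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import models as model_registry
from ._kernels import sweep_single, sweep_multistate
from .capture_data import (
    CaptureHistoryMatrix,
    Encoding,
    build_marray,
    build_multistate_marray,
    pool,
    recode,
)
from .errors import EncodingError, ValidationError
from .likelihoods import (
    detection_matrix,
    forward_loglik_multistate,
    forward_loglik_single_dr,
    forward_loglik_single_joint,
    marray_cell_probs,
    multinomial_loglik,
    multistate_cell_probs,
    observation_matrix_bpa,
    observation_matrix_classical,
    transition_matrix_bpa,
    transition_matrix_classical,
)
from .simulator import ParamSet

__all__ = [
    "MCMCConfig",
    "PosteriorSummary",
    "MCMCResult",
    "RHAT_THRESHOLD",
    "INIT_STRATEGIES",
    "init_latent",
    "gibbs_update_latent",
    "gibbs_update_params",
    "run_mcmc",
    "efficiency",
]

RHAT_THRESHOLD = 1.1
INIT_STRATEGIES = ("alive", "dead", "random")


@dataclass(frozen=True)
class MCMCConfig:
    """MCMC run settings.

    ``n_iter`` is the total chain length including burn-in; draws after
    ``n_burnin`` are kept (thinned by ``thin``).  ``init`` selects the
    latent-state initialization strategy for state-space models.
    """

    n_iter: int = 3000
    n_burnin: int = 1000
    n_chains: int = 3
    thin: int = 1
    init: str = "random"
    seed: Union[int, np.random.SeedSequence] = 0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValidationError("burn-in must be shorter than the chain")
        if self.n_chains < 2:
            raise ValidationError("at least two chains are needed for R-hat")
        if self.init not in INIT_STRATEGIES:
            raise ValidationError(f"unknown init strategy {self.init!r}")

    def seed_sequence(self) -> np.random.SeedSequence:
        if isinstance(self.seed, np.random.SeedSequence):
            return self.seed
        return np.random.SeedSequence(self.seed)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior summaries and convergence diagnostics."""

    table: pd.DataFrame  # index: parameter; columns: mean, q2.5, q97.5, rhat, ess
    converged: bool

    def __getitem__(self, param: str) -> pd.Series:
        return self.table.loc[param]

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())


@dataclass
class MCMCResult:
    model_id: str
    draws: Dict[str, np.ndarray]  # param -> (chains, kept draws)
    summary: PosteriorSummary
    config: MCMCConfig
    seconds: float
    n_trapped: int = 0

    def stacked(self, param: str) -> np.ndarray:
        return self.draws[param].reshape(-1)


def _summarize_draws(draws: Dict[str, np.ndarray]) -> PosteriorSummary:
    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    rhat = az.rhat(idata, method="rank")
    ess = az.ess(idata, method="bulk")
    rows = []
    for name, arr in draws.items():
        flat = arr.reshape(-1)
        rows.append(
            {
                "parameter": name,
                "mean": float(flat.mean()),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
                "rhat": float(rhat[name].values),
                "ess": float(ess[name].values),
            }
        )
    table = pd.DataFrame(rows).set_index("parameter")
    converged = bool((table["rhat"] < RHAT_THRESHOLD).all())
    return PosteriorSummary(table=table, converged=converged)


# ---------------------------------------------------------------------------
# latent-state preparation and initialization
# ---------------------------------------------------------------------------


@dataclass
class _LatentData:
    """Arrays shared by the latent sweeps and the conjugate updates."""

    f0: np.ndarray  # 0-based marking occasion
    live: np.ndarray  # (n, T) live encounters after marking (0 for DR data)
    obs: Optional[np.ndarray]  # (n, T) multistate codes 1..3, or None
    recovered: np.ndarray  # (n,) int64 recovery indicator
    rec0: np.ndarray  # (n,) 0-based recovery occasion or -1
    last0: np.ndarray  # (n,) 0-based last live encounter (incl. marking)
    n_rec: int
    n_seen: int
    joint: bool


def _prep_latent(histories: CaptureHistoryMatrix, model: str) -> _LatentData:
    enc = histories.encoding
    if model == "single":
        ok = (Encoding.DR_BINARY, Encoding.JOINT)
    else:
        ok = (Encoding.DR_MULTISTATE, Encoding.JOINT_MULTISTATE)
    if enc not in ok:
        raise EncodingError(
            f"model family {model!r} cannot use encoding {enc.value}"
        )
    joint = enc in (Encoding.JOINT, Encoding.JOINT_MULTISTATE)
    f0 = histories.f - 1
    rec = histories.recovery_occasions()
    rec0 = rec - 1  # -1 where never recovered
    T = histories.n_occasions
    occ0 = np.arange(T)[None, :]
    live = ((histories.codes == 1) & (occ0 > f0[:, None])).astype(np.int64)
    if not joint:
        live = np.zeros_like(live)
    obs = histories.codes.copy() if model != "single" else None
    return _LatentData(
        f0=f0.astype(np.int64),
        live=live,
        obs=obs,
        recovered=(rec > 0).astype(np.int64),
        rec0=rec0.astype(np.int64),
        last0=histories.last_live_occasions() - 1,
        n_rec=int((rec > 0).sum()),
        n_seen=int(live.sum()),
        joint=joint,
    )


def _death_occasions(
    data: _LatentData, T: int, strategy: str, rng: np.random.Generator
) -> np.ndarray:
    """0-based first-dead occasion per individual; T means alive at the end.

    Recovered individuals die at their recovery occasion regardless of the
    strategy.  For the rest, ``alive`` keeps them alive to the end,
    ``dead`` kills them immediately after their last encounter, and
    ``random`` draws the death occasion uniformly between the last
    encounter and the study end (survival to the end included as one
    outcome, so every legal completion has positive probability).
    """
    if strategy not in INIT_STRATEGIES:
        raise ValidationError(f"unknown init strategy {strategy!r}")
    n = data.f0.size
    d = np.full(n, T, dtype=np.int64)
    known = data.recovered == 1
    d[known] = data.rec0[known]
    free = ~known
    if strategy == "dead":
        d[free] = np.minimum(data.last0[free] + 1, T)
    elif strategy == "random":
        lo = data.last0[free] + 1
        d[free] = rng.integers(lo, T + 1)
    return d


def init_latent(
    histories: CaptureHistoryMatrix,
    model: str,
    strategy: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Initial latent-state matrix consistent with the data.

    ``model`` is one of ``single`` (codes 1 alive / 0 dead), ``classical``
    (1 alive / 2 recently dead / 3 long dead) or ``bpa`` (1 alive /
    2 recovered / 3 other dead).  Known segments (release to last live
    encounter; recovery onward) are fixed by the data; only the unknown
    tails depend on the strategy.
    """
    if model not in ("single", "classical", "bpa"):
        raise ValidationError(f"unknown latent model {model!r}")
    data = _prep_latent(histories, model)
    T = histories.n_occasions
    d = _death_occasions(data, T, strategy, rng)
    occ0 = np.arange(T)[None, :]
    alive = (occ0 >= data.f0[:, None]) & (occ0 < d[:, None])
    if model == "single":
        return alive.astype(np.int64)
    z = np.zeros((data.f0.size, T), dtype=np.int64)
    z[alive] = 1
    after = occ0 > d[:, None]
    at = occ0 == d[:, None]
    if model == "classical":
        z[at] = 2
        z[after] = 3
    else:  # bpa: state 2 only for actual recoveries
        z[at] = 3
        z[after] = 3
        rec_rows = data.recovered == 1
        z[rec_rows, data.rec0[rec_rows]] = 2
    z[occ0 < data.f0[:, None]] = 0
    return z


# ---------------------------------------------------------------------------
# Gibbs updates
# ---------------------------------------------------------------------------


def _model_matrices(model: str, params: ParamSet, joint: bool):
    p = params.p if (joint and params.p is not None) else 0.0
    if model == "classical":
        return (
            transition_matrix_classical(params.s),
            observation_matrix_classical(params.r, p),
        )
    return transition_matrix_bpa(params.s, params.r), observation_matrix_bpa(p)


def gibbs_update_latent(
    z: np.ndarray,
    data: Union[CaptureHistoryMatrix, _LatentData],
    params: ParamSet,
    model: str,
    rng: np.random.Generator,
) -> int:
    """One in-place systematic single-site sweep; returns the number of
    zero-support (trapped) sites encountered."""
    if isinstance(data, CaptureHistoryMatrix):
        data = _prep_latent(data, model)
    n, T = z.shape
    u = rng.random((n, T))
    if model == "single":
        p = params.p if (data.joint and params.p is not None) else 0.0
        return int(
            sweep_single(
                z, data.f0, data.live, data.recovered, params.s, params.r, p, u
            )
        )
    omega, theta = _model_matrices(model, params, data.joint)
    return int(
        sweep_multistate(z, data.f0, data.obs, data.recovered, omega, theta, u)
    )


def gibbs_update_params(
    z: np.ndarray,
    data: Union[CaptureHistoryMatrix, _LatentData],
    model: str,
    rng: np.random.Generator,
) -> ParamSet:
    """Conjugate Beta draws for (s, r[, p]) given the latent states.

    With no trials for a parameter the draw is Beta(1, 1) = Uniform(0, 1),
    which is the exact full conditional under the flat prior.
    """
    if isinstance(data, CaptureHistoryMatrix):
        data = _prep_latent(data, model)
    n, T = z.shape
    cols = np.arange(T)
    tm = cols[None, : T - 1] >= data.f0[:, None]
    am = cols[None, :] > data.f0[:, None]
    from1 = (z[:, :-1] == 1) & tm
    if model == "single":
        n11 = int((from1 & (z[:, 1:] == 1)).sum())
        n10 = int((from1 & (z[:, 1:] == 0)).sum())
        s = rng.beta(1 + n11, 1 + n10)
        r = rng.beta(1 + data.n_rec, 1 + n10 - data.n_rec)
    elif model == "classical":
        n11 = int((from1 & (z[:, 1:] == 1)).sum())
        n12 = int((from1 & (z[:, 1:] == 2)).sum())
        s = rng.beta(1 + n11, 1 + n12)
        nz2 = int(((z == 2) & am).sum())
        r = rng.beta(1 + data.n_rec, 1 + nz2 - data.n_rec)
    elif model == "bpa":
        n11 = int((from1 & (z[:, 1:] == 1)).sum())
        n12 = int((from1 & (z[:, 1:] == 2)).sum())
        n13 = int((from1 & (z[:, 1:] == 3)).sum())
        s = rng.beta(1 + n11, 1 + n12 + n13)
        r = rng.beta(1 + n12, 1 + n13)
    else:
        raise ValidationError(f"unknown latent model {model!r}")
    p = None
    if data.joint:
        n_alive = int(((z == 1) & am).sum())
        p = rng.beta(1 + data.n_seen, 1 + n_alive - data.n_seen)
    return ParamSet(s=s, r=r, p=p)


def _run_latent(
    model: str,
    histories: CaptureHistoryMatrix,
    config: MCMCConfig,
) -> Tuple[Dict[str, np.ndarray], int, float]:
    data = _prep_latent(histories, model)
    n, T = histories.codes.shape
    names = ["s", "r"] + (["p"] if data.joint else [])
    kept = (config.n_iter - config.n_burnin - 1) // config.thin + 1
    draws = {k: np.empty((config.n_chains, kept)) for k in names}
    trapped = 0
    t0 = time.perf_counter()
    for c, child in enumerate(config.seed_sequence().spawn(config.n_chains)):
        rng = np.random.default_rng(child)
        z = init_latent(histories, model, config.init, rng)
        params = ParamSet(
            s=rng.uniform(), r=rng.uniform(), p=rng.uniform() if data.joint else None
        )
        kidx = 0
        for it in range(config.n_iter):
            trapped += gibbs_update_latent(z, data, params, model, rng)
            params = gibbs_update_params(z, data, model, rng)
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                for k in names:
                    draws[k][c, kidx] = getattr(params, k)
                kidx += 1
    return draws, trapped, time.perf_counter() - t0


# ---------------------------------------------------------------------------
# adaptive Metropolis for marginal / multinomial models
# ---------------------------------------------------------------------------

_ADAPT_BATCH = 50
_ADAPT_TARGET = 0.35  # inside the 0.2-0.5 band aimed for


def _run_metropolis(
    loglik: Callable[[Sequence[float]], float],
    names: Sequence[str],
    config: MCMCConfig,
) -> Tuple[Dict[str, np.ndarray], float]:
    k = len(names)
    kept = (config.n_iter - config.n_burnin - 1) // config.thin + 1
    draws = {nm: np.empty((config.n_chains, kept)) for nm in names}
    t0 = time.perf_counter()
    for c, child in enumerate(config.seed_sequence().spawn(config.n_chains)):
        rng = np.random.default_rng(child)
        x = rng.uniform(size=k)  # init from the flat prior
        theta = logit(x)
        lp = loglik(x) + np.sum(np.log(x * (1.0 - x)))
        if not np.isfinite(lp):
            raise ValidationError(
                "non-finite likelihood at initialization; the data contain "
                "histories impossible under this model"
            )
        step = np.full(k, 1.0)
        acc = np.zeros(k)
        kidx = 0
        for it in range(config.n_iter):
            for j in range(k):
                prop = theta.copy()
                prop[j] = theta[j] + step[j] * rng.standard_normal()
                xp = expit(prop)
                lpp = loglik(xp) + np.sum(np.log(xp * (1.0 - xp)))
                if np.log(rng.random()) < lpp - lp:
                    theta, x, lp = prop, xp, lpp
                    acc[j] += 1
            if it < config.n_burnin and (it + 1) % _ADAPT_BATCH == 0:
                rate = acc / _ADAPT_BATCH
                step = np.clip(step * np.exp(rate - _ADAPT_TARGET), 1e-3, 20.0)
                acc[:] = 0.0
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                for jj, nm in enumerate(names):
                    draws[nm][c, kidx] = x[jj]
                kidx += 1
    return draws, time.perf_counter() - t0


# ---------------------------------------------------------------------------
# model dispatch
# ---------------------------------------------------------------------------


def _to_multistate(histories: CaptureHistoryMatrix) -> CaptureHistoryMatrix:
    if histories.encoding is Encoding.DR_BINARY:
        return recode(histories, Encoding.DR_MULTISTATE)
    if histories.encoding is Encoding.JOINT:
        return recode(histories, Encoding.JOINT_MULTISTATE)
    return histories


def _marginal_loglik_fn(spec, histories: CaptureHistoryMatrix):
    joint = spec.data_kind == "joint"
    T = histories.n_occasions
    if spec.family == "marg_single":
        data = pool(histories) if spec.pooled else histories
        if joint:
            return lambda x: forward_loglik_single_joint(
                ParamSet(s=x[0], r=x[1], p=x[2]), data
            )
        return lambda x: forward_loglik_single_dr(ParamSet(s=x[0], r=x[1]), data)
    if spec.family == "marg_multistate":
        v = _to_multistate(histories)
        data = pool(v) if spec.pooled else v
        if joint:
            return lambda x: forward_loglik_multistate(
                transition_matrix_classical(x[0]),
                observation_matrix_classical(x[1], x[2]),
                data,
            )
        return lambda x: forward_loglik_multistate(
            transition_matrix_classical(x[0]),
            observation_matrix_classical(x[1]),
            data,
        )
    if spec.family == "multinomial_single":
        ma = build_marray(histories)
        return lambda x: multinomial_loglik(
            ma, marray_cell_probs(ParamSet(s=x[0], r=x[1]), T)
        )
    if spec.family == "multinomial_multistate":
        w = recode(_to_multistate(histories), Encoding.MULTISTATE_ZERO)
        msma = build_multistate_marray(w)
        if joint:
            return lambda x: multinomial_loglik(
                msma,
                multistate_cell_probs(
                    transition_matrix_classical(x[0]),
                    detection_matrix(x[1], x[2]),
                    T,
                ),
            )
        return lambda x: multinomial_loglik(
            msma,
            multistate_cell_probs(
                transition_matrix_classical(x[0]), detection_matrix(x[1]), T
            ),
        )
    raise ValidationError(f"unknown model family {spec.family!r}")


def run_mcmc(
    model_id: str,
    histories: CaptureHistoryMatrix,
    config: Optional[MCMCConfig] = None,
) -> MCMCResult:
    """Fit one of the registered models to capture-history data.

    ``histories`` must be in the source encoding for the model's data kind
    (DR_BINARY for dead-recovery models, JOINT for joint models); model-
    specific recoding, splitting, pooling, and m-array construction happen
    internally.
    """
    spec = model_registry.get_model(model_id)
    want = Encoding.JOINT if spec.data_kind == "joint" else Encoding.DR_BINARY
    if histories.encoding is not want:
        raise EncodingError(
            f"model {model_id} expects {want.value} data, "
            f"got {histories.encoding.value}"
        )
    if config is None:
        config = model_registry.default_config(model_id)
    trapped = 0
    if spec.family.startswith("latent_"):
        latent = spec.family.removeprefix("latent_")
        hist = histories if latent == "single" else _to_multistate(histories)
        draws, trapped, seconds = _run_latent(latent, hist, config)
    else:
        fn = _marginal_loglik_fn(spec, histories)
        draws, seconds = _run_metropolis(fn, spec.params, config)
    summary = _summarize_draws(draws)
    return MCMCResult(
        model_id=model_id,
        draws=draws,
        summary=summary,
        config=config,
        seconds=seconds,
        n_trapped=trapped,
    )


def efficiency(result_or_draws, seconds: Optional[float] = None) -> float:
    """Effective independent samples per second for the least-converged
    (minimum-ESS) parameter."""
    if isinstance(result_or_draws, MCMCResult):
        draws = result_or_draws.draws
        seconds = result_or_draws.seconds if seconds is None else seconds
    else:
        draws = result_or_draws
        if seconds is None:
            raise ValidationError("seconds required when passing raw draws")
    idata = az.from_dict(posterior=dict(draws))
    ess = az.ess(idata, method="bulk")
    min_ess = min(float(ess[k].values) for k in draws)
    return min_ess / float(seconds)
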