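"""Registry of the thirteen model configurations (plus pooled variants).

Identifiers combine the data kind (a ``joint-`` prefix for models of joint
live-encounter/dead-recovery data), the state structure (``ss`` single
state, ``ms`` multistate), and the fitting route (``ss`` state-space with
latent sampling, ``marg`` marginalized forward likelihood, ``multinomial``
m-array likelihood).  Marginalized models have ``-pooled`` variants that
fit the identical likelihood from unique-history frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .errors import ValidationError

__all__ = [
    "ModelSpec",
    "MODELS",
    "TABLE2_MODELS",
    "get_model",
    "default_config",
    "desk_config",
]


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    label: str
    data_kind: str  # "dr" | "joint"
    family: str  # latent_single | latent_classical | latent_bpa |
    #              marg_single | marg_multistate |
    #              multinomial_single | multinomial_multistate
    pooled: bool
    n_burnin: int  # default burn-in (total-iteration counts incl. burn-in)
    n_iter: int
    params: Tuple[str, ...]

    @property
    def has_latent(self) -> bool:
        return self.family.startswith("latent_")


def _spec(model_id, label, kind, family, pooled, burnin, iters):
    params = ("s", "r", "p") if kind == "joint" else ("s", "r")
    return ModelSpec(model_id, label, kind, family, pooled, burnin, iters, params)


MODELS = {
    m.model_id: m
    for m in [
        # dead-recovery data only
        _spec("ss-ss", "Single-state SS", "dr", "latent_single", False, 2000, 5000),
        _spec("ms-ss-classical", "Multistate SS, classical", "dr", "latent_classical", False, 2000, 5000),
        _spec("ms-ss-bpa", "Multistate SS, BPA", "dr", "latent_bpa", False, 2000, 5000),
        _spec("ss-marg", "Single-state SS, marginalized", "dr", "marg_single", False, 1000, 3000),
        _spec("ss-marg-pooled", "Single-state SS, marginalized, pooled", "dr", "marg_single", True, 1000, 3000),
        _spec("ms-marg", "Multistate SS, marginalized", "dr", "marg_multistate", False, 1000, 3000),
        _spec("ms-marg-pooled", "Multistate SS, marginalized, pooled", "dr", "marg_multistate", True, 1000, 3000),
        _spec("ss-multinomial", "Single-state multinomial", "dr", "multinomial_single", False, 1000, 3000),
        _spec("ms-multinomial", "Multistate multinomial", "dr", "multinomial_multistate", False, 1000, 3000),
        # joint dead-recovery and live-encounter data
        _spec("joint-ss-ss", "Single-state SS (joint)", "joint", "latent_single", False, 1000, 3000),
        _spec("joint-ms-ss-classical", "Multistate SS, classical (joint)", "joint", "latent_classical", False, 2000, 5000),
        _spec("joint-ms-ss-bpa", "Multistate SS, BPA (joint)", "joint", "latent_bpa", False, 2000, 5000),
        _spec("joint-ss-marg", "Single-state SS, marginalized (joint)", "joint", "marg_single", False, 1000, 3000),
        _spec("joint-ss-marg-pooled", "Single-state SS, marginalized, pooled (joint)", "joint", "marg_single", True, 1000, 3000),
        _spec("joint-ms-marg", "Multistate SS, marginalized (joint)", "joint", "marg_multistate", False, 1000, 3000),
        _spec("joint-ms-marg-pooled", "Multistate SS, marginalized, pooled (joint)", "joint", "marg_multistate", True, 1000, 3000),
        _spec("joint-ms-multinomial", "Multistate multinomial (joint)", "joint", "multinomial_multistate", False, 1000, 3000),
    ]
}

#: the thirteen canonical configurations (pooled variants excluded)
TABLE2_MODELS = [m for m in MODELS if not m.endswith("-pooled")]


def get_model(model_id: str) -> ModelSpec:
    try:
        return MODELS[model_id]
    except KeyError:
        raise ValidationError(
            f"unknown model {model_id!r}; known: {sorted(MODELS)}"
        ) from None


def default_config(model_id: str, **overrides):
    """Full-scale MCMC settings for a model (3 chains, default lengths)."""
    from .samplers import MCMCConfig

    spec = get_model(model_id)
    kw = dict(n_iter=spec.n_iter, n_burnin=spec.n_burnin)
    kw.update(overrides)
    return MCMCConfig(**kw)


def desk_config(model_id: str, **overrides):
    """Reduced-scale settings: default chain lengths halved."""
    spec = get_model(model_id)
    kw = dict(n_iter=spec.n_iter // 2, n_burnin=spec.n_burnin // 2)
    kw.update(overrides)
    from .samplers import MCMCConfig

    return MCMCConfig(**kw)
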