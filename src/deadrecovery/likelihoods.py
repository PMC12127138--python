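"""Marginal (latent-state-free) likelihoods.

Three equivalent routes to the same likelihood are implemented:

* single-state forward recursions over {alive, death-already-accounted},
  for dead-recovery data and for joint data split into binary layers;
* a generic 3-state hidden-Markov forward pass over multistate-coded
  histories, parameterized by a state-transition matrix ``Omega`` and an
  observation matrix ``Theta``;
* multinomial likelihoods over (multistate) m-arrays with cell
  probabilities built from the Seber parameters or from matrix products
  of ``Omega`` with a diagonal detection matrix ``Gamma``.

For these models each capture history factorizes exactly into m-array
cells, so the multinomial kernel log-likelihood (multinomial coefficient
dropped) equals the summed history log-likelihood *exactly*, not merely up
to a constant; the test suite relies on this.

Forward recursions run in linear space with per-occasion rescaling, the
log of the normalization being accumulated, so histories much longer than
the default 8 occasions do not underflow.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from . import _kernels
from .capture_data import (
    BinarySplitPair,
    CaptureHistoryMatrix,
    Encoding,
    MArray,
    MultistateMArray,
    PooledHistories,
    split_joint,
)
from .errors import EncodingError, ValidationError
from .simulator import ParamSet

__all__ = [
    "transition_matrix_classical",
    "transition_matrix_bpa",
    "observation_matrix_classical",
    "observation_matrix_bpa",
    "detection_matrix",
    "marray_cell_probs",
    "multistate_cell_probs",
    "multinomial_loglik",
    "forward_loglik_single_dr",
    "forward_loglik_multistate",
    "forward_loglik_single_joint",
]

# ---------------------------------------------------------------------------
# model matrices
# ---------------------------------------------------------------------------


def transition_matrix_classical(s: float) -> np.ndarray:
    """Latent transitions over {alive, recently dead, long dead}."""
    return np.array(
        [
            [s, 1.0 - s, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 1.0],
        ]
    )


def transition_matrix_bpa(s: float, r: float) -> np.ndarray:
    """Latent transitions with the recovery event folded into the state
    process: {alive, recently dead & recovered, other dead}."""
    return np.array(
        [
            [s, (1.0 - s) * r, (1.0 - s) * (1.0 - r)],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, 1.0],
        ]
    )


def observation_matrix_classical(r: float, p: float = 0.0) -> np.ndarray:
    """Latent states (rows) to observed codes 1/2/3 (columns); p=0 gives
    the dead-recovery-only case where live individuals are never seen."""
    return np.array(
        [
            [p, 0.0, 1.0 - p],
            [0.0, r, 1.0 - r],
            [0.0, 0.0, 1.0],
        ]
    )


def observation_matrix_bpa(p: float = 0.0) -> np.ndarray:
    """Deterministic-in-r observation matrix of the reparameterized model."""
    return np.array(
        [
            [p, 0.0, 1.0 - p],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
        ]
    )


def detection_matrix(r: float, p: float = 0.0) -> np.ndarray:
    """Diagonal per-state detection probabilities for m-array cells."""
    return np.diag([p, r, 0.0])


def _check_stochastic(omega: np.ndarray) -> None:
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (3, 3):
        raise ValidationError("transition matrix must be 3x3")
    if (omega < -1e-12).any() or (omega > 1 + 1e-12).any():
        raise ValidationError("transition probabilities outside [0, 1]")
    if not np.allclose(omega.sum(axis=1), 1.0, atol=1e-10):
        raise ValidationError("transition matrix rows must sum to 1")


# ---------------------------------------------------------------------------
# m-array cell probabilities
# ---------------------------------------------------------------------------


def marray_cell_probs(params: ParamSet, T: int) -> np.ndarray:
    """Single-state m-array cell probabilities.

    Row t (release occasion t+1, 0-based row index t) assigns probability
    s**(k-t-1) * (1-s) * r to a recovery k intervals later; the final
    column is the never-recovered complement.
    """
    if T < 2:
        raise ValidationError("need at least two occasions")
    s, r = params.s, params.r
    pi = np.zeros((T - 1, T))
    for t in range(T - 1):  # release occasion t+1
        for k in range(t + 1, T):  # recovery occasion k+1
            pi[t, k - 1] = s ** (k - t - 1) * (1.0 - s) * r
        pi[t, T - 1] = 1.0 - pi[t, : T - 1].sum()
    return pi


def multistate_cell_probs(omega: np.ndarray, gamma: np.ndarray, T: int):
    """Multistate m-array cell probabilities by alternating transition and
    (non-)detection matrix products.

    Returns ``(tau, tau_never)`` with ``tau[t, j, k, i]`` the probability
    that an individual released at occasion t+1 in observable state j
    (0 alive, 1 dead) is first re-encountered at occasion k+2 in state i,
    and ``tau_never`` the per-release complement.
    """
    if T < 2:
        raise ValidationError("need at least two occasions")
    omega = np.asarray(omega, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    _check_stochastic(omega)
    if not np.allclose(gamma, np.diag(np.diag(gamma))):
        raise ValidationError("detection matrix must be diagonal")
    if ((np.diag(gamma) < 0) | (np.diag(gamma) > 1)).any():
        raise ValidationError("detection probabilities outside [0, 1]")
    eye = np.eye(3)
    tau = np.zeros((T - 1, 2, T - 1, 2))
    tau_never = np.zeros((T - 1, 2))
    # with time-constant parameters a cell depends only on the lag, so the
    # alternating transition/non-detection products are computed once
    cells = []
    A = omega
    for _ in range(T - 1):
        cells.append((A @ gamma)[:2, :2])
        A = A @ (eye - gamma) @ omega
    for t in range(T - 1):
        for k in range(t, T - 1):
            tau[t, :, k, :] = cells[k - t]
        tau_never[t, :] = 1.0 - tau[t].sum(axis=(1, 2))
    return tau, tau_never


# ---------------------------------------------------------------------------
# multinomial likelihood
# ---------------------------------------------------------------------------


def _xlogy_sum(counts: np.ndarray, probs: np.ndarray) -> float:
    counts = counts.ravel()
    probs = probs.ravel()
    pos = counts > 0
    if (probs[pos] <= 0).any():
        return -np.inf
    return float(np.sum(counts[pos] * np.log(probs[pos])))


def multinomial_loglik(marray: Union[MArray, MultistateMArray], cellprobs) -> float:
    """Multinomial kernel log-likelihood of an m-array.

    The multinomial coefficient (constant in the parameters) is dropped.
    A positive count in a zero-probability cell yields ``-inf``.
    """
    if isinstance(marray, MArray):
        pi = np.asarray(cellprobs, dtype=float)
        if pi.shape != marray.m.shape:
            raise ValidationError("cell-probability shape mismatch")
        return _xlogy_sum(marray.m, pi)
    if isinstance(marray, MultistateMArray):
        tau, tau_never = cellprobs
        if np.shape(tau) != marray.n.shape:
            raise ValidationError("cell-probability shape mismatch")
        out = _xlogy_sum(marray.n, np.asarray(tau, dtype=float))
        out += _xlogy_sum(marray.never, np.asarray(tau_never, dtype=float))
        return out
    raise ValidationError("expected an MArray or MultistateMArray")


# ---------------------------------------------------------------------------
# forward recursions
# ---------------------------------------------------------------------------


def _unpack(data, expected: tuple):
    """Return (histories, weights) from a matrix or pooled histories."""
    if isinstance(data, PooledHistories):
        hist, w = data.histories, data.freq.astype(float)
    elif isinstance(data, CaptureHistoryMatrix):
        hist, w = data, np.ones(data.n_individuals)
    else:
        raise ValidationError("expected a CaptureHistoryMatrix or PooledHistories")
    if hist.encoding not in expected:
        raise EncodingError(
            f"encoding {hist.encoding.value} not accepted here; "
            f"expected one of {[e.value for e in expected]}"
        )
    return hist, w


def _forward_two_state(
    live: np.ndarray,
    dead: np.ndarray,
    f: np.ndarray,
    s: float,
    r: float,
    p: float,
    weights: np.ndarray,
) -> float:
    """Two-component filter over {alive, death-already-accounted}.

    The second component carries the mass of all death times whose
    recovery/non-recovery outcome has already been absorbed into the
    likelihood, which is equivalent to (and regression-tested against) the
    literal 3-state algebra.
    """
    logl = _kernels.forward_two_state(
        np.ascontiguousarray(live),
        np.ascontiguousarray(dead),
        np.ascontiguousarray(f - 1),
        float(s),
        float(r),
        float(p),
    )
    return float(np.dot(weights, logl))


def forward_loglik_single_dr(params: ParamSet, data) -> float:
    """Marginal log-likelihood of dead-recovery histories under the
    single-state model, summed (frequency-weighted if pooled)."""
    hist, w = _unpack(data, (Encoding.DR_BINARY,))
    occ = np.arange(1, hist.n_occasions + 1)[None, :]
    marking = occ == hist.f[:, None]
    dead = ((hist.codes == 1) & ~marking).astype(np.int64)
    live = np.zeros_like(dead)
    return _forward_two_state(live, dead, hist.f, params.s, params.r, 0.0, w)


def forward_loglik_single_joint(params: ParamSet, data) -> float:
    """Marginal log-likelihood of joint data via the split binary layers.

    Accepts a ``BinarySplitPair``, a JOINT-coded matrix (split
    internally), or pooled JOINT histories.  The known-alive segment
    (marking to last live encounter) and known-dead segment (from the
    recovery onward) are enforced by the filter itself: live encounters
    zero the dead component and recoveries zero the live component.
    """
    if params.p is None:
        raise ValidationError("joint likelihood requires p")
    if isinstance(data, BinarySplitPair):
        live, dead, f = data.live, data.dead, data.f
        w = np.ones(live.shape[0])
        occ = np.arange(1, live.shape[1] + 1)[None, :]
        if (live[occ == f[:, None]] != 1).any():
            raise ValidationError("split layers inconsistent with f")
        live = live * (occ > f[:, None])  # marking is not a Bernoulli trial
    else:
        hist, w = _unpack(data, (Encoding.JOINT,))
        pair = split_joint(hist)
        occ = np.arange(1, hist.n_occasions + 1)[None, :]
        live = pair.live * (occ > pair.f[:, None])
        dead, f = pair.dead, pair.f
    return _forward_two_state(live, dead, f, params.s, params.r, params.p, w)


def forward_loglik_multistate(omega: np.ndarray, theta: np.ndarray, data) -> float:
    """Generic 3-state HMM forward log-likelihood over multistate-coded
    histories (codes 1/2/3), seeded in the alive state at marking."""
    hist, w = _unpack(data, (Encoding.DR_MULTISTATE, Encoding.JOINT_MULTISTATE))
    omega = np.asarray(omega, dtype=float)
    theta = np.asarray(theta, dtype=float)
    _check_stochastic(omega)
    _check_stochastic(theta)
    logl = _kernels.forward_multistate(
        np.ascontiguousarray(hist.codes),
        np.ascontiguousarray(hist.f - 1),
        np.ascontiguousarray(omega),
        np.ascontiguousarray(theta),
    )
    return float(np.dot(w, logl))
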