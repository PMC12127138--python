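"""Generative model for dead-recovery and joint live-encounter data.

Individuals are marked in per-occasion cohorts and released.  Survival
from one occasion to the next is Bernoulli(s).  An individual that dies in
the interval (t, t+1] may be found and reported dead at t+1 with
probability r (recovery happens only in the interval of death, and at most
once).  In the joint design a living marked individual is additionally
re-encountered alive at each occasion after marking with probability p.

The default study design is 8 occasions with 100 newly marked individuals
on each occasion except the last (700 individuals in total), with the
generating parameters drawn per dataset from s ~ U(0.1, 0.9),
r ~ U(0.05, 0.4), and (joint data) p ~ U(0.1, 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .capture_data import CaptureHistoryMatrix, Encoding
from .errors import ValidationError

__all__ = [
    "ParamSet",
    "StudyDesign",
    "DEFAULT_DESIGN",
    "draw_parameters",
    "simulate_dr",
    "simulate_joint",
    "simulate_default_dataset",
]


@dataclass(frozen=True)
class ParamSet:
    """Time-constant model parameters (Seber parameterization).

    s : probability of surviving an inter-occasion interval
    r : probability that an individual dying in an interval is recovered
    p : probability of re-encountering a living marked individual at an
        occasion (``None`` for dead-recovery-only data)
    """

    s: float
    r: float
    p: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("s", "r", "p"):
            v = getattr(self, name)
            if v is None:
                continue
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")

    def as_dict(self) -> dict:
        d = {"s": self.s, "r": self.r}
        if self.p is not None:
            d["p"] = self.p
        return d


def _check_range(name: str, rng_pair: Sequence[float]) -> Tuple[float, float]:
    lo, hi = float(rng_pair[0]), float(rng_pair[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValidationError(f"{name} range ({lo}, {hi}) invalid")
    return lo, hi


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: occasions, release cohorts, and parameter ranges."""

    T: int = 8
    releases: Tuple[int, ...] = (100, 100, 100, 100, 100, 100, 100, 0)
    s_range: Tuple[float, float] = (0.1, 0.9)
    r_range: Tuple[float, float] = (0.05, 0.4)
    p_range: Tuple[float, float] = (0.1, 0.9)

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValidationError("need at least two occasions")
        if len(self.releases) != self.T:
            raise ValidationError("one release count per occasion required")
        if any(n < 0 for n in self.releases):
            raise ValidationError("negative release count")
        _check_range("s", self.s_range)
        _check_range("r", self.r_range)
        _check_range("p", self.p_range)

    @property
    def n_individuals(self) -> int:
        return int(sum(self.releases))

    def first_captures(self) -> np.ndarray:
        """0-based marking occasion per individual."""
        return np.repeat(np.arange(self.T), self.releases)


DEFAULT_DESIGN = StudyDesign()


def draw_parameters(
    design: StudyDesign, rng: np.random.Generator, joint: bool = False
) -> ParamSet:
    """Draw a generating parameter set uniformly from the design ranges."""
    s = rng.uniform(*design.s_range)
    r = rng.uniform(*design.r_range)
    p = rng.uniform(*design.p_range) if joint else None
    return ParamSet(s=s, r=r, p=p)


def _simulate_core(
    params: ParamSet, design: StudyDesign, rng: np.random.Generator, joint: bool
):
    """Latent survival first, then the observation layers.

    The draw order (survival uniforms, then recovery uniforms, then live
    uniforms) is fixed so that dead-recovery and joint simulations with a
    shared generator state produce coupled latent processes.
    """
    T = design.T
    f0 = design.first_captures()
    n = f0.size
    u_surv = rng.random((n, T))
    u_rec = rng.random((n, T))
    alive = np.zeros((n, T), dtype=bool)
    alive[np.arange(n), f0] = True
    for t in range(1, T):
        started = f0 < t
        alive[:, t] |= alive[:, t - 1] & (u_surv[:, t] < params.s) & started
    # death occasion (0-based): first occasion at which the individual is dead
    dead_after = (~alive) & (np.arange(T)[None, :] > f0[:, None])
    death_occ = np.where(dead_after.any(axis=1), dead_after.argmax(axis=1), -1)
    died = death_occ >= 0
    recovered = died & (u_rec[np.arange(n), np.maximum(death_occ, 0)] < params.r)

    codes = np.zeros((n, T), dtype=np.int64)
    codes[np.arange(n), f0] = 1
    if joint:
        if params.p is None:
            raise ValidationError("joint simulation requires p")
        u_live = rng.random((n, T))
        seen = alive & (np.arange(T)[None, :] > f0[:, None]) & (u_live < params.p)
        codes[seen] = 1
        codes[recovered, death_occ[recovered]] = 2
        return CaptureHistoryMatrix(codes=codes, encoding=Encoding.JOINT, f=f0 + 1)
    codes[recovered, death_occ[recovered]] = 1
    return CaptureHistoryMatrix(codes=codes, encoding=Encoding.DR_BINARY, f=f0 + 1)


def simulate_dr(
    params: ParamSet, design: StudyDesign, rng: np.random.Generator
) -> CaptureHistoryMatrix:
    """Simulate dead-recovery-only capture histories (DR_BINARY)."""
    return _simulate_core(params, design, rng, joint=False)


def simulate_joint(
    params: ParamSet, design: StudyDesign, rng: np.random.Generator
) -> CaptureHistoryMatrix:
    """Simulate joint live-encounter / dead-recovery histories (JOINT)."""
    return _simulate_core(params, design, rng, joint=True)


def simulate_default_dataset(
    rng: np.random.Generator,
    joint: bool = False,
    params: Optional[ParamSet] = None,
    design: StudyDesign = DEFAULT_DESIGN,
) -> Tuple[CaptureHistoryMatrix, ParamSet]:
    """One dataset under the default design; parameters drawn if not given."""
    if params is None:
        params = draw_parameters(design, rng, joint=joint)
    sim = simulate_joint if joint else simulate_dr
    return sim(params, design, rng), params
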