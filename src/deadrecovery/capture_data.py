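"""Capture-history containers, encodings, recoding, m-arrays, and pooling.

A capture history records, per individual and sampling occasion, whether the
individual was newly marked, re-encountered alive, recovered dead, or not
encountered.  Five integer encodings of the same information are used by the
different model families:

``DR_BINARY`` (y)
    Dead-recovery data: 1 at marking and (if it occurs) at the dead
    recovery, 0 otherwise.
``DR_MULTISTATE`` (v)
    Dead-recovery data for multistate models: 1 marked, 2 recovered dead,
    3 not encountered.
``JOINT`` (y')
    Joint live-encounter / dead-recovery data: 1 seen alive (incl. the
    marking occasion), 2 recovered dead, 0 not encountered.
``JOINT_MULTISTATE`` (v')
    As ``JOINT`` but with 3 in place of 0.
``MULTISTATE_ZERO`` (w, wI)
    As the multistate encodings but with 0 in place of 3; the input format
    for multistate m-array construction.

Occasions are 1-based in the user-facing model (``f``, m-array release
rows); array indexing inside the package is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import EncodingError, ValidationError

__all__ = [
    "Encoding",
    "CaptureHistoryMatrix",
    "BinarySplitPair",
    "MArray",
    "MultistateMArray",
    "PooledHistories",
    "recode",
    "split_joint",
    "join_split",
    "build_marray",
    "build_multistate_marray",
    "pool",
]


class Encoding(str, Enum):
    DR_BINARY = "dr_binary"
    DR_MULTISTATE = "dr_multistate"
    JOINT = "joint"
    JOINT_MULTISTATE = "joint_multistate"
    MULTISTATE_ZERO = "multistate_zero"


#: code used for "not encountered", per encoding
_NOT_ENCOUNTERED = {
    Encoding.DR_BINARY: 0,
    Encoding.DR_MULTISTATE: 3,
    Encoding.JOINT: 0,
    Encoding.JOINT_MULTISTATE: 3,
    Encoding.MULTISTATE_ZERO: 0,
}

_ALPHABET = {
    Encoding.DR_BINARY: {0, 1},
    Encoding.DR_MULTISTATE: {1, 2, 3},
    Encoding.JOINT: {0, 1, 2},
    Encoding.JOINT_MULTISTATE: {1, 2, 3},
    Encoding.MULTISTATE_ZERO: {0, 1, 2},
}

#: code for a dead recovery, per encoding
_DEAD_CODE = {
    Encoding.DR_BINARY: 1,  # positional: a 1 after the marking occasion
    Encoding.DR_MULTISTATE: 2,
    Encoding.JOINT: 2,
    Encoding.JOINT_MULTISTATE: 2,
    Encoding.MULTISTATE_ZERO: 2,
}


@dataclass(eq=False)
class CaptureHistoryMatrix:
    """Individuals x occasions integer codes plus first-capture vector.

    Parameters
    ----------
    codes
        Integer matrix, one row per individual, one column per occasion.
    encoding
        Which of the five encodings ``codes`` uses.
    f
        1-based occasion of first capture (marking) per individual.
        Derived from ``codes`` by :meth:`from_codes`.
    """

    codes: np.ndarray
    encoding: Encoding
    f: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.f = np.asarray(self.f, dtype=np.int64)
        self.encoding = Encoding(self.encoding)
        self.validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_codes(cls, codes, encoding) -> "CaptureHistoryMatrix":
        """Build a matrix from raw codes, deriving ``f`` per row."""
        codes = np.atleast_2d(np.asarray(codes, dtype=np.int64))
        encoding = Encoding(encoding)
        ne = _NOT_ENCOUNTERED[encoding]
        observed = codes != ne
        if not observed.any(axis=1).all():
            bad = int(np.flatnonzero(~observed.any(axis=1))[0])
            raise ValidationError(f"row {bad} has no release entry")
        f = observed.argmax(axis=1) + 1
        return cls(codes=codes, encoding=encoding, f=f)

    # -- properties --------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.codes.shape[1]

    # -- derived per-row summaries ----------------------------------------
    def recovery_occasions(self) -> np.ndarray:
        """1-based occasion of the dead recovery per row, 0 if none."""
        enc = self.encoding
        if enc is Encoding.DR_BINARY:
            hit = (self.codes == 1) & (
                np.arange(1, self.n_occasions + 1)[None, :] != self.f[:, None]
            )
        else:
            hit = self.codes == 2
        occ = np.where(hit.any(axis=1), hit.argmax(axis=1) + 1, 0)
        return occ.astype(np.int64)

    def last_live_occasions(self) -> np.ndarray:
        """1-based last occasion each individual was seen alive.

        The marking occasion counts as a live observation; dead recoveries
        do not.  This is the "known alive until" auxiliary used by the
        marginalized joint likelihood.
        """
        live_code = 1
        occs = np.arange(1, self.n_occasions + 1)[None, :]
        if self.encoding is Encoding.DR_BINARY:
            live = occs == self.f[:, None]
        else:
            live = self.codes == live_code
        rev = live[:, ::-1]
        last = self.n_occasions - rev.argmax(axis=1)
        return np.where(live.any(axis=1), last, self.f).astype(np.int64)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        codes, enc, f = self.codes, self.encoding, self.f
        if codes.ndim != 2:
            raise ValidationError("codes must be a 2-D matrix")
        n, T = codes.shape
        if f.shape != (n,):
            raise ValidationError("f must have one entry per individual")
        if (f < 1).any() or (f > T).any():
            raise ValidationError("f out of range 1..T")
        alphabet = _ALPHABET[enc]
        bad = ~np.isin(codes, list(alphabet))
        if bad.any():
            i, t = np.argwhere(bad)[0]
            raise ValidationError(
                f"code {codes[i, t]} at row {i}, occasion {t + 1} not in "
                f"alphabet {sorted(alphabet)} of encoding {enc.value}"
            )
        ne = _NOT_ENCOUNTERED[enc]
        occs = np.arange(1, T + 1)[None, :]
        before = occs < f[:, None]
        if (codes[before] != ne).any():
            raise ValidationError("encounter before first capture")
        # release entry present
        release = codes[np.arange(n), f - 1]
        if (release != 1).any():
            raise ValidationError("release occasion must carry code 1")
        # dead recoveries: at most one, nothing observed afterwards
        rec = self.recovery_occasions()
        if enc is Encoding.DR_BINARY:
            extra = (codes == 1).sum(axis=1)
            if (extra > 2).any():
                raise ValidationError("more than one recovery in a row")
        elif enc is Encoding.DR_MULTISTATE:
            if ((codes == 1).sum(axis=1) != 1).any():
                raise ValidationError(
                    "dead-recovery multistate rows carry exactly one marking"
                )
            if ((codes == 2).sum(axis=1) > 1).any():
                raise ValidationError("more than one dead recovery in a row")
        else:
            if ((codes == 2).sum(axis=1) > 1).any():
                raise ValidationError("more than one dead recovery in a row")
        after_rec = (occs > rec[:, None]) & (rec[:, None] > 0)
        if (codes[after_rec] != ne).any():
            raise ValidationError("encounter after a dead recovery")
        if ((rec > 0) & (rec <= f)).any():
            raise ValidationError("dead recovery at or before release")


@dataclass(eq=False)
class BinarySplitPair:
    """Joint histories split into binary live-encounter and dead-recovery
    layers, one Bernoulli observation model per layer."""

    live: np.ndarray
    dead: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        self.live = np.asarray(self.live, dtype=np.int64)
        self.dead = np.asarray(self.dead, dtype=np.int64)
        self.f = np.asarray(self.f, dtype=np.int64)
        if self.live.shape != self.dead.shape:
            raise ValidationError("live and dead layers must share a shape")
        if ((self.live + self.dead) > 1).any():
            raise ValidationError("live and dead encounters overlap")


@dataclass(eq=False)
class MArray:
    """Single-state m-array: releases by occasion of first (and only)
    dead recovery, plus a never-recovered column.

    ``m`` has T-1 release rows; columns are recovery occasions 2..T
    followed by the never column.  ``R`` holds release totals.
    """

    m: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=np.int64)
        self.R = np.asarray(self.R, dtype=np.int64)
        self.validate()

    @property
    def n_occasions(self) -> int:
        return self.m.shape[0] + 1

    def validate(self) -> None:
        if (self.m < 0).any():
            raise ValidationError("negative m-array count")
        if not np.array_equal(self.m.sum(axis=1), self.R):
            raise ValidationError("m-array rows must sum to release totals")
        # upper-triangular: no recovery at or before release
        T = self.n_occasions
        for t in range(T - 1):
            if self.m[t, : t].any():
                raise ValidationError("recovery at or before release")


@dataclass(eq=False)
class MultistateMArray:
    """Multistate m-array with live re-releases.

    ``n[t, j, k, i]`` counts individuals released at occasion ``t+1`` in
    state ``j`` (0 alive, 1 dead) first re-encountered at occasion ``k+2``
    in state ``i``; ``never[t, j]`` is the never-re-encountered cell and
    ``R[t, j]`` the release totals.  A live re-encounter re-releases the
    individual; a dead recovery is terminal.
    """

    n: np.ndarray
    never: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=np.int64)
        self.never = np.asarray(self.never, dtype=np.int64)
        self.R = np.asarray(self.R, dtype=np.int64)
        self.validate()

    @property
    def n_occasions(self) -> int:
        return self.n.shape[0] + 1

    def validate(self) -> None:
        if (self.n < 0).any() or (self.never < 0).any():
            raise ValidationError("negative multistate m-array count")
        tot = self.n.sum(axis=(2, 3)) + self.never
        if not np.array_equal(tot, self.R):
            raise ValidationError("counts plus never-cell must equal releases")
        T = self.n_occasions
        for t in range(T - 1):
            if self.n[t, :, : t, :].any():
                raise ValidationError("re-encounter at or before release")


@dataclass(eq=False)
class PooledHistories:
    """Unique capture-history rows with multiplicities.

    Pooling keys on the full coded row, so two rows pool together only if
    they agree on every occasion (and therefore on the derived
    known-alive-until / known-dead-from auxiliaries as well).
    """

    histories: CaptureHistoryMatrix
    freq: np.ndarray
    known_alive_until: np.ndarray = field(default=None)
    known_dead_from: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=np.int64)
        if self.freq.shape[0] != self.histories.n_individuals:
            raise ValidationError("one frequency per unique row required")
        if (self.freq < 1).any():
            raise ValidationError("frequencies must be positive")
        if self.known_alive_until is None:
            self.known_alive_until = self.histories.last_live_occasions()
        if self.known_dead_from is None:
            self.known_dead_from = self.histories.recovery_occasions()

    @property
    def n_total(self) -> int:
        return int(self.freq.sum())

    def expand(self) -> CaptureHistoryMatrix:
        """Reconstruct the unpooled multiset of rows (row order is the
        lexicographic order of the unique rows)."""
        codes = np.repeat(self.histories.codes, self.freq, axis=0)
        return CaptureHistoryMatrix.from_codes(codes, self.histories.encoding)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

#: recoding paths defined for this data model (and their inverses)
_RECODE_PATHS = {
    (Encoding.DR_BINARY, Encoding.DR_MULTISTATE),
    (Encoding.DR_MULTISTATE, Encoding.DR_BINARY),
    (Encoding.DR_MULTISTATE, Encoding.MULTISTATE_ZERO),
    (Encoding.MULTISTATE_ZERO, Encoding.DR_MULTISTATE),
    (Encoding.JOINT, Encoding.JOINT_MULTISTATE),
    (Encoding.JOINT_MULTISTATE, Encoding.JOINT),
    (Encoding.JOINT_MULTISTATE, Encoding.MULTISTATE_ZERO),
    (Encoding.MULTISTATE_ZERO, Encoding.JOINT_MULTISTATE),
}


def recode(histories: CaptureHistoryMatrix, target) -> CaptureHistoryMatrix:
    """Recode a capture-history matrix into another encoding.

    Only the pairs defined by the data model are accepted; every recode is
    a cellwise bijection (given the first-capture vector), so round trips
    are exact.
    """
    target = Encoding(target)
    source = histories.encoding
    if source is target:
        return CaptureHistoryMatrix(
            codes=histories.codes.copy(), encoding=source, f=histories.f.copy()
        )
    if (source, target) not in _RECODE_PATHS:
        raise EncodingError(f"no recoding defined from {source.value} to {target.value}")
    codes = histories.codes
    n, T = codes.shape
    occ_is_f = np.arange(1, T + 1)[None, :] == histories.f[:, None]
    if (source, target) == (Encoding.DR_BINARY, Encoding.DR_MULTISTATE):
        out = np.full_like(codes, 3)
        out[occ_is_f] = 1
        out[(codes == 1) & ~occ_is_f] = 2
    elif (source, target) == (Encoding.DR_MULTISTATE, Encoding.DR_BINARY):
        out = np.zeros_like(codes)
        out[codes == 1] = 1
        out[codes == 2] = 1
    else:
        # remaining paths only swap the "not encountered" code (0 <-> 3)
        src_ne = _NOT_ENCOUNTERED[source]
        tgt_ne = _NOT_ENCOUNTERED[target]
        out = np.where(codes == src_ne, tgt_ne, codes)
    return CaptureHistoryMatrix(codes=out, encoding=target, f=histories.f.copy())


def split_joint(histories: CaptureHistoryMatrix) -> BinarySplitPair:
    """Split joint histories into binary live and dead layers."""
    if histories.encoding is not Encoding.JOINT:
        raise EncodingError("split_joint requires the JOINT encoding")
    return BinarySplitPair(
        live=(histories.codes == 1).astype(np.int64),
        dead=(histories.codes == 2).astype(np.int64),
        f=histories.f.copy(),
    )


def join_split(pair: BinarySplitPair) -> CaptureHistoryMatrix:
    """Inverse of :func:`split_joint`."""
    codes = pair.live + 2 * pair.dead
    return CaptureHistoryMatrix.from_codes(codes, Encoding.JOINT)


def build_marray(histories: CaptureHistoryMatrix) -> MArray:
    """Summarize dead-recovery histories into the single-state m-array.

    Individuals marked on the final occasion cannot be re-encountered and
    contribute no m-array row.
    """
    if histories.encoding is not Encoding.DR_BINARY:
        raise EncodingError("build_marray requires the DR_BINARY encoding")
    T = histories.n_occasions
    m = np.zeros((T - 1, T), dtype=np.int64)
    rec = histories.recovery_occasions()
    f = histories.f
    for fi, ki in zip(f, rec):
        if fi >= T:
            continue
        if ki > 0:
            m[fi - 1, ki - 2] += 1
        else:
            m[fi - 1, T - 1] += 1
    R = m.sum(axis=1)
    return MArray(m=m, R=R)


def build_multistate_marray(histories: CaptureHistoryMatrix) -> MultistateMArray:
    """Summarize multistate (0-coded) histories into a multistate m-array.

    Each live re-encounter before the final occasion re-releases the
    individual in the alive state; a dead recovery is terminal.  Releases
    on the final occasion open no new m-array row.
    """
    if histories.encoding is not Encoding.MULTISTATE_ZERO:
        raise EncodingError("build_multistate_marray requires MULTISTATE_ZERO")
    T = histories.n_occasions
    n = np.zeros((T - 1, 2, T - 1, 2), dtype=np.int64)
    never = np.zeros((T - 1, 2), dtype=np.int64)
    R = np.zeros((T - 1, 2), dtype=np.int64)
    for row, fi in zip(histories.codes, histories.f):
        t = int(fi)  # current release occasion (1-based), state alive
        if t >= T:
            continue
        R[t - 1, 0] += 1
        open_release = True
        for k in range(t + 1, T + 1):
            c = row[k - 1]
            if c == 0:
                continue
            state = 0 if c == 1 else 1
            n[t - 1, 0, k - 2, state] += 1
            open_release = False
            if c == 2:
                break  # dead recovery is terminal
            if k < T:  # live re-encounter: re-release
                t = k
                R[t - 1, 0] += 1
                open_release = True
            else:
                break
        if open_release:
            never[t - 1, 0] += 1
    return MultistateMArray(n=n, never=never, R=R)


def pool(histories: CaptureHistoryMatrix) -> PooledHistories:
    """Collapse to unique capture-history rows with frequencies."""
    codes, freq = np.unique(histories.codes, axis=0, return_counts=True)
    unique = CaptureHistoryMatrix.from_codes(codes, histories.encoding)
    return PooledHistories(histories=unique, freq=freq)
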