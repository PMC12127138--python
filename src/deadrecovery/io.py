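"""File formats: capture-history CSV, m-array CSV, fit results, fixtures.

Capture-history files are plain CSV with one row per individual and
columns ``occ1..occT``, preceded by a metadata line ``# encoding=<name>``
so that files declare their own encoding instead of it being guessed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .capture_data import CaptureHistoryMatrix, Encoding, MArray
from .errors import ValidationError
from .samplers import MCMCResult
from .simulator import ParamSet, StudyDesign, simulate_dr, simulate_joint

__all__ = [
    "read_histories",
    "write_histories",
    "write_marray",
    "write_results",
    "read_results",
    "make_fixtures",
    "FIXTURE_SEED",
]


def _parse_encoding(token: str) -> Encoding:
    token = token.strip().lower()
    for enc in Encoding:
        if token in (enc.value, enc.name.lower()):
            return enc
    raise ValidationError(f"unknown encoding {token!r}")


def write_histories(path, histories: CaptureHistoryMatrix) -> None:
    path = Path(path)
    T = histories.n_occasions
    header = ",".join(f"occ{t}" for t in range(1, T + 1))
    lines = [f"# encoding={histories.encoding.value}", header]
    lines += [",".join(map(str, row)) for row in histories.codes]
    path.write_text("\n".join(lines) + "\n")


def read_histories(path, encoding: Optional[str] = None) -> CaptureHistoryMatrix:
    """Read a capture-history CSV; the encoding comes from the file's
    metadata line unless explicitly declared (which then must match)."""
    path = Path(path)
    declared = _parse_encoding(encoding) if encoding is not None else None
    file_enc = None
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#"):
        body = first.lstrip("# ").strip()
        if "=" in body:
            key, _, val = body.partition("=")
        else:
            key, _, val = body.partition(":")
        if key.strip().lower() == "encoding":
            file_enc = _parse_encoding(val)
    if file_enc is None and declared is None:
        raise ValidationError(
            f"{path}: no encoding metadata line and none declared"
        )
    if file_enc is not None and declared is not None and file_enc is not declared:
        raise ValidationError(
            f"{path}: declared encoding {declared.value} contradicts "
            f"file metadata {file_enc.value}"
        )
    enc = declared or file_enc
    df = pd.read_csv(path, comment="#")
    expected = [f"occ{t}" for t in range(1, len(df.columns) + 1)]
    if list(df.columns) != expected:
        raise ValidationError(f"{path}: columns must be occ1..occT")
    codes = df.to_numpy(dtype=np.int64)
    try:
        return CaptureHistoryMatrix.from_codes(codes, enc)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_marray(path, marray: MArray) -> None:
    T = marray.n_occasions
    cols = [f"rec{t}" for t in range(2, T + 1)] + ["never"]
    df = pd.DataFrame(marray.m, columns=cols)
    df.insert(0, "release_occ", np.arange(1, T))
    df["R"] = marray.R
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------


def write_results(result: MCMCResult, prefix) -> Tuple[Path, Path]:
    """Write a fit as ``<prefix>_summary.json`` + ``<prefix>_draws.csv``.

    The draws CSV schema is: ``chain`` (0-based), ``draw`` (0-based,
    post burn-in), then one column per parameter in registry order.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    names = list(result.draws)
    chains, kept = result.draws[names[0]].shape
    frame = {
        "chain": np.repeat(np.arange(chains), kept),
        "draw": np.tile(np.arange(kept), chains),
    }
    for nm in names:
        frame[nm] = result.draws[nm].reshape(-1)
    draws_path = prefix.with_name(prefix.name + "_draws.csv")
    pd.DataFrame(frame).to_csv(draws_path, index=False)

    cfg = asdict(result.config)
    if isinstance(cfg["seed"], np.random.SeedSequence):
        cfg["seed"] = cfg["seed"].entropy
    summary = {
        "model": result.model_id,
        "config": cfg,
        "converged": result.summary.converged,
        "n_trapped_sites": result.n_trapped,
        "seconds": result.seconds,
        "parameters": {
            name: {k: float(v) for k, v in row.items()}
            for name, row in result.summary.table.iterrows()
        },
    }
    summary_path = prefix.with_name(prefix.name + "_summary.json")
    summary_path.write_text(json.dumps(summary, indent=2))
    return summary_path, draws_path


def read_results(prefix) -> dict:
    prefix = Path(prefix)
    summary = json.loads(prefix.with_name(prefix.name + "_summary.json").read_text())
    draws = pd.read_csv(prefix.with_name(prefix.name + "_draws.csv"))
    return {"summary": summary, "draws": draws}


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

FIXTURE_SEED = 20250930
_FIXTURE_DESIGN = StudyDesign(
    T=4,
    releases=(10, 10, 10, 0),
    s_range=(0.6, 0.6),
    r_range=(0.3, 0.3),
    p_range=(0.5, 0.5),
)


def make_fixtures(seed: int = FIXTURE_SEED) -> Dict[str, tuple]:
    """Small deterministic datasets with known truth, for tests and docs.

    Returns ``{"dr": (histories, params), "joint": (histories, params)}``
    with 30 individuals over 4 occasions, s=0.6, r=0.3 (p=0.5 joint).
    """
    rng = np.random.default_rng(seed)
    dr_params = ParamSet(s=0.6, r=0.3)
    joint_params = ParamSet(s=0.6, r=0.3, p=0.5)
    dr = simulate_dr(dr_params, _FIXTURE_DESIGN, rng)
    joint = simulate_joint(joint_params, _FIXTURE_DESIGN, rng)
    return {"dr": (dr, dr_params), "joint": (joint, joint_params)}
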