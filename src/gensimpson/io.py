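"""Reading abundance tables and writing profile tables.

The input format is a minimal two-column table (species label, integer
count), TSV or CSV, with an optional header.  A wide table (species x
community) loader is provided for two-plot comparisons.  Profiles are
written as TSV or JSON with a fixed schema that round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .comparison import DifferenceProfile
from .errors import AbundanceParseError
from .estimation import Profile, SampleCounts

logger = logging.getLogger("gensimpson")


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise AbundanceParseError(f"unknown format {fmt!r}; use 'tsv' or 'csv'")
    return "," if fmt == "csv" else "\t"


def _has_header(first_line: str, sep: str) -> bool:
    fields = first_line.rstrip("\n").split(sep)
    if len(fields) < 2:
        return False
    try:
        float(fields[1])
    except ValueError:
        return True
    return False


def read_abundances(path, fmt: str | None = None) -> SampleCounts:
    """Load a two-column (species, count) table into SampleCounts.

    Zero-count rows are dropped with a logged notice; negative or
    non-integer counts and duplicate labels are errors.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    with open(path) as fh:
        first = fh.readline()
    header = 0 if _has_header(first, sep) else None
    df = pd.read_csv(path, sep=sep, header=header, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise AbundanceParseError(f"{path}: expected two columns, found {df.shape[1]}")
    labels = df.iloc[:, 0].astype(str).str.strip()
    if labels.duplicated().any():
        dups = labels[labels.duplicated()].tolist()
        raise AbundanceParseError(f"{path}: duplicate species labels {dups}")
    counts = np.empty(len(df), dtype=np.int64)
    for i, raw in enumerate(df.iloc[:, 1]):
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise AbundanceParseError(
                f"{path}: row {i + 1} ({labels.iloc[i]!r}): count {raw!r} is not a number"
            ) from None
        if val != int(val):
            raise AbundanceParseError(
                f"{path}: row {i + 1} ({labels.iloc[i]!r}): count {raw!r} is not an integer"
            )
        if val < 0:
            raise AbundanceParseError(
                f"{path}: row {i + 1} ({labels.iloc[i]!r}): negative count {raw!r}"
            )
        counts[i] = int(val)
    keep = counts > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d zero-count rows", path, n_dropped)
    if not keep.any():
        raise AbundanceParseError(f"{path}: no positive counts")
    return SampleCounts(counts[keep], labels=tuple(labels[keep]))


def read_community_table(path, fmt: str | None = None) -> dict[str, SampleCounts]:
    """Load a wide table (first column: species; remaining columns: one
    community each) into a dict of SampleCounts keyed by column name."""
    path = Path(path)
    sep = _sep_for(path, fmt)
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    out = {}
    for col in df.columns:
        counts = df[col].to_numpy()
        if np.any(counts < 0) or np.any(counts != np.floor(counts)):
            raise AbundanceParseError(f"{path}: column {col!r} has invalid counts")
        counts = counts.astype(np.int64)
        keep = counts > 0
        if (~keep).any():
            logger.info(
                "%s[%s]: dropped %d zero-count rows", path, col, int((~keep).sum())
            )
        out[str(col)] = SampleCounts(counts[keep], labels=tuple(df.index[keep].astype(str)))
    return out


_COLUMNS = ["r", "estimate", "lower", "upper", "scale", "level"]


def _profile_rows(profile) -> tuple[list[dict], str, float]:
    if isinstance(profile, DifferenceProfile):
        scale, vals = "difference", profile.differences
    elif isinstance(profile, Profile):
        scale, vals = profile.scale, profile.estimates
    else:
        raise TypeError(f"cannot serialize {type(profile).__name__}")
    rows = [
        {
            "r": int(r),
            "estimate": float(e),
            "lower": float(lo),
            "upper": float(hi),
            "scale": scale,
            "level": float(profile.level),
        }
        for r, e, lo, hi in zip(profile.orders, vals, profile.lower, profile.upper)
    ]
    return rows, scale, float(profile.level)


def write_profile(profile, path, fmt: str | None = None) -> None:
    """Write a profile as TSV (columns r, estimate, lower, upper, scale,
    level) or JSON mirroring the same schema."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    rows, scale, level = _profile_rows(profile)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump({"scale": scale, "level": level, "rows": rows}, fh, indent=2)
            fh.write("\n")
    elif fmt == "tsv":
        pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise AbundanceParseError(f"unknown profile format {fmt!r}; use 'tsv' or 'json'")


def read_profile(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a profile file back as a DataFrame with the fixed column schema."""
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        df = pd.DataFrame(payload["rows"], columns=_COLUMNS)
    else:
        df = pd.read_csv(path, sep="\t")
    return df[_COLUMNS].astype(
        {"r": int, "estimate": float, "lower": float, "upper": float, "level": float}
    )
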