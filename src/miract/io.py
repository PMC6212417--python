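"""Readers and writers for the plain-text interchange formats.

All matrices are TSV with the feature ID in the first column and sample IDs
in the header row. Gene sets travel as GMT (name, description, members).
Values are written with 12 significant digits so fixtures round-trip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

FLOAT_FMT = "%.12g"


class InputError(ValueError):
    """A malformed or inconsistent input file."""


def read_matrix(path: str | Path, *, name: str = "matrix") -> pd.DataFrame:
    """Read a feature x sample TSV matrix; strict about duplicates and NaNs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{name}: duplicate feature ID {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise InputError(f"{name}: duplicate sample ID {dup!r} in {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise InputError(f"{name}: non-numeric cell in {path}: {exc}") from exc
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise InputError(f"{name}: missing value at feature {gene!r} in {path}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, *, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT: one set per line — name <TAB> description <TAB> member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise InputError(f"GMT line {lineno} has fewer than 2 fields: {path}")
            name = fields[0]
            if name in sets:
                raise InputError(f"GMT: duplicate set name {name!r} in {path}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, *, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival TSV with columns sample_id, time, event (0/1)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required.issubset(df.columns):
        raise InputError(f"survival table must have columns {sorted(required)}: {path}")
    if df["sample_id"].duplicated().any():
        raise InputError(f"survival table has duplicate sample IDs: {path}")
    if (df["time"] < 0).any():
        raise InputError(f"survival table has negative time: {path}")
    if not df["event"].isin([0, 1]).all():
        raise InputError(f"survival event must be 0/1: {path}")
    return df.set_index("sample_id")[["time", "event"]]


def write_survival(df: pd.DataFrame, path: str | Path) -> None:
    df[["time", "event"]].to_csv(
        path, sep="\t", float_format=FLOAT_FMT, index_label="sample_id"
    )


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = read_matrix(path, name="mutations")
    if not df.isin([0.0, 1.0]).all().all():
        raise InputError(f"mutation table must be binary 0/1: {path}")
    return df.astype(int)


def read_centroids(path: str | Path) -> pd.DataFrame:
    """Centroid TSV: gene, classI, classII, classIII, classIV."""
    df = read_matrix(path, name="centroids")
    if df.shape[1] != 4:
        raise InputError(f"centroid table must have exactly 4 class columns: {path}")
    return df


def read_signature_values(path: str | Path) -> pd.Series:
    """Two-column TSV (gene, value) — e.g. the p53-like signature."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] != 1:
        raise InputError(f"signature table must have exactly 2 columns: {path}")
    if df.index.has_duplicates:
        raise InputError(f"signature table has duplicate genes: {path}")
    return df.iloc[:, 0].astype(float)


def read_config(path: str | Path) -> dict[str, str]:
    """Flat key = value config file; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"config line {lineno} is not key = value: {raw!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: dict[str, Path], out_path: str | Path) -> dict:
    manifest = {
        key: {"path": str(p), "sha256": sha256_of(p)} for key, p in paths.items()
    }
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def check_sample_agreement(*frames: pd.DataFrame) -> None:
    """All frames must share identical, identically ordered sample columns."""
    first = list(frames[0].columns)
    for other in frames[1:]:
        cols = list(other.columns)
        if cols != first:
            bad = None
            for a, b in zip(first, cols):
                if a != b:
                    bad = b
                    break
            if bad is None:  # one is a prefix of the other
                longer = first if len(first) > len(cols) else cols
                bad = longer[min(len(first), len(cols))]
            raise InputError(f"sample IDs disagree across matrices, first offender: {bad!r}")


def zscore_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise z-score; constant rows are dropped and reported."""
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()].tolist()
    kept = df.drop(index=constant)
    z = kept.sub(mu.drop(constant), axis=0).div(sd.drop(constant), axis=0)
    return z, constant


def as_float_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise InputError("non-finite value in numeric input")
    return arr
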