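"""File I/O: sleep-event CSV, genotype/variant TSV, report bundles.

Timestamps are serialized as ISO-8601 local wall-clock time without
timezone offsets: the whole analysis runs in local clock time and the
skipped hour is handled explicitly by the generator and classifier, so
attaching offsets would only invite double conversion.  All writers emit
deterministic bytes (stable column order, fixed float formatting, sorted
JSON keys) so identical inputs give identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import ReportBundle
from .pgs import GenotypeSet, VARIANT_COLUMNS
from .synthetic import EVENT_COLUMNS

__all__ = [
    "SchemaError",
    "read_sleep_events",
    "write_sleep_events",
    "read_genotypes",
    "write_genotypes",
    "write_report",
]

_TS_FORMAT = "%Y-%m-%dT%H:%M:%S"


class SchemaError(ValueError):
    """Input file is missing required columns."""


def read_sleep_events(path, strict: bool = True) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate a sleep-event CSV.

    Required columns: subject_id, start, end, minutes_asleep, minutes_in_bed.
    Rows failing validation (unparseable timestamps, end <= start,
    non-positive or inconsistent minutes) abort in strict mode; in lenient
    mode they are dropped and described in the returned error list, one
    entry per rejected row with its (0-based) data row number.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sleep-event file {path} is missing columns {missing}")
    df = df[EVENT_COLUMNS]

    errors: list[str] = []
    bad = pd.Series(False, index=df.index)
    for col in ("start", "end"):
        parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
        newly = parsed.isna()
        for i in df.index[newly & ~bad]:
            errors.append(f"row {i}: unparseable {col} {df.loc[i, col]!r}")
        bad |= newly
        df[col] = parsed
    for col in ("minutes_asleep", "minutes_in_bed"):
        num = pd.to_numeric(df[col], errors="coerce")
        newly = num.isna()
        for i in df.index[newly & ~bad]:
            errors.append(f"row {i}: non-numeric {col} {df.loc[i, col]!r}")
        bad |= newly
        df[col] = num

    ok = ~bad
    inverted = ok & (df["end"] <= df["start"])
    for i in df.index[inverted]:
        errors.append(f"row {i}: end {df.loc[i, 'end']} not after start "
                      f"{df.loc[i, 'start']}")
    bad |= inverted
    ok = ~bad
    nonpos = ok & ((df["minutes_asleep"] <= 0)
                   | (df["minutes_asleep"] > df["minutes_in_bed"]))
    for i in df.index[nonpos]:
        errors.append(f"row {i}: minutes_asleep must satisfy "
                      "0 < minutes_asleep <= minutes_in_bed")
    bad |= nonpos

    if bad.any() and strict:
        raise ValueError("invalid sleep-event rows:\n" + "\n".join(errors))
    return df[~bad].reset_index(drop=True), errors


def write_sleep_events(events: pd.DataFrame, path) -> None:
    out = events[EVENT_COLUMNS].copy()
    for col in ("start", "end"):
        out[col] = pd.to_datetime(out[col]).dt.strftime(_TS_FORMAT)
    out.to_csv(path, index=False)


def write_genotypes(genotypes: GenotypeSet, dosage_path, variant_path) -> None:
    """Write the dosage matrix (subjects x variants, NA = missing) and the
    variant table as TSV."""
    mat = pd.DataFrame(genotypes.dosages,
                       index=pd.Index(genotypes.subjects, name="subject_id"),
                       columns=genotypes.variants["variant_id"])
    mat.to_csv(dosage_path, sep="\t", na_rep="NA", float_format="%g")
    genotypes.variants.to_csv(variant_path, sep="\t", index=False)


def read_genotypes(dosage_path, variant_path,
                   exclusion_flags: dict[str, list[str]] | None = None) -> GenotypeSet:
    mat = pd.read_csv(dosage_path, sep="\t", index_col="subject_id")
    variants = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise SchemaError(f"variant file {variant_path} is missing columns {missing}")
    if list(mat.columns) != list(variants["variant_id"]):
        raise SchemaError("dosage matrix columns do not match the variant table")
    return GenotypeSet(dosages=mat.to_numpy(dtype=float),
                       variants=variants[VARIANT_COLUMNS],
                       subjects=[str(s) for s in mat.index],
                       exclusion_flags=exclusion_flags or {})


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(bundle: ReportBundle, directory) -> list[Path]:
    """Write a report bundle to ``directory``; returns the written paths.

    Files: counts.tsv, profiles.tsv, shifts.tsv, sjl.tsv, pgs.tsv,
    comparisons.json, config.yaml, run.log — deterministic bytes for a
    given bundle.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []

    def tsv(df: pd.DataFrame, name: str):
        p = directory / name
        df.to_csv(p, sep="\t", index=False, float_format="%.6f")
        paths.append(p)

    tsv(bundle.counts, "counts.tsv")
    tsv(bundle.profiles, "profiles.tsv")
    tsv(bundle.shifts, "shifts.tsv")
    tsv(bundle.sjl_table, "sjl.tsv")
    tsv(bundle.pgs.to_frame(), "pgs.tsv")

    p = directory / "comparisons.json"
    p.write_text(json.dumps(bundle.comparisons, indent=2, sort_keys=True,
                            default=_json_default, allow_nan=True) + "\n")
    paths.append(p)

    p = directory / "config.yaml"
    bundle.config.to_yaml(p)
    paths.append(p)

    p = directory / "run.log"
    p.write_text("\n".join(bundle.log_lines) + "\n")
    paths.append(p)
    return paths
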