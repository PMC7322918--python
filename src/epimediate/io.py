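"""Interchange formats: plain TSV tables shared by every pipeline stage.

Dialect: tab-delimited, UTF-8, Unix newlines, ``.`` for missing values,
floats serialised with 17 significant digits so write -> read -> write is
byte-identical.  Validation failures name the offending file line.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_table", "write_table",
    "read_matrix", "write_matrix",
    "read_ld_matrix", "write_ld_matrix",
    "write_bed", "write_vcf_dosage",
    "sha256sum",
    "SCHEMAS",
]

# fixed headers for the stage tables (column -> pandas dtype)
SCHEMAS = {
    "annotation": {"cpg": str, "chrom": str, "pos": "int64"},
    "ewas": {"cpg": str, "chrom": str, "pos": "int64", "estimate": float,
             "se": float, "p": float, "n": "int64", "status": str},
    "snp_survival": {"snp": str, "effect_allele": str, "loghr": float,
                     "se": float, "p": float, "n_events": "int64",
                     "status": str},
    "dmr": {"chrom": str, "start": "int64", "end": "int64", "n_cpg": "int64",
            "cpgs": str, "estimate": float, "se": float, "p": float,
            "p_adj": float},
    "mqtl": {"snp": str, "cpg": str, "effect_allele": str,
             "other_allele": str, "eaf": float, "beta": float, "se": float,
             "p": float},
    "instrument": {"region": str, "snp": str, "beta_gp": float,
                   "se_gp": float, "tau2": float, "n_cpg": "int64",
                   "cpg_trail": str, "effect_allele": str,
                   "other_allele": str, "eaf": float, "source_cpg": str},
    "mr": {"region": str, "layout": str, "method": str, "n_snp": "int64",
           "beta": float, "se": float, "hr": float, "ci_low": float,
           "ci_high": float, "p": float, "intercept": float,
           "intercept_se": float, "intercept_p": float},
    "phenotypes": None,  # free-form numeric columns keyed by sample
    "truth_regions": None,
    "truth_snps": None,
}


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float) or isinstance(value, np.floating):
        if np.isnan(value):
            return "."
        return "%.17g" % value
    if isinstance(value, (bool, np.bool_)):
        return str(int(value))
    return str(value)


def write_table(df: pd.DataFrame, path, columns: list[str] | None = None) -> Path:
    """Write a stage table in the interchange dialect."""
    path = Path(path)
    cols = list(columns) if columns is not None else list(df.columns)
    lines = ["\t".join(cols)]
    for row in df[cols].itertuples(index=False):
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_table(path, schema: str | dict | None = None) -> pd.DataFrame:
    """Read a stage table, coercing to the schema's dtypes."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False,
                     dtype=str, float_precision="round_trip")
    dtypes = SCHEMAS.get(schema) if isinstance(schema, str) else schema
    if dtypes:
        missing = [c for c in dtypes if c not in df.columns]
        if missing:
            raise ValueError(f"{path.name}: missing columns {missing}")
        for col, dtype in dtypes.items():
            if dtype is str:
                df[col] = df[col].fillna(".")
                continue
            try:
                df[col] = df[col].astype(float)
            except ValueError as exc:
                bad = _first_bad_numeric(df[col])
                raise ValueError(
                    f"{path.name}: malformed value in column {col!r} "
                    f"at line {bad + 2}") from exc
            if dtype == "int64":
                df[col] = df[col].astype("int64")
    else:
        for col in df.columns:
            try:
                df[col] = df[col].astype(float)
            except (ValueError, TypeError):
                pass
    return df


def _first_bad_numeric(series: pd.Series) -> int:
    for i, v in enumerate(series):
        if pd.isna(v):
            continue
        try:
            float(v)
        except ValueError:
            return i
    return 0


def write_matrix(df: pd.DataFrame, path, index_name: str = "sample") -> Path:
    """Samples-by-features matrix with the sample id as the first column."""
    out = df.copy()
    out.insert(0, index_name, df.index)
    return write_table(out, path)


def read_matrix(path, kind: str | None = None,
                index_name: str = "sample") -> pd.DataFrame:
    """Read a samples-by-features matrix; ``kind`` enables range checks.

    ``kind='beta'`` requires values in [0, 1]; ``kind='dosage'`` requires
    [0, 2].  Violations raise with the offending file line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False,
                     float_precision="round_trip")
    if index_name not in df.columns:
        raise ValueError(f"{path.name}: missing index column {index_name!r}")
    df = df.set_index(index_name)
    vals = df.to_numpy(dtype=float)
    bounds = {"beta": (0.0, 1.0), "dosage": (0.0, 2.0)}.get(kind)
    if bounds is not None and vals.size:
        lo, hi = bounds
        bad = np.where((vals < lo) | (vals > hi))
        if bad[0].size:
            raise ValueError(
                f"{path.name}: {kind} value {vals[bad[0][0], bad[1][0]]!r} "
                f"outside [{lo}, {hi}] at line {bad[0][0] + 2}")
    return df.astype(float)


def write_ld_matrix(r: pd.DataFrame, path) -> Path:
    return write_matrix(r, path, index_name="snp")


def read_ld_matrix(path) -> pd.DataFrame:
    df = read_matrix(path, index_name="snp")
    df.columns = list(df.columns)
    return df


def write_bed(bed: pd.DataFrame, path) -> Path:
    """BED6 (0-based half-open), no header."""
    path = Path(path)
    lines = ["\t".join(_fmt(v) for v in row)
             for row in bed.itertuples(index=False)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_vcf_dosage(dosage: pd.DataFrame, alleles: pd.DataFrame, path) -> Path:
    """Minimal sites+DS VCF for the simulated dosages.

    ``alleles`` is indexed by SNP with effect_allele (ALT, the dosage-
    counted allele) and other_allele (REF) columns.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(dosage.index),
    ]
    for i, snp in enumerate(dosage.columns):
        a = alleles.loc[snp]
        ds = "\t".join("%.3f" % v for v in dosage[snp])
        lines.append(f"{a.get('chrom', '1')}\t{i + 1}\t{snp}\t"
                     f"{a['other_allele']}\t{a['effect_allele']}\t.\t.\t.\tDS\t{ds}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def sha256sum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
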