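"""Readers and writers for the screen's tabular formats and FASTQ input.

All tables are tab-separated with a header line; lines starting with ``#``
are comments; ``NA`` encodes an undefined value. Round-tripping a table
through :func:`write_table` / the typed readers is lossless.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from typing import Iterable, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    FEATURE_NAMES,
    PegRNADesign,
    Sample,
    SchemaError,
    Variant,
)

_LIBRARY_COLUMNS = (
    "pegrna_id",
    "variant_id",
    "spacer",
    "scaffold",
    "extension",
    "st_ref",
    "st_edit_core",
    "pegrna_bc",
    "library_bc",
)

_VARIANT_COLUMNS = ("gene", "genomic_pos", "consequence", "clinvar",
                    "neutral_set", "plof_set")

_SAMPLE_COLUMNS = ("sample_id", "screen_id", "cell_line", "coselection",
                   "timepoint", "replicate", "role")

OBSERVATION_COLUMNS = ("pegrna_id", "sample_id", "read_count", "st_total",
                       "st_correct", "st_editing_pct")


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                         keep_default_na=False, na_values=["NA"])
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty table") from exc
    if df.empty and df.columns.empty:
        raise SchemaError(f"{path}: empty table")
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _as_bool(value, what: str) -> bool:
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise SchemaError(f"{what}: not a boolean: {value!r}")


def read_library(path) -> Tuple[List[PegRNADesign], List[Variant]]:
    """Read a library design table (one row per pegRNA).

    Variant annotation columns (gene, genomic_pos, consequence, clinvar and
    optional explicit neutral_set/plof_set flags) live on the same rows and
    must agree across pegRNAs programming the same variant.
    """
    df = _read_tsv(path)
    _require_columns(df, _LIBRARY_COLUMNS + ("consequence",), path)

    if df["pegrna_id"].duplicated().any():
        dup = df.loc[df["pegrna_id"].duplicated(), "pegrna_id"].iloc[0]
        raise SchemaError(f"{path}: duplicate pegrna_id {dup!r}")
    for bc_col in ("pegrna_bc",):
        if df[bc_col].duplicated().any():
            raise SchemaError(f"{path}: duplicate {bc_col}")

    feature_cols = [c for c in df.columns if c in FEATURE_NAMES]
    designs: List[PegRNADesign] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        features = {c: float(d[c]) for c in feature_cols if pd.notna(d[c])}
        design = PegRNADesign(
            pegrna_id=d["pegrna_id"],
            variant_id=d["variant_id"],
            spacer=d["spacer"],
            scaffold=d["scaffold"],
            extension=d["extension"],
            st_ref=d["st_ref"],
            st_edit_core=d["st_edit_core"],
            pegrna_bc=d["pegrna_bc"],
            library_bc=d["library_bc"],
            features=features,
        )
        design.validate()
        designs.append(design)

    variants: List[Variant] = []
    seen: dict = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        vid = d["variant_id"]
        pos = d.get("genomic_pos")
        variant = Variant(
            variant_id=vid,
            gene=d.get("gene", "") or "",
            genomic_pos=int(pos) if pos not in (None, "") and pd.notna(pos) else None,
            consequence=d["consequence"],
            clinvar=(d.get("clinvar") or "none") if pd.notna(d.get("clinvar", "none")) else "none",
            neutral_set=_as_bool(d["neutral_set"], f"{vid}.neutral_set")
            if "neutral_set" in d and pd.notna(d["neutral_set"]) else False,
            plof_set=_as_bool(d["plof_set"], f"{vid}.plof_set")
            if "plof_set" in d and pd.notna(d["plof_set"]) else False,
        )
        variant.validate()
        if vid in seen:
            if seen[vid] != variant:
                raise SchemaError(
                    f"{path}: conflicting annotations for variant {vid!r}"
                )
        else:
            seen[vid] = variant
            variants.append(variant)
    return designs, variants


def read_sample_sheet(path) -> List[Sample]:
    """Read the sample sheet; every screen needs pre, post and a negative
    control."""
    df = _read_tsv(path)
    if df.empty:
        raise SchemaError(f"{path}: no samples")
    _require_columns(df, _SAMPLE_COLUMNS, path)
    if df["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample_id")
    samples: List[Sample] = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        s = Sample(
            sample_id=d["sample_id"],
            screen_id=d["screen_id"],
            cell_line=d["cell_line"],
            coselection=_as_bool(d["coselection"], f"{d['sample_id']}.coselection"),
            timepoint=int(d["timepoint"]),
            replicate=int(d["replicate"]),
            role=d["role"],
        )
        s.validate()
        samples.append(s)
    for screen_id in sorted({s.screen_id for s in samples}):
        roles = {s.role for s in samples if s.screen_id == screen_id}
        for needed in ("pre", "post", "negative_control"):
            if needed not in roles:
                raise SchemaError(
                    f"{path}: screen {screen_id!r} has no {needed} sample"
                )
    return samples


def library_to_frame(designs: Iterable[PegRNADesign],
                     variants: Iterable[Variant]) -> pd.DataFrame:
    """Flatten designs + variants back into the library table layout."""
    vmap = {v.variant_id: v for v in variants}
    rows = []
    for d in designs:
        v = vmap[d.variant_id]
        row = {c: getattr(d, c) for c in _LIBRARY_COLUMNS}
        row.update(
            gene=v.gene,
            genomic_pos=v.genomic_pos,
            consequence=v.consequence,
            clinvar=v.clinvar,
            neutral_set=v.neutral_set,
            plof_set=v.plof_set,
        )
        row.update(d.features)
        rows.append(row)
    return pd.DataFrame(rows)


def samples_to_frame(samples: Iterable[Sample]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(s, c) for c in _SAMPLE_COLUMNS}
                         for s in samples])


def write_table(df: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    """Write a TSV with optional '#' comment lines; NaN encodes as NA."""
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


_DTYPES = {
    "read_count": "int64",
    "st_total": "int64",
    "st_correct": "int64",
    "st_editing_pct": "float64",
    "freq_pre": "float64",
    "freq_post": "float64",
    "pegrna_score": "float64",
    "st_editing_pre_pct": "float64",
    "passed_freq_filter": "boolean",
    "passed_activity_filter": "boolean",
    "passed_negctrl_filter": "boolean",
    "retained": "boolean",
    "n_conditions": "int64",
    "n_pegrnas": "int64",
    "function_score": "float64",
    "p_value": "float64",
    "q_value": "float64",
    "lof_call": "boolean",
    "timepoint": "int64",
    "replicate": "int64",
    "count": "int64",
    "freq": "float64",
    "corrected_freq": "float64",
    "excluded": "boolean",
    "genomic_pos": "Int64",
    "neutral_set": "boolean",
    "plof_set": "boolean",
    "coselection": "boolean",
    "effect": "float64",
    "true_editing_rate": "float64",
    "base_abundance": "float64",
}


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, restoring known dtypes."""
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                     keep_default_na=False)
    for col in df.columns:
        if col in _DTYPES:
            dtype = _DTYPES[col]
            if dtype == "boolean":
                df[col] = df[col].map(
                    {True: True, False: False, "True": True, "False": False}
                ).astype("boolean")
            else:
                df[col] = df[col].astype(dtype)
        elif df[col].dtype == object:
            df[col] = df[col].astype(str).where(df[col].notna(), np.nan)
    return df


def open_maybe_gzip(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(path1, path2) -> Iterator[Tuple[str, str, str]]:
    """Yield (read_id, seq1, seq2) from a FASTQ pair (optionally gzipped)."""
    with open_maybe_gzip(path1) as fh1, open_maybe_gzip(path2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for rec1, rec2 in zip(it1, it2, strict=True):
            yield rec1.id, str(rec1.seq), str(rec2.seq)


def write_fastq(path, records: Iterable[Tuple[str, str]]) -> None:
    """Write (read_id, sequence) records with constant 'I' quality.

    Gzipped output is written with a zeroed header timestamp so identical
    records produce byte-identical files.
    """
    if str(path).endswith(".gz"):
        with open(path, "wb") as raw, \
                gzip.GzipFile(fileobj=raw, mode="wb", mtime=0) as gz, \
                _io.TextIOWrapper(gz) as fh:
            for rid, seq in records:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
    else:
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_config(path) -> dict:
    """Read a YAML config file; returns the raw mapping."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
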