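"""Readers and writers for the cohort input tables.

Five tab-separated inputs feed the analysis:

* segmented copy-number profiles (SEG dialect),
* somatic mutation calls (MAF-like or a simple canonical TSV),
* a clinical table (demographics, stage/grade, response, survival),
* gene-level thresholded copy-number calls (GISTIC ``all_thresholded``
  matrix or a long three-column TSV),
* per-sample BRCA1 promoter methylation + expression ("two channel").

All tables are held in memory as :class:`pandas.DataFrame` objects with the
canonical column names below; the readers normalise dialect differences,
enforce the record invariants and degrade unknown category strings to
``missing`` (missing values are excluded from downstream tests rather than
being fatal).

Coordinates are 1-based inclusive, so a segment's length is
``end_bp - start_bp + 1``.  Durations are stored in days; year-based
reporting converts at 365.25 days per year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("giscore")

DAYS_PER_YEAR = 365.25

SEGMENT_COLUMNS = ["sample_id", "chrom", "start_bp", "end_bp", "log2_ratio"]
MUTATION_COLUMNS = ["sample_id", "gene", "variant_class", "validation_status"]
CLINICAL_COLUMNS = [
    "sample_id", "age_years", "stage", "grade", "residual_cm",
    "response", "platinum", "os_days", "os_event", "pfs_days", "pfs_event",
]
CN_CALL_COLUMNS = ["sample_id", "gene", "call"]
TWO_CHANNEL_COLUMNS = ["sample_id", "methylation_beta", "expression_value"]

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frame_shift", "in_frame_indel",
     "splice", "silent", "other"}
)
#: variant classes that alter the protein sequence (used for BRCA carrier
#: flags and HR-gene deficiency evidence)
NONSYNONYMOUS_CLASSES = frozenset(VARIANT_CLASSES - {"silent"})

VALIDATION_STATUSES = frozenset({"validated", "unvalidated"})

STAGES = frozenset({"II", "III", "IV", "missing"})
GRADES = frozenset({"G2", "G3_G4", "missing"})
RESIDUALS = frozenset({"0", "lt1", "1to2", "gt2", "missing"})
RESPONSES = frozenset({"CR", "nonCR", "missing"})
PLATINUM = frozenset({"sensitive", "resistant", "missing"})

#: MAF ``Variant_Classification`` strings mapped onto the canonical enum.
MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Frame_Shift_Del": "frame_shift",
    "Frame_Shift_Ins": "frame_shift",
    "In_Frame_Del": "in_frame_indel",
    "In_Frame_Ins": "in_frame_indel",
    "Splice_Site": "splice",
    "Splice_Region": "splice",
    "Silent": "silent",
}

_MAF_VALIDATED = {"valid", "validated", "verified"}


class FormatError(ValueError):
    """A required column is missing or a value cannot be parsed."""


def _require_columns(df: pd.DataFrame, mapping: dict[str, str], path) -> None:
    missing = [src for src in mapping if src not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

def read_segments(path, dialect: str = "seg_tsv") -> pd.DataFrame:
    """Read a SEG file into the canonical segment table.

    SEG columns are ``Sample, Chromosome, Start, End[, Num_Probes],
    Segment_Mean`` (case-insensitive).  Rows violating the record
    invariants (end < start, start < 1, non-finite log2 ratio) are dropped
    with a logged count; unparseable coordinates raise a row-level error.
    """
    if dialect != "seg_tsv":
        raise ValueError(f"unknown segment dialect: {dialect!r}")
    raw = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in raw.columns}
    name_map = {}
    for canon, aliases in {
        "sample_id": ("sample", "sample_id", "id"),
        "chrom": ("chromosome", "chrom", "chr"),
        "start_bp": ("start", "start_bp", "loc.start"),
        "end_bp": ("end", "end_bp", "loc.end"),
        "log2_ratio": ("segment_mean", "log2_ratio", "seg.mean"),
    }.items():
        found = next((cols[a] for a in aliases if a in cols), None)
        if found is None:
            raise FormatError(f"{path}: missing required column for {canon!r}")
        name_map[canon] = found

    df = pd.DataFrame({canon: raw[src] for canon, src in name_map.items()})
    for col in ("start_bp", "end_bp"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise FormatError(
                f"{path}: unparseable coordinate in column {col!r} at line {line}"
            )
        df[col] = coerced.astype("int64")
    df["log2_ratio"] = pd.to_numeric(df["log2_ratio"], errors="coerce")

    n0 = len(df)
    keep = (
        np.isfinite(df["log2_ratio"])
        & (df["start_bp"] >= 1)
        & (df["end_bp"] >= df["start_bp"])
    )
    dropped = n0 - int(keep.sum())
    if dropped:
        logger.warning("%s: rejected %d segment row(s) violating invariants", path, dropped)
    return df.loc[keep, SEGMENT_COLUMNS].reset_index(drop=True)


def write_segments(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={
        "sample_id": "Sample", "chrom": "Chromosome", "start_bp": "Start",
        "end_bp": "End", "log2_ratio": "Segment_Mean",
    })
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def _map_validation(values: pd.Series) -> pd.Series:
    return values.fillna("").str.strip().str.lower().isin(_MAF_VALIDATED).map(
        {True: "validated", False: "unvalidated"}
    )


def read_mutations(path, dialect: str = "maf_tsv") -> pd.DataFrame:
    """Read somatic mutation calls.

    ``maf_tsv`` expects MAF headers (``Tumor_Sample_Barcode, Hugo_Symbol,
    Variant_Classification, Validation_Status``); ``simple_tsv`` expects the
    canonical column names directly.  Variant classifications with no
    mapping become ``other`` with a logged warning.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "maf_tsv":
        mapping = {
            "Tumor_Sample_Barcode": "sample_id",
            "Hugo_Symbol": "gene",
            "Variant_Classification": "variant_class",
            "Validation_Status": "validation_status",
        }
        _require_columns(raw, mapping, path)
        df = raw[list(mapping)].rename(columns=mapping)
        unmapped = ~df["variant_class"].isin(MAF_CLASS_MAP)
        if unmapped.any():
            logger.warning(
                "%s: %d mutation row(s) with unmapped classification -> 'other' (%s)",
                path, int(unmapped.sum()),
                sorted(df.loc[unmapped, "variant_class"].unique())[:5],
            )
        df["variant_class"] = df["variant_class"].map(MAF_CLASS_MAP).fillna("other")
        df["validation_status"] = _map_validation(df["validation_status"])
    elif dialect == "simple_tsv":
        _require_columns(raw, {c: c for c in MUTATION_COLUMNS}, path)
        df = raw[MUTATION_COLUMNS].copy()
        bad_class = ~df["variant_class"].isin(VARIANT_CLASSES)
        if bad_class.any():
            logger.warning("%s: %d unknown variant_class value(s) -> 'other'",
                           path, int(bad_class.sum()))
            df.loc[bad_class, "variant_class"] = "other"
        bad_val = ~df["validation_status"].isin(VALIDATION_STATUSES)
        if bad_val.any():
            df.loc[bad_val, "validation_status"] = _map_validation(
                df.loc[bad_val, "validation_status"]
            )
    else:
        raise ValueError(f"unknown mutation dialect: {dialect!r}")

    empty_gene = df["gene"].isna() | (df["gene"].str.strip() == "")
    if empty_gene.any():
        logger.warning("%s: rejected %d mutation row(s) with empty gene",
                       path, int(empty_gene.sum()))
        df = df.loc[~empty_gene]
    return df.reset_index(drop=True)


def write_mutations(df: pd.DataFrame, path) -> None:
    df[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

def _norm_stage(v: str) -> str:
    v = v.strip().upper()
    # collapse sub-stage suffixes (IIIC -> III); order matters for prefixes
    for major in ("IV", "III", "II"):
        if v.startswith(major):
            return major
    return ""


def _norm_grade(v: str) -> str:
    v = v.strip().upper().replace(" ", "").replace("G", "")
    if v == "2":
        return "G2"
    if v in {"3", "4", "3_4", "3AND4"}:
        return "G3_G4"
    return ""


def _norm_residual(v: str) -> str:
    v = v.strip().lower().replace(" ", "")
    table = {
        "0": "0", "nomacroscopicdisease": "0",
        "<1": "lt1", "lt1": "lt1", "1-2": "1to2", "1to2": "1to2",
        ">2": "gt2", "gt2": "gt2",
    }
    return table.get(v, "")


def _norm_cat(v: str, canon: dict[str, str]) -> str:
    return canon.get(v.strip().lower(), "")


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table (canonical column names, TSV).

    Unknown category strings degrade to ``missing`` with a warning;
    duplicated sample ids are an error.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(raw, {c: c for c in CLINICAL_COLUMNS}, path)
    dup = raw["sample_id"][raw["sample_id"].duplicated()].unique()
    if len(dup):
        raise FormatError(f"{path}: duplicated sample_id(s): {sorted(dup)}")

    df = raw[CLINICAL_COLUMNS].copy()
    normalisers = {
        "stage": _norm_stage,
        "grade": _norm_grade,
        "residual_cm": _norm_residual,
        "response": lambda v: _norm_cat(v, {"cr": "CR", "noncr": "nonCR",
                                            "non-cr": "nonCR"}),
        "platinum": lambda v: _norm_cat(v, {"sensitive": "sensitive",
                                            "sensitivity": "sensitive",
                                            "resistant": "resistant"}),
    }
    for col, fn in normalisers.items():
        vals = df[col].fillna("").map(fn)
        unknown = (vals == "") & df[col].notna() & (df[col].str.strip() != "") \
            & (df[col].str.strip().str.lower() != "missing")
        if unknown.any():
            logger.warning("%s: %d unknown %s value(s) -> missing",
                           path, int(unknown.sum()), col)
        df[col] = vals.replace("", "missing")

    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    for col in ("os_days", "pfs_days"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("os_event", "pfs_event"):
        df[col] = (
            df[col].fillna("").str.strip().str.lower()
            .isin({"1", "true", "yes", "dead", "event"})
        )
    neg = (df["os_days"] < 0) | (df["pfs_days"] < 0)
    if neg.any():
        raise FormatError(f"{path}: negative survival time(s) in {int(neg.sum())} row(s)")
    flagged = df["pfs_days"] > df["os_days"]
    if flagged.any():
        logger.warning("%s: %d row(s) with pfs_days > os_days", path, int(flagged.sum()))
    return df.reset_index(drop=True)


def write_clinical(df: pd.DataFrame, path) -> None:
    out = df[CLINICAL_COLUMNS].copy()
    for col in ("os_event", "pfs_event"):
        out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-level thresholded copy-number calls
# ---------------------------------------------------------------------------

def read_cn_calls(path, dialect: str = "auto") -> pd.DataFrame:
    """Read gene-level thresholded copy-number calls (−2 … +2).

    ``gistic_matrix``: GISTIC ``all_thresholded.by_genes`` layout — first
    column is the gene symbol, optional ``Locus ID``/``Cytoband`` columns,
    remaining columns are samples.  ``long_tsv``: canonical three-column
    table.  ``auto`` picks by header.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "auto":
        dialect = "long_tsv" if set(CN_CALL_COLUMNS) <= set(raw.columns) else "gistic_matrix"
    if dialect == "long_tsv":
        df = raw[CN_CALL_COLUMNS].copy()
        df["call"] = pd.to_numeric(df["call"], errors="coerce")
    elif dialect == "gistic_matrix":
        gene_col = raw.columns[0]
        drop = [c for c in raw.columns[1:3] if c.lower() in {"locus id", "cytoband"}]
        long = raw.drop(columns=drop).melt(
            id_vars=[gene_col], var_name="sample_id", value_name="call"
        )
        df = long.rename(columns={gene_col: "gene"})[CN_CALL_COLUMNS]
        df["call"] = pd.to_numeric(df["call"], errors="coerce")
    else:
        raise ValueError(f"unknown cn-call dialect: {dialect!r}")
    bad = df["call"].isna() | ~df["call"].isin([-2, -1, 0, 1, 2])
    if bad.any():
        logger.warning("%s: rejected %d cn-call row(s) outside {-2..2}",
                       path, int(bad.sum()))
        df = df.loc[~bad]
    df["call"] = df["call"].astype(int)
    return df.reset_index(drop=True)


def write_cn_calls(df: pd.DataFrame, path) -> None:
    df[CN_CALL_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# methylation / expression two-channel table
# ---------------------------------------------------------------------------

def read_two_channel(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(raw, {c: c for c in TWO_CHANNEL_COLUMNS}, path)
    df = raw[TWO_CHANNEL_COLUMNS].copy()
    for col in ("methylation_beta", "expression_value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    keep = (
        np.isfinite(df["methylation_beta"]) & np.isfinite(df["expression_value"])
        & df["methylation_beta"].between(0.0, 1.0)
    )
    dropped = len(df) - int(keep.sum())
    if dropped:
        logger.warning("%s: rejected %d two-channel row(s)", path, dropped)
    return df.loc[keep].reset_index(drop=True)


def write_two_channel(df: pd.DataFrame, path) -> None:
    df[TWO_CHANNEL_COLUMNS].to_csv(path, sep="\t", index=False)
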