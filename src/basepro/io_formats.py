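"""Readers/writers for the tabular formats the pipeline touches.

Conventions used throughout the package:

* Expression matrices are genes x samples TSV files (gene identifiers in the
  first column, sample identifiers as column headers), on the log2(x+1) scale
  internally.  A config flag ``expression_scale: raw|log2`` controls whether
  ``log2(x+1)`` is applied at load time.
* Clinical / survival tables are samples x columns TSV files (sample
  identifiers in the first column).
* BED gene annotations are 0-based half-open; SEG segments are 1-based
  inclusive on disk.  All internal genomic arithmetic converts to 0-based
  half-open coordinates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("basepro.io")

#: Variant classifications accepted in MAF files.  Unknown values are kept
#: (real-world MAFs carry center-specific labels) but reported once.
MAF_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Silent",
        "Intron",
        "3'UTR",
        "5'UTR",
        "3'Flank",
        "5'Flank",
        "IGR",
        "RNA",
        "Targeted_Region",
    }
)

ONCO_CLASS_BINS = ((0, 17, "low"), (18, 30, "intermediate"), (31, 100, "high"))


class FormatError(ValueError):
    """A file does not conform to the expected tabular format."""


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MafRecord:
    """One somatic variant call (one MAF data row)."""

    hugo_symbol: str
    sample_barcode: str
    variant_classification: str
    variant_type: str


@dataclass(frozen=True)
class SegRecord:
    """One copy-number segment; coordinates 1-based inclusive as in SEG."""

    sample_barcode: str
    chrom: str
    start: int
    end: int
    value: float


@dataclass
class CohortBundle:
    """All per-cohort tables, restricted to a shared, sorted sample set."""

    expression: pd.DataFrame  # genes x samples, log2 scale
    clinical: pd.DataFrame  # samples x covariates
    survival: pd.DataFrame  # samples x [time, event]
    aberrations: pd.DataFrame | None = None  # samples x events, 0/1
    comparator: pd.Series | None = None  # Onco-score, 0..100

    @property
    def samples(self) -> pd.Index:
        return self.expression.columns


# ---------------------------------------------------------------------------
# MAF / SEG / BED readers
# ---------------------------------------------------------------------------

_MAF_COLUMNS = {
    "hugo_symbol": ("Hugo_Symbol",),
    "sample_barcode": ("Tumor_Sample_Barcode", "Sample_Barcode"),
    "variant_classification": ("Variant_Classification",),
    "variant_type": ("Variant_Type",),
}

_SEG_COLUMNS = {
    "sample_barcode": ("Sample", "ID", "sample"),
    "chrom": ("chrom", "Chromosome", "chr"),
    "start": ("start", "loc.start", "Start"),
    "end": ("end", "loc.end", "End"),
    "value": ("value", "seg.mean", "Segment_Mean"),
}


def _resolve_columns(
    header: Sequence[str], wanted: Mapping[str, tuple[str, ...]], path
) -> dict[str, str]:
    resolved = {}
    for key, aliases in wanted.items():
        hit = next((a for a in aliases if a in header), None)
        if hit is None:
            raise FormatError(
                f"{path}: missing required column {aliases[0]!r} "
                f"(accepted aliases: {', '.join(aliases)})"
            )
        resolved[key] = hit
    return resolved


def read_maf(path: str | Path) -> list[MafRecord]:
    """Read a tab-delimited MAF file into records.

    Column order is irrelevant; unknown columns are ignored; '#' comment
    lines are skipped.  Raises :class:`FormatError` if a required column is
    missing.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(df.columns, _MAF_COLUMNS, path)
    records = []
    unknown_classes: set[str] = set()
    for row in df.itertuples(index=False):
        rec = MafRecord(
            hugo_symbol=getattr(row, cols["hugo_symbol"]),
            sample_barcode=getattr(row, cols["sample_barcode"]),
            variant_classification=getattr(row, cols["variant_classification"]),
            variant_type=getattr(row, cols["variant_type"]),
        )
        if not rec.hugo_symbol or not rec.sample_barcode:
            raise FormatError(f"{path}: empty gene or sample identifier")
        if rec.variant_classification not in MAF_VARIANT_CLASSES:
            unknown_classes.add(rec.variant_classification)
        records.append(rec)
    if unknown_classes:
        logger.warning(
            "%s: %d variant classification(s) outside the documented vocabulary: %s",
            path,
            len(unknown_classes),
            sorted(unknown_classes),
        )
    return records


def read_seg(path: str | Path) -> list[SegRecord]:
    """Read a SEG file (1-based inclusive coordinates, log2 copy ratios)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = _resolve_columns(df.columns, _SEG_COLUMNS, path)
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            start = int(getattr(row, cols["start"]))
            end = int(getattr(row, cols["end"]))
            value = float(getattr(row, cols["value"]))
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: row {i + 1}: non-numeric field ({exc})") from exc
        if start > end:
            raise FormatError(f"{path}: row {i + 1}: start {start} > end {end}")
        if not math.isfinite(value):
            raise FormatError(f"{path}: row {i + 1}: non-finite segment value")
        records.append(
            SegRecord(
                sample_barcode=getattr(row, cols["sample_barcode"]),
                chrom=getattr(row, cols["chrom"]),
                start=start,
                end=end,
                value=value,
            )
        )
    return records


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read gene intervals from BED (0-based half-open).

    Returns a DataFrame indexed by gene with columns chrom/start/end.
    Duplicate gene names or empty intervals are rejected.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "gene"],
        usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "start": int, "end": int, "gene": str},
    )
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise FormatError(f"{path}: row {bad + 1}: empty or inverted interval")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise FormatError(f"{path}: duplicate gene {dup!r}")
    return df.set_index("gene")


# ---------------------------------------------------------------------------
# Matrices / tables
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, scale: str = "log2") -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    ``scale='raw'`` applies log2(x+1) at load; ``'log2'`` takes values as-is.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if scale == "raw":
        if (df.values < 0).any():
            raise FormatError(f"{path}: negative values under expression_scale=raw")
        df = np.log2(df + 1.0)
    elif scale != "log2":
        raise ValueError(f"unknown expression_scale {scale!r}")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate gene identifiers")
    if df.columns.duplicated().any():
        raise FormatError(f"{path}: duplicate sample identifiers")
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x columns TSV table (samples in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate sample identifiers")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    """Write a matrix/table as TSV with repr-faithful decimals (round-trips)."""
    df.to_csv(path, sep="\t", index_label=index_label)


def write_weights(weight_sets, path: str | Path, fit=None) -> None:
    """Write signature weight sets as a long TSV (gene, event, w_plus, w_minus).

    If a regression fit table is supplied, beta and p columns are included.
    """
    rows = []
    for name, ws in weight_sets.items():
        nz = (ws.w_plus != 0) | (ws.w_minus != 0)
        for gene in ws.w_plus.index[nz]:
            row = {
                "gene": gene,
                "event": name,
                "w_plus": ws.w_plus[gene],
                "w_minus": ws.w_minus[gene],
            }
            if fit is not None and name in fit.beta.columns and gene in fit.beta.index:
                row["beta"] = fit.beta.at[gene, name]
                row["p"] = fit.pvalue.at[gene, name]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Comparator (Onco-score) semantics
# ---------------------------------------------------------------------------


def onco_class(score: float) -> str:
    """Map a 0-100 recurrence score to its risk class (low/intermediate/high)."""
    if not 0 <= score <= 100:
        raise ValueError(f"comparator score {score} outside [0, 100]")
    for lo, hi, label in ONCO_CLASS_BINS:
        if lo <= score <= hi:
            return label
    return "high"  # non-integer scores in (17, 18) / (30, 31) round up a class


# ---------------------------------------------------------------------------
# Cohort bundle assembly
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def read_cohort_bundle(config: Mapping) -> CohortBundle:
    """Assemble a :class:`CohortBundle` from a config mapping of file paths.

    Sample sets are intersected across components, dropped samples are
    logged per component, and the final ordering is lexicographic.
    """
    scale = config.get("expression_scale", "log2")
    expression = read_expression(config["expression"], scale=scale)
    clinical = read_table(config["clinical"])
    survival = read_table(config["survival"])
    components: dict[str, pd.Index] = {
        "expression": expression.columns,
        "clinical": clinical.index,
        "survival": survival.index,
    }
    aberrations = comparator = None
    if config.get("aberrations"):
        aberrations = read_table(config["aberrations"])
        components["aberrations"] = aberrations.index
    if config.get("comparator"):
        comp_tab = read_table(config["comparator"])
        comparator = comp_tab.iloc[:, 0].astype(float)
        components["comparator"] = comparator.index

    shared: set | None = None
    for ids in components.values():
        shared = set(ids) if shared is None else shared & set(ids)
    assert shared is not None
    if not shared:
        raise ValueError("no samples shared across cohort components")
    order = sorted(shared)
    for name, ids in components.items():
        dropped = len(ids) - len(order)
        if dropped:
            logger.info("cohort bundle: dropped %d sample(s) from %s", dropped, name)

    bundle = CohortBundle(
        expression=expression.loc[:, order],
        clinical=clinical.loc[order],
        survival=survival.loc[order],
        aberrations=aberrations.loc[order] if aberrations is not None else None,
        comparator=comparator.loc[order] if comparator is not None else None,
    )
    if bundle.comparator is not None:
        bundle.comparator.apply(onco_class)  # validates the 0-100 range
    return bundle
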