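"""Recurrent genomic-aberration event calling from MAF/SEG inputs.

Produces the binary samples x events AberrationMatrix that drives the
signature regressions: a mutation event is a gene with a qualifying
nonsynonymous variant in at least ``min_fraction`` of the cohort; CNV events
are genes whose gene-level log2 copy ratio exceeds the amplification
threshold (default log2(2.82)) or falls below the deletion threshold
(default -log2(1.32)) in at least ``min_fraction`` of samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import MafRecord, SegRecord

logger = logging.getLogger("basepro.aberrations")

#: Nonsynonymous point-mutation classes that qualify a sample as a carrier.
POINT_MUTATION_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

#: Frameshift / in-frame indel classes, included by default (`include_indels`).
INDEL_CLASSES = frozenset(
    {"Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins"}
)

DEFAULT_AMP_THRESHOLD = float(np.log2(2.82))
DEFAULT_DEL_THRESHOLD = float(-np.log2(1.32))


@dataclass(frozen=True)
class AberrationEvent:
    gene: str
    kind: str  # mut | amp | del
    carrier_fraction: float

    @property
    def label(self) -> str:
        return f"{self.gene}_{self.kind}"


def default_mutation_classes(include_indels: bool = True) -> frozenset[str]:
    return POINT_MUTATION_CLASSES | INDEL_CLASSES if include_indels else POINT_MUTATION_CLASSES


def call_recurrent_mutations(
    maf_records: Iterable[MafRecord],
    sample_ids: Sequence[str],
    min_fraction: float = 0.10,
    classes: frozenset[str] | None = None,
) -> tuple[list[AberrationEvent], pd.DataFrame]:
    """Call genes mutated in at least ``min_fraction`` of ``sample_ids``.

    The carrier fraction denominator is the full cohort (``sample_ids``),
    including samples absent from the MAF.  Multiple qualifying rows for the
    same gene/sample count once.  Returns the retained events and a binary
    samples x events indicator matrix.
    """
    if len(sample_ids) == 0:
        raise ValueError("sample_ids must be non-empty")
    sample_index = pd.Index(sample_ids)
    if sample_index.duplicated().any():
        raise ValueError("duplicate sample identifiers")
    classes = classes if classes is not None else default_mutation_classes()

    known = set(sample_index)
    carriers: dict[str, set[str]] = {}
    skipped = set()
    for rec in maf_records:
        if rec.sample_barcode not in known:
            skipped.add(rec.sample_barcode)
            continue
        if rec.variant_classification in classes:
            carriers.setdefault(rec.hugo_symbol, set()).add(rec.sample_barcode)
    if skipped:
        logger.info("MAF: ignored %d sample(s) not in the cohort", len(skipped))

    events: list[AberrationEvent] = []
    columns = {}
    for gene in sorted(carriers):
        frac = len(carriers[gene]) / len(sample_index)
        if frac >= min_fraction:
            events.append(AberrationEvent(gene, "mut", frac))
            columns[f"{gene}_mut"] = sample_index.isin(list(carriers[gene])).astype(int)
    matrix = pd.DataFrame(columns, index=sample_index, dtype=int)
    return events, matrix


def gene_level_copy_number(
    seg_records: Iterable[SegRecord], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Overlap-length-weighted mean segment value per gene per sample.

    ``annotation`` holds 0-based half-open gene intervals (chrom/start/end).
    Genes with no overlapping segment in a sample are copy-neutral (0).
    """
    records = list(seg_records)
    samples = sorted({r.sample_barcode for r in records})
    matrix = pd.DataFrame(0.0, index=annotation.index, columns=samples)
    if not records:
        return matrix

    sample_pos = {s: j for j, s in enumerate(samples)}
    by_chrom: dict[str, list[SegRecord]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append(r)
    # per-chromosome arrays: SEG 1-based inclusive -> half-open [start-1, end)
    chrom_arrays = {
        chrom: (
            np.array([r.start - 1 for r in segs]),
            np.array([r.end for r in segs]),
            np.array([r.value for r in segs]),
            np.array([sample_pos[r.sample_barcode] for r in segs]),
        )
        for chrom, segs in by_chrom.items()
    }

    values = matrix.to_numpy()
    weights = np.zeros_like(values)
    gene_pos = {g: i for i, g in enumerate(annotation.index)}
    missing_chroms = set()
    for gene, row in annotation.iterrows():
        chrom = row["chrom"]
        if chrom not in chrom_arrays:
            missing_chroms.add(chrom)
            continue
        gs, ge = int(row["start"]), int(row["end"])  # 0-based half-open
        starts, ends, vals, samp = chrom_arrays[chrom]
        ov = np.minimum(ge, ends) - np.maximum(gs, starts)
        hit = ov > 0
        if hit.any():
            i = gene_pos[gene]
            np.add.at(values[i], samp[hit], ov[hit] * vals[hit])
            np.add.at(weights[i], samp[hit], ov[hit])
    for chrom in sorted(missing_chroms):
        logger.info("no segments on %s; genes there set copy-neutral", chrom)
    covered = weights > 0
    values[covered] /= weights[covered]
    return matrix


def call_recurrent_cnv(
    cn_matrix: pd.DataFrame,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
    min_fraction: float = 0.10,
) -> tuple[list[AberrationEvent], pd.DataFrame]:
    """Call recurrent amplifications/deletions from gene-level log2 ratios.

    A sample carries an amplification when its value is strictly greater
    than ``amp_threshold``, a deletion when strictly below ``del_threshold``;
    a gene may yield both an amp and a del event.
    """
    if amp_threshold <= del_threshold:
        raise ValueError("amp_threshold must exceed del_threshold")
    n = cn_matrix.shape[1]
    events: list[AberrationEvent] = []
    columns = {}
    for kind, indic in (
        ("amp", cn_matrix.gt(amp_threshold)),
        ("del", cn_matrix.lt(del_threshold)),
    ):
        frac = indic.sum(axis=1) / n
        for gene in sorted(frac.index[frac >= min_fraction]):
            events.append(AberrationEvent(gene, kind, float(frac[gene])))
            columns[f"{gene}_{kind}"] = indic.loc[gene].astype(int)
    matrix = pd.DataFrame(columns, index=cn_matrix.columns, dtype=int)
    return events, matrix


def assemble_aberration_matrix(
    mutation_events: tuple[list[AberrationEvent], pd.DataFrame],
    cnv_events: tuple[list[AberrationEvent], pd.DataFrame],
    sample_ids: Sequence[str],
) -> pd.DataFrame:
    """Combine mutation and CNV indicator columns into one binary matrix.

    Column order is mut, then amp, then del events, alphabetical within each
    kind.  Samples with no events keep an all-zero row.
    """
    mut_ev, mut_mat = mutation_events
    cnv_ev, cnv_mat = cnv_events
    labels = [e.label for e in mut_ev] + [e.label for e in cnv_ev]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise ValueError(f"duplicate event label {dup!r}")
    order = [e.label for kind in ("mut", "amp", "del")
             for e in sorted(mut_ev + cnv_ev, key=lambda e: e.gene) if e.kind == kind]
    sample_index = pd.Index(sample_ids)
    combined = pd.concat(
        [mut_mat.reindex(sample_index, fill_value=0), cnv_mat.reindex(sample_index, fill_value=0)],
        axis=1,
    )
    return combined.loc[:, order].astype(int)
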