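"""Synthetic ER+ breast-cancer-like cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes:

* binary genomic-aberration status per recurrent event (mutation,
  amplification, deletion), with exact carrier counts;
* expression shifted additively (log2 units) in event carriers on a planted
  signature gene set, half of the set up- and half down-regulated;
* immune-cell admixture: six cell types with disjoint marker sets, reference
  profiles, and Dirichlet sample fractions added to the expression;
* clinical covariates (age, tumour size, grade, stage, node count);
* right-censored exponential survival whose log hazard is linear in planted
  event status and standardised clinical covariates, with independent
  uniform censoring calibrated to a target censoring fraction.

All randomness flows from a master seed through named substreams
(expression, clinical, survival, censoring, immune), so regeneration from
the same config is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CohortBundle

logger = logging.getLogger("basepro.synthetic")

_SUBSTREAMS = ("expression", "clinical", "survival", "censoring", "immune")

DEFAULT_CELL_TYPES = ("NavB", "MemB", "CD4T", "CD8T", "NKcell", "Monocytes")

AMP_SEG_VALUE = 2.0  # log2 copy ratio written for amplification carriers
DEL_SEG_VALUE = -1.0  # log2 copy ratio written for deletion carriers


@dataclass(frozen=True)
class EventSpec:
    """One planted genomic-aberration event."""

    label: str  # "<GENE>_<kind>", e.g. "G0007_amp"
    carrier_fraction: float
    set_size: int = 150  # planted signature gene-set size
    effect: float = 1.0  # |log2 expression shift| in carriers

    @property
    def gene(self) -> str:
        return self.label.rsplit("_", 1)[0]

    @property
    def kind(self) -> str:
        kind = self.label.rsplit("_", 1)[1]
        if kind not in ("mut", "amp", "del"):
            raise ValueError(f"event label {self.label!r} must end in _mut/_amp/_del")
        return kind


@dataclass(frozen=True)
class ImmuneSpec:
    cell_type: str
    mean_fraction: float = 0.05
    n_markers: int = 60


@dataclass(frozen=True)
class SurvivalSpec:
    """Exponential survival with log-linear hazard and uniform censoring."""

    baseline_hazard: float = 0.05  # events per year at covariates zero
    event_coef: float = 0.7  # log-HR per planted event carried
    clinical_coefs: dict = field(
        default_factory=lambda: {"age": 0.2, "grade": 0.3, "nodes": 0.2}
    )  # log-HR per SD of the covariate
    censoring_rate: float = 0.3
    horizon: float = 10.0  # years, used for prognosis labels downstream


def default_events(n_events: int = 10) -> tuple[EventSpec, ...]:
    """A mixed slate of recurrent events at realistic carrier fractions."""
    kinds = ["mut", "amp", "del"]
    fractions = [0.35, 0.25, 0.20, 0.15, 0.12, 0.30, 0.18, 0.15, 0.25, 0.12]
    events = []
    for i in range(n_events):
        events.append(
            EventSpec(
                label=f"G{i:04d}_{kinds[i % 3]}",
                carrier_fraction=fractions[i % len(fractions)],
            )
        )
    return tuple(events)


@dataclass
class SimulationConfig:
    n_samples: int = 400
    n_genes: int = 2000
    events: Sequence[EventSpec] = field(default_factory=default_events)
    immune: Sequence[ImmuneSpec] = field(
        default_factory=lambda: tuple(ImmuneSpec(ct) for ct in DEFAULT_CELL_TYPES)
    )
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    noise_sd: float = 0.5
    baseline_mean: float = 7.0  # log2 expression grand mean
    baseline_sd: float = 2.0
    marker_level: float = 6.0  # log2 reference expression of a marker gene
    immune_concentration: float = 30.0  # Dirichlet concentration for fractions
    event_correlation: float = 0.0  # pairwise latent correlation of event status
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 20:
            raise ValueError("n_samples must be >= 20")
        for ev in self.events:
            ev.kind  # validates the label suffix
            if not 0 < ev.carrier_fraction < 1:
                raise ValueError(f"{ev.label}: carrier fraction must be in (0,1)")
            if round(ev.carrier_fraction * self.n_samples) < 2:
                raise ValueError(f"{ev.label}: fewer than 2 carriers is infeasible")
            if ev.set_size > self.n_genes:
                raise ValueError(f"{ev.label}: signature set exceeds gene universe")
        labels = [ev.label for ev in self.events]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate event labels")
        total_markers = sum(im.n_markers for im in self.immune)
        reserved = len(self.events) * max((ev.set_size for ev in self.events), default=0)
        if total_markers + reserved > self.n_genes:
            raise ValueError("marker sets and signature sets exceed the gene universe")
        frac = sum(im.mean_fraction for im in self.immune)
        if not 0 <= frac < 1:
            raise ValueError("mean immune fractions must sum to < 1")


@dataclass
class ImmuneReferencePanel:
    """Cell-type x gene reference expression with planted marker sets."""

    profiles: pd.DataFrame  # cell types x genes (log2 scale)
    marker_sets: dict  # cell type -> list of marker genes


@dataclass
class SyntheticCohort:
    bundle: CohortBundle
    config: SimulationConfig
    carrier_sets: dict  # event label -> list of carrier sample ids
    signature_sets: dict  # event label -> {gene: +1/-1 effect direction}
    immune_panel: ImmuneReferencePanel
    immune_fractions: pd.DataFrame  # samples x cell types
    true_risk: pd.Series  # per-sample linear log-hazard
    gene_annotation: pd.DataFrame  # gene -> chrom/start/end (0-based half-open)

    def truth_dict(self) -> dict:
        return {
            "carrier_sets": {k: list(v) for k, v in self.carrier_sets.items()},
            "signature_sets": {
                k: {g: int(d) for g, d in v.items()} for k, v in self.signature_sets.items()
            },
            "immune_fractions": self.immune_fractions.to_dict(orient="index"),
            "true_risk": self.true_risk.to_dict(),
        }


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _annotation(genes: pd.Index) -> pd.DataFrame:
    # one synthetic chromosome, 1 kb genes separated by 1 kb gaps
    start = np.arange(len(genes), dtype=int) * 2000
    return pd.DataFrame(
        {"chrom": "chr1", "start": start, "end": start + 1000}, index=genes
    )


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort with ground truth attached."""
    config = config or SimulationConfig()
    config.validate()
    rngs = _rngs(config.seed)
    n, g = config.n_samples, config.n_genes
    samples = pd.Index([f"S{i:04d}" for i in range(n)], name="sample")
    genes = pd.Index([f"G{i:04d}" for i in range(g)], name="gene")

    # --- aberration status: exact carrier counts per event -----------------
    rng = rngs["expression"]
    aberrations = pd.DataFrame(0, index=samples, columns=[e.label for e in config.events])
    carrier_sets: dict[str, list[str]] = {}
    if config.event_correlation > 0 and len(config.events) > 1:
        # Gaussian copula: shared latent factor induces pairwise correlation,
        # then per-event thresholding at the exact carrier count.
        rho = config.event_correlation
        shared = rng.standard_normal(n)
        latents = {
            e.label: np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n)
            for e in config.events
        }
    else:
        latents = {e.label: rng.standard_normal(n) for e in config.events}
    for ev in config.events:
        k = int(round(ev.carrier_fraction * n))
        carriers = samples[np.argsort(-latents[ev.label], kind="stable")[:k]]
        carrier_sets[ev.label] = list(carriers)
        aberrations.loc[carriers, ev.label] = 1

    # --- gene partition: disjoint signature sets, then marker sets ---------
    pool = list(genes)
    signature_sets: dict[str, dict[str, int]] = {}
    for ev in config.events:
        idx = rng.choice(len(pool), size=ev.set_size, replace=False)
        chosen = [pool[i] for i in idx]
        pool = [p for i, p in enumerate(pool) if i not in set(idx)]
        directions = rng.permutation(
            np.r_[np.ones(ev.set_size // 2, int), -np.ones(ev.set_size - ev.set_size // 2, int)]
        )
        signature_sets[ev.label] = dict(zip(chosen, directions))

    rng_imm = rngs["immune"]
    marker_sets: dict[str, list[str]] = {}
    for im in config.immune:
        idx = rng_imm.choice(len(pool), size=im.n_markers, replace=False)
        marker_sets[im.cell_type] = [pool[i] for i in idx]
        pool = [p for i, p in enumerate(pool) if i not in set(idx)]

    panel, fractions = _reference_profiles(config, genes, marker_sets, rng_imm, samples)

    # --- expression ---------------------------------------------------------
    mu = config.baseline_mean + config.baseline_sd * rng.standard_normal(g)
    expr = np.tile(mu[:, None], (1, n))
    gene_pos = {gname: i for i, gname in enumerate(genes)}
    for ev in config.events:
        x = aberrations[ev.label].to_numpy()
        for gname, direction in signature_sets[ev.label].items():
            expr[gene_pos[gname]] += direction * ev.effect * x
    # immune admixture: fraction-weighted reference added on the log2 scale
    expr += panel.profiles.to_numpy().T @ fractions.to_numpy().T
    expr += config.noise_sd * rng.standard_normal((g, n))
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    # --- clinical -----------------------------------------------------------
    rc = rngs["clinical"]
    clinical = pd.DataFrame(
        {
            "age": rc.normal(60.0, 10.0, n),
            "size": rc.lognormal(mean=np.log(2.0), sigma=0.5, size=n),  # cm
            "grade": rc.choice([1, 2, 3], size=n, p=[0.2, 0.45, 0.35]),
            "stage": rc.choice([1, 2, 3, 4], size=n, p=[0.3, 0.4, 0.2, 0.1]),
            "nodes": rc.poisson(1.5, n),
        },
        index=samples,
    )

    # --- survival -----------------------------------------------------------
    sv = config.survival
    risk = np.zeros(n)
    for ev in config.events:
        risk += sv.event_coef * aberrations[ev.label].to_numpy()
    for cov, coef in sv.clinical_coefs.items():
        col = clinical[cov].to_numpy(float)
        sd = col.std()
        if sd > 0:
            risk += coef * (col - col.mean()) / sd
    risk -= risk.mean()  # baseline hazard refers to the cohort-average sample
    rates = sv.baseline_hazard * np.exp(risk)
    t_event = rngs["survival"].exponential(1.0 / rates)
    time, event = _apply_censoring(t_event, rates, sv.censoring_rate, rngs["censoring"])
    survival = pd.DataFrame({"time": time, "event": event}, index=samples)

    bundle = CohortBundle(
        expression=expression,
        clinical=clinical,
        survival=survival,
        aberrations=aberrations,
    )
    return SyntheticCohort(
        bundle=bundle,
        config=config,
        carrier_sets=carrier_sets,
        signature_sets=signature_sets,
        immune_panel=panel,
        immune_fractions=fractions,
        true_risk=pd.Series(risk, index=samples, name="true_risk"),
        gene_annotation=_annotation(genes),
    )


def _reference_profiles(config, genes, marker_sets, rng, samples):
    """Reference panel (cell x gene) and Dirichlet per-sample fractions."""
    cells = [im.cell_type for im in config.immune]
    profiles = pd.DataFrame(
        np.abs(rng.normal(1.0, 0.3, (len(cells), len(genes)))), index=cells, columns=genes
    )
    for ct in cells:
        profiles.loc[ct, marker_sets[ct]] = np.abs(
            rng.normal(config.marker_level, 0.5, len(marker_sets[ct]))
        )
    means = np.array([im.mean_fraction for im in config.immune])
    alpha = np.r_[means, 1.0 - means.sum()] * config.immune_concentration
    frac = rng.dirichlet(alpha, size=len(samples))[:, : len(cells)]
    fractions = pd.DataFrame(frac, index=samples, columns=cells)
    return ImmuneReferencePanel(profiles=profiles, marker_sets=marker_sets), fractions


def simulate_reference_profiles(
    config: SimulationConfig | None = None,
) -> tuple[ImmuneReferencePanel, pd.DataFrame]:
    """Standalone immune panel + ground-truth fractions (same substream as
    :func:`simulate_cohort`, so the two agree for the same config)."""
    cohort = simulate_cohort(config)
    return cohort.immune_panel, cohort.immune_fractions


def _apply_censoring(t_event, rates, target_rate, rng):
    """Independent uniform censoring C ~ U(0, c_max).

    c_max is found by bisection on the analytic expected censoring fraction
    E[P(C < T | rate)] = mean over samples of (1 - exp(-rate*c)) / (rate*c),
    so the realised censoring fraction matches the target in expectation.
    """
    n = len(t_event)
    if target_rate <= 0:
        return t_event, np.ones(n, dtype=int)

    def expected_censored(c):
        x = rates * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if expected_censored(mid) > target_rate:
            lo = mid  # too much censoring -> lengthen follow-up
        else:
            hi = mid
    c_max = np.sqrt(lo * hi)
    t_cens = rng.uniform(0.0, c_max, n)
    event = (t_event <= t_cens).astype(int)
    return np.minimum(t_event, t_cens), event


# ---------------------------------------------------------------------------
# Genomic file emission (MAF / SEG / BED round trip)
# ---------------------------------------------------------------------------


def simulate_genomic_files(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write MAF + SEG + BED files consistent with the cohort's ground truth.

    Mutation-event carriers get exactly one nonsynonymous MAF row each; CNV
    carriers get a segment covering the event gene with a log2 ratio beyond
    the default calling thresholds; non-carriers get a copy-neutral segment
    on the same interval.  Re-running aberration calling on these files
    recovers the planted AberrationMatrix exactly (for events at or above
    the recurrence threshold).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann = cohort.gene_annotation
    samples = list(cohort.bundle.samples)

    maf_rows = []
    seg_rows = []
    for ev in cohort.config.events:
        carriers = set(cohort.carrier_sets[ev.label])
        if ev.kind == "mut":
            for s in sorted(carriers):
                maf_rows.append((ev.gene, s, "Missense_Mutation", "SNP"))
        else:
            value = AMP_SEG_VALUE if ev.kind == "amp" else DEL_SEG_VALUE
            row = ann.loc[ev.gene]
            for s in samples:
                seg_rows.append(
                    (s, row["chrom"], row["start"] + 1, row["end"],
                     value if s in carriers else 0.0)
                )
    if not seg_rows:  # keep the SEG non-empty: copy-neutral genome-wide segments
        for s in samples:
            seg_rows.append((s, "chr1", 1, int(ann["end"].max()), 0.0))

    maf_path = out_dir / "mutations.maf"
    pd.DataFrame(
        maf_rows,
        columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification", "Variant_Type"],
    ).to_csv(maf_path, sep="\t", index=False)

    seg_path = out_dir / "segments.seg"
    pd.DataFrame(
        seg_rows, columns=["Sample", "chrom", "start", "end", "value"]
    ).to_csv(seg_path, sep="\t", index=False)

    bed_path = out_dir / "genes.bed"
    ann.reset_index()[["chrom", "start", "end", "gene"]].to_csv(
        bed_path, sep="\t", index=False, header=False
    )
    return {"maf": maf_path, "seg": seg_path, "bed": bed_path}


def write_cohort_dir(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the full bundle (expression/clinical/survival/aberrations),
    genomic files, and ground truth to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = simulate_genomic_files(cohort, out_dir)
    b = cohort.bundle
    for name, frame, label in [
        ("expression", b.expression, "gene"),
        ("clinical", b.clinical, "sample"),
        ("survival", b.survival, "sample"),
        ("aberrations", b.aberrations, "sample"),
    ]:
        p = out_dir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index_label=label)
        paths[name] = p
    truth_path = out_dir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump(cohort.truth_dict(), fh)
    paths["truth"] = truth_path
    return paths
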