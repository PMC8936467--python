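"""Sample-specific BASE scores for weighted gene signatures.

BASE ("Binding Association with Sorted Expression") contrasts a weighted
foreground with a complementary background cumulative curve over a sample's
sorted expression profile:

1. Each gene is centred by its cohort median; the sample's genes are ranked
   by signed centred value (most up-regulated first) and the magnitudes
   g_k = |centred value| of the ranked genes form the profile.
2. With weights w aligned to the ranking,

       f(i) = sum_{k<=i} g_k w_k / sum_k g_k w_k
       b(i) = sum_{k<=i} g_k (1-w_k) / sum_k g_k (1-w_k)

   and the signed value of f - b at its largest absolute excursion is the
   raw score (computed separately for the w+ and the w- vector).
3. Each raw score is normalised against a permutation null obtained by
   recomputing it on random orderings of the profile (gene/weight pairs
   shuffled jointly), by default dividing by the mean |null| deviation.
4. The final score is normalised Score+ minus normalised Score-.  High
   scores mean the sample's deregulation pattern resembles event carriers.

Immune infiltration scores use the same statistic with weights derived from
cell-type-specific reference profiles (marker specificity).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .signature_model import SignatureWeightSet

logger = logging.getLogger("basepro.scoring")


# ---------------------------------------------------------------------------
# Profile preparation
# ---------------------------------------------------------------------------


def prepare_profile(expr: pd.DataFrame, sample: str) -> tuple[pd.Index, np.ndarray]:
    """Median-centred, rank-ordered magnitude profile for one sample.

    Genes are centred by their cohort median and ordered by signed centred
    value, decreasing (so +2 ranks before -3 despite the smaller magnitude);
    the returned ``g`` holds absolute centred values in that order.
    """
    if expr.shape[1] < 2:
        raise ValueError(
            "gene-wise median centring needs >= 2 samples; provide an external "
            "reference median for single-sample use"
        )
    centred = expr[sample].to_numpy(float) - np.median(expr.to_numpy(float), axis=1)
    order = np.argsort(-centred, kind="stable")
    return expr.index[order], np.abs(centred[order])


# ---------------------------------------------------------------------------
# The BASE statistic
# ---------------------------------------------------------------------------


@dataclass
class BaseScoreResult:
    score: float  # normalised Score+ - normalised Score-
    score_plus: float  # raw signed maximum deviation, w+ side
    score_minus: float
    norm_plus: float
    norm_minus: float
    null_plus: np.ndarray  # permutation-null deviations, one per permutation
    null_minus: np.ndarray
    trace: dict | None = None  # observed f/b curves per side, if requested


def make_permutations(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    """The permutation stream: row t is ``rng.permutation(n)`` drawn in order."""
    return np.stack([rng.permutation(n) for _ in range(n_perm)])


def _signed_max(dev: np.ndarray) -> np.ndarray | float:
    """Value of f-b at its largest |f-b| (sign kept; positive wins exact ties)."""
    hi = dev.max(axis=-1)
    lo = dev.min(axis=-1)
    return np.where(hi >= -lo, hi, lo)


def _side(g, w, perms):
    """Observed signed max deviation and its permutation null for one side.

    Uses the identity f(i) - b(i) = cumsum(g * (w*(1/F + 1/B) - 1/B))_i with
    F = sum g*w and B = sum g*(1-w), so each side costs one cumulative sum;
    the null jointly permutes the gene/weight pairs.
    """
    if w.max(initial=0.0) == w.min(initial=0.0):
        # constant weights: f == b identically, deviation is exactly zero
        return 0.0, np.zeros(perms.shape[0]), None
    F = float(np.dot(g, w))
    B = float(g.sum()) - F
    if F <= 0 or B <= 0:
        return 0.0, np.zeros(perms.shape[0]), None
    q = g * (w * (1.0 / F + 1.0 / B) - 1.0 / B)
    dev = np.cumsum(q)
    null = _signed_max(np.cumsum(q[perms], axis=1))
    return float(_signed_max(dev)), null, dev


def base_score(
    g: np.ndarray,
    w_plus: np.ndarray,
    w_minus: np.ndarray,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    perms: np.ndarray | None = None,
    null_norm: str = "mean_abs",
    trace: bool = False,
) -> BaseScoreResult:
    """BASE score of one ranked profile ``g`` against aligned weight vectors.

    ``w_plus``/``w_minus`` must already be aligned to the ranking of ``g``.
    The permutation null shuffles gene/weight pairs jointly; the same
    permutations serve both sides.  Pass either ``rng`` (permutations drawn
    as ``rng.permutation(n)``, ``n_perm`` times) or an explicit ``perms``
    index matrix.  ``null_norm`` is ``mean_abs`` (divide by mean |null|) or
    ``zscore`` ((obs - null mean) / null sd).
    """
    g = np.asarray(g, float)
    n = g.size
    if perms is None:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = rng if rng is not None else np.random.default_rng()
        perms = make_permutations(rng, n_perm, n)
    if np.all(g == 0):
        logger.warning("flat profile: BASE score defined as 0")
        zeros = np.zeros(perms.shape[0])
        return BaseScoreResult(0.0, 0.0, 0.0, 0.0, 0.0, zeros, zeros.copy())

    obs_p, null_p, dev_p = _side(g, np.asarray(w_plus, float), perms)
    obs_m, null_m, dev_m = _side(g, np.asarray(w_minus, float), perms)
    if dev_p is None and dev_m is None:
        logger.warning("all weights zero (or degenerate): BASE score defined as 0")

    norm_p = _normalise(obs_p, null_p, null_norm)
    norm_m = _normalise(obs_m, null_m, null_norm)
    result = BaseScoreResult(
        score=norm_p - norm_m,
        score_plus=obs_p,
        score_minus=obs_m,
        norm_plus=norm_p,
        norm_minus=norm_m,
        null_plus=null_p,
        null_minus=null_m,
    )
    if trace:
        zeros = np.zeros_like(g)
        result.trace = {
            "dev_plus": dev_p if dev_p is not None else zeros,
            "dev_minus": dev_m if dev_m is not None else zeros,
        }
    return result


def _normalise(obs: float, null: np.ndarray, null_norm: str) -> float:
    if null_norm == "mean_abs":
        scale = float(np.mean(np.abs(null)))
        return obs / scale if scale > 0 else 0.0
    if null_norm == "zscore":
        sd = float(np.std(null))
        return (obs - float(np.mean(null))) / sd if sd > 0 else 0.0
    raise ValueError(f"unknown null_norm {null_norm!r}")


# ---------------------------------------------------------------------------
# Cohort scoring
# ---------------------------------------------------------------------------


def _fingerprint(ws: SignatureWeightSet) -> int:
    """Stable 32-bit content hash of a weight set (labels excluded)."""
    h = hashlib.sha256()
    h.update("\x00".join(map(str, ws.genes)).encode())
    h.update(np.ascontiguousarray(ws.w_plus.to_numpy(float)).tobytes())
    h.update(np.ascontiguousarray(ws.w_minus.to_numpy(float)).tobytes())
    return int.from_bytes(h.digest()[:4], "little")


def score_cohort(
    expr: pd.DataFrame,
    weight_sets: Mapping[str, SignatureWeightSet],
    n_perm: int = 1000,
    seed: int = 0,
    null_norm: str = "mean_abs",
    share_permutations: bool = False,
) -> pd.DataFrame:
    """Score every sample against every weight set; samples x sets DataFrame.

    Permutation substreams are keyed on (sample position, weight-set content
    fingerprint): independent across distinct signatures, and identical for
    duplicated weight sets regardless of their labels.  With
    ``share_permutations`` one substream per sample serves all weight sets
    (faster; changes scores at the Monte-Carlo-noise level).
    """
    if not weight_sets:
        raise ValueError("need at least one weight set")
    genes = expr.index
    n = len(genes)
    aligned: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for name, ws in weight_sets.items():
        missing = ws.genes.difference(genes)
        if len(missing):
            logger.info("%s: %d weight gene(s) absent from expression, dropped", name, len(missing))
        wp = ws.w_plus.reindex(genes, fill_value=0.0).to_numpy(float)
        wm = ws.w_minus.reindex(genes, fill_value=0.0).to_numpy(float)
        if wp.max(initial=0.0) == 0.0 and wm.max(initial=0.0) == 0.0:
            raise ValueError(f"{name}: no overlapping genes with nonzero weight")
        aligned[name] = (wp, wm, _fingerprint(ws))

    median = np.median(expr.to_numpy(float), axis=1)
    centred_all = expr.to_numpy(float) - median[:, None]
    scores = pd.DataFrame(
        np.zeros((expr.shape[1], len(aligned))), index=expr.columns, columns=list(aligned)
    )
    arange = np.arange(n)
    for i, sample in enumerate(expr.columns):
        centred = centred_all[:, i]
        order = np.argsort(-centred, kind="stable")
        g = np.abs(centred[order])
        if share_permutations:
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
            perms = rng.permuted(np.tile(arange, (n_perm, 1)), axis=1)
        for name, (wp, wm, fp) in aligned.items():
            if not share_permutations:
                rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i, fp)))
                perms = rng.permuted(np.tile(arange, (n_perm, 1)), axis=1)
            result = base_score(g, wp[order], wm[order], perms=perms, null_norm=null_norm)
            scores.iloc[i, scores.columns.get_loc(name)] = result.score
    return scores


def permutation_control_scores(
    expr: pd.DataFrame,
    weight_set: SignatureWeightSet,
    n_shuffles: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
    null_norm: str = "mean_abs",
) -> pd.DataFrame:
    """Negative-control scores with the gene-weight correspondence destroyed.

    For every sample and every control replicate the pairing between the
    expression profile and the weight vectors is shuffled independently
    before scoring, so the resulting scores carry no signature information
    and any phenotype discrimination they show is chance.  (A single shuffle
    shared across the cohort is not a clean control: it defines a fixed
    arbitrary signature that can retain chance discrimination on strongly
    structured profiles.)  Returns a samples x replicates DataFrame.
    """
    genes = expr.index
    wp_full = weight_set.w_plus.reindex(genes, fill_value=0.0).to_numpy(float)
    wm_full = weight_set.w_minus.reindex(genes, fill_value=0.0).to_numpy(float)
    median = np.median(expr.to_numpy(float), axis=1)
    centred_all = expr.to_numpy(float) - median[:, None]
    n = len(genes)
    out = pd.DataFrame(
        np.zeros((expr.shape[1], n_shuffles)),
        index=expr.columns,
        columns=[f"shuffle{r}" for r in range(n_shuffles)],
    )
    arange = np.arange(n)
    for i in range(expr.shape[1]):
        centred = centred_all[:, i]
        order = np.argsort(-centred, kind="stable")
        g = np.abs(centred[order])
        # the null permutations are shared across replicates of a sample;
        # only the pairing shuffle differs per replicate
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        perms = rng.permuted(np.tile(arange, (n_perm, 1)), axis=1)
        for r in range(n_shuffles):
            pairing = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(i, r))
            ).permutation(n)
            res = base_score(
                g, wp_full[order][pairing], wm_full[order][pairing],
                perms=perms, null_norm=null_norm,
            )
            out.iloc[i, r] = res.score
    return out


# ---------------------------------------------------------------------------
# Immune weight derivation
# ---------------------------------------------------------------------------


def derive_immune_weights(panel, top_k: int = 100) -> dict[str, SignatureWeightSet]:
    """Marker-specificity weights per immune cell type.

    For cell type c, a gene's specificity is its reference expression in c
    minus the maximum across the other types (log scale); the ``top_k``
    genes with positive specificity get w+ = s / max(s); everything else is
    zero (w- is identically zero: infiltration only adds transcripts).
    """
    profiles = panel.profiles if hasattr(panel, "profiles") else panel
    if profiles.shape[0] < 2:
        raise ValueError("need at least two cell types")
    out: dict[str, SignatureWeightSet] = {}
    for cell in profiles.index:
        s = profiles.loc[cell] - profiles.drop(index=cell).max(axis=0)
        positive = s[s > 0]
        if len(positive) < top_k:
            logger.warning(
                "%s: only %d gene(s) with positive specificity (top_k=%d)",
                cell, len(positive), top_k,
            )
        # stable sort: ties keep gene-universe order, so selection is deterministic
        chosen = positive.sort_values(ascending=False, kind="stable")[:top_k]
        w_plus = pd.Series(0.0, index=profiles.columns)
        if len(chosen):
            w_plus[chosen.index] = chosen / positive.max()
        out[cell] = SignatureWeightSet(
            name=cell, w_plus=w_plus, w_minus=pd.Series(0.0, index=profiles.columns)
        )
    return out


# ---------------------------------------------------------------------------
# Signature validation (ROC / AUC)
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def mann_whitney_auc(scores, status) -> float:
    """AUC as the Mann-Whitney probability that a carrier outscores a
    non-carrier, ties counted 1/2."""
    scores = np.asarray(scores, float)
    status = np.asarray(status).astype(bool)
    n1, n0 = int(status.sum()), int((~status).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    return float((ranks[status].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def validate_signature(scores, status) -> RocResult:
    """ROC curve plus Mann-Whitney AUC of scores against binary status."""
    auc = mann_whitney_auc(scores, status)
    fpr, tpr, thr = roc_curve(np.asarray(status).astype(int), np.asarray(scores, float))
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=thr)
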