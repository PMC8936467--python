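"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a statistic from its definition (explicit loops,
naive cumulative sums, all-pairs enumeration) without sharing code with the
package paths it checks.
"""

import numpy as np
from scipy import stats


def naive_base_score(g, w_plus, w_minus, perms, null_norm="mean_abs"):
    """BASE score by direct evaluation of the f/b definitions.

    Shares only the permutation index matrix with the implementation under
    test; every cumulative curve is built explicitly.
    """
    g = np.asarray(g, float)

    def max_dev(gv, wv, F, B):
        f = np.cumsum(gv * wv) / F
        b = np.cumsum(gv * (1.0 - wv)) / B
        d = f - b
        hi, lo = d.max(), d.min()
        return hi if hi >= -lo else lo

    def side(w):
        w = np.asarray(w, float)
        if len(w) == 0 or w.max() == w.min():
            return 0.0, np.zeros(len(perms))
        F = float(np.sum(g * w))
        B = float(np.sum(g * (1.0 - w)))
        if F <= 0 or B <= 0:
            return 0.0, np.zeros(len(perms))
        obs = max_dev(g, w, F, B)
        null = np.array([max_dev(g[p], w[p], F, B) for p in perms])
        return obs, null

    def normalise(obs, null):
        if null_norm == "mean_abs":
            scale = np.mean(np.abs(null))
            return obs / scale if scale > 0 else 0.0
        sd = np.std(null)
        return (obs - np.mean(null)) / sd if sd > 0 else 0.0

    obs_p, null_p = side(w_plus)
    obs_m, null_m = side(w_minus)
    return normalise(obs_p, null_p) - normalise(obs_m, null_m)


def ols_fit_per_gene(y, X):
    """Normal-equations OLS with t-distribution p-values for one gene.

    ``X`` already includes the intercept column.  Returns (beta, p).
    """
    n, k = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta, p


def pairwise_auc(scores, status):
    """AUC by O(n^2) pair counting, ties 1/2."""
    scores = np.asarray(scores, float)
    status = np.asarray(status).astype(bool)
    pos = scores[status]
    neg = scores[~status]
    wins = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def pairwise_concordance(risk, time, event):
    """Concordance index by explicit pair enumeration.

    Comparable: both events, or one event strictly before the other's time.
    Concordant: higher risk with shorter survival; risk ties (and event-time
    ties) count 1/2.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int).astype(bool)
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                if not (event[i] and event[j]):
                    continue
                den += 1
                num += 0.5
                continue
            first, second = (i, j) if time[i] < time[j] else (j, i)
            if not event[first]:
                continue
            den += 1
            if risk[first] == risk[second]:
                num += 0.5
            elif risk[first] > risk[second]:
                num += 1.0
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def logrank_two_group(time, event, group):
    """Two-group log-rank chi-squared p by direct risk-table accumulation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group).astype(bool)
    u = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & group).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & group).sum()
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = u * u / v
    return float(stats.chi2.sf(chi2, 1))


def bootstrap_delong_p(probs_a, probs_b, labels, n_boot=10_000, seed=0):
    """Paired-bootstrap two-sided p for the AUC difference.

    Resamples samples with replacement, recomputes both AUCs, and converts
    the observed difference to a normal-approximation p using the bootstrap
    standard error (matching the asymptotic test's null).
    """
    rng = np.random.default_rng(seed)
    probs_a = np.asarray(probs_a, float)
    probs_b = np.asarray(probs_b, float)
    labels = np.asarray(labels).astype(bool)
    n = len(labels)

    def fast_auc(x, y):
        r = stats.rankdata(x)
        n1 = y.sum()
        return (r[y].sum() - n1 * (n1 + 1) / 2) / (n1 * (n - n1))

    obs = fast_auc(probs_a, labels) - fast_auc(probs_b, labels)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        y = labels[idx]
        if y.all() or not y.any():
            diffs[b] = np.nan
            continue
        diffs[b] = fast_auc(probs_a[idx], y) - fast_auc(probs_b[idx], y)
    se = np.nanstd(diffs)
    z = obs / se
    return float(2.0 * stats.norm.sf(abs(z)))
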