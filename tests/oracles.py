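"""Independent numerical oracles used only by the tests.

These deliberately avoid the package's production code paths: the
uniformization series checks the scaling-and-squaring matrix exponential,
sums-of-squares arithmetic checks the ANOVA implementations, and pairwise
comparison counting checks the trapezoidal AUC.
"""

import itertools

import numpy as np


def uniformization_probability(Q, t, tol=1e-14, max_terms=500):
    """P(t) by the uniformization (randomization) series.

    With lam >= max_i |Q_ii| and M = I + Q/lam (a stochastic matrix),
    P(t) = sum_k Poisson(k; lam*t) * M^k.  Truncated when the remaining
    Poisson mass drops below `tol`.
    """
    Q = np.asarray(Q, dtype=float)
    m = Q.shape[0]
    lam = float(np.max(-np.diag(Q)))
    if lam == 0.0:
        return np.eye(m)
    M = np.eye(m) + Q / lam
    mu = lam * t
    P = np.zeros((m, m))
    Mk = np.eye(m)
    weight = np.exp(-mu)  # Poisson(0)
    cum = 0.0
    for k in range(max_terms):
        P += weight * Mk
        cum += weight
        if 1.0 - cum < tol:
            break
        Mk = Mk @ M
        weight *= mu / (k + 1)
    return P


def anova_f_from_sums_of_squares(groups):
    """Classic one-way F statistic by direct sums-of-squares arithmetic."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    k, N = len(groups), len(allv)
    return (ssb / (k - 1)) / (ssw / (N - k))


def auc_by_pairwise_comparison(scores, labels):
    """AUC as the Mann-Whitney probability: over all (positive, negative)
    pairs, the fraction where the positive scores higher, ties counting 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p, n in itertools.product(pos, neg):
        if p > n:
            wins += 1.0
        elif p == n:
            wins += 0.5
    return wins / (len(pos) * len(neg))


def permutation_anova_p(groups, n_perm, rng):
    """Monte-Carlo permutation p-value for the classic one-way F."""
    sizes = [len(g) for g in groups]
    allv = np.concatenate([np.asarray(g, float) for g in groups])
    obs = anova_f_from_sums_of_squares(groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(allv)
        parts = np.split(perm, np.cumsum(sizes)[:-1])
        if anova_f_from_sums_of_squares(parts) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)
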