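"""Independent brute-force oracles used by the test suite.

Each function re-derives a published formula from scratch (plain loops,
explicit matrices, its own root finder) so the package implementation can
be held against it at tight tolerances.
"""

import itertools

import numpy as np
from scipy import special
from scipy.optimize import brentq
from scipy.stats import rankdata, t as t_dist


def enumeration_rank_sum_p(x, y):
    """Exact two-sided Wilcoxon p by full enumeration over rank subsets."""
    pooled = np.concatenate([x, y])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n1 = len(x)
    observed = ranks[:n1].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, n1)]
    total = len(sums)
    lower = sum(s <= observed for s in sums) / total
    upper = sum(s >= observed for s in sums) / total
    return min(1.0, 2.0 * min(lower, upper))


def step_up_bh(p):
    """Literal evaluation of q_(i) = min_{j>=i} p_(j) * m / j in input order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = running
    return adj


def brute_force_tmm_factor(counts, ref_idx, sample_idx):
    """Scalar re-evaluation of the TMM trim-and-weight formula (one sample)."""
    lib = counts.sum(axis=0)
    obs, ref = counts[:, sample_idx], counts[:, ref_idx]
    m_vals, a_vals, weights = [], [], []
    for g in range(counts.shape[0]):
        if obs[g] > 0 and ref[g] > 0:
            po, pr = obs[g] / lib[sample_idx], ref[g] / lib[ref_idx]
            m_vals.append(np.log2(po / pr))
            a_vals.append(0.5 * np.log2(po * pr))
            weights.append(
                1.0
                / (
                    (lib[sample_idx] - obs[g]) / (lib[sample_idx] * obs[g])
                    + (lib[ref_idx] - ref[g]) / (lib[ref_idx] * ref[g])
                )
            )
    m_vals, a_vals, weights = map(np.array, (m_vals, a_vals, weights))
    n = len(m_vals)
    lo_m = np.floor(n * 0.3) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * 0.05) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m_vals), rankdata(a_vals)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    return 2.0 ** (np.sum(m_vals[keep] * weights[keep]) / np.sum(weights[keep]))


def brute_force_tmm(counts):
    """All TMM factors (reference choice + per-sample factor + rescale)."""
    lib = counts.sum(axis=0)
    n_samples = counts.shape[1]
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    raw = np.array([brute_force_tmm_factor(counts, ref, j) for j in range(n_samples)])
    return raw / np.exp(np.mean(np.log(raw)))


def brute_force_moderated(y, w, g, df):
    """Explicit-matrix WLS + moment-matched variance shrinkage + step-up BH.

    Returns (t, p, adj_p); the prior df is solved with brentq on the
    trigamma equation, independent of the package's Newton solver.
    """
    n_genes = y.shape[0]
    x_design = np.column_stack([np.ones_like(g), g])
    beta1, u, s2 = np.zeros(n_genes), np.zeros(n_genes), np.zeros(n_genes)
    for i in range(n_genes):
        wi = np.diag(w[i])
        xtx = x_design.T @ wi @ x_design
        beta = np.linalg.solve(xtx, x_design.T @ wi @ y[i])
        resid = y[i] - x_design @ beta
        s2[i] = float(resid @ wi @ resid) / df
        beta1[i] = beta[1]
        u[i] = np.sqrt(np.linalg.inv(xtx)[1, 1])
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    evar = e.var(ddof=1) - special.polygamma(1, df / 2)
    if evar <= 0:
        raise AssertionError("degenerate fixture: no between-gene variance signal")
    half_d0 = brentq(lambda v: special.polygamma(1, v) - evar, 1e-6, 1e8, xtol=1e-14)
    d0 = 2 * half_d0
    s0 = np.exp(e.mean() + special.digamma(half_d0) - np.log(half_d0))
    post = (d0 * s0 + df * s2) / (d0 + df)
    t = beta1 / (u * np.sqrt(post))
    p = 2 * t_dist.sf(np.abs(t), df + d0)
    return t, p, step_up_bh(p)
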