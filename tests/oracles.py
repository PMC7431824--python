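"""Independent reference implementations used only to check the package.

Each oracle is deliberately written in the most direct way possible
(enumeration, closed forms, scalar loops) and shares no code with the
implementation it checks.
"""

import math

import numpy as np


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    likelihood does not exceed the observed table's (minimum-likelihood
    two-sided rule).
    """
    n = a + b + c + d
    row = a + b
    col = a + c
    denom = math.comb(n, col)
    lo = max(0, col - (n - row))
    hi = min(row, col)
    pmf = {
        x: math.comb(row, x) * math.comb(n - row, col - x) / denom
        for x in range(lo, hi + 1)
    }
    cutoff = pmf[a] * (1 + 1e-9)
    return min(1.0, sum(p for p in pmf.values() if p <= cutoff))


def bh_stepup(p):
    """Benjamini-Hochberg adjusted values by the literal step-up rule."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return np.asarray(q)


def kde_sum_of_gaussians(sites, bandwidth, grid):
    """Scalar-loop Gaussian KDE evaluation."""
    out = []
    n = len(sites)
    norm = 1.0 / (n * bandwidth * math.sqrt(2 * math.pi))
    for g in grid:
        total = 0.0
        for s in sites:
            z = (g - s) / bandwidth
            total += math.exp(-0.5 * z * z)
        out.append(norm * total)
    return np.asarray(out)


def ols_normal_equations(x, y):
    """Slope/intercept/R^2 from the closed-form normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    resid = y - (intercept + slope * x)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else float("nan")
    return slope, intercept, r2


def brute_force_dmrs(site_results, lambda_bp=1000, min_cpgs=3,
                     min_mean_abs_delta=10.0, alpha=0.05):
    """O(n^2) region caller: pairwise chaining + maximal merging.

    Significant sites are linked whenever any pair lies within lambda_bp;
    components are grown to transitive closure by repeated merging, then
    each component is filtered per direction.
    """
    sig = site_results[
        (site_results.p_value <= alpha) & (site_results.delta != 0)
    ]
    regions = []
    for chrom in sorted(set(sig.chrom)):
        sub = sig[sig.chrom == chrom]
        pos = sub.pos.to_numpy()
        delta = sub.delta.to_numpy()
        n = len(pos)
        adjacency = [
            [j for j in range(n) if j != i and abs(int(pos[i]) - int(pos[j])) <= lambda_bp]
            for i in range(n)
        ]
        comp = [-1] * n
        n_comp = 0
        for start in range(n):
            if comp[start] != -1:
                continue
            stack = [start]
            comp[start] = n_comp
            while stack:
                i = stack.pop()
                for j in adjacency[i]:
                    if comp[j] == -1:
                        comp[j] = n_comp
                        stack.append(j)
            n_comp += 1
        for label in range(n_comp):
            idx = [i for i in range(n) if comp[i] == label]
            for direction, sign in (("hyper", 1), ("hypo", -1)):
                members = [i for i in idx if sign * delta[i] > 0]
                if len(members) < min_cpgs:
                    continue
                mean_delta = float(np.mean([delta[i] for i in members]))
                if abs(mean_delta) < min_mean_abs_delta:
                    continue
                mpos = [int(pos[i]) for i in members]
                regions.append(
                    (chrom, min(mpos), max(mpos) + 1, direction,
                     len(members), round(mean_delta, 9), tuple(sorted(mpos)))
                )
    return sorted(regions)
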