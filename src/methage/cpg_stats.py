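"""Per-CpG methylation levels and differential tests.

Two designs are supported, mirroring the two tissue protocols: an unpaired
t-test on per-sample methylation percentages (replicated RRBS-style data)
and a pooled-count Fisher exact test (single-embryo WGBS-style data, where
within-group replication of percentages is not the tested unit).

The case-minus-control sign convention is fixed: delta = mean(APA) -
mean(young); positive delta is hypermethylation in the aged group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .meth_io import APA, YOUNG, MethylationDataset

RESULT_COLUMNS = [
    "chrom", "pos", "mean_young", "mean_apa", "delta", "p_value",
    "significant", "direction",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_COVERAGE = 5


def theoretical_resolution(min_coverage: int) -> float:
    """Smallest nonzero methylation step (in %) representable at minimum coverage.

    One methylated read out of ``min_coverage`` total reads; 100/5 = 20%
    at the default 5x filter.
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    return 100.0 / min_coverage


def site_methylation_percent(n_meth, n_unmeth):
    """Methylated reads / total reads x 100. Errors on zero total coverage."""
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    total = n_meth + n_unmeth
    if (total <= 0).any():
        raise ValueError("methylation percent undefined at zero total coverage")
    result = 100.0 * n_meth / total
    return float(result) if result.ndim == 0 else result


def _direction(delta: np.ndarray, significant: np.ndarray) -> np.ndarray:
    out = np.full(delta.shape, "none", dtype=object)
    out[significant & (delta > 0)] = "hyper"
    out[significant & (delta < 0)] = "hypo"
    return out


def _assemble(ds, mean_young, mean_apa, p, alpha) -> pd.DataFrame:
    delta = mean_apa - mean_young
    significant = p <= alpha
    return pd.DataFrame(
        {
            "chrom": ds.chrom,
            "pos": ds.pos,
            "mean_young": mean_young,
            "mean_apa": mean_apa,
            "delta": delta,
            "p_value": p,
            "significant": significant,
            "direction": _direction(delta, significant),
        },
        columns=RESULT_COLUMNS,
    )


def test_sites_ttest(
    dataset: MethylationDataset,
    alpha: float = DEFAULT_ALPHA,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided unpaired t-test on per-sample methylation percentages.

    Welch's unequal-variance form by default (``equal_var=True`` restores
    the pooled-variance Student form). Degenerate sites where both groups
    are constant get p = 1 when the means agree and p = 0 otherwise.
    """
    iy = dataset.group_indices(YOUNG)
    ia = dataset.group_indices(APA)
    if len(iy) < 2 or len(ia) < 2:
        raise ValueError("t-test requires >=2 samples per group")
    pct = dataset.percent()
    if np.isnan(pct).any():
        raise ValueError("zero-coverage sites present; apply the coverage filter first")
    young, apa = pct[:, iy], pct[:, ia]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(apa, young, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    mean_young = young.mean(axis=1)
    mean_apa = apa.mean(axis=1)
    delta = mean_apa - mean_young
    degenerate = ~np.isfinite(p)
    p[degenerate & (delta == 0)] = 1.0
    p[degenerate & (delta != 0)] = 0.0
    return _assemble(dataset, mean_young, mean_apa, p, alpha)


def test_sites_fisher(
    dataset: MethylationDataset,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-site Fisher exact test on counts pooled within each group.

    Each site's 2x2 table is (group) x (methylated / unmethylated reads)
    with counts summed across the samples of each group; the two-sided
    minimum-likelihood p-value is reported. Group means are still computed
    from per-sample percentages, so delta matches the t-test design.
    """
    iy = dataset.group_indices(YOUNG)
    ia = dataset.group_indices(APA)
    my = dataset.n_meth[:, iy].sum(axis=1)
    uy = dataset.n_unmeth[:, iy].sum(axis=1)
    ma = dataset.n_meth[:, ia].sum(axis=1)
    ua = dataset.n_unmeth[:, ia].sum(axis=1)
    p = np.ones(dataset.n_sites)
    cache: dict[tuple[int, int, int, int], float] = {}
    for i in range(dataset.n_sites):
        key = (int(ma[i]), int(ua[i]), int(my[i]), int(uy[i]))
        pv = cache.get(key)
        if pv is None:
            pv = stats.fisher_exact([[key[0], key[1]], [key[2], key[3]]])[1]
            cache[key] = pv
        p[i] = pv
    pct = dataset.percent()
    if np.isnan(pct).any():
        raise ValueError("zero-coverage sites present; apply the coverage filter first")
    mean_young = pct[:, iy].mean(axis=1)
    mean_apa = pct[:, ia].mean(axis=1)
    return _assemble(dataset, mean_young, mean_apa, p, alpha)


def write_site_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
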