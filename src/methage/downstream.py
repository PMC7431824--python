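"""Downstream analyses: hierarchical clustering of DMR CpGs, validation-style
group comparisons, age regression, and the 450K beta-matrix reanalysis
adapter that routes array data through the same DMR caller with a relaxed
(>= 2 significant probes) membership rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .cpg_stats import RESULT_COLUMNS, _direction
from .dmr_caller import DMR, DMRCallerConfig, call_dmrs
from .meth_io import APA, YOUNG, BetaMatrix, MethylationDataset

logger = logging.getLogger(__name__)

ARRAY_CALLER_CONFIG = DMRCallerConfig(min_cpgs=2)


@dataclass(frozen=True)
class RegressionFit:
    """Simple linear regression of methylation (%) on age (years)."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float


@dataclass
class ClusterResult:
    z_matrix: pd.DataFrame        # CpGs x samples, row z-scores
    linkage: np.ndarray
    labels: np.ndarray            # 2-cluster cut, one label per sample
    n_dropped_rows: int = 0


def cluster_dmr_cpgs(
    dataset: MethylationDataset,
    dmrs: Sequence[DMR],
    method: str = "pearson",
) -> ClusterResult:
    """Cluster samples on z-scored DMR member CpG percentages.

    Rows are the member CpGs of the called regions, z-scored per row so a
    positive score is hypermethylation relative to the site mean. Sample
    distance is 1 - correlation between sample columns (Pearson by default,
    ``method='spearman'`` for the rank variant), agglomerated with average
    linkage; the 2-cluster cut labels are returned.
    """
    if dataset.n_samples < 2:
        raise ValueError("clustering requires >=2 samples")
    members: dict[str, set[int]] = {}
    for d in dmrs:
        members.setdefault(d.chrom, set()).update(d.member_positions)
    mask = np.array(
        [c in members and p in members[c] for c, p in zip(dataset.chrom, dataset.pos)]
    )
    if mask.sum() < 2:
        raise ValueError("need >=2 DMR member CpGs to cluster")
    pct = dataset.percent()[mask]
    index = [f"{c}:{p}" for c, p in zip(dataset.chrom[mask], dataset.pos[mask])]

    sd = pct.std(axis=1, ddof=0)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} constant CpG rows (z-score undefined)")
    pct = pct[keep]
    index = [ix for ix, k in zip(index, keep) if k]
    z = (pct - pct.mean(axis=1, keepdims=True)) / pct.std(axis=1, ddof=0, keepdims=True)

    cols = z if method == "pearson" else _rank_rows(z)
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(cols.T)
    # constant columns have undefined correlation; treat as uncorrelated
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = average(squareform(dist, checks=False))
    labels = fcluster(linkage, t=2, criterion="maxclust")
    return ClusterResult(
        z_matrix=pd.DataFrame(z, index=index, columns=dataset.sample_ids),
        linkage=linkage,
        labels=labels,
        n_dropped_rows=n_dropped,
    )


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, x)


def regress_meth_on_age(
    percent_by_sample: Sequence[float],
    age_by_sample: Sequence[float],
) -> RegressionFit:
    """OLS of methylation percentage on age; slope in % per year."""
    y = np.asarray(percent_by_sample, dtype=float)
    x = np.asarray(age_by_sample, dtype=float)
    if len(x) < 3:
        raise ValueError("regression requires >=3 samples with age")
    if np.ptp(x) == 0:
        raise ValueError("ages are constant; slope undefined")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
    )


def compare_groups(
    values_young: Sequence[float],
    values_apa: Sequence[float],
) -> tuple[float, float]:
    """Two-sided t-test and Mann-Whitney U p-values for a validation assay.

    The exact Mann-Whitney distribution is used for small tie-free groups
    (scipy's automatic policy); identical groups return p = 1 for both.
    """
    y = np.asarray(values_young, dtype=float)
    a = np.asarray(values_apa, dtype=float)
    if len(y) < 2 or len(a) < 2:
        raise ValueError("need >=2 values per group")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_p = float(stats.ttest_ind(a, y, equal_var=False).pvalue)
        u_p = float(stats.mannwhitneyu(a, y, alternative="two-sided").pvalue)
    if not np.isfinite(t_p):
        t_p = 1.0 if np.isclose(a.mean(), y.mean()) else 0.0
    if not np.isfinite(u_p):
        u_p = 1.0
    return t_p, u_p


def test_probes_ttest(
    beta_matrix: BetaMatrix,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-probe two-sided t-test on beta values between groups.

    delta is on the percent scale (100 x difference of group mean betas,
    APA-like group minus control) so array results flow through the same
    region caller and thresholds as sequencing results. Probes without
    coordinates are dropped (count logged).
    """
    probes = beta_matrix.probes
    located = probes.dropna(subset=["chrom", "pos"]).index.to_numpy()
    dropped = len(probes) - len(located)
    if dropped:
        logger.info("dropped %d probes without genomic coordinates", dropped)
    beta = beta_matrix.beta[located]
    chrom = probes.chrom.to_numpy()[located]
    pos = probes.pos.to_numpy()[located].astype(np.int64)

    iy = np.flatnonzero(beta_matrix.group == YOUNG)
    ia = np.flatnonzero(beta_matrix.group == APA)
    if len(iy) < 2 or len(ia) < 2:
        raise ValueError("t-test requires >=2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.asarray(
            stats.ttest_ind(beta[:, ia], beta[:, iy], axis=1, equal_var=equal_var).pvalue,
            dtype=float,
        )
    mean_young = 100.0 * beta[:, iy].mean(axis=1)
    mean_apa = 100.0 * beta[:, ia].mean(axis=1)
    delta = mean_apa - mean_young
    degenerate = ~np.isfinite(p)
    p[degenerate & (delta == 0)] = 1.0
    p[degenerate & (delta != 0)] = 0.0

    order = np.lexsort((pos, chrom))
    df = pd.DataFrame(
        {
            "chrom": chrom[order],
            "pos": pos[order],
            "mean_young": mean_young[order],
            "mean_apa": mean_apa[order],
            "delta": delta[order],
            "p_value": p[order],
        }
    )
    df["significant"] = df.p_value <= alpha
    df["direction"] = _direction(df.delta.to_numpy(), df.significant.to_numpy())
    return df[RESULT_COLUMNS]


def reanalyze_beta_matrix(
    beta_matrix: BetaMatrix,
    alpha: float = 0.05,
    caller_config: DMRCallerConfig = ARRAY_CALLER_CONFIG,
) -> list[DMR]:
    """Array-mode reanalysis: per-probe t-test, then the DMR caller with the
    relaxed >= 2 significant-probe membership rule (other thresholds, 1 kb
    window and 10% mean-difference filter, unchanged)."""
    site_results = test_probes_ttest(beta_matrix, alpha=alpha)
    return call_dmrs(site_results, caller_config)
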