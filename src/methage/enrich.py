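"""2x2 enrichment statistics: Fisher exact tests with odds ratios and Woolf
confidence intervals, gene-set overlaps, sperm-blastocyst directional
overlap, per-cytoband enrichment, and Benjamini-Hochberg correction.

Every gene-set test is performed against an explicit gene universe; query
and target sets are intersected with the universe before counting, since
the universe choice materially changes odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .meth_io import GeneModel, GenomicInterval


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 table with odds ratio, 95% CI, Fisher p and optional BH q.

    Cell layout: a = in both classifications, b = in first only,
    c = in second only, d = in neither.
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float | None = None
    testable: bool = True


def fisher_or_ci(a: int, b: int, c: int, d: int, label: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact test with cross-product OR and Woolf 95% CI.

    The Haldane-Anscombe +0.5 correction is applied to *all* cells for the
    OR and CI whenever any cell is zero; the p-value is always computed on
    the raw counts.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("2x2 cells must be non-negative")
    if sum(cells) == 0:
        raise ValueError("all-zero 2x2 table")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if 0 in cells:
        aa, bb, cc, dd = (x + 0.5 for x in cells)
    else:
        aa, bb, cc, dd = (float(x) for x in cells)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(or_) - 1.96 * se)
    ci_high = math.exp(math.log(or_) + 1.96 * se)
    return EnrichmentResult(
        label=label, a=a, b=b, c=c, d=d,
        odds_ratio=or_, ci_low=ci_low, ci_high=ci_high, p_value=p,
    )


def geneset_enrichment(
    query_genes: Iterable[str],
    target_set: Iterable[str],
    universe: Iterable[str],
    label: str = "",
) -> EnrichmentResult:
    """Fisher enrichment of a query gene set against a target set.

    a = |query n target|, b = |query \\ target|, c = |target \\ query|,
    d = rest of the universe.
    """
    uni = {g.upper() for g in universe}
    if not uni:
        raise ValueError("empty gene universe")
    q = {g.upper() for g in query_genes} & uni
    t = {g.upper() for g in target_set} & uni
    a = len(q & t)
    b = len(q - t)
    c = len(t - q)
    d = len(uni) - a - b - c
    return fisher_or_ci(a, b, c, d, label=label)


def directional_overlap(
    sperm_annotated: Sequence,
    blast_annotated: Sequence,
    universe: Iterable[str],
) -> dict[str, tuple[EnrichmentResult, set[str]]]:
    """Sperm-blastocyst overlap of DMR-associated genes, per direction.

    For each direction d in {hyper, hypo}, the query is the set of genes
    with >=1 d-DMR in sperm and the target the same in blastocyst; "any"
    ignores direction. The per-direction overlap gene sets are returned
    alongside the statistics and are deliberately not deduplicated across
    directions: a gene with both a hyper and a hypo region counts in both.
    """
    def genes_for(annotated, direction):
        out: set[str] = set()
        for a in annotated:
            if direction == "any" or a.dmr.direction == direction:
                out |= a.genes
        return out

    results = {}
    for direction in ("hyper", "hypo", "any"):
        q = genes_for(sperm_annotated, direction)
        t = genes_for(blast_annotated, direction)
        res = geneset_enrichment(q, t, universe, label=f"overlap_{direction}")
        uni = {g.upper() for g in universe}
        results[direction] = (res, (q & t) & uni)
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up FDR-adjusted q-values, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_to_band_map(
    gene_models: Sequence[GeneModel],
    cytobands: Sequence[GenomicInterval],
) -> dict[str, str]:
    """Map each gene to the cytoband containing its promoter start site."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for band in cytobands:
        by_chrom.setdefault(band.chrom, []).append(band)
    mapping: dict[str, str] = {}
    for g in gene_models:
        hit = None
        for band in by_chrom.get(g.chrom, []):
            if band.start <= g.tss < band.end:
                hit = band
                break
        if hit is None:
            raise ValueError(
                f"gene {g.symbol} TSS {g.chrom}:{g.tss} falls outside all cytobands"
            )
        mapping[g.symbol] = f"{g.chrom}:{hit.name}"
    return mapping


def cytoband_enrichment(
    dmr_genes: Iterable[str],
    gene_models: Sequence[GeneModel],
    cytobands: Sequence[GenomicInterval],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-band Fisher enrichment of DMR-gene density, BH-adjusted.

    Genes are localized to bands by promoter start site. A band is called
    significant iff p <= alpha and q <= q_threshold.
    """
    if universe is None:
        universe = {g.symbol for g in gene_models}
    uni = {g.upper() for g in universe}
    band_of = gene_to_band_map([g for g in gene_models if g.symbol in uni], cytobands)
    dmr = {g.upper() for g in dmr_genes} & uni

    bands = sorted({band_of[g] for g in uni})
    rows = []
    for band in bands:
        on_band = {g for g in uni if band_of[g] == band}
        a = len(dmr & on_band)
        b = len(dmr - on_band)
        c = len(on_band - dmr)
        d = len(uni) - a - b - c
        res = fisher_or_ci(a, b, c, d, label=band)
        rows.append(res)
    q = benjamini_hochberg([r.p_value for r in rows])
    frame = pd.DataFrame(
        {
            "band": [r.label for r in rows],
            "a": [r.a for r in rows],
            "b": [r.b for r in rows],
            "c": [r.c for r in rows],
            "d": [r.d for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p_value": [r.p_value for r in rows],
            "q_value": q,
        }
    )
    frame["significant"] = (frame.p_value <= alpha) & (frame.q_value <= q_threshold)
    return frame


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = list(results)
    return pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "a": [r.a for r in rows],
            "b": [r.b for r in rows],
            "c": [r.c for r in rows],
            "d": [r.d for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "p_value": [r.p_value for r in rows],
            "q_value": [r.q_value for r in rows],
            "testable": [r.testable for r in rows],
        }
    )
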