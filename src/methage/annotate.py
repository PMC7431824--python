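"""Genomic-context annotation of DMRs.

Island context follows the classic flanking definition: shores are the 2 kb
on either side of a CpG island, shelves the next 2 kb beyond the shores,
everything else open sea, with precedence island > shore > shelf so the
three context sets are pairwise disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dmr_caller import DMR, HYPER, HYPO
from .enrich import EnrichmentResult, fisher_or_ci
from .meth_io import GeneModel, GenomicInterval

ISLAND = "island"
SHORE = "shore"
SHELF = "shelf"
OPEN_SEA = "open_sea"
CONTEXT_PRECEDENCE = (ISLAND, SHORE, SHELF)

FLANK_BP = 2000
PROMOTER_UPSTREAM = 2000
PROMOTER_DOWNSTREAM = 500


# --- minimal interval algebra on (starts, ends) arrays ----------------------

def _merge(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s), np.asarray(out_e)


def _subtract(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Set difference a \\ b; both merged and sorted."""
    (as_, ae), (bs, be) = a, b
    out_s: list[int] = []
    out_e: list[int] = []
    j = 0
    for s, e in zip(as_, ae):
        cur = s
        while j < len(bs) and be[j] <= cur:
            j += 1
        k = j
        while k < len(bs) and bs[k] < e:
            if bs[k] > cur:
                out_s.append(cur)
                out_e.append(int(bs[k]))
            cur = max(cur, int(be[k]))
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(int(e))
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


def _expand(
    ivs: tuple[np.ndarray, np.ndarray], pad: int, chrom_length: int | None
) -> tuple[np.ndarray, np.ndarray]:
    s = np.maximum(ivs[0] - pad, 0)
    e = ivs[1] + pad
    if chrom_length is not None:
        e = np.minimum(e, chrom_length)
    return _merge(s, e)


def _contains(ivs: tuple[np.ndarray, np.ndarray], pos: int) -> bool:
    s, e = ivs
    i = np.searchsorted(s, pos, side="right") - 1
    return i >= 0 and pos < e[i]


class IslandContext:
    """Per-chromosome island/shore/shelf interval sets with point lookup."""

    def __init__(
        self,
        islands: Sequence[GenomicInterval],
        chrom_lengths: Mapping[str, int] | None = None,
        flank_bp: int = FLANK_BP,
    ):
        self._ctx: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in islands:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            clen = chrom_lengths.get(chrom) if chrom_lengths else None
            isl = _merge(
                np.asarray([i.start for i in ivs], dtype=np.int64),
                np.asarray([i.end for i in ivs], dtype=np.int64),
            )
            shore = _subtract(_expand(isl, flank_bp, clen), isl)
            shelf = _subtract(_subtract(_expand(isl, 2 * flank_bp, clen), isl), shore)
            self._ctx[chrom] = {ISLAND: isl, SHORE: shore, SHELF: shelf}

    def classify(self, chrom: str, pos: int) -> str:
        ctx = self._ctx.get(chrom)
        if ctx is None:
            return OPEN_SEA
        for label in CONTEXT_PRECEDENCE:
            if _contains(ctx[label], pos):
                return label
        return OPEN_SEA

    def intervals(self, chrom: str, label: str) -> list[tuple[int, int]]:
        ctx = self._ctx.get(chrom)
        if ctx is None:
            return []
        s, e = ctx[label]
        return list(zip(s.tolist(), e.tolist()))


def build_island_context(
    islands: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int] | None = None,
    flank_bp: int = FLANK_BP,
) -> IslandContext:
    return IslandContext(islands, chrom_lengths=chrom_lengths, flank_bp=flank_bp)


# --- gene / promoter association -------------------------------------------

def promoter_interval(
    gene: GeneModel,
    upstream: int = PROMOTER_UPSTREAM,
    downstream: int = PROMOTER_DOWNSTREAM,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS.

    On the + strand the window covers directed offsets [-upstream,
    +downstream) from the TSS; on the - strand the same offsets run toward
    decreasing coordinates, giving [tss - downstream + 1, tss + upstream + 1).
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream + 1, gene.tss + upstream + 1
    return GenomicInterval(gene.chrom, max(start, 0), max(end, 1), name=gene.symbol)


@dataclass(frozen=True)
class AnnotatedDMR:
    dmr: DMR
    island_context: str
    genes: frozenset[str]
    cytobands: frozenset[str]
    nucleosome_overlap: bool
    nucleosome_gene: bool = False


def _overlapping_names(
    dmr: DMR, intervals: Sequence[GenomicInterval]
) -> set[str]:
    span = GenomicInterval(dmr.chrom, dmr.start, dmr.end)
    return {
        iv.name for iv in intervals if iv.name is not None and span.overlaps(iv)
    }


def annotate_dmrs(
    dmrs: Sequence[DMR],
    islands: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    cytobands: Sequence[GenomicInterval],
    nucleosomes: Sequence[GenomicInterval] = (),
    nucleosome_genes: Iterable[str] = (),
    promoter_upstream: int = PROMOTER_UPSTREAM,
    promoter_downstream: int = PROMOTER_DOWNSTREAM,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[AnnotatedDMR]:
    """Attach island context, gene, cytoband and nucleosome annotations.

    A DMR is associated with a gene iff it overlaps the gene body or the
    strand-aware promoter window; one DMR may hit several genes. Island
    context is decided by member CpGs (highest-precedence context any member
    falls in). Cytobands must cover every DMR chromosome.
    """
    ctx = build_island_context(islands, chrom_lengths=chrom_lengths)
    band_chroms = {b.chrom for b in cytobands}
    nuc_genes = {g.upper() for g in nucleosome_genes}

    gene_regions: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        prom = promoter_interval(g, promoter_upstream, promoter_downstream)
        gene_regions.setdefault(g.chrom, []).append(
            (g.interval.start, g.interval.end, g.symbol)
        )
        gene_regions[prom.chrom].append((prom.start, prom.end, g.symbol))

    out: list[AnnotatedDMR] = []
    for dmr in dmrs:
        if dmr.chrom not in band_chroms:
            raise ValueError(
                f"chromosome {dmr.chrom} has DMRs but no cytobands; bands must "
                "partition every chromosome"
            )
        contexts = {ctx.classify(dmr.chrom, p) for p in dmr.member_positions}
        island_context = next(
            (c for c in CONTEXT_PRECEDENCE if c in contexts), OPEN_SEA
        )
        hit_genes = {
            sym
            for (s, e, sym) in gene_regions.get(dmr.chrom, [])
            if s < dmr.end and dmr.start < e
        }
        bands = _overlapping_names(dmr, [b for b in cytobands if b.chrom == dmr.chrom])
        nuc = any(
            n.chrom == dmr.chrom and n.start < dmr.end and dmr.start < n.end
            for n in nucleosomes
        )
        out.append(
            AnnotatedDMR(
                dmr=dmr,
                island_context=island_context,
                genes=frozenset(hit_genes),
                cytobands=frozenset(bands),
                nucleosome_overlap=nuc,
                nucleosome_gene=bool(hit_genes & nuc_genes),
            )
        )
    return out


def island_context_enrichment(
    annotated: Sequence[AnnotatedDMR],
) -> dict[str, EnrichmentResult]:
    """Per-context Fisher test of direction (hypo vs hyper) against context.

    Asks the Figure-1-style question: are hypomethylated regions
    preferentially located in a given context relative to hypermethylated
    ones? If one direction is absent the result is flagged untestable.
    """
    hypo = [a for a in annotated if a.dmr.direction == HYPO]
    hyper = [a for a in annotated if a.dmr.direction == HYPER]
    results: dict[str, EnrichmentResult] = {}
    for context in (*CONTEXT_PRECEDENCE, OPEN_SEA):
        if not hypo or not hyper:
            results[context] = EnrichmentResult(
                label=context, a=len([x for x in hypo if x.island_context == context]),
                b=0, c=0, d=0, odds_ratio=np.nan, ci_low=np.nan, ci_high=np.nan,
                p_value=np.nan, testable=False,
            )
            continue
        a = sum(x.island_context == context for x in hypo)
        b = len(hypo) - a
        c = sum(x.island_context == context for x in hyper)
        d = len(hyper) - c
        results[context] = fisher_or_ci(a, b, c, d, label=context)
    return results


def annotated_to_rows(annotated: Sequence[AnnotatedDMR]) -> list[dict]:
    rows = []
    for a in annotated:
        rows.append(
            {
                "chrom": a.dmr.chrom,
                "start": a.dmr.start,
                "end": a.dmr.end,
                "direction": a.dmr.direction,
                "n_sig_cpgs": a.dmr.n_sig_cpgs,
                "mean_delta": a.dmr.mean_delta,
                "island_context": a.island_context,
                "genes": ",".join(sorted(a.genes)),
                "cytobands": ",".join(sorted(a.cytobands)),
                "nucleosome_overlap": a.nucleosome_overlap,
                "nucleosome_gene": a.nucleosome_gene,
            }
        )
    return rows
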