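"""Synthetic bisulfite-count worlds with known spiked truth.

The generator emulates the structure of a sperm/embryo methylome cohort:
CpGs clustered densely inside CpG islands and sparse outside, a sperm-like
baseline (islands hypomethylated ~10%, background hypermethylated ~80%),
beta-binomial inter-individual noise on top of Poisson read depth, two
groups of six samples with ages drawn from the young (<=35) and advanced
paternal age (>=50) windows, and hyper/hypomethylated regions of >=3 CpGs
spiked into the case group at a known effect size. Matched gene models,
cytobands and nucleosome-retention regions are generated alongside so
annotation and enrichment stages can be scored against planted truth.

Islands chosen for hypomethylated spikes have their baseline raised to the
background level first (a "methylated island"), so a -30% effect is
representable without clamping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import meth_io
from .meth_io import (
    APA,
    YOUNG,
    BetaMatrix,
    GeneModel,
    GenomicInterval,
    MethylationDataset,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the stated synthetic world (defaults = cohort design)."""

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_islands: int = 20              # per chromosome
    island_length: int = 1_000
    cpgs_per_island: int = 10
    background_cpg_rate: float = 5e-5   # CpGs per bp outside islands
    island_baseline_meth: float = 10.0  # %
    background_baseline_meth: float = 80.0
    dispersion: float = 0.02         # beta-binomial rho; 0 = no overdispersion
    coverage_mean: float = 20.0
    n_young: int = 6
    n_apa: int = 6
    n_spiked_hyper: int = 4          # total across the genome
    n_spiked_hypo: int = 4
    effect_sizes: tuple[float, ...] = (30.0,)   # |delta %| applied to APA group
    age_young: tuple[float, float] = (25.0, 35.0)
    age_apa: tuple[float, float] = (50.0, 64.0)
    age_slope: float = 0.0           # optional % per year inside spiked regions
    n_genes_per_chrom: int = 40
    n_bands_per_chrom: int = 8
    nucleosome_gene_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.cpgs_per_island, self.n_young, self.n_apa,
               self.n_genes_per_chrom, self.n_bands_per_chrom) < 1:
            raise ValueError("all counts must be positive")
        if self.n_islands < 0:
            raise ValueError("n_islands must be >= 0")
        for b in (self.island_baseline_meth, self.background_baseline_meth):
            if not 0 <= b <= 100:
                raise ValueError("baselines must lie in [0, 100]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if any(abs(e) < 10 for e in self.effect_sizes):
            raise ValueError("spiked effects must have magnitude >= 10%")


@dataclass
class SyntheticGenome:
    chrom_lengths: dict[str, int]
    islands: list[GenomicInterval]
    genes: list[GeneModel]
    cytobands: list[GenomicInterval]
    nucleosomes: list[GenomicInterval]
    cpg_positions: dict[str, np.ndarray]
    nucleosome_genes: set[str]


@dataclass
class SyntheticTruth:
    """Ground truth of the simulation: spiked regions and planted gene sets."""

    spiked_dmrs: list[tuple[GenomicInterval, str, float, int]]  # (span, direction, effect, n_cpgs)
    enriched_gene_sets: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def simulate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Deterministic genome scaffold: islands, CpGs, genes, bands, nucleosomes."""
    if config.n_islands * config.island_length > config.chrom_length:
        raise ValueError("total island length exceeds chromosome length")
    rng = np.random.default_rng(config.seed)
    chrom_lengths = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    islands: list[GenomicInterval] = []
    genes: list[GeneModel] = []
    cytobands: list[GenomicInterval] = []
    nucleosomes: list[GenomicInterval] = []
    cpg_positions: dict[str, np.ndarray] = {}
    nucleosome_genes: set[str] = set()

    for ci, (chrom, clen) in enumerate(chrom_lengths.items(), start=1):
        # islands: one per equal slot, jittered inside the slot
        slot = clen // config.n_islands if config.n_islands else clen
        chrom_islands = []
        for k in range(config.n_islands):
            room = max(slot - config.island_length, 1)
            start = k * slot + int(rng.integers(0, room))
            iv = GenomicInterval(chrom, start, start + config.island_length,
                                 name=f"{chrom}_ISL{k}")
            chrom_islands.append(iv)
        islands.extend(chrom_islands)

        # CpGs: evenly spaced within islands, Poisson background outside
        pos: list[int] = []
        for iv in chrom_islands:
            step = max(iv.width // config.cpgs_per_island, 1)
            pos.extend(range(iv.start + step // 2, iv.end, step)[: config.cpgs_per_island])
        n_bg = rng.poisson(config.background_cpg_rate * clen)
        bg = rng.integers(0, clen, size=n_bg)
        in_island = np.zeros(len(bg), dtype=bool)
        for iv in chrom_islands:
            in_island |= (bg >= iv.start) & (bg < iv.end)
        pos.extend(bg[~in_island].tolist())
        cpg_positions[chrom] = np.unique(np.asarray(pos, dtype=np.int64))

        # genes tile the chromosome with alternating strands
        gene_slot = clen // config.n_genes_per_chrom
        gene_len = max(int(gene_slot * 0.6), 2)
        for j in range(config.n_genes_per_chrom):
            start = j * gene_slot + gene_slot // 5
            strand = "+" if j % 2 == 0 else "-"
            symbol = f"G{ci}_{j:03d}"
            genes.append(
                GeneModel(
                    interval=GenomicInterval(
                        chrom, start, start + gene_len, name=symbol, strand=strand
                    ),
                    symbol=symbol,
                )
            )

        # cytobands exactly partition the chromosome: p-arm then q-arm
        n_bands = config.n_bands_per_chrom
        edges = np.linspace(0, clen, n_bands + 1, dtype=np.int64)
        half = n_bands // 2
        for k in range(n_bands):
            if k < half:
                name = f"p{half - k}"
            else:
                name = f"q{k - half + 1}"
            cytobands.append(
                GenomicInterval(chrom, int(edges[k]), int(edges[k + 1]), name=name)
            )

    # nucleosome-retention regions: promoters of a random gene subset
    n_nuc = int(round(config.nucleosome_gene_fraction * len(genes)))
    for g in (genes[i] for i in rng.choice(len(genes), size=n_nuc, replace=False)):
        nucleosome_genes.add(g.symbol)
        start = max(g.tss - 1000, 0)
        nucleosomes.append(
            GenomicInterval(g.chrom, start, g.tss + 1000, name=g.symbol)
        )
    nucleosomes.sort(key=lambda iv: (iv.chrom, iv.start))

    return SyntheticGenome(
        chrom_lengths=chrom_lengths,
        islands=islands,
        genes=genes,
        cytobands=cytobands,
        nucleosomes=nucleosomes,
        cpg_positions=cpg_positions,
        nucleosome_genes=nucleosome_genes,
    )


def sample_site_fractions(
    mean: np.ndarray, dispersion: float, size: tuple, rng: np.random.Generator
) -> np.ndarray:
    """Beta-distributed per-sample methylation fractions.

    ``mean`` in [0,1]; ``dispersion`` is the beta-binomial rho: the Beta
    concentration is (1-rho)/rho, so variance is rho*m*(1-m). At rho = 0
    the fractions equal the mean exactly (no inter-individual variability).
    """
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion == 0:
        return mean.copy()
    s = (1.0 - dispersion) / dispersion
    a = np.clip(mean * s, 1e-9, None)
    b = np.clip((1.0 - mean) * s, 1e-9, None)
    return rng.beta(a, b)


def _spike_plan(
    genome: SyntheticGenome, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[GenomicInterval, str, float]]:
    eligible = [
        iv
        for iv in genome.islands
        if ((genome.cpg_positions[iv.chrom] >= iv.start)
            & (genome.cpg_positions[iv.chrom] < iv.end)).sum() >= 3
    ]
    n_wanted = config.n_spiked_hyper + config.n_spiked_hypo
    if n_wanted > len(eligible):
        raise ValueError(
            f"requested {n_wanted} spiked DMRs but only {len(eligible)} eligible regions"
        )
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=n_wanted, replace=False)]
    plan = []
    for i, iv in enumerate(chosen):
        direction = "hyper" if i < config.n_spiked_hyper else "hypo"
        effect = abs(config.effect_sizes[i % len(config.effect_sizes)])
        plan.append((iv, direction, effect if direction == "hyper" else -effect))
    return plan


def _site_means(
    genome: SyntheticGenome,
    config: SimulationConfig,
    plan: Sequence[tuple[GenomicInterval, str, float]],
    ages: np.ndarray,
    is_apa: np.ndarray,
) -> tuple[list[str], np.ndarray, np.ndarray, list[tuple[GenomicInterval, str, float, int]]]:
    """Per-site per-sample mean methylation fractions plus truth records."""
    chroms: list[str] = []
    all_pos: list[int] = []
    base: list[float] = []
    for chrom in genome.chrom_lengths:
        pos = genome.cpg_positions[chrom]
        in_island = np.zeros(len(pos), dtype=bool)
        for iv in (i for i in genome.islands if i.chrom == chrom):
            in_island |= (pos >= iv.start) & (pos < iv.end)
        chroms.extend([chrom] * len(pos))
        all_pos.extend(pos.tolist())
        base.extend(
            np.where(in_island, config.island_baseline_meth,
                     config.background_baseline_meth).tolist()
        )
    pos_arr = np.asarray(all_pos, dtype=np.int64)
    chrom_arr = np.asarray(chroms, dtype=object)
    baseline = np.asarray(base, dtype=float)

    n_samples = len(is_apa)
    mean = np.tile(baseline[:, None], (1, n_samples))
    truth: list[tuple[GenomicInterval, str, float, int]] = []
    for iv, direction, effect in plan:
        member = (chrom_arr == iv.chrom) & (pos_arr >= iv.start) & (pos_arr < iv.end)
        if direction == "hypo":
            # methylated island: representable room for the negative effect
            mean[member, :] = config.background_baseline_meth
        shift = effect + config.age_slope * np.where(is_apa, ages - 50.0, 0.0)
        mean[np.ix_(member, is_apa)] += shift[None, is_apa]
        mpos = pos_arr[member]
        truth.append(
            (
                GenomicInterval(iv.chrom, int(mpos.min()), int(mpos.max()) + 1,
                                name=iv.name),
                direction,
                effect,
                int(member.sum()),
            )
        )
    mean = np.clip(mean, 1.0, 99.0) / 100.0
    return chroms, pos_arr, mean, truth


def _sample_frame(config: SimulationConfig, rng: np.random.Generator):
    sample_ids = [f"young_{i + 1}" for i in range(config.n_young)] + [
        f"apa_{i + 1}" for i in range(config.n_apa)
    ]
    group = np.asarray([YOUNG] * config.n_young + [APA] * config.n_apa, dtype=object)
    ages = np.concatenate(
        [
            rng.uniform(*config.age_young, size=config.n_young),
            rng.uniform(*config.age_apa, size=config.n_apa),
        ]
    ).round(1)
    return sample_ids, group, ages


def simulate_counts(
    genome: SyntheticGenome, config: SimulationConfig
) -> tuple[MethylationDataset, SyntheticTruth]:
    """Beta-binomial read counts with spiked case-group regions.

    Per site and sample: fraction ~ Beta(mean, rho), reads ~
    Poisson(coverage_mean), methylated reads ~ Binomial(reads, fraction).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sample_ids, group, ages = _sample_frame(config, rng)
    is_apa = group == APA
    plan = _spike_plan(genome, config, rng)
    chroms, pos, mean, truth = _site_means(genome, config, plan, ages, is_apa)

    shape = mean.shape
    fractions = sample_site_fractions(mean, config.dispersion, shape, rng)
    reads = rng.poisson(config.coverage_mean, size=shape)
    n_meth = rng.binomial(reads, fractions)
    n_unmeth = reads - n_meth

    order = np.lexsort((pos, np.asarray(chroms, dtype=object)))
    ds = MethylationDataset(
        chrom=np.asarray(chroms, dtype=object)[order],
        pos=pos[order],
        n_meth=n_meth[order],
        n_unmeth=n_unmeth[order],
        sample_ids=sample_ids,
        group=group,
        age=ages,
    )
    return ds, SyntheticTruth(spiked_dmrs=truth, seed=config.seed)


def simulate_beta_matrix(
    genome: SyntheticGenome, config: SimulationConfig
) -> tuple[BetaMatrix, SyntheticTruth]:
    """Array-style beta values: the Beta draw directly, no read sampling."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    sample_ids, group, ages = _sample_frame(config, rng)
    is_apa = group == APA
    plan = _spike_plan(genome, config, rng)
    chroms, pos, mean, truth = _site_means(genome, config, plan, ages, is_apa)

    beta = sample_site_fractions(mean, config.dispersion, mean.shape, rng)
    order = np.lexsort((pos, np.asarray(chroms, dtype=object)))
    probes = pd.DataFrame(
        {
            "probe_id": [f"cg{i:08d}" for i in range(len(pos))],
            "chrom": np.asarray(chroms, dtype=object)[order],
            "pos": pos[order],
        }
    )
    bm = BetaMatrix(
        probes=probes, beta=beta[order], sample_ids=sample_ids, group=group
    )
    return bm, SyntheticTruth(spiked_dmrs=truth, seed=config.seed)


def planted_gene_sets(
    genome: SyntheticGenome,
    truth: SyntheticTruth,
    fractions: Mapping[str, float],
    set_size: int = 40,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Gene lists with a planted overlap fraction with spiked-DMR genes.

    For each named set, ``fraction`` of its members are drawn from genes
    whose body or promoter overlaps a spiked region, the rest from the
    remaining genes; the fractions are recorded in the truth object.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    spiked_genes = sorted(
        g.symbol
        for g in genome.genes
        for (iv, *_rest) in truth.spiked_dmrs
        if g.chrom == iv.chrom
        and g.interval.start - 2500 < iv.end
        and iv.start < g.interval.end + 2500
    )
    others = sorted(set(g.symbol for g in genome.genes) - set(spiked_genes))
    out: dict[str, set[str]] = {}
    for name, frac in fractions.items():
        n_in = min(int(round(frac * set_size)), len(spiked_genes))
        n_out = min(set_size - n_in, len(others))
        chosen = set()
        if n_in:
            chosen |= set(rng.choice(spiked_genes, size=n_in, replace=False))
        if n_out:
            chosen |= set(rng.choice(others, size=n_out, replace=False))
        out[name] = chosen
        truth.enriched_gene_sets[name] = frac
    return out


def write_simulation(
    outdir: str | Path,
    genome: SyntheticGenome,
    dataset: MethylationDataset,
    truth: SyntheticTruth,
    gene_sets: Mapping[str, set[str]] | None = None,
) -> dict[str, Path]:
    """Write every file dialect the readers understand, plus a truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for sid, frame in meth_io.dataset_to_sample_frames(dataset).items():
        p = outdir / f"{sid}.cov.tsv"
        meth_io.write_coverage_file(frame, p)
        paths[f"coverage:{sid}"] = p
    meth_io.write_bed(genome.islands, outdir / "islands.bed")
    meth_io.write_cytobands(genome.cytobands, outdir / "cytobands.tsv")
    meth_io.write_gene_models(genome.genes, outdir / "genes.tsv")
    meth_io.write_bed(genome.nucleosomes, outdir / "nucleosomes.bed")
    meth_io.write_gene_list(genome.nucleosome_genes, outdir / "nucleosome_genes.txt")
    for key in ("islands.bed", "cytobands.tsv", "genes.tsv", "nucleosomes.bed",
                "nucleosome_genes.txt"):
        paths[key] = outdir / key
    if gene_sets:
        for name, symbols in gene_sets.items():
            p = outdir / f"geneset_{name}.txt"
            meth_io.write_gene_list(symbols, p)
            paths[f"geneset:{name}"] = p
    truth_frame = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv, *_ in truth.spiked_dmrs],
            "start": [iv.start for iv, *_ in truth.spiked_dmrs],
            "end": [iv.end for iv, *_ in truth.spiked_dmrs],
            "direction": [d for _, d, *_ in truth.spiked_dmrs],
            "effect": [e for _, _, e, _ in truth.spiked_dmrs],
            "n_cpgs": [n for *_, n in truth.spiked_dmrs],
        }
    )
    truth_path = outdir / "truth.tsv"
    truth_frame.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    groups_path = outdir / "samples.tsv"
    pd.DataFrame(
        {"sample_id": dataset.sample_ids, "group": dataset.group,
         "age": dataset.age if dataset.age is not None else np.nan}
    ).to_csv(groups_path, sep="\t", index=False)
    paths["samples"] = groups_path
    return paths
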