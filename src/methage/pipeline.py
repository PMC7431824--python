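"""End-to-end orchestration: file-based pipeline runs and the self-scoring
simulation study.

A run sequences: coverage ingestion -> per-CpG test (t-test or pooled
Fisher) -> directional DMR calling -> context/gene/band annotation ->
enrichment statistics -> chromosomal density localization -> clustering and
age regression, writing one TSV per stage and a manifest (parameters,
seeds, input checksums) that makes reruns byte-identical apart from
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, annotate, cpg_stats, dmr_caller, downstream, enrich
from . import localize as loc
from . import meth_io, synthetic_data
from .dmr_caller import DMR, DMRCallerConfig
from .meth_io import APA, YOUNG

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and options for a file-based run; loadable from YAML."""

    samples: dict[str, str]             # sample_id -> coverage path
    groups: dict[str, str]              # sample_id -> young/APA
    islands: str
    genes: str
    cytobands: str
    outdir: str
    nucleosomes: str | None = None
    nucleosome_genes: str | None = None
    gene_lists: dict[str, str] = field(default_factory=dict)
    ages: dict[str, float] = field(default_factory=dict)
    test_design: str = "ttest"          # or "fisher"
    min_coverage: int = 5
    alpha: float = 0.05
    caller: DMRCallerConfig = field(default_factory=DMRCallerConfig)
    universe: str = "annotation"        # or "covered"
    n_boot: int = loc.DEFAULT_N_BOOT
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        caller_raw = raw.pop("caller", {})
        cfg = cls(**raw)
        if caller_raw:
            cfg.caller = DMRCallerConfig(**caller_raw)
        return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def gene_universe(
    genes: Sequence[meth_io.GeneModel],
    dataset: meth_io.MethylationDataset | None,
    mode: str,
) -> set[str]:
    """Default universe = all annotated symbols; 'covered' keeps only genes
    whose body contains at least one tested CpG."""
    if mode == "annotation" or dataset is None:
        return {g.symbol for g in genes}
    if mode != "covered":
        raise ValueError("universe must be 'annotation' or 'covered'")
    out = set()
    for g in genes:
        mask = (dataset.chrom == g.chrom) & (dataset.pos >= g.interval.start) & (
            dataset.pos < g.interval.end
        )
        if mask.any():
            out.add(g.symbol)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on files and write the result bundle + manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    frames = _stage("read_coverage")(
        lambda: {
            sid: meth_io.read_coverage_file(path, sid)
            for sid, path in config.samples.items()
        }
    )()
    dataset = _stage("merge_samples")(meth_io.merge_samples)(
        frames, config.groups, min_coverage=config.min_coverage,
        ages=config.ages or None,
    )
    if config.test_design == "ttest":
        site_results = _stage("cpg_test")(cpg_stats.test_sites_ttest)(
            dataset, alpha=config.alpha
        )
    elif config.test_design == "fisher":
        site_results = _stage("cpg_test")(cpg_stats.test_sites_fisher)(
            dataset, alpha=config.alpha
        )
    else:
        raise ValueError("test_design must be 'ttest' or 'fisher'")
    cpg_stats.write_site_results(site_results, outdir / "site_results.tsv")

    caller = dataclasses.replace(config.caller, alpha=config.alpha)
    dmrs = _stage("call_dmrs")(dmr_caller.call_dmrs)(site_results, caller)
    dmr_caller.write_dmr_bed(dmrs, outdir / "dmrs.bed")
    dmr_caller.summarize_dmrs(dmrs).to_csv(outdir / "dmr_summary.tsv", sep="\t")

    islands = meth_io.read_bed(config.islands)
    genes = meth_io.read_gene_models(config.genes)
    cytobands = meth_io.read_cytobands(config.cytobands)
    nucleosomes = meth_io.read_bed(config.nucleosomes) if config.nucleosomes else []
    nuc_genes = (
        meth_io.read_gene_list(config.nucleosome_genes)
        if config.nucleosome_genes
        else set()
    )
    annotated = _stage("annotate")(annotate.annotate_dmrs)(
        dmrs, islands, genes, cytobands, nucleosomes, nuc_genes
    )
    pd.DataFrame(annotate.annotated_to_rows(annotated)).to_csv(
        outdir / "annotated_dmrs.tsv", sep="\t", index=False
    )

    universe = gene_universe(genes, dataset, config.universe)
    dmr_genes = set().union(*(a.genes for a in annotated)) if annotated else set()

    context_enr = annotate.island_context_enrichment(annotated)
    enrich.results_to_frame(context_enr.values()).to_csv(
        outdir / "island_context_enrichment.tsv", sep="\t", index=False
    )

    geneset_rows = []
    for name, path in config.gene_lists.items():
        target = meth_io.read_gene_list(path)
        geneset_rows.append(
            enrich.geneset_enrichment(dmr_genes, target, universe, label=name)
        )
    if nuc_genes:
        geneset_rows.append(
            enrich.geneset_enrichment(
                dmr_genes, nuc_genes, universe, label="nucleosome_retention"
            )
        )
    if geneset_rows:
        frame = enrich.results_to_frame(geneset_rows)
        frame["q_value"] = enrich.benjamini_hochberg(frame.p_value.to_numpy())
        frame.to_csv(outdir / "geneset_enrichment.tsv", sep="\t", index=False)

    band_table = _stage("cytoband_enrichment")(enrich.cytoband_enrichment)(
        dmr_genes, genes, cytobands, universe=universe, alpha=config.alpha
    )
    band_table.to_csv(outdir / "cytoband_enrichment.tsv", sep="\t", index=False)

    chrom_lengths = {
        b.chrom: max(bb.end for bb in cytobands if bb.chrom == b.chrom)
        for b in cytobands
    }
    flagged: dict[str, list[str]] = {}
    for chrom, clen in sorted(chrom_lengths.items()):
        all_tss = [g.tss for g in genes if g.chrom == chrom]
        dmr_tss = [g.tss for g in genes if g.chrom == chrom and g.symbol in dmr_genes]
        if len(all_tss) < 2 or len(dmr_tss) < 2:
            continue
        profile = _stage("localize")(loc.build_density_profile)(
            chrom, all_tss, dmr_tss, clen,
            cytobands=[b for b in cytobands if b.chrom == chrom],
            n_boot=config.n_boot, seed=config.seed,
        )
        loc.profile_to_frame(profile).to_csv(
            outdir / f"density_{chrom}.tsv", sep="\t", index=False
        )
        flagged[chrom] = sorted(profile.flagged_bands)
    with open(outdir / "flagged_bands.json", "w") as fh:
        json.dump(flagged, fh, indent=2, sort_keys=True)

    cluster = None
    if dmrs and dataset.n_samples >= 2:
        try:
            cluster = _stage("cluster")(downstream.cluster_dmr_cpgs)(dataset, dmrs)
            cluster.z_matrix.to_csv(outdir / "cluster_zmatrix.tsv", sep="\t")
            pd.DataFrame(
                {"sample_id": dataset.sample_ids, "cluster": cluster.labels}
            ).to_csv(outdir / "cluster_labels.tsv", sep="\t", index=False)
        except (ValueError, RuntimeError) as exc:
            logger.warning("clustering skipped: %s", exc)

    regression_rows = []
    if dataset.age is not None and not np.isnan(dataset.age).any():
        apa_idx = dataset.group_indices(APA)
        pct = dataset.percent()
        for d in dmrs:
            mask = np.array(
                [c == d.chrom and p in d.member_positions
                 for c, p in zip(dataset.chrom, dataset.pos)]
            )
            mean_pct = pct[mask][:, apa_idx].mean(axis=0)
            ages = dataset.age[apa_idx]
            if len(ages) >= 3 and np.ptp(ages) > 0:
                fit = downstream.regress_meth_on_age(mean_pct, ages)
                regression_rows.append(
                    {"chrom": d.chrom, "start": d.start, "end": d.end,
                     "direction": d.direction, "slope": fit.slope,
                     "intercept": fit.intercept, "r_squared": fit.r_squared,
                     "p_value": fit.p_value}
                )
    pd.DataFrame(regression_rows).to_csv(
        outdir / "age_regression.tsv", sep="\t", index=False
    )

    manifest = {
        "version": __version__,
        "parameters": {
            "test_design": config.test_design,
            "min_coverage": config.min_coverage,
            "alpha": config.alpha,
            "caller": dataclasses.asdict(caller),
            "universe": config.universe,
            "n_boot": config.n_boot,
            "seed": config.seed,
        },
        "inputs": {
            **{f"coverage:{s}": _sha256(p) for s, p in config.samples.items()},
            "islands": _sha256(config.islands),
            "genes": _sha256(config.genes),
            "cytobands": _sha256(config.cytobands),
        },
        "stages": [
            "read_coverage", "merge_samples", "cpg_test", "call_dmrs", "annotate",
            "island_context_enrichment", "geneset_enrichment",
            "cytoband_enrichment", "localize", "cluster", "age_regression",
        ],
        "n_sites": int(dataset.n_sites),
        "n_dmrs": len(dmrs),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "dataset": dataset,
        "site_results": site_results,
        "dmrs": dmrs,
        "annotated": annotated,
        "cluster": cluster,
        "manifest": manifest,
    }


# ---------------------------------------------------------------------------
# simulation study

def score_dmr_calls(
    called: Sequence[DMR], truth: synthetic_data.SyntheticTruth
) -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) of region calls vs truth.

    A spiked region is recovered if any called DMR of the matching
    direction overlaps it; a call is false if it overlaps no spiked region
    (either direction).
    """
    def overlaps(d: DMR, iv) -> bool:
        return d.chrom == iv.chrom and d.start < iv.end and iv.start < d.end

    spiked = truth.spiked_dmrs
    recovered = sum(
        any(overlaps(d, iv) and d.direction == direction for d in called)
        for iv, direction, *_ in spiked
    )
    sensitivity = recovered / len(spiked) if spiked else float("nan")
    if called:
        false = sum(
            not any(overlaps(d, iv) for iv, *_ in spiked) for d in called
        )
        fdp = false / len(called)
    else:
        fdp = 0.0
    return sensitivity, fdp


def run_simulation_study(
    sim_config: synthetic_data.SimulationConfig | None = None,
    caller_config: DMRCallerConfig = DMRCallerConfig(),
    test_design: str = "ttest",
    min_coverage: int = 5,
    gene_set_fractions: Mapping[str, float] | None = None,
) -> dict:
    """Simulate, run the core stages in memory, and score against truth.

    Returns a flat report: DMR sensitivity and FDP, planted gene-set
    detection (Fisher p at the planted and background fractions), and the
    adjusted Rand index of the 2-cluster cut against the true group labels.
    """
    from sklearn.metrics import adjusted_rand_score  # optional convenience

    cfg = sim_config or synthetic_data.SimulationConfig()
    genome = synthetic_data.simulate_genome(cfg)
    dataset, truth = synthetic_data.simulate_counts(genome, cfg)
    frames = meth_io.dataset_to_sample_frames(dataset)
    group_map = dict(zip(dataset.sample_ids, dataset.group))
    ages = dict(zip(dataset.sample_ids, dataset.age))
    dataset = meth_io.merge_samples(frames, group_map, min_coverage=min_coverage,
                                    ages=ages)
    if test_design == "ttest":
        site_results = cpg_stats.test_sites_ttest(dataset, alpha=caller_config.alpha)
    else:
        site_results = cpg_stats.test_sites_fisher(dataset, alpha=caller_config.alpha)
    dmrs = dmr_caller.call_dmrs(site_results, caller_config)
    sensitivity, fdp = score_dmr_calls(dmrs, truth)

    report: dict[str, float] = {
        "n_sites": float(dataset.n_sites),
        "n_spiked": float(len(truth.spiked_dmrs)),
        "n_called": float(len(dmrs)),
        "sensitivity": sensitivity,
        "fdp": fdp,
        "frac_significant_cpgs": float(site_results.significant.mean()),
    }

    if dmrs:
        cluster = downstream.cluster_dmr_cpgs(dataset, dmrs)
        true_labels = (dataset.group == APA).astype(int)
        report["cluster_ari"] = float(
            adjusted_rand_score(true_labels, cluster.labels)
        )

    fractions = gene_set_fractions or {"planted": 0.5, "background": 0.1}
    gene_sets = synthetic_data.planted_gene_sets(
        genome, truth, fractions, seed=cfg.seed
    )
    annotated = annotate.annotate_dmrs(
        dmrs, genome.islands, genome.genes, genome.cytobands,
        genome.nucleosomes, genome.nucleosome_genes,
    )
    dmr_genes = set().union(*(a.genes for a in annotated)) if annotated else set()
    universe = {g.symbol for g in genome.genes}
    for name, target in gene_sets.items():
        res = enrich.geneset_enrichment(dmr_genes, target, universe, label=name)
        report[f"geneset_{name}_or"] = res.odds_ratio
        report[f"geneset_{name}_p"] = res.p_value
    return report
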