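"""Directional differentially methylated region (DMR) calling.

The rule: significant CpGs are clustered per chromosome by cutting wherever
the gap to the previous significant site exceeds ``lambda_bp`` (1 kb).
Within a cluster, each direction is evaluated independently: if at least
``min_cpgs`` significant CpGs share a sign and the mean of their deltas has
magnitude >= ``min_mean_abs_delta`` (10%), a DMR spanning those member CpGs
is emitted. A cluster can therefore yield at most one hypermethylated and
one hypomethylated region — mixed clusters are real and retained.

Region width is the half-open span of member CpGs, so three adjacent CpGs
can produce a region only a few bp wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HYPER = "hyper"
HYPO = "hypo"


@dataclass(frozen=True)
class DMRCallerConfig:
    """Window and filter parameters for region calling.

    ``kernel_C`` records the kernel scaling constant of the original
    smoothing-based caller for provenance; the normative rule here is the
    cluster-and-filter definition, which does not use it.
    """

    lambda_bp: int = 1000
    min_cpgs: int = 3
    min_mean_abs_delta: float = 10.0
    alpha: float = 0.05
    mean_over: str = "significant"   # or "all": average deltas of every tested CpG in the span
    kernel_C: float = 75.0

    def __post_init__(self) -> None:
        if self.lambda_bp <= 0:
            raise ValueError("lambda_bp must be positive")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be >= 2")
        if self.mean_over not in ("significant", "all"):
            raise ValueError("mean_over must be 'significant' or 'all'")


ARRAY_MODE = DMRCallerConfig(min_cpgs=2)


@dataclass(frozen=True)
class DMR:
    """A called region: the half-open span of its member CpGs."""

    chrom: str
    start: int
    end: int
    direction: str
    n_sig_cpgs: int
    mean_delta: float
    member_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.direction not in (HYPER, HYPO):
            raise ValueError(f"direction must be hyper/hypo, got {self.direction!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if any(p < self.start or p >= self.end for p in self.member_positions):
            raise ValueError("member positions must lie within the region span")

    @property
    def width(self) -> int:
        return self.end - self.start


def call_dmrs(site_results: pd.DataFrame, config: DMRCallerConfig = DMRCallerConfig()) -> list[DMR]:
    """Call directional DMRs from a per-CpG test result table.

    ``site_results`` must be sorted by (chrom, pos); it needs columns
    chrom, pos, delta, p_value (significance is re-derived from
    ``config.alpha`` so the caller can be re-run at other thresholds).
    """
    df = site_results
    order = np.lexsort((df.pos.to_numpy(), df.chrom.to_numpy()))
    if not np.array_equal(order, np.arange(len(df))):
        raise ValueError("site_results must be sorted by (chrom, pos)")

    sig = df[(df.p_value <= config.alpha) & (df.delta != 0)]
    out: list[DMR] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        pos = grp.pos.to_numpy()
        delta = grp.delta.to_numpy()
        # cut whenever the gap to the previous significant site exceeds lambda
        cuts = np.flatnonzero(np.diff(pos) > config.lambda_bp) + 1
        for cluster_idx in np.split(np.arange(len(pos)), cuts):
            out.extend(
                _emit_cluster(
                    str(chrom), pos[cluster_idx], delta[cluster_idx], df, config
                )
            )
    out.sort(key=lambda d: (d.chrom, d.start, d.direction))
    return out


def _emit_cluster(
    chrom: str,
    pos: np.ndarray,
    delta: np.ndarray,
    all_sites: pd.DataFrame,
    config: DMRCallerConfig,
) -> list[DMR]:
    emitted = []
    for direction, mask in ((HYPER, delta > 0), (HYPO, delta < 0)):
        if mask.sum() < config.min_cpgs:
            continue
        mpos, mdelta = pos[mask], delta[mask]
        start, end = int(mpos.min()), int(mpos.max()) + 1
        if config.mean_over == "significant":
            mean_delta = float(mdelta.mean())
        else:
            span = all_sites[
                (all_sites.chrom == chrom)
                & (all_sites.pos >= start)
                & (all_sites.pos < end)
            ]
            mean_delta = float(span.delta.mean())
        if abs(mean_delta) < config.min_mean_abs_delta:
            continue
        emitted.append(
            DMR(
                chrom=chrom,
                start=start,
                end=end,
                direction=direction,
                n_sig_cpgs=int(mask.sum()),
                mean_delta=mean_delta,
                member_positions=tuple(int(p) for p in mpos),
            )
        )
    return emitted


def summarize_dmrs(dmrs: Sequence[DMR]) -> pd.DataFrame:
    """Per-direction tallies: counts, CpGs per region, width distribution."""
    rows = {}
    for direction in (HYPER, HYPO):
        sub = [d for d in dmrs if d.direction == direction]
        if sub:
            cpgs = np.array([d.n_sig_cpgs for d in sub])
            widths = np.array([d.width for d in sub])
            rows[direction] = {
                "total_dmrs": len(sub),
                "total_sig_cpgs": int(cpgs.sum()),
                "mean_cpgs_per_dmr": float(cpgs.mean()),
                "min_cpgs_per_dmr": int(cpgs.min()),
                "max_cpgs_per_dmr": int(cpgs.max()),
                "mean_width_bp": float(widths.mean()),
                "min_width_bp": int(widths.min()),
                "max_width_bp": int(widths.max()),
            }
        else:
            rows[direction] = {
                "total_dmrs": 0,
                "total_sig_cpgs": 0,
                "mean_cpgs_per_dmr": np.nan,
                "min_cpgs_per_dmr": np.nan,
                "max_cpgs_per_dmr": np.nan,
                "mean_width_bp": np.nan,
                "min_width_bp": np.nan,
                "max_width_bp": np.nan,
            }
    return pd.DataFrame(rows).T.rename_axis("direction")


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [d.chrom for d in dmrs],
            "start": [d.start for d in dmrs],
            "end": [d.end for d in dmrs],
            "name": [f"DMR_{i + 1:05d}" for i in range(len(dmrs))],
            "score": [d.n_sig_cpgs for d in dmrs],
            "strand": ["."] * len(dmrs),
            "direction": [d.direction for d in dmrs],
            "mean_delta": [d.mean_delta for d in dmrs],
            "width": [d.width for d in dmrs],
        }
    )


def write_dmr_bed(dmrs: Sequence[DMR], path) -> None:
    """BED6+3: name=DMR id, score=number of significant member CpGs."""
    dmrs_to_frame(dmrs).to_csv(path, sep="\t", index=False, header=False)
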