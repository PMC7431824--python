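"""Readers, writers and core containers for methylation count data and annotations.

All public coordinates are 0-based half-open. Bismark-style coverage files
(1-based inclusive, single-base rows) are converted on read; nothing
downstream ever sees 1-based positions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

YOUNG = "young"
APA = "APA"
GROUPS = (YOUNG, APA)


class FileFormatError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with a strand-aware transcription start site.

    tss is interval.start on the + strand and interval.end - 1 on the -
    strand (the last covered base, in 0-based coordinates).
    """

    interval: GenomicInterval
    symbol: str

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.symbol!r} must carry a strand")
        if not self.symbol:
            raise ValueError("gene symbol must be non-empty")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand  # type: ignore[return-value]

    @property
    def tss(self) -> int:
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass
class MethylationDataset:
    """CpG sites x samples matrix of (methylated, unmethylated) read counts.

    Sites are sorted by (chrom, pos) and unique. ``group`` labels each sample
    as ``young`` or ``APA``; ``age`` (years) is optional.
    """

    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int
    n_meth: np.ndarray         # (n_sites, n_samples) int
    n_unmeth: np.ndarray       # (n_sites, n_samples) int
    sample_ids: list[str]
    group: np.ndarray          # (n_samples,) str in {young, APA}
    age: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.n_meth = np.asarray(self.n_meth, dtype=np.int64)
        self.n_unmeth = np.asarray(self.n_unmeth, dtype=np.int64)
        self.group = np.asarray(self.group, dtype=object)
        if self.n_meth.shape != self.n_unmeth.shape:
            raise ValueError("count matrices must have identical shapes")
        if self.n_meth.shape != (len(self.chrom), len(self.sample_ids)):
            raise ValueError("count matrix shape does not match sites x samples")
        if (self.n_meth < 0).any() or (self.n_unmeth < 0).any():
            raise ValueError("read counts must be non-negative")
        bad = set(self.group) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if (self.group == g).sum() < 1:
                raise ValueError(f"need at least one sample in group {g!r}")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("sites must be sorted by (chrom, pos)")
        key = list(zip(self.chrom, self.pos))
        if len(set(key)) != len(key):
            raise ValueError("sites must be unique")
        if self.age is not None:
            self.age = np.asarray(self.age, dtype=float)
            if self.age.shape != self.group.shape:
                raise ValueError("age must have one entry per sample")

    @property
    def n_sites(self) -> int:
        return len(self.chrom)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def total(self) -> np.ndarray:
        return self.n_meth + self.n_unmeth

    def percent(self) -> np.ndarray:
        """Per-site per-sample methylation percentage; NaN where coverage is 0."""
        tot = self.total().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, 100.0 * self.n_meth / tot, np.nan)

    def group_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.group == label)


@dataclass
class BetaMatrix:
    """450K-style probes x samples matrix of beta values in [0, 1]."""

    probes: pd.DataFrame       # columns: probe_id, chrom, pos
    beta: np.ndarray           # (n_probes, n_samples)
    sample_ids: list[str]
    group: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        required = {"probe_id", "chrom", "pos"}
        if not required.issubset(self.probes.columns):
            raise ValueError(f"probes frame must have columns {sorted(required)}")
        if self.beta.shape != (len(self.probes), len(self.sample_ids)):
            raise ValueError("beta shape does not match probes x samples")
        finite = self.beta[np.isfinite(self.beta)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("beta values must lie in [0, 1]")
        located = self.probes.dropna(subset=["chrom", "pos"])
        if located.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("probe positions must be unique per chromosome")


# ---------------------------------------------------------------------------
# coverage files

def read_coverage_file(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read a Bismark-dialect coverage file for one sample.

    Expected columns: chrom, start(1-based), end, %methylation,
    count-methylated, count-unmethylated. Returns a frame with 0-based
    ``pos`` plus a ``zero_coverage`` flag; rows with zero total reads are
    retained but flagged.
    """
    path = Path(path)
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    unmeths: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise FileFormatError(
                    f"{path.name} line {lineno} unparseable: expected 6 "
                    f"tab-separated columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start = int(fields[1])
                pct = float(fields[3])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise FileFormatError(
                    f"{path.name} line {lineno} unparseable: {exc}"
                ) from None
            if n_meth < 0 or n_unmeth < 0:
                raise FileFormatError(
                    f"{path.name} line {lineno}: negative read count"
                )
            total = n_meth + n_unmeth
            if total > 0:
                recomputed = 100.0 * n_meth / total
                if abs(recomputed - pct) > 0.1:
                    raise FileFormatError(
                        f"{path.name} line {lineno}: %methylation column "
                        f"({pct}) disagrees with counts ({recomputed:.2f})"
                    )
            chroms.append(chrom)
            poss.append(start - 1)  # 1-based inclusive -> 0-based
            meths.append(n_meth)
            unmeths.append(n_unmeth)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "n_meth": np.asarray(meths, dtype=np.int64),
            "n_unmeth": np.asarray(unmeths, dtype=np.int64),
        }
    )
    df["zero_coverage"] = (df.n_meth + df.n_unmeth) == 0
    df.attrs["sample_id"] = sample_id
    return df


def write_coverage_file(df: pd.DataFrame, path: str | Path) -> None:
    """Write per-sample counts back to the 1-based coverage dialect."""
    tot = (df.n_meth + df.n_unmeth).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(tot > 0, 100.0 * df.n_meth / tot, 0.0)
    out = pd.DataFrame(
        {
            "chrom": df.chrom,
            "start": df.pos + 1,
            "end": df.pos + 1,
            "pct": np.round(pct, 6),
            "n_meth": df.n_meth,
            "n_unmeth": df.n_unmeth,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def merge_samples(
    samples: Mapping[str, pd.DataFrame],
    group_map: Mapping[str, str],
    min_coverage: int = 5,
    ages: Mapping[str, float] | None = None,
) -> MethylationDataset:
    """Combine per-sample count frames into one dataset.

    Keeps only sites where *every* sample reaches ``min_coverage`` total
    reads (the strictest reading of a minimum read-count filter), so the
    per-site tests are well defined in both groups.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to merge")
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    sample_ids = list(samples)
    missing = [s for s in sample_ids if s not in group_map]
    if missing:
        raise ValueError(f"samples missing from group map: {missing}")

    frames = []
    for sid in sample_ids:
        df = samples[sid]
        frames.append(
            df.set_index(["chrom", "pos"])[["n_meth", "n_unmeth"]].add_suffix(f"::{sid}")
        )
    wide = pd.concat(frames, axis=1, join="outer").fillna(0).astype(np.int64)
    wide = wide.sort_index()

    n_meth = np.column_stack([wide[f"n_meth::{s}"].to_numpy() for s in sample_ids])
    n_unmeth = np.column_stack([wide[f"n_unmeth::{s}"].to_numpy() for s in sample_ids])
    keep = ((n_meth + n_unmeth) >= min_coverage).all(axis=1)
    if not keep.any():
        raise ValueError("no sites pass coverage in all samples")

    idx = wide.index[keep]
    group = np.asarray([group_map[s] for s in sample_ids], dtype=object)
    age = None
    if ages is not None:
        age = np.asarray([ages.get(s, np.nan) for s in sample_ids], dtype=float)
    return MethylationDataset(
        chrom=np.asarray(idx.get_level_values("chrom"), dtype=object),
        pos=idx.get_level_values("pos").to_numpy(),
        n_meth=n_meth[keep],
        n_unmeth=n_unmeth[keep],
        sample_ids=sample_ids,
        group=group,
        age=age,
    )


# ---------------------------------------------------------------------------
# annotation files

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED6 file (0-based half-open)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FileFormatError(f"{path.name} line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FileFormatError(f"{path.name} line {lineno}: non-integer coordinates") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            try:
                out.append(GenomicInterval(fields[0], start, end, name=name, strand=strand))
            except ValueError as exc:
                raise FileFormatError(f"{path.name} line {lineno}: {exc}") from None
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None:
                fields += [iv.name or ".", "0", iv.strand or "."]
            fh.write("\t".join(fields) + "\n")


def read_cytobands(path: str | Path) -> list[GenomicInterval]:
    """Read a UCSC cytoBand.txt-dialect table: chrom, start, end, band, stain.

    Band names must be unique per chromosome; the returned interval name is
    the band name alone (e.g. "p13.3"), as in the UCSC table.
    """
    path = Path(path)
    out: list[GenomicInterval] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FileFormatError(f"{path.name} line {lineno}: fewer than 4 columns")
            chrom, band = fields[0], fields[3]
            key = (chrom, band)
            if key in seen:
                raise FileFormatError(
                    f"{path.name} line {lineno}: duplicate band {band!r} on {chrom}"
                )
            seen.add(key)
            try:
                out.append(GenomicInterval(chrom, int(fields[1]), int(fields[2]), name=band))
            except ValueError as exc:
                raise FileFormatError(f"{path.name} line {lineno}: {exc}") from None
    return out


def write_cytobands(bands: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in bands:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\tgneg\n")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-like gene TSV: symbol, chrom, strand, txStart, txEnd."""
    path = Path(path)
    out: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise FileFormatError(f"{path.name} line {lineno}: fewer than 5 columns")
            symbol, chrom, strand = fields[0].upper(), fields[1], fields[2]
            try:
                iv = GenomicInterval(chrom, int(fields[3]), int(fields[4]), name=symbol, strand=strand)
                out.append(GeneModel(interval=iv, symbol=symbol))
            except ValueError as exc:
                raise FileFormatError(f"{path.name} line {lineno}: {exc}") from None
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.symbol}\t{g.chrom}\t{g.strand}\t{g.interval.start}\t{g.interval.end}\n"
            )


def read_gene_list(path: str | Path) -> set[str]:
    """Read a plain-text gene list (one symbol per line), upper-cased."""
    with open(path) as fh:
        return {line.strip().upper() for line in fh if line.strip()}


def write_gene_list(symbols: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(set(symbols)):
            fh.write(s.upper() + "\n")


# ---------------------------------------------------------------------------
# beta matrices

def read_beta_matrix(
    probes_path: str | Path,
    beta_path: str | Path,
    group_map: Mapping[str, str],
) -> BetaMatrix:
    """Read a probe map TSV (probe_id, chrom, pos) and a beta TSV (probe_id x samples)."""
    probes = pd.read_csv(probes_path, sep="\t", dtype={"probe_id": str, "chrom": str})
    beta_df = pd.read_csv(beta_path, sep="\t", index_col=0)
    beta_df = beta_df.reindex(probes.probe_id)
    sample_ids = list(beta_df.columns)
    group = np.asarray([group_map[s] for s in sample_ids], dtype=object)
    return BetaMatrix(
        probes=probes.reset_index(drop=True),
        beta=beta_df.to_numpy(dtype=float),
        sample_ids=sample_ids,
        group=group,
    )


def write_beta_matrix(bm: BetaMatrix, probes_path: str | Path, beta_path: str | Path) -> None:
    bm.probes.to_csv(probes_path, sep="\t", index=False)
    pd.DataFrame(bm.beta, index=bm.probes.probe_id, columns=bm.sample_ids).to_csv(
        beta_path, sep="\t"
    )


def dataset_to_sample_frames(ds: MethylationDataset) -> dict[str, pd.DataFrame]:
    """Split a dataset back into per-sample count frames (for round-tripping)."""
    out = {}
    for j, sid in enumerate(ds.sample_ids):
        out[sid] = pd.DataFrame(
            {
                "chrom": ds.chrom,
                "pos": ds.pos,
                "n_meth": ds.n_meth[:, j],
                "n_unmeth": ds.n_unmeth[:, j],
            }
        )
    return out
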