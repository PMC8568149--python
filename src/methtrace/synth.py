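"""Synthetic nanopore methylation call generator with known ground truth.

Emulates the statistical structure the downstream analyses assume, on a
small artificial genome:

* CpG sites placed either at explicit positions or at random with a
  given per-bp density (default 0.02, roughly one CpG per 50 bp);
* a per-group methylation landscape: a background level mu with interval
  overrides (promoter/TSS dips, imprinting-like differentially
  methylated regions with per-group levels);
* reads with lognormal lengths and uniform starts at a target coverage;
* per (read, site) a single Bernoulli(mu) methylation state — reads are
  single-molecule consistent so per-read spaghetti lines are meaningful;
* a two-component call noise model: methylated states emit
  LLR ~ Normal(+m, s), unmethylated states Normal(-m, s). The defaults
  m=4, s=1.5 produce mostly confident calls with a realistic ambiguous
  tail around probability 0.5.

Output is written in both the nanopolish and the Megalodon dialect for
the same realized calls (so both parse to identical statistics), plus a
per-site truth table of mu. A configurable fraction of nanopolish rows
are grouped multi-motif calls with consistent sequence contexts. All
output is deterministic given the seed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .ingest import MethylationRecord

__all__ = [
    "RegionEffect",
    "MethylationLandscape",
    "simulate_calls",
    "simulate_reads",
    "simulate_records",
    "two_group_landscape",
]

NANOPOLISH_COLUMNS = [
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "log_lik_methylated",
    "log_lik_unmethylated",
    "num_calling_strands",
    "num_motifs",
    "sequence",
]

MEGALODON_COLUMNS = [
    "read_id",
    "chrm",
    "strand",
    "pos",
    "mod_log_prob",
    "can_log_prob",
    "mod_base",
]


@dataclass(frozen=True)
class RegionEffect:
    """Interval override of the methylation level, optionally per group."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int
    mu: float | Mapping[str, float]  # scalar applies to every group

    def level(self, group: str, default: float) -> float:
        if isinstance(self.mu, Mapping):
            return float(self.mu.get(group, default))
        return float(self.mu)


@dataclass
class MethylationLandscape:
    """Ground-truth methylation levels plus read and noise models."""

    chrom_lengths: dict[str, int]
    background_mu: float = 0.75
    regions: list[RegionEffect] = field(default_factory=list)
    cpg_sites: dict[str, Sequence[int]] | None = None  # explicit 1-based sites
    cpg_density: float = 0.02  # used when cpg_sites is None
    site_seed: int = 7  # sites are part of the landscape, shared by samples
    read_length_median: float = 5000.0
    read_length_sigma: float = 0.55
    coverage: float = 50.0
    llr_mean: float = 4.0  # m: mean |LLR| of a confident call
    llr_sd: float = 1.5  # s: per-call noise
    grouped_fraction: float = 0.2  # fraction of nanopolish calls grouping >1 motif
    max_group_size: int = 3

    def __post_init__(self):
        if not 0.0 <= self.background_mu <= 1.0:
            raise ValueError("background_mu must be in [0, 1]")
        for r in self.regions:
            if r.chromosome not in self.chrom_lengths:
                raise ValueError(f"region on unknown chromosome: {r}")
            L = self.chrom_lengths[r.chromosome]
            if not (1 <= r.start <= r.end <= L):
                raise ValueError(f"region outside chromosome bounds: {r}")
            levels = r.mu.values() if isinstance(r.mu, Mapping) else [r.mu]
            if any(not 0.0 <= float(m) <= 1.0 for m in levels):
                raise ValueError(f"region mu outside [0, 1]: {r}")

    def sites(self, chromosome: str) -> np.ndarray:
        """1-based CpG cytosine positions, deterministic per landscape."""
        if self.cpg_sites is not None:
            return np.asarray(sorted(self.cpg_sites[chromosome]), dtype=np.int64)
        L = self.chrom_lengths[chromosome]
        rng = np.random.default_rng(
            [self.site_seed, zlib.crc32(chromosome.encode()) % (2**31)]
        )
        raw = np.flatnonzero(rng.random(L) < self.cpg_density) + 1
        if raw.size == 0:
            return raw.astype(np.int64)
        # CpGs cannot overlap: enforce >= 2 bp spacing
        keep = [int(raw[0])]
        for p in raw[1:]:
            if p - keep[-1] >= 2:
                keep.append(int(p))
        return np.asarray(keep, dtype=np.int64)

    def mu_at(self, chromosome: str, positions: np.ndarray, group: str) -> np.ndarray:
        """Per-position methylation level for *group* (later regions win)."""
        mu = np.full(len(positions), self.background_mu, dtype=float)
        for r in self.regions:
            if r.chromosome != chromosome:
                continue
            mask = (positions >= r.start) & (positions <= r.end)
            mu[mask] = r.level(group, self.background_mu)
        return mu

    def truth_table(self, group: str) -> pd.DataFrame:
        rows = []
        for chrom in self.chrom_lengths:
            sites = self.sites(chrom)
            mu = self.mu_at(chrom, sites, group)
            rows.append(
                pd.DataFrame(
                    {"chromosome": chrom, "position": sites, "group": group, "mu": mu}
                )
            )
        return pd.concat(rows, ignore_index=True)


def _group_sequence(offsets: np.ndarray) -> str:
    """Sequence context with 'CG' at the given relative offsets (offset 0
    first), padded with non-CG bases and a short leading context."""
    prefix = "TAT"
    span = int(offsets[-1]) + 2
    seq = ["T"] * span
    for off in offsets:
        seq[int(off)] = "C"
        seq[int(off) + 1] = "G"
    return prefix + "".join(seq) + "AT"


@dataclass
class _Call:
    chromosome: str
    read_id: str
    positions: np.ndarray  # 1-based sites in the call (>=1 means grouped)
    llr: float


def _simulate_chromosome(
    landscape: MethylationLandscape,
    chromosome: str,
    sample_id: str,
    group: str,
    rng: np.random.Generator,
) -> Iterator[_Call]:
    L = landscape.chrom_lengths[chromosome]
    sites = landscape.sites(chromosome)
    if sites.size == 0:
        return
    mu = landscape.mu_at(chromosome, sites, group)
    mean_len = landscape.read_length_median * math.exp(
        landscape.read_length_sigma**2 / 2
    )
    n_reads = max(1, int(math.ceil(landscape.coverage * L / mean_len)))
    starts = rng.integers(1, L + 1, size=n_reads)
    lengths = rng.lognormal(
        math.log(landscape.read_length_median), landscape.read_length_sigma, n_reads
    ).astype(np.int64)
    ends = np.minimum(starts + np.maximum(lengths, 50) - 1, L)
    for ridx in range(n_reads):
        read_id = f"{sample_id}_{chromosome}_read{ridx:06d}"
        lo = int(np.searchsorted(sites, starts[ridx], side="left"))
        hi = int(np.searchsorted(sites, ends[ridx], side="right"))
        if hi <= lo:
            continue
        i = lo
        while i < hi:
            remaining = hi - i
            if remaining >= 2 and rng.random() < landscape.grouped_fraction:
                g = int(rng.integers(2, min(landscape.max_group_size, remaining) + 1))
            else:
                g = 1
            pos = sites[i : i + g]
            state = rng.random() < float(np.mean(mu[i : i + g]))
            center = landscape.llr_mean if state else -landscape.llr_mean
            llr = float(rng.normal(center, landscape.llr_sd))
            yield _Call(chromosome, read_id, pos, llr)
            i += g


def simulate_calls(
    landscape: MethylationLandscape, sample_id: str, group: str, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one sample; return (nanopolish, megalodon, truth) frames.

    The Megalodon frame carries one row per site with
    mod_log_prob = ln sigmoid(LLR) and can_log_prob = ln sigmoid(-LLR),
    so parsing it recovers the same statistics as the nanopolish frame.
    """
    rng = np.random.default_rng([int(seed), 0xC9])
    nano_rows = []
    mega_rows = []
    for chrom in landscape.chrom_lengths:
        for call in _simulate_chromosome(landscape, chrom, sample_id, group, rng):
            first = int(call.positions[0])
            last = int(call.positions[-1])
            offsets = call.positions - first
            llr = call.llr
            nano_rows.append(
                (
                    chrom,
                    "+",
                    first - 1,  # nanopolish start is 0-based at the first CpG
                    last - 1,
                    call.read_id,
                    f"{llr:.3f}",
                    f"{llr / 2:.3f}",
                    f"{-llr / 2:.3f}",
                    1,
                    len(call.positions),
                    _group_sequence(offsets),
                )
            )
            llr_r = float(f"{llr:.3f}")  # the value a parser will see
            # log sigmoid(±llr), computed stably
            lp_mod = -np.logaddexp(0.0, -llr_r)
            lp_can = -np.logaddexp(0.0, llr_r)
            for p in call.positions:
                mega_rows.append(
                    (
                        call.read_id,
                        chrom,
                        "+",
                        int(p) - 1,
                        f"{lp_mod:.6f}",
                        f"{lp_can:.6f}",
                        "m",
                    )
                )
    nano = pd.DataFrame(nano_rows, columns=NANOPOLISH_COLUMNS)
    mega = pd.DataFrame(mega_rows, columns=MEGALODON_COLUMNS)
    truth = landscape.truth_table(group)
    return nano, mega, truth


def simulate_reads(
    landscape: MethylationLandscape,
    sample_id: str,
    group: str,
    seed: int,
    out_dir,
) -> dict[str, Path]:
    """Simulate one sample and write caller-format files plus the truth.

    Writes ``<sample>_nanopolish.tsv``, ``<sample>_megalodon.tsv`` and
    ``<sample>_truth.tsv`` under *out_dir*; byte-identical across runs
    with the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nano, mega, truth = simulate_calls(landscape, sample_id, group, seed)
    paths = {
        "nanopolish": out_dir / f"{sample_id}_nanopolish.tsv",
        "megalodon": out_dir / f"{sample_id}_megalodon.tsv",
        "truth": out_dir / f"{sample_id}_truth.tsv",
    }
    nano.to_csv(paths["nanopolish"], sep="\t", index=False, lineterminator="\n")
    mega.to_csv(paths["megalodon"], sep="\t", index=False, lineterminator="\n")
    truth.to_csv(
        paths["truth"], sep="\t", index=False, float_format="%.6f", lineterminator="\n"
    )
    return paths


def simulate_records(
    landscape: MethylationLandscape, sample_id: str, group: str, seed: int
) -> Iterator[MethylationRecord]:
    """Simulate one sample directly as a MethylationRecord stream.

    Statistics match what parsing the written nanopolish file yields
    (LLRs serialized at 3 decimals), so file-based and in-memory routes
    agree exactly.
    """
    rng = np.random.default_rng([int(seed), 0xC9])
    for chrom in landscape.chrom_lengths:
        for call in _simulate_chromosome(landscape, chrom, sample_id, group, rng):
            llr = float(f"{call.llr:.3f}")
            for p in call.positions:
                yield MethylationRecord(sample_id, chrom, int(p), llr, call.read_id)


def two_group_landscape(
    n_sites: int = 150,
    spacing: int = 40,
    mu_high: float = 0.7,
    delta: float = 0.4,
    coverage: float = 50.0,
    groups: tuple[str, str] = ("A", "B"),
    **kwargs,
) -> MethylationLandscape:
    """A single-chromosome landscape where the two groups differ by *delta*
    in methylation level at every site (the canonical two-condition
    comparison used for embedding and recovery checks)."""
    length = spacing * (n_sites + 1)
    sites = {"chr1": list(range(spacing, spacing * (n_sites + 1), spacing))}
    return MethylationLandscape(
        chrom_lengths={"chr1": length},
        background_mu=mu_high,
        regions=[
            RegionEffect("chr1", 1, length, {groups[0]: mu_high, groups[1]: mu_high - delta})
        ],
        cpg_sites=sites,
        coverage=coverage,
        **kwargs,
    )
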