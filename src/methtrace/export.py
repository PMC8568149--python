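"""Site-level count matrices and exports for downstream DMR tools.

Per-read log-likelihood-ratio calls are binarized by sign (with an
optional ambiguity dead-zone) and tallied into a site x sample matrix of
methylated / unmethylated counts — the bridge to bsseq-, DSS- and
edgeR-style differential methylation inputs — plus the log-methylation-
ratio matrix used for sample embeddings:

    log-ratio(site, sample) = log2((Me + prior) / (Un + prior))

with a pseudocount prior (default 2) keeping every entry finite, the
usual convention for log-ratios of small counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .store import MethylationStore

__all__ = [
    "SiteCountMatrix",
    "LogMethylationRatioMatrix",
    "count_sites",
    "to_dmr_tables",
    "from_dss_tables",
    "log_methy_ratio",
]

DMR_FLAVORS = ("bsseq", "dss", "edger")


@dataclass
class SiteCountMatrix:
    """Per-site x per-sample methylated/unmethylated call counts.

    Both matrices share a (chromosome, position) MultiIndex sorted by
    chromosome then position, and the same ordered sample columns.
    ``n_total`` and ``n_discarded`` record the binarization bookkeeping:
    retained + discarded = records seen.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    call_threshold: float = 0.0
    n_total: int = 0
    n_discarded: int = 0

    @property
    def samples(self) -> list[str]:
        return list(self.methylated.columns)

    @property
    def sites(self) -> pd.MultiIndex:
        return self.methylated.index

    @property
    def coverage(self) -> pd.DataFrame:
        return self.methylated + self.unmethylated


@dataclass
class LogMethylationRatioMatrix:
    """Sites x samples log2 methylated/unmethylated ratio with pseudocount."""

    values: pd.DataFrame
    prior_count: float
    coverage: pd.DataFrame | None = None  # total counts for the retained sites

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def _counts_from_frame(
    df: pd.DataFrame, samples: list[str], call_threshold: float
) -> SiteCountMatrix:
    t = call_threshold
    meth_mask = df["statistic"] > t
    unmeth_mask = df["statistic"] < -t
    n_total = len(df)
    n_discarded = int((~meth_mask & ~unmeth_mask).sum())

    def tally(mask) -> pd.DataFrame:
        sub = df.loc[mask, ["chromosome", "position", "sample_id"]]
        counts = (
            sub.groupby(["chromosome", "position", "sample_id"], observed=True)
            .size()
            .unstack("sample_id", fill_value=0)
        )
        return counts

    meth = tally(meth_mask)
    unmeth = tally(unmeth_mask)
    sites = meth.index.union(unmeth.index).sort_values()
    meth = meth.reindex(index=sites, columns=samples, fill_value=0).astype(np.int64)
    unmeth = unmeth.reindex(index=sites, columns=samples, fill_value=0).astype(np.int64)
    meth.index.names = unmeth.index.names = ["chromosome", "position"]
    return SiteCountMatrix(meth, unmeth, call_threshold, n_total, n_discarded)


def count_sites(
    store: MethylationStore, call_threshold: float = 0.0
) -> SiteCountMatrix:
    """Tally methylated/unmethylated calls per site and sample.

    A record is counted methylated when ``statistic > +t``, unmethylated
    when ``statistic < -t``, and discarded when ``|statistic| <= t`` where
    ``t`` is *call_threshold* (default 0: binarize by sign, a statistic of
    exactly 0 carries no evidence and is dropped). ``t = 2`` is a common
    nanopolish-style confidence filter.
    """
    if call_threshold < 0:
        raise ValueError("call_threshold must be >= 0")
    df = store.to_frame()
    return _counts_from_frame(df, store.samples.sample_ids, call_threshold)


# -- DMR-tool table emission -------------------------------------------------


def to_dmr_tables(
    counts: SiteCountMatrix, flavor: str, out_dir
) -> dict[str, Path]:
    """Write *counts* in the input format of a downstream DMR tool.

    ``dss``   — one TSV per sample with columns (chr, pos, N, X) where
                N = coverage and X = methylated count.
    ``edger`` — one wide TSV with paired ``Me_<sample>`` / ``Un_<sample>``
                columns in sample-sheet order.
    ``bsseq`` — a site-coordinate TSV plus methylation and coverage
                matrix TSVs.

    Returns a mapping of logical name -> written path.
    """
    if flavor not in DMR_FLAVORS:
        raise ValueError(f"unknown flavor {flavor!r}; expected one of {DMR_FLAVORS}")
    if len(counts.sites) == 0:
        raise ValueError("empty count matrix")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coords = counts.methylated.index.to_frame(index=False)
    written: dict[str, Path] = {}

    if flavor == "dss":
        for sample in counts.samples:
            df = coords.rename(columns={"chromosome": "chr", "position": "pos"}).copy()
            df["N"] = (
                counts.methylated[sample] + counts.unmethylated[sample]
            ).to_numpy()
            df["X"] = counts.methylated[sample].to_numpy()
            path = out_dir / f"dss_{sample}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written[sample] = path
    elif flavor == "edger":
        wide = coords.copy()
        for sample in counts.samples:
            wide[f"Me_{sample}"] = counts.methylated[sample].to_numpy()
            wide[f"Un_{sample}"] = counts.unmethylated[sample].to_numpy()
        path = out_dir / "edger_counts.tsv"
        wide.to_csv(path, sep="\t", index=False)
        written["edger"] = path
    else:  # bsseq
        sites_path = out_dir / "bsseq_sites.tsv"
        meth_path = out_dir / "bsseq_methylation.tsv"
        cov_path = out_dir / "bsseq_coverage.tsv"
        coords.to_csv(sites_path, sep="\t", index=False)
        counts.methylated.reset_index(drop=True).to_csv(meth_path, sep="\t", index=False)
        counts.coverage.reset_index(drop=True).to_csv(cov_path, sep="\t", index=False)
        written.update(sites=sites_path, methylation=meth_path, coverage=cov_path)
    return written


def from_dss_tables(paths: Mapping[str, Path | str]) -> SiteCountMatrix:
    """Re-assemble a SiteCountMatrix from DSS-style per-sample tables.

    *paths* maps sample_id -> TSV path with columns (chr, pos, N, X).
    Sites absent from a sample contribute zero counts.
    """
    meth_cols = {}
    unmeth_cols = {}
    for sample, path in paths.items():
        df = pd.read_csv(path, sep="\t", dtype={"chr": str})
        idx = pd.MultiIndex.from_frame(
            df[["chr", "pos"]].rename(columns={"chr": "chromosome", "pos": "position"})
        )
        meth_cols[sample] = pd.Series(df["X"].to_numpy(), index=idx)
        unmeth_cols[sample] = pd.Series((df["N"] - df["X"]).to_numpy(), index=idx)
    meth = pd.DataFrame(meth_cols).fillna(0).astype(np.int64)
    unmeth = pd.DataFrame(unmeth_cols).fillna(0).astype(np.int64)
    sites = meth.index.sort_values()
    meth = meth.reindex(sites)
    unmeth = unmeth.reindex(sites)
    meth.index.names = unmeth.index.names = ["chromosome", "position"]
    n = int(meth.to_numpy().sum() + unmeth.to_numpy().sum())
    return SiteCountMatrix(meth, unmeth, n_total=n)


def log_methy_ratio(
    counts: SiteCountMatrix,
    prior_count: float = 2.0,
    min_coverage: int = 1,
) -> LogMethylationRatioMatrix:
    """Log2 methylation ratio per site and sample, with pseudocounts.

    entry = log2((Me + prior_count) / (Un + prior_count)). Sites whose
    total coverage summed over all samples is below *min_coverage* are
    dropped so all-pseudocount rows cannot dominate variance selection.
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be > 0")
    cov = counts.coverage
    keep = cov.sum(axis=1) >= min_coverage
    me = counts.methylated.loc[keep]
    un = counts.unmethylated.loc[keep]
    values = np.log2((me + prior_count) / (un + prior_count))
    return LogMethylationRatioMatrix(values, prior_count, cov.loc[keep])
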