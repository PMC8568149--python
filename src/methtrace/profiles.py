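"""Probability transforms and the curves behind the plot families.

The per-call statistic is a natural-log likelihood ratio; the sigmoid
transform p = 1/(1 + e^-LLR) maps it onto a methylation probability.
Smoothing always happens on probabilities. Two performance-critical
reductions precede smoothing:

* per-site means — reads are averaged at each site before locally
  weighted regression, so the smoother's cost scales with the number of
  sites rather than the number of calls;
* binned means on the relative axis — feature bodies are mapped to
  [0, 1] and fixed-width flanks to [-f, 0) and (1, 1+f], then averaged
  in equal-width bins so point density is uniform along x (a body
  otherwise contributes far more points per axis unit than its flanks
  and skews a nearest-neighbour smoother near the boundary).

Aggregate (metagene-style) profiles are a two-stage average: bin within
each feature first, then average across features per bin, giving every
feature equal weight regardless of its read coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .features import Feature, FeatureSet  # re-exported: FeatureSet lives here
from .ingest import MethylationRecord
from .store import MethylationStore

__all__ = [
    "Feature",
    "FeatureSet",
    "ProfileCurve",
    "sigmoid",
    "per_site_means",
    "relative_position",
    "binned_means",
    "aggregate_features",
    "smooth_curve",
    "region_summary",
    "DEFAULT_FLANK",
    "FLANK_FRACTION",
    "DEFAULT_BINS",
]

DEFAULT_FLANK = 2000  # bp of flanking sequence either side of a feature body
FLANK_FRACTION = 1.0 / 3.0  # relative-axis width of each flank vs the body
DEFAULT_BINS = 100
MIN_SMOOTH_POINTS = 5


@dataclass
class ProfileCurve:
    """A plottable (x, probability) series for one grouping level."""

    x: np.ndarray
    y: np.ndarray
    group: str = ""
    kind: str = "group-trend"  # per-read | group-trend | aggregate
    smoothed: bool = True

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing within one curve")
        if self.y.size and (np.nanmin(self.y) < -1e-9 or np.nanmax(self.y) > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")


def sigmoid(statistic):
    """Methylation probability from a log-likelihood ratio: 1/(1+e^-LLR)."""
    return expit(statistic)


def _records_frame(records: Iterable[MethylationRecord]) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        [(r.sample_id, r.chromosome, r.position, r.statistic, r.read_id) for r in records],
        columns=["sample_id", "chromosome", "position", "statistic", "read_id"],
    )


def per_site_means(
    records,
    group_by: str = "sample",
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Unweighted mean methylation probability per site and grouping level.

    Each read contributes sigmoid(statistic) at its site; means are taken
    over all reads of a (site, group). With ``group_by="sample"`` each
    sample is its own level; with ``group_by="group"`` samples are mapped
    through *groups* (sample_id -> group label) first.

    Returns a DataFrame with columns chromosome, position, group,
    mean_probability, n_reads.
    """
    df = _records_frame(records)
    if df.empty:
        raise ValueError("per_site_means requires at least one record")
    if group_by == "sample":
        label = df["sample_id"]
    elif group_by == "group":
        if groups is None:
            raise ValueError('group_by="group" requires a sample->group mapping')
        label = df["sample_id"].map(dict(groups))
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    work = pd.DataFrame(
        {
            "chromosome": df["chromosome"],
            "position": df["position"],
            "group": label,
            "p": expit(df["statistic"].to_numpy(dtype=float)),
        }
    )
    out = (
        work.groupby(["chromosome", "position", "group"], observed=True)["p"]
        .agg(mean_probability="mean", n_reads="size")
        .reset_index()
        .sort_values(["chromosome", "position", "group"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def relative_position(
    feature: Feature,
    position,
    flank: int = DEFAULT_FLANK,
    flank_fraction: float = FLANK_FRACTION,
):
    """Map genomic positions into feature-relative coordinates.

    The feature body maps linearly onto [0, 1]; the upstream flank onto
    [-f, 0) and the downstream flank onto (1, 1+f], each scaled by the
    actual bp offset into the flank (f = *flank_fraction*). Minus-strand
    features are mirrored so 0 is always the 5' end of the feature.

    Accepts a scalar or array of positions; positions outside the flanked
    window raise a ValueError.
    """
    pos = np.asarray(position, dtype=float)
    scalar = pos.ndim == 0
    pos = np.atleast_1d(pos)
    lo, hi = feature.start - flank, feature.end + flank
    if np.any(pos < lo) or np.any(pos > hi):
        raise ValueError(
            f"position outside the flanked window [{lo}, {hi}] of {feature.feature_id!r}"
        )
    f = flank_fraction
    body_len = feature.end - feature.start
    rel = np.empty_like(pos)
    before = pos < feature.start
    after = pos > feature.end
    body = ~(before | after)
    if flank > 0:
        rel[before] = -f * (feature.start - pos[before]) / flank
        rel[after] = 1 + f * (pos[after] - feature.end) / flank
    if body_len > 0:
        rel[body] = (pos[body] - feature.start) / body_len
    else:
        rel[body] = 0.5  # single-bp body: place at the midpoint
    if feature.strand == "-":
        rel = 1.0 - rel
    return float(rel[0]) if scalar else rel


def binned_means(
    x,
    y,
    n_bins: int,
    domain: tuple[float, float],
) -> pd.DataFrame:
    """Mean of *y* within equal-width bins of *x* over *domain*.

    *domain* is partitioned into ``n_bins`` half-open bins [lo, hi), the
    last bin closed. Empty bins emit no row. Returns columns bin, x
    (bin midpoint), mean, n.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    lo, hi = domain
    if not hi > lo:
        raise ValueError("domain must be non-degenerate")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError(f"x values outside domain [{lo}, {hi}]")
    width = (hi - lo) / n_bins
    idx = np.minimum(((x - lo) / width).astype(int), n_bins - 1)
    df = pd.DataFrame({"bin": idx, "y": y})
    agg = df.groupby("bin")["y"].agg(mean="mean", n="size").reset_index()
    agg["x"] = lo + (agg["bin"] + 0.5) * width
    return agg[["bin", "x", "mean", "n"]]


def aggregate_features(
    store: MethylationStore,
    features: FeatureSet,
    flank: int = DEFAULT_FLANK,
    n_bins: int = DEFAULT_BINS,
    group_by: str = "group",
    flank_fraction: float = FLANK_FRACTION,
) -> list[ProfileCurve]:
    """Equal-feature-weight aggregate methylation profile per group.

    Two-stage average: (1) within each feature, per-site mean
    probabilities are binned along the relative axis; (2) across features,
    each bin is the unweighted mean over the features that have data in
    it. A feature with 100x the coverage of another therefore contributes
    no more to the aggregate, and features missing data in a bin simply
    do not enter that bin's cross-feature mean.

    Returns one aggregate ProfileCurve per grouping level.
    """
    f = flank_fraction
    domain = (-f, 1 + f)
    groups = store.samples.groups if group_by == "group" else None
    # accumulate per (group, bin): sum of per-feature bin means + feature count
    sums: dict[tuple[str, int], float] = {}
    counts: dict[tuple[str, int], int] = {}
    any_data = False
    for feature in features:
        recs = store.query_region(
            feature.chromosome, max(1, feature.start - flank), feature.end + flank
        )
        if not recs:
            continue
        any_data = True
        means = per_site_means(recs, group_by=group_by, groups=groups)
        rel = relative_position(
            feature, means["position"].to_numpy(), flank, flank_fraction
        )
        means = means.assign(rel=rel)
        # positions below a clipped query start can't occur; rel is in-domain
        for grp, sub in means.groupby("group", observed=True):
            binned = binned_means(sub["rel"], sub["mean_probability"], n_bins, domain)
            for b, m in zip(binned["bin"], binned["mean"]):
                key = (str(grp), int(b))
                sums[key] = sums.get(key, 0.0) + float(m)
                counts[key] = counts.get(key, 0) + 1
    if not any_data:
        raise ValueError("no features overlap any records in the store")
    width = (domain[1] - domain[0]) / n_bins
    curves = []
    for grp in sorted({g for g, _ in sums}):
        bins = sorted(b for g, b in sums if g == grp)
        x = np.array([domain[0] + (b + 0.5) * width for b in bins])
        y = np.array([sums[(grp, b)] / counts[(grp, b)] for b in bins])
        curves.append(ProfileCurve(x, y, group=grp, kind="aggregate", smoothed=False))
    return curves


def smooth_curve(
    x,
    y,
    span: float = 0.2,
    group: str = "",
    kind: str = "group-trend",
    clamp: bool = True,
) -> ProfileCurve:
    """Locally weighted linear regression (lowess) of probabilities on x.

    Degree-1 local fits with tricube weights, evaluated at the input x.
    With fewer than 5 points the data are passed through unsmoothed and
    the curve is flagged (``smoothed=False``). Output is clamped to
    [0, 1] since the quantity is a probability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x.size < MIN_SMOOTH_POINTS:
        return ProfileCurve(x, y, group=group, kind=kind, smoothed=False)
    fitted = _sm_lowess(y, x, frac=span, it=0, return_sorted=False)
    if clamp:
        fitted = np.clip(fitted, 0.0, 1.0)
    return ProfileCurve(x, fitted, group=group, kind=kind, smoothed=True)


def region_summary(
    store: MethylationStore,
    regions: FeatureSet,
    group_by: str = "group",
    complement_label: str | None = None,
) -> pd.DataFrame:
    """Pooled per-site mean probabilities per region class and group.

    For each class label in *regions* and each grouping level, collects
    the per-site mean probabilities of the sites falling inside that
    class's regions (regions must not overlap within a class, so no site
    is double counted). When *complement_label* is given, sites covered
    by no region are pooled under that label. The result feeds box plots.

    Returns columns region_class, group, chromosome, position,
    mean_probability, n_reads.
    """
    groups = store.samples.groups if group_by == "group" else None
    pieces = []
    covered: set[tuple[str, int]] = set()
    for label in regions.labels:
        for feature in regions.with_label(label):
            recs = store.query_region(feature.chromosome, feature.start, feature.end)
            if not recs:
                continue
            means = per_site_means(recs, group_by=group_by, groups=groups)
            means.insert(0, "region_class", label)
            pieces.append(means)
            covered.update(
                zip(means["chromosome"], means["position"].astype(int))
            )
    if complement_label is not None:
        all_means = per_site_means(
            store.to_frame(), group_by=group_by, groups=groups
        )
        mask = [
            (c, int(p)) not in covered
            for c, p in zip(all_means["chromosome"], all_means["position"])
        ]
        rest = all_means.loc[mask].copy()
        rest.insert(0, "region_class", complement_label)
        pieces.append(rest)
    if not pieces:
        return pd.DataFrame(
            columns=[
                "region_class",
                "chromosome",
                "position",
                "group",
                "mean_probability",
                "n_reads",
            ]
        )
    return pd.concat(pieces, ignore_index=True)
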