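"""Figure rendering: spaghetti, heatmap, aggregate, embedding, box plots.

All plot functions return a matplotlib Figure; nothing is shown or saved
implicitly. Regions are given as (chromosome, start, end) tuples or
"chr:start-end" strings with 1-based closed coordinates. Group panels
and legends follow sample-sheet order so repeated renders are identical;
:func:`save_figure` additionally pins the SVG hash salt and drops the
date stamp so vector output is byte-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Rectangle

from .dimred import Embedding
from .profiles import ProfileCurve, per_site_means, sigmoid, smooth_curve
from .store import MethylationStore

__all__ = [
    "GeneModel",
    "ExonAnnotation",
    "AnnotationError",
    "EmptyRegionError",
    "read_annotation",
    "load_dmr_table",
    "pack_reads",
    "plot_spaghetti",
    "plot_heatmap",
    "plot_aggregate",
    "plot_embedding",
    "plot_region_summary",
    "parse_region",
    "save_figure",
]

DEFAULT_TOP_DMRS = 500
HEATMAP_CMAP = "coolwarm"  # diverging, anchored at p=0.5


class AnnotationError(ValueError):
    pass


class EmptyRegionError(ValueError):
    pass


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    chromosome: str
    strand: str
    exons: list[tuple[int, int]]  # merged, sorted, 1-based closed

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


@dataclass
class ExonAnnotation:
    """Per-gene merged exon intervals with a symbol lookup index."""

    genes: dict[str, GeneModel]

    def lookup(self, symbol: str) -> GeneModel:
        hits = [
            g
            for g in self.genes.values()
            if g.symbol == symbol or g.gene_id == symbol
        ]
        if not hits:
            raise LookupError(f"no gene named {symbol!r} in annotation")
        if len(hits) > 1:
            raise LookupError(
                f"{symbol!r} is ambiguous: {[g.gene_id for g in hits]}"
            )
        return hits[0]

    def overlapping(self, chromosome: str, start: int, end: int) -> list[GeneModel]:
        return [
            g
            for g in self.genes.values()
            if g.chromosome == chromosome and g.start <= end and g.end >= start
        ]


def read_annotation(path) -> ExonAnnotation:
    """Read exon structure from a GTF/GFF file.

    Exons are grouped by gene id, merged and sorted; gene symbols come
    from the ``gene_name`` attribute when present, else the gene id.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    raw: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        gene_ids = exon.attributes.get("gene_id") or exon.attributes.get("Parent")
        if not gene_ids:
            continue
        gid = gene_ids[0]
        symbol = (exon.attributes.get("gene_name") or [gid])[0]
        entry = raw.setdefault(
            gid,
            {"symbol": symbol, "chromosome": exon.seqid, "strand": exon.strand, "exons": []},
        )
        entry["exons"].append((exon.start, exon.end))  # gffutils is 1-based closed
    if not raw:
        raise AnnotationError(f"no exon features found in {path}")
    genes = {
        gid: GeneModel(gid, e["symbol"], e["chromosome"], e["strand"], _merge_intervals(e["exons"]))
        for gid, e in raw.items()
    }
    return ExonAnnotation(genes)


def load_dmr_table(path) -> pd.DataFrame:
    """Read a DMR table (chromosome, start, end, rank); larger rank = more
    differential."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"chromosome", "start", "end", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DMR table missing columns: {sorted(missing)}")
    if (df["start"] > df["end"]).any():
        raise ValueError("DMR table contains intervals with start > end")
    return df


def parse_region(region) -> tuple[str, int, int]:
    """Accept "chr:start-end" or a (chromosome, start, end) tuple."""
    if isinstance(region, str):
        chrom, span = region.rsplit(":", 1)
        start, end = span.replace(",", "").split("-")
        return chrom, int(start), int(end)
    chrom, start, end = region
    return str(chrom), int(start), int(end)


# -- read lane packing --------------------------------------------------------


def pack_reads(spans) -> np.ndarray:
    """Assign reads to plot lanes so overlapping spans never share a lane.

    Greedy first-fit by ascending start (ties broken by read id, then by
    input order): each read goes to the lowest lane whose last end is
    strictly before the read's start (closed intervals: touching reads
    conflict). On interval graphs first-fit by start is optimal, so the
    lane count equals the maximum overlap depth.

    *spans* is a sequence of (start, end) or (start, end, read_id); the
    returned array gives each input's lane in input order.
    """
    keyed = []
    for i, span in enumerate(spans):
        start, end = span[0], span[1]
        read_id = span[2] if len(span) > 2 else ""
        keyed.append((start, str(read_id), i, end))
    keyed.sort(key=lambda t: (t[0], t[1], t[2]))
    lanes_end: list[float] = []
    out = np.empty(len(keyed), dtype=int)
    for start, _, i, end in keyed:
        for lane, last_end in enumerate(lanes_end):
            if last_end < start:
                lanes_end[lane] = end
                out[i] = lane
                break
        else:
            lanes_end.append(end)
            out[i] = len(lanes_end) - 1
    return out


# -- shared plot furniture ----------------------------------------------------


def _group_labels(store: MethylationStore) -> list[str]:
    seen = []
    for _, g in store.samples.entries:
        if g not in seen:
            seen.append(g)
    return seen


def _records_by_group(store, chrom, start, end):
    records = store.query_region(chrom, start, end)
    if not records:
        raise EmptyRegionError(f"no methylation calls in {chrom}:{start}-{end}")
    groups = store.samples.groups
    df = pd.DataFrame(
        [(r.sample_id, r.chromosome, r.position, r.statistic, r.read_id) for r in records],
        columns=["sample_id", "chromosome", "position", "statistic", "read_id"],
    )
    df["group"] = df["sample_id"].map(groups)
    return df


def _draw_site_ticks(ax, positions):
    ymin, _ = ax.get_ylim()
    ax.plot(
        np.asarray(sorted(set(positions))),
        np.full(len(set(positions)), -0.03),
        marker="|",
        linestyle="none",
        color="black",
        markersize=6,
        clip_on=False,
    )


def _shade_dmrs(ax, dmrs, chrom, start, end, top_n):
    if dmrs is None or len(dmrs) == 0:
        return 0
    top = dmrs.nlargest(min(top_n, len(dmrs)), "rank")
    hit = top[
        (top["chromosome"] == chrom) & (top["start"] <= end) & (top["end"] >= start)
    ]
    for _, row in hit.iterrows():
        ax.axvspan(row["start"], row["end"], color="0.85", zorder=0)
    return len(hit)


def _draw_exons(ax, annotation, chrom, start, end):
    if annotation is None:
        return
    y = -0.12
    for gene in annotation.overlapping(chrom, start, end):
        ax.plot([gene.start, gene.end], [y, y], color="darkblue", lw=1, clip_on=False)
        for s, e in gene.exons:
            ax.add_patch(
                Rectangle((s, y - 0.02), e - s + 1, 0.04, color="darkblue", clip_on=False)
            )
        ax.annotate(
            gene.symbol,
            ((gene.start + gene.end) / 2, y - 0.05),
            ha="center",
            va="top",
            fontsize=8,
            annotation_clip=False,
        )


def _group_colors(groups):
    cmap = plt.get_cmap("tab10")
    return {g: cmap(i % 10) for i, g in enumerate(groups)}


# -- figures ------------------------------------------------------------------


def plot_spaghetti(
    store: MethylationStore,
    region,
    annotation: ExonAnnotation | None = None,
    dmrs: pd.DataFrame | None = None,
    top_n: int = DEFAULT_TOP_DMRS,
    span: float = 0.2,
):
    """Per-read smoothed methylation lines with per-group trends.

    Thin lines: each read's probabilities smoothed along its own sites
    (reads with fewer than 5 sites are drawn unsmoothed). Thick lines:
    the per-group trend, computed from per-site means then smoothed.
    CpG site positions are ticked along the x-axis, exons drawn below it,
    and DMRs among the *top_n* by rank that overlap the window shaded.
    """
    chrom, start, end = parse_region(region)
    df = _records_by_group(store, chrom, start, end)
    groups = _group_labels(store)
    colors = _group_colors(groups)

    fig, ax = plt.subplots(figsize=(9, 4))
    _shade_dmrs(ax, dmrs, chrom, start, end, top_n)
    for (read_id, group), sub in df.groupby(["read_id", "group"], observed=True):
        sub = sub.sort_values("position")
        curve = smooth_curve(
            sub["position"], sigmoid(sub["statistic"].to_numpy()),
            span=min(1.0, max(span * 3, 0.5)), kind="per-read",
        )
        ax.plot(curve.x, curve.y, color=colors.get(group, "gray"), alpha=0.25, lw=0.7)
    for group in groups:
        sub = df[df["group"] == group]
        if sub.empty:
            warnings.warn(f"group {group!r} has no records in the plotted region")
            continue
        means = per_site_means(sub, group_by="group", groups=store.samples.groups)
        means = means[means["group"] == group]
        curve = smooth_curve(
            means["position"], means["mean_probability"], span=span, group=group
        )
        ax.plot(curve.x, curve.y, color=colors[group], lw=2.5, label=group)
    ax.set_ylim(-0.05, 1.05)
    _draw_site_ticks(ax, df["position"])
    _draw_exons(ax, annotation, chrom, start, end)
    ax.set_xlim(start, end)
    ax.set_xlabel(f"{chrom} position (bp)")
    ax.set_ylabel("methylation probability")
    ax.legend(title="group", loc="upper right")
    fig.tight_layout()
    return fig


def plot_heatmap(store: MethylationStore, region, cell_bp: float | None = None):
    """Per-read heatmap: one lane-packed row per read, one cell per call.

    Cells are colored by methylation probability on a fixed diverging
    scale anchored at 0.5 (an LLR of 0 maps to the midpoint color); no
    smoothing is applied. Each group gets its own panel, in sample-sheet
    order. With *cell_bp* set, cells are drawn bp-proportional instead of
    fixed width.
    """
    chrom, start, end = parse_region(region)
    df = _records_by_group(store, chrom, start, end)
    groups = [g for g in _group_labels(store) if (df["group"] == g).any()]
    for g in _group_labels(store):
        if g not in groups:
            warnings.warn(f"group {g!r} has no records in the plotted region")
    fig, axes = plt.subplots(
        len(groups), 1, figsize=(9, 2 + 1.2 * len(groups)), squeeze=False, sharex=True
    )
    for ax, group in zip(axes[:, 0], groups):
        sub = df[df["group"] == group]
        spans = (
            sub.groupby("read_id")["position"]
            .agg(["min", "max"])
            .reset_index()
        )
        lanes = pack_reads(
            list(zip(spans["min"], spans["max"], spans["read_id"]))
        )
        lane_of = dict(zip(spans["read_id"], lanes))
        y = sub["read_id"].map(lane_of)
        p = sigmoid(sub["statistic"].to_numpy())
        if cell_bp is None:
            ax.scatter(
                sub["position"], y, c=p, cmap=HEATMAP_CMAP, vmin=0, vmax=1,
                marker="s", s=18, linewidths=0,
            )
        else:
            for xp, yp, pp in zip(sub["position"], y, p):
                ax.add_patch(
                    Rectangle(
                        (xp - cell_bp / 2, yp - 0.4), cell_bp, 0.8,
                        color=plt.get_cmap(HEATMAP_CMAP)(pp),
                    )
                )
        ax.set_ylim(-0.6, max(lanes) + 0.6 if len(lanes) else 0.6)
        ax.set_ylabel(f"{group}\nreads")
        ax.set_yticks([])
    axes[-1, 0].set_xlim(start, end)
    axes[-1, 0].set_xlabel(f"{chrom} position (bp)")
    sm = matplotlib.cm.ScalarMappable(
        norm=matplotlib.colors.Normalize(0, 1), cmap=HEATMAP_CMAP
    )
    fig.colorbar(sm, ax=axes[:, 0], label="methylation probability")
    return fig


def plot_aggregate(curves: list[ProfileCurve], span: float = 0.3):
    """Aggregate profile lines over the relative axis with guides at the
    feature start (0) and end (1)."""
    if not curves:
        raise ValueError("no curves to plot")
    fig, ax = plt.subplots(figsize=(7, 4))
    colors = _group_colors([c.group for c in curves])
    for curve in curves:
        sm = smooth_curve(curve.x, curve.y, span=span, group=curve.group, kind="aggregate")
        ax.plot(sm.x, sm.y, lw=2, color=colors[curve.group], label=curve.group or "all")
    for guide in (0.0, 1.0):
        ax.axvline(guide, color="0.4", ls="--", lw=0.8)
    ax.set_ylim(0, 1)
    ax.set_xlabel("relative position (0 = feature start, 1 = feature end)")
    ax.set_ylabel("methylation probability")
    ax.legend(title="group")
    fig.tight_layout()
    return fig


def plot_embedding(embedding: Embedding, labels: dict[str, str] | None = None):
    """Scatter of embedding dimensions 1-2, colored by group label."""
    coords = embedding.coordinates
    if coords.shape[1] < 2:
        raise ValueError("embedding must have at least 2 dimensions")
    labels = labels or {s: s for s in embedding.samples}
    groups = []
    for s in embedding.samples:
        g = labels.get(s, s)
        if g not in groups:
            groups.append(g)
    colors = _group_colors(groups)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    for g in groups:
        samples = [s for s in embedding.samples if labels.get(s, s) == g]
        sub = coords.loc[samples]
        ax.scatter(sub["dim1"], sub["dim2"], color=colors[g], label=g, s=40)
        for s in samples:
            ax.annotate(s, (coords.loc[s, "dim1"], coords.loc[s, "dim2"]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
    if embedding.method == "PCA" and embedding.explained is not None:
        ax.set_xlabel(f"PC-1 ({100 * embedding.explained[0]:.1f}% var)")
        ax.set_ylabel(f"PC-2 ({100 * embedding.explained[1]:.1f}% var)")
    else:
        ax.set_xlabel(f"{embedding.method}-1")
        ax.set_ylabel(f"{embedding.method}-2")
    ax.legend(title="group")
    fig.tight_layout()
    return fig


def plot_region_summary(summary: pd.DataFrame):
    """Box plots of per-site mean probabilities per region class and group."""
    if summary.empty:
        raise ValueError("empty region summary")
    classes = list(dict.fromkeys(summary["region_class"]))
    groups = list(dict.fromkeys(summary["group"]))
    colors = _group_colors(groups)
    fig, ax = plt.subplots(figsize=(1.8 * len(classes) * len(groups) + 2, 4))
    width = 0.8 / len(groups)
    for gi, group in enumerate(groups):
        data, positions = [], []
        for ci, cls in enumerate(classes):
            vals = summary.loc[
                (summary["region_class"] == cls) & (summary["group"] == group),
                "mean_probability",
            ]
            data.append(vals.to_numpy())
            positions.append(ci + (gi - (len(groups) - 1) / 2) * width)
        bp = ax.boxplot(data, positions=positions, widths=width * 0.9,
                        patch_artist=True)
        for box in bp["boxes"]:
            box.set_facecolor(colors[group])
        ax.plot([], [], color=colors[group], label=group, lw=6)
    ax.set_xticks(range(len(classes)))
    ax.set_xticklabels(classes)
    ax.set_ylabel("methylation probability")
    ax.set_ylim(0, 1)
    ax.legend(title="group")
    fig.tight_layout()
    return fig


def save_figure(fig, path):
    """Save a figure reproducibly (fixed SVG hash salt, no date stamp)."""
    path = str(path)
    with matplotlib.rc_context({"svg.hashsalt": "methtrace"}):
        if path.endswith(".svg"):
            fig.savefig(path, metadata={"Date": None})
        else:
            fig.savefig(path)
    return path
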