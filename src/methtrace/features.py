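"""Genomic feature tables used for aggregation, annotation and lookup.

Internal coordinates are 1-based fully closed. BED input (0-based
half-open) is converted on read.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

__all__ = ["Feature", "FeatureSet", "AmbiguousFeatureError", "UnknownFeatureError"]


class UnknownFeatureError(LookupError):
    pass


class AmbiguousFeatureError(LookupError):
    pass


@dataclass(frozen=True, slots=True)
class Feature:
    chromosome: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    strand: str = "+"
    feature_id: str = ""
    label: str = ""  # class label used for grouped aggregation / summaries

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"feature start > end: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


class FeatureSet:
    """An ordered collection of features with unique ids and name lookup."""

    def __init__(self, features: Iterable[Feature]):
        self._features = list(features)
        ids = [f.feature_id for f in self._features]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate feature_ids: {dupes}")
        self._by_id = {f.feature_id: f for f in self._features}

    def __iter__(self) -> Iterator[Feature]:
        return iter(self._features)

    def __len__(self) -> int:
        return len(self._features)

    def __getitem__(self, i) -> Feature:
        return self._features[i]

    @property
    def labels(self) -> list[str]:
        out: list[str] = []
        for f in self._features:
            if f.label not in out:
                out.append(f.label)
        return out

    def with_label(self, label: str) -> "FeatureSet":
        return FeatureSet([f for f in self._features if f.label == label])

    def lookup(self, name: str) -> Feature:
        """Resolve *name* to exactly one feature.

        Raises an error listing near matches when absent, or listing the
        colliding entries when more than one feature carries the name.
        """
        matches = [f for f in self._features if f.feature_id == name]
        if len(matches) > 1:
            raise AmbiguousFeatureError(
                f"{name!r} matches {len(matches)} features: {matches}"
            )
        if matches:
            return matches[0]
        near = difflib.get_close_matches(name, list(self._by_id), n=5)
        raise UnknownFeatureError(f"unknown feature {name!r}; near matches: {near}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_bed(cls, path, label: str = "") -> "FeatureSet":
        """Read a BED file (0-based half-open), converting to 1-based closed.

        Column 4 (name) becomes the feature_id when present; column 6 the
        strand. Unnamed intervals get positional ids.
        """
        feats = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 and parts[3] != "." else f"feature_{i}"
                strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
                feats.append(
                    Feature(chrom, start0 + 1, end0, strand, name, label)
                )
        return cls(feats)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureSet":
        """Build from a DataFrame with columns chromosome, start, end and
        optional strand, feature_id, label (1-based closed coordinates)."""
        feats = []
        for i, row in enumerate(df.itertuples(index=False)):
            feats.append(
                Feature(
                    str(row.chromosome),
                    int(row.start),
                    int(row.end),
                    str(getattr(row, "strand", "+") or "+"),
                    str(getattr(row, "feature_id", "") or f"feature_{i}"),
                    str(getattr(row, "label", "") or ""),
                )
            )
        return cls(feats)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (f.chromosome, f.start, f.end, f.strand, f.feature_id, f.label)
                for f in self._features
            ],
            columns=["chromosome", "start", "end", "strand", "feature_id", "label"],
        )
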