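"""Sorted, bgzip-compressed, tabix-indexed storage of methylation records.

The on-disk layout is a 5-column TSV (sample_id, chromosome, position,
statistic, read_id) sorted by chromosome (lexicographic byte order) then
position, block-compressed with bgzip and indexed with tabix (sequence
column 2, begin/end column 3, 1-based coordinates). Region queries
decompress only the blocks overlapping the request, so arbitrarily large
datasets can be sliced on ordinary hardware.

Sorting during construction is an external merge sort with a bounded
per-chunk row count, so building the store also runs in bounded memory.
"""

from __future__ import annotations

import heapq
import os
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .ingest import MethylationRecord

__all__ = ["MethylationStore", "SampleSheet", "build_store"]

DEFAULT_CHUNK_SIZE = 1_000_000


@dataclass(frozen=True)
class SampleSheet:
    """Sample manifest: ordered (sample_id, group) pairs.

    Groups carry the experimental labels (condition, haplotype, ...) that
    drive grouped plots and exports. Stored as a small TSV sidecar next to
    the data file so the indexed file itself stays minimal.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        ids = [s for s, _ in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate sample_ids in sample sheet: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def groups(self) -> dict[str, str]:
        return dict(self.entries)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SampleSheet":
        return cls(tuple((str(s), str(g)) for s, g in pairs))

    @classmethod
    def read(cls, path) -> "SampleSheet":
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sample_id", "group"]:
                raise ValueError(f"malformed sample sheet header: {header}")
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                sample, group = line.split("\t")[:2]
                entries.append((sample, group))
        return cls(tuple(entries))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tgroup\n")
            for sample, group in self.entries:
                fh.write(f"{sample}\t{group}\n")


def _sidecar_path(data_path) -> Path:
    return Path(str(data_path) + ".samples.tsv")


def _format_record(rec: MethylationRecord) -> str:
    # statistic kept to 6 significant digits; round-trip tolerance 1e-6 rel.
    return f"{rec.sample_id}\t{rec.chromosome}\t{rec.position}\t{rec.statistic:.6g}\t{rec.read_id}\n"


def _parse_row(line: str) -> MethylationRecord:
    sample, chrom, pos, stat, read = line.rstrip("\n").split("\t")
    return MethylationRecord(sample, chrom, int(pos), float(stat), read)


def build_store(
    records: Iterable[MethylationRecord],
    out_path,
    samples: SampleSheet | Iterable[tuple[str, str]] | None = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
) -> "MethylationStore":
    """Sort, compress and index a finite record stream.

    Parameters
    ----------
    records : iterable of MethylationRecord
        Finite stream; consumed once. Records with position < 1 are
        rejected.
    out_path : path
        Destination for the bgzip file (a ``.tbi`` index is written next
        to it, and a ``.samples.tsv`` sidecar when *samples* is given).
    samples : SampleSheet or (sample_id, group) pairs, optional
        Sample manifest. If omitted, a sheet is synthesized from the
        sample ids seen in the data, each its own group.
    chunk_size : int
        Rows sorted in memory per external-sort chunk.
    """
    out_path = Path(out_path)
    key = lambda row: (row[0], row[1])  # (chromosome, position)

    chunk_files: list[str] = []
    chunk: list[tuple[str, int, str]] = []
    seen_samples: dict[str, None] = {}
    tmpdir = tempfile.mkdtemp(prefix="methtrace_sort_")

    def flush():
        if not chunk:
            return
        chunk.sort(key=key)
        fd, name = tempfile.mkstemp(dir=tmpdir, suffix=".tsv")
        with os.fdopen(fd, "w") as fh:
            fh.writelines(row[2] for row in chunk)
        chunk_files.append(name)
        chunk.clear()

    try:
        for rec in records:
            if rec.position < 1:
                raise ValueError(f"record with position < 1 rejected: {rec}")
            seen_samples.setdefault(rec.sample_id)
            chunk.append((rec.chromosome, rec.position, _format_record(rec)))
            if len(chunk) >= chunk_size:
                flush()
        flush()

        plain = str(out_path) + ".plain.tmp"
        with open(plain, "w") as out:
            if len(chunk_files) <= 1:
                if chunk_files:
                    with open(chunk_files[0]) as fh:
                        for line in fh:
                            out.write(line)
            else:
                streams = [open(name) for name in chunk_files]
                try:
                    def keyed(fh):
                        for line in fh:
                            parts = line.split("\t", 3)
                            yield (parts[1], int(parts[2]), line)

                    # key= keeps the merge stable for equal (chrom, position)
                    merged = heapq.merge(
                        *(keyed(fh) for fh in streams), key=lambda t: (t[0], t[1])
                    )
                    for _, _, line in merged:
                        out.write(line)
                finally:
                    for fh in streams:
                        fh.close()
    finally:
        for name in chunk_files:
            try:
                os.unlink(name)
            except OSError:
                pass
        try:
            os.rmdir(tmpdir)
        except OSError:
            pass

    pysam.tabix_compress(plain, str(out_path), force=True)
    os.unlink(plain)
    # tabix generic TSV preset: sequence col 2, begin/end col 3, 1-based
    pysam.tabix_index(
        str(out_path), force=True, seq_col=1, start_col=2, end_col=2, zerobased=False
    )

    if samples is None:
        sheet = SampleSheet.from_pairs((s, s) for s in seen_samples)
    elif isinstance(samples, SampleSheet):
        sheet = samples
    else:
        sheet = SampleSheet.from_pairs(samples)
    sheet.write(_sidecar_path(out_path))
    return MethylationStore(out_path)


class MethylationStore:
    """Read handle to a built store (bgzip data + tabix index + samples)."""

    def __init__(self, data_path, samples: SampleSheet | None = None):
        self.data_path = Path(data_path)
        self.index_path = Path(str(data_path) + ".tbi")
        if not self.data_path.exists():
            raise FileNotFoundError(self.data_path)
        if not self.index_path.exists():
            raise FileNotFoundError(
                f"tabix index not found: {self.index_path} (rebuild the store)"
            )
        if samples is not None:
            self.samples = samples
        else:
            sidecar = _sidecar_path(data_path)
            if sidecar.exists():
                self.samples = SampleSheet.read(sidecar)
            else:
                ids = sorted(
                    {rec.sample_id for rec in self.iter_records()}
                )
                self.samples = SampleSheet.from_pairs((s, s) for s in ids)

    # -- queries ---------------------------------------------------------

    def contigs(self) -> list[str]:
        with pysam.TabixFile(str(self.data_path)) as tbx:
            return list(tbx.contigs)

    def query_region(
        self, chromosome: str, start: int, end: int
    ) -> list[MethylationRecord]:
        """All records with ``start <= position <= end`` on *chromosome*.

        Coordinates are 1-based and fully closed, matching the stored
        format. A chromosome absent from the index yields an empty list
        with a warning, not an error.
        """
        if start > end:
            raise ValueError(f"start > end in query: {start} > {end}")
        start = max(1, start)
        with pysam.TabixFile(str(self.data_path)) as tbx:
            if chromosome not in tbx.contigs:
                warnings.warn(
                    f"chromosome {chromosome!r} not present in store index",
                    stacklevel=2,
                )
                return []
            # pysam.fetch takes 0-based half-open coordinates
            return [_parse_row(row) for row in tbx.fetch(chromosome, start - 1, end)]

    def query_genes(
        self, feature_set, name: str, flank: int = 0
    ) -> list[MethylationRecord]:
        """Records over a named feature's span, extended by *flank* bp.

        The window is clipped to begin at position 1. Unknown or ambiguous
        names raise a lookup error listing near matches.
        """
        feature = feature_set.lookup(name)
        start = max(1, feature.start - flank)
        return self.query_region(feature.chromosome, start, feature.end + flank)

    def iter_records(self) -> Iterator[MethylationRecord]:
        """Stream every record in file order (whole-genome scan)."""
        import gzip  # bgzip is valid gzip; stream without loading the file

        with gzip.open(self.data_path, "rt") as fh:
            for line in fh:
                if line.strip():
                    yield _parse_row(line)

    def to_frame(self):
        """Load the full store as a pandas DataFrame (small stores only)."""
        import pandas as pd

        return pd.read_csv(
            self.data_path,
            sep="\t",
            compression="gzip",
            names=["sample_id", "chromosome", "position", "statistic", "read_id"],
            dtype={"chromosome": str, "sample_id": str, "read_id": str},
        )
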