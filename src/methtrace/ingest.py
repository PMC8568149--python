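"""Parsers for per-read methylation caller output.

Supported dialects:

* **nanopolish / f5c** — ``nanopolish call-methylation`` style TSV. f5c
  emits the same columns and is handled by the same parser. A single row
  may describe a *group* of nearby CpG motifs (``num_motifs > 1``); such
  rows are split into one record per motif using the CG offsets in the
  reported ``sequence`` context.
* **Megalodon** — per-read modified-base text output. The methylation
  statistic is formed as ``mod_log_prob - can_log_prob``, which is the
  natural-log likelihood ratio of modification; applying the sigmoid to
  it recovers the normalized modification probability exactly.

All parsers emit :class:`MethylationRecord` streams with 1-based
single-nucleotide positions at the CpG cytosine, positive statistic =
evidence for methylation. Parsing is lazy (generator based), so peak
memory is independent of input size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "MethylationRecord",
    "ParseReport",
    "FormatError",
    "ParseError",
    "InconsistentCallError",
    "parse_nanopolish",
    "parse_megalodon",
    "split_grouped_call",
    "read_calls",
    "CALLERS",
]


class FormatError(ValueError):
    """The input file does not look like the declared caller dialect."""


class ParseError(ValueError):
    """A data line could not be parsed (strict mode only)."""


class InconsistentCallError(ValueError):
    """A grouped call's sequence context disagrees with its num_motifs."""


@dataclass(frozen=True, slots=True)
class MethylationRecord:
    """One per-read, per-site methylation call.

    Attributes
    ----------
    sample_id : str
        Sample the originating file was imported as.
    chromosome : str
        Reference sequence name.
    position : int
        1-based position of the CpG cytosine on the reported strand.
    statistic : float
        Natural-log likelihood ratio; positive favors methylation.
    read_id : str
        Identifier of the sequencing read carrying the call.
    """

    sample_id: str
    chromosome: str
    position: int
    statistic: float
    read_id: str


@dataclass
class ParseReport:
    """Mutable tally of a lenient parse, updated in place by the parsers."""

    lines: int = 0
    records: int = 0
    skipped: int = 0

    def summary(self) -> str:
        return f"{self.lines} lines, {self.records} records, {self.skipped} skipped"


NANOPOLISH_REQUIRED = (
    "chromosome",
    "strand",
    "start",
    "read_name",
    "log_lik_ratio",
    "num_motifs",
    "sequence",
)

MEGALODON_REQUIRED = (
    "read_id",
    "chrm",
    "strand",
    "pos",
    "mod_log_prob",
    "can_log_prob",
)


def _header_index(header_line: str, required: Sequence[str], dialect: str) -> dict:
    cols = header_line.rstrip("\n").rstrip("\r").split("\t")
    idx = {name: i for i, name in enumerate(cols)}
    for name in required:
        if name not in idx:
            raise FormatError(
                f"{dialect} input is missing required column {name!r}; "
                f"found columns {cols!r}"
            )
    return idx


def _cg_offsets(sequence: str) -> list[int]:
    """0-based offsets of every 'CG' in *sequence* (case-insensitive)."""
    seq = sequence.upper()
    out = []
    i = seq.find("CG")
    while i != -1:
        out.append(i)
        i = seq.find("CG", i + 1)
    return out


def split_grouped_call(
    start: int, log_lik_ratio: float, num_motifs: int, sequence: str
) -> list[tuple[int, float]]:
    """Split a (possibly grouped) nanopolish call into per-motif positions.

    The caller reports ``start`` as the 0-based position of the first CpG
    cytosine; the first motif therefore maps to 1-based ``start + 1``.
    Subsequent motifs are offset by the spacing between successive "CG"
    occurrences in the reported sequence context. Every motif inherits the
    group's log-likelihood ratio unchanged.

    Returns a list of ``(position, statistic)`` pairs, one per motif.

    Raises
    ------
    InconsistentCallError
        If the number of "CG" occurrences in *sequence* differs from
        ``num_motifs``.
    """
    offsets = _cg_offsets(sequence)
    if len(offsets) != num_motifs:
        raise InconsistentCallError(
            f"call at start={start} declares num_motifs={num_motifs} but its "
            f"sequence {sequence!r} contains {len(offsets)} CG motif(s)"
        )
    first = offsets[0]
    return [(start + 1 + (off - first), log_lik_ratio) for off in offsets]


def parse_nanopolish(
    lines: Iterable[str],
    sample_id: str,
    *,
    strict: bool = False,
    report: ParseReport | None = None,
) -> Iterator[MethylationRecord]:
    """Parse nanopolish/f5c methylation-call TSV into record stream.

    Parameters
    ----------
    lines : iterable of str
        An open text file or any line iterable; the first line must be the
        header naming the nanopolish columns.
    sample_id : str
        Sample name to stamp onto every record.
    strict : bool
        If True, malformed data lines raise :class:`ParseError` with the
        line number; otherwise they are counted in *report* and skipped.
    report : ParseReport, optional
        Tally object updated in place (lenient mode bookkeeping).
    """
    if not sample_id:
        raise ValueError("sample_id must be non-empty")
    if report is None:
        report = ParseReport()
    it = iter(lines)
    try:
        header = next(it)
    except StopIteration:
        raise FormatError("nanopolish input is empty (no header)") from None
    idx = _header_index(header, NANOPOLISH_REQUIRED, "nanopolish")

    for lineno, line in enumerate(it, start=2):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        report.lines += 1
        fields = line.split("\t")
        try:
            chrom = fields[idx["chromosome"]]
            start = int(fields[idx["start"]])
            read = fields[idx["read_name"]]
            llr = float(fields[idx["log_lik_ratio"]])
            nmot = int(fields[idx["num_motifs"]])
            seq = fields[idx["sequence"]]
            if not chrom or not read or nmot < 1 or not math.isfinite(llr):
                raise ValueError("invalid field value")
            split = split_grouped_call(start, llr, nmot, seq)
        except (IndexError, ValueError) as exc:
            if strict:
                raise ParseError(f"line {lineno}: {exc}") from exc
            report.skipped += 1
            continue
        for pos, stat in split:
            report.records += 1
            yield MethylationRecord(sample_id, chrom, pos, stat, read)


def parse_megalodon(
    lines: Iterable[str],
    sample_id: str,
    *,
    strict: bool = False,
    collapse_strands: bool = False,
    report: ParseReport | None = None,
) -> Iterator[MethylationRecord]:
    """Parse Megalodon per-read modified-base TSV into a record stream.

    The statistic is ``mod_log_prob - can_log_prob`` so that the sigmoid
    transform reproduces the normalized modification probability. Columns
    are located by header name, not by position, because Megalodon's column
    order varies across versions.

    With ``collapse_strands=True``, minus-strand calls are shifted by
    -1 bp onto the forward-strand cytosine so both strands of a CpG stack
    on one position; the default preserves the caller's coordinates.
    """
    if not sample_id:
        raise ValueError("sample_id must be non-empty")
    if report is None:
        report = ParseReport()
    it = iter(lines)
    try:
        header = next(it)
    except StopIteration:
        raise FormatError("Megalodon input is empty (no header)") from None
    idx = _header_index(header, MEGALODON_REQUIRED, "Megalodon")

    for lineno, line in enumerate(it, start=2):
        line = line.rstrip("\n").rstrip("\r")
        if not line:
            continue
        report.lines += 1
        fields = line.split("\t")
        try:
            read = fields[idx["read_id"]]
            chrom = fields[idx["chrm"]]
            strand = fields[idx["strand"]]
            pos = int(fields[idx["pos"]])
            mlp = float(fields[idx["mod_log_prob"]])
            clp = float(fields[idx["can_log_prob"]])
            if not read or not chrom or pos < 0:
                raise ValueError("invalid field value")
            stat = mlp - clp
            if not math.isfinite(stat):
                raise ValueError("non-finite statistic")
        except (IndexError, ValueError) as exc:
            if strict:
                raise ParseError(f"line {lineno}: {exc}") from exc
            report.skipped += 1
            continue
        position = pos + 1
        if collapse_strands and strand == "-":
            position = max(1, position - 1)
        report.records += 1
        yield MethylationRecord(sample_id, chrom, position, stat, read)


CALLERS = {
    "nanopolish": parse_nanopolish,
    "f5c": parse_nanopolish,  # identical column dialect
    "megalodon": parse_megalodon,
}


def read_calls(
    path,
    caller: str,
    sample_id: str,
    *,
    strict: bool = False,
    report: ParseReport | None = None,
    **kwargs,
) -> Iterator[MethylationRecord]:
    """Open *path* and parse it with the named caller dialect."""
    try:
        parser = CALLERS[caller]
    except KeyError:
        raise ValueError(
            f"unknown caller {caller!r}; expected one of {sorted(CALLERS)}"
        ) from None
    with open(path, "rt") as fh:
        yield from parser(fh, sample_id, strict=strict, report=report, **kwargs)
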