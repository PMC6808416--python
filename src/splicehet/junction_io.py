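"""Readers and writers for splice-junction count tables.

A splice junction is an intron inferred from spliced read alignments,
identified by chromosome, intron start/end and strand, and carrying the
number of supporting reads. Coordinates are 1-based and both-ends-inclusive
over the intron (the STAR ``SJ.out.tab`` convention) everywhere in this
package; the first intronic base is ``intron_start`` and the last is
``intron_end``.

Two input dialects are supported:

* STAR ``SJ.out.tab``: nine tab-separated columns, no header
  (chrom, intron first base, intron last base, strand code 0/1/2,
  intron motif, annotation flag, unique reads, multimapping reads,
  max overhang).
* A generic junction TSV with header ``chrom	start	end	strand	count``
  and strand in ``{+, -, .}``.

Strand ``.`` denotes an unknown strand (STAR code 0, typically
noncanonical junctions); such junctions are retained as their own strand
class rather than merged into ``+`` or ``-``.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import IO

__all__ = [
    "STRANDS",
    "JunctionKey",
    "JunctionParseError",
    "SpliceJunction",
    "JunctionProfile",
    "parse_star_sj",
    "parse_junction_tsv",
    "write_junction_tsv",
    "write_sith_report",
]

#: Recognised strand classes: forward, reverse, unknown.
STRANDS = ("+", "-", ".")

_STAR_STRAND_CODES = {"0": ".", "1": "+", "2": "-"}

#: (chrom, intron_start, intron_end, strand) — unique within a profile.
JunctionKey = tuple[str, int, int, str]

_TSV_HEADER = ("chrom", "start", "end", "strand", "count")


class JunctionParseError(ValueError):
    """Malformed junction table input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True)
class SpliceJunction:
    """One intron with its supporting read count.

    Counts are non-negative reals: raw alignments give integers, but
    in-silico mixtures produce fractional counts.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    count: float

    def __post_init__(self) -> None:
        if self.intron_start > self.intron_end:
            raise ValueError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not (self.count >= 0) or math.isinf(self.count):
            raise ValueError(f"count must be finite and >= 0, got {self.count!r}")

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)


@dataclass
class JunctionProfile:
    """One sample's full junction → count table, keyed by junction key."""

    sample_id: str
    junctions: dict[JunctionKey, float] = field(default_factory=dict)

    @classmethod
    def from_junctions(
        cls, sample_id: str, junctions: Iterable[SpliceJunction]
    ) -> "JunctionProfile":
        table: dict[JunctionKey, float] = {}
        for j in junctions:
            if j.key in table:
                raise ValueError(f"duplicate junction key {j.key}")
            table[j.key] = j.count
        return cls(sample_id, table)

    def __len__(self) -> int:
        return len(self.junctions)

    def __contains__(self, key: JunctionKey) -> bool:
        return key in self.junctions

    def count(self, key: JunctionKey) -> float:
        """Read count for ``key``, 0 if the junction was not observed."""
        return self.junctions.get(key, 0.0)

    def sorted_keys(self) -> list[JunctionKey]:
        return sorted(self.junctions)


def _parse_int(token: str, what: str, line_number: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise JunctionParseError(f"non-integer {what} {token!r}", line_number) from None


def parse_star_sj(
    stream: IO[str] | Iterable[str],
    sample_id: str = "sample",
    include_multimappers: bool = False,
) -> JunctionProfile:
    """Parse a STAR ``SJ.out.tab`` table into a :class:`JunctionProfile`.

    By default the count is the uniquely-mapping read count (column 7);
    ``include_multimappers`` adds the multimapper count (column 8).
    Junctions whose resulting count is 0 are dropped. Strand codes map
    0 → unknown, 1 → ``+``, 2 → ``-``.
    """
    table: dict[JunctionKey, float] = {}
    for line_number, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 9:
            raise JunctionParseError(
                f"expected >= 9 tab-separated columns, got {len(cols)}", line_number
            )
        chrom = cols[0]
        start = _parse_int(cols[1], "intron start", line_number)
        end = _parse_int(cols[2], "intron end", line_number)
        if start > end:
            raise JunctionParseError(
                f"intron start {start} > intron end {end}", line_number
            )
        strand = _STAR_STRAND_CODES.get(cols[3])
        if strand is None:
            raise JunctionParseError(f"bad strand code {cols[3]!r}", line_number)
        count = float(_parse_int(cols[6], "unique-read count", line_number))
        if include_multimappers:
            count += _parse_int(cols[7], "multimapper count", line_number)
        if count < 0:
            raise JunctionParseError(f"negative count {count}", line_number)
        if count == 0:
            continue
        key = (chrom, start, end, strand)
        if key in table:
            raise JunctionParseError(f"duplicate junction {key}", line_number)
        table[key] = count
    return JunctionProfile(sample_id, table)


def parse_junction_tsv(
    stream: IO[str] | Iterable[str], sample_id: str = "sample"
) -> JunctionProfile:
    """Parse the generic junction TSV dialect (header required)."""
    table: dict[JunctionKey, float] = {}
    lines = iter(stream)
    try:
        header = next(lines).rstrip("\n")
    except StopIteration:
        raise JunctionParseError("empty input: missing header", 1) from None
    if tuple(header.split("\t")) != _TSV_HEADER:
        raise JunctionParseError(
            f"expected header {'	'.join(_TSV_HEADER)!r}, got {header!r}", 1
        )
    for line_number, line in enumerate(lines, start=2):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise JunctionParseError(
                f"expected 5 columns, got {len(cols)}", line_number
            )
        chrom, strand = cols[0], cols[3]
        start = _parse_int(cols[1], "start", line_number)
        end = _parse_int(cols[2], "end", line_number)
        if start > end:
            raise JunctionParseError(f"start {start} > end {end}", line_number)
        if strand not in STRANDS:
            raise JunctionParseError(f"bad strand {strand!r}", line_number)
        try:
            count = float(cols[4])
        except ValueError:
            raise JunctionParseError(f"non-numeric count {cols[4]!r}", line_number) from None
        if not (count >= 0) or math.isinf(count):
            raise JunctionParseError(f"negative or non-finite count {count}", line_number)
        key = (chrom, start, end, strand)
        if key in table:
            raise JunctionParseError(f"duplicate junction {key}", line_number)
        table[key] = count
    return JunctionProfile(sample_id, table)


def _format_count(count: float) -> str:
    # Integer counts round-trip bit-exactly; fractional counts (mixtures)
    # use repr, which preserves the full float value.
    if count == int(count):
        return str(int(count))
    return repr(count)


def write_junction_tsv(profile: JunctionProfile, stream: IO[str]) -> None:
    """Write the generic junction TSV, rows sorted by (chrom, start, end, strand)."""
    stream.write("\t".join(_TSV_HEADER) + "\n")
    for key in profile.sorted_keys():
        chrom, start, end, strand = key
        stream.write(
            f"{chrom}\t{start}\t{end}\t{strand}\t{_format_count(profile.junctions[key])}\n"
        )


def write_sith_report(result, stream: IO[str], per_unit: bool = True) -> None:
    """Write a sITH report: one summary row, then optional per-unit rows.

    ``result`` is a :class:`splicehet.divergence.SithResult`. An undefined
    score (no usable units) is written as ``NA``.
    """
    reasons = sorted(result.drop_log)
    header = ["sample_p", "sample_q", "sith", "L"] + [f"dropped_{r}" for r in reasons]
    sith = "NA" if result.sith is None else repr(result.sith)
    row = [result.sample_p, result.sample_q, sith, str(result.L)] + [
        str(result.drop_log[r]) for r in reasons
    ]
    stream.write("# summary\n")
    stream.write("\t".join(header) + "\n")
    stream.write("\t".join(row) + "\n")
    if per_unit and result.unit_divergences:
        stream.write("# per_unit\n")
        stream.write("unit_id\tjsd\n")
        for ud in result.unit_divergences:
            stream.write(f"{ud.unit_id}\t{ud.jsd!r}\n")
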