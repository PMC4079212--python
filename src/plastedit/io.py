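"""Alignment and track I/O.

Reads are exchanged in a minimal SAM dialect: header (@HD/@SQ/@CO) plus
the 11 mandatory columns with simple all-match CIGARs.  SEQ is stored in
reference-forward orientation (standard SAM); FLAG bit 0x10 marks
reverse-strand reads.  Files written here are parseable by samtools and
pysam.

5'-end count tracks are two-column TSV (0-based position, count) or
4-column bedGraph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence


class SamFormatError(ValueError):
    """A SAM line falls outside the supported minimal dialect."""


@dataclass(frozen=True)
class AlignedRead:
    """A gap-free mapped read.

    ``seq`` is in reference-forward orientation (as in SAM SEQ); the
    physical read is its reverse complement when ``strand == '-'``.
    ``start`` is 0-based on the reference.
    """

    qname: str
    rname: str
    start: int
    strand: str  # '+' or '-'
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")

    @property
    def end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.start + len(self.seq)

    def five_prime_offset(self, ref_pos: int) -> int:
        """Offset of ``ref_pos`` from the read's 5' end."""
        i = ref_pos - self.start
        if not 0 <= i < len(self.seq):
            raise IndexError(f"position {ref_pos} not covered by read")
        return i if self.strand == "+" else len(self.seq) - 1 - i


_CIGAR_MATCH = re.compile(r"^(\d+)[M=X]$")


def write_sam(
    reads: Iterable[AlignedRead],
    ref_lengths: Mapping[str, int],
    path: str | Path,
    comments: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in ref_lengths.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for comment in comments:
            fh.write(f"@CO\t{comment}\n")
        for read in reads:
            flag = 16 if read.strand == "-" else 0
            fh.write(
                f"{read.qname}\t{flag}\t{read.rname}\t{read.start + 1}\t60\t"
                f"{len(read.seq)}M\t*\t0\t0\t{read.seq}\t*\n"
            )


def read_sam(path: str | Path) -> tuple[list[AlignedRead], dict[str, int]]:
    """Parse a minimal SAM file; returns (reads, reference lengths)."""
    reads: list[AlignedRead] = []
    ref_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                if line.startswith("@SQ"):
                    tags = dict(
                        t.split(":", 1) for t in line.split("\t")[1:] if ":" in t
                    )
                    if "SN" in tags and "LN" in tags:
                        ref_lengths[tags["SN"]] = int(tags["LN"])
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise SamFormatError(f"{path}:{lineno}: fewer than 11 SAM columns")
            qname, flag, rname, pos, _mapq, cigar, _, _, _, seq = fields[:10]
            flag_int = int(flag)
            if flag_int & 0x4:  # unmapped
                continue
            match = _CIGAR_MATCH.match(cigar)
            if match is None:
                raise SamFormatError(
                    f"{path}:{lineno}: unsupported CIGAR {cigar!r} "
                    "(only all-match alignments are handled)"
                )
            if int(match.group(1)) != len(seq):
                raise SamFormatError(f"{path}:{lineno}: CIGAR/SEQ length mismatch")
            reads.append(
                AlignedRead(
                    qname=qname,
                    rname=rname,
                    start=int(pos) - 1,
                    strand="-" if flag_int & 0x10 else "+",
                    seq=seq.upper(),
                )
            )
    return reads, ref_lengths


def deduplicate_reads(reads: Iterable[AlignedRead]) -> list[AlignedRead]:
    """Drop exact duplicates by (reference, start, strand, sequence)."""
    seen = set()
    out = []
    for read in reads:
        key = (read.rname, read.start, read.strand, read.seq)
        if key not in seen:
            seen.add(key)
            out.append(read)
    return out


def write_five_prime_counts(counts: Mapping[int, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# 0-based position\tcount\n")
        for pos in sorted(counts):
            fh.write(f"{pos}\t{counts[pos]}\n")


def read_five_prime_counts(path: str | Path) -> dict[int, int]:
    """Read a 5'-end count track (2-column TSV or 4-column bedGraph)."""
    counts: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                counts[int(fields[0])] = counts.get(int(fields[0]), 0) + int(fields[1])
            elif len(fields) == 4:  # bedGraph: chrom start end value
                start, end, value = int(fields[1]), int(fields[2]), int(float(fields[3]))
                for pos in range(start, end):
                    counts[pos] = counts.get(pos, 0) + value
            else:
                raise ValueError(f"unrecognized 5'-count line: {line!r}")
    return counts
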