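"""Editing-site calling from RNA/DNA read pileups.

A site is called when the RNA pileup shows a dominant non-reference base
at sufficient depth and support, the position is not a genomic variant in
the DNA pileup, and the supporting observations show neither strand bias
(two-sided Fisher exact plus a one-strand-only requirement) nor
alignment-end position bias.  The strand/position tests are explicit
stand-ins for a manual inspection step and are fully parameterized.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact

from . import __version__ as _version
from .core import DNA_BASES, EditType, GeneRecord, classify_edit
from .io import AlignedRead

_CODE = {b: i for i, b in enumerate(DNA_BASES)}


class CoordinateError(ValueError):
    """A read lies outside the reference in non-circular mode."""


class IdentityError(ValueError):
    """Gene and pileup do not describe the same reference."""


class NoObservationError(ValueError):
    """The requested alternative base has no supporting observations."""


@dataclass
class CallingParams:
    """Thresholds for editing-site calling.

    ``min_coverage`` of 11 encodes a strict more-than-10-read rule.
    """

    min_coverage: int = 11
    min_edited_fraction: float = 0.5
    min_edited_reads: int = 3
    max_dna_alt_fraction: float = 0.01
    strand_bias_p: float = 0.005
    end_window_nt: int = 10
    max_end_fraction: float = 0.9
    multiallelic_min_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.min_coverage < 1 or self.min_edited_reads < 1:
            raise ValueError("read-count thresholds must be >= 1")
        for name in ("min_edited_fraction", "max_dna_alt_fraction",
                     "strand_bias_p", "max_end_fraction",
                     "multiallelic_min_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.end_window_nt < 0:
            raise ValueError("end_window_nt must be >= 0")


@dataclass
class PileupColumn:
    """Strand-resolved base counts at one reference position.

    ``base_counts`` maps base -> (forward, reverse) read counts;
    ``read_offsets`` maps base -> list of (5'-offset, read length) for
    each supporting observation.  ``end_distances`` (parallel to
    ``read_offsets``) holds each observation's distance to the nearest
    alignment end that lies strictly inside the reference — an alignment
    end flush with a reference boundary is not an artifact signal.  When
    None (hand-built columns), the distance is derived from the offsets.
    """

    position: int
    ref_base: str
    base_counts: dict[str, tuple[int, int]]
    read_offsets: dict[str, list[tuple[int, int]]]
    end_distances: Optional[dict[str, list[int]]] = None

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.base_counts.values())

    def count(self, base: str) -> int:
        f, r = self.base_counts.get(base, (0, 0))
        return f + r


class Pileup:
    """Per-position strand-resolved base counts over one reference."""

    def __init__(self, reference: str, ref_name: str = "ref") -> None:
        self.reference = reference.upper()
        self.ref_name = ref_name
        # counts[pos, base, strand]: strand 0 = forward, 1 = reverse
        self.counts = np.zeros((len(reference), 4, 2), dtype=np.int32)
        self._reads: list[AlignedRead] = []
        self._starts: Optional[np.ndarray] = None
        self._max_len = 0

    def add_read(self, read: AlignedRead) -> None:
        if read.start < 0 or read.end > len(self.reference):
            raise CoordinateError(
                f"read {read.qname} [{read.start}, {read.end}) overhangs "
                f"reference of length {len(self.reference)}"
            )
        codes = np.fromiter((_CODE[b] for b in read.seq), dtype=np.intp)
        strand = 0 if read.strand == "+" else 1
        self.counts[np.arange(read.start, read.end), codes, strand] += 1
        self._reads.append(read)
        self._max_len = max(self._max_len, len(read.seq))
        self._starts = None

    @property
    def depth_array(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2))

    def _overlapping(self, position: int) -> Iterable[AlignedRead]:
        if self._starts is None:
            self._reads.sort(key=lambda r: r.start)
            self._starts = np.array([r.start for r in self._reads])
        lo = int(np.searchsorted(self._starts, position - self._max_len, "left"))
        hi = int(np.searchsorted(self._starts, position, "right"))
        for read in self._reads[lo:hi]:
            if read.start <= position < read.end:
                yield read

    def column(self, position: int) -> PileupColumn:
        base_counts = {
            b: (int(self.counts[position, i, 0]), int(self.counts[position, i, 1]))
            for i, b in enumerate(DNA_BASES)
            if self.counts[position, i].any()
        }
        offsets: dict[str, list[tuple[int, int]]] = {}
        end_distances: dict[str, list[int]] = {}
        far = len(self.reference)
        for read in self._overlapping(position):
            base = read.seq[position - read.start]
            offsets.setdefault(base, []).append(
                (read.five_prime_offset(position), len(read.seq))
            )
            dist_left = position - read.start if read.start > 0 else far
            dist_right = (
                read.end - 1 - position if read.end < len(self.reference) else far
            )
            end_distances.setdefault(base, []).append(min(dist_left, dist_right))
        return PileupColumn(
            position, self.reference[position], base_counts, offsets, end_distances
        )


def build_pileup(
    reads: Iterable[AlignedRead], reference: str, ref_name: str = "ref"
) -> Pileup:
    """Accumulate reads into a strand-resolved pileup over ``reference``."""
    pileup = Pileup(reference, ref_name)
    for read in reads:
        pileup.add_read(read)
    return pileup


# ---------------------------------------------------------------------------
# Filters


def detect_dna_variants(dna_pileup: Pileup, params: CallingParams) -> set[int]:
    """Genomic positions where a non-reference base exceeds
    ``max_dna_alt_fraction`` with at least two supporting reads."""
    counts = dna_pileup.counts.sum(axis=2)  # (L, 4)
    depth = counts.sum(axis=1)
    ref_codes = np.fromiter(
        (_CODE.get(b, 0) for b in dna_pileup.reference), dtype=np.intp
    )
    alt = counts.copy()
    alt[np.arange(len(ref_codes)), ref_codes] = 0
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = alt / np.maximum(depth, 1)[:, None]
    variant = ((alt >= 2) & (frac > params.max_dna_alt_fraction)).any(axis=1)
    return set(int(p) for p in np.nonzero(variant)[0])


@dataclass(frozen=True)
class BiasResult:
    strand_pass: bool
    position_pass: bool
    fisher_p: float
    end_fraction: float


def bias_tests(
    column: PileupColumn, alt_base: str, params: CallingParams
) -> BiasResult:
    """Strand- and position-bias tests for one candidate site.

    Strand: two-sided Fisher exact on the ref/alt x forward/reverse
    table; fails only when significant AND every alt observation sits on
    a single strand while the column is covered on both strands.
    Position: fails when at least ``max_end_fraction`` of alt
    observations lie within ``end_window_nt`` of a read end.
    """
    ref_f, ref_r = column.base_counts.get(column.ref_base, (0, 0))
    alt_f, alt_r = column.base_counts.get(alt_base, (0, 0))
    if alt_f + alt_r == 0:
        raise NoObservationError(
            f"no {alt_base} observations at position {column.position}"
        )
    _, p_value = fisher_exact([[ref_f, ref_r], [alt_f, alt_r]])
    both_strands_covered = (ref_f + alt_f > 0) and (ref_r + alt_r > 0)
    one_sided_alt = alt_f == 0 or alt_r == 0
    strand_pass = not (
        p_value < params.strand_bias_p and one_sided_alt and both_strands_covered
    )

    observations = column.read_offsets.get(alt_base, [])
    if column.end_distances is not None:
        distances = column.end_distances.get(alt_base, [])
    else:
        distances = [
            min(offset, read_len - 1 - offset)
            for offset, read_len in observations
        ]
    near_end = sum(1 for d in distances if d < params.end_window_nt)
    end_fraction = near_end / len(distances) if distances else 0.0
    position_pass = end_fraction < params.max_end_fraction
    return BiasResult(strand_pass, position_pass, float(p_value), end_fraction)


# ---------------------------------------------------------------------------
# Site calling


@dataclass
class EditingSite:
    """One called RNA-DNA difference; codon-level fields are filled by
    the consequence-annotation stage."""

    gene_id: str
    position: int
    dna_base: str
    rna_base: str  # RNA notation
    type: EditType
    depth: int
    edited_reads: int
    edited_fraction: float
    strand_bias_pass: bool = True
    position_bias_pass: bool = True
    codon_index: Optional[int] = None
    codon_position: Optional[int] = None
    ref_codon: Optional[str] = None
    alt_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    synonymous: Optional[bool] = None
    stop_restoration: Optional[bool] = None


def call_editing_sites(
    rna_pileup: Pileup,
    dna_pileup: Optional[Pileup],
    gene: GeneRecord,
    params: Optional[CallingParams] = None,
    multiallelic_out: Optional[list[int]] = None,
) -> list[EditingSite]:
    """Call editing sites on one gene from RNA and DNA pileups.

    A position is called iff RNA depth >= ``min_coverage``, the dominant
    non-reference base reaches ``min_edited_fraction`` and
    ``min_edited_reads``, the position is not a DNA variant, both bias
    tests pass, and no second alternative base reaches the multiallelic
    threshold (such positions go to ``multiallelic_out`` instead).
    """
    params = params or CallingParams()
    if rna_pileup.reference != gene.seq:
        raise IdentityError(
            f"pileup reference does not match gene {gene.gene_id} sequence"
        )
    if dna_pileup is not None and dna_pileup.reference != gene.seq:
        raise IdentityError("DNA pileup reference does not match gene sequence")

    dna_variants = (
        detect_dna_variants(dna_pileup, params) if dna_pileup is not None else set()
    )

    counts = rna_pileup.counts.sum(axis=2)
    depth = counts.sum(axis=1)
    ref_codes = np.fromiter((_CODE[b] for b in gene.seq), dtype=np.intp)
    alt = counts.copy()
    alt[np.arange(len(ref_codes)), ref_codes] = 0
    dominant = alt.argmax(axis=1)
    dom_count = alt.max(axis=1)
    candidate = (
        (depth >= params.min_coverage)
        & (dom_count >= params.min_edited_reads)
        & (dom_count >= params.min_edited_fraction * depth)
    )

    sites: list[EditingSite] = []
    for pos in np.nonzero(candidate)[0]:
        pos = int(pos)
        if pos in dna_variants:
            continue
        alt_base = DNA_BASES[int(dominant[pos])]
        second = alt[pos].copy()
        second[int(dominant[pos])] = 0
        if (
            second.max() >= params.min_edited_reads
            and second.max() >= params.multiallelic_min_fraction * depth[pos]
        ):
            if multiallelic_out is not None:
                multiallelic_out.append(pos)
            continue
        column = rna_pileup.column(pos)
        bias = bias_tests(column, alt_base, params)
        if not (bias.strand_pass and bias.position_pass):
            continue
        etype = classify_edit(gene.seq[pos], alt_base)
        sites.append(
            EditingSite(
                gene_id=gene.gene_id,
                position=pos,
                dna_base=gene.seq[pos],
                rna_base=etype.rna_base,
                type=etype,
                depth=int(depth[pos]),
                edited_reads=int(dom_count[pos]),
                edited_fraction=float(dom_count[pos] / depth[pos]),
                strand_bias_pass=bias.strand_pass,
                position_bias_pass=bias.position_pass,
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Site table serialization

_TSV_COLUMNS = (
    "gene_id", "position", "dna_base", "rna_base", "type", "depth",
    "edited_reads", "edited_fraction", "strand_bias_pass",
    "position_bias_pass", "codon_index", "codon_position", "ref_codon",
    "alt_codon", "ref_aa", "alt_aa", "synonymous", "stop_restoration",
)


def _fmt(value) -> str:
    if value is None:
        return "."
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.6g}"
    if isinstance(value, EditType):
        return value.label
    return str(value)


def write_sites_tsv(
    sites: Sequence[EditingSite], path: str | Path, comments: Sequence[str] = ()
) -> None:
    """Editing-site table; positions are 0-based."""
    with open(path, "w") as fh:
        fh.write(f"# plastedit {_version} editing sites; 0-based positions\n")
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for site in sites:
            fh.write(
                "\t".join(_fmt(getattr(site, col)) for col in _TSV_COLUMNS) + "\n"
            )


def read_sites_tsv(path: str | Path) -> list[EditingSite]:
    sites: list[EditingSite] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            values = dict(zip(_TSV_COLUMNS, line.split("\t")))

            def get(key, cast=str):
                raw = values[key]
                if raw == ".":
                    return None
                if cast is bool:
                    return raw == "1"
                return cast(raw)

            site = EditingSite(
                gene_id=values["gene_id"],
                position=int(values["position"]),
                dna_base=values["dna_base"],
                rna_base=values["rna_base"],
                type=classify_edit(values["dna_base"], values["rna_base"]),
                depth=int(values["depth"]),
                edited_reads=int(values["edited_reads"]),
                edited_fraction=float(values["edited_fraction"]),
                strand_bias_pass=get("strand_bias_pass", bool),
                position_bias_pass=get("position_bias_pass", bool),
                codon_index=get("codon_index", int),
                codon_position=get("codon_position", int),
                ref_codon=get("ref_codon"),
                alt_codon=get("alt_codon"),
                ref_aa=get("ref_aa"),
                alt_aa=get("alt_aa"),
                synonymous=get("synonymous", bool),
                stop_restoration=get("stop_restoration", bool),
            )
            sites.append(site)
    return sites


def write_sites_vcf(
    sites: Sequence[EditingSite],
    ref_lengths: Mapping[str, int],
    path: str | Path,
    comments: Sequence[str] = (),
) -> None:
    """VCF-like output: CHROM is the gene, POS is 1-based; INFO carries
    TYPE/DP/AD/AF and codon annotation when present."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=plastedit {_version}\n")
        for comment in comments:
            fh.write(f"##plastedit_{comment}\n")
        for name, length in ref_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for key, desc in (
            ("TYPE", "Editing type label (DNA/RNA, RNA notation)"),
            ("DP", "Total RNA read depth"),
            ("AD", "Edited-base read count"),
            ("AF", "Edited-base fraction"),
            ("CODON", "Reference>edited codon"),
            ("AA", "Reference>edited amino acid"),
        ):
            number = "1"
            fh.write(
                f'##INFO=<ID={key},Number={number},Type=String,'
                f'Description="{desc}">\n'
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for site in sites:
            info = [
                f"TYPE={site.type.label}",
                f"DP={site.depth}",
                f"AD={site.edited_reads}",
                f"AF={site.edited_fraction:.4f}",
            ]
            if site.ref_codon is not None:
                info.append(f"CODON={site.ref_codon}>{site.alt_codon}")
            if site.ref_aa is not None:
                info.append(f"AA={site.ref_aa}>{site.alt_aa}")
            alt_dna = site.rna_base.replace("U", "T")
            fh.write(
                f"{site.gene_id}\t{site.position + 1}\t.\t{site.dna_base}\t"
                f"{alt_dna}\t.\tPASS\t{';'.join(info)}\n"
            )
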