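"""Synthetic minicircle data with known ground truth.

Generates minicircle-like references (single ORF plus a GC-rich
inverted-repeat core carrying the conserved RNA-binding motif), plants
editing events and SNPs from a configurable 12-category substitution
spectrum, and emits pre-mapped RNA/DNA reads, so that every downstream
stage can be tested against recorded truth without any external data.

Also packages the per-gene editing-count fixture table used by the
summary statistics (see :func:`table1_fixture`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .core import (
    ALL_TYPE_ORDER,
    EDIT_TYPE_BY_LABEL,
    EditType,
    GeneRecord,
    MoleculeClass,
    classify_edit,
    revcomp,
    translate,
)
from .io import AlignedRead


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


class PlacementError(RuntimeError):
    """The requested edits cannot be placed on the reference."""


#: Default planting spectrum: all 12 categories non-zero, weighted toward
#: the transition-heavy, A/G-dominated pattern seen in dinoflagellate
#: plastid transcripts.
DEFAULT_TYPE_SPECTRUM: dict[str, float] = {
    "A/G": 0.40, "C/U": 0.10, "U/C": 0.10, "G/A": 0.06,
    "G/C": 0.08, "A/C": 0.05, "G/U": 0.05, "U/G": 0.04,
    "A/U": 0.04, "C/A": 0.03, "C/G": 0.03, "U/A": 0.02,
}

CONSERVED_MOTIF = "CACCAATGCACC"
#: Fixed pseudo-prokaryotic promoter-like element planted upstream of the
#: TSS (a -35/-10 flavored 21-mer; not a prediction, just a landmark).
PROMOTER_ELEMENT = "TTGACTAGCTTAAGGTATAAT"

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        raise ConfigError("template contains non-ACGT characters")
    return arr


@dataclass
class SimulationConfig:
    """Knobs for reference generation, edit planting, and read emission."""

    seed: int = 0
    gene_length_nt: int = 1200
    gene_gc_fraction: float = 0.40
    n_edits: Optional[int] = None
    edit_frequency: float = 0.03
    type_spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_SPECTRUM)
    )
    edited_fraction: float = 1.0
    rna_coverage: float = 300.0
    dna_coverage: float = 300.0
    read_length_nt: int = 100
    sequencing_error_rate: float = 0.0
    strand_mix: float = 0.5
    n_snps: int = 0
    cns_ir_count: int = 17
    motif: str = CONSERVED_MOTIF
    exclude_start_codon: bool = True
    allow_origin_wrap: bool = False

    def __post_init__(self) -> None:
        if self.gene_length_nt <= 0 or self.gene_length_nt % 3:
            raise ConfigError(
                f"gene_length_nt must be a positive multiple of 3, "
                f"got {self.gene_length_nt}"
            )
        for name in ("gene_gc_fraction", "edited_fraction", "strand_mix",
                     "sequencing_error_rate", "edit_frequency"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.rna_coverage <= 0 or self.dna_coverage <= 0:
            raise ConfigError("coverage must be positive")
        if self.read_length_nt <= 0:
            raise ConfigError("read_length_nt must be positive")
        if self.n_snps < 0 or self.cns_ir_count < 0:
            raise ConfigError("counts must be non-negative")
        spectrum = dict(self.type_spectrum)
        unknown = set(spectrum) - set(EDIT_TYPE_BY_LABEL)
        if unknown:
            raise ConfigError(f"unknown editing-type labels: {sorted(unknown)}")
        if any(w < 0 for w in spectrum.values()) or not any(spectrum.values()):
            raise ConfigError("type-spectrum weights must be >=0 and not all zero")
        if not self.motif:
            raise ConfigError("motif must be non-empty")

    def resolved_n_edits(self, gene_length: int) -> int:
        if self.n_edits is not None:
            return self.n_edits
        return int(round(self.edit_frequency * gene_length))


@dataclass
class SyntheticTruth:
    """Everything a simulation run guarantees, for recovery testing.

    Coordinates are 0-based half-open on the simulated sequence.
    """

    planted_edits: list[tuple[int, EditType]] = field(default_factory=list)
    planted_snps: dict[int, str] = field(default_factory=dict)
    ir_coordinates: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list
    )
    motif_position: Optional[int] = None
    promoter_position: Optional[int] = None
    tss_position: Optional[int] = None
    core_span: Optional[tuple[int, int]] = None
    orf_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.planted_edits]
        if len(positions) != len(set(positions)):
            raise ValueError("planted edit positions must be unique")

    @property
    def edit_positions(self) -> list[int]:
        return sorted(p for p, _ in self.planted_edits)


# ---------------------------------------------------------------------------
# Reference generation


def _sample_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=probs))


def make_gene(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    gene_id: str = "simgene",
    start_override: Optional[str] = None,
    n_internal_stops: int = 0,
) -> GeneRecord:
    """Random stop-free CDS at the configured GC level, starting ATG
    (or ``start_override``); optionally with planted internal stop codons."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_codons = config.gene_length_nt // 3
    if n_internal_stops > max(0, n_codons - 2):
        raise ConfigError("more internal stops requested than internal codons")
    codons = [start_override or "ATG"]
    while len(codons) < n_codons:
        codon = _sample_bases(rng, 3, config.gene_gc_fraction)
        if codon not in _STOP_CODONS:
            codons.append(codon)
    if n_internal_stops:
        idx = rng.choice(np.arange(1, n_codons), size=n_internal_stops, replace=False)
        for i in sorted(int(j) for j in idx):
            codons[i] = ["TAA", "TAG", "TGA"][int(rng.integers(3))]
    return GeneRecord(
        gene_id=gene_id,
        name=gene_id,
        seq="".join(codons),
        molecule_class=MoleculeClass.protein_coding,
        start_override=start_override,
    )


def make_minicircle(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    gene_id: str = "simgene",
) -> tuple[str, GeneRecord, SyntheticTruth]:
    """Simulated minicircle: IR-rich core, promoter element, TSS, conserved
    motif, then the ORF.  The motif is guaranteed to occur exactly once.

    Layout (5'->3' on the linearized circle)::

        [core: AT-rich spacers + cns_ir_count GC-rich IRs] [promoter] [TSS]
        [V spacer 1-41 nt] [motif] [spacer] [ORF]
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    for _attempt in range(20):
        gene = make_gene(config, rng, gene_id=gene_id)
        parts: list[str] = []
        pos = 0

        def emit(fragment: str) -> int:
            nonlocal pos
            parts.append(fragment)
            start = pos
            pos += len(fragment)
            return start

        truth = SyntheticTruth()
        core_start = pos
        for _ in range(config.cns_ir_count):
            emit(_at_rich(rng, int(rng.integers(10, 26))))
            arm_len = int(rng.integers(8, 15))
            arm = _gc_rich_arm(rng, arm_len)
            loop = "A" + _at_rich(rng, int(rng.integers(2, 9))) + "A"
            emit("A")
            left_start = emit(arm)
            emit(loop)
            right_start = emit(revcomp(arm))
            emit("A")
            truth.ir_coordinates.append(
                ((left_start, left_start + arm_len),
                 (right_start, right_start + arm_len))
            )
        emit(_at_rich(rng, int(rng.integers(10, 26))))
        truth.core_span = (core_start, pos)
        truth.promoter_position = emit(PROMOTER_ELEMENT)
        emit(_at_rich(rng, 5))
        truth.tss_position = pos
        emit(_at_rich(rng, int(rng.integers(1, 42))))
        truth.motif_position = emit(config.motif)
        emit(_at_rich(rng, int(rng.integers(5, 16))))
        orf_start = emit(gene.seq)
        truth.orf_span = (orf_start, pos)
        seq = "".join(parts)
        if seq.count(config.motif) == 1:
            return seq, gene, truth
    raise RuntimeError("could not build a minicircle with a unique motif")


def _at_rich(rng: np.random.Generator, n: int, at: float = 0.85) -> str:
    return _sample_bases(rng, n, 1.0 - at)


def _gc_rich_arm(rng: np.random.Generator, n: int, min_gc: float = 0.70) -> str:
    while True:
        arm = _sample_bases(rng, n, 0.80)
        if (arm.count("G") + arm.count("C")) / n >= min_gc:
            return arm


# ---------------------------------------------------------------------------
# Edit and SNP planting


def plant_edits(
    gene: GeneRecord,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    allow_stop_creation: bool = False,
) -> tuple[str, SyntheticTruth]:
    """Plant editing events on a gene; returns (edited transcript, truth).

    Positions are drawn without replacement uniformly over the CDS
    (excluding the start codon unless configured otherwise); each event's
    DNA base matches the reference, and by default no event may turn a
    transcript codon into a stop.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.resolved_n_edits(len(gene.seq))
    exclude = (
        {0, 1, 2}
        if gene.is_coding and config.exclude_start_codon and len(gene.seq) > 3
        else set()
    )
    eligible = [p for p in range(len(gene.seq)) if p not in exclude]
    if n > len(eligible):
        raise PlacementError(
            f"{n} edits requested but only {len(eligible)} eligible positions"
        )

    labels = [lab for lab in ALL_TYPE_ORDER if config.type_spectrum.get(lab, 0) > 0]
    weights = np.array([config.type_spectrum[lab] for lab in labels], dtype=float)
    types = [EDIT_TYPE_BY_LABEL[lab] for lab in labels]
    by_base: dict[str, list[int]] = {b: [] for b in "ACGT"}
    for p in eligible:
        by_base[gene.seq[p]].append(p)

    edited = list(gene.seq)
    planted: list[tuple[int, EditType]] = []

    def candidates(etype: EditType) -> list[int]:
        out = []
        for p in by_base[etype.dna_base]:
            if gene.is_coding and not allow_stop_creation:
                ci = p // 3
                codon = edited[3 * ci: 3 * ci + 3]
                codon[p % 3] = etype.rna_base.replace("U", "T")
                if "".join(codon) in _STOP_CODONS:
                    continue
            out.append(p)
        return out

    for _ in range(n):
        live = weights.copy()
        while True:
            if live.sum() <= 0:
                raise PlacementError(
                    "type spectrum is incompatible with the reference "
                    "composition at the remaining eligible positions"
                )
            k = int(rng.choice(len(labels), p=live / live.sum()))
            cand = candidates(types[k])
            if cand:
                break
            live[k] = 0.0
        p = int(cand[int(rng.integers(len(cand)))])
        by_base[types[k].dna_base].remove(p)
        edited[p] = types[k].rna_base.replace("U", "T")
        planted.append((p, types[k]))

    truth = SyntheticTruth(planted_edits=sorted(planted))
    return "".join(edited), truth


def plant_snps(
    reference: str,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    forbidden: Optional[set[int]] = None,
) -> dict[int, str]:
    """Choose ``n_snps`` genomic variant positions with random alt bases,
    avoiding ``forbidden`` positions (e.g. planted edit sites)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    forbidden = forbidden or set()
    pool = [p for p in range(len(reference)) if p not in forbidden]
    if config.n_snps > len(pool):
        raise ConfigError("more SNPs requested than available positions")
    chosen = rng.choice(len(pool), size=config.n_snps, replace=False)
    snps: dict[int, str] = {}
    for j in sorted(int(i) for i in chosen):
        p = pool[j]
        alts = [b for b in "ACGT" if b != reference[p]]
        snps[p] = alts[int(rng.integers(3))]
    return snps


# ---------------------------------------------------------------------------
# Read emission

_ROLE_CODE = {"RNA": 0, "DNA": 1}


def simulate_reads(
    template: str,
    truth: SyntheticTruth,
    config: SimulationConfig,
    role: str,
    ref_name: str = "simgene",
    rng: Optional[np.random.Generator] = None,
) -> list[AlignedRead]:
    """Emit pre-mapped reads from a reference template.

    Read start points are uniform over all placements overlapping the
    template; reads extending past a template end are clipped to it (as
    when reads from the surrounding minicircle are mapped to a gene
    region), which makes expected depth uniform at the target coverage
    across every position.  RNA reads carry each planted edit with
    probability ``edited_fraction`` per read; DNA reads never carry edits
    but always carry planted SNPs (haploid genome).  Per-base errors are
    i.i.d. at ``sequencing_error_rate``.  Deterministic given the config
    seed (a role-specific substream, so RNA and DNA draws are
    independent).
    """
    if role not in _ROLE_CODE:
        raise ConfigError(f"role must be 'RNA' or 'DNA', got {role!r}")
    length = len(template)
    read_len = config.read_length_nt
    if read_len > length:
        raise ConfigError("read length exceeds template length")
    coverage = config.rna_coverage if role == "RNA" else config.dna_coverage
    n_reads = max(1, int(round(coverage * (length + read_len - 1) / read_len)))
    if rng is None:
        rng = np.random.default_rng([config.seed, _ROLE_CODE[role]])

    # starts may be negative / run past the end; such reads are clipped
    starts = rng.integers(1 - read_len, length, size=n_reads)
    forward = rng.random(n_reads) < config.strand_mix
    pad = read_len - 1
    padded = np.concatenate(
        [np.zeros(pad, np.uint8), _encode(template), np.zeros(pad, np.uint8)]
    )
    mat = padded[(starts + pad)[:, None] + np.arange(read_len)[None, :]]

    if role == "RNA":
        for pos, etype in truth.planted_edits:
            rows = np.nonzero((starts <= pos) & (pos < starts + read_len))[0]
            if config.edited_fraction < 1.0:
                rows = rows[rng.random(rows.size) < config.edited_fraction]
            mat[rows, pos - starts[rows]] = _CODE[ord(etype.rna_base.replace("U", "T"))]
    else:
        for pos, alt in sorted(truth.planted_snps.items()):
            rows = np.nonzero((starts <= pos) & (pos < starts + read_len))[0]
            mat[rows, pos - starts[rows]] = _CODE[ord(alt)]

    if config.sequencing_error_rate > 0:
        err = rng.random(mat.shape) < config.sequencing_error_rate
        n_err = int(err.sum())
        if n_err:
            mat[err] = (mat[err] + rng.integers(1, 4, size=n_err)) % 4

    prefix = role.lower()
    reads = []
    for i in range(n_reads):
        s = int(starts[i])
        clip_start = max(0, s)
        clip_end = min(length, s + read_len)
        reads.append(
            AlignedRead(
                qname=f"{prefix}{i}",
                rname=ref_name,
                start=clip_start,
                strand="+" if forward[i] else "-",
                seq=_BASES[mat[i, clip_start - s: clip_end - s]].tobytes().decode(),
            )
        )
    return reads


def simulate_five_prime_counts(
    truth: SyntheticTruth,
    length: int,
    rng: Optional[np.random.Generator] = None,
    tss_count_range: tuple[int, int] = (60, 200),
    n_background: int = 30,
) -> dict[int, int]:
    """A 5'-end count track with an enriched pile at the true TSS and a
    low scattered background (counts <= 3)."""
    rng = np.random.default_rng(0) if rng is None else rng
    counts: dict[int, int] = {}
    for p in rng.integers(0, length, size=n_background):
        p = int(p)
        if p != truth.tss_position:
            counts[p] = int(rng.integers(1, 4))
    if truth.tss_position is not None:
        counts[truth.tss_position] = int(rng.integers(*tss_count_range))
    return counts


@dataclass
class SimulatedDataset:
    """A multi-gene simulation bundle keyed by gene id."""

    genes: list[GeneRecord]
    transcripts: dict[str, str]
    truths: dict[str, SyntheticTruth]
    rna_reads: dict[str, list[AlignedRead]]
    dna_reads: dict[str, list[AlignedRead]]

    @property
    def total_reference_nt(self) -> int:
        return sum(len(g.seq) for g in self.genes)


def simulate_dataset(config: SimulationConfig, n_genes: int = 1) -> SimulatedDataset:
    """Simulate several genes with independent per-gene substreams derived
    from the single config seed (fully deterministic)."""
    genes: list[GeneRecord] = []
    transcripts: dict[str, str] = {}
    truths: dict[str, SyntheticTruth] = {}
    rna: dict[str, list[AlignedRead]] = {}
    dna: dict[str, list[AlignedRead]] = {}
    for i in range(n_genes):
        rng = np.random.default_rng([config.seed, i])
        gene = make_gene(config, rng, gene_id=f"gene{i + 1}")
        transcript, truth = plant_edits(gene, config, rng=rng)
        truth.planted_snps = plant_snps(
            gene.seq, config, rng=rng, forbidden=set(truth.edit_positions)
        )
        genes.append(gene)
        transcripts[gene.gene_id] = transcript
        truths[gene.gene_id] = truth
        rna[gene.gene_id] = simulate_reads(
            gene.seq, truth, config, "RNA", ref_name=gene.gene_id,
            rng=np.random.default_rng([config.seed, i, 100]),
        )
        dna[gene.gene_id] = simulate_reads(
            gene.seq, truth, config, "DNA", ref_name=gene.gene_id,
            rng=np.random.default_rng([config.seed, i, 101]),
        )
    return SimulatedDataset(genes, transcripts, truths, rna, dna)


# ---------------------------------------------------------------------------
# Directional-property scenarios


def stop_restoration_scenario(
    config: SimulationConfig,
    n_stops: int = 3,
    rng: Optional[np.random.Generator] = None,
    gene_id: str = "stopgene",
) -> tuple[GeneRecord, str, SyntheticTruth]:
    """A gene with planted internal stop codons plus exactly the editing
    events that restore each of them to a sense codon."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    gene = make_gene(config, rng, gene_id=gene_id, n_internal_stops=n_stops)
    restorers = {"TGA": (2, "G"), "TAA": (0, "C"), "TAG": (1, "G")}
    edited = list(gene.seq)
    planted = []
    for ci in range(1, len(gene.seq) // 3):
        codon = gene.seq[3 * ci: 3 * ci + 3]
        if codon in _STOP_CODONS:
            offset, rna = restorers[codon]
            pos = 3 * ci + offset
            planted.append((pos, classify_edit(gene.seq[pos], rna)))
            edited[pos] = rna
    truth = SyntheticTruth(planted_edits=sorted(planted))
    return gene, "".join(edited), truth


def homolog_restoration_scenario(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    gene_id: str = "homgene",
) -> tuple[GeneRecord, str, SyntheticTruth]:
    """A gene whose planted edits exactly restore the homolog's residues:
    the homolog protein is the translation of the edited transcript, so
    post-editing identity is guaranteed to exceed pre-editing identity."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    for _ in range(50):
        gene = make_gene(config, rng, gene_id=gene_id)
        transcript, truth = plant_edits(gene, config, rng=rng)
        if translate(transcript) != gene.translate():
            gene.homolog_protein = translate(transcript)
            return gene, transcript, truth
    raise RuntimeError("failed to plant a non-synonymous edit")


# ---------------------------------------------------------------------------
# Truth table serialization (TSV; 0-based half-open coordinates)


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# synthetic truth; 0-based half-open coordinates\n")
        fh.write("kind\tstart\tend\tdetail\n")
        for pos, etype in truth.planted_edits:
            fh.write(f"edit\t{pos}\t{pos + 1}\t{etype.label}\n")
        for pos, alt in sorted(truth.planted_snps.items()):
            fh.write(f"snp\t{pos}\t{pos + 1}\t{alt}\n")
        for i, (left, right) in enumerate(truth.ir_coordinates):
            fh.write(f"ir_left\t{left[0]}\t{left[1]}\t{i}\n")
            fh.write(f"ir_right\t{right[0]}\t{right[1]}\t{i}\n")
        for kind in ("motif", "promoter", "tss"):
            pos = getattr(truth, f"{kind}_position")
            if pos is not None:
                fh.write(f"{kind}\t{pos}\t{pos + 1}\t.\n")
        for kind in ("core", "orf"):
            span = getattr(truth, f"{kind}_span")
            if span is not None:
                fh.write(f"{kind}\t{span[0]}\t{span[1]}\t.\n")


def read_truth(path: str | Path) -> SyntheticTruth:
    truth = SyntheticTruth()
    lefts: dict[int, tuple[int, int]] = {}
    rights: dict[int, tuple[int, int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("kind\t"):
                continue
            kind, start, end, detail = line.split("\t")
            start, end = int(start), int(end)
            if kind == "edit":
                truth.planted_edits.append((start, EDIT_TYPE_BY_LABEL[detail]))
            elif kind == "snp":
                truth.planted_snps[start] = detail
            elif kind == "ir_left":
                lefts[int(detail)] = (start, end)
            elif kind == "ir_right":
                rights[int(detail)] = (start, end)
            elif kind in ("motif", "promoter", "tss"):
                setattr(truth, f"{kind}_position", start)
            elif kind in ("core", "orf"):
                setattr(truth, f"{kind}_span", (start, end))
    truth.planted_edits.sort()
    truth.ir_coordinates = [(lefts[i], rights[i]) for i in sorted(lefts)]
    return truth


# ---------------------------------------------------------------------------
# Packaged fixture

_COUNT_COLUMNS = (
    "cds_length_nt", "n_edits", "A/G", "G/A", "C/U", "U/C", "G/C", "G/U",
    "U/G", "A/C", "A/U", "n_aa_substitutions", "protein_length_aa",
    "n_stop_restorations",
)


def table1_fixture() -> pd.DataFrame:
    """The packaged 14-gene editing-count table (12 protein-coding genes
    plus the 16S and 23S rRNAs).

    Per-type counts are stored only where the row's digit run resolves
    consistently to the row total (``types_consistent == 1``); the 16S row
    stores NA types and only its total.
    """
    resource = importlib.resources.files("plastedit.data") / "table1.tsv"
    with importlib.resources.as_file(resource) as path:
        df = pd.read_csv(path, sep="\t", comment="#", na_values="NA")
    for col in _COUNT_COLUMNS:
        df[col] = df[col].astype("Int64")
    df["types_consistent"] = df["types_consistent"].astype(bool)
    return df
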