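"""Core sequence domain model.

Gene records, plastid genetic-code translation with alternative start
codons, editing-type classification on the 12-category DNA->RNA
substitution space, and scalar protein/nucleotide descriptors (GRAVY,
average molecular weight, GC content).

DNA is handled internally in the {A,C,G,T} alphabet only; the RNA ``U``
notation appears solely in editing-type labels (e.g. ``"G/U"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import KYTE_DOOLITTLE, PLASTID_CODON_TABLE, RESIDUE_MASS_AVG, WATER_MASS_AVG


class AlphabetError(ValueError):
    """A sequence contains characters outside its declared alphabet."""


class LengthError(ValueError):
    """A sequence has an invalid length for the requested operation."""


class CompositionError(ValueError):
    """A protein string contains residues a descriptor cannot score."""


class NoEditError(ValueError):
    """The two bases of a putative edit are identical."""


DNA_BASES = "ACGT"
_DNA_SET = frozenset(DNA_BASES)
_PURINES = frozenset("AG")
_RC_TABLE = str.maketrans("ACGT", "TGCA")
_AA_SET = frozenset(KYTE_DOOLITTLE)


def _check_dna(seq: str) -> None:
    if not _DNA_SET.issuperset(seq):
        bad = sorted(set(seq) - _DNA_SET)
        raise AlphabetError(f"non-DNA characters in sequence: {bad}")


def revcomp(seq: str) -> str:
    """Reverse complement of an {A,C,G,T} string."""
    _check_dna(seq)
    return seq.translate(_RC_TABLE)[::-1]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as in the printed summary tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class MoleculeClass(str, Enum):
    protein_coding = "protein_coding"
    rRNA = "rRNA"


# ---------------------------------------------------------------------------
# Editing types


@dataclass(frozen=True, order=True)
class EditType:
    """One of the 12 ordered DNA->RNA substitution categories.

    ``dna_base`` is in DNA notation ({A,C,G,T}); ``rna_base`` in RNA
    notation ({A,C,G,U}).  The label writes both sides in RNA notation,
    e.g. genomic T read as C is ``"U/C"``.
    """

    dna_base: str
    rna_base: str

    @property
    def label(self) -> str:
        return f"{self.dna_base.replace('T', 'U')}/{self.rna_base}"

    @property
    def is_transversion(self) -> bool:
        dna_purine = self.dna_base in _PURINES
        rna_purine = self.rna_base.replace("U", "T") in _PURINES
        return dna_purine != rna_purine

    @property
    def is_transition(self) -> bool:
        return not self.is_transversion


def classify_edit(dna_base: str, rna_base: str) -> EditType:
    """Classify a single RNA-DNA difference.

    ``rna_base`` may be given in DNA or RNA notation; it is stored in RNA
    notation.  Identical bases (after T<->U mapping) raise
    :class:`NoEditError`.
    """
    dna_base = dna_base.upper()
    rna_dna = rna_base.upper().replace("U", "T")
    if dna_base not in _DNA_SET:
        raise AlphabetError(f"invalid DNA base {dna_base!r}")
    if rna_dna not in _DNA_SET:
        raise AlphabetError(f"invalid RNA base {rna_base!r}")
    if dna_base == rna_dna:
        raise NoEditError(f"{dna_base} -> {rna_base} is not an edit")
    return EditType(dna_base, rna_dna.replace("T", "U"))


#: All 12 categories, paper column order first (the nine observed types),
#: then the three never-observed transversions.
PAPER_TYPE_ORDER = ("A/G", "G/A", "C/U", "U/C", "G/C", "G/U", "U/G", "A/C", "A/U")
ALL_EDIT_TYPES = tuple(
    classify_edit(d, r)
    for d in DNA_BASES
    for r in DNA_BASES
    if d != r
)
EDIT_TYPE_BY_LABEL = {t.label: t for t in ALL_EDIT_TYPES}
assert len(EDIT_TYPE_BY_LABEL) == 12
ALL_TYPE_ORDER = PAPER_TYPE_ORDER + tuple(
    sorted(set(EDIT_TYPE_BY_LABEL) - set(PAPER_TYPE_ORDER))
)


# ---------------------------------------------------------------------------
# Gene records


@dataclass
class GeneRecord:
    """A minicircle gene on its coding strand, 5'->3'.

    ``start_override`` records a non-ATG start codon (e.g. ``"TTG"``);
    when set it must equal the first codon of ``seq`` and is translated
    as methionine.
    """

    gene_id: str
    name: str
    seq: str
    molecule_class: MoleculeClass = MoleculeClass.protein_coding
    start_override: Optional[str] = None
    homolog_protein: Optional[str] = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        self.molecule_class = MoleculeClass(self.molecule_class)
        if len(self.seq) == 0:
            raise LengthError(f"{self.gene_id}: empty sequence")
        _check_dna(self.seq)
        if self.molecule_class is MoleculeClass.protein_coding and len(self.seq) % 3:
            raise LengthError(
                f"{self.gene_id}: protein-coding length {len(self.seq)} "
                "is not a multiple of 3"
            )
        if self.start_override is not None:
            self.start_override = self.start_override.upper()
            if self.start_override != self.seq[:3]:
                raise ValueError(
                    f"{self.gene_id}: start_override {self.start_override} "
                    f"does not match first codon {self.seq[:3]}"
                )

    @property
    def is_coding(self) -> bool:
        return self.molecule_class is MoleculeClass.protein_coding

    def translate(self) -> str:
        return translate(self.seq, start_override=self.start_override)


def translate(seq: str, start_override: Optional[str] = None) -> str:
    """Translate a CDS with the bacterial/plastid code (table 11).

    Internal stop codons are emitted as ``'*'`` rather than truncating the
    product, so premature stops remain visible downstream.  If
    ``start_override`` equals the first codon, the first residue is forced
    to methionine (alternative start codons).
    """
    seq = seq.upper()
    _check_dna(seq)
    if len(seq) % 3:
        raise LengthError(f"CDS length {len(seq)} is not a multiple of 3")
    protein = str(Seq(seq).translate(table=PLASTID_CODON_TABLE))
    if start_override is not None and seq[:3] == start_override.upper():
        protein = "M" + protein[1:]
    return protein


# ---------------------------------------------------------------------------
# Scalar descriptors


def _check_protein(protein: str) -> None:
    if not protein:
        raise CompositionError("empty protein string")
    if not _AA_SET.issuperset(protein):
        bad = sorted(set(protein) - _AA_SET)
        raise CompositionError(f"unscorable residues: {bad}")


def gravy(protein: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle score per residue."""
    _check_protein(protein)
    return sum(KYTE_DOOLITTLE[a] for a in protein) / len(protein)


def molecular_weight(protein: str) -> float:
    """Average-isotope molecular weight in daltons (residues + one water)."""
    _check_protein(protein)
    return sum(RESIDUE_MASS_AVG[a] for a in protein) + WATER_MASS_AVG


def gc_content(seq: str) -> float:
    """GC percentage of a DNA string."""
    if not seq:
        raise LengthError("empty sequence")
    seq = seq.upper()
    _check_dna(seq)
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class ProteinDescriptors:
    length_aa: int
    gravy: float
    mw: float


def describe_protein(protein: str) -> ProteinDescriptors:
    return ProteinDescriptors(len(protein), gravy(protein), molecular_weight(protein))


# ---------------------------------------------------------------------------
# FASTA interface

_TAG_FIELDS = ("molecule_class", "start_override", "name")


def write_gene_fasta(records: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene records; description carries key=value metadata tags."""
    seq_records = []
    for rec in records:
        tags = [f"name={rec.name}", f"molecule_class={rec.molecule_class.value}"]
        if rec.start_override:
            tags.append(f"start_override={rec.start_override}")
        seq_records.append(
            SeqRecord(Seq(rec.seq), id=rec.gene_id, description=" ".join(tags))
        )
    SeqIO.write(seq_records, str(path), "fasta")


def read_gene_fasta(path: str | Path) -> list[GeneRecord]:
    """Read gene records written by :func:`write_gene_fasta`.

    Plain FASTA without tags is accepted: such records default to
    protein-coding with name equal to the id.
    """
    out = []
    for sr in SeqIO.parse(str(path), "fasta"):
        tags = {}
        for token in sr.description.split()[1:]:
            if "=" in token:
                key, _, value = token.partition("=")
                tags[key] = value
        out.append(
            GeneRecord(
                gene_id=sr.id,
                name=tags.get("name", sr.id),
                seq=str(sr.seq),
                molecule_class=MoleculeClass(
                    tags.get("molecule_class", "protein_coding")
                ),
                start_override=tags.get("start_override"),
            )
        )
    return out
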