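"""Codon-level annotation and summary statistics for called editing sites.

Builds per-gene summary rows (edit counts, per-type counts, amino-acid
substitution counts, stop-codon restorations, homolog identity before and
after editing) and cross-gene aggregates (type spectrum, transversion
fraction, codon-position distribution, GC shift, molecular-weight and
hydropathy shift, Spearman rank correlation).

Counting conventions:

* Amino-acid substitutions are counted per edited site: all edits within
  one codon are applied jointly, and each site whose codon's translation
  changes counts once.  (Switchable to per-codon counting via
  ``summarize_gene(..., count_per_codon=True)``.)
* rRNA edits enter type spectra and totals but not codon/protein
  statistics.
* Percentages are rounded half-up, one decimal, matching the summary
  table style; homolog identities are rounded to integers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import t as t_dist

from .calling import EditingSite
from .core import (
    ALL_TYPE_ORDER,
    EDIT_TYPE_BY_LABEL,
    EditType,
    GeneRecord,
    LengthError,
    MoleculeClass,
    classify_edit,
    gc_content,
    gravy,
    molecular_weight,
    round_half_up,
    translate,
)
from .simulate import SyntheticTruth


class ConsistencyError(ValueError):
    """A site's recorded DNA base does not match the reference."""


class UndefinedCorrelationError(ValueError):
    """Rank correlation is undefined (constant input vector)."""


# ---------------------------------------------------------------------------
# Transcript reconstruction


def _site_items(sites: Iterable) -> list[tuple[int, str, Optional[str]]]:
    """Normalize sites to (position, rna_base_dna_notation, dna_base)."""
    out = []
    for site in sites:
        if isinstance(site, EditingSite):
            out.append(
                (site.position, site.rna_base.replace("U", "T"), site.dna_base)
            )
        else:  # (position, EditType) pairs, e.g. from SyntheticTruth
            pos, etype = site
            out.append((pos, etype.rna_base.replace("U", "T"), etype.dna_base))
    return out


def apply_edits(gene: GeneRecord | str, sites: Iterable) -> str:
    """Reference sequence with all site substitutions applied."""
    seq = gene.seq if isinstance(gene, GeneRecord) else gene
    edited = list(seq)
    for pos, rna_dna, dna in _site_items(sites):
        if not 0 <= pos < len(seq):
            raise IndexError(f"site position {pos} outside sequence")
        if dna is not None and seq[pos] != dna:
            raise ConsistencyError(
                f"site at {pos} records DNA base {dna} but reference has {seq[pos]}"
            )
        edited[pos] = rna_dna
    return "".join(edited)


def sites_from_truth(gene: GeneRecord, truth: SyntheticTruth) -> list[EditingSite]:
    """Promote planted truth edits to nominal EditingSite records (full
    support), for running consequence analysis without a calling step."""
    return [
        EditingSite(
            gene_id=gene.gene_id,
            position=pos,
            dna_base=etype.dna_base,
            rna_base=etype.rna_base,
            type=etype,
            depth=1,
            edited_reads=1,
            edited_fraction=1.0,
        )
        for pos, etype in truth.planted_edits
    ]


# ---------------------------------------------------------------------------
# Codon annotation


def annotate_codon_effects(
    gene: GeneRecord, sites: Sequence[EditingSite]
) -> list[EditingSite]:
    """Annotate sites with codon-level consequences.

    All edits falling in one codon are applied jointly, so a double edit
    is evaluated against the fully edited codon.  rRNA genes are returned
    with no codon annotation.
    """
    if not gene.is_coding:
        return [replace(site) for site in sites]
    by_codon: dict[int, list[EditingSite]] = {}
    for site in sites:
        if site.position >= len(gene.seq):
            raise IndexError(
                f"site position {site.position} beyond CDS of {gene.gene_id}"
            )
        by_codon.setdefault(site.position // 3, []).append(site)

    annotated: list[EditingSite] = []
    for codon_index, codon_sites in sorted(by_codon.items()):
        ref_codon = gene.seq[3 * codon_index: 3 * codon_index + 3]
        alt = list(ref_codon)
        for site in codon_sites:
            if gene.seq[site.position] != site.dna_base:
                raise ConsistencyError(
                    f"{gene.gene_id}:{site.position} DNA base mismatch"
                )
            alt[site.position % 3] = site.rna_base.replace("U", "T")
        alt_codon = "".join(alt)
        ref_aa = _translate_codon(gene, codon_index, ref_codon)
        alt_aa = _translate_codon(gene, codon_index, alt_codon, edited=True)
        for site in sorted(codon_sites, key=lambda s: s.position):
            annotated.append(
                replace(
                    site,
                    codon_index=codon_index,
                    codon_position=site.position % 3 + 1,
                    ref_codon=ref_codon,
                    alt_codon=alt_codon,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    synonymous=ref_aa == alt_aa,
                    stop_restoration=ref_aa == "*" and alt_aa != "*",
                )
            )
    annotated.sort(key=lambda s: s.position)
    return annotated


def _translate_codon(
    gene: GeneRecord, codon_index: int, codon: str, edited: bool = False
) -> str:
    # Alternative start codons: the unedited first codon reads as Met.
    if codon_index == 0 and not edited and gene.start_override == codon:
        return "M"
    return translate(codon)


# ---------------------------------------------------------------------------
# Per-gene summary


@dataclass
class GeneEditingSummary:
    """One summary-table row for a gene."""

    gene_id: str
    molecule_class: MoleculeClass
    cds_length_nt: int
    n_edits: int
    edit_frequency_pct: float
    type_counts: Optional[dict[str, int]]  # None when per-type counts unknown
    n_aa_substitutions: Optional[int] = None
    protein_length_aa: Optional[int] = None
    aa_substitution_pct: Optional[float] = None
    n_stop_restorations: int = 0
    identity_pre_pct: Optional[int] = None
    identity_post_pct: Optional[int] = None

    def type_share_pct(self, label: str, ndigits: int = 0) -> float:
        """Share of this gene's edits of one type, percent."""
        if not self.type_counts or not self.n_edits:
            raise ValueError(f"{self.gene_id}: no per-type counts available")
        return round_half_up(
            100.0 * self.type_counts.get(label, 0) / self.n_edits, ndigits
        )


def edit_frequency_pct(n_edits: int, cds_length_nt: int) -> float:
    """Percent of CDS positions edited, one decimal, half-up."""
    return round_half_up(100.0 * n_edits / cds_length_nt, 1)


def summarize_gene(
    gene: GeneRecord,
    sites: Sequence[EditingSite],
    count_per_codon: bool = False,
) -> GeneEditingSummary:
    """Build the summary row for one gene from its (annotated) sites.

    Unannotated coding sites are annotated on the fly.  With
    ``count_per_codon`` a multiply-edited changed codon counts once
    instead of once per non-synonymous site.
    """
    for site in sites:
        if site.gene_id != gene.gene_id:
            raise ValueError(
                f"site for {site.gene_id} passed to summary of {gene.gene_id}"
            )
    if gene.is_coding and any(s.synonymous is None for s in sites):
        sites = annotate_codon_effects(gene, sites)

    type_counts = Counter(s.type.label for s in sites)
    summary = GeneEditingSummary(
        gene_id=gene.gene_id,
        molecule_class=gene.molecule_class,
        cds_length_nt=len(gene.seq),
        n_edits=len(sites),
        edit_frequency_pct=edit_frequency_pct(len(sites), len(gene.seq)),
        type_counts={k: type_counts[k] for k in ALL_TYPE_ORDER if type_counts[k]},
    )
    if not gene.is_coding:
        return summary

    non_syn = [s for s in sites if s.synonymous is False]
    if count_per_codon:
        n_aa = len({s.codon_index for s in non_syn})
    else:
        n_aa = len(non_syn)
    summary.n_aa_substitutions = n_aa
    summary.protein_length_aa = len(gene.seq) // 3
    summary.aa_substitution_pct = round_half_up(
        100.0 * n_aa / summary.protein_length_aa, 1
    )
    summary.n_stop_restorations = sum(bool(s.stop_restoration) for s in sites)
    if gene.homolog_protein:
        shift = hydropathy_mw_shift(gene, sites)
        summary.identity_pre_pct, summary.identity_post_pct = identity_to_homolog(
            shift.protein_pre, shift.protein_post, gene.homolog_protein
        )
    return summary


# ---------------------------------------------------------------------------
# Aggregate statistics


@dataclass
class AggregateStats:
    """Cross-gene totals and derived statistics.

    ``type_spectrum_pct`` and ``transversion_pct`` are computed over the
    edits with known per-type counts.  ``double_substitution_pct`` is the
    number of codons edited at both positions 1 and 2, as a percentage of
    all mRNA edits.  Sequence-dependent fields (codon positions, GC,
    MW/GRAVY correlation) are None unless sites/genes were supplied.
    """

    total_edits: int
    total_mrna_edits: int
    total_aa_substitutions: int
    pct_aa_changing: Optional[float]
    type_spectrum_pct: dict[str, float]
    transversion_pct: Optional[float]
    observed_types: tuple[str, ...]
    codon_position_counts: Optional[dict[int, int]] = None
    codon_position_pcts: Optional[dict[int, float]] = None
    double_substitution_pct: Optional[float] = None
    gc_pre_pct: Optional[float] = None
    gc_post_pct: Optional[float] = None
    spearman_rho: Optional[float] = None
    spearman_p: Optional[float] = None


def aggregate(
    summaries: Sequence[GeneEditingSummary],
    annotated_sites: Optional[Sequence[EditingSite]] = None,
    genes: Optional[Sequence[GeneRecord]] = None,
) -> AggregateStats:
    """Aggregate per-gene summaries (and optionally sites + genes) into
    cross-gene statistics."""
    if not summaries:
        raise ValueError("at least one gene summary is required")
    coding = [s for s in summaries if s.molecule_class is MoleculeClass.protein_coding]
    total_edits = sum(s.n_edits for s in summaries)
    total_mrna = sum(s.n_edits for s in coding)
    total_aa = sum(s.n_aa_substitutions or 0 for s in coding)

    type_totals: Counter[str] = Counter()
    for s in summaries:
        if s.type_counts is not None:
            type_totals.update(s.type_counts)
    known = sum(type_totals.values())
    spectrum = {
        label: round_half_up(100.0 * type_totals[label] / known, 1)
        for label in ALL_TYPE_ORDER
        if type_totals[label]
    }
    transversions = sum(
        c for label, c in type_totals.items()
        if EDIT_TYPE_BY_LABEL[label].is_transversion
    )
    stats = AggregateStats(
        total_edits=total_edits,
        total_mrna_edits=total_mrna,
        total_aa_substitutions=total_aa,
        pct_aa_changing=(
            round_half_up(100.0 * total_aa / total_mrna) if total_mrna else None
        ),
        type_spectrum_pct=spectrum,
        transversion_pct=(
            round_half_up(100.0 * transversions / known, 1) if known else None
        ),
        observed_types=tuple(
            label for label in ALL_TYPE_ORDER if type_totals[label] > 0
        ),
    )

    if annotated_sites is not None:
        coding_ids = {s.gene_id for s in coding}
        mrna_sites = [
            s
            for s in annotated_sites
            if s.gene_id in coding_ids and s.codon_position is not None
        ]
        counts = Counter(s.codon_position for s in mrna_sites)
        stats.codon_position_counts = {p: counts.get(p, 0) for p in (1, 2, 3)}
        n_mrna = len(mrna_sites)
        if n_mrna:
            stats.codon_position_pcts = {
                p: round_half_up(100.0 * counts.get(p, 0) / n_mrna, 1)
                for p in (1, 2, 3)
            }
            codon_positions: dict[tuple[str, int], set[int]] = {}
            for s in mrna_sites:
                codon_positions.setdefault(
                    (s.gene_id, s.codon_index), set()
                ).add(s.codon_position)
            doubles = sum(
                1 for ps in codon_positions.values() if {1, 2} <= ps
            )
            stats.double_substitution_pct = round_half_up(
                100.0 * doubles / n_mrna, 1
            )

    if genes is not None and annotated_sites is not None:
        by_gene: dict[str, list[EditingSite]] = {}
        for s in annotated_sites:
            by_gene.setdefault(s.gene_id, []).append(s)
        pre_cat = "".join(g.seq for g in genes)
        post_cat = "".join(
            apply_edits(g, by_gene.get(g.gene_id, [])) for g in genes
        )
        stats.gc_pre_pct = round_half_up(gc_content(pre_cat), 2)
        stats.gc_post_pct = round_half_up(gc_content(post_cat), 2)

        shifts = [
            hydropathy_mw_shift(g, by_gene.get(g.gene_id, []))
            for g in genes
            if g.is_coding
        ]
        if len(shifts) >= 3:
            try:
                rho, p = spearman_rank(
                    [sh.mw_post for sh in shifts],
                    [sh.gravy_post for sh in shifts],
                )
                stats.spearman_rho, stats.spearman_p = rho, p
            except UndefinedCorrelationError:
                pass
    return stats


# ---------------------------------------------------------------------------
# Homolog identity


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identity_pct(a: str, b: str, aligner: Align.PairwiseAligner) -> int:
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return int(round_half_up(100.0 * identities / alignment.length))


def identity_to_homolog(
    protein_pre: str, protein_post: str, homolog: str
) -> tuple[int, int]:
    """Global-alignment percent identity of the pre- and post-editing
    translations to a homolog (identical columns / alignment length,
    rounded to integers)."""
    for name, value in (
        ("protein_pre", protein_pre),
        ("protein_post", protein_post),
        ("homolog", homolog),
    ):
        if not value:
            raise LengthError(f"{name} is empty")
    aligner = _make_aligner()
    return (
        _identity_pct(protein_pre, homolog, aligner),
        _identity_pct(protein_post, homolog, aligner),
    )


# ---------------------------------------------------------------------------
# MW / GRAVY shift


@dataclass(frozen=True)
class HydropathyShift:
    mw_pre: float
    mw_post: float
    gravy_pre: float
    gravy_post: float
    protein_pre: str
    protein_post: str
    pre_internal_stops: int
    post_internal_stops: int


def hydropathy_mw_shift(
    gene: GeneRecord, sites: Sequence[EditingSite]
) -> HydropathyShift:
    """Protein descriptors before and after editing.

    Premature stops ('*') are excluded from the descriptor strings rather
    than truncating the protein; their counts are reported so callers can
    flag affected genes.
    """
    if not gene.is_coding:
        raise ValueError(f"{gene.gene_id} is not protein-coding")
    pre = gene.translate()
    post = translate(apply_edits(gene, sites), start_override=gene.start_override)
    pre_clean = pre.replace("*", "")
    post_clean = post.replace("*", "")
    return HydropathyShift(
        mw_pre=molecular_weight(pre_clean),
        mw_post=molecular_weight(post_clean),
        gravy_pre=gravy(pre_clean),
        gravy_post=gravy(post_clean),
        protein_pre=pre_clean,
        protein_post=post_clean,
        pre_internal_stops=pre.count("*"),
        post_internal_stops=post.count("*"),
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation


def _average_ranks(values: Sequence[float]) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    sorted_v = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i: j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rank(
    xs: Sequence[float], ys: Sequence[float]
) -> tuple[float, float]:
    """Spearman's rho with average ranks for ties; p-value by the
    t-distribution approximation."""
    if len(xs) != len(ys):
        raise ValueError("input vectors must have equal length")
    n = len(xs)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = _average_ranks(xs), _average_ranks(ys)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("constant input vector")
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t_stat = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * float(t_dist.sf(abs(t_stat), n - 2))
    return rho, p


# ---------------------------------------------------------------------------
# Fixture adapter


def summaries_from_fixture(fixture: pd.DataFrame) -> list[GeneEditingSummary]:
    """Promote packaged fixture rows to GeneEditingSummary records.

    Edit frequencies are recomputed from count/length (one printed row is
    internally inconsistent; the counts govern).  Per-type counts are
    None for rows flagged inconsistent in the fixture.
    """
    from .core import PAPER_TYPE_ORDER

    out = []
    for row in fixture.to_dict("records"):
        if row["types_consistent"]:
            type_counts = {
                label: int(row[label])
                for label in PAPER_TYPE_ORDER
                if int(row[label])
            }
        else:
            type_counts = None

        def opt(key, cast=int):
            return cast(row[key]) if pd.notna(row[key]) else None

        n_aa = opt("n_aa_substitutions")
        protein_len = opt("protein_length_aa")
        out.append(
            GeneEditingSummary(
                gene_id=row["gene"],
                molecule_class=MoleculeClass(row["molecule_class"]),
                cds_length_nt=int(row["cds_length_nt"]),
                n_edits=int(row["n_edits"]),
                edit_frequency_pct=edit_frequency_pct(
                    int(row["n_edits"]), int(row["cds_length_nt"])
                ),
                type_counts=type_counts,
                n_aa_substitutions=n_aa,
                protein_length_aa=protein_len,
                aa_substitution_pct=(
                    round_half_up(100.0 * n_aa / protein_len, 1)
                    if n_aa is not None and protein_len
                    else None
                ),
                n_stop_restorations=int(row["n_stop_restorations"]),
                identity_pre_pct=opt("identity_pre_pct"),
                identity_post_pct=opt("identity_post_pct"),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Writers

SUMMARY_COLUMNS = (
    "gene_id", "molecule_class", "cds_length_nt", "n_edits",
    "edit_frequency_pct",
    *ALL_TYPE_ORDER,
    "n_aa_substitutions", "protein_length_aa", "aa_substitution_pct",
    "n_stop_restorations", "identity_pre_pct", "identity_post_pct",
)


def write_summary_tsv(
    summaries: Sequence[GeneEditingSummary],
    path: str | Path,
    comments: Sequence[str] = (),
) -> None:
    from . import __version__

    def fmt(value) -> str:
        if value is None:
            return "."
        if isinstance(value, float):
            return f"{value:.1f}"
        return str(value)

    with open(path, "w") as fh:
        fh.write(f"# plastedit {__version__} per-gene editing summary\n")
        for comment in comments:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for s in summaries:
            row = [
                s.gene_id, s.molecule_class.value, str(s.cds_length_nt),
                str(s.n_edits), fmt(s.edit_frequency_pct),
            ]
            for label in ALL_TYPE_ORDER:
                if s.type_counts is None:
                    row.append(".")
                else:
                    row.append(str(s.type_counts.get(label, 0)))
            row += [
                fmt(s.n_aa_substitutions), fmt(s.protein_length_aa),
                fmt(s.aa_substitution_pct), str(s.n_stop_restorations),
                fmt(s.identity_pre_pct), fmt(s.identity_post_pct),
            ]
            fh.write("\t".join(row) + "\n")


def read_summary_tsv(path: str | Path) -> list[GeneEditingSummary]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) != len(SUMMARY_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(SUMMARY_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            values = dict(zip(SUMMARY_COLUMNS, fields))

            def get(key, cast):
                return None if values[key] == "." else cast(values[key])

            if any(values[label] == "." for label in ALL_TYPE_ORDER):
                type_counts = None
            else:
                type_counts = {
                    label: int(values[label])
                    for label in ALL_TYPE_ORDER
                    if int(values[label])
                }
            out.append(
                GeneEditingSummary(
                    gene_id=values["gene_id"],
                    molecule_class=MoleculeClass(values["molecule_class"]),
                    cds_length_nt=int(values["cds_length_nt"]),
                    n_edits=int(values["n_edits"]),
                    edit_frequency_pct=float(values["edit_frequency_pct"]),
                    type_counts=type_counts,
                    n_aa_substitutions=get("n_aa_substitutions", int),
                    protein_length_aa=get("protein_length_aa", int),
                    aa_substitution_pct=get("aa_substitution_pct", float),
                    n_stop_restorations=int(values["n_stop_restorations"]),
                    identity_pre_pct=get("identity_pre_pct", int),
                    identity_post_pct=get("identity_post_pct", int),
                )
            )
    return out


def aggregate_to_dict(stats: AggregateStats) -> dict:
    return {
        "total_edits": stats.total_edits,
        "total_mrna_edits": stats.total_mrna_edits,
        "total_aa_substitutions": stats.total_aa_substitutions,
        "pct_aa_changing": stats.pct_aa_changing,
        "type_spectrum_pct": stats.type_spectrum_pct,
        "transversion_pct": stats.transversion_pct,
        "observed_types": list(stats.observed_types),
        "codon_position_counts": stats.codon_position_counts,
        "codon_position_pcts": stats.codon_position_pcts,
        "double_substitution_pct": stats.double_substitution_pct,
        "gc_pre_pct": stats.gc_pre_pct,
        "gc_post_pct": stats.gc_post_pct,
        "spearman_rho": stats.spearman_rho,
        "spearman_p": stats.spearman_p,
    }
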