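"""Minicircle core-region feature scanning.

Finds GC-rich inverted repeats, the conserved RNA-binding motif and its
embedded CCAAT-box, candidate transcription start sites from 5'-end count
tracks, and a windowed GC profile.  Eubacterial promoter calling is NOT
re-implemented here; the annotation reports CCAAT boxes only and leaves
promoter prediction to external tools.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .core import gc_content, revcomp


class ParameterError(ValueError):
    pass


class DataError(ValueError):
    pass


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class InvertedRepeat:
    """Two complementary arms around a loop; spans 0-based half-open."""

    left: tuple[int, int]
    right: tuple[int, int]
    arm_length_nt: int
    loop_length_nt: int
    arm_gc_pct: float
    mismatches: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.left[0], self.right[1])


@dataclass(frozen=True)
class MotifHit:
    position: int
    mismatches: int


@dataclass(frozen=True)
class MotifScan:
    motif: str
    hits: tuple[MotifHit, ...]
    ccaat_positions: tuple[int, ...]

    @property
    def positions(self) -> list[int]:
        return [h.position for h in self.hits]


@dataclass
class MinicircleAnnotation:
    ir_list: list[InvertedRepeat]
    ir_count: int
    motif_hits: MotifScan
    ccaat_positions: list[int]
    tss_candidates: list[tuple[int, int]]  # (position, 5'-end count)
    gc_profile: list[tuple[int, float]]  # (window start, GC %)


# ---------------------------------------------------------------------------
# Inverted repeats


def find_inverted_repeats(
    seq: str,
    min_arm: int = 8,
    max_loop: int = 60,
    max_mismatch: int = 0,
    min_arm_gc_pct: float = 0.0,
    merge_overlap_fraction: float = 0.5,
) -> list[InvertedRepeat]:
    """Maximal, non-redundant inverted repeats.

    Expands arms outward around every candidate loop span with a mismatch
    budget; arms never start or end on a mismatch.  Overlapping IRs
    sharing >= ``merge_overlap_fraction`` of their span are merged,
    keeping the longest arm.  Sorted by left-arm start.
    """
    if min_arm < 3:
        raise ParameterError(f"min_arm must be >= 3, got {min_arm}")
    if not seq:
        raise ParameterError("empty sequence")
    seq = seq.upper()
    n = len(seq)
    found: list[InvertedRepeat] = []
    for loop_len in range(0, max_loop + 1):
        for loop_start in range(1, n - loop_len):
            left_end = loop_start  # exclusive end of left arm
            right_start = loop_start + loop_len
            # expand outward
            pairs: list[bool] = []  # True where complementary
            i, j = left_end - 1, right_start
            budget = max_mismatch
            while i >= 0 and j < n:
                match = _COMPLEMENT.get(seq[i]) == seq[j]
                if not match:
                    if budget == 0:
                        break
                    budget -= 1
                pairs.append(match)
                i -= 1
                j += 1
            # arms must not end on a mismatch
            while pairs and not pairs[-1]:
                pairs.pop()
            if not pairs or not pairs[0]:
                continue
            arm = len(pairs)
            if arm < min_arm:
                continue
            left = (left_end - arm, left_end)
            right = (right_start, right_start + arm)
            arms_seq = seq[left[0]: left[1]] + seq[right[0]: right[1]]
            gc = gc_content(arms_seq)
            if gc < min_arm_gc_pct:
                continue
            found.append(
                InvertedRepeat(
                    left=left,
                    right=right,
                    arm_length_nt=arm,
                    loop_length_nt=loop_len,
                    arm_gc_pct=gc,
                    mismatches=pairs.count(False),
                )
            )
    return _merge_redundant(found, merge_overlap_fraction)


def _merge_redundant(
    irs: list[InvertedRepeat], overlap_fraction: float
) -> list[InvertedRepeat]:
    kept: list[InvertedRepeat] = []
    for ir in sorted(irs, key=lambda r: (-r.arm_length_nt, r.left[0])):
        redundant = False
        for other in kept:
            lo = max(ir.span[0], other.span[0])
            hi = min(ir.span[1], other.span[1])
            overlap = max(0, hi - lo)
            shorter = min(ir.span[1] - ir.span[0], other.span[1] - other.span[0])
            if shorter and overlap / shorter >= overlap_fraction:
                redundant = True
                break
        if not redundant:
            kept.append(ir)
    kept.sort(key=lambda r: r.left[0])
    return kept


# ---------------------------------------------------------------------------
# Motif scan


def find_motif(
    seq: str, motif: str = "CACCAATGCACC", max_mismatch: int = 0
) -> MotifScan:
    """All (possibly overlapping) motif matches with up to ``max_mismatch``
    substitutions, plus positions of the CCAAT promoter sub-box."""
    if not motif:
        raise ParameterError("motif must be non-empty")
    seq, motif = seq.upper(), motif.upper()
    hits = []
    for pos in range(len(seq) - len(motif) + 1):
        mm = sum(a != b for a, b in zip(seq[pos: pos + len(motif)], motif))
        if mm <= max_mismatch:
            hits.append(MotifHit(pos, mm))
    ccaat = tuple(
        pos
        for pos in range(len(seq) - 4)
        if seq[pos: pos + 5] == "CCAAT"
    )
    return MotifScan(motif=motif, hits=tuple(hits), ccaat_positions=ccaat)


# ---------------------------------------------------------------------------
# TSS detection


def detect_tss(
    five_prime_counts: Mapping[int, int], threshold: int = 50
) -> list[int]:
    """Positions whose 5'-end count strictly exceeds ``threshold``."""
    for pos, count in five_prime_counts.items():
        if count < 0:
            raise DataError(f"negative 5'-end count at position {pos}")
    return sorted(p for p, c in five_prime_counts.items() if c > threshold)


# ---------------------------------------------------------------------------
# Composite annotation


def gc_profile(seq: str, window: int = 50, step: int = 10) -> list[tuple[int, float]]:
    if window <= 0 or step <= 0:
        raise ParameterError("window and step must be positive")
    out = []
    for start in range(0, max(1, len(seq) - window + 1), step):
        out.append((start, round(gc_content(seq[start: start + window]), 2)))
    return out


def annotate_minicircle(
    seq: str,
    five_prime_counts: Optional[Mapping[int, int]] = None,
    min_arm: int = 8,
    max_loop: int = 60,
    max_mismatch: int = 0,
    min_ir_gc_pct: float = 70.0,
    motif: str = "CACCAATGCACC",
    motif_max_mismatch: int = 0,
    tss_threshold: int = 50,
    window: int = 50,
    step: int = 10,
) -> MinicircleAnnotation:
    """Bundle the three scans plus a windowed GC profile.

    ``ir_count`` counts GC-rich IRs only (arm GC >= ``min_ir_gc_pct``),
    matching how core-region repeat density is described; pass 0 to count
    every repeat.
    """
    ir_list = find_inverted_repeats(
        seq,
        min_arm=min_arm,
        max_loop=max_loop,
        max_mismatch=max_mismatch,
        min_arm_gc_pct=min_ir_gc_pct,
    )
    scan = find_motif(seq, motif=motif, max_mismatch=motif_max_mismatch)
    tss: list[tuple[int, int]] = []
    if five_prime_counts is not None:
        tss = [
            (pos, int(five_prime_counts[pos]))
            for pos in detect_tss(five_prime_counts, threshold=tss_threshold)
        ]
    return MinicircleAnnotation(
        ir_list=ir_list,
        ir_count=len(ir_list),
        motif_hits=scan,
        ccaat_positions=list(scan.ccaat_positions),
        tss_candidates=tss,
        gc_profile=gc_profile(seq, window=window, step=step),
    )


# ---------------------------------------------------------------------------
# Writers


def write_gff3(
    annotation: MinicircleAnnotation,
    seqid: str,
    path: str | Path,
    source: str = "plastedit",
) -> None:
    """GFF3 (1-based, inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, ir in enumerate(annotation.ir_list):
            attrs = (
                f"ID=ir{i};arm_length={ir.arm_length_nt};"
                f"loop_length={ir.loop_length_nt};arm_gc_pct={ir.arm_gc_pct:.1f};"
                f"mismatches={ir.mismatches}"
            )
            fh.write(
                f"{seqid}\t{source}\tinverted_repeat\t{ir.span[0] + 1}\t"
                f"{ir.span[1]}\t.\t+\t.\t{attrs}\n"
            )
        for j, hit in enumerate(annotation.motif_hits.hits):
            end = hit.position + len(annotation.motif_hits.motif)
            fh.write(
                f"{seqid}\t{source}\tsequence_motif\t{hit.position + 1}\t{end}"
                f"\t.\t+\t.\tID=motif{j};mismatches={hit.mismatches}\n"
            )
        for k, pos in enumerate(annotation.ccaat_positions):
            fh.write(
                f"{seqid}\t{source}\tCCAAT_box\t{pos + 1}\t{pos + 5}\t.\t+\t.\t"
                f"ID=ccaat{k}\n"
            )
        for m, (pos, count) in enumerate(annotation.tss_candidates):
            fh.write(
                f"{seqid}\t{source}\tTSS\t{pos + 1}\t{pos + 1}\t{count}\t+\t.\t"
                f"ID=tss{m};five_prime_count={count}\n"
            )


def annotation_to_dict(annotation: MinicircleAnnotation) -> dict:
    return {
        "ir_count": annotation.ir_count,
        "inverted_repeats": [
            {
                "left": list(ir.left),
                "right": list(ir.right),
                "arm_length_nt": ir.arm_length_nt,
                "loop_length_nt": ir.loop_length_nt,
                "arm_gc_pct": round(ir.arm_gc_pct, 2),
                "mismatches": ir.mismatches,
            }
            for ir in annotation.ir_list
        ],
        "motif": annotation.motif_hits.motif,
        "motif_hits": [
            {"position": h.position, "mismatches": h.mismatches}
            for h in annotation.motif_hits.hits
        ],
        "ccaat_positions": annotation.ccaat_positions,
        "tss_candidates": [
            {"position": p, "count": c} for p, c in annotation.tss_candidates
        ],
        "gc_profile": [
            {"start": s, "gc_pct": g} for s, g in annotation.gc_profile
        ],
    }


def write_annotation_json(
    annotation: MinicircleAnnotation, path: str | Path, meta: Optional[dict] = None
) -> None:
    payload = annotation_to_dict(annotation)
    if meta:
        payload["meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
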