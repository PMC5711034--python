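"""Candidate 9-mer peptide generation around nonsynonymous GVH variants.

Each variant residue is embedded in a 17-mer context (truncated, never
padded, at protein termini) and expanded into every 9-mer window covering
the variant position — nine windows for a full-length context. Y-chromosome
proteins of sex-mismatched pairs are tiled exhaustively into 9-mers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

NINE = 9
FLANK = 8  # residues either side of the variant in a full context


@dataclass(frozen=True)
class PeptideWindow:
    """A 9-mer candidate peptide.

    ``variant_offset`` is the 1-based position of the polymorphic residue
    within the 9-mer (0 for Y-chromosome-derived peptides, which carry no
    variant). ``aa_pos`` is the variant's protein coordinate, kept for
    deterministic deduplication ordering.
    """

    sequence: str
    source_protein: str
    source_gene: str
    variant_offset: int
    origin: str  # "snv" | "y_chromosome"
    aa_pos: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.sequence) != NINE:
            raise ValueError(f"peptide {self.sequence!r} is not a 9-mer")
        if self.origin == "snv" and not (1 <= self.variant_offset <= NINE):
            raise ValueError(f"variant_offset {self.variant_offset} outside 1..9")
        if self.origin == "y_chromosome" and self.variant_offset != 0:
            raise ValueError("y_chromosome peptides must have variant_offset 0")
        if self.origin not in ("snv", "y_chromosome"):
            raise ValueError(f"unknown origin {self.origin!r}")


def seventeen_mer(protein_seq: str, aa_pos: int, alt_aa: str) -> str:
    """Variant context: up to 8 residues either side, variant substituted.

    Returns the slice ``protein_seq[aa_pos-8 .. aa_pos+8]`` (1-based,
    inclusive) with the residue at ``aa_pos`` replaced by ``alt_aa``;
    truncated at protein termini, so the result has 9..17 residues when the
    protein itself has >= 9 and can be shorter for very short proteins.
    """
    if not (1 <= aa_pos <= len(protein_seq)):
        raise ValueError(
            f"aa_pos {aa_pos} outside protein of length {len(protein_seq)}"
        )
    context, _ = variant_context(protein_seq, aa_pos, alt_aa)
    return context


def variant_context(protein_seq: str, aa_pos: int, alt_aa: str) -> tuple[str, int]:
    """Like :func:`seventeen_mer` but also returns the variant's 1-based
    index within the returned context."""
    if not (1 <= aa_pos <= len(protein_seq)):
        raise ValueError(
            f"aa_pos {aa_pos} outside protein of length {len(protein_seq)}"
        )
    start = max(0, aa_pos - 1 - FLANK)  # 0-based inclusive
    end = min(len(protein_seq), aa_pos + FLANK)  # 0-based exclusive
    idx_in_context = aa_pos - 1 - start
    context = (
        protein_seq[start : aa_pos - 1] + alt_aa + protein_seq[aa_pos:end]
    )
    return context, idx_in_context + 1


def nine_mer_windows(
    context: str,
    variant_index_in_context: int,
    *,
    source_protein: str = "",
    source_gene: str = "",
    aa_pos: Optional[int] = None,
) -> list[PeptideWindow]:
    """All 9-mer substrings of ``context`` containing the variant residue.

    For a full 17-mer with the variant central, this is exactly nine
    windows with ``variant_offset`` running 9, 8, ..., 1. Contexts shorter
    than 9 produce an empty list (logged). Windows containing non-standard
    residues are dropped (logged).
    """
    n = len(context)
    if not (1 <= variant_index_in_context <= n):
        raise ValueError(
            f"variant index {variant_index_in_context} outside context of length {n}"
        )
    if n < NINE:
        logger.warning("context %r shorter than 9 residues; no windows", context)
        return []

    windows: list[PeptideWindow] = []
    n_dropped = 0
    for start in range(n - NINE + 1):  # 0-based window start
        lo, hi = start + 1, start + NINE  # 1-based inclusive span
        if not (lo <= variant_index_in_context <= hi):
            continue
        seq = context[start : start + NINE]
        if not set(seq) <= STANDARD_AA:
            n_dropped += 1
            continue
        windows.append(
            PeptideWindow(
                sequence=seq,
                source_protein=source_protein,
                source_gene=source_gene,
                variant_offset=variant_index_in_context - start,
                origin="snv",
                aa_pos=aa_pos,
            )
        )
    if n_dropped:
        logger.info("nine_mer_windows: dropped %d windows with non-standard residues", n_dropped)
    return windows


def y_chromosome_peptides(
    y_proteins: Iterable[tuple[str, str]] | Iterable,
) -> list[PeptideWindow]:
    """Tile every Y-chromosome protein into overlapping 9-mers (stride 1).

    Accepts ``(protein_id, sequence)`` pairs or Biopython ``SeqRecord``
    objects. Windows containing non-standard residues are dropped with a
    log line. Intended for female-donor -> male-recipient pairs only.
    """
    peptides: list[PeptideWindow] = []
    n_dropped = 0
    for rec in y_proteins:
        if isinstance(rec, tuple):
            protein_id, seq = rec
        else:  # SeqRecord
            protein_id, seq = rec.id, str(rec.seq)
        seq = seq.upper()
        for start in range(len(seq) - NINE + 1):
            window = seq[start : start + NINE]
            if not set(window) <= STANDARD_AA:
                n_dropped += 1
                continue
            peptides.append(
                PeptideWindow(
                    sequence=window,
                    source_protein=protein_id,
                    source_gene=protein_id,
                    variant_offset=0,
                    origin="y_chromosome",
                )
            )
    if n_dropped:
        logger.info("y_chromosome_peptides: dropped %d windows with non-standard residues", n_dropped)
    return peptides


def donor_self_filter(
    candidates: Sequence[PeptideWindow],
    donor_proteome_9mers: frozenset[str] | set[str],
) -> list[PeptideWindow]:
    """Remove candidates identical to a donor self 9-mer and deduplicate.

    Identical sequences arising from different variants are collapsed,
    keeping the first candidate in (source_gene, aa_pos) order so the
    result is deterministic.
    """
    ordered = sorted(
        candidates,
        key=lambda w: (w.source_gene, w.aa_pos if w.aa_pos is not None else -1, w.variant_offset),
    )
    seen: set[str] = set()
    kept: list[PeptideWindow] = []
    n_self = 0
    for w in ordered:
        if w.sequence in donor_proteome_9mers:
            n_self += 1
            continue
        if w.sequence in seen:
            continue
        seen.add(w.sequence)
        kept.append(w)
    if n_self:
        logger.info("donor_self_filter: removed %d donor-self peptides", n_self)
    return kept


def reference_self_9mers(protein_seq: str, aa_pos: int) -> set[str]:
    """Donor self-peptidome approximation at one variant locus: the 9-mers
    of the unmutated reference context around ``aa_pos``."""
    ref_context, _ = variant_context(protein_seq, aa_pos, protein_seq[aa_pos - 1])
    return {
        ref_context[i : i + NINE]
        for i in range(max(0, len(ref_context) - NINE + 1))
        if len(ref_context) >= NINE
    }


def build_snv_candidates(
    variants: Iterable,
    proteome: dict[str, str],
) -> tuple[list[PeptideWindow], set[str]]:
    """Generate candidate windows for annotated nonsynonymous GVH variants.

    Returns the candidate list and the reference-derived donor self 9-mer
    set for the same loci. Variants touching stop codons or proteins
    missing from ``proteome`` are skipped with logged counts.
    """
    candidates: list[PeptideWindow] = []
    self_set: set[str] = set()
    n_skipped_stop = 0
    n_missing_protein = 0
    for v in variants:
        if v.consequence != "nonsynonymous":
            continue
        if "*" in (v.ref_aa or "", v.alt_aa or ""):
            n_skipped_stop += 1
            continue
        seq = proteome.get(v.protein_id)
        if seq is None:
            n_missing_protein += 1
            continue
        context, idx = variant_context(seq, v.aa_pos, v.alt_aa)
        candidates.extend(
            nine_mer_windows(
                context,
                idx,
                source_protein=v.protein_id,
                source_gene=v.gene_id,
                aa_pos=v.aa_pos,
            )
        )
        self_set |= reference_self_9mers(seq, v.aa_pos)
    if n_skipped_stop:
        logger.info("build_snv_candidates: %d stop-gain/loss variants excluded", n_skipped_stop)
    if n_missing_protein:
        logger.info("build_snv_candidates: %d variants with unknown protein skipped", n_missing_protein)
    return candidates, self_set
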