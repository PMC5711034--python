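"""Peptide-HLA binding affinities (IC50, nM) and binder filtering.

Real predictions are consumed through a column-mapped table parser; a
deterministic hash-based synthetic model stands in for the external
predictor when no table is available. Affinity is 1/IC50 (nM^-1), used
unscaled as the carrying-capacity exponent downstream.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_IC50_RANGE = (1.0, 50_000.0)
BINDER_CUTOFF_NM = 500.0  # working-library cutoff (inclusive)
STRONG_BINDER_NM = 50.0  # strong-binder tally (strict)


@dataclass(frozen=True)
class PmHA:
    """One 9-mer peptide bound to one HLA allele: an operator matrix element."""

    sequence: str
    hla_allele: str
    ic50_nm: float
    gene_id: str = ""
    variant_offset: int = 0
    origin: str = "snv"

    def __post_init__(self) -> None:
        if not (self.ic50_nm > 0):
            raise ValueError(
                f"IC50 must be positive, got {self.ic50_nm!r} for "
                f"({self.sequence}, {self.hla_allele})"
            )

    @property
    def affinity(self) -> float:
        """Binding affinity in nM^-1, exactly 1/IC50."""
        return 1.0 / self.ic50_nm


DEFAULT_COLUMNS = {"peptide": "peptide", "allele": "allele", "ic50": "ic50_nm"}


def parse_affinity_table(
    rows: pd.DataFrame | Iterable[Mapping],
    *,
    column_map: Optional[Mapping[str, str]] = None,
    meta: Optional[Mapping[tuple[str, str], Mapping]] = None,
) -> list[PmHA]:
    """Build PmHA records from predictor-style output rows.

    ``column_map`` maps the logical names peptide/allele/ic50 onto the
    table's actual column headers. Duplicate (peptide, allele) pairs are
    collapsed to the minimum IC50; rows with non-positive or non-numeric
    IC50 are rejected. Both events are logged. ``meta`` optionally supplies
    gene_id/variant_offset/origin per (peptide, allele) or per peptide.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))

    best: dict[tuple[str, str], float] = {}
    n_rejected = 0
    n_duplicate = 0
    for _, row in rows.iterrows():
        peptide = str(row[cols["peptide"]])
        allele = str(row[cols["allele"]])
        try:
            ic50 = float(row[cols["ic50"]])
        except (TypeError, ValueError):
            n_rejected += 1
            continue
        if not (ic50 > 0) or math.isnan(ic50):
            n_rejected += 1
            continue
        key = (peptide, allele)
        if key in best:
            n_duplicate += 1
            best[key] = min(best[key], ic50)
        else:
            best[key] = ic50

    if n_rejected:
        logger.info("parse_affinity_table: rejected %d rows with invalid IC50", n_rejected)
    if n_duplicate:
        logger.info("parse_affinity_table: collapsed %d duplicate (peptide, allele) rows to min IC50", n_duplicate)

    out = []
    for (peptide, allele), ic50 in best.items():
        extra = {}
        if meta:
            extra = dict(meta.get((peptide, allele)) or meta.get(peptide, {}) or {})
        out.append(PmHA(sequence=peptide, hla_allele=allele, ic50_nm=ic50, **extra))
    return out


def synthetic_affinity(
    sequence: str,
    hla_allele: str,
    *,
    ic50_range: tuple[float, float] = DEFAULT_IC50_RANGE,
    seed: int = 0,
) -> float:
    """Deterministic stand-in for an external binding predictor.

    Hashes (sequence, allele, seed) to a uniform variate and maps it
    log-uniformly onto ``ic50_range``; identical inputs always give the
    identical IC50, independent of call order and process.
    """
    lo, hi = ic50_range
    if not (0 < lo <= hi):
        raise ValueError(f"invalid IC50 range {ic50_range}")
    digest = hashlib.blake2b(
        f"{sequence}|{hla_allele}|{seed}".encode(), digest_size=8
    ).digest()
    u = int.from_bytes(digest, "big") / 2**64
    if lo == hi:
        return lo
    return lo * (hi / lo) ** u


def attach_affinities(
    windows: Sequence,
    hla_alleles: Sequence[str],
    *,
    table: Optional[list[PmHA]] = None,
    ic50_range: tuple[float, float] = DEFAULT_IC50_RANGE,
    seed: int = 0,
) -> list[PmHA]:
    """Cross every candidate peptide with every HLA allele.

    Uses ``table`` records when supplied (pairs absent from the table are
    dropped with a log count), otherwise the synthetic model. The result
    is unique per (sequence, allele).
    """
    by_key: Optional[dict[tuple[str, str], PmHA]] = None
    if table is not None:
        by_key = {(p.sequence, p.hla_allele): p for p in table}

    out: list[PmHA] = []
    seen: set[tuple[str, str]] = set()
    n_missing = 0
    for w in windows:
        for allele in hla_alleles:
            key = (w.sequence, allele)
            if key in seen:
                continue
            seen.add(key)
            if by_key is not None:
                rec = by_key.get(key)
                if rec is None:
                    n_missing += 1
                    continue
                ic50 = rec.ic50_nm
            else:
                ic50 = synthetic_affinity(
                    w.sequence, allele, ic50_range=ic50_range, seed=seed
                )
            out.append(
                PmHA(
                    sequence=w.sequence,
                    hla_allele=allele,
                    ic50_nm=ic50,
                    gene_id=w.source_gene,
                    variant_offset=w.variant_offset,
                    origin=w.origin,
                )
            )
    if n_missing:
        logger.info("attach_affinities: %d (peptide, allele) pairs missing from table", n_missing)
    return out


def filter_binders(pmhas: Sequence[PmHA], cutoff_nm: float = BINDER_CUTOFF_NM) -> list[PmHA]:
    """Retain records with IC50 <= cutoff (inclusive); order preserved."""
    if not (cutoff_nm > 0):
        raise ValueError(f"cutoff must be positive, got {cutoff_nm}")
    kept = [p for p in pmhas if p.ic50_nm <= cutoff_nm]
    n_strong = sum(1 for p in kept if p.ic50_nm < STRONG_BINDER_NM)
    logger.info(
        "filter_binders: %d/%d records at IC50 <= %g nM (%d strong, < %g nM)",
        len(kept), len(pmhas), cutoff_nm, n_strong, STRONG_BINDER_NM,
    )
    return kept


def count_strong_binders(pmhas: Sequence[PmHA], cutoff_nm: float = STRONG_BINDER_NM) -> int:
    """Strong-binder tally with a strict cutoff (IC50 < cutoff)."""
    return sum(1 for p in pmhas if p.ic50_nm < cutoff_nm)
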