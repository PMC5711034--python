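"""Per-tissue expression joins: one organ-specific operator per tissue.

A peptide-HLA record enters an organ's operator iff its source gene is
expressed at RPKM >= cutoff (default 1) in that tissue. Entries are sorted
by ascending IC50 so the downstream competition matrix has its documented
above/below-diagonal structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from allosim.affinity import PmHA

logger = logging.getLogger(__name__)

TISSUES = (
    "skin",
    "salivary gland",
    "esophagus",
    "stomach",
    "small intestine",
    "colon",
    "liver",
    "lung",
    "blood",
)

RPKM_CUTOFF = 1.0
Y_DEFAULT_PEXP = 1.0  # neutral K multiplier for Y peptides without an expression row


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tissue: str
    rpkm: float

    def __post_init__(self) -> None:
        if self.rpkm < 0:
            raise ValueError(f"negative RPKM for {self.gene_id}/{self.tissue}")
        if self.tissue not in TISSUES:
            raise ValueError(
                f"unknown tissue {self.tissue!r}; valid tissues: {', '.join(TISSUES)}"
            )


@dataclass(frozen=True)
class OrganOperator:
    """Tissue-specific target set: (peptide-HLA, expression weight) pairs,
    sorted by ascending IC50 with (sequence, hla_allele) tie-break."""

    tissue: str
    entries: tuple[tuple[PmHA, float], ...]

    def __len__(self) -> int:
        return len(self.entries)


def read_rpkm_table(
    path_or_df,
    *,
    column_map: Optional[Mapping[str, str]] = None,
    gene_column: str = "gene_id",
) -> pd.DataFrame:
    """Read a wide gene-by-tissue RPKM table into a gene-indexed frame.

    ``column_map`` maps canonical tissue names onto the file's headers
    (e.g. ``{"blood": "Whole Blood"}``). If multiple rows share a gene_id
    (per-transcript tables), the per-gene maximum is used (logged).
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df, sep="\t")
    rename = {v: k for k, v in (column_map or {}).items()}
    df = df.rename(columns=rename)
    missing = [t for t in TISSUES if t not in df.columns]
    if missing:
        raise ValueError(f"expression table lacks tissue columns: {missing}")
    n_before = len(df)
    df = df.groupby(gene_column, sort=True)[list(TISSUES)].max()
    if len(df) < n_before:
        logger.info(
            "read_rpkm_table: collapsed %d per-transcript rows to %d genes (max RPKM)",
            n_before, len(df),
        )
    return df


def build_organ_operator(
    pmhas: Sequence[PmHA],
    expression_records: pd.DataFrame | Sequence[ExpressionRecord],
    tissue: str,
    rpkm_cutoff: float = RPKM_CUTOFF,
) -> OrganOperator:
    """Join binder-filtered peptide-HLA records to one tissue's expression.

    Genes missing from the table are excluded (logged), except Y-chromosome
    peptides, which receive a neutral expression weight of 1 so they
    participate in every organ. Inclusion uses RPKM >= cutoff (inclusive).
    """
    if tissue not in TISSUES:
        raise ValueError(
            f"unknown tissue {tissue!r}; valid tissues: {', '.join(TISSUES)}"
        )
    if isinstance(expression_records, pd.DataFrame):
        rpkm_by_gene = expression_records[tissue].to_dict()
    else:
        rpkm_by_gene = {
            r.gene_id: r.rpkm for r in expression_records if r.tissue == tissue
        }

    entries: list[tuple[PmHA, float]] = []
    n_missing = 0
    for p in pmhas:
        rpkm = rpkm_by_gene.get(p.gene_id)
        if rpkm is None:
            if p.origin == "y_chromosome":
                entries.append((p, Y_DEFAULT_PEXP))
            else:
                n_missing += 1
            continue
        if rpkm >= rpkm_cutoff:
            entries.append((p, float(rpkm)))
    if n_missing:
        logger.info(
            "build_organ_operator[%s]: %d records with genes missing from expression table excluded",
            tissue, n_missing,
        )
    entries.sort(key=lambda e: (e[0].ic50_nm, e[0].sequence, e[0].hla_allele))
    return OrganOperator(tissue=tissue, entries=tuple(entries))


def build_all_operators(
    pmhas: Sequence[PmHA],
    expression_records,
    tissues: Sequence[str] = TISSUES,
    rpkm_cutoff: float = RPKM_CUTOFF,
) -> dict[str, OrganOperator]:
    """One operator per requested tissue."""
    return {
        t: build_organ_operator(pmhas, expression_records, t, rpkm_cutoff)
        for t in tissues
    }
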