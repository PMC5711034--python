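"""Readers and writers for the standard formats the pipeline consumes.

VCFs are read with cyvcf2, FASTA with Biopython; tabular interchange is
plain TSV via pandas.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from allosim.affinity import PmHA
from allosim.peptide_library import PeptideWindow
from allosim.variant_gvh import GenotypeCall, GvhVariant

logger = logging.getLogger(__name__)


def read_vcf_calls(path: str | Path, sample_role: str, sample: Optional[str] = None) -> list[GenotypeCall]:
    """Read one sample's genotype calls from a VCF.

    ``sample`` selects the column in a multi-sample file; defaults to the
    first sample. Sites without a usable genotype are skipped. The VCF ID
    column (or chrom:pos:ref when missing) becomes ``site_id``.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns")
    if sample is None:
        sample_idx = 0
    else:
        if sample not in samples:
            raise ValueError(f"{path}: sample {sample!r} not in {samples}")
        sample_idx = samples.index(sample)

    calls: list[GenotypeCall] = []
    n_missing_gt = 0
    for v in vcf:
        gt = v.genotypes[sample_idx]
        allele_idx = [a for a in gt[:-1] if a is not None and a >= 0]
        if len(allele_idx) != 2:
            n_missing_gt += 1
            continue
        site_id = v.ID or f"{v.CHROM}:{v.POS}:{v.REF}"
        calls.append(
            GenotypeCall(
                site_id=site_id,
                chrom=v.CHROM,
                pos=v.POS,
                ref_allele=v.REF,
                alt_alleles=tuple(v.ALT),
                genotype=(allele_idx[0], allele_idx[1]),
                sample_role=sample_role,
            )
        )
    if n_missing_gt:
        logger.info("read_vcf_calls[%s]: skipped %d sites with missing genotypes", path, n_missing_gt)
    return calls


def read_proteome(path: str | Path) -> dict[str, str]:
    """FASTA -> {record id: residue string}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


ANNOTATION_COLUMNS = ["site_id", "gene_id", "protein_id", "aa_pos", "ref_aa", "alt_aa"]


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns: {missing}")
    return df.set_index("site_id")


def annotate_from_table(variants: Sequence[GvhVariant], annotation: pd.DataFrame) -> list[GvhVariant]:
    """Join an annotation table onto extracted GVH variants.

    Consequence is synonymous iff ref_aa == alt_aa. Variants without an
    annotation row are dropped with a logged count (non-coding sites).
    """
    out: list[GvhVariant] = []
    n_unannotated = 0
    for v in variants:
        if v.site_id not in annotation.index:
            n_unannotated += 1
            continue
        row = annotation.loc[v.site_id]
        ref_aa, alt_aa = str(row["ref_aa"]), str(row["alt_aa"])
        out.append(
            replace(
                v,
                gene_id=str(row["gene_id"]),
                protein_id=str(row["protein_id"]),
                aa_pos=int(row["aa_pos"]),
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                consequence="synonymous" if ref_aa == alt_aa else "nonsynonymous",
            )
        )
    if n_unannotated:
        logger.info("annotate_from_table: %d variants without annotation dropped", n_unannotated)
    return out


def write_gvh_tsv(variants: Sequence[GvhVariant], path: str | Path) -> None:
    rows = [
        {
            "site_id": v.site_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref_allele": v.ref_allele,
            "gvh_alleles": ",".join(sorted(v.gvh_alleles)),
            "gene_id": v.gene_id or "",
            "protein_id": v.protein_id or "",
            "aa_pos": v.aa_pos if v.aa_pos is not None else "",
            "ref_aa": v.ref_aa or "",
            "alt_aa": v.alt_aa or "",
            "consequence": v.consequence or "",
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gvh_tsv(path: str | Path) -> list[GvhVariant]:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            GvhVariant(
                site_id=str(row["site_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref_allele=str(row["ref_allele"]),
                gvh_alleles=frozenset(str(row["gvh_alleles"]).split(",")),
                gene_id=str(row["gene_id"]) or None,
                protein_id=str(row["protein_id"]) or None,
                aa_pos=int(row["aa_pos"]) if str(row["aa_pos"]) else None,
                ref_aa=str(row["ref_aa"]) or None,
                alt_aa=str(row["alt_aa"]) or None,
                consequence=str(row["consequence"]) or None,
            )
        )
    return out


def write_peptides_tsv(windows: Sequence[PeptideWindow], path: str | Path) -> None:
    rows = [
        {
            "sequence": w.sequence,
            "gene_id": w.source_gene,
            "protein_id": w.source_protein,
            "variant_offset": w.variant_offset,
            "origin": w.origin,
            "aa_pos": w.aa_pos if w.aa_pos is not None else "",
        }
        for w in windows
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_peptides_tsv(path: str | Path) -> list[PeptideWindow]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        PeptideWindow(
            sequence=str(row["sequence"]),
            source_gene=str(row["gene_id"]),
            source_protein=str(row["protein_id"]),
            variant_offset=int(row["variant_offset"]),
            origin=str(row["origin"]),
            aa_pos=int(row["aa_pos"]) if str(row["aa_pos"]) else None,
        )
        for _, row in df.iterrows()
    ]


def write_pmha_tsv(pmhas: Sequence[PmHA], path: str | Path) -> None:
    rows = [
        {
            "sequence": p.sequence,
            "hla_allele": p.hla_allele,
            "ic50_nm": repr(p.ic50_nm),
            "affinity": repr(p.affinity),
            "gene_id": p.gene_id,
            "variant_offset": p.variant_offset,
            "origin": p.origin,
        }
        for p in pmhas
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pmha_tsv(path: str | Path) -> list[PmHA]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        PmHA(
            sequence=str(row["sequence"]),
            hla_allele=str(row["hla_allele"]),
            ic50_nm=float(row["ic50_nm"]),
            gene_id=str(row["gene_id"]),
            variant_offset=int(row["variant_offset"]),
            origin=str(row["origin"]),
        )
        for _, row in df.iterrows()
    ]
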