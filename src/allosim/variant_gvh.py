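"""Graft-versus-host-direction variant extraction from paired genotype calls.

A variant is in the GVH direction when the recipient genotype carries at
least one allele that the donor genotype does not (R+/D-): the encoded
peptide is foreign to donor T cells. Only SNVs are processed; indels and
MNPs are skipped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional

from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

_STANDARD_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one biallelic or multiallelic site.

    ``genotype`` is an unordered pair of allele indices into
    ``(ref_allele,) + alt_alleles``; phasing is ignored throughout.
    """

    site_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    genotype: tuple[int, int]
    sample_role: str  # "donor" | "recipient"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.site_id}: pos must be >= 1, got {self.pos}")
        n_alleles = 1 + len(self.alt_alleles)
        for idx in self.genotype:
            if not (0 <= idx < n_alleles):
                raise ValueError(
                    f"{self.site_id}: genotype index {idx} out of range for "
                    f"{n_alleles} alleles"
                )
        if self.sample_role not in ("donor", "recipient"):
            raise ValueError(f"invalid sample_role {self.sample_role!r}")

    @property
    def alleles(self) -> frozenset[str]:
        """Set of allele strings carried by this genotype."""
        all_alleles = (self.ref_allele,) + self.alt_alleles
        return frozenset(all_alleles[i] for i in self.genotype)

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and all(len(a) == 1 for a in self.alt_alleles)


@dataclass(frozen=True)
class GvhVariant:
    """A recipient-present / donor-absent coding variant.

    Annotation fields (``gene_id`` .. ``consequence``) are filled by
    :func:`annotate_consequence` or joined from an annotation table; they
    default to ``None`` on freshly extracted variants.
    """

    site_id: str
    chrom: str
    pos: int
    ref_allele: str
    gvh_alleles: frozenset[str]
    gene_id: Optional[str] = None
    protein_id: Optional[str] = None
    aa_pos: Optional[int] = None  # 1-based protein coordinate
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None
    consequence: Optional[str] = None  # "synonymous" | "nonsynonymous"

    def __post_init__(self) -> None:
        if not self.gvh_alleles:
            raise ValueError(f"{self.site_id}: gvh_alleles must be non-empty")
        if self.consequence == "nonsynonymous" and self.ref_aa == self.alt_aa:
            raise ValueError(
                f"{self.site_id}: nonsynonymous variant must change the amino acid"
            )


def _chrom_key(chrom: str) -> tuple[int, int | str]:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return (0, int(c))
    except ValueError:
        return (1, c)


def _hom_ref(template: GenotypeCall, role: str) -> GenotypeCall:
    return GenotypeCall(
        site_id=template.site_id,
        chrom=template.chrom,
        pos=template.pos,
        ref_allele=template.ref_allele,
        alt_alleles=template.alt_alleles,
        genotype=(0, 0),
        sample_role=role,
    )


def gvh_variants(
    donor_calls: Iterable[GenotypeCall],
    recipient_calls: Iterable[GenotypeCall],
) -> list[GvhVariant]:
    """Extract recipient-only variant alleles (GVH direction, R+/D-).

    Sites present in only one sample are treated as homozygous reference in
    the other (the single-sample VCF convention); the count of such sites is
    logged. Each recipient-only alt allele at a multiallelic site yields its
    own :class:`GvhVariant`. Output is ordered by (chrom, pos).

    Raises
    ------
    ValueError
        If the two samples disagree on the reference allele at a shared
        ``site_id``.
    """
    donor_by_site = {c.site_id: c for c in donor_calls}
    recip_by_site = {c.site_id: c for c in recipient_calls}

    n_missing_donor = 0
    n_skipped_non_snv = 0
    out: list[GvhVariant] = []

    for site_id, recip in recip_by_site.items():
        donor = donor_by_site.get(site_id)
        if donor is None:
            n_missing_donor += 1
            donor = _hom_ref(recip, "donor")
        elif donor.ref_allele != recip.ref_allele:
            raise ValueError(
                f"inconsistent ref alleles at site {site_id}: "
                f"donor={donor.ref_allele!r} recipient={recip.ref_allele!r}"
            )
        if not recip.is_snv or not donor.is_snv:
            n_skipped_non_snv += 1
            continue

        # one record per recipient-only allele; a recipient ref allele a
        # hom-alt donor lacks also counts (its codon annotates as an
        # identity/synonymous change and drops out of peptide generation)
        recipient_only = recip.alleles - donor.alleles
        for allele in sorted(recipient_only):
            out.append(
                GvhVariant(
                    site_id=site_id,
                    chrom=recip.chrom,
                    pos=recip.pos,
                    ref_allele=recip.ref_allele,
                    gvh_alleles=frozenset({allele}),
                )
            )

    if n_missing_donor:
        logger.info("gvh_variants: %d sites absent from donor treated as hom-ref", n_missing_donor)
    if n_skipped_non_snv:
        logger.info("gvh_variants: %d non-SNV sites skipped", n_skipped_non_snv)

    out.sort(key=lambda v: (_chrom_key(v.chrom), v.pos, v.site_id, min(v.gvh_alleles)))
    return out


def annotate_consequence(
    variant: GvhVariant,
    cds: str,
    cds_pos: int,
    *,
    protein_id: Optional[str] = None,
    gene_id: Optional[str] = None,
    codon_table: str = "Standard",
) -> GvhVariant:
    """Classify a GVH SNV as synonymous/nonsynonymous against a CDS.

    ``cds_pos`` is the 1-based position of the variant base within the
    coding sequence. The affected codon is translated with the reference
    and the alternate base; stop-gain/stop-loss variants come back
    nonsynonymous with ``'*'`` as the gained/lost residue (they are
    excluded from peptide generation downstream).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if not (1 <= cds_pos <= len(cds)):
        raise ValueError(f"cds_pos {cds_pos} outside CDS of length {len(cds)}")
    ref_base = cds[cds_pos - 1]
    if ref_base not in _STANDARD_BASES:
        raise ValueError(f"ambiguous reference base {ref_base!r} at cds_pos {cds_pos}")
    if ref_base != variant.ref_allele:
        raise ValueError(
            f"{variant.site_id}: CDS base {ref_base!r} at cds_pos {cds_pos} "
            f"does not match variant ref allele {variant.ref_allele!r}"
        )
    (alt_base,) = variant.gvh_alleles
    if alt_base not in _STANDARD_BASES:
        raise ValueError(f"ambiguous alternate base {alt_base!r}")

    codon_index = (cds_pos - 1) // 3  # 0-based codon number == aa_pos - 1
    within = (cds_pos - 1) % 3
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]

    table = CodonTable.unambiguous_dna_by_name[codon_table]
    ref_aa = str(Seq(ref_codon).translate(table=table.id))
    alt_aa = str(Seq(alt_codon).translate(table=table.id))

    consequence = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
    if "*" in (ref_aa, alt_aa) and ref_aa != alt_aa:
        logger.info(
            "annotate_consequence: stop-gain/loss at %s (%s->%s); "
            "excluded from peptide generation downstream",
            variant.site_id,
            ref_aa,
            alt_aa,
        )
    return replace(
        variant,
        gene_id=gene_id if gene_id is not None else variant.gene_id,
        protein_id=protein_id if protein_id is not None else variant.protein_id,
        aa_pos=codon_index + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
    )
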