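"""Self-contained toy donor-recipient pair and cohort generation.

Every pair gets its own toy proteome (random CDS, standard codon table),
planted variants of four kinds (GVH nonsynonymous, GVH synonymous, shared,
donor-only), a per-tissue log-normal RPKM table, an HLA class-I allele
list, and — for female-donor -> male-recipient pairs — a small Y-protein
FASTA. All outputs are plain text and byte-deterministic per
(spec, pair_index, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from allosim.expression import TISSUES

logger = logging.getLogger(__name__)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOP_CODONS
]
_AA = "ACDEFGHIKLMNPQRSTVWY"

HLA_POOL = {
    "A": ["A0101", "A0201", "A0301", "A2402"],
    "B": ["B0702", "B0801", "B1501", "B3501"],
    "C": ["C0102", "C0401", "C0602", "C0702"],
}

# per-type nsSNP count defaults (mean, sd): matched-related-like vs
# matched-unrelated-like pairs
DEFAULT_NSSNP = {"MRD": (2463.0, 603.0), "MUD": (4287.0, 1154.0)}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters for a synthetic donor-recipient cohort."""

    n_pairs: int = 10
    donor_type_mix: float = 27 / 77  # fraction MRD-like
    mean_nssnp: dict = field(default_factory=lambda: {k: v[0] for k, v in DEFAULT_NSSNP.items()})
    sd_nssnp: dict = field(default_factory=lambda: {k: v[1] for k, v in DEFAULT_NSSNP.items()})
    syn_ratio: float = 1.1  # synonymous GVH variants per nsSNP
    shared_ratio: float = 0.3  # identical-genotype variants per nsSNP
    donor_only_ratio: float = 0.3  # D+/R- variants per nsSNP
    ic50_log_range: tuple[float, float] = (1.0, 50_000.0)
    rpkm_log10_median: float = np.log10(5.0)
    rpkm_log10_sigma: float = 0.8
    min_expressed_fraction: float = 0.6  # clamp: fraction of genes at RPKM >= 1
    female_to_male_fraction: float = 17 / 77
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (100, 500)  # residues
    n_y_proteins: int = 3
    y_protein_length_range: tuple[int, int] = (50, 120)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be non-negative")
        if not (0 <= self.donor_type_mix <= 1):
            raise ValueError("donor_type_mix must be in [0, 1]")
        if not (0 <= self.female_to_male_fraction <= 1):
            raise ValueError("female_to_male_fraction must be in [0, 1]")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


@dataclass
class PairData:
    """Paths and planted ground truth for one generated pair."""

    pair_id: str
    pair_dir: Path
    donor_type: str  # "MRD" | "MUD"
    sex_mismatch: bool  # female donor -> male recipient
    n_nssnp: int  # planted GVH nonsynonymous count
    donor_vcf: Path = field(init=False)
    recipient_vcf: Path = field(init=False)
    proteome_fasta: Path = field(init=False)
    annotation_tsv: Path = field(init=False)
    rpkm_tsv: Path = field(init=False)
    hla_file: Path = field(init=False)
    y_fasta: Optional[Path] = None

    def __post_init__(self) -> None:
        d = self.pair_dir
        self.donor_vcf = d / "donor.vcf"
        self.recipient_vcf = d / "recipient.vcf"
        self.proteome_fasta = d / "proteome.fasta"
        self.annotation_tsv = d / "annotation.tsv"
        self.rpkm_tsv = d / "rpkm.tsv"
        self.hla_file = d / "hla.txt"

    @property
    def hla_alleles(self) -> list[str]:
        return self.hla_file.read_text().split()


def _random_cds(rng: np.random.Generator, n_residues: int) -> str:
    codons = rng.choice(_CODONS, size=n_residues - 1)
    return "ATG" + "".join(codons)


def _translate(cds: str) -> str:
    return str(Seq(cds).translate())


def _pick_substitution(
    rng: np.random.Generator, cds: str, cds_pos: int, synonymous: bool
) -> Optional[tuple[str, str, str]]:
    """Try alt bases at a CDS position; return (alt_base, ref_aa, alt_aa)
    matching the requested consequence, or None if impossible there."""
    codon_idx = (cds_pos - 1) // 3
    within = (cds_pos - 1) % 3
    ref_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    ref_aa = _translate(ref_codon)
    ref_base = cds[cds_pos - 1]
    for alt_base in rng.permutation([b for b in _BASES if b != ref_base]):
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        if alt_codon in _STOP_CODONS:
            continue
        alt_aa = _translate(alt_codon)
        if synonymous == (alt_aa == ref_aa):
            return alt_base, ref_aa, alt_aa
    return None


def _plant_variants(
    rng: np.random.Generator,
    cds_by_gene: list[str],
    n: int,
    synonymous: bool,
    used_codons: set[tuple[int, int]],
) -> list[dict]:
    """Sample ``n`` single-base substitutions of the requested consequence,
    at most one per codon across all variant classes."""
    out: list[dict] = []
    n_genes = len(cds_by_gene)
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError("variant planting failed to converge; proteome too small")
        g = int(rng.integers(n_genes))
        cds = cds_by_gene[g]
        codon_idx = int(rng.integers(len(cds) // 3))
        if (g, codon_idx) in used_codons:
            continue
        cds_pos = codon_idx * 3 + 1 + int(rng.integers(3))
        pick = _pick_substitution(rng, cds, cds_pos, synonymous)
        if pick is None:
            continue
        alt_base, ref_aa, alt_aa = pick
        used_codons.add((g, codon_idx))
        out.append(
            {
                "gene_idx": g,
                "cds_pos": cds_pos,
                "ref_base": cds[cds_pos - 1],
                "alt_base": alt_base,
                "aa_pos": codon_idx + 1,
                "ref_aa": ref_aa,
                "alt_aa": alt_aa,
            }
        )
    return out


def _write_vcf(path: Path, sample_name: str, rows: list[tuple[int, str, str, str, str]]) -> None:
    """rows: (pos, site_id, ref, alt, gt) sorted by pos."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=1>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}\n")
        for pos, site_id, ref, alt, gt in rows:
            fh.write(f"1\t{pos}\t{site_id}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")


def _write_fasta(path: Path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _count(rng: np.random.Generator, mean: float, sd: float) -> int:
    if sd == 0:
        return int(round(mean))
    return max(0, int(round(rng.normal(mean, sd))))


def generate_pair(spec: CohortSpec, pair_index: int, out_dir: str | Path) -> PairData:
    """Generate one internally consistent donor-recipient pair.

    Deterministic per (spec.seed, pair_index): the RNG stream is derived
    from both, so pairs are independent but individually reproducible.
    """
    rng = np.random.default_rng([spec.seed, pair_index])
    pair_dir = Path(out_dir)
    pair_dir.mkdir(parents=True, exist_ok=True)

    donor_type = "MRD" if rng.random() < spec.donor_type_mix else "MUD"
    sex_mismatch = bool(rng.random() < spec.female_to_male_fraction)

    # toy proteome
    lo, hi = spec.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    cds_by_gene = [_random_cds(rng, int(L)) for L in lengths]
    gene_ids = [f"GENE{g:05d}" for g in range(spec.n_genes)]
    protein_ids = [f"PROT{g:05d}" for g in range(spec.n_genes)]
    proteins = [_translate(cds) for cds in cds_by_gene]

    # genomic layout: genes laid head-to-tail on one contig with spacing
    spacing = 100
    offsets = np.concatenate([[1000], 1000 + np.cumsum([len(c) + spacing for c in cds_by_gene[:-1]])])

    n_nssnp = _count(rng, spec.mean_nssnp[donor_type], spec.sd_nssnp[donor_type])
    n_syn = int(round(spec.syn_ratio * n_nssnp))
    n_shared = int(round(spec.shared_ratio * n_nssnp))
    n_donor_only = int(round(spec.donor_only_ratio * n_nssnp))

    used: set[tuple[int, int]] = set()
    gvh_nonsyn = _plant_variants(rng, cds_by_gene, n_nssnp, False, used)
    gvh_syn = _plant_variants(rng, cds_by_gene, n_syn, True, used)
    shared = _plant_variants(rng, cds_by_gene, n_shared, False, used)
    donor_only = _plant_variants(rng, cds_by_gene, n_donor_only, False, used)

    # assemble VCF rows; alternate explicit donor 0/0 with donor-absent
    # rows for GVH sites so the missing-site (hom-ref) policy is exercised
    all_variants = (
        [(v, "gvh_nonsyn") for v in gvh_nonsyn]
        + [(v, "gvh_syn") for v in gvh_syn]
        + [(v, "shared") for v in shared]
        + [(v, "donor_only") for v in donor_only]
    )
    for v, _ in all_variants:
        v["pos"] = int(offsets[v["gene_idx"]]) + v["cds_pos"] - 1
    all_variants.sort(key=lambda item: item[0]["pos"])

    donor_rows, recip_rows, ann_rows = [], [], []
    for i, (v, kind) in enumerate(all_variants):
        site_id = f"s{i:06d}"
        v["site_id"] = site_id
        row = (v["pos"], site_id, v["ref_base"], v["alt_base"])
        if kind in ("gvh_nonsyn", "gvh_syn"):
            recip_rows.append(row + ("0/1",))
            if i % 2 == 0:
                donor_rows.append(row + ("0/0",))
        elif kind == "shared":
            recip_rows.append(row + ("0/1",))
            donor_rows.append(row + ("0/1",))
        else:  # donor_only
            donor_rows.append(row + ("0/1",))
        ann_rows.append(
            {
                "site_id": site_id,
                "gene_id": gene_ids[v["gene_idx"]],
                "protein_id": protein_ids[v["gene_idx"]],
                "aa_pos": v["aa_pos"],
                "ref_aa": v["ref_aa"],
                "alt_aa": v["alt_aa"],
            }
        )

    _write_vcf(pair_dir / "donor.vcf", "DONOR", donor_rows)
    _write_vcf(pair_dir / "recipient.vcf", "RECIPIENT", recip_rows)
    _write_fasta(pair_dir / "proteome.fasta", list(zip(protein_ids, proteins)))
    _write_fasta(pair_dir / "cds.fasta", list(zip(protein_ids, cds_by_gene)))
    pd.DataFrame(ann_rows).to_csv(pair_dir / "annotation.tsv", sep="\t", index=False)

    # per-tissue log-normal RPKM, clamped so enough genes pass the
    # RPKM >= 1 inclusion rule at toy scale
    rpkm = pd.DataFrame(
        {
            t: 10.0 ** rng.normal(spec.rpkm_log10_median, spec.rpkm_log10_sigma, size=spec.n_genes)
            for t in TISSUES
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    for t in TISSUES:
        q = rpkm[t].quantile(1.0 - spec.min_expressed_fraction)
        if q < 1.0:
            rpkm[t] *= 1.0 / q
    rpkm.reset_index().to_csv(
        pair_dir / "rpkm.tsv", sep="\t", index=False, float_format="%.6g"
    )

    hla = sorted(
        [str(a) for locus in ("A", "B", "C") for a in rng.choice(HLA_POOL[locus], size=2, replace=False)]
    )
    (pair_dir / "hla.txt").write_text("\n".join(hla) + "\n")

    pair = PairData(
        pair_id=f"pair_{pair_index:04d}",
        pair_dir=pair_dir,
        donor_type=donor_type,
        sex_mismatch=sex_mismatch,
        n_nssnp=n_nssnp,
    )
    if sex_mismatch:
        lo_y, hi_y = spec.y_protein_length_range
        y_records = [
            (
                f"YPROT{j:02d}",
                "".join(rng.choice(list(_AA), size=int(rng.integers(lo_y, hi_y + 1)))),
            )
            for j in range(spec.n_y_proteins)
        ]
        y_path = pair_dir / "y_proteins.fasta"
        _write_fasta(y_path, y_records)
        pair.y_fasta = y_path

    with open(pair_dir / "pair.json", "w") as fh:
        json.dump(
            {
                "pair_id": pair.pair_id,
                "donor_type": donor_type,
                "sex_mismatch": sex_mismatch,
                "n_nssnp": n_nssnp,
                "seed": spec.seed,
            },
            fh,
            indent=1,
        )
    return pair


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> pd.DataFrame:
    """Generate ``spec.n_pairs`` pairs under ``out_dir`` plus a manifest.

    Returns the manifest frame (pair_id, donor_type, sex_mismatch,
    n_nssnp, seed); it is also written to ``out_dir/manifest.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(spec.n_pairs):
        pair = generate_pair(spec, i, out_dir / f"pair_{i:04d}")
        rows.append(
            {
                "pair_id": pair.pair_id,
                "donor_type": pair.donor_type,
                "sex_mismatch": pair.sex_mismatch,
                "n_nssnp": pair.n_nssnp,
                "seed": spec.seed,
            }
        )
    manifest = pd.DataFrame(
        rows, columns=["pair_id", "donor_type", "sex_mismatch", "n_nssnp", "seed"]
    )
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest
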