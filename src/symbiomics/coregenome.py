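"""Core-genome SNP statistics and pangenome summaries.

Operates on per-gene codon-aware alignment blocks of the core genome:
masks high-gap columns, calls polymorphic sites, computes gene-length
normalized SNP densities (SNPs per kb) stratified by pathway category,
compares categories with one-sided Mann-Whitney U tests, summarizes gene
presence/absence across genome groups, and extrapolates clade age from
16S rRNA divergence on a linear clock.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GAP_CHARS = frozenset("-.")
VALID_BASES = frozenset("ACGT")


@dataclass
class GeneAlignmentBlock:
    """One gene's alignment: ordered isolates and equal-length sequences."""

    gene_id: str
    isolates: list[str]
    sequences: list[str]
    category: str = "background"

    def __post_init__(self):
        if len(set(self.isolates)) != len(self.isolates):
            raise ValueError(f"duplicate isolate ids in gene {self.gene_id}")
        if len({len(s) for s in self.sequences}) > 1:
            raise ValueError(f"unequal sequence lengths in gene {self.gene_id}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclass
class SnpRecord:
    """A polymorphic alignment column with per-isolate alleles."""

    gene_id: str
    column: int  # 0-based within the gene alignment
    alleles: dict[str, str]

    @property
    def n_alleles(self) -> int:
        return len(set(self.alleles.values()))


def mask_gap_columns(
    sequences: Sequence[str], max_gap_frac: float = 0.05
) -> tuple[list[str], list[int]]:
    """Remove columns whose gap fraction is strictly greater than ``max_gap_frac``.

    Returns the masked sequences and the 0-based indices of kept columns.
    """
    if not sequences:
        raise ValueError("empty alignment")
    arr = np.array([list(s.upper()) for s in sequences])
    if arr.ndim != 2:
        raise ValueError("sequences must have equal length")
    gap_frac = np.isin(arr, list(GAP_CHARS)).mean(axis=0)
    kept = np.flatnonzero(gap_frac <= max_gap_frac)
    masked = ["".join(row) for row in arr[:, kept]]
    return masked, kept.tolist()


def _column_states(block: GeneAlignmentBlock, col: int) -> list[str]:
    return [seq[col].upper() for seq in block.sequences]


def call_snps(block: GeneAlignmentBlock) -> list[SnpRecord]:
    """Polymorphic sites of one gene block.

    A column is a SNP when it contains at least two distinct bases among
    A/C/G/T; columns containing any gap or ambiguity character are skipped
    entirely (they are also excluded from the effective length used for
    densities).  Multi-allelic columns yield a single record.
    """
    if len(block.isolates) < 2:
        raise ValueError("need at least two isolates to call SNPs")
    records = []
    for col in range(block.length):
        states = _column_states(block, col)
        if any(s not in VALID_BASES for s in states):
            continue
        if len(set(states)) >= 2:
            records.append(SnpRecord(block.gene_id, col, dict(zip(block.isolates, states))))
    return records


def effective_length(block: GeneAlignmentBlock) -> int:
    """Number of columns counted for SNP calling (all-ACGT columns)."""
    n = 0
    for col in range(block.length):
        if all(s in VALID_BASES for s in _column_states(block, col)):
            n += 1
    return n


def write_vcf(records: Iterable[SnpRecord], isolates: Sequence[str], path: str) -> None:
    """Write SNP records as VCF v4.2, one pseudo-contig per gene (1-based POS)."""
    records = list(records)
    genes = sorted({r.gene_id for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=symbiomics\n")
        for g in genes:
            fh.write(f"##contig=<ID={g}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(isolates) + "\n")
        for rec in sorted(records, key=lambda r: (r.gene_id, r.column)):
            ref = rec.alleles[isolates[0]]
            alts = sorted({a for a in rec.alleles.values() if a != ref})
            allele_index = {ref: 0, **{a: i + 1 for i, a in enumerate(alts)}}
            gts = "\t".join(str(allele_index[rec.alleles[iso]]) for iso in isolates)
            fh.write(
                f"{rec.gene_id}\t{rec.column + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str) -> list[SnpRecord]:
    """Read SNP records back from a VCF written by :func:`write_vcf`."""
    import pysam

    records = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for row in vcf:
            alleles_list = [row.ref] + list(row.alts or ())
            alleles = {}
            for iso in samples:
                idx = row.samples[iso]["GT"][0]
                alleles[iso] = alleles_list[idx]
            records.append(SnpRecord(row.chrom, row.pos - 1, alleles))
    return records


def snp_density(
    records: Iterable[SnpRecord], blocks: Mapping[str, GeneAlignmentBlock]
) -> pd.DataFrame:
    """Per-gene SNP density in SNPs per kb of effective (counted) length."""
    counts: dict[str, int] = {g: 0 for g in blocks}
    for rec in records:
        if rec.gene_id not in blocks:
            raise KeyError(f"SNP record references unknown gene {rec.gene_id}")
        counts[rec.gene_id] += 1
    rows = []
    for gene_id, block in blocks.items():
        eff = effective_length(block)
        if eff == 0:
            logger.warning("gene %s has zero effective length; density undefined", gene_id)
            density = np.nan
        else:
            density = 1000.0 * counts[gene_id] / eff
        rows.append(
            {
                "gene_id": gene_id,
                "category": block.category,
                "snp_count": counts[gene_id],
                "effective_length": eff,
                "density": density,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CategoryComparison:
    """One-sided Mann-Whitney U comparison of two density groups."""

    group1: str
    group2: str
    n1: int
    n2: int
    u_statistic: float  # U for group1
    z_score: float
    p_value: float  # one-sided, in the direction of the observed difference


EXACT_MW_MAX_N = 16  # total sample size up to which the permutation p is exact


def _exact_mw_p(ranks: np.ndarray, n1: int, u_obs: float, mu: float) -> float:
    """One-sided permutation p by complete enumeration of labelings."""
    import itertools

    offset = n1 * (n1 + 1) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(ranks)), n1):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if (u_obs > mu and u >= u_obs) or (u_obs < mu and u <= u_obs):
            count += 1
    return count / total


def mann_whitney_one_sided(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Rank-sum U, tie-corrected normal Z, and one-sided p.

    Mid-ranks for ties; variance with tie correction; no continuity
    correction.  Positive Z means the first sample ranks higher; the
    one-sided p is taken in the direction of the observed mean-rank
    difference (p = 0.5 when there is no difference).  For small samples
    (n1 + n2 <= 16) the p-value comes from complete enumeration of the
    permutation distribution, where the normal approximation is poor;
    beyond that the tail of the tie-corrected normal is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0 or u1 == mu:
        return float(u1), 0.0, 0.5
    z = (u1 - mu) / math.sqrt(var)
    if n <= EXACT_MW_MAX_N:
        p = _exact_mw_p(ranks, n1, u1, mu)
    else:
        p = float(stats.norm.sf(abs(z)))
    return float(u1), float(z), p


def compare_categories(
    densities: pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> list[CategoryComparison]:
    """Mann-Whitney comparisons of SNP densities between category pairs."""
    out = []
    for g1, g2 in pairs:
        x = densities.loc[densities["category"] == g1, "density"].dropna().to_numpy()
        y = densities.loc[densities["category"] == g2, "density"].dropna().to_numpy()
        if len(x) == 0:
            raise ValueError(f"category {g1!r} has no genes")
        if len(y) == 0:
            raise ValueError(f"category {g2!r} has no genes")
        u, z, p = mann_whitney_one_sided(x, y)
        out.append(CategoryComparison(g1, g2, len(x), len(y), u, z, p))
    return out


def percentage(count: int, denominator: int) -> float:
    """Percentage rounded to 1 decimal, as printed in pangenome summaries."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * count / denominator, 1)


@dataclass
class PangenomeSummary:
    """Core / group-unique / shared gene counts with printed-style percentages."""

    n_genes: int
    n_genomes: int
    core_count: int
    core_pct: float
    group_unique: dict[str, int] = field(default_factory=dict)
    group_unique_pct: dict[str, float] = field(default_factory=dict)


def summarize_pangenome(matrix: pd.DataFrame, group_labels: Mapping[str, str]) -> PangenomeSummary:
    """Summarize a boolean gene x genome presence/absence matrix.

    ``group_labels`` maps genome -> group.  Core = genes present in every
    genome; a gene is unique to a group when it occurs in at least one of
    that group's genomes and in no genome outside the group.  Percentages
    use the total gene count as denominator, rounded to one decimal.
    """
    if matrix.empty:
        raise ValueError("empty presence/absence matrix")
    groups = set(group_labels.values())
    if len(groups) < 2:
        raise ValueError("need at least two genome groups")
    mat = matrix.astype(bool)
    n_genes, n_genomes = mat.shape
    core = int(mat.all(axis=1).sum())
    unique: dict[str, int] = {}
    unique_pct: dict[str, float] = {}
    for grp in sorted(groups):
        members = [g for g in mat.columns if group_labels[g] == grp]
        others = [g for g in mat.columns if group_labels[g] != grp]
        mask = mat[members].any(axis=1) & ~mat[others].any(axis=1)
        unique[grp] = int(mask.sum())
        unique_pct[grp] = percentage(unique[grp], n_genes)
    return PangenomeSummary(
        n_genes=n_genes,
        n_genomes=n_genomes,
        core_count=core,
        core_pct=percentage(core, n_genes),
        group_unique=unique,
        group_unique_pct=unique_pct,
    )


def shared_in_subset(matrix: pd.DataFrame, subset: Sequence[str]) -> tuple[int, int, float]:
    """Genes present in all genomes of ``subset`` among genes present in any of them.

    Returns (shared_count, subset_pangenome_size, percentage).
    """
    mat = matrix[list(subset)].astype(bool)
    pangenome = mat.any(axis=1)
    shared = int((mat.all(axis=1) & pangenome).sum())
    total = int(pangenome.sum())
    return shared, total, percentage(shared, total)


def extrapolate_age(
    divergence_pct: float, calib_age: float = 216.0, calib_pct: float = 2.8
) -> int:
    """Clade age in whole millions of years from 16S divergence (linear clock).

    Defaults calibrate 216 My per 2.8% 16S rRNA divergence; the result is
    floored to whole My.
    """
    if calib_pct <= 0 or calib_age <= 0:
        raise ValueError("calibration must be positive")
    if divergence_pct < 0:
        raise ValueError("divergence must be nonnegative")
    return int(math.floor(calib_age * divergence_pct / calib_pct))
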