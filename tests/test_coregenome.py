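"""Gap masking, SNP calling, densities, rank tests, pangenome arithmetic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from symbiomics import coregenome as cg


# ---------------------------------------------------------------------------
# gap-column masking
# ---------------------------------------------------------------------------


def test_mask_gap_columns_boundary_behaviour():
    # 8 sequences, one gap in column 0: 12.5% > 5% -> removed
    seqs = ["A" * 3 for _ in range(7)] + ["-AA"]
    masked, kept = cg.mask_gap_columns(seqs)
    assert kept == [1, 2]
    # 20 sequences, one gap: exactly 5% is not strictly greater -> retained
    seqs20 = ["AAA"] * 19 + ["-AA"]
    _, kept20 = cg.mask_gap_columns(seqs20)
    assert kept20 == [0, 1, 2]


def test_mask_gap_free_alignment_unchanged():
    seqs = ["ACGT", "ACGA"]
    masked, kept = cg.mask_gap_columns(seqs)
    assert masked == seqs and kept == [0, 1, 2, 3]
    with pytest.raises(ValueError):
        cg.mask_gap_columns([])


# ---------------------------------------------------------------------------
# SNP calling and density
# ---------------------------------------------------------------------------


def _block(seqs, gene="g1", cat="EAA"):
    return cg.GeneAlignmentBlock(gene, [f"i{j}" for j in range(len(seqs))], seqs, cat)


def test_call_snps_single_difference_and_gap_skip():
    recs = cg.call_snps(_block(["AAA", "AAA", "AAT"]))
    assert len(recs) == 1 and recs[0].column == 2
    assert cg.call_snps(_block(["A-A", "AAA", "ACA"])) == []  # variant col contains a gap
    assert cg.call_snps(_block(["AAA", "AAA", "AAA"])) == []


def test_call_snps_gap_column_skipped_but_others_counted():
    recs = cg.call_snps(_block(["ATA", "A-A", "ATA"]))
    assert recs == []
    recs = cg.call_snps(_block(["ATC", "A-C", "ATA"]))
    assert len(recs) == 1 and recs[0].column == 2


def test_call_snps_multiallelic_counts_once():
    recs = cg.call_snps(_block(["AAA", "ACA", "AGA"]))
    assert len(recs) == 1 and recs[0].n_alleles == 3


def test_call_snps_errors():
    with pytest.raises(ValueError):
        cg.GeneAlignmentBlock("g", ["a", "b"], ["AAA", "AA"])
    with pytest.raises(ValueError):
        cg.call_snps(cg.GeneAlignmentBlock("g", ["a"], ["AAA"]))


def test_snp_density_arithmetic():
    block = _block(["A" * 900, "A" * 900], gene="g1")
    recs = [cg.SnpRecord("g1", i, {"i0": "A", "i1": "T"}) for i in range(9)]
    table = cg.snp_density(recs, {"g1": block})
    assert table.iloc[0]["density"] == pytest.approx(10.0)  # 9 per 900 bases
    empty = cg.snp_density([], {"g1": block})
    assert empty.iloc[0]["density"] == 0.0


def test_snp_density_halves_when_length_doubles():
    b1 = _block(["A" * 500, "A" * 500], gene="g1")
    b2 = _block(["A" * 1000, "A" * 1000], gene="g2")
    recs = [cg.SnpRecord(g, 0, {"i0": "A", "i1": "T"}) for g in ("g1", "g2")]
    t = cg.snp_density(recs, {"g1": b1, "g2": b2}).set_index("gene_id")
    assert t.loc["g1", "density"] == pytest.approx(2 * t.loc["g2", "density"])


def test_vcf_round_trip(tmp_path):
    recs = [
        cg.SnpRecord("g1", 4, {"i0": "A", "i1": "T", "i2": "A"}),
        cg.SnpRecord("g1", 9, {"i0": "C", "i1": "C", "i2": "G"}),
        cg.SnpRecord("g2", 0, {"i0": "A", "i1": "G", "i2": "T"}),
    ]
    path = str(tmp_path / "test.vcf")
    cg.write_vcf(recs, ["i0", "i1", "i2"], path)
    back = cg.read_vcf(path)
    key = lambda r: (r.gene_id, r.column)
    assert sorted((r.gene_id, r.column, tuple(sorted(r.alleles.items()))) for r in back) == sorted(
        (r.gene_id, r.column, tuple(sorted(r.alleles.items()))) for r in recs
    )


# ---------------------------------------------------------------------------
# Mann-Whitney with exact-enumeration oracle
# ---------------------------------------------------------------------------


def exact_one_sided_p(x, y):
    """Permutation p of observing a U at least as extreme, enumerated fully."""
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = x + y
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    if u_obs == mu:
        return 0.5
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        if (u_obs > mu and u >= u_obs) or (u_obs < mu and u <= u_obs):
            count += 1
    return count / total


def test_mann_whitney_extreme_separation_oracle():
    x, y = [0.1, 0.2, 0.3], [0.4, 0.5, 0.6]
    u, z, p = cg.mann_whitney_one_sided(x, y)
    assert u == 0.0 and z < 0
    assert exact_one_sided_p(x, y) == pytest.approx(0.05)  # 1 of C(6,3)=20 labelings
    assert p == pytest.approx(0.05)  # small samples use the exact distribution


def test_mann_whitney_identical_groups():
    u, z, p = cg.mann_whitney_one_sided([1, 2, 3], [1, 2, 3])
    assert z == 0.0 and p == 0.5


def test_mann_whitney_matches_scipy_asymptotic(rng):
    x = rng.normal(size=12)
    y = rng.normal(0.5, size=9)
    u, z, p = cg.mann_whitney_one_sided(x, y)
    alt = "greater" if z > 0 else "less"
    res = sps.mannwhitneyu(x, y, alternative=alt, method="asymptotic", use_continuity=False)
    assert p == pytest.approx(res.pvalue)


def test_mann_whitney_normal_vs_exact_enumeration(rng):
    """The normal approximation is within 0.02 of full enumeration at n1=n2=8."""
    for _ in range(3):
        x = rng.normal(size=8)
        y = rng.normal(0.8, size=8)
        _, z, p = cg.mann_whitney_one_sided(x, y)
        p_normal = float(sps.norm.sf(abs(z))) if z != 0 else 0.5
        exact = exact_one_sided_p(x, y)
        assert p_normal == pytest.approx(exact, abs=0.02)
        assert p == pytest.approx(exact, abs=1e-12)  # small n: p is the exact value


def test_compare_categories_direction_and_errors():
    dens = pd.DataFrame(
        {
            "category": ["EAA"] * 3 + ["vitamin"] * 3,
            "density": [5.0, 6.0, 7.0, 1.0, 2.0, 3.0],
        }
    )
    (c,) = cg.compare_categories(dens, [("EAA", "vitamin")])
    assert c.z_score > 0 and c.p_value < 0.1
    with pytest.raises(ValueError):
        cg.compare_categories(dens, [("EAA", "missing")])


# ---------------------------------------------------------------------------
# pangenome summaries and age extrapolation
# ---------------------------------------------------------------------------


def test_pangenome_all_core():
    mat = pd.DataFrame(True, index=["g1", "g2"], columns=["a", "b", "c"])
    s = cg.summarize_pangenome(mat, {"a": "in", "b": "in", "c": "out"})
    assert s.core_count == 2 and s.core_pct == 100.0


def test_pangenome_group_unique_and_shared():
    mat = pd.DataFrame(
        {
            "a": [True, True, False, True],
            "b": [True, True, True, True],
            "o": [True, False, False, False],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    s = cg.summarize_pangenome(mat, {"a": "in", "b": "in", "o": "out"})
    assert s.core_count == 1
    assert s.group_unique["in"] == 3  # g2, g3, g4 absent from the outgroup
    shared, total, pct = cg.shared_in_subset(mat, ["a", "b"])
    assert (shared, total) == (3, 4)


def test_printed_percentage_arithmetic():
    assert cg.percentage(349, 14893) == 2.3
    assert cg.percentage(716, 1096) == 65.3
    assert cg.percentage(739, 975) == 75.8
    assert cg.percentage(470, 747) == 62.9


def test_equal_rate_categories_type_i_controlled():
    """With identical mutation rates in both categories, the EAA-vs-background
    comparison rejects at alpha=0.05 in at most 7% of seeds."""
    from symbiomics import studies

    assert studies.snp_density_type_i(n_seeds=200, seed0=500) <= 0.07


def test_age_extrapolation():
    assert cg.extrapolate_age(4.0) == 308
    assert cg.extrapolate_age(2.8) == 216
    assert cg.extrapolate_age(0.0) == 0
    with pytest.raises(ValueError):
        cg.extrapolate_age(1.0, calib_pct=0.0)
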