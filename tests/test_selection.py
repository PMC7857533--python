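"""Pairwise NG86 dN/dS, beta discretization, and the LRT wrapper."""

import itertools
import math
import warnings

import numpy as np
import pytest
from Bio.Seq import Seq

from symbiomics import selection
from symbiomics.coregenome import GeneAlignmentBlock

# ---------------------------------------------------------------------------
# Independent NG86 oracle built directly on Biopython's translation table:
# enumerates mutational opportunities and substitution pathways explicitly.
# ---------------------------------------------------------------------------

STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon):
    return str(Seq(codon).translate())


def oracle_site_counts(codon):
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOPS:
                continue
            valid += 1
            if _aa(mut) == _aa(codon):
                syn += 1
        if valid:
            s += syn / valid
    return 3.0 - s, s


def oracle_diff_counts(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, nd, sd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((nd, sd))
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths), sum(p[1] for p in paths) / len(paths))


def random_codon_seq(rng, n_codons):
    from symbiomics.codons import SENSE_CODONS

    return "".join(SENSE_CODONS[i] for i in rng.integers(61, size=n_codons))


def test_ng86_pair_matches_enumeration_oracle(rng):
    """Pooled pair counts equal codon-by-codon oracle sums on random short pairs."""
    for _ in range(60):
        n = int(rng.integers(1, 6))
        a, b = random_codon_seq(rng, n), random_codon_seq(rng, n)
        got = selection.ng86_pair(a, b)
        exp_n = exp_s = exp_nd = exp_sd = 0.0
        for i in range(n):
            ca, cb = a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]
            na, sa = oracle_site_counts(ca)
            nb, sb = oracle_site_counts(cb)
            d = oracle_diff_counts(ca, cb)
            if d is None:
                d = selection.ng86_pair(ca, cb).n_diffs, selection.ng86_pair(ca, cb).s_diffs
            exp_n += (na + nb) / 2
            exp_s += (sa + sb) / 2
            exp_nd += d[0]
            exp_sd += d[1]
        assert got.n_sites == pytest.approx(exp_n)
        assert got.s_sites == pytest.approx(exp_s)
        assert got.n_diffs == pytest.approx(exp_nd)
        assert got.s_diffs == pytest.approx(exp_sd)


def test_ng86_pair_agrees_with_biopython(rng):
    """Cross-check dN/dS against Bio.codonalign's NG86 where both are defined.

    The two implementations treat stop codons differently (site
    denominators, and Biopython keeps stop-passing substitution pathways
    that this package excludes), so the comparison is restricted to pairs
    whose pathways are all stop-free and uses a loose tolerance.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    checked = 0
    for seed in range(40):
        r = np.random.default_rng(seed)
        a = random_codon_seq(r, 30)
        # mutate a handful of bases to stay in the low-divergence regime
        b = list(a)
        for _ in range(4):
            i = int(r.integers(len(b)))
            b[i] = "ACGT"[int(r.integers(4))]
        b = "".join(b)
        if any(b[i : i + 3] in STOPS for i in range(0, len(b), 3)):
            continue
        # skip pairs where any codon has a stop-blocked substitution pathway
        def n_valid_paths(c1, c2):
            diff = [i for i in range(3) if c1[i] != c2[i]]
            valid = 0
            for order in itertools.permutations(diff):
                cur, ok = c1, True
                for pos in order:
                    cur = cur[:pos] + c2[pos] + cur[pos + 1 :]
                    if cur in STOPS:
                        ok = False
                        break
                valid += ok
            return valid, math.factorial(len(diff))

        blocked = False
        for i in range(0, len(a), 3):
            nv, total = n_valid_paths(a[i : i + 3], b[i : i + 3])
            if nv != total:
                blocked = True
                break
        if blocked:
            continue
        ours = selection.ng86_pair(a, b)
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        if ds < 0 or dn < 0:  # biopython sentinel for undefined correction
            continue
        checked += 1
        assert ours.d_n == pytest.approx(dn, rel=0.2, abs=5e-3)
        assert ours.d_s == pytest.approx(ds, rel=0.2, abs=5e-3)
    assert checked >= 10


def test_ng86_pair_worked_examples():
    r = selection.ng86_pair("TTT", "TTC")
    assert (r.n_diffs, r.s_diffs) == (0.0, 1.0)
    assert r.d_n == 0.0
    assert r.ratio == 0.0  # no nonsynonymous divergence at all

    same = selection.ng86_pair("ATGAAA", "ATGAAA")
    assert same.d_n == 0.0 and same.d_s == 0.0
    assert same.ratio is None  # NA: no divergence of either kind

    forced = selection.ng86_pair("GAA", "GAC")
    assert forced.s_diffs == 0.0
    assert forced.ratio is None  # dS = 0


def test_ng86_pair_symmetry_and_column_skipping(rng):
    a, b = random_codon_seq(rng, 20), random_codon_seq(rng, 20)
    ab, ba = selection.ng86_pair(a, b), selection.ng86_pair(b, a)
    assert ab.n_sites == ba.n_sites and ab.n_diffs == ba.n_diffs
    # gap codons are skipped pairwise
    gapped = selection.ng86_pair("ATG---AAA", "ATGCCCAAA")
    assert gapped.codons_compared == 2


def test_ng86_pair_site_identity():
    """N + S = 3 * compared codons."""
    r = selection.ng86_pair("ATGAAATTTGGG", "ATGAAATTCGGA")
    assert r.n_sites + r.s_sites == pytest.approx(3 * r.codons_compared)


def test_saturated_distance_flagged():
    # every codon differs synonymously -> pS = 1 within one codon pair
    r = selection.ng86_pair("TTT", "TTC")
    assert any("dS undefined" in f for f in r.flags)


# ---------------------------------------------------------------------------
# pathway_dnds
# ---------------------------------------------------------------------------


def _blocks():
    return [
        GeneAlignmentBlock("g1", ["a1", "a2", "b1", "b2"],
                           ["ATGAAATTT", "ATGAAATTT", "ATGAATTTT", "ATGAATTTT"]),
        GeneAlignmentBlock("g2", ["a1", "a2", "b1", "b2"],
                           ["ATGCCC", "ATGCCC", "ATGCCC", "ATGCCC"]),
    ]


def test_pathway_dnds_pooling_matches_per_pair_oracle():
    blocks = _blocks()
    clades = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
    table = selection.pathway_dnds(blocks, clades, "between", {"g1": "pw"})
    row = table.set_index("pathway").loc["pw"]
    pooled = selection.NgCounts()
    for a in clades["A"]:
        for b in clades["B"]:
            seq = {"a1": "ATGAAATTT", "a2": "ATGAAATTT", "b1": "ATGAATTTT", "b2": "ATGAATTTT"}
            pooled = pooled.add(selection.ng86_pair(seq[a], seq[b]))
    assert row["n_diffs"] == pytest.approx(pooled.n_diffs)
    assert row["s_diffs"] == pytest.approx(pooled.s_diffs)


def test_pathway_identical_gives_na():
    blocks = _blocks()
    clades = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
    table = selection.pathway_dnds(blocks, clades, "between", {"g2": "flat"})
    assert math.isnan(table.set_index("pathway").loc["flat", "dnds"])


def test_within_mode_uses_within_clade_pairs():
    blocks = _blocks()
    clades = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
    table = selection.pathway_dnds(blocks, clades, "within", {"g1": "pw"})
    # within clades the sequences are identical -> no differences at all
    row = table.set_index("pathway").loc["pw"]
    assert row["n_diffs"] == 0.0 and row["s_diffs"] == 0.0


# ---------------------------------------------------------------------------
# discretize_beta
# ---------------------------------------------------------------------------


def test_discretize_uniform_gives_deciles():
    rates, weights = selection.discretize_beta(1.0, 1.0, 10)
    assert rates == pytest.approx(np.arange(0.05, 1.0, 0.1))
    assert weights == pytest.approx(np.full(10, 0.1))


@pytest.mark.parametrize("p,q,ncat", [(0.5, 1.5, 10), (2.0, 5.0, 11), (0.2, 0.3, 4)])
def test_discretize_conserves_mean_and_is_increasing(p, q, ncat):
    rates, weights = selection.discretize_beta(p, q, ncat)
    assert float(np.dot(rates, weights)) == pytest.approx(p / (p + q), abs=1e-10)
    assert np.all(np.diff(rates) > 0)


def test_discretize_rejects_bad_shapes():
    with pytest.raises(ValueError):
        selection.discretize_beta(0.0, 1.0, 10)
    with pytest.raises(ValueError):
        selection.discretize_beta(1.0, 1.0, 0)


# ---------------------------------------------------------------------------
# LRT arithmetic
# ---------------------------------------------------------------------------


class _FakeFit:
    def __init__(self, lnl, post=None, h="x"):
        self.lnl = lnl
        self.data_hash = h
        self.site_posteriors = post if post is not None else np.zeros((3, 11))


def test_lrt_equal_likelihoods_gives_p_one():
    res = selection.lrt(_FakeFit(-100.0), _FakeFit(-100.0))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_lrt_chi2_closed_form():
    # chi^2 df=2 upper tail at x is exp(-x/2)
    res = selection.lrt(_FakeFit(-103.0), _FakeFit(-100.005))
    assert res.p_value == pytest.approx(math.exp(-res.statistic / 2.0))
    near_05 = selection.lrt(_FakeFit(-100.0), _FakeFit(-100.0 + 5.99 / 2.0))
    assert near_05.p_value == pytest.approx(0.050, abs=5e-4)


def test_lrt_flags_neb_sites_and_checks_hashes():
    post = np.zeros((4, 11))
    post[2, -1] = 0.99
    res = selection.lrt(_FakeFit(-10.0), _FakeFit(-8.0, post))
    assert res.positive_sites == [(3, pytest.approx(0.99))]
    with pytest.raises(ValueError):
        selection.lrt(_FakeFit(-10.0, h="a"), _FakeFit(-8.0, h="b"))
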