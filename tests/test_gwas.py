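"""De Bruijn graph construction, unitig compaction, and association testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from symbiomics import gwas
from symbiomics.codons import revcomp


def naive_kmer_set(seq, k):
    return {gwas.canonical(seq[i : i + k]) for i in range(len(seq) - k + 1)}


def random_genome(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def test_hand_canonicalization_example():
    g = gwas.build_graph({"g1": "ACGGT"}, k=3)
    assert set(g.presence) == {"ACG", "CCG", "ACC"}
    unitigs = gwas.compact_unitigs(g)
    assert len(unitigs) == 1
    assert unitigs[0].sequence in ("ACGGT", revcomp("ACGGT"))


def test_identical_genomes_all_ones_presence():
    seq = "ACGTACGGTACC" * 5
    g = gwas.build_graph({"a": seq, "b": seq}, k=5)
    assert all(vec.all() for vec in g.presence.values())


def test_node_set_matches_naive_oracle(rng):
    for _ in range(10):
        seqs = {f"g{i}": random_genome(rng, int(rng.integers(60, 300))) for i in range(3)}
        g = gwas.build_graph(seqs, k=11)
        oracle = set().union(*(naive_kmer_set(s, 11) for s in seqs.values()))
        assert set(g.presence) == oracle


def test_graph_invariant_to_order_and_strand(rng):
    s1, s2 = random_genome(rng, 200), random_genome(rng, 180)
    g1 = gwas.build_graph({"a": s1, "b": s2}, k=15)
    g2 = gwas.build_graph({"b": s2, "a": s1}, k=15)
    g3 = gwas.build_graph({"a": revcomp(s1), "b": s2}, k=15)
    assert set(g1.presence) == set(g2.presence) == set(g3.presence)
    assert set(g1.adjacency) == set(g3.adjacency)


def test_build_graph_errors_and_warnings(rng):
    with pytest.raises(ValueError):
        gwas.build_graph({"a": "ACGT"}, k=10)
    with pytest.warns(UserWarning):
        gwas.build_graph({"a": random_genome(rng, 50)}, k=4)


# ---------------------------------------------------------------------------
# unitig compaction
# ---------------------------------------------------------------------------


def test_single_genome_low_k_round_trip(rng):
    seq = random_genome(rng, 400)
    g = gwas.build_graph({"a": seq}, k=21)
    unitigs = gwas.compact_unitigs(g)
    spelled = set().union(*(naive_kmer_set(u.sequence, 21) for u in unitigs))
    assert spelled == set(g.presence)
    # every kmer in exactly one unitig
    assert sum(len(u.kmers) for u in unitigs) == g.n_nodes


def test_bubble_from_single_substitution(rng):
    base = random_genome(rng, 300)
    alt = base[:150] + ("A" if base[150] != "A" else "C") + base[151:]
    g = gwas.build_graph({"x": base, "y": alt}, k=31)
    unitigs = gwas.compact_unitigs(g)
    solo = [u for u in unitigs if u.presence.sum() == 1]
    shared = [u for u in unitigs if u.presence.sum() == 2]
    assert len(solo) == 2 and len(shared) == 2
    # presence vectors are uniform within each unitig by construction
    for u in unitigs:
        for km in u.kmers:
            assert np.array_equal(g.presence[km], u.presence)


def test_compaction_round_trip_oracle_many_genomes(rng):
    seqs = {f"g{i}": random_genome(rng, 500) for i in range(4)}
    g = gwas.build_graph(seqs, k=17)
    unitigs = gwas.compact_unitigs(g)
    spelled = set().union(*(naive_kmer_set(u.sequence, 17) for u in unitigs))
    oracle = set().union(*(naive_kmer_set(s, 17) for s in seqs.values()))
    assert spelled == oracle


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------


def _unitig(uid, presence):
    return gwas.Unitig(uid, "A" * 35, ["A" * 31], np.array(presence, dtype=bool))


def test_fisher_small_table_hand_enumeration():
    # 4 tested isolates (2 per phenotype); unitig present in both phenotype-1
    # isolates only: one table of C(4,2)=6 equally likely -> p = 1/6
    genomes = ["a0", "a1", "b0", "b1"]
    phen = {"a0": 0, "a1": 0, "b0": 1, "b1": 1}
    unitigs = [_unitig(0, [0, 0, 1, 1])]
    (rec,) = gwas.associate(unitigs, genomes, phen)
    assert rec.p_value == pytest.approx(1 / 6)
    assert rec.direction == 1


def test_fisher_matches_hypergeometric_oracle(rng):
    """One-sided Fisher p equals the closed-form hypergeometric tail."""
    genomes = [f"i{j}" for j in range(8)]
    phen = {g: (0 if j < 4 else 1) for j, g in enumerate(genomes)}
    for trial in range(30):
        presence = rng.integers(0, 2, size=8).astype(bool)
        if presence.all() or not presence.any():
            continue
        recs = gwas.associate([_unitig(0, presence)], genomes, phen)
        if recs == []:
            continue
        a1 = int(presence[4:].sum())
        total = int(presence.sum())
        # oracle: hypergeometric tail in the tested direction
        rec = recs[0]
        if rec.direction == 1:
            oracle = sps.hypergeom.sf(a1 - 1, 8, total, 4)
        else:
            oracle = sps.hypergeom.cdf(a1, 8, total, 4)
        assert rec.p_value == pytest.approx(float(oracle))


def test_non_informative_unitigs_skipped():
    genomes = ["a0", "a1", "b0", "b1"]
    phen = {"a0": 0, "a1": 0, "b0": 1, "b1": 1}
    assert gwas.associate([_unitig(0, [1, 1, 1, 1])], genomes, phen) == []
    assert gwas.associate([_unitig(0, [0, 0, 0, 0])], genomes, phen) == []


def test_outgroup_only_presence_is_non_informative():
    genomes = ["a0", "a1", "b0", "b1", "o1"]
    phen = {"a0": 0, "a1": 0, "b0": 1, "b1": 1, "o1": 2}
    # present everywhere among tested isolates, absent only in the outgroup
    assert gwas.associate([_unitig(0, [1, 1, 1, 1, 0])], genomes, phen) == []


def test_bh_qvalues_monotone(rng):
    genomes = [f"i{j}" for j in range(10)]
    phen = {g: (0 if j < 5 else 1) for j, g in enumerate(genomes)}
    unitigs = [
        _unitig(i, rng.integers(0, 2, size=10).astype(bool)) for i in range(40)
    ]
    recs = gwas.associate(unitigs, genomes, phen)
    recs = sorted(recs, key=lambda r: r.p_value)
    qs = [r.q_value for r in recs]
    assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
    assert all(r.q_value >= r.p_value for r in recs)


def test_associate_requires_two_per_phenotype():
    with pytest.raises(ValueError):
        gwas.associate([_unitig(0, [1, 0, 1])], ["a", "b", "c"], {"a": 0, "b": 1, "c": 1})


# ---------------------------------------------------------------------------
# mapping and density
# ---------------------------------------------------------------------------


def test_map_density_hand_built_gene():
    rng = np.random.default_rng(0)
    ref = "".join("ACGT"[i] for i in rng.integers(4, size=700))
    ann = pd.DataFrame(
        [
            {"isolate": "ref", "gene_id": "gA", "start": 101, "end": 600,
             "strand": "+", "pathway": "p", "category": "EAA"},
        ]
    )
    k = 31
    # two "variant" unitigs whose kmers sit inside the gene, one intergenic
    u1 = gwas.Unitig(0, ref[150:150 + 40], [gwas.canonical(ref[150 + i:150 + i + k]) for i in range(5)], np.array([True]))
    u2 = gwas.Unitig(1, ref[400:400 + 35], [gwas.canonical(ref[400:400 + k])], np.array([True]))
    u3 = gwas.Unitig(2, ref[620:620 + 35], [gwas.canonical(ref[620:620 + k])], np.array([True]))
    recs = [
        gwas.AssociationRecord(i, 2, 0, 0, 2, 0.01, 0.01, 1) for i in range(3)
    ]
    dens = gwas.map_and_density(recs, [u1, u2, u3], ref, ann, "ref", k)
    row = dens.set_index("gene_id").loc["gA"]
    assert row["variant_count"] == 2
    assert row["density"] == pytest.approx(1000.0 * 2 / 500)
    assert dens.attrs["intergenic_variants"] == 1


def test_density_two_variants_500bp_gene():
    assert 1000.0 * 2 / 500 == pytest.approx(4.0)
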