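"""Independent brute-force oracles used by the acceptance suite.

Everything here is computed by enumeration or first principles, never by
calling the implementation under test.
"""

import itertools
import math

from Bio.Seq import Seq
from scipy import stats as sps

STOPS = {"TAA", "TAG", "TGA"}
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def exact_mann_whitney_one_sided(x, y):
    """Full enumeration of all C(n1+n2, n1) labelings; one-sided tail of U."""
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = x + y
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * len(y) / 2
    if u_obs == mu:  # no observed difference: symmetric midpoint convention
        return 0.5
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
        total += 1
        if (u_obs > mu and u >= u_obs) or (u_obs < mu and u <= u_obs):
            count += 1
    return count / total


def hypergeom_upper_tail(annotated, significant, n_study, n_universe):
    """P(X >= significant) by direct combinatorial summation."""
    max_sig = min(annotated, n_study)
    return sum(
        math.comb(annotated, s) * math.comb(n_universe - annotated, n_study - s)
        for s in range(significant, max_sig + 1)
    ) / math.comb(n_universe, n_study)


def naive_canonical_kmers(seq, k):
    out = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        rc = kmer.translate(COMPLEMENT)[::-1]
        out.add(min(kmer, rc))
    return out


def _aa(codon):
    return str(Seq(codon).translate())


def ng86_codon_sites(codon):
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


def ng86_codon_diffs(c1, c2):
    """Average (nd, sd) over stop-free substitution pathways; None if all blocked."""
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
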