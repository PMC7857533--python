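"""Selection inference on codon alignments.

Two complementary layers:

* pairwise counting dN/dS after Nei & Gojobori (1986): synonymous and
  nonsynonymous site and difference counts with all-pathway averaging and
  Jukes-Cantor correction, pooled per pathway between or within clades;
* site-model likelihood ratio tests (M7 beta vs M8 beta + positive-selection
  class) on a GY94-style codon model, with naive-empirical-Bayes (NEB)
  identification of positively selected sites — see :mod:`symbiomics.codonmodel`
  for the likelihood engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .codons import CODON_INDEX, ng86_diff_counts, ng86_site_counts

__all__ = [
    "NgCounts",
    "ng86_pair",
    "pathway_dnds",
    "discretize_beta",
    "LrtResult",
    "lrt",
]


def _jukes_cantor(p: float) -> float | None:
    """JC-corrected distance d = -(3/4)ln(1 - 4p/3); None when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class NgCounts:
    """NG86 site and difference counts for one comparison (or a pooled set)."""

    n_sites: float = 0.0          # N: nonsynonymous sites
    s_sites: float = 0.0          # S: synonymous sites
    n_diffs: float = 0.0          # Nd
    s_diffs: float = 0.0          # Sd
    codons_compared: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def p_n(self) -> float:
        return self.n_diffs / self.n_sites if self.n_sites > 0 else float("nan")

    @property
    def p_s(self) -> float:
        return self.s_diffs / self.s_sites if self.s_sites > 0 else float("nan")

    @property
    def d_n(self) -> float | None:
        if self.n_sites <= 0:
            return None
        return _jukes_cantor(self.p_n)

    @property
    def d_s(self) -> float | None:
        if self.s_sites <= 0:
            return None
        return _jukes_cantor(self.p_s)

    @property
    def ratio(self) -> float | None:
        """dN/dS.

        NA (None) when both distances are zero, when dS is zero or
        undefined while dN is positive, or when dN is undefined; exactly
        zero when dN = 0 but synonymous divergence exists.
        """
        dn, ds = self.d_n, self.d_s
        if dn is not None and dn == 0.0:
            return None if (ds is None and self.s_diffs == 0) or ds == 0.0 else 0.0
        if dn is None or ds is None or ds == 0.0:
            return None
        return dn / ds

    def add(self, other: "NgCounts") -> "NgCounts":
        return NgCounts(
            self.n_sites + other.n_sites,
            self.s_sites + other.s_sites,
            self.n_diffs + other.n_diffs,
            self.s_diffs + other.s_diffs,
            self.codons_compared + other.codons_compared,
            self.flags + other.flags,
        )


def _clean_codon_pairs(seq_a: str, seq_b: str) -> list[tuple[str, str]]:
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("sequence length must be a multiple of 3 (in-frame)")
    pairs = []
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
        if ca in CODON_INDEX and cb in CODON_INDEX:
            pairs.append((ca, cb))
        # codons with gaps/ambiguity or stops are skipped pairwise
    return pairs


def ng86_pair(seq_a: str, seq_b: str) -> NgCounts:
    """NG86 counts for one pair of equal-length in-frame sequences.

    Site counts are averaged over the two sequences; difference counts are
    averaged over all minimal substitution pathways that avoid stop codons.
    Codon columns containing gaps, ambiguity characters or stops in either
    sequence are excluded from both sites and differences.
    """
    counts = NgCounts()
    for ca, cb in _clean_codon_pairs(seq_a, seq_b):
        na, sa = ng86_site_counts(ca)
        nb, sb = ng86_site_counts(cb)
        nd, sd = ng86_diff_counts(ca, cb)
        counts.n_sites += (na + nb) / 2.0
        counts.s_sites += (sa + sb) / 2.0
        counts.n_diffs += nd
        counts.s_diffs += sd
        counts.codons_compared += 1
    if counts.s_sites > 0 and counts.p_s >= 0.75:
        counts.flags.append("pS>=0.75: dS undefined")
    if counts.n_sites > 0 and counts.p_n >= 0.75:
        counts.flags.append("pN>=0.75: dN undefined")
    return counts


def _pairs(mode: str, clades: Mapping[str, Sequence[str]]) -> list[tuple[str, str]]:
    names = list(clades)
    out: list[tuple[str, str]] = []
    if mode == "between":
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                for a in clades[names[i]]:
                    for b in clades[names[j]]:
                        out.append((a, b))
    elif mode == "within":
        for members in clades.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    out.append((members[i], members[j]))
    else:
        raise ValueError(f"mode must be 'between' or 'within', got {mode!r}")
    return out


def pathway_dnds(
    blocks: Iterable,
    clades: Mapping[str, Sequence[str]],
    mode: str = "between",
    pathway_of: Mapping[str, str] | None = None,
    average_pairs: bool = False,
) -> pd.DataFrame:
    """Pooled NG86 dN/dS per pathway (and a 'background' bucket).

    Parameters
    ----------
    blocks
        Iterable of objects with attributes ``gene_id``, ``isolates``
        (ordered ids) and ``sequences`` (aligned, same order), e.g.
        :class:`symbiomics.coregenome.GeneAlignmentBlock`.
    clades
        Mapping clade name -> isolate ids.  ``between`` compares all
        cross-clade pairs, ``within`` all within-clade pairs.
    pathway_of
        gene_id -> pathway name; genes absent from the map are pooled into
        the ``background`` bucket.
    average_pairs
        When True report the mean of per-pair dN/dS ratios instead of the
        default pooled-count ratio (pairs with undefined ratio are dropped
        from the mean).

    Returns a DataFrame with one row per pathway: pooled N, S, Nd, Sd, dN,
    dS and the ratio (NaN when undefined).
    """
    pathway_of = dict(pathway_of or {})
    pathway_seqs: dict[str, dict[str, str]] = {}
    for block in blocks:
        pw = pathway_of.get(block.gene_id, "background")
        store = pathway_seqs.setdefault(pw, {iso: "" for iso in block.isolates})
        for iso, seq in zip(block.isolates, block.sequences):
            store[iso] = store.get(iso, "") + seq
    pair_list = _pairs(mode, clades)
    rows = []
    for pw, seqs in pathway_seqs.items():
        pooled = NgCounts()
        per_pair_ratios = []
        for a, b in pair_list:
            if a not in seqs or b not in seqs:
                continue
            c = ng86_pair(seqs[a], seqs[b])
            pooled = pooled.add(c)
            if average_pairs and c.ratio is not None:
                per_pair_ratios.append(c.ratio)
        if pooled.codons_compared == 0:
            continue
        if average_pairs:
            ratio = float(np.mean(per_pair_ratios)) if per_pair_ratios else None
        else:
            ratio = pooled.ratio
        rows.append(
            {
                "pathway": pw,
                "mode": mode,
                "n_sites": pooled.n_sites,
                "s_sites": pooled.s_sites,
                "n_diffs": pooled.n_diffs,
                "s_diffs": pooled.s_diffs,
                "dN": pooled.d_n if pooled.d_n is not None else np.nan,
                "dS": pooled.d_s if pooled.d_s is not None else np.nan,
                "dnds": ratio if ratio is not None else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("pathway").reset_index(drop=True)


def discretize_beta(p: float, q: float, ncat: int) -> tuple[np.ndarray, np.ndarray]:
    """Discretize Beta(p, q) into ``ncat`` equal-probability categories.

    The rate of each category is the conditional mean of the distribution
    within its bin, computed from the regularized incomplete beta ratio
    E[X | a<X<b] = mean * (I_b(p+1,q) - I_a(p+1,q)) / (I_b(p,q) - I_a(p,q)).
    Weights are uniform 1/ncat.
    """
    if p <= 0 or q <= 0:
        raise ValueError("beta shapes must be positive")
    if ncat < 1:
        raise ValueError("ncat must be >= 1")
    probs = np.linspace(0.0, 1.0, ncat + 1)
    edges = stats.beta.ppf(probs, p, q)
    mean = p / (p + q)
    upper = special.betainc(p + 1.0, q, edges[1:])
    lower = special.betainc(p + 1.0, q, edges[:-1])
    rates = mean * (upper - lower) * ncat
    weights = np.full(ncat, 1.0 / ncat)
    return rates, weights


@dataclass
class LrtResult:
    """M7-vs-M8 likelihood ratio test for one pathway alignment."""

    pathway: str
    lnl_m7: float
    lnl_m8: float
    statistic: float
    df: int
    p_value: float
    positive_sites: list[tuple[int, float]]  # (1-based codon site, NEB posterior)


def lrt(fit_m7, fit_m8, pathway: str = "", neb_cutoff: float = 0.95) -> LrtResult:
    """Likelihood ratio test of M8 (positive selection) over nested M7.

    The statistic 2(lnL8 - lnL7) is clamped at zero and referred to a
    chi-squared distribution with 2 degrees of freedom (conservative at the
    boundary).  Positively selected sites are those whose NEB posterior for
    the omega_s class exceeds ``neb_cutoff``.
    """
    if fit_m7.data_hash != fit_m8.data_hash:
        raise ValueError("fits were computed on different data")
    stat = max(0.0, 2.0 * (fit_m8.lnl - fit_m7.lnl))
    p = float(stats.chi2.sf(stat, df=2))
    post = fit_m8.site_posteriors  # (n_sites, ncat); last class is omega_s
    sites = [
        (i + 1, float(post[i, -1]))
        for i in range(post.shape[0])
        if post[i, -1] > neb_cutoff
    ]
    return LrtResult(pathway, fit_m7.lnl, fit_m8.lnl, stat, 2, p, sites)
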