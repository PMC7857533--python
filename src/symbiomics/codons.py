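"""Genetic-code tables and codon-level utilities.

Standard genetic code throughout (the bacterial table differs only in
alternative start codons, which play no role in site counting or in the
codon substitution model).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)) if c not in STOP_CODONS)
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID: dict[str, str] = dict(_TABLE.forward_table)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_transition(a: str, b: str) -> bool:
    """True if the single-base change a->b is a transition (purine<->purine or pyrimidine<->pyrimidine)."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def translate(codon: str) -> str:
    """One-letter amino acid for a sense codon; '*' for a stop."""
    return AMINO_ACID.get(codon, "*")


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_synonymous(c1: str, c2: str) -> bool:
    """True if two sense codons encode the same amino acid."""
    return AMINO_ACID[c1] == AMINO_ACID[c2]


def codon_neighbors(codon: str) -> list[str]:
    """All 9 single-base mutants of a codon (including stops)."""
    out = []
    for pos in range(3):
        for b in NUCLEOTIDES:
            if b != codon[pos]:
                out.append(codon[:pos] + b + codon[pos + 1 :])
    return out


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous site counts (n, s) of one sense codon.

    At each of the three positions the synonymous fraction is the number of
    synonymous single-base changes divided by the number of changes that do
    not create a stop codon; s is the sum over positions and n = 3 - s.

    Raises ValueError for stop codons (they carry no site counts).
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if codon not in CODON_INDEX:
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in NUCLEOTIDES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            valid += 1
            if is_synonymous(codon, mut):
                syn += 1
        if valid:
            s += syn / valid
    return 3.0 - s, s


@lru_cache(maxsize=None)
def ng86_diff_counts(codon1: str, codon2: str) -> tuple[float, float]:
    """Nonsynonymous and synonymous difference counts (nd, sd) between two sense codons.

    Codons differing at d positions are connected by d! single-step
    substitution pathways; pathways passing through a stop codon are
    excluded and the per-step synonymous/nonsynonymous classifications are
    averaged over the remaining pathways.  If every pathway passes through
    a stop (possible only for d >= 2), all pathways are used.
    """
    for c in (codon1, codon2):
        if c not in CODON_INDEX:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid_paths: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon1
        nd = sd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if is_synonymous(cur, nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            valid_paths.append((nd, sd))
        # a blocked path contributes to the fallback set only when complete
        # enumeration is forced; partial counts are not meaningful, so for the
        # fallback we classify steps ignoring the stop constraint
    if not valid_paths:
        for order in itertools.permutations(diff_pos):
            cur = codon1
            nd = sd = 0
            for pos in order:
                nxt = cur[:pos] + codon2[pos] + cur[pos + 1 :]
                if nxt in STOP_CODONS or cur in STOP_CODONS:
                    nd += 1  # count through-stop steps as nonsynonymous
                elif is_synonymous(cur, nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            all_paths.append((nd, sd))
        valid_paths = all_paths
    nd = sum(p[0] for p in valid_paths) / len(valid_paths)
    sd = sum(p[1] for p in valid_paths) / len(valid_paths)
    return nd, sd
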