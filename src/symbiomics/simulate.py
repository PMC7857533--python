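"""Synthetic endosymbiont dataset generator with known ground truth.

Emulates the structure of a two-clade obligate endosymbiont study: isolate
genomes from two host-associated symbiont clades plus outgroups evolve on
a known tree under per-pathway selection regimes (omega), with clade-fixed
variant sites planted as a genome-wide-association signal.  The generator
emits the same file bundle a real study would provide — genome FASTA per
isolate, per-gene codon alignments, an annotation table with pathway and
GO assignments, a phenotype table, the tree, a mini GO DAG, and a
similarity-hit table consistent with the kmer-coverage equation — plus a
truth file that downstream tests use as a recovery oracle.

The codon process is propose-filter: single-base proposals (transitions
weighted kappa), stop codons rejected, synonymous changes accepted, and
nonsynonymous changes accepted with probability min(1, omega); for
omega > 1 the proposal rate is inflated by omega so that the realized
nonsynonymous/synonymous rate ratio tracks omega in both regimes.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .codons import (
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    is_synonymous,
    is_transition,
)
from .community import HIT_COLUMNS

SPACER_LENGTH = 50  # non-coding bases between genes, shared across isolates


@dataclass
class PathwaySpec:
    """One pathway's simulation plan."""

    name: str
    category: str  # EAA | nonEAA | vitamin | background
    n_genes: int
    omega: float
    n_clade_fixed_sites: int = 0  # per gene of this pathway

    def __post_init__(self):
        if self.category not in ("EAA", "nonEAA", "vitamin", "background"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_genes < 0 or self.n_clade_fixed_sites < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic dataset.

    Defaults mirror the study layout: five newly sequenced isolates in one
    host clade, two previously sequenced isolates in the second clade, one
    outgroup genome, ~250-codon genes grouped into amino-acid and
    vitamin/cofactor biosynthesis pathways plus background, moderate
    purifying selection, and assembler-style kmer coverage (R = 150,
    K = 101).
    """

    n_isolates_clade_a: int = 5
    n_isolates_clade_b: int = 2
    n_outgroups: int = 1
    gene_length_codons: int = 250
    pathway_plan: list[PathwaySpec] = field(
        default_factory=lambda: [
            PathwaySpec("histidine", "EAA", 3, 0.15, 2),
            PathwaySpec("threonine", "EAA", 3, 0.25, 2),
            PathwaySpec("serine", "nonEAA", 3, 0.20, 0),
            PathwaySpec("thiamine", "vitamin", 3, 0.10, 2),
            PathwaySpec("riboflavin", "vitamin", 3, 0.12, 0),
            PathwaySpec("background", "background", 15, 0.20, 0),
        ]
    )
    kappa: float = 2.0
    tree_depth: float = 0.05  # expected substitutions/site, root to ingroup tip
    read_length_r: int = 150
    kmer_length_k: int = 101
    species_coverages: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("Xiphinema_americanum", "americanum_complex", 35.0),
            ("Xiphinema_rivesi", "americanum_complex", 20.0),
            ("Xiphinema_bakeri", "non_americanum", 8.0),
            ("Xiphinema_krugi", "non_americanum", 3.0),
        ]
    )
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return sum(p.n_genes for p in self.pathway_plan)

    def validate(self) -> None:
        if self.n_isolates_clade_a < 1 or self.n_isolates_clade_b < 1:
            raise ValueError("each ingroup clade needs at least one isolate")
        if self.n_genes < 1:
            raise ValueError("need at least one gene")
        if self.tree_depth <= 0:
            raise ValueError("tree depth must be positive")
        if not (1 <= self.kmer_length_k <= self.read_length_r):
            raise ValueError("need 1 <= K <= R")
        if any(c <= 0 for _, _, c in self.species_coverages):
            raise ValueError("species coverages must be positive")
        for p in self.pathway_plan:
            if p.omega < 0:
                raise ValueError("omega must be >= 0")

    def isolate_names(self) -> tuple[list[str], list[str], list[str]]:
        a = [f"A{i + 1}" for i in range(self.n_isolates_clade_a)]
        b = [f"B{i + 1}" for i in range(self.n_isolates_clade_b)]
        o = [f"O{i + 1}" for i in range(self.n_outgroups)]
        return a, b, o

    def phenotypes(self) -> dict[str, int]:
        a, b, o = self.isolate_names()
        return {**{x: 0 for x in a}, **{x: 1 for x in b}, **{x: 2 for x in o}}


@dataclass
class PlantedSite:
    gene_id: str
    codon_index: int  # 0-based codon within the gene
    clade_a_codon: str
    clade_b_codon: str


@dataclass
class SyntheticTruth:
    """The generator's planted parameters: the recovery oracle."""

    seed: int
    newick: str
    pathway_omega: dict[str, float]
    gene_pathway: dict[str, str]
    clade_fixed_sites: list[PlantedSite]
    species_coverages: dict[str, float]

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["clade_fixed_sites"] = [PlantedSite(**s) for s in d["clade_fixed_sites"]]
        return cls(**d)

    @property
    def planted_genes(self) -> set[str]:
        return {s.gene_id for s in self.clade_fixed_sites}


def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None) -> Tree:
    """Rooted tree with two monophyletic ingroup clades and outgroup tips.

    Ingroup root-to-tip depth equals ``config.tree_depth`` in expectation
    (tip branch lengths are jittered); outgroup tips attach at the root
    with longer branches.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    d = config.tree_depth
    a, b, o = config.isolate_names()

    def clade_of(tips: list[str]) -> Clade:
        anc = Clade(branch_length=d * 0.25)
        for name in tips:
            anc.clades.append(
                Clade(branch_length=d * 0.5 * rng.uniform(0.8, 1.2), name=name)
            )
        return anc

    ingroup = Clade(branch_length=d * 0.25)
    ingroup.clades.append(clade_of(a))
    ingroup.clades.append(clade_of(b))
    root = Clade()
    root.clades.append(ingroup)
    for name in o:
        root.clades.append(Clade(branch_length=2.0 * d * rng.uniform(0.9, 1.1), name=name))
    return Tree(root=root, rooted=True)


def tree_to_newick(tree: Tree) -> str:
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip()


def _propose_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    others = [b for b in NUCLEOTIDES if b != base]
    weights = np.array([kappa if is_transition(base, b) else 1.0 for b in others])
    return others[rng.choice(3, p=weights / weights.sum())]


def _evolve_branch(
    codons: list[str], t: float, omega: float, kappa: float, rng: np.random.Generator
) -> list[str]:
    """Propose-filter codon evolution along one branch of length t (subs/site)."""
    codons = list(codons)
    n_codons = len(codons)
    scale = max(1.0, omega)
    n_events = rng.poisson(3.0 * n_codons * t * scale)
    for _ in range(n_events):
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        cur = codons[ci]
        new_base = _propose_base(cur[pos], kappa, rng)
        cand = cur[:pos] + new_base + cur[pos + 1 :]
        if cand in STOP_CODONS:
            continue
        # thinning against the max rate: realized nonsyn:syn rate ratio is omega
        accept_p = (1.0 / scale) if is_synonymous(cur, cand) else (omega / scale)
        if rng.random() < accept_p:
            codons[ci] = cand
    return codons


def evolve_genes(
    tree: Tree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, dict[str, str]], SyntheticTruth]:
    """Evolve every gene along the tree and plant clade-fixed sites.

    Returns ``(alignments, truth)`` where ``alignments`` maps
    gene_id -> {tip -> in-frame sequence} (no indels, so the alignment is
    trivial) and ``truth`` records the planted parameters.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    a_tips, b_tips, o_tips = config.isolate_names()
    margin = config.gene_length_codons // 8 + 12  # keep planted bubbles inside the gene

    gene_pathway: dict[str, str] = {}
    pathway_omega: dict[str, float] = {}
    gene_specs: list[tuple[str, PathwaySpec]] = []
    gid = 0
    for spec in config.pathway_plan:
        pathway_omega[spec.name] = spec.omega
        for _ in range(spec.n_genes):
            gid += 1
            gene_id = f"g{gid:04d}"
            gene_pathway[gene_id] = spec.name
            gene_specs.append((gene_id, spec))

    alignments: dict[str, dict[str, str]] = {}
    planted: list[PlantedSite] = []
    for gene_id, spec in gene_specs:
        root_codons = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=config.gene_length_codons)]
        tip_codons: dict[str, list[str]] = {}

        def walk(clade, codons):
            for child in clade.clades:
                evolved = _evolve_branch(codons, child.branch_length, spec.omega, config.kappa, rng)
                if child.is_terminal():
                    tip_codons[child.name] = evolved
                else:
                    walk(child, evolved)

        walk(tree.root, root_codons)
        # plant clade-fixed sites: single-base codon differences, fixed
        # within each ingroup clade (outgroups carry the clade-A state)
        if spec.n_clade_fixed_sites:
            lo = min(margin, config.gene_length_codons // 3)
            hi = max(lo + spec.n_clade_fixed_sites, config.gene_length_codons - lo)
            idx = rng.choice(np.arange(lo, hi), size=spec.n_clade_fixed_sites, replace=False)
            for codon_i in sorted(int(i) for i in idx):
                while True:
                    ca = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
                    pos = int(rng.integers(3))
                    cb = ca[:pos] + _propose_base(ca[pos], config.kappa, rng) + ca[pos + 1 :]
                    if cb not in STOP_CODONS and cb != ca:
                        break
                for tip in a_tips + o_tips:
                    tip_codons[tip][codon_i] = ca
                for tip in b_tips:
                    tip_codons[tip][codon_i] = cb
                planted.append(PlantedSite(gene_id, codon_i, ca, cb))
        alignments[gene_id] = {tip: "".join(codons) for tip, codons in tip_codons.items()}

    truth = SyntheticTruth(
        seed=config.seed,
        newick=tree_to_newick(tree),
        pathway_omega=pathway_omega,
        gene_pathway=gene_pathway,
        clade_fixed_sites=planted,
        species_coverages={name: c for name, _, c in config.species_coverages},
    )
    return alignments, truth


def simulate_hits(config: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Similarity-hit table whose kmer coverages invert to the true coverages.

    For each species one passing hit carries the full coverage with
    C_K = C * (R - K + 1) / R, accompanied by decoy rows that fail the
    identity or length filters (including an identity of exactly 75, which
    the strict filter must remove).
    """
    config.validate()
    if not config.species_coverages:
        raise ValueError("species_coverages must be nonempty")
    rng = rng or np.random.default_rng(config.seed + 1)
    r, k = config.read_length_r, config.kmer_length_k
    rows = []
    qid = 0
    for species, _group, cov in config.species_coverages:
        c_k = cov * (r - k + 1) / r
        qid += 1
        rows.append(
            ("S1", f"contig{qid:03d}", species, float(rng.uniform(80, 99)), int(rng.integers(150, 800)), c_k, k, r)
        )
        qid += 1
        rows.append(("S1", f"contig{qid:03d}", species, 70.0, 400, float(rng.uniform(1, 5)), k, r))
        qid += 1
        rows.append(("S1", f"contig{qid:03d}", species, 75.0, 50, float(rng.uniform(1, 5)), k, r))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _go_dag_terms(config: SimulationConfig) -> list[dict]:
    """Three-level mini GO DAG: root, biosynthetic process, one term per pathway."""
    terms = [
        {"id": "GO:0008150", "name": "biological_process", "namespace": "biological_process", "is_a": []},
        {
            "id": "GO:0009058",
            "name": "biosynthetic process",
            "namespace": "biological_process",
            "is_a": ["GO:0008150"],
        },
        {
            "id": "GO:0090001",
            "name": "cellular housekeeping process",
            "namespace": "biological_process",
            "is_a": ["GO:0008150"],
        },
    ]
    for i, spec in enumerate(config.pathway_plan):
        if spec.category == "background":
            continue
        terms.append(
            {
                "id": f"GO:09{i + 1:05d}",
                "name": f"{spec.name} biosynthetic process",
                "namespace": "biological_process",
                "is_a": ["GO:0009058"],
            }
        )
    return terms


def pathway_go_term(config: SimulationConfig, pathway: str) -> str | None:
    for i, spec in enumerate(config.pathway_plan):
        if spec.name == pathway:
            if spec.category == "background":
                return "GO:0090001"
            return f"GO:09{i + 1:05d}"
    return None


def write_obo(terms: list[dict], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: go-mini\n")
        for t in terms:
            fh.write("\n[Term]\n")
            fh.write(f"id: {t['id']}\nname: {t['name']}\nnamespace: {t['namespace']}\n")
            for parent in t["is_a"]:
                fh.write(f"is_a: {parent}\n")


def emit_dataset(
    alignments: dict[str, dict[str, str]],
    truth: SyntheticTruth,
    config: SimulationConfig,
    out_dir: str,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Write the full file bundle; returns a map of logical name -> path.

    Genomes concatenate genes in id order, separated (and flanked) by
    fixed 50-bp non-coding spacers shared across isolates, so annotation
    coordinates slice each gene back out of the genome exactly.
    """
    if config.n_genes == 0 or not alignments:
        raise ValueError("no genes to emit")
    rng = rng or np.random.default_rng(config.seed + 2)
    os.makedirs(out_dir, exist_ok=True)
    genome_dir = os.path.join(out_dir, "genomes")
    aln_dir = os.path.join(out_dir, "alignments")
    os.makedirs(genome_dir, exist_ok=True)
    os.makedirs(aln_dir, exist_ok=True)
    a, b, o = config.isolate_names()
    isolates = a + b + o
    gene_ids = sorted(alignments)
    cat_of = {spec.name: spec.category for spec in config.pathway_plan}

    spacers = [
        "".join(NUCLEOTIDES[i] for i in rng.integers(4, size=SPACER_LENGTH))
        for _ in range(len(gene_ids) + 1)
    ]
    ann_rows = []
    paths: dict[str, str] = {}
    for iso in isolates:
        parts = [spacers[0]]
        pos = SPACER_LENGTH
        for gi, gene_id in enumerate(gene_ids):
            seq = alignments[gene_id][iso]
            start = pos + 1  # 1-based inclusive
            end = pos + len(seq)
            pw = truth.gene_pathway[gene_id]
            ann_rows.append(
                {
                    "isolate": iso,
                    "gene_id": gene_id,
                    "start": start,
                    "end": end,
                    "strand": "+",
                    "pathway": pw,
                    "category": cat_of[pw],
                    "go_terms": pathway_go_term(config, pw) or "",
                }
            )
            parts.append(seq)
            parts.append(spacers[gi + 1])
            pos = end + SPACER_LENGTH
        genome = "".join(parts)
        gpath = os.path.join(genome_dir, f"{iso}.fasta")
        with open(gpath, "w") as fh:
            fh.write(f">{iso}\n")
            for i in range(0, len(genome), 80):
                fh.write(genome[i : i + 80] + "\n")
        paths[f"genome:{iso}"] = gpath

    for gene_id in gene_ids:
        apath = os.path.join(aln_dir, f"{gene_id}.fasta")
        with open(apath, "w") as fh:
            for iso in isolates:
                fh.write(f">{iso}\n{alignments[gene_id][iso]}\n")
        paths[f"alignment:{gene_id}"] = apath

    ann = pd.DataFrame(ann_rows)
    paths["annotation"] = os.path.join(out_dir, "annotation.tsv")
    ann.to_csv(paths["annotation"], sep="\t", index=False)

    pheno = pd.DataFrame(
        [{"isolate": iso, "phenotype": code} for iso, code in config.phenotypes().items()]
    )
    paths["phenotypes"] = os.path.join(out_dir, "phenotypes.tsv")
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False)

    paths["tree"] = os.path.join(out_dir, "tree.nwk")
    with open(paths["tree"], "w") as fh:
        fh.write(truth.newick + "\n")

    paths["truth"] = os.path.join(out_dir, "truth.json")
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())

    paths["go_obo"] = os.path.join(out_dir, "go.obo")
    write_obo(_go_dag_terms(config), paths["go_obo"])

    groups = pd.DataFrame(
        [{"species": s, "group_label": g} for s, g, _ in config.species_coverages]
    )
    paths["species_groups"] = os.path.join(out_dir, "species_groups.tsv")
    groups.to_csv(paths["species_groups"], sep="\t", index=False)

    hits = simulate_hits(config, np.random.default_rng(config.seed + 1))
    paths["hits"] = os.path.join(out_dir, "hits.tsv")
    hits.to_csv(paths["hits"], sep="\t", index=False)
    return paths


def generate_dataset(config: SimulationConfig, out_dir: str) -> tuple[SyntheticTruth, dict[str, str]]:
    """Convenience wrapper: tree -> genes -> file bundle, all from one seed."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    alignments, truth = evolve_genes(tree, config, rng)
    paths = emit_dataset(alignments, truth, config, out_dir)
    return truth, paths
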