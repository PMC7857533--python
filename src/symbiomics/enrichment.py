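"""GO-term enrichment with DAG-aware (elim) correction.

Tests a study gene set against a universe per GO namespace with the
one-sided hypergeometric (Fisher) test, and applies the elim topology
correction: terms are processed leaves-first and the genes of terms that
test significant are removed from all of their strict ancestors before
those are tested, so that enrichment concentrated in a specific term does
not spuriously light up its parents.  Both raw and elim p-values are
reported; following common practice for topology-corrected GO tests, no
further multiple-testing adjustment is applied to the reported p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import stats

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


@dataclass
class GoDag:
    """GO terms (is_a DAG) plus direct gene annotations.

    ``graph`` edges point child -> parent (is_a).  ``annotations`` maps
    gene -> set of directly annotated term ids.
    """

    graph: nx.DiGraph
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO graph contains a cycle")
        for gene, terms in self.annotations.items():
            missing = terms - set(self.graph.nodes)
            if missing:
                raise ValueError(f"gene {gene} annotated to unknown terms {sorted(missing)}")

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term].get("namespace", "biological_process")

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def ancestors(self, term: str) -> set[str]:
        """Strict ancestors (all terms reachable via is_a)."""
        return nx.descendants(self.graph, term)


def read_obo(path: str) -> nx.DiGraph:
    """Read an OBO subset (id, name, namespace, is_a) into a child->parent DiGraph."""
    import obonet

    multi = obonet.read_obo(path)
    g = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        g.add_node(node, name=data.get("name", node), namespace=data.get("namespace", "biological_process"))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return g


def read_annotations(path: str) -> dict[str, set[str]]:
    """Gene-association TSV: gene_id <tab> semicolon-separated GO ids."""
    out: dict[str, set[str]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for _, row in df.iterrows():
        terms = {t for t in str(row.iloc[1]).split(";") if t}
        out.setdefault(str(row.iloc[0]), set()).update(terms)
    return out


def propagate(dag: GoDag) -> GoDag:
    """Apply the true-path rule: annotate every gene to all ancestors of its terms.

    Idempotent; raises on cyclic graphs (checked at construction).
    """
    new_annotations = {}
    cache: dict[str, set[str]] = {}
    for gene, terms in dag.annotations.items():
        full = set(terms)
        for t in terms:
            if t not in cache:
                cache[t] = dag.ancestors(t)
            full |= cache[t]
        new_annotations[gene] = full
    return GoDag(graph=dag.graph, annotations=new_annotations)


def expected_count(annotated: int, n_study: int, n_universe: int) -> float:
    """Hypergeometric mean: annotated * n_study / n_universe."""
    if n_universe <= 0:
        raise ValueError("universe must be nonempty")
    if annotated > n_universe:
        raise ValueError("annotated count exceeds universe size")
    return annotated * n_study / n_universe


def fisher_term(annotated: int, significant: int, n_study: int, n_universe: int) -> float:
    """Upper-tail hypergeometric p of >= ``significant`` study genes in the term."""
    if not (0 <= significant <= min(annotated, n_study)) or annotated > n_universe or n_study > n_universe:
        raise ValueError("inconsistent counts")
    return float(stats.hypergeom.sf(significant - 1, n_universe, annotated, n_study))


@dataclass
class EnrichmentRow:
    term: str
    name: str
    namespace: str
    annotated: int
    significant: int
    expected: float
    p_raw: float
    p_elim: float


def _term_depth(graph: nx.DiGraph, term: str) -> int:
    """Longest is_a path from the term up to a root (for leaves-first order)."""
    depth = 0
    frontier = {term}
    while frontier:
        nxt = set()
        for t in frontier:
            nxt.update(graph.successors(t))
        if not nxt:
            break
        depth += 1
        frontier = nxt
    return depth


def elim_enrichment(
    dag: GoDag,
    study: Iterable[str],
    universe: Iterable[str],
    threshold: float = 0.05,
    namespaces: Iterable[str] = NAMESPACES,
) -> pd.DataFrame:
    """Classic Fisher and elim enrichment per namespace.

    ``dag`` must already be propagated.  For each namespace, terms are
    processed by decreasing depth; when a term's elim p is <= ``threshold``
    its (propagated) study and universe genes are removed from all strict
    ancestors before those are tested.  Rows sorted by elim p within
    namespace.
    """
    study = set(study)
    universe = set(universe)
    if not study:
        raise ValueError("empty study set")
    if not study <= universe:
        raise ValueError("study set must be contained in the universe")
    genes_of: dict[str, set[str]] = {}
    for gene, terms in dag.annotations.items():
        for t in terms:
            genes_of.setdefault(t, set()).add(gene)

    rows: list[EnrichmentRow] = []
    for ns in namespaces:
        ns_terms = [t for t in dag.graph.nodes if dag.namespace(t) == ns and t in genes_of]
        if not ns_terms:
            continue
        n_universe = len(universe)
        n_study = len(study)
        removed: dict[str, set[str]] = {t: set() for t in ns_terms}
        order = sorted(ns_terms, key=lambda t: -_term_depth(dag.graph, t))
        for term in order:
            members = genes_of[term]
            annotated_all = members & universe
            significant_all = members & study
            kept_univ = annotated_all - removed[term]
            kept_study = significant_all - removed[term]
            p_raw = fisher_term(len(annotated_all), len(significant_all), n_study, n_universe)
            p_elim = fisher_term(len(kept_univ), len(kept_study), n_study, n_universe)
            if p_elim <= threshold:
                for anc in dag.ancestors(term):
                    if anc in removed:
                        removed[anc] |= annotated_all
            rows.append(
                EnrichmentRow(
                    term=term,
                    name=dag.name(term),
                    namespace=ns,
                    annotated=len(annotated_all),
                    significant=len(significant_all),
                    expected=expected_count(len(annotated_all), n_study, n_universe),
                    p_raw=p_raw,
                    p_elim=p_elim,
                )
            )
    df = pd.DataFrame([r.__dict__ for r in rows])
    if not df.empty:
        df = df.sort_values(["namespace", "p_elim", "term"]).reset_index(drop=True)
    return df
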