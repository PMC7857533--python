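#!/usr/bin/env python
"""GO enrichment of GWAS-flagged genes against the annotated universe.

Propagates annotations up the is_a DAG (true-path rule), then reports
classic Fisher and elim-corrected hypergeometric p per term, mirroring the
annotated / significant / expected table structure of topology-aware GO
tools.  Requires 04_kmer_gwas.py to have produced gwas_density.tsv.
"""

import argparse
import os

import pandas as pd

from symbiomics import enrichment, io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/synthetic")
    ap.add_argument("--out", default="results")
    ap.add_argument("--threshold", type=float, default=0.05)
    args = ap.parse_args()

    ann = io.read_annotation(os.path.join(args.data, "annotation.tsv"))
    graph = enrichment.read_obo(os.path.join(args.data, "go.obo"))
    gene_terms = {
        row.gene_id: {t for t in str(row.go_terms).split(";") if t and t != "nan"}
        for row in ann.drop_duplicates("gene_id").itertuples()
    }
    dag = enrichment.propagate(enrichment.GoDag(graph, gene_terms))

    dens = pd.read_csv(os.path.join(args.out, "gwas_density.tsv"), sep="\t")
    universe = set(gene_terms)
    study = set(dens.loc[dens["variant_count"] > 0, "gene_id"]) & universe
    table = enrichment.elim_enrichment(dag, study, universe, threshold=args.threshold)
    table.to_csv(os.path.join(args.out, "go_enrichment.tsv"), sep="\t", index=False)

    print(f"study {len(study)} genes / universe {len(universe)}")
    cols = ["term", "name", "annotated", "significant", "expected", "p_raw", "p_elim"]
    print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))


if __name__ == "__main__":
    main()
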