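"""Readers for the standard input bundle (FASTA, TSV, newick, OBO)."""

from __future__ import annotations

import glob
import os

import pandas as pd
from Bio import Phylo, SeqIO

from .coregenome import GeneAlignmentBlock


def read_genomes(genome_dir: str) -> dict[str, str]:
    """One sequence per isolate from ``<dir>/<isolate>.fasta``."""
    genomes: dict[str, str] = {}
    for path in sorted(glob.glob(os.path.join(genome_dir, "*.fasta"))):
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        name = os.path.splitext(os.path.basename(path))[0]
        genomes[name] = str(records[0].seq)
    if not genomes:
        raise FileNotFoundError(f"no genome FASTA files under {genome_dir}")
    return genomes


def read_alignment_blocks(aln_dir: str, annotation: pd.DataFrame) -> dict[str, GeneAlignmentBlock]:
    """Per-gene alignment FASTAs -> blocks, with categories from the annotation."""
    cat = (
        annotation.drop_duplicates("gene_id").set_index("gene_id")["category"].to_dict()
    )
    blocks: dict[str, GeneAlignmentBlock] = {}
    for path in sorted(glob.glob(os.path.join(aln_dir, "*.fasta"))):
        gene_id = os.path.splitext(os.path.basename(path))[0]
        records = list(SeqIO.parse(path, "fasta"))
        blocks[gene_id] = GeneAlignmentBlock(
            gene_id=gene_id,
            isolates=[r.id for r in records],
            sequences=[str(r.seq).upper() for r in records],
            category=cat.get(gene_id, "background"),
        )
    if not blocks:
        raise FileNotFoundError(f"no alignment FASTA files under {aln_dir}")
    return blocks


def read_phenotypes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["isolate"], df["phenotype"].astype(int)))


def read_annotation(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"isolate", "gene_id", "start", "end", "strand", "pathway", "category"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def read_tree(path: str):
    return Phylo.read(path, "newick")


def read_hits(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_group_lookup(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["species"], df["group_label"]))
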