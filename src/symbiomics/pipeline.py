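"""End-to-end orchestration of the analysis stages with a run manifest.

Stages (synthetic mode): dataset generation -> community profile ->
core-genome SNP densities -> kmer GWAS -> GO enrichment -> selection
(NG86 per pathway; optional site-model LRT).  Each stage writes TSV
outputs with a header line; the manifest records input hashes, row counts
and wall time per stage so that a rerun with the same config and seed is
verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__, community, coregenome, enrichment, gwas, io, selection
from .simulate import SimulationConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds and switches for one pipeline run."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    synthetic: bool = True
    simulation: SimulationConfig | None = None
    input_dir: str | None = None  # real mode: a directory shaped like the synthetic bundle
    min_identity: float = 75.0
    min_length: int = 100
    max_gap_frac: float = 0.05
    k: int = 31
    alpha: float = 0.05
    go_threshold: float = 0.05
    neb_cutoff: float = 0.95
    run_site_models: bool = False  # M7/M8 fits are the slow stage; off by default

    def resolved_simulation(self) -> SimulationConfig:
        sim = self.simulation or SimulationConfig(seed=self.seed)
        return sim


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dictionary (also written to disk)."""
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                manifest["stages"].setdefault(name, {})
                logger.info("[%s] started", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                dt = time.perf_counter() - self.t0
                if exc_type is not None:
                    logger.error("[%s] FAILED after %.1fs: %s", name, dt, exc)
                    return False
                manifest["stages"].setdefault(name, {})["seconds"] = round(dt, 3)
                logger.info("[%s] finished in %.1fs", name, dt)
                return True

        return _Timer()

    # --- inputs -----------------------------------------------------------
    if config.synthetic:
        with stage("simulate"):
            sim = config.resolved_simulation()
            data_dir = os.path.join(config.out_dir, "synthetic")
            truth, paths = generate_dataset(sim, data_dir)
            manifest["stages"]["simulate"] = {
                "n_genes": sim.n_genes,
                "n_isolates": len(sim.phenotypes()),
            }
    else:
        if not config.input_dir:
            raise FileNotFoundError("real mode requires input_dir")
        data_dir = config.input_dir
        for required in ("annotation.tsv", "phenotypes.tsv"):
            if not os.path.exists(os.path.join(data_dir, required)):
                raise FileNotFoundError(f"missing input file: {os.path.join(data_dir, required)}")
        sim = None
        truth = None

    annotation = io.read_annotation(os.path.join(data_dir, "annotation.tsv"))
    phenotypes = io.read_phenotypes(os.path.join(data_dir, "phenotypes.tsv"))
    manifest["input_hashes"] = {
        "annotation.tsv": _hash_file(os.path.join(data_dir, "annotation.tsv")),
        "phenotypes.tsv": _hash_file(os.path.join(data_dir, "phenotypes.tsv")),
    }

    # --- community profile ------------------------------------------------
    with stage("profile"):
        hits = io.read_hits(os.path.join(data_dir, "hits.tsv"))
        groups = io.read_group_lookup(os.path.join(data_dir, "species_groups.tsv"))
        kept = community.filter_hits(hits, config.min_identity, config.min_length)
        species_tab, group_tab = community.aggregate_abundance(kept, groups)
        species_tab.to_csv(os.path.join(config.out_dir, "abundance_species.tsv"), sep="\t", index=False)
        group_tab.to_csv(os.path.join(config.out_dir, "abundance_groups.tsv"), sep="\t", index=False)
        manifest["stages"]["profile"].update(
            {"hits_in": len(hits), "hits_kept": len(kept), "species_rows": len(species_tab)}
        )

    # --- core-genome SNPs ---------------------------------------------------
    with stage("snps"):
        blocks = io.read_alignment_blocks(os.path.join(data_dir, "alignments"), annotation)
        records = []
        for block in blocks.values():
            records.extend(coregenome.call_snps(block))
        isolates = next(iter(blocks.values())).isolates
        coregenome.write_vcf(records, isolates, os.path.join(config.out_dir, "snps.vcf"))
        densities = coregenome.snp_density(records, blocks)
        densities.to_csv(os.path.join(config.out_dir, "snp_density.tsv"), sep="\t", index=False)
        cats = [c for c in ("EAA", "nonEAA", "vitamin", "background") if (densities["category"] == c).any()]
        pairs = [(a, b) for i, a in enumerate(cats) for b in cats[i + 1 :]]
        comps = coregenome.compare_categories(densities, pairs)
        pd.DataFrame([dataclasses.asdict(c) for c in comps]).to_csv(
            os.path.join(config.out_dir, "snp_density_tests.tsv"), sep="\t", index=False
        )
        manifest["stages"]["snps"].update({"n_snps": len(records), "n_genes": len(blocks)})

    # --- kmer GWAS ----------------------------------------------------------
    with stage("gwas"):
        genomes = io.read_genomes(os.path.join(data_dir, "genomes"))
        graph = gwas.build_graph(genomes, k=config.k)
        unitigs = gwas.compact_unitigs(graph)
        assoc = gwas.associate(unitigs, graph.genome_names, phenotypes, alpha=config.alpha)
        sig, criterion = gwas.select_associated(assoc, alpha=config.alpha)
        ref_isolate = next(g for g in graph.genome_names if phenotypes.get(g) == 0)
        density = gwas.map_and_density(
            sig, unitigs, genomes[ref_isolate], annotation, ref_isolate, config.k
        )
        pd.DataFrame([dataclasses.asdict(a) for a in assoc]).to_csv(
            os.path.join(config.out_dir, "gwas_associations.tsv"), sep="\t", index=False
        )
        density.to_csv(os.path.join(config.out_dir, "gwas_density.tsv"), sep="\t", index=False)
        manifest["stages"]["gwas"].update(
            {
                "n_unitigs": len(unitigs),
                "n_tested": len(assoc),
                "n_significant": len(sig),
                "significance_rule": criterion,
            }
        )

    # --- GO enrichment ------------------------------------------------------
    with stage("enrich"):
        graph_go = enrichment.read_obo(os.path.join(data_dir, "go.obo"))
        ann_map = {
            row.gene_id: {t for t in str(row.go_terms).split(";") if t and t != "nan"}
            for row in annotation.drop_duplicates("gene_id").itertuples()
        }
        dag = enrichment.propagate(enrichment.GoDag(graph_go, ann_map))
        universe = set(ann_map)
        study = {g for g in (density.loc[density["variant_count"] > 0, "gene_id"]) if g in universe}
        if study:
            table = enrichment.elim_enrichment(dag, study, universe, threshold=config.go_threshold)
        else:
            logger.warning("no GWAS-flagged genes; enrichment skipped")
            table = pd.DataFrame()
        table.to_csv(os.path.join(config.out_dir, "go_enrichment.tsv"), sep="\t", index=False)
        manifest["stages"]["enrich"].update({"study_size": len(study), "terms_tested": len(table)})

    # --- selection ----------------------------------------------------------
    with stage("select"):
        a_tips = [iso for iso, code in phenotypes.items() if code == 0]
        b_tips = [iso for iso, code in phenotypes.items() if code == 1]
        clades = {"cladeA": a_tips, "cladeB": b_tips}
        pathway_of = (
            annotation.drop_duplicates("gene_id").set_index("gene_id")["pathway"].to_dict()
        )
        pathway_of = {g: p for g, p in pathway_of.items() if p != "background"}
        ingroup_blocks = []
        for block in blocks.values():
            keep_idx = [i for i, iso in enumerate(block.isolates) if iso in a_tips + b_tips]
            ingroup_blocks.append(
                coregenome.GeneAlignmentBlock(
                    block.gene_id,
                    [block.isolates[i] for i in keep_idx],
                    [block.sequences[i] for i in keep_idx],
                    block.category,
                )
            )
        between = selection.pathway_dnds(ingroup_blocks, clades, "between", pathway_of)
        within = selection.pathway_dnds(ingroup_blocks, clades, "within", pathway_of)
        dnds = pd.concat([between, within], ignore_index=True)
        dnds.to_csv(os.path.join(config.out_dir, "pathway_dnds.tsv"), sep="\t", index=False)
        manifest["stages"]["select"].update({"pathways": int(between.shape[0])})

        if config.run_site_models:
            from . import codonmodel

            tree = io.read_tree(os.path.join(data_dir, "tree.nwk"))
            ingroup_names = set(a_tips + b_tips)
            from Bio.Phylo.BaseTree import Tree as _Tree

            tree = _Tree(root=tree.common_ancestor(list(ingroup_names)), rooted=True)
            lrt_rows = []
            for pw in sorted(set(pathway_of.values())):
                seqs: dict[str, str] = {}
                for block in ingroup_blocks:
                    if pathway_of.get(block.gene_id) != pw:
                        continue
                    for iso, s in zip(block.isolates, block.sequences):
                        seqs[iso] = seqs.get(iso, "") + s
                if not seqs:
                    continue
                fit7 = codonmodel.fit_site_model(seqs, tree, "M7", n_starts=1, seed=config.seed)
                fit8 = codonmodel.fit_site_model(
                    seqs, tree, "M8", n_starts=2, seed=config.seed, init=fit7.params
                )
                res = selection.lrt(fit7, fit8, pathway=pw, neb_cutoff=config.neb_cutoff)
                lrt_rows.append(
                    {
                        "pathway": pw,
                        "lnl_m7": res.lnl_m7,
                        "lnl_m8": res.lnl_m8,
                        "statistic": res.statistic,
                        "p_value": res.p_value,
                        "positive_sites": ";".join(str(s) for s, _ in res.positive_sites),
                    }
                )
            pd.DataFrame(lrt_rows).to_csv(
                os.path.join(config.out_dir, "site_model_lrt.tsv"), sep="\t", index=False
            )
            manifest["stages"]["select"]["site_models"] = len(lrt_rows)

    manifest_path = os.path.join(config.out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
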