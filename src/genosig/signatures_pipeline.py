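"""Bray-Curtis signature clustering and end-to-end pipeline orchestration.

Signature matrices (orthologous-group counts, multiheme-cytochrome OGC
counts, IS-family counts, chemotaxis gene counts) are compared between
genomes by Bray-Curtis dissimilarity and summarised by agglomerative
clustering (UPGMA/average linkage by default). ``run_pipeline`` wires the
whole analysis together on either real annotated genomes or a simulated
dataset, writing every section as plain TSV/Newick/JSON files plus a JSON
index; expensive stages (similarity search, ANI) are cached by a content
hash of inputs and parameters so interrupted runs resume cheaply.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from . import ani as ani_mod
from . import chemotaxis_mapper as chemo
from . import cytochrome_profiler as cytpro
from . import mobilome as mob
from . import orthology as orth
from . import phylogenomics as phylo
from .genome_io import (
    GeneFeature,
    GenomeRecord,
    derive_proteome,
    genome_stats,
    read_annotated_genome,
    usable_proteins,
)
from .synthetic_data import SimulationConfig, emit_dataset, simulate_dataset

logger = logging.getLogger(__name__)


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) on nonnegative count
    vectors; 0 iff equal, 1 for disjoint supports."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors differ in length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative counts")
    denom = float((u + v).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.abs(u - v).sum() / denom)


def bray_curtis_similarity(u, v) -> float:
    return 1.0 - bray_curtis(u, v)


@dataclass
class Dendrogram:
    labels: list[str]
    linkage: np.ndarray
    leaf_order: list[str]

    def newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            bl = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{bl:.6f}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{bl:.6f}"

        return walk(tree, tree.dist) + ";"


def hierarchical_cluster(
    matrix: pd.DataFrame, axis: str = "columns", linkage: str = "average"
) -> Dendrogram:
    """Agglomerative clustering on pairwise Bray-Curtis dissimilarities.

    ``axis="columns"`` clusters genomes, ``axis="rows"`` clusters features.
    Labels are pre-sorted so scipy's index-order tie-breaking is a
    deterministic label-order tie-break.
    """
    if linkage not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    data = matrix.T if axis == "columns" else matrix
    labels = sorted(str(x) for x in data.index)
    data = data.loc[labels]
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    vectors = data.to_numpy(dtype=float)
    condensed = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        try:
            condensed.append(bray_curtis(vectors[i], vectors[j]))
        except ValueError as exc:
            raise ValueError(
                f"undefined distance between {labels[i]} and {labels[j]}: {exc}"
            ) from exc
    Z = hierarchy.linkage(np.array(condensed), method=linkage)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return Dendrogram(labels, Z, order)


# ----------------------------------------------------------------- pipeline

@dataclass
class PipelineConfig:
    out_dir: str
    genome_inputs: list[dict] | None = None  # fasta, annotation, genome_id, assembly_level
    simulation: SimulationConfig | None = None
    seed: int = 0
    run_phylogenomics: bool = True
    run_ani: bool = True
    run_aai: bool = True
    run_cytochromes: bool = True
    run_chemotaxis: bool = True
    run_mobilome: bool = True
    bootstrap_reps: int = 100
    heme_mode: str = "canonical"
    heme_threshold: int = 4
    linkage: str = "average"
    ani_fragment_len: int = 1020
    is_library_path: str | None = None

    def content_hash(self) -> str:
        payload = {
            k: (asdict(v) if isinstance(v, SimulationConfig) else v)
            for k, v in asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    out_dir: Path
    sections: dict[str, dict] = field(default_factory=dict)

    def mark(self, name: str, status: str, **info):
        self.sections[name] = {"status": status, **info}

    def write_index(self):
        (self.out_dir / "index.json").write_text(
            json.dumps(self.sections, indent=1, sort_keys=True, default=str)
        )


def _write_tsv(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t")


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute genome I/O -> orthology -> ANI/AAI -> phylogenomics ->
    cytochrome/chemotaxis/mobilome censuses -> Bray-Curtis clustering.

    Every section lands as files under ``out_dir`` and is recorded in
    ``index.json``; a failed optional stage is marked skipped with the
    error. Outputs are a pure function of (inputs, config, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out)
    cache_tag = config.content_hash()
    bundle.mark("config", "ok", hash=cache_tag)

    # ---- inputs
    truth = None
    genomes: dict[str, GenomeRecord] = {}
    features: dict[str, list[GeneFeature]] = {}
    if config.simulation is not None:
        data_dir = out / "data"
        sim_genomes, truth = simulate_dataset(config.simulation)
        emit_dataset(sim_genomes, truth, data_dir)
        for gid, (g, f) in sim_genomes.items():
            genomes[gid], features[gid] = g, f
    elif config.genome_inputs:
        for item in config.genome_inputs:
            g, f = read_annotated_genome(
                item["fasta"], item["annotation"],
                genome_id=item.get("genome_id"),
                strain_name=item.get("strain_name", ""),
                assembly_level=item.get("assembly_level", "complete"),
            )
            genomes[g.genome_id], features[g.genome_id] = g, f
    else:
        raise ValueError("config must provide genome_inputs or simulation")
    gids = sorted(genomes)

    proteomes = {
        gid: usable_proteins(derive_proteome(genomes[gid], features[gid]))
        for gid in gids
    }
    stats = pd.DataFrame(
        {gid: genome_stats(genomes[gid], features[gid]) for gid in gids}
    ).T
    _write_tsv(stats, out / "genome_stats.tsv")
    bundle.mark("genome_stats", "ok", files=["genome_stats.tsv"])

    # ---- orthology (hits cached by content hash)
    hits_path = out / "hits.tsv"
    hits = None
    if hits_path.exists():
        try:
            cached = pd.read_csv(hits_path, sep="\t")
            if cached.attrs is not None and (out / "hits.hash").exists():
                if (out / "hits.hash").read_text() == cache_tag:
                    hits = [
                        orth.SimilarityHit(
                            r.query_id, r.subject_id, r.query_genome,
                            r.subject_genome, r.percent_identity,
                            r.query_coverage, r.score,
                        )
                        for r in cached.itertuples()
                    ]
                    logger.info("reusing cached similarity hits")
        except Exception:
            hits = None
    if hits is None:
        hits = orth.all_vs_all(proteomes)
        pd.DataFrame([asdict(h) for h in hits]).to_csv(hits_path, sep="\t", index=False)
        (out / "hits.hash").write_text(cache_tag)
    rbh_all = {}
    for a, b in itertools.combinations(gids, 2):
        rbh_all[(a, b)] = orth.build_rbh(hits, a, b)
    ogset = orth.cluster_ogs(
        [p for pairs in rbh_all.values() for p in pairs], hits, proteomes
    )
    counts, sharing = orth.og_matrices(ogset)
    _write_tsv(counts, out / "og_counts.tsv")
    sharing.to_csv(out / "og_sharing.tsv", sep="\t", index=False)
    with open(out / "og_membership.tsv", "w") as fh:
        fh.write("og_id\tgenome_id\tgene_id\n")
        for og_id in sorted(ogset.groups):
            for gid in sorted(ogset.groups[og_id]):
                for gene in ogset.groups[og_id][gid]:
                    fh.write(f"{og_id}\t{gid}\t{gene}\n")
    bundle.mark(
        "orthology", "ok",
        files=["hits.tsv", "og_counts.tsv", "og_sharing.tsv", "og_membership.tsv"],
        n_ogs=len(ogset.groups), n_core=len(ogset.core_ogs()),
        fraction_assigned=ogset.fraction_assigned,
    )
    og_dendro = hierarchical_cluster(counts, axis="columns", linkage=config.linkage)
    (out / "og_dendrogram.nwk").write_text(og_dendro.newick() + "\n")

    # ---- ANI / AAI
    if config.run_ani:
        ani_path = out / "ani_matrix.tsv"
        if ani_path.exists() and (out / "ani.hash").exists() and (
            out / "ani.hash"
        ).read_text() == cache_tag:
            logger.info("reusing cached ANI matrix")
        else:
            ani_df = ani_mod.ani_matrix(genomes, fragment_len=config.ani_fragment_len)
            _write_tsv(ani_df, ani_path)
            (out / "ani.hash").write_text(cache_tag)
        bundle.mark("ani", "ok", files=["ani_matrix.tsv"])
    else:
        bundle.mark("ani", "skipped")
    if config.run_aai:
        aai_df = orth.aai_matrix(proteomes, hits)
        _write_tsv(aai_df, out / "aai_matrix.tsv")
        bundle.mark("aai", "ok", files=["aai_matrix.tsv"])
    else:
        bundle.mark("aai", "skipped")

    # ---- phylogenomics
    if config.run_phylogenomics:
        try:
            markers = phylo.select_single_copy(ogset)
            sm = phylo.build_supermatrix(ogset, markers, proteomes)
            tree = phylo.bootstrap_support(
                sm, n_reps=config.bootstrap_reps, seed=config.seed
            )
            (out / "tree.nwk").write_text(tree.newick() + "\n")
            sm.to_fasta(out / "supermatrix.faa")
            sm.to_phylip(out / "supermatrix.phy")
            with open(out / "partitions.tsv", "w") as fh:
                fh.write("og_id\tstart\tend\n")
                for og, (s, e) in sorted(sm.partitions.items()):
                    fh.write(f"{og}\t{s}\t{e}\n")
            bundle.mark(
                "phylogenomics", "ok",
                files=["tree.nwk", "supermatrix.faa", "supermatrix.phy", "partitions.tsv"],
                n_markers=len(markers), n_columns=sm.n_columns,
            )
        except ValueError as exc:
            bundle.mark("phylogenomics", "skipped", error=str(exc))
    else:
        bundle.mark("phylogenomics", "skipped")

    # ---- cytochromes
    if config.run_cytochromes:
        scans = {
            p.protein_id: cytpro.scan_heme_motifs(p, config.heme_mode)
            for prots in proteomes.values()
            for p in prots
        }
        multiheme = {
            pid for pid, s in scans.items()
            if cytpro.classify_multiheme(s, config.heme_threshold)
        }
        with open(out / "heme_scans.tsv", "w") as fh:
            fh.write("protein_id\tmotif_count\tis_multiheme\tpositions\n")
            for pid in sorted(scans):
                s = scans[pid]
                fh.write(
                    f"{pid}\t{s.motif_count}\t{int(pid in multiheme)}\t"
                    + ",".join(map(str, s.motif_positions)) + "\n"
                )
        ogc = cytpro.ogc_profile(multiheme, ogset, gids)
        _write_tsv(ogc, out / "ogc_matrix.tsv")
        section = {"files": ["heme_scans.tsv", "ogc_matrix.tsv"],
                   "ogc_per_genome": {g: int((ogc[g] > 0).sum()) for g in gids}}
        if len(ogc) >= 2 and ogc.to_numpy().sum() > 0:
            ogc_dendro = hierarchical_cluster(ogc, axis="columns", linkage=config.linkage)
            (out / "ogc_dendrogram.nwk").write_text(ogc_dendro.newick() + "\n")
            section["files"].append("ogc_dendrogram.nwk")
        bundle.mark("cytochromes", "ok", **section)
    else:
        bundle.mark("cytochromes", "skipped")

    # ---- chemotaxis
    if config.run_chemotaxis:
        rows = []
        cluster_rows = []
        mcp_rows = []
        flag = {}
        che_counts = {}
        for gid in gids:
            catalog = chemo.catalog_che_genes(features[gid])
            prot_by_tag = {p.locus_tag: p for p in proteomes[gid]}
            mcp_classes = {
                g.locus_tag: chemo.classify_mcp(prot_by_tag[g.locus_tag])
                for g in catalog
                if g.kind == "mcp" and g.locus_tag in prot_by_tag
            }
            clusters, dispersed = chemo.detect_che_clusters(catalog, features[gid])
            for c in clusters:
                label = chemo.type_cluster(c, mcp_classes)
                cluster_rows.append({
                    "genome_id": gid, "replicon": c.replicon_id,
                    "start": c.start, "end": c.end, "type": label,
                    "n_che": len(c.che_genes),
                    "kinds": ",".join(sorted(c.kinds)),
                    "locus_tags": ",".join(g.locus_tag for g in c.che_genes),
                })
            for g in catalog:
                rows.append({"genome_id": gid, "locus_tag": g.locus_tag,
                             "kind": g.kind, "evidence": g.evidence})
            for tag, m in sorted(mcp_classes.items()):
                mcp_rows.append({
                    "genome_id": gid, "locus_tag": tag,
                    "heptad_count": m.heptad_count,
                    "class": f"{m.mcp_class}H" if m.mcp_class else "unclassified",
                    "dispersed": tag in {d.locus_tag for d in dispersed},
                })
            flag[gid] = chemo.flagellar_census(features[gid])
            che_counts[gid] = chemo.che_summary(catalog, mcp_classes)
        pd.DataFrame(rows).to_csv(out / "che_catalog.tsv", sep="\t", index=False)
        pd.DataFrame(cluster_rows).to_csv(out / "che_clusters.tsv", sep="\t", index=False)
        pd.DataFrame(mcp_rows).to_csv(out / "mcp_classes.tsv", sep="\t", index=False)
        (out / "flagellar_census.json").write_text(
            json.dumps(flag, indent=1, sort_keys=True)
        )
        bundle.mark(
            "chemotaxis", "ok",
            files=["che_catalog.tsv", "che_clusters.tsv", "mcp_classes.tsv",
                   "flagellar_census.json"],
            clusters_per_genome={
                g: sum(1 for r in cluster_rows if r["genome_id"] == g) for g in gids
            },
            che_counts=che_counts,
        )
    else:
        bundle.mark("chemotaxis", "skipped")

    # ---- mobilome
    if config.run_mobilome:
        census = {
            gid: mob.transposase_census(features[gid], genomes[gid].assembly_level)
            for gid in gids
        }
        with open(out / "transposase_census.tsv", "w") as fh:
            fh.write("genome_id\tcount\tcds_count\tfraction_of_cds\n")
            for gid in gids:
                c = census[gid]
                fh.write(f"{gid}\t{c['count']}\t{c['cds_count']}\t{c['fraction_of_cds']}\n")
        section = {"files": ["transposase_census.tsv"],
                   "fractions": {g: census[g]["fraction_of_cds"] for g in gids}}
        library = None
        if config.is_library_path:
            library = mob.read_family_library(config.is_library_path)
        elif truth is not None and truth.library:
            library = truth.library
        if library:
            assignments = {}
            for gid in gids:
                prot_by_tag = {p.locus_tag: p for p in proteomes[gid]}
                assignments[gid] = [
                    mob.assign_is_family(prot_by_tag[tag], library)
                    for tag in census[gid]["locus_tags"]
                    if tag in prot_by_tag
                ]
            fam = mob.is_family_matrix(assignments)
            _write_tsv(fam, out / "is_family_matrix.tsv")
            section["files"].append("is_family_matrix.tsv")
            if len(fam) >= 2 and fam.to_numpy().sum() > 0:
                # cluster genomes only when every genome carries a transposase
                if (fam.sum(axis=0) > 0).all():
                    dendro = hierarchical_cluster(fam, axis="columns",
                                                  linkage=config.linkage)
                    (out / "is_dendrogram.nwk").write_text(dendro.newick() + "\n")
                    section["files"].append("is_dendrogram.nwk")
        bundle.mark("mobilome", "ok", **section)
    else:
        bundle.mark("mobilome", "skipped")

    bundle.write_index()
    return bundle
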