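"""All-vs-all protein comparison, reciprocal best hits, orthologous groups,
core-genome accounting and average amino-acid identity (AAI).

The similarity search pairs a shared-k-mer prefilter with gapped local
alignment (BLOSUM62, affine gaps open 11 / extend 1). Orthologous groups are
the connected components of the graph whose edges are reciprocal best hits
between genomes plus within-genome in-paralog edges (a within-genome hit at
least as strong as the gene's best inter-genome hit); this deterministic
construction stands in for normalized-score + MCL machinery, so absolute OG
counts on real genome sets are approximate while presence/absence and
count-matrix structure are stable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    query_genome: str
    subject_genome: str
    percent_identity: float
    query_coverage: float
    score: float


@dataclass(frozen=True)
class RbhPair:
    gene_a: str
    gene_b: str
    genome_a: str
    genome_b: str
    percent_identity: float
    coverage_a: float
    coverage_b: float
    score: float

    @property
    def min_coverage(self) -> float:
        return min(self.coverage_a, self.coverage_b)


@dataclass
class OrthologousGroupSet:
    """OG id -> members grouped by genome, plus the unassigned singletons."""

    groups: dict[str, dict[str, list[str]]]
    singletons: list[str]
    genome_ids: list[str]
    total_genes: int

    @property
    def n_assigned(self) -> int:
        return sum(
            len(m) for members in self.groups.values() for m in members.values()
        )

    @property
    def fraction_assigned(self) -> float:
        return fraction_assigned(self.n_assigned, self.total_genes)

    def core_ogs(self) -> list[str]:
        return [
            og for og, members in self.groups.items()
            if all(len(members.get(g, [])) >= 1 for g in self.genome_ids)
        ]

    def single_copy_ogs(self) -> list[str]:
        return [
            og for og, members in self.groups.items()
            if all(len(members.get(g, [])) == 1 for g in self.genome_ids)
        ]

    def count_matrix(self) -> pd.DataFrame:
        data = {
            og: {g: len(members.get(g, [])) for g in self.genome_ids}
            for og, members in self.groups.items()
        }
        mat = pd.DataFrame.from_dict(data, orient="index").reindex(
            columns=self.genome_ids
        ).fillna(0).astype(int)
        mat.index.name = "og_id"
        return mat.sort_index()

    def presence_matrix(self) -> pd.DataFrame:
        return (self.count_matrix() > 0).astype(int)


def fraction_assigned(n_assigned: int, n_total: int) -> float:
    """Percent of genes assigned to OGs, one decimal (e.g. 14437 of 17479
    genes -> 82.6)."""
    if n_total <= 0:
        raise ValueError("total gene count must be positive")
    return round(100.0 * n_assigned / n_total, 1)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_pair(aligner, rec_a: ProteinRecord, rec_b: ProteinRecord):
    """Best local alignment of two proteins; returns (identity%, coverage of
    a, coverage of b, score) or None when no positive-scoring alignment."""
    try:
        alns = aligner.align(rec_a.sequence, rec_b.sequence)
    except Exception:  # e.g. unrepresentable characters
        return None
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    c = aln.counts()
    cols = c.identities + c.mismatches + c.gaps
    if cols == 0:
        return None
    identity = 100.0 * c.identities / cols
    blocks_a, blocks_b = aln.aligned
    len_a = sum(int(e - s) for s, e in blocks_a)
    len_b = sum(int(e - s) for s, e in blocks_b)
    return identity, len_a / len(rec_a.sequence), len_b / len(rec_b.sequence), float(aln.score)


def all_vs_all(
    proteomes: dict[str, list[ProteinRecord]],
    min_identity: float = 30.0,
    min_coverage: float = 0.5,
    kmer_prefilter_k: int = 5,
) -> list[SimilarityHit]:
    """Similarity hits between every pair of proteins sharing a k-mer seed.

    Both within- and between-genome pairs are aligned (within-genome hits
    feed the in-paralog rule). A pair is kept only when identity and
    coverage pass in both directions, so hit content is symmetric.
    """
    for gid, prots in proteomes.items():
        if not prots:
            raise ValueError(f"empty proteome for genome {gid}")
    records: list[ProteinRecord] = [p for prots in proteomes.values() for p in prots]
    index: dict[str, set[int]] = {}
    for i, rec in enumerate(records):
        seq = rec.sequence
        for j in range(0, len(seq) - kmer_prefilter_k + 1):
            index.setdefault(seq[j : j + kmer_prefilter_k], set()).add(i)
    candidates: set[tuple[int, int]] = set()
    for bucket in index.values():
        if len(bucket) > 1:
            candidates.update(itertools.combinations(sorted(bucket), 2))
    aligner = _make_aligner()
    hits: list[SimilarityHit] = []
    for i, j in sorted(candidates):
        a, b = records[i], records[j]
        res = align_pair(aligner, a, b)
        if res is None:
            continue
        identity, cov_a, cov_b, score = res
        if identity < min_identity or cov_a < min_coverage or cov_b < min_coverage:
            continue
        hits.append(SimilarityHit(a.protein_id, b.protein_id, a.genome_id,
                                  b.genome_id, identity, cov_a, score))
        hits.append(SimilarityHit(b.protein_id, a.protein_id, b.genome_id,
                                  a.genome_id, identity, cov_b, score))
    return hits


def _best_hits(hits: list[SimilarityHit], genome_from: str, genome_to: str) -> dict[str, SimilarityHit]:
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        if h.query_genome != genome_from or h.subject_genome != genome_to:
            continue
        if h.query_id == h.subject_id:
            continue
        cur = best.get(h.query_id)
        # max score; ties by higher identity, then lexicographic subject id
        if cur is None or (
            (h.score, h.percent_identity, cur.subject_id)
            > (cur.score, cur.percent_identity, h.subject_id)
        ):
            best[h.query_id] = h
    return best


def build_rbh(hits: list[SimilarityHit], genome_a: str, genome_b: str) -> list[RbhPair]:
    """Reciprocal best-hit pairs between two genomes (deterministic under
    input permutation: score ties break by identity, then subject id)."""
    if genome_a == genome_b:
        raise ValueError("RBH requires two distinct genomes")
    ab = _best_hits(hits, genome_a, genome_b)
    ba = _best_hits(hits, genome_b, genome_a)
    pairs = []
    for qa, h in sorted(ab.items()):
        back = ba.get(h.subject_id)
        if back is not None and back.subject_id == qa:
            cov_b = back.query_coverage
            pairs.append(RbhPair(qa, h.subject_id, genome_a, genome_b,
                                 round(h.percent_identity, 3), h.query_coverage,
                                 cov_b, h.score))
    return pairs


def cluster_ogs(
    rbh_pairs: list[RbhPair],
    hits: list[SimilarityHit],
    proteomes: dict[str, list[ProteinRecord]] | None = None,
) -> OrthologousGroupSet:
    """Orthologous groups as connected components of the RBH + in-paralog
    graph; components of size 1 are singletons.

    ``proteomes`` supplies the full gene universe (genes without any hit are
    singletons); without it the universe is the genes seen in hits.
    """
    graph = nx.Graph()
    all_genes: dict[str, str] = {}
    if proteomes:
        for gid, prots in proteomes.items():
            for p in prots:
                all_genes[p.protein_id] = gid
    for h in hits:
        all_genes.setdefault(h.query_id, h.query_genome)
        all_genes.setdefault(h.subject_id, h.subject_genome)
    graph.add_nodes_from(all_genes)
    for pair in rbh_pairs:
        graph.add_edge(pair.gene_a, pair.gene_b)
    # in-paralog rule: within-genome edge at least as strong as either
    # endpoint's best inter-genome score
    best_inter: dict[str, float] = {}
    for h in hits:
        if h.query_genome != h.subject_genome:
            best_inter[h.query_id] = max(best_inter.get(h.query_id, 0.0), h.score)
    for h in hits:
        if h.query_genome == h.subject_genome and h.query_id != h.subject_id:
            if h.score >= best_inter.get(h.query_id, 0.0) or h.score >= best_inter.get(
                h.subject_id, 0.0
            ):
                graph.add_edge(h.query_id, h.subject_id)
    genome_ids = sorted(set(all_genes.values()))
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: c[0])
    groups: dict[str, dict[str, list[str]]] = {}
    singletons: list[str] = []
    n = 0
    for comp in components:
        if len(comp) == 1:
            singletons.append(comp[0])
            continue
        n += 1
        og_id = f"OG{n:05d}"
        members: dict[str, list[str]] = {}
        for gene in comp:
            members.setdefault(all_genes[gene], []).append(gene)
        groups[og_id] = members
    return OrthologousGroupSet(groups, sorted(singletons), genome_ids, len(all_genes))


def og_matrices(ogset: OrthologousGroupSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count matrix plus the sharing table: for every nonempty genome subset,
    the number of OGs present in exactly that subset. The full-set row is the
    core-OG count; the subset counts partition the OG total."""
    counts = ogset.count_matrix()
    rows = {}
    for og, members in ogset.groups.items():
        subset = tuple(sorted(g for g in ogset.genome_ids if members.get(g)))
        rows[subset] = rows.get(subset, 0) + 1
    sharing = pd.DataFrame(
        [
            {"genomes": ",".join(subset), "n_genomes": len(subset), "n_ogs": n}
            for subset, n in sorted(rows.items(), key=lambda kv: (-len(kv[0]), kv[0]))
        ]
    )
    return counts, sharing


def compute_aai(
    rbh_pairs: list[RbhPair],
    min_identity: float = 30.0,
    min_coverage: float = 0.7,
) -> tuple[float | None, int]:
    """AAI: unweighted mean identity over RBH pairs passing the two-way
    filters (default 30% identity, 70% coverage both directions), one
    decimal; returns (aai, n pairs used), aai None when no pair qualifies."""
    used = [
        p.percent_identity
        for p in rbh_pairs
        if p.percent_identity >= min_identity and p.min_coverage >= min_coverage
    ]
    if not used:
        logger.warning("AAI undefined: no RBH pair passes the filters")
        return None, 0
    return round(sum(used) / len(used), 1), len(used)


def aai_matrix(
    proteomes: dict[str, list[ProteinRecord]],
    hits: list[SimilarityHit] | None = None,
    **aai_kwargs,
) -> pd.DataFrame:
    """Symmetric AAI matrix over all genome pairs."""
    if hits is None:
        hits = all_vs_all(proteomes)
    gids = sorted(proteomes)
    mat = pd.DataFrame(100.0, index=gids, columns=gids)
    for a, b in itertools.combinations(gids, 2):
        aai, _ = compute_aai(build_rbh(hits, a, b), **aai_kwargs)
        mat.loc[a, b] = mat.loc[b, a] = float("nan") if aai is None else aai
    return mat
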