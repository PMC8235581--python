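"""Concatenated single-copy-gene supermatrix and bootstrap-supported
distance phylogeny.

Single-copy orthologous groups are aligned per gene by progressive alignment
(guide order from k-mer distances, pairwise/profile merges scored by mean
BLOSUM62 column score), concatenated into a supermatrix, converted to
Poisson-corrected distances under pairwise gap deletion, and summarised as a
Saitou-Nei neighbor-joining tree with column-bootstrap support values. This
distance pipeline is a self-contained, deterministic stand-in for
maximum-likelihood inference; at the clade level the topology is robust for
moderately diverged genomes, and a hook accepts externally computed per-gene
alignments instead of the built-in aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")
_GAP_RES = -4.0  # residue-vs-gap column score
_GAP_OPEN = -6.0  # new gap column in profile merge


def _score(a: str, b: str) -> float:
    if a == "-" and b == "-":
        return 0.0
    if a == "-" or b == "-":
        return _GAP_RES
    try:
        return float(_BLOSUM[a, b])
    except (KeyError, IndexError):
        return 0.0


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]

    def __post_init__(self):
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("supermatrix rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def resample_columns(self, rng) -> "Supermatrix":
        n = self.n_columns
        cols = rng.integers(0, n, size=n)
        rows = {t: "".join(self.rows[t][c] for c in cols) for t in self.taxa}
        return Supermatrix(list(self.taxa), rows, {"resampled": (0, n)})

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.taxa:
                fh.write(f">{t}\n{self.rows[t]}\n")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.taxa)} {self.n_columns}\n")
            for t in self.taxa:
                fh.write(f"{t}  {self.rows[t]}\n")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray
    model: str = "poisson"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class TreeNode:
    name: str = ""
    branch_length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._newick_node() + ";"

    def _newick_node(self) -> str:
        bl = self.branch_length if self.branch_length > 0 else 0.0
        if self.is_leaf:
            return f"{self.name}:{bl:.6f}"
        inner = ",".join(c._newick_node() for c in self.children)
        label = "" if self.support is None else f"{self.support:.2f}"
        return f"({inner}){label}:{bl:.6f}"


@dataclass
class PhyloTree:
    """Unrooted tree kept as a trifurcating (or star) root node."""

    root: TreeNode

    @property
    def taxa(self) -> list[str]:
        return sorted(self.root.leaves())

    def newick(self) -> str:
        return self.root.newick()

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal bipartitions: the side not containing the
        lexicographically first taxon, for splits with both sides >= 2."""
        all_taxa = set(self.root.leaves())
        anchor = min(all_taxa)
        out = set()

        def visit(node):
            for child in node.children:
                side = frozenset(child.leaves())
                if 2 <= len(side) <= len(all_taxa) - 2:
                    canon = side if anchor not in side else frozenset(all_taxa - side)
                    out.add(canon)
                visit(child)

        visit(self.root)
        return out

    def _internal_nodes(self):
        def visit(node):
            for child in node.children:
                if not child.is_leaf:
                    yield child
                    yield from visit(child)

        yield from visit(self.root)


# ------------------------------------------------------------ single copy

def select_single_copy(ogset, required_fraction: float = 1.0) -> list[str]:
    """OGs with exactly one member in at least ``required_fraction`` of
    genomes and no genome carrying more than one member."""
    if len(ogset.genome_ids) < 3:
        raise ValueError("single-copy selection needs at least 3 genomes")
    need = math.ceil(required_fraction * len(ogset.genome_ids))
    chosen = []
    for og_id in sorted(ogset.groups):
        members = ogset.groups[og_id]
        counts = [len(members.get(g, [])) for g in ogset.genome_ids]
        if any(c > 1 for c in counts):
            continue
        if sum(1 for c in counts if c == 1) >= need:
            chosen.append(og_id)
    if not chosen:
        raise ValueError(
            "no single-copy OGs qualify; lower required_fraction to admit "
            "markers missing from some genomes"
        )
    return chosen


# ------------------------------------------------------- progressive MSA

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _merge_profiles(pa: list[str], pb: list[str]) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment with mean-BLOSUM column scores and a
    linear gap-column penalty; deterministic (diagonal > up > left on ties).

    Returns the two input profiles expanded with gap columns to a common
    length; each profile is a list of equal-length aligned rows.
    """
    ca = list(zip(*pa)) if pa[0] else []
    cb = list(zip(*pb)) if pb[0] else []
    la, lb = len(ca), len(cb)

    def colscore(i, j):
        return sum(_score(x, y) for x in ca[i] for y in cb[j]) / (len(ca[i]) * len(cb[j]))

    score = np.zeros((la + 1, lb + 1))
    move = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, la + 1):
        score[i, 0] = score[i - 1, 0] + _GAP_OPEN
        move[i, 0] = 1
    for j in range(1, lb + 1):
        score[0, j] = score[0, j - 1] + _GAP_OPEN
        move[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            d = score[i - 1, j - 1] + colscore(i - 1, j - 1)
            u = score[i - 1, j] + _GAP_OPEN
            l = score[i, j - 1] + _GAP_OPEN
            best = max(d, u, l)
            score[i, j] = best
            move[i, j] = 0 if best == d else (1 if best == u else 2)
    out_a: list[list[str]] = [[] for _ in pa]
    out_b: list[list[str]] = [[] for _ in pb]
    i, j = la, lb
    steps = []
    while i > 0 or j > 0:
        m = move[i, j]
        steps.append(m)
        if m == 0:
            i, j = i - 1, j - 1
        elif m == 1:
            i -= 1
        else:
            j -= 1
    i = j = 0
    for m in reversed(steps):
        if m in (0, 1):
            for r, row in enumerate(pa):
                out_a[r].append(row[i])
            i += 1
        else:
            for r in out_a:
                r.append("-")
        if m in (0, 2):
            for r, row in enumerate(pb):
                out_b[r].append(row[j])
            j += 1
        else:
            for r in out_b:
                r.append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def align_gene(seqs: dict[str, str]) -> dict[str, str]:
    """Progressive multiple alignment of one gene family.

    Guide order: repeatedly merge the two clusters with the smallest mean
    k-mer distance (ties by label), merging alignments profile-to-profile.
    """
    names = sorted(seqs)
    if len(names) == 1:
        return {names[0]: seqs[names[0]]}
    dist = {
        (a, b): _kmer_distance(seqs[a], seqs[b]) for a, b in combinations(names, 2)
    }
    clusters: dict[tuple[str, ...], list[str]] = {(n,): [seqs[n]] for n in names}
    members: dict[tuple[str, ...], list[str]] = {(n,): [n] for n in names}

    def cdist(ka, kb):
        pairs = [(a, b) for a in members[ka] for b in members[kb]]
        return sum(dist[tuple(sorted(p))] for p in pairs) / len(pairs)

    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for ka, kb in combinations(keys, 2):
            d = cdist(ka, kb)
            if best is None or d < best[0]:
                best = (d, ka, kb)
        _, ka, kb = best
        merged_a, merged_b = _merge_profiles(clusters[ka], clusters[kb])
        knew = tuple(sorted(ka + kb))
        clusters[knew] = merged_a + merged_b
        members[knew] = members[ka] + members[kb]
        del clusters[ka], members[ka]
        del clusters[kb], members[kb]
    (key,) = clusters
    return dict(zip(members[key], clusters[key]))


def build_supermatrix(
    ogset,
    single_copy_ogs: list[str],
    proteomes: dict[str, list],
    aligned_files: dict[str, str] | None = None,
) -> Supermatrix:
    """Concatenate per-gene alignments of the selected single-copy OGs.

    ``aligned_files`` optionally maps an OG id to a FASTA file of an
    externally computed alignment (taxon names as headers), bypassing the
    built-in aligner for that gene.
    """
    seq_by_id = {
        p.protein_id: p.sequence for prots in proteomes.values() for p in prots
    }
    taxa = list(ogset.genome_ids)
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    partitions = {}
    offset = 0
    for og_id in sorted(single_copy_ogs):
        members = ogset.groups[og_id]
        gene_seqs = {}
        for t in taxa:
            m = members.get(t, [])
            if len(m) != 1:
                raise ValueError(f"OG {og_id} lacks a single member in genome {t}")
            gene_seqs[t] = seq_by_id[m[0]]
        if aligned_files and og_id in aligned_files:
            from Bio import SeqIO

            aligned = {
                rec.id: str(rec.seq) for rec in SeqIO.parse(str(aligned_files[og_id]), "fasta")
            }
        else:
            aligned = align_gene(gene_seqs)
        width = len(next(iter(aligned.values())))
        for t in taxa:
            pieces[t].append(aligned[t])
        partitions[og_id] = (offset, offset + width)
        offset += width
    rows = {t: "".join(pieces[t]) for t in taxa}
    return Supermatrix(taxa, rows, partitions)


# ----------------------------------------------------------- distances, NJ

def distance_matrix(sm: Supermatrix, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances under pairwise deletion of gap-containing columns.

    p-distance = mismatches / compared columns; the Poisson correction is
    -ln(1 - p). A pair with no comparable columns, or p >= 1, is an error.
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    taxa = sm.taxa
    n = len(taxa)
    vals = np.zeros((n, n))
    arrs = {t: np.frombuffer(sm.rows[t].encode(), dtype=np.uint8) for t in taxa}
    gap = ord("-")
    for i, j in combinations(range(n), 2):
        a, b = arrs[taxa[i]], arrs[taxa[j]]
        ok = (a != gap) & (b != gap)
        compared = int(ok.sum())
        if compared == 0:
            raise ValueError(f"no comparable columns for pair {taxa[i]}, {taxa[j]}")
        p = float((a[ok] != b[ok]).mean())
        if model == "poisson":
            if p >= 1.0:
                raise ValueError(f"saturated pair {taxa[i]}, {taxa[j]} (p = {p})")
            d = -math.log(1.0 - p)
        else:
            d = p
        vals[i, j] = vals[j, i] = d
    return DistanceMatrix(list(taxa), vals, model)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking by taxon
    label; negative branch-length estimates are clamped to zero with the
    deficit moved to the sibling branch."""
    if len(dm.taxa) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[str, TreeNode] = {t: TreeNode(name=t) for t in dm.taxa}
    # label of a cluster = lexicographically first leaf inside it
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(dm.taxa):
        for b in dm.taxa[i + 1:]:
            dist[(a, b)] = dm.get(a, b)

    def d(a, b):
        return dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    active = sorted(nodes)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in combinations(active, 2):  # sorted order -> deterministic ties
            q = (n - 2) * d(a, b) - r[a] - r[b]
            if best is None or q < best[0]:
                best = (q, a, b)
        _, a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (n - 2))
        lb = d(a, b) - la
        if la < 0:
            lb += -la
            la = 0.0
        if lb < 0:
            la += -lb
            lb = 0.0
        na, nb = nodes[a], nodes[b]
        na.branch_length, nb.branch_length = la, lb
        parent = TreeNode(children=[na, nb])
        label = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            nd = 0.5 * (d(a, c) + d(b, c) - d(a, b))
            dist[(label, c) if label < c else (c, label)] = max(nd, 0.0)
        active = sorted(set(active) - {a, b} | {label})
        nodes[label] = parent
    # join the last three on a central node
    a, b, c = active
    la = 0.5 * (d(a, b) + d(a, c) - d(b, c))
    lb = 0.5 * (d(a, b) + d(b, c) - d(a, c))
    lc = 0.5 * (d(a, c) + d(b, c) - d(a, b))
    for label, ln in ((a, la), (b, lb), (c, lc)):
        nodes[label].branch_length = max(ln, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root)


def bootstrap_support(
    sm: Supermatrix,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "poisson",
) -> PhyloTree:
    """NJ tree on the full supermatrix with column-bootstrap support.

    Support of each internal bipartition is the fraction of replicate trees
    (columns resampled with replacement) containing it; replicates whose
    distances are undefined (saturated) are skipped and logged in counts.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(distance_matrix(sm, model))
    target = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    done = 0
    for _ in range(n_reps):
        rep = sm.resample_columns(rng)
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except ValueError:
            continue
        done += 1
        reps = rep_tree.bipartitions()
        for bp in target:
            if bp in reps:
                target[bp] += 1
    support = {bp: (cnt / done if done else 0.0) for bp, cnt in target.items()}
    all_taxa = set(tree.root.leaves())
    anchor = min(all_taxa)

    def annotate(node):
        for child in node.children:
            if not child.is_leaf:
                side = frozenset(child.leaves())
                if 2 <= len(side) <= len(all_taxa) - 2:
                    canon = side if anchor not in side else frozenset(all_taxa - side)
                    child.support = support.get(canon)
            annotate(child)

    annotate(tree.root)
    return tree
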