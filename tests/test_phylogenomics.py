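"""Supermatrix construction, distances, neighbor joining, bootstrap."""

import random

import numpy as np
import pytest

from genosig.phylogenomics import (
    DistanceMatrix,
    Supermatrix,
    align_gene,
    bootstrap_support,
    build_supermatrix,
    distance_matrix,
    nj_tree,
    select_single_copy,
)
from genosig.orthology import OrthologousGroupSet

AA = "ACDEFGHIKLMNPQRSTVWY"


def make_ogset(families: dict[str, dict[str, list[str]]], genomes, total=None):
    n = sum(len(m) for fam in families.values() for m in fam.values())
    return OrthologousGroupSet(families, [], list(genomes), total or n)


class TestSelectSingleCopy:
    def test_all_single_copy_selected(self):
        fams = {
            f"OG{i}": {g: [f"{g}|t{i}"] for g in "ABC"} for i in range(10)
        }
        ogset = make_ogset(fams, "ABC")
        assert len(select_single_copy(ogset)) == 10

    def test_duplicated_family_excluded(self):
        fams = {
            "OG1": {g: [f"{g}|a"] for g in "ABC"},
            "OG2": {"A": ["A|b", "A|b2"], "B": ["B|b"], "C": ["C|b"]},
        }
        assert select_single_copy(make_ogset(fams, "ABC")) == ["OG1"]

    def test_missing_taxon_tolerated_at_lower_fraction(self):
        fams = {"OG1": {"A": ["A|a"], "B": ["B|a"]}}
        ogset = make_ogset(fams, "ABC")
        with pytest.raises(ValueError, match="required_fraction"):
            select_single_copy(ogset, 1.0)
        assert select_single_copy(ogset, 0.6) == ["OG1"]


class TestBuildSupermatrix:
    def _ogset_and_proteomes(self, seqs_by_og):
        from genosig.genome_io import ProteinRecord

        genomes = sorted({g for m in seqs_by_og.values() for g in m})
        fams = {
            og: {g: [f"{g}|{og}"] for g in m} for og, m in seqs_by_og.items()
        }
        proteomes = {
            g: [
                ProteinRecord(f"{g}|{og}", og, g, seqs_by_og[og][g])
                for og in seqs_by_og if g in seqs_by_og[og]
            ]
            for g in genomes
        }
        return make_ogset(fams, genomes), proteomes

    def test_identical_sequences_align_without_gaps(self):
        ogset, prots = self._ogset_and_proteomes(
            {"OG1": {g: "MKVLAAGGTREQW" for g in "ABC"}}
        )
        sm = build_supermatrix(ogset, ["OG1"], prots)
        assert set(sm.rows.values()) == {"MKVLAAGGTREQW"}

    def test_concatenation_widths_and_partition_map(self):
        rng = random.Random(1)
        g1 = "".join(rng.choice(AA) for _ in range(100))
        g2 = "".join(rng.choice(AA) for _ in range(50))
        ogset, prots = self._ogset_and_proteomes(
            {"OG1": {g: g1 for g in "ABC"}, "OG2": {g: g2 for g in "ABC"}}
        )
        sm = build_supermatrix(ogset, ["OG1", "OG2"], prots)
        assert sm.n_columns == 150
        assert sm.partitions == {"OG1": (0, 100), "OG2": (100, 150)}

    def test_planted_insertion_produces_gap_block_in_other_rows(self):
        rng = random.Random(2)
        base = "".join(rng.choice(AA) for _ in range(60))
        with_ins = base[:30] + "WWW" + base[30:]
        seqs = {"A": base, "B": base, "C": base, "D": with_ins}
        aligned = align_gene(seqs)
        assert len(aligned["D"]) == 63
        assert aligned["D"].count("-") == 0
        for t in "ABC":
            assert aligned[t].count("-") == 3
            assert "---" in aligned[t]


class TestDistanceMatrix:
    def _sm(self, rows):
        return Supermatrix(sorted(rows), rows, {"g": (0, len(next(iter(rows.values()))))})

    def test_p_distance_quarter(self):
        dm = distance_matrix(
            self._sm({"A": "AAAA", "B": "AAAT", "C": "AAAA"}), "p-distance"
        )
        assert dm.get("A", "B") == 0.25
        assert dm.get("A", "C") == 0.0

    def test_gap_columns_pairwise_deleted(self):
        dm = distance_matrix(
            self._sm({"A": "AA-A", "B": "AAAA", "C": "TTTT"}), "p-distance"
        )
        assert dm.get("A", "B") == 0.0  # 3 compared columns, 0 mismatches
        assert dm.get("A", "C") == 1.0

    def test_poisson_correction(self):
        dm = distance_matrix(self._sm({"A": "AAAA", "B": "AAAT", "C": "AAAA"}))
        assert dm.get("A", "B") == pytest.approx(-np.log(0.75))


class TestNjTree:
    def test_three_taxon_branch_lengths_solve_linear_system(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm)
        bl = {c.name: c.branch_length for c in tree.root.children}
        assert bl == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_four_taxon_matrix_recovers_topology(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): additive distances
        taxa = ["A", "B", "C", "D"]
        bl = {"A": 1, "B": 2, "C": 3, "D": 4}
        m = np.zeros((4, 4))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i < j:
                    inner = 0 if {x, y} in ({"A", "B"}, {"C", "D"}) else 1
                    m[i, j] = m[j, i] = bl[x] + bl[y] + inner
        tree = nj_tree(DistanceMatrix(taxa, m))
        assert tree.bipartitions() == {frozenset({"C", "D"})}

    def test_random_additive_trees_recovered(self):
        """NJ on additive matrices returns the generating quartets."""
        rng = random.Random(7)
        for trial in range(5):
            n = rng.choice([5, 6, 7])
            taxa = [f"T{i}" for i in range(n)]
            # random binary tree by sequential attachment; path-length metric
            import itertools

            edges = {}  # adjacency with weights
            def add_edge(a, b, w):
                edges.setdefault(a, {})[b] = w
                edges.setdefault(b, {})[a] = w

            add_edge("T0", "T1", rng.uniform(0.5, 2))
            internal = 0
            attached = ["T0", "T1"]
            for leaf in taxa[2:]:
                # split a random existing edge, hang the new leaf
                a = rng.choice(list(edges))
                b = rng.choice(list(edges[a]))
                w = edges[a].pop(b)
                edges[b].pop(a)
                internal += 1
                mid = f"I{internal}"
                add_edge(a, mid, w * 0.5)
                add_edge(mid, b, w * 0.5)
                add_edge(mid, leaf, rng.uniform(0.5, 2))
                attached.append(leaf)

            def path(a, b):
                # dijkstra-lite on the small graph
                import heapq

                dist = {a: 0.0}
                heap = [(0.0, a)]
                while heap:
                    d, x = heapq.heappop(heap)
                    if x == b:
                        return d
                    for y, w in edges[x].items():
                        nd = d + w
                        if nd < dist.get(y, float("inf")):
                            dist[y] = nd
                            heapq.heappush(heap, (nd, y))
                return dist[b]

            m = np.zeros((n, n))
            for i, j in itertools.combinations(range(n), 2):
                m[i, j] = m[j, i] = path(taxa[i], taxa[j])
            tree = nj_tree(DistanceMatrix(taxa, m))
            # true bipartitions: reachability with each edge removed in turn
            true_bps = set()
            anchor = min(taxa)
            seen_pairs = set()
            for a in list(edges):
                for b in edges[a]:
                    if (b, a) in seen_pairs:
                        continue
                    seen_pairs.add((a, b))
                    # side of a without edge (a,b)
                    stack, side = [a], set()
                    while stack:
                        x = stack.pop()
                        if x in side:
                            continue
                        side.add(x)
                        for y in edges[x]:
                            if not (x == a and y == b):
                                stack.append(y)
                    leaves = frozenset(t for t in taxa if t in side)
                    if 2 <= len(leaves) <= n - 2:
                        canon = leaves if anchor not in leaves else frozenset(set(taxa) - leaves)
                        true_bps.add(canon)
            assert tree.bipartitions() == true_bps

    def test_matches_scikit_bio_reference(self):
        """Cross-check against an independent NJ implementation."""
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        rng = np.random.default_rng(5)
        n = 6
        taxa = [f"T{i}" for i in range(n)]
        base = rng.random((n, n))
        m = (base + base.T) / 2 + 1.0
        np.fill_diagonal(m, 0.0)
        ours = nj_tree(DistanceMatrix(taxa, m))
        theirs = sk_nj(SkDM(m, ids=taxa))
        anchor = min(taxa)
        sk_bps = set()
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= n - 2:
                canon = side if anchor not in side else frozenset(set(taxa) - side)
                sk_bps.add(canon)
        assert ours.bipartitions() == sk_bps

    def test_equal_distances_resolve_deterministically(self):
        taxa = ["A", "B", "C", "D"]
        m = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(DistanceMatrix(taxa, m)).newick()
        t2 = nj_tree(DistanceMatrix(taxa, m)).newick()
        assert t1 == t2


class TestBootstrap:
    def _simulate_supermatrix(self, n_columns=200, p=0.05, seed=123):
        """Protein evolution along ((A,B),(C,(D,E))) with per-branch
        substitution probability p; the test's own simulation truth."""
        rng = random.Random(seed)
        root = [rng.choice(AA) for _ in range(n_columns)]

        def evolve(seq):
            return [c if rng.random() > p else rng.choice(AA) for c in seq]

        ab = evolve(root)
        cde = evolve(root)
        de = evolve(cde)
        rows = {
            "A": "".join(evolve(ab)),
            "B": "".join(evolve(ab)),
            "C": "".join(evolve(cde)),
            "D": "".join(evolve(de)),
            "E": "".join(evolve(de)),
        }
        sm = Supermatrix(sorted(rows), rows, {"sim": (0, n_columns)})
        truth = {frozenset({"D", "E"}), frozenset({"C", "D", "E"})}
        return sm, truth

    def test_planted_topology_gets_high_support(self):
        sm, truth = self._simulate_supermatrix()
        tree = bootstrap_support(sm, n_reps=100, seed=7)
        assert tree.bipartitions() == truth
        supports = {
            frozenset(c.leaves()): c.support
            for c in tree._internal_nodes()
        }
        anchor = min(sm.taxa)
        for bp in truth:
            found = [
                s for side, s in supports.items()
                if side == bp or frozenset(set(sm.taxa) - side) == bp
            ]
            assert found and found[0] >= 0.9

    def test_single_replicate_supports_are_zero_or_one(self):
        sm, _ = self._simulate_supermatrix(seed=5)
        tree = bootstrap_support(sm, n_reps=1, seed=3)
        for node in tree._internal_nodes():
            assert node.support in (0.0, 1.0)

    def test_duplicated_columns_leave_topology_unchanged(self):
        sm, truth = self._simulate_supermatrix(seed=9)
        doubled = Supermatrix(
            sm.taxa, {t: sm.rows[t] * 2 for t in sm.taxa}, {"sim": (0, 2 * sm.n_columns)}
        )
        assert nj_tree(distance_matrix(doubled)).bipartitions() == \
            nj_tree(distance_matrix(sm)).bipartitions()

    def test_zero_replicates_rejected(self):
        sm, _ = self._simulate_supermatrix()
        with pytest.raises(ValueError):
            bootstrap_support(sm, n_reps=0)
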