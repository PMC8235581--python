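"""Orthology: similarity search, RBH determinism, OG clustering, AAI."""

import random

import pytest

from genosig.genome_io import ProteinRecord, derive_proteome, usable_proteins
from genosig.orthology import (
    RbhPair,
    aai_matrix,
    align_pair,
    all_vs_all,
    build_rbh,
    cluster_ogs,
    compute_aai,
    fraction_assigned,
    og_matrices,
    _make_aligner,
)
from genosig.synthetic_data import evolve_genome, simulate_ancestor, simulate_dataset, SimulationConfig

AA = "ACDEFGHIKLMNPQRSTVWY"


def prot(gid, tag, seq):
    return ProteinRecord(f"{gid}|{tag}", tag, gid, seq)


def random_protein(rng, n):
    return "".join(rng.choice(AA) for _ in range(n))


def make_proteomes(n_families=10, length=100, seed=1):
    rng = random.Random(seed)
    fams = [random_protein(rng, length) for _ in range(n_families)]
    return {
        gid: [prot(gid, f"t{i}", s) for i, s in enumerate(fams)]
        for gid in ("A", "B")
    }


class TestAllVsAll:
    def test_identical_proteins_full_identity_and_coverage(self):
        p = make_proteomes(n_families=3)
        hits = all_vs_all(p)
        ab = [h for h in hits if h.query_id == "A|t0" and h.subject_id == "B|t0"]
        assert ab and ab[0].percent_identity == 100.0
        assert ab[0].query_coverage == 1.0

    def test_no_shared_kmer_no_hit(self):
        a = prot("A", "x", "AAAAAAAAAA")
        b = prot("B", "y", "WWWWWWWWWW")
        assert all_vs_all({"A": [a], "B": [b]}) == []

    def test_empty_proteome_errors_with_genome_name(self):
        with pytest.raises(ValueError, match="B"):
            all_vs_all({"A": [prot("A", "x", "MKV" * 20)], "B": []})

    def test_prefilter_loses_no_hit_vs_exhaustive_alignment(self):
        """Identities through the k-mer prefilter equal a full all-pairs
        dynamic-programming sweep for related protein pairs."""
        rng = random.Random(42)
        base = [random_protein(rng, 200) for _ in range(10)]
        mutated = [
            "".join(c if rng.random() > 0.1 else rng.choice(AA) for c in s)
            for s in base
        ]
        proteomes = {
            "A": [prot("A", f"t{i}", s) for i, s in enumerate(base)],
            "B": [prot("B", f"t{i}", s) for i, s in enumerate(mutated)],
        }
        hits = {(h.query_id, h.subject_id): h.percent_identity
                for h in all_vs_all(proteomes)}
        aligner = _make_aligner()
        for i, a in enumerate(proteomes["A"]):
            for b in proteomes["B"]:
                res = align_pair(aligner, a, b)  # exhaustive: every pair
                if res is None:
                    continue
                identity, cov_a, cov_b, _ = res
                if identity >= 30 and cov_a >= 0.5 and cov_b >= 0.5:
                    assert hits[(a.protein_id, b.protein_id)] == pytest.approx(identity)


class TestBuildRbh:
    def test_identical_proteomes_pair_every_gene(self):
        p = make_proteomes(n_families=10)
        pairs = build_rbh(all_vs_all(p), "A", "B")
        assert len(pairs) == 10
        assert all(pr.gene_a.split("|")[1] == pr.gene_b.split("|")[1] for pr in pairs)

    def test_non_reciprocal_best_is_dropped(self):
        # B|y0 is best for A|x, but B|y0's best is A|z (identical copy)
        core = "MKVLAAGGTREQWSDFGHKLMNPQRSTVWYAC" * 4
        proteomes = {
            "A": [prot("A", "x", core[:100] + "WWWWWWWWWW"), prot("A", "z", core)],
            "B": [prot("B", "y0", core)],
        }
        pairs = build_rbh(all_vs_all(proteomes), "A", "B")
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("A|z", "B|y0")]

    def test_tie_break_invariant_under_input_order(self):
        # two identical subjects -> tie on score and identity; lexicographic
        # subject id must win regardless of hit order
        seq = "MKVLAAGGTREQWSDFGHKL" * 5
        proteomes = {
            "A": [prot("A", "q", seq)],
            "B": [prot("B", "s2", seq), prot("B", "s1", seq)],
        }
        hits = all_vs_all(proteomes)
        for trial in (hits, hits[::-1]):
            pairs = build_rbh(trial, "A", "B")
            # q's best is s1 (lexicographic), but s1's own best among {q} is q
            assert [(p.gene_a, p.gene_b) for p in pairs] == [("A|q", "B|s1")]


def union_find_components(nodes, edges):
    """Independent union-find oracle for connected components."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return {frozenset(c) for c in comps.values()}


class TestClusterOgs:
    def test_three_genomes_ten_families_all_core_single_copy(self):
        rng = random.Random(3)
        fams = [random_protein(rng, 120) for _ in range(10)]
        proteomes = {
            gid: [prot(gid, f"t{i}", s) for i, s in enumerate(fams)]
            for gid in ("A", "B", "C")
        }
        hits = all_vs_all(proteomes)
        pairs = [p for x, y in (("A", "B"), ("A", "C"), ("B", "C"))
                 for p in build_rbh(hits, x, y)]
        ogset = cluster_ogs(pairs, hits, proteomes)
        assert len(ogset.groups) == 10
        assert len(ogset.core_ogs()) == 10
        assert len(ogset.single_copy_ogs()) == 10
        assert ogset.singletons == []

    def test_unique_gene_becomes_singleton_without_changing_og_count(self):
        rng = random.Random(4)
        fams = [random_protein(rng, 120) for _ in range(5)]
        proteomes = {
            gid: [prot(gid, f"t{i}", s) for i, s in enumerate(fams)]
            for gid in ("A", "B")
        }
        proteomes["A"].append(prot("A", "orphan", random_protein(rng, 120)))
        hits = all_vs_all(proteomes)
        pairs = build_rbh(hits, "A", "B")
        ogset = cluster_ogs(pairs, hits, proteomes)
        assert len(ogset.groups) == 5
        assert ogset.singletons == ["A|orphan"]

    def test_component_structure_equals_union_find_oracle(self, recovery_dataset):
        genomes, truth = recovery_dataset
        proteomes = {
            gid: usable_proteins(derive_proteome(g, f))
            for gid, (g, f) in genomes.items()
        }
        hits = all_vs_all(proteomes)
        gids = sorted(proteomes)
        pairs = [
            p for i, a in enumerate(gids) for b in gids[i + 1:]
            for p in build_rbh(hits, a, b)
        ]
        ogset = cluster_ogs(pairs, hits, proteomes)
        # rebuild the same edge list and compare against union-find
        nodes = {p.protein_id for prots in proteomes.values() for p in prots}
        edges = [(p.gene_a, p.gene_b) for p in pairs]
        best_inter = {}
        for h in hits:
            if h.query_genome != h.subject_genome:
                best_inter[h.query_id] = max(best_inter.get(h.query_id, 0.0), h.score)
        for h in hits:
            if h.query_genome == h.subject_genome and h.query_id != h.subject_id:
                if h.score >= best_inter.get(h.query_id, 0.0) or \
                        h.score >= best_inter.get(h.subject_id, 0.0):
                    edges.append((h.query_id, h.subject_id))
        oracle = union_find_components(nodes, edges)
        ours = {
            frozenset(g for members in og.values() for g in members)
            for og in ogset.groups.values()
        } | {frozenset([s]) for s in ogset.singletons}
        assert ours == oracle

    def test_og_membership_matches_planted_families(self, recovery_dataset):
        """At path divergence p <= 0.1, at least 99% of genes cluster with
        their planted family."""
        genomes, truth = recovery_dataset
        proteomes = {
            gid: usable_proteins(derive_proteome(g, f))
            for gid, (g, f) in genomes.items()
        }
        hits = all_vs_all(proteomes)
        gids = sorted(proteomes)
        pairs = [
            p for i, a in enumerate(gids) for b in gids[i + 1:]
            for p in build_rbh(hits, a, b)
        ]
        ogset = cluster_ogs(pairs, hits, proteomes)
        in_analysis = {
            p.protein_id for prots in proteomes.values() for p in prots
        }
        fam_of = {
            f"{g.genome_id}|{g.locus_tag}": g.family_id
            for g in truth.genes
            if g.genome_id != "ancestor"
            and f"{g.genome_id}|{g.locus_tag}" in in_analysis
        }
        # truth OGs: genes sharing a family present in >1 copy overall
        gene_to_og = {}
        for og_id, members in ogset.groups.items():
            for mlist in members.values():
                for gene in mlist:
                    gene_to_og[gene] = og_id
        total = correct = 0
        from collections import Counter

        fam_sizes = Counter(fam_of.values())
        for gene, fam in fam_of.items():
            if fam_sizes[fam] < 2:
                continue  # genuine singleton
            total += 1
            og = gene_to_og.get(gene)
            if og is None:
                continue
            members = {
                g for ms in ogset.groups[og].values() for g in ms
            }
            fams = {fam_of[m] for m in members if m in fam_of}
            if fams == {fam}:
                correct += 1
        assert total > 0
        assert correct / total >= 0.99


class TestOgMatrices:
    def test_sharing_table_partitions_og_total(self, recovery_dataset):
        genomes, _ = recovery_dataset
        proteomes = {
            gid: usable_proteins(derive_proteome(g, f))
            for gid, (g, f) in genomes.items()
        }
        hits = all_vs_all(proteomes)
        gids = sorted(proteomes)
        pairs = [
            p for i, a in enumerate(gids) for b in gids[i + 1:]
            for p in build_rbh(hits, a, b)
        ]
        ogset = cluster_ogs(pairs, hits, proteomes)
        counts, sharing = og_matrices(ogset)
        assert sharing["n_ogs"].sum() == len(ogset.groups)
        full = sharing[sharing["n_genomes"] == len(gids)]
        assert full["n_ogs"].iloc[0] == len(ogset.core_ogs())

    def test_fraction_assigned_from_printed_totals(self):
        assert fraction_assigned(14437, 17479) == 82.6


class TestAai:
    def test_identical_proteomes_give_100(self):
        p = make_proteomes(n_families=8)
        aai, n = compute_aai(build_rbh(all_vs_all(p), "A", "B"))
        assert aai == 100.0 and n == 8

    def test_gene_order_shuffle_does_not_change_aai(self):
        p = make_proteomes(n_families=8, seed=9)
        shuffled = {"A": p["A"], "B": list(reversed(p["B"]))}
        h1 = all_vs_all(p)
        h2 = all_vs_all(shuffled)
        assert compute_aai(build_rbh(h1, "A", "B")) == compute_aai(build_rbh(h2, "A", "B"))

    def test_no_qualifying_pairs_is_undefined(self):
        aai, n = compute_aai([], min_identity=30)
        assert aai is None and n == 0

    def test_aai_symmetric_and_monotone_in_divergence(self, neutral_cfg_factory):
        """AAI decreases as proteome divergence grows (neutral families)."""
        cfg = neutral_cfg_factory(seed=31, p=0.0, length=40_000, genes=35)
        anc, feats, _ = simulate_ancestor(cfg)
        values = []
        for p in (0.02, 0.05, 0.10, 0.20):
            child, cfeats = evolve_genome(anc, feats, p, 0.0, seed=77, genome_id="C")
            proteomes = {
                "ancestor": usable_proteins(derive_proteome(anc, feats)),
                "C": usable_proteins(derive_proteome(child, cfeats)),
            }
            mat = aai_matrix(proteomes)
            assert abs(mat.loc["ancestor", "C"] - mat.loc["C", "ancestor"]) <= 0.1
            values.append(mat.loc["ancestor", "C"])
        assert values == sorted(values, reverse=True)
        assert values[0] > values[-1]
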