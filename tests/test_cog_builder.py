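import itertools
import math

import numpy as np
import pytest

from mitoevo import cog_builder as cog
from mitoevo._alignment import (
    encode, fit_gumbel, gumbel_sf, local_align, make_aligner, sw_profile,
)
from mitoevo.io_formats import GenomeMeta, SequenceRecord, SimilarityHit

from conftest import toy_records


def hit(q, s, score, qc=1.0, sc=1.0):
    return SimilarityHit(q, s, score, float("nan"), qc, sc)


def meta_for(pairs):
    return [GenomeMeta(s, g, "mito", ("E",)) for s, g in pairs]


# ---------------------------------------------------------------------------
# local alignment
# ---------------------------------------------------------------------------

class TestLocalAlignment:
    def test_blosum62_identity_score(self):
        # ACDE vs ACDE: diagonal BLOSUM62 entries 4 + 9 + 6 + 5 = 24
        aligner = make_aligner("BLOSUM62", 11, 1)
        score, q_cov, s_cov = local_align(aligner, "ACDE", "ACDE")
        assert score == 24.0
        assert q_cov == 1.0 and s_cov == 1.0

    def test_no_positive_pair_scores_zero(self):
        # G vs P is negative in BLOSUM62; single-residue sequences
        aligner = make_aligner("BLOSUM62", 11, 1)
        score, *_ = local_align(aligner, "G", "P")
        assert score == 0.0

    def test_profile_dp_matches_slow_oracle(self):
        rng = np.random.default_rng(0)

        def slow(columns, seq, go, ge):
            L, M = columns.shape[0], len(seq)
            H = np.zeros((L + 1, M + 1))
            E = np.full((L + 1, M + 1), -1e30)
            F = np.full((L + 1, M + 1), -1e30)
            best = 0.0
            for i in range(1, L + 1):
                for j in range(1, M + 1):
                    E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - ge)
                    F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - ge)
                    sub = columns[i - 1, seq[j - 1]] if seq[j - 1] < 20 else 0.0
                    H[i, j] = max(0.0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
                    best = max(best, H[i, j])
            return best

        for _ in range(25):
            L, M = rng.integers(3, 15, 2)
            columns = rng.normal(0, 3, (L, 20))
            seq = rng.integers(0, 21, M)
            got, _, _ = sw_profile(columns, seq.astype(np.int8), 5.0, 1.0)
            assert got == pytest.approx(slow(columns, seq, 5.0, 1.0))

    def test_gumbel_tail_monotone(self):
        mu, beta = fit_gumbel(np.random.default_rng(1).gumbel(10, 2, 500))
        xs = np.linspace(0, 40, 50)
        sf = gumbel_sf(xs, mu, beta)
        assert np.all(np.diff(sf) <= 0)
        assert 0 <= sf[-1] <= sf[0] <= 1


class TestScoreAllVsAll:
    def test_symmetric_scores_and_coverage(self):
        records, meta = toy_records()
        hits = cog.score_all_vs_all(records, meta)
        scores = {(h.query, h.subject): h.score for h in hits}
        for (q, s), v in scores.items():
            assert scores[(s, q)] == v
        same = [h for h in hits
                if h.query[0] == h.subject[0]]  # same-genome pairs
        assert not same
        identical = next(h for h in hits if {h.query, h.subject} == {"a1", "b1"})
        assert identical.q_cov == 1.0 and identical.s_cov == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            cog.score_all_vs_all([], [])


class TestCoverageFilter:
    def test_boundary_inclusive(self):
        hits = [hit("a", "b", 10, 0.50, 0.50)]
        assert cog.filter_by_coverage(hits, 0.5) == hits

    def test_one_sided_failure_drops(self):
        hits = [hit("a", "b", 10, 0.49, 0.90)]
        assert cog.filter_by_coverage(hits, 0.5) == []

    def test_empty(self):
        assert cog.filter_by_coverage([], 0.5) == []


class TestSymmetricBestHits:
    def test_mutual_best_forms_edge(self):
        meta = meta_for([("p1", "G1"), ("p2", "G2")])
        hits = [hit("p1", "p2", 50), hit("p2", "p1", 50)]
        assert cog.symmetric_best_hits(hits, meta) == [("p1", "p2")]

    def test_asymmetry_breaks_edge(self):
        meta = meta_for([("p1", "G1"), ("p3", "G1"), ("p2", "G2")])
        hits = [hit("p1", "p2", 50), hit("p2", "p1", 40),
                hit("p2", "p3", 60), hit("p3", "p2", 60)]
        edges = cog.symmetric_best_hits(hits, meta)
        assert edges == [("p2", "p3")]

    def test_score_tie_prefers_lower_seq_id(self):
        meta = meta_for([("p1", "G1"), ("pa", "G2"), ("pb", "G2")])
        hits = [hit("p1", "pa", 50), hit("p1", "pb", 50),
                hit("pa", "p1", 50), hit("pb", "p1", 50)]
        assert cog.symmetric_best_hits(hits, meta) == [("p1", "pa")]


class TestTriangleClusters:
    def test_three_genomes_full_triangle(self):
        meta = meta_for([("a", "G1"), ("b", "G2"), ("c", "G3")])
        cs = cog.triangle_clusters([("a", "b"), ("a", "c"), ("b", "c")], meta)
        assert len(cs) == 1
        (cluster,) = cs.clusters.values()
        assert cluster.members == {"a", "b", "c"}
        assert cluster.origin == "triangle"

    def test_edge_sharing_triangles_merge(self):
        meta = meta_for([("a", "G1"), ("b", "G2"), ("c", "G3"), ("d", "G4")])
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("b", "d"), ("c", "d")]
        cs = cog.triangle_clusters(edges, meta)
        assert len(cs) == 1
        assert set().union(*(c.members for c in cs.clusters.values())) == {"a", "b", "c", "d"}

    def test_path_without_triangle_yields_nothing(self):
        meta = meta_for([("a", "G1"), ("b", "G2"), ("c", "G3")])
        cs = cog.triangle_clusters([("a", "b"), ("b", "c")], meta)
        assert len(cs) == 0

    def test_same_genome_triangle_excluded(self):
        meta = meta_for([("a", "G1"), ("b", "G2"), ("c", "G2")])
        cs = cog.triangle_clusters([("a", "b"), ("a", "c"), ("b", "c")], meta)
        assert len(cs) == 0

    def test_edge_order_invariance(self):
        rng = np.random.default_rng(4)
        names = [f"p{i}" for i in range(12)]
        meta = meta_for([(n, f"G{i % 4}") for i, n in enumerate(names)])
        edges = sorted({tuple(sorted(rng.choice(names, 2, replace=False)))
                        for _ in range(30)})
        ref = cog.triangle_clusters(edges, meta)
        for _ in range(5):
            shuffled = list(edges)
            rng.shuffle(shuffled)
            got = cog.triangle_clusters(shuffled, meta)
            assert {frozenset(c.members) for c in got.clusters.values()} == \
                   {frozenset(c.members) for c in ref.clusters.values()}

    def test_component_members_match_networkx_oracle(self):
        import networkx as nx
        rng = np.random.default_rng(11)
        names = [f"p{i}" for i in range(15)]
        meta = meta_for([(n, f"G{i % 5}") for i, n in enumerate(names)])
        genome = {n: f"G{i % 5}" for i, n in enumerate(names)}
        edges = sorted({tuple(sorted(rng.choice(names, 2, replace=False)))
                        for _ in range(45)})
        g = nx.Graph(edges)
        triangles = [t for t in
                     (tuple(sorted(c)) for c in nx.enumerate_all_cliques(g)
                      if len(c) == 3)
                     if len({genome[x] for x in t}) == 3]
        tg = nx.Graph()
        tg.add_nodes_from(triangles)
        for t1, t2 in itertools.combinations(triangles, 2):
            if len(set(t1) & set(t2)) == 2:
                tg.add_edge(t1, t2)
        sets = [set(itertools.chain(*comp))
                for comp in nx.connected_components(tg)]
        # vertex-sharing components collapse too (disjointness requirement)
        og = nx.Graph()
        og.add_nodes_from(range(len(sets)))
        for i, j in itertools.combinations(range(len(sets)), 2):
            if sets[i] & sets[j]:
                og.add_edge(i, j)
        expected = {frozenset().union(*(sets[i] for i in comp))
                    for comp in nx.connected_components(og)}
        got = cog.triangle_clusters(edges, meta)
        assert {frozenset(c.members) for c in got.clusters.values()} == expected


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

class TestAlignCluster:
    def test_single_member_ungapped(self):
        records, _ = toy_records()
        cluster = cog.Cluster("c", {"a1"}, "triangle")
        aln = cog.align_cluster(cluster, records)
        assert aln == {"a1": records[0].residues}

    def test_identical_members_ungapped(self):
        records, _ = toy_records()
        cluster = cog.Cluster("c", {"a1", "b1"}, "triangle")
        aln = cog.align_cluster(cluster, records)
        assert aln["a1"] == aln["b1"] == records[0].residues

    def test_rows_restore_sequences(self):
        records, _ = toy_records()
        cluster = cog.Cluster("c", {"a1", "b1", "c1"}, "triangle")
        aln = cog.align_cluster(cluster, records)
        recmap = {r.seq_id: r for r in records}
        widths = {len(v) for v in aln.values()}
        assert len(widths) == 1
        for sid, row in aln.items():
            assert row.replace("-", "") == recmap[sid].residues

    def test_external_alignment_member_mismatch(self):
        records, _ = toy_records()
        cluster = cog.Cluster("c", {"a1", "b1"}, "triangle")
        with pytest.raises(ValueError, match="missing"):
            cog.align_cluster(cluster, records,
                              external_alignment={"a1": records[0].residues})


class TestBuildProfile:
    def test_single_sequence_beta_zero(self):
        b = np.full(20, 0.05)
        profile = cog.build_profile({"s": "A"}, background=b, beta=0.0)
        a_idx = cog.AA_ORDER.index("A")
        c_idx = cog.AA_ORDER.index("C")
        assert profile.columns[0, a_idx] == pytest.approx(math.log2(1 / 0.05))
        assert profile.columns[0, c_idx] == cog.SCORE_FLOOR

    def test_gap_fraction_boundary_inclusive(self):
        aln = {"s1": "A-", "s2": "-C"}  # both columns exactly 50% gapped
        profile = cog.build_profile(aln, max_gap_fraction=0.5)
        assert profile.length == 2
        with pytest.raises(ValueError, match="excluded"):
            # both columns now exceed the (stricter) threshold
            cog.build_profile(aln, max_gap_fraction=0.4)

    def test_pseudocount_formula(self):
        b = np.full(20, 0.05)
        profile = cog.build_profile({"s1": "A", "s2": "A"}, background=b, beta=20.0)
        a_idx = cog.AA_ORDER.index("A")
        expected = math.log2(((2 + 20 * 0.05) / (2 + 20)) / 0.05)
        assert profile.columns[0, a_idx] == pytest.approx(expected)


class TestProfileSearch:
    def _profile_and_db(self):
        rng = np.random.default_rng(2)
        aas = cog.AA_ORDER
        source = "".join(rng.choice(list(aas), 60))
        db = [SequenceRecord("src", source)]
        for i in range(6):
            db.append(SequenceRecord(
                f"r{i}", "".join(rng.choice(list(aas), 60))))
        profile = cog.build_profile({"src": source})
        return profile, db

    def test_source_sequence_top_ranked(self):
        profile, db = self._profile_and_db()
        hits = cog.profile_search(profile, db, seed=0)
        assert hits[0].seq_id == "src"

    def test_evalues_decrease_with_score(self):
        profile, db = self._profile_and_db()
        hits = cog.profile_search(profile, db, seed=0)
        scores = [h.score for h in hits]
        evalues = [h.evalue for h in hits]
        assert scores == sorted(scores, reverse=True)
        assert evalues == sorted(evalues)

    def test_seeded_determinism(self):
        profile, db = self._profile_and_db()
        h1 = cog.profile_search(profile, db, seed=7)
        h2 = cog.profile_search(profile, db, seed=7)
        assert h1 == h2

    def test_min_shuffles_enforced(self):
        profile, db = self._profile_and_db()
        with pytest.raises(ValueError):
            cog.profile_search(profile, db, n_shuffles=10)


# ---------------------------------------------------------------------------
# expansion / merging / orphans on constructed cases
# ---------------------------------------------------------------------------

def _family_records(seed, n_genomes=4, length=80, n_families=2):
    rng = np.random.default_rng(seed)
    aas = list(cog.AA_ORDER)
    records, meta = [], []
    for f in range(n_families):
        root = rng.choice(aas, length)
        for g in range(n_genomes):
            seq = root.copy()
            mutate = rng.random(length) < 0.05
            for pos in np.where(mutate)[0]:
                seq[pos] = rng.choice([a for a in aas if a != seq[pos]])
            sid = f"f{f}_g{g}"
            records.append(SequenceRecord(sid, "".join(seq)))
            meta.append(GenomeMeta(sid, f"G{g}", "mito", ("E",)))
    return records, meta


def _initial_clusters(records, meta):
    hits = cog.filter_by_coverage(cog.score_all_vs_all(records, meta), 0.5)
    edges = cog.symmetric_best_hits(hits, meta)
    return cog.triangle_clusters(edges, meta)


class TestExpandClusters:
    def test_fragment_recruited_to_its_family(self):
        records, meta = _family_records(seed=3)
        parent = records[0]
        frag = SequenceRecord(parent.seq_id + "_frag",
                              parent.residues[:int(0.6 * parent.length)])
        records = records + [frag]
        meta = meta + [GenomeMeta(frag.seq_id, "G0", "mito", ("E",))]
        clusters = _initial_clusters(records, meta)
        assert frag.seq_id not in clusters.assigned()
        expanded = cog.expand_clusters(clusters, records, meta, seed=0)
        target = expanded.assignment[frag.seq_id]
        assert parent.seq_id in expanded.clusters[target].members
        assert expanded.member_origin[frag.seq_id] == "expansion"

    def test_shuffled_decoy_not_recruited(self):
        records, meta = _family_records(seed=4)
        rng = np.random.default_rng(0)
        decoy = SequenceRecord(
            "decoy", "".join(rng.permutation(list(records[0].residues))))
        records = records + [decoy]
        meta = meta + [GenomeMeta("decoy", "G0", "mito", ("E",))]
        clusters = _initial_clusters(records, meta)
        expanded = cog.expand_clusters(clusters, records, meta, seed=0)
        assert "decoy" not in expanded.assigned()

    def test_assigned_sequences_never_move(self):
        records, meta = _family_records(seed=5)
        clusters = _initial_clusters(records, meta)
        before = clusters.assignment
        expanded = cog.expand_clusters(clusters, records, meta, seed=0)
        for sid, cid in before.items():
            assert expanded.assignment[sid] == cid


class TestMergeClusters:
    def test_split_family_merges(self):
        records, meta = _family_records(seed=6, n_genomes=6, n_families=1)
        members = {r.seq_id for r in records}
        half1 = {m for m in members if int(m.split("_g")[1]) < 3}
        cs = cog.ClusterSet([
            cog.Cluster("A", half1, "triangle"),
            cog.Cluster("B", members - half1, "triangle"),
        ])
        merged = cog.merge_clusters(cs, records, seed=0)
        assert len(merged) == 1
        (cluster,) = merged.clusters.values()
        assert cluster.members == members
        assert cluster.origin == "merge"

    def test_unrelated_families_unchanged_and_idempotent(self):
        records, meta = _family_records(seed=7, n_genomes=4, n_families=2)
        clusters = _initial_clusters(records, meta)
        assert len(clusters) == 2
        merged = cog.merge_clusters(clusters, records, seed=0)
        assert {frozenset(c.members) for c in merged.clusters.values()} == \
               {frozenset(c.members) for c in clusters.clusters.values()}
        again = cog.merge_clusters(merged, records, seed=0)
        assert {frozenset(c.members) for c in again.clusters.values()} == \
               {frozenset(c.members) for c in merged.clusters.values()}

    def test_single_cluster_unchanged(self):
        records, meta = _family_records(seed=8, n_genomes=3, n_families=1)
        cs = cog.ClusterSet([cog.Cluster("A", {r.seq_id for r in records},
                                         "triangle")])
        merged = cog.merge_clusters(cs, records, seed=0)
        assert len(merged) == 1


class TestOrphanClusters:
    def _setup(self):
        records = [SequenceRecord(s, "ACDEFGHIKL")
                   for s in ("u1", "u2", "m1")]
        meta = [GenomeMeta(r.seq_id, "G1", "mito", ("E",)) for r in records]
        clusters = cog.ClusterSet([cog.Cluster("C1", {"m1"}, "triangle")])
        return records, meta, clusters

    def test_singleton_orphans(self):
        records, meta, clusters = self._setup()
        out = cog.add_orphan_clusters(clusters, records, meta)
        assert out.assigned() == {"u1", "u2", "m1"}
        assert out.member_origin["u1"] == "orphan"

    def test_curated_grouping(self):
        records, meta, clusters = self._setup()
        out = cog.add_orphan_clusters(clusters, records, meta,
                                      curated={"u1": "CU1", "u2": "CU1"})
        assert out.clusters["CU1"].members == {"u1", "u2"}
        assert out.clusters["CU1"].origin == "curated"

    def test_conflicting_curation_raises(self, tmp_path):
        path = tmp_path / "curated.tsv"
        path.write_text("seq_id\tcluster_id\nu1\tA\nu1\tB\n")
        with pytest.raises(ValueError, match="u1"):
            cog.read_curated_tsv(path)

    def test_partition_invariant(self):
        records, meta, clusters = self._setup()
        out = cog.add_orphan_clusters(clusters, records, meta)
        seen = [s for c in out.clusters.values() for s in c.members]
        assert sorted(seen) == sorted({r.seq_id for r in records})
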