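"""Construction of clusters of orthologous organelle proteins.

The procedure mirrors classic COG construction: all-vs-all local
alignment, a bidirectional coverage filter, symmetric (reciprocal) best
hits per genome, 3-genome triangles merged on shared edges into initial
clusters, profile-based recruitment of sequences the strict stage
missed (short fragments, paralogs), iterative merging of clusters that
are reciprocally each other's best profile match, and finally orphan /
curated cluster injection so the result partitions the input.

All tie-breaks are lexicographic, which makes every stage deterministic
for a fixed input set.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._alignment import (
    AA_ORDER,
    encode,
    fit_gumbel,
    gumbel_sf,
    local_align,
    make_aligner,
    sw_profile,
)
from .io_formats import GenomeMeta, SequenceRecord, SimilarityHit

# Robinson-Robinson amino-acid background frequencies, reordered to AA_ORDER.
_RR = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}
DEFAULT_BACKGROUND = np.array([_RR[a] for a in AA_ORDER])
DEFAULT_BACKGROUND /= DEFAULT_BACKGROUND.sum()

SCORE_FLOOR = -30.0  # guard for log-odds of residues absent at beta = 0


# ---------------------------------------------------------------------------
# cluster containers
# ---------------------------------------------------------------------------

@dataclass
class Cluster:
    cluster_id: str
    members: set[str]
    origin: str  # how the cluster came to exist

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")


class ClusterSet:
    """A collection of pairwise-disjoint clusters with per-member origins."""

    def __init__(self, clusters: list[Cluster] | None = None,
                 member_origin: dict[str, str] | None = None):
        self.clusters: dict[str, Cluster] = {}
        self.member_origin: dict[str, str] = {}
        for cluster in clusters or []:
            self._add_cluster(cluster)
        if member_origin:
            self.member_origin.update(member_origin)

    def _add_cluster(self, cluster: Cluster) -> None:
        if cluster.cluster_id in self.clusters:
            raise ValueError(f"duplicate cluster_id {cluster.cluster_id!r}")
        for seq_id in cluster.members:
            if seq_id in self.member_origin:
                raise ValueError(
                    f"sequence {seq_id!r} assigned to more than one cluster")
            self.member_origin[seq_id] = cluster.origin
        self.clusters[cluster.cluster_id] = cluster

    @property
    def assignment(self) -> dict[str, str]:
        out = {}
        for cid, cluster in self.clusters.items():
            for seq_id in cluster.members:
                out[seq_id] = cid
        return out

    def assigned(self) -> set[str]:
        return set(self.member_origin)

    def add_member(self, cluster_id: str, seq_id: str, origin: str) -> None:
        if seq_id in self.member_origin:
            raise ValueError(f"sequence {seq_id!r} already assigned")
        self.clusters[cluster_id].members.add(seq_id)
        self.member_origin[seq_id] = origin

    def copy(self) -> "ClusterSet":
        return ClusterSet(
            [Cluster(c.cluster_id, set(c.members), c.origin)
             for c in self.clusters.values()],
            dict(self.member_origin),
        )

    def to_frame(self, meta: list[GenomeMeta] | None = None) -> pd.DataFrame:
        genome = {m.seq_id: m.genome_id for m in meta or []}
        rows = []
        for cid in sorted(self.clusters):
            for seq_id in sorted(self.clusters[cid].members):
                rows.append((cid, seq_id, genome.get(seq_id, ""),
                             self.member_origin[seq_id]))
        return pd.DataFrame(rows, columns=["cluster_id", "seq_id",
                                           "genome_id", "origin"])

    def write_tsv(self, path, meta=None) -> None:
        self.to_frame(meta).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "ClusterSet":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        clusters = {}
        origins = {}
        for _, row in frame.iterrows():
            clusters.setdefault(row["cluster_id"], set()).add(row["seq_id"])
            origins[row["seq_id"]] = row["origin"]
        cluster_origin = {}
        for cid, members in clusters.items():
            # cluster-level origin: the most specific creation origin present
            cluster_origin[cid] = origins[sorted(members)[0]]
        return cls([Cluster(cid, members, cluster_origin[cid])
                    for cid, members in clusters.items()], origins)

    def __len__(self):
        return len(self.clusters)

    def __repr__(self):  # pragma: no cover
        return f"ClusterSet({len(self.clusters)} clusters, {len(self.member_origin)} sequences)"


@dataclass
class Profile:
    """Position-specific scoring matrix over the 20 standard residues."""

    columns: np.ndarray  # (L, 20) log-odds scores (bits)
    background: np.ndarray  # (20,) frequencies summing to 1
    pseudocount_weight: float
    kept_columns: tuple[int, ...] = ()  # alignment columns retained

    def __post_init__(self):
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ValueError("profile columns must be (L, 20)")
        if self.columns.shape[0] < 1:
            raise ValueError("profile must have at least one column")
        if not np.isfinite(self.columns).all():
            raise ValueError("profile contains non-finite scores")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")
        if self.pseudocount_weight < 0:
            raise ValueError("pseudocount weight must be >= 0")

    @property
    def length(self) -> int:
        return self.columns.shape[0]


@dataclass(frozen=True)
class ProfileHit:
    seq_id: str
    score: float
    evalue: float
    p_cov: float  # profile span covered
    s_cov: float  # sequence span covered


# ---------------------------------------------------------------------------
# all-vs-all scoring and reciprocal best hits
# ---------------------------------------------------------------------------

def score_all_vs_all(records: list[SequenceRecord], meta: list[GenomeMeta],
                     substitution_matrix="BLOSUM62",
                     gap_open: float = 11, gap_extend: float = 1,
                     e_threshold: float | None = 0.01,
                     n_null_pairs: int = 500, seed: int = 0,
                     ) -> list[SimilarityHit]:
    """Smith-Waterman hits for every cross-genome ordered pair.

    Scores are symmetric; coverages are the aligned span divided by
    each sequence's length.  Like a database search tool, the stand-in
    reports only significant hits: an empirical null (local scores of
    residue-shuffled cross-genome pairs, Gumbel-fitted by method of
    moments) assigns each hit an e-value of ``len(records) * P(S >= s)``
    and hits above ``e_threshold`` are omitted, as are pairs with no
    positive-scoring local alignment.  ``e_threshold=None`` reports
    every positive-scoring pair.
    """
    if len(records) < 2:
        raise ValueError("need at least two sequences")
    genome = {m.seq_id: m.genome_id for m in meta}
    missing = [r.seq_id for r in records if r.seq_id not in genome]
    if missing:
        raise ValueError(f"records without metadata: {missing[:5]}")
    aligner = make_aligner(substitution_matrix, gap_open, gap_extend)

    evalue_of = None
    if e_threshold is not None:
        rng = np.random.default_rng(seed)
        cross = [(a, b) for a, b in itertools.combinations(records, 2)
                 if genome[a.seq_id] != genome[b.seq_id]]
        if cross:
            null_scores = []
            for _ in range(n_null_pairs):
                a, b = cross[rng.integers(len(cross))]
                sa = "".join(rng.permutation(list(a.residues)))
                sb = "".join(rng.permutation(list(b.residues)))
                s, _, _ = local_align(aligner, sa, sb)
                null_scores.append(s)
            mu, beta = fit_gumbel(np.asarray(null_scores))
            n_db = len(records)

            def evalue_of(score):
                return float(n_db * gumbel_sf(score, mu, beta))

    hits: list[SimilarityHit] = []
    for a, b in itertools.combinations(records, 2):
        if genome[a.seq_id] == genome[b.seq_id]:
            continue
        score, a_cov, b_cov = local_align(aligner, a.residues, b.residues)
        if score <= 0:
            continue
        evalue = evalue_of(score) if evalue_of else float("nan")
        if e_threshold is not None and evalue > e_threshold:
            continue
        hits.append(SimilarityHit(a.seq_id, b.seq_id, score, evalue,
                                  a_cov, b_cov))
        hits.append(SimilarityHit(b.seq_id, a.seq_id, score, evalue,
                                  b_cov, a_cov))
    return hits


def filter_by_coverage(hits: list[SimilarityHit],
                       min_cov: float = 0.5) -> list[SimilarityHit]:
    """Keep hits covering at least ``min_cov`` of BOTH sequences (inclusive)."""
    if not (0.0 <= min_cov <= 1.0):
        raise ValueError("min_cov must be within [0, 1]")
    return [h for h in hits if h.q_cov >= min_cov and h.s_cov >= min_cov]


def symmetric_best_hits(hits: list[SimilarityHit], meta: list[GenomeMeta],
                        ) -> list[tuple[str, str]]:
    """Undirected reciprocal-best-hit edges.

    For each query and each foreign genome the single best-scoring
    subject is retained (score ties broken by lexicographically smaller
    subject id); an edge exists iff the choice is mutual.
    """
    genome = {m.seq_id: m.genome_id for m in meta}
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for h in hits:
        g_subject = genome[h.subject]
        if genome[h.query] == g_subject:
            continue
        key = (h.query, g_subject)
        cur = best.get(key)
        # higher score wins; on a tie the smaller subject id wins
        if cur is None or (h.score, _neg(h.subject)) > (cur[0], _neg(cur[1])):
            best[key] = (h.score, h.subject)
    edges = set()
    for (query, _), (_, subject) in best.items():
        back = best.get((subject, genome[query]))
        if back is not None and back[1] == query:
            edges.add((min(query, subject), max(query, subject)))
    return sorted(edges)


class _NegStr(str):
    """Reverses comparison order so min-id wins inside a max-comparison."""
    def __lt__(self, other):
        return str.__gt__(self, other)
    def __gt__(self, other):
        return str.__lt__(self, other)


def _neg(s: str) -> _NegStr:
    return _NegStr(s)


def triangle_clusters(edges: list[tuple[str, str]], meta: list[GenomeMeta],
                      id_prefix: str = "MC") -> ClusterSet:
    """Merge 3-genome RBH triangles sharing an edge into initial clusters."""
    genome = {m.seq_id: m.genome_id for m in meta}
    adjacency: dict[str, set[str]] = defaultdict(set)
    for a, b in edges:
        adjacency[a].add(b)
        adjacency[b].add(a)
    triangles = []
    for a, b in sorted({(min(a, b), max(a, b)) for a, b in edges}):
        for c in sorted(adjacency[a] & adjacency[b]):
            if c <= b:
                continue  # enumerate each triangle once (a < b < c)
            if len({genome[a], genome[b], genome[c]}) == 3:
                triangles.append((a, b, c))
    # union-find over triangles: two triangles merge iff they share an edge
    parent = list(range(len(triangles)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    edge_owner: dict[tuple[str, str], int] = {}
    for idx, tri in enumerate(triangles):
        for pair in itertools.combinations(tri, 2):
            if pair in edge_owner:
                union(edge_owner[pair], idx)
            else:
                edge_owner[pair] = idx
    components: dict[int, set[str]] = defaultdict(set)
    for idx, tri in enumerate(triangles):
        components[find(idx)].update(tri)
    # components sharing a member (triangles joined only through a vertex)
    # are merged as well so the result is a disjoint cluster set
    member_sets = _merge_overlapping(list(components.values()))
    member_sets = sorted(member_sets, key=lambda s: sorted(s)[0])
    clusters = [Cluster(f"{id_prefix}{i:04d}", members, "triangle")
                for i, members in enumerate(member_sets, start=1)]
    return ClusterSet(clusters)


def _merge_overlapping(sets: list[set[str]]) -> list[set[str]]:
    owner: dict[str, int] = {}
    parent = list(range(len(sets)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for idx, members in enumerate(sets):
        for m in members:
            if m in owner:
                ri, rj = find(owner[m]), find(idx)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
            else:
                owner[m] = idx
    merged: dict[int, set[str]] = defaultdict(set)
    for idx, members in enumerate(sets):
        merged[find(idx)] |= members
    return list(merged.values())


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def align_cluster(cluster: Cluster, records: dict[str, SequenceRecord] | list,
                  external_alignment: dict[str, str] | None = None,
                  substitution_matrix="BLOSUM62",
                  gap_open: float = 11, gap_extend: float = 1,
                  ) -> dict[str, str]:
    """Multiple alignment of a cluster's members.

    When ``external_alignment`` is given it must cover exactly the
    members and is validated and returned.  Otherwise a center-star
    alignment is built: the star is the member with the largest summed
    pairwise local score, every member is aligned globally to the star,
    and the pairwise alignments are merged by gap propagation.
    """
    recmap = _as_map(records)
    members = sorted(cluster.members)
    missing = [m for m in members if m not in recmap]
    if missing:
        raise ValueError(f"cluster {cluster.cluster_id!r}: no sequence for {missing}")

    if external_alignment is not None:
        extra = set(external_alignment) - set(members)
        absent = set(members) - set(external_alignment)
        if extra or absent:
            raise ValueError(
                f"external alignment for {cluster.cluster_id!r} mismatches "
                f"members (missing {sorted(absent)}, extra {sorted(extra)})")
        lengths = {len(row) for row in external_alignment.values()}
        if len(lengths) != 1:
            raise ValueError("external alignment rows differ in length")
        for m in members:
            if external_alignment[m].replace("-", "") != recmap[m].residues:
                raise ValueError(
                    f"external alignment row for {m!r} does not match its sequence")
        return {m: external_alignment[m] for m in members}

    if len(members) == 1:
        return {members[0]: recmap[members[0]].residues}

    local = make_aligner(substitution_matrix, gap_open, gap_extend, mode="local")
    # star: maximal summed pairwise local score, lexicographic tie-break
    totals = {m: 0.0 for m in members}
    for a, b in itertools.combinations(members, 2):
        s, _, _ = local_align(local, recmap[a].residues, recmap[b].residues)
        totals[a] += s
        totals[b] += s
    star = max(members, key=lambda m: (totals[m], _neg(m)))
    others = [m for m in members if m != star]

    glob = make_aligner(substitution_matrix, gap_open, gap_extend, mode="global")
    alphabet = glob.substitution_matrix.alphabet
    star_seq = recmap[star].residues
    per_member: dict[str, list[list[str]]] = {}
    n_slots = len(star_seq) + 1  # insertions before star residue k (k = L: after)
    for m in others:
        aln = glob.align(_sanitize(star_seq, alphabet),
                         _sanitize(recmap[m].residues, alphabet))[0]
        s_row, m_row = str(aln[0]), str(aln[1])
        m_row = _restore(m_row, recmap[m].residues)
        slots = [[] for _ in range(n_slots)]
        aligned = []  # other-row char aligned with each star residue
        k = 0
        for sc, mc in zip(s_row, m_row):
            if sc == "-":
                slots[k].append(mc)
            else:
                aligned.append(mc)
                k += 1
        per_member[m] = [slots, aligned]

    ins = [0] * n_slots
    for slots, _ in per_member.values():
        for k in range(n_slots):
            ins[k] = max(ins[k], len(slots[k]))

    out: dict[str, str] = {}
    star_chars = []
    for k in range(len(star_seq)):
        star_chars.append("-" * ins[k] + star_seq[k])
    star_chars.append("-" * ins[-1])
    out[star] = "".join(star_chars)
    for m in others:
        slots, aligned = per_member[m]
        chars = []
        for k in range(len(star_seq)):
            chars.append("".join(slots[k]).ljust(ins[k], "-") + aligned[k])
        chars.append("".join(slots[-1]).ljust(ins[-1], "-"))
        out[m] = "".join(chars)
    return {m: out[m] for m in members}


def _sanitize(seq, alphabet):
    allowed = set(alphabet)
    return "".join(c if c in allowed else "X" for c in seq.upper())


def _restore(gapped_sanitized: str, original: str) -> str:
    chars = []
    it = iter(original)
    for c in gapped_sanitized:
        chars.append("-" if c == "-" else next(it))
    return "".join(chars)


def build_profile(alignment: dict[str, str],
                  background: np.ndarray | None = None,
                  beta: float = 5.0,
                  max_gap_fraction: float = 0.5) -> Profile:
    """Log-odds PSSM from a multiple alignment.

    Columns with gap fraction strictly above ``max_gap_fraction`` are
    excluded (the boundary is inclusive).  Per retained column,
    ``score(c) = log2(((n_c + beta*b_c) / (N + beta)) / b_c)`` with
    ``n_c`` the residue count, ``N`` the non-gap count and ``b_c`` the
    background frequency; with ``beta = 0`` absent residues are floored
    at a large negative constant instead of -inf.
    """
    if not alignment:
        raise ValueError("empty alignment")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if background is None:
        background = DEFAULT_BACKGROUND
    background = np.asarray(background, dtype=float)
    rows = list(alignment.values())
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows differ in length")
    columns = []
    kept = []
    for j in range(width):
        col = [r[j] for r in rows]
        gap_fraction = col.count("-") / len(col)
        if gap_fraction > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for c in col:
            idx = AA_ORDER.find(c)
            if idx >= 0:
                counts[idx] += 1
        n_total = counts.sum()  # non-gap, standard residues (X excluded)
        if n_total == 0:
            continue
        freq = (counts + beta * background) / (n_total + beta)
        with np.errstate(divide="ignore"):
            scores = np.log2(freq / background)
        scores = np.maximum(scores, SCORE_FLOOR)
        columns.append(scores)
        kept.append(j)
    if not columns:
        raise ValueError("all alignment columns were excluded by the gap filter")
    return Profile(np.array(columns), background, beta, tuple(kept))


def profile_search(profile: Profile, records: list[SequenceRecord],
                   gap_open: float = 11, gap_extend: float = 1,
                   n_shuffles: int = 30, seed: int = 0,
                   ) -> list[ProfileHit]:
    """Score a profile against a database with empirical Gumbel e-values.

    Each database sequence is aligned to the profile; the null
    distribution pools the scores of ``n_shuffles`` residue-shuffled
    versions of every database sequence, a Gumbel is fitted by method
    of moments and ``e-value = len(records) * P(S >= s)``.
    """
    if profile.length == 0:
        raise ValueError("zero-length profile")
    if n_shuffles < 30:
        raise ValueError("n_shuffles must be >= 30")
    rng = np.random.default_rng(seed)
    coded = {r.seq_id: encode(r.residues) for r in records}
    real: dict[str, tuple[float, float, float]] = {}
    for r in records:
        score, (ps, pe), (ss, se) = sw_profile(
            profile.columns, coded[r.seq_id], gap_open, gap_extend)
        real[r.seq_id] = (score,
                          (pe - ps) / profile.length,
                          (se - ss) / r.length)
    null_scores = np.empty(len(records) * n_shuffles)
    k = 0
    for r in records:
        base = coded[r.seq_id]
        for _ in range(n_shuffles):
            shuffled = rng.permutation(base)
            s, _, _ = sw_profile(profile.columns, shuffled, gap_open, gap_extend)
            null_scores[k] = s
            k += 1
    mu, gum_beta = fit_gumbel(null_scores)
    n_db = len(records)
    hits = []
    for r in records:
        score, p_cov, s_cov = real[r.seq_id]
        evalue = float(n_db * gumbel_sf(score, mu, gum_beta))
        hits.append(ProfileHit(r.seq_id, score, evalue, p_cov, s_cov))
    hits.sort(key=lambda h: (-h.score, h.seq_id))
    return hits


# ---------------------------------------------------------------------------
# expansion, merging, orphans
# ---------------------------------------------------------------------------

def _cluster_profiles(clusters: ClusterSet, recmap: dict[str, SequenceRecord],
                      external_alignments, beta, max_gap_fraction,
                      substitution_matrix, gap_open, gap_extend,
                      ) -> dict[str, Profile]:
    profiles = {}
    for cid in sorted(clusters.clusters):
        cluster = clusters.clusters[cid]
        ext = (external_alignments or {}).get(cid)
        alignment = align_cluster(cluster, recmap, ext, substitution_matrix,
                                  gap_open, gap_extend)
        profiles[cid] = build_profile(alignment, beta=beta,
                                      max_gap_fraction=max_gap_fraction)
    return profiles


def expand_clusters(clusters: ClusterSet, records: list[SequenceRecord],
                    meta: list[GenomeMeta], e_threshold: float = 0.01,
                    *, beta: float = 5.0, max_gap_fraction: float = 0.5,
                    substitution_matrix="BLOSUM62",
                    gap_open: float = 11, gap_extend: float = 1,
                    n_shuffles: int = 30, seed: int = 0,
                    external_alignments: dict[str, dict[str, str]] | None = None,
                    ) -> ClusterSet:
    """Recruit unassigned sequences to their best-matching cluster profile.

    Every unassigned sequence with at least one profile hit at
    ``e <= e_threshold`` joins the cluster giving its best hit (lowest
    e-value, then highest score, then smallest cluster id).  Assigned
    sequences never move.
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be positive")
    recmap = _as_map(records)
    out = clusters.copy()
    unassigned = sorted(set(recmap) - clusters.assigned())
    if not unassigned:
        return out
    profiles = _cluster_profiles(clusters, recmap, external_alignments,
                                 beta, max_gap_fraction, substitution_matrix,
                                 gap_open, gap_extend)
    best: dict[str, tuple[float, float, str]] = {}
    for cid, profile in profiles.items():
        for hit in profile_search(profile, records, gap_open, gap_extend,
                                  n_shuffles, seed):
            if hit.seq_id not in clusters.assigned() and hit.evalue <= e_threshold:
                cand = (hit.evalue, -hit.score, cid)
                if hit.seq_id not in best or cand < best[hit.seq_id]:
                    best[hit.seq_id] = cand
    for seq_id in unassigned:
        if seq_id in best:
            out.add_member(best[seq_id][2], seq_id, "expansion")
    return out


def merge_clusters(clusters: ClusterSet, records: list[SequenceRecord],
                   e_threshold: float = 0.01,
                   *, beta: float = 5.0, max_gap_fraction: float = 0.5,
                   substitution_matrix="BLOSUM62",
                   gap_open: float = 11, gap_extend: float = 1,
                   n_shuffles: int = 30, seed: int = 0,
                   max_rounds: int = 50) -> ClusterSet:
    """Iteratively merge clusters that are each other's best profile match.

    Per round: rebuild every cluster's profile, search all clustered
    sequences, keep hits at ``e <= e_threshold`` to sequences of OTHER
    clusters, average the scores per hit cluster, let each cluster
    nominate its best-mean partner (ties to the smaller cluster id) and
    merge reciprocal nominations pairwise (smallest id pair first when
    chains occur).  Terminates because the cluster count strictly
    decreases whenever a merge happens.
    """
    if len(clusters) == 0:
        raise ValueError("need at least one cluster")
    recmap = _as_map(records)
    current = clusters.copy()
    for _ in range(max_rounds):
        if len(current) < 2:
            break
        assignment = current.assignment
        database = [recmap[s] for s in sorted(assignment)]
        profiles = _cluster_profiles(current, recmap, None, beta,
                                     max_gap_fraction, substitution_matrix,
                                     gap_open, gap_extend)
        nomination: dict[str, str] = {}
        for cid, profile in profiles.items():
            by_cluster: dict[str, list[float]] = defaultdict(list)
            for hit in profile_search(profile, database, gap_open, gap_extend,
                                      n_shuffles, seed):
                if hit.evalue > e_threshold:
                    continue
                target = assignment[hit.seq_id]
                if target == cid:
                    continue  # self-cluster hits discarded
                by_cluster[target].append(hit.score)
            if by_cluster:
                means = {t: float(np.mean(v)) for t, v in by_cluster.items()}
                nomination[cid] = max(sorted(means), key=lambda t: (means[t], _neg(t)))
        pairs = sorted(
            {tuple(sorted((a, b))) for a, b in nomination.items()
             if nomination.get(b) == a}
        )
        if not pairs:
            break
        merged_this_round: set[str] = set()
        for keep, drop in pairs:
            if keep in merged_this_round or drop in merged_this_round:
                continue  # pairwise merging only, chains wait a round
            current = _merge_pair(current, keep, drop)
            merged_this_round.update((keep, drop))
    return current


def _merge_pair(clusters: ClusterSet, keep: str, drop: str) -> ClusterSet:
    out_clusters = []
    for cid, cluster in clusters.clusters.items():
        if cid == drop:
            continue
        members = set(cluster.members)
        origin = cluster.origin
        if cid == keep:
            members |= clusters.clusters[drop].members
            origin = "merge"
        out_clusters.append(Cluster(cid, members, origin))
    return ClusterSet(out_clusters, dict(clusters.member_origin))


def read_curated_tsv(path) -> dict[str, str]:
    """Read a curated-membership TSV (seq_id <tab> cluster_id)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns[:2]) != ["seq_id", "cluster_id"]:
        frame.columns = ["seq_id", "cluster_id"] + list(frame.columns[2:])
    mapping: dict[str, str] = {}
    for _, row in frame.iterrows():
        sid, cid = row["seq_id"], row["cluster_id"]
        if sid in mapping and mapping[sid] != cid:
            raise ValueError(
                f"curated file assigns {sid!r} to both {mapping[sid]!r} and {cid!r}")
        mapping[sid] = cid
    return mapping


def add_orphan_clusters(clusters: ClusterSet, records: list[SequenceRecord],
                        meta: list[GenomeMeta],
                        curated: dict[str, str] | None = None) -> ClusterSet:
    """Assign every remaining sequence so the result partitions the input.

    Sequences named in ``curated`` (seq_id -> cluster_id) join or found
    the named cluster with origin ``curated``; all other unassigned
    sequences become singleton clusters with origin ``orphan``.
    """
    recmap = _as_map(records)
    out = clusters.copy()
    curated = dict(curated or {})
    for seq_id in sorted(set(recmap) - clusters.assigned()):
        if seq_id in curated:
            cid = curated[seq_id]
            if cid in out.clusters:
                out.add_member(cid, seq_id, "curated")
            else:
                out._add_cluster(Cluster(cid, {seq_id}, "curated"))
        else:
            out._add_cluster(Cluster(f"orphan_{seq_id}", {seq_id}, "orphan"))
    return out


def _as_map(records) -> dict[str, SequenceRecord]:
    if isinstance(records, dict):
        return records
    return {r.seq_id: r for r in records}
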