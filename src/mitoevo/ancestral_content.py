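"""Ancestral gene content under a pure-loss birth-and-death model,
and Dollo parsimony for arbitrary binary characters.

Model
-----
A gene family present at the root survives each branch independently:
on the branch above node *c* it is lost with probability ``q_c``.  Gains
never occur, so a family absent at a node is absent in the entire
subtree below it.  The number of families at the root is Poisson with
intensity ``lam``; conditioning on a family being observed in at least
one extant genome corrects for unobservable (all-zero) families, and
the Poisson thins neatly so the correction only involves
``E0 = P(all leaves 0 | present at root)``.

Branch loss probabilities are estimated by EM: the E-step computes
expected per-branch loss events from an up-down (inside-outside) pass,
including the expected contribution of unobserved families
(``F * E0 / (1 - E0)`` phantom all-zero profiles), and the M-step sets
``q_b = E[losses on b] / E[present at parent of b]``.  The conditional
log-likelihood is non-decreasing across iterations.

Dollo parsimony assumes each character was gained exactly once, at the
last common ancestor of the leaves carrying it, and lost as few times
as possible; this placement and the induced loss set are optimal among
all single-gain scenarios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import PhyleticMatrix
from .trees import RootedTree, TreeNode


# ---------------------------------------------------------------------------
# model containers
# ---------------------------------------------------------------------------

@dataclass
class LossModel:
    """Pure-loss model: per-branch loss probabilities and a Poisson root."""

    tree: RootedTree
    q: dict[str, float]  # keyed by the child node id of each branch
    lam: float = 1.0

    def __post_init__(self):
        non_root = [n.id for n in self.tree.preorder() if n.parent is not None]
        missing = set(non_root) - set(self.q)
        if missing:
            raise ValueError(f"no loss probability for branches above {sorted(missing)}")
        for node_id, value in self.q.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"q[{node_id!r}] = {value} outside [0, 1]")
        if self.lam <= 0:
            raise ValueError("Poisson intensity must be positive")

    def to_json_dict(self) -> dict:
        return {"lambda": self.lam, "q": dict(sorted(self.q.items())),
                "tree": self.tree.to_newick()}


@dataclass
class FitResult:
    model: LossModel
    log_likelihood: float
    n_iter: int
    converged: bool
    trajectory: list[float] = field(default_factory=list)


@dataclass
class PosteriorReconstruction:
    """Posterior presence per node and expected per-branch losses."""

    posteriors: pd.DataFrame     # families x node ids (all nodes)
    branch_losses: pd.DataFrame  # families x non-root node ids
    log_likelihoods: pd.Series   # per family, conditional on observation

    @property
    def expected_counts(self) -> pd.Series:
        """Expected gene count per node (sum of posteriors over families)."""
        return self.posteriors.sum(axis=0)


# ---------------------------------------------------------------------------
# pruning and up-down passes (vectorised over families)
# ---------------------------------------------------------------------------

def _observations(tree: RootedTree, matrix: PhyleticMatrix) -> np.ndarray:
    leaf_names = tree.leaf_names()
    if set(leaf_names) != set(matrix.species_ids):
        raise ValueError(
            "matrix species do not match tree leaves: "
            f"only-in-matrix {sorted(set(matrix.species_ids) - set(leaf_names))}, "
            f"only-in-tree {sorted(set(leaf_names) - set(matrix.species_ids))}")
    return matrix.frame[leaf_names].to_numpy(dtype=float), leaf_names


def _downward(tree: RootedTree, q: dict[str, float], obs: np.ndarray,
              leaf_names: list[str]):
    """Post-order partial likelihoods D0, D1 per node, arrays over families."""
    col = {name: j for j, name in enumerate(leaf_names)}
    D0: dict[str, np.ndarray] = {}
    D1: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            x = obs[:, col[node.name]]
            D1[node.id] = x
            D0[node.id] = 1.0 - x
        else:
            d0 = np.ones(obs.shape[0])
            d1 = np.ones(obs.shape[0])
            for child in node.children:
                qc = q[child.id]
                d0 = d0 * D0[child.id]
                d1 = d1 * (qc * D0[child.id] + (1.0 - qc) * D1[child.id])
            D0[node.id] = d0
            D1[node.id] = d1
    return D0, D1


def _upward(tree: RootedTree, q: dict[str, float],
            D0: dict[str, np.ndarray], D1: dict[str, np.ndarray],
            n_families: int):
    """Pre-order outside partials conditional on the root being present.

    A1[v] (A0[v]) = P(data outside subtree(v), state(v)=1 (0) | root=1).
    """
    A1 = {tree.root.id: np.ones(n_families)}
    A0 = {tree.root.id: np.zeros(n_families)}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        children = node.children
        m1 = [q[c.id] * D0[c.id] + (1.0 - q[c.id]) * D1[c.id] for c in children]
        m0 = [D0[c.id] for c in children]
        # prefix/suffix products over siblings (no division: zeros are common)
        k = len(children)
        pre1 = [np.ones(n_families)]
        pre0 = [np.ones(n_families)]
        for i in range(k - 1):
            pre1.append(pre1[-1] * m1[i])
            pre0.append(pre0[-1] * m0[i])
        suf1 = [np.ones(n_families)] * k
        suf0 = [np.ones(n_families)] * k
        acc1 = np.ones(n_families)
        acc0 = np.ones(n_families)
        for i in range(k - 1, -1, -1):
            suf1[i] = acc1
            suf0[i] = acc0
            acc1 = acc1 * m1[i]
            acc0 = acc0 * m0[i]
        for i, child in enumerate(children):
            sib1 = pre1[i] * suf1[i]
            sib0 = pre0[i] * suf0[i]
            above1 = A1[node.id] * sib1  # parent present, siblings integrated
            above0 = A0[node.id] * sib0
            qc = q[child.id]
            A1[child.id] = above1 * (1.0 - qc)
            A0[child.id] = above1 * qc + above0
    return A1, A0


def profile_likelihood(model: LossModel, profile: dict[str, int]) -> float:
    """P(leaf pattern | family present at root) by pruning."""
    leaf_names = model.tree.leaf_names()
    missing = set(leaf_names) ^ set(profile)
    if missing:
        raise ValueError(f"profile does not match tree leaves: {sorted(missing)}")
    obs = np.array([[float(profile[name]) for name in leaf_names]])
    _, D1 = _downward(model.tree, model.q, obs, leaf_names)
    return float(D1[model.tree.root.id][0])


def _unobservable_prob(tree: RootedTree, q: dict[str, float]) -> float:
    """E0 = P(all leaves absent | present at root)."""
    leaf_names = tree.leaf_names()
    zeros = np.zeros((1, len(leaf_names)))
    _, D1 = _downward(tree, q, zeros, leaf_names)
    return float(D1[tree.root.id][0])


def _branch_expectations(tree: RootedTree, q: dict[str, float],
                         obs: np.ndarray, leaf_names: list[str]):
    """Per-family likelihoods, posteriors and expected branch losses."""
    n_fam = obs.shape[0]
    D0, D1 = _downward(tree, q, obs, leaf_names)
    L = D1[tree.root.id]
    A1, A0 = _upward(tree, q, D0, D1, n_fam)
    post1 = {}
    loss = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for node in tree.preorder():
            p1 = np.where(L > 0, A1[node.id] * D1[node.id] / np.where(L > 0, L, 1.0), 0.0)
            post1[node.id] = np.clip(p1, 0.0, 1.0)
        for node in tree.preorder():
            if node.parent is None:
                continue
            qc = q[node.id]
            if qc < 1.0:
                above1 = A1[node.id] / (1.0 - qc)
            else:
                above1 = _above1_direct(tree, q, D0, D1, A1, A0, node, n_fam)
            joint = above1 * qc * D0[node.id]
            loss[node.id] = np.clip(
                np.where(L > 0, joint / np.where(L > 0, L, 1.0), 0.0), 0.0, 1.0)
    return L, post1, loss


def _above1_direct(tree, q, D0, D1, A1, A0, node, n_fam):
    """Outside partial with parent present, recomputed without dividing by 1-q."""
    parent = node.parent
    sib1 = np.ones(n_fam)
    for sibling in parent.children:
        if sibling is node:
            continue
        qs = q[sibling.id]
        sib1 = sib1 * (qs * D0[sibling.id] + (1.0 - qs) * D1[sibling.id])
    return A1[parent.id] * sib1


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def fit_pure_loss(tree: RootedTree, matrix: PhyleticMatrix,
                  tol: float = 1e-8, max_iter: int = 500,
                  seed: int | None = None,
                  init_q: float | dict[str, float] | None = None) -> FitResult:
    """Maximum-likelihood branch loss probabilities by EM.

    Maximises the observability-corrected log-likelihood
    ``sum_f log(L_f / (1 - E0))`` over per-branch ``q``.  Families with
    all-zero profiles violate the observability assumption and raise.
    The fitted Poisson intensity is ``lam = F / (1 - E0)``.

    ``init_q`` may be a scalar, a per-branch dict, or None: branch
    lengths (when present on every branch) initialise ``q = 1 - e^-l``,
    otherwise a flat 0.2 (or a seeded uniform draw when ``seed`` is
    given).
    """
    obs, leaf_names = _observations(tree, matrix)
    empty = np.where(obs.sum(axis=1) == 0)[0]
    if empty.size:
        fam = matrix.family_ids[empty[0]]
        raise ValueError(
            f"family {fam!r} is absent from every leaf; the pure-loss model "
            "conditions on observed families")
    n_fam = obs.shape[0]
    branches = [n.id for n in tree.preorder() if n.parent is not None]
    q = _initial_q(tree, branches, init_q, seed)

    trajectory: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        L, post1, loss = _branch_expectations(tree, q, obs, leaf_names)
        e0 = _unobservable_prob(tree, q)
        if np.any(L <= 0):
            raise FloatingPointError("zero likelihood during EM; bad initial q")
        ll = float(np.log(L).sum() - n_fam * math.log1p(-e0)) if e0 < 1 else -math.inf
        trajectory.append(ll)
        # phantom all-zero families
        weight = n_fam * e0 / (1.0 - e0) if e0 < 1.0 else 0.0
        if weight > 0:
            zeros = np.zeros((1, len(leaf_names)))
            _, post1_z, loss_z = _branch_expectations(tree, q, zeros, leaf_names)
        new_q = {}
        parent_of = {n.id: n.parent for n in tree.preorder() if n.parent is not None}
        for b in branches:
            num = float(loss[b].sum())
            den = float(post1[parent_of[b].id].sum())
            if weight > 0:
                num += weight * float(loss_z[b][0])
                den += weight * float(post1_z[parent_of[b].id][0])
            new_q[b] = min(1.0, max(0.0, num / den)) if den > 0 else q[b]
        if len(trajectory) > 1 and abs(trajectory[-1] - trajectory[-2]) < tol:
            q = new_q
            converged = True
            break
        q = new_q
    e0 = _unobservable_prob(tree, q)
    lam = n_fam / (1.0 - e0) if e0 < 1.0 else float("inf")
    model = LossModel(tree=tree, q=q, lam=lam)
    L, _, _ = _branch_expectations(tree, q, obs, leaf_names)
    final_ll = float(np.log(L).sum() - n_fam * math.log1p(-e0)) if e0 < 1 else -math.inf
    return FitResult(model, final_ll, n_iter, converged, trajectory)


def _initial_q(tree, branches, init_q, seed):
    if isinstance(init_q, dict):
        return {b: float(init_q[b]) for b in branches}
    if init_q is not None:
        return {b: float(init_q) for b in branches}
    lengths = {n.id: n.length for n in tree.preorder() if n.parent is not None}
    if all(v is not None for v in lengths.values()):
        return {b: min(0.95, max(0.02, 1.0 - math.exp(-lengths[b])))
                for b in branches}
    if seed is not None:
        rng = np.random.default_rng(seed)
        return {b: float(rng.uniform(0.05, 0.5)) for b in branches}
    return {b: 0.2 for b in branches}


def node_posteriors(model: LossModel, matrix: PhyleticMatrix,
                    ) -> PosteriorReconstruction:
    """Posterior presence per node and expected per-branch loss events.

    Under pure loss any node on a path between two present leaves, or
    between the root and a present leaf, has posterior exactly 1; the
    root posterior is 1 for every observed family, so the expected root
    count equals the number of observed families.
    """
    obs, leaf_names = _observations(model.tree, matrix)
    L, post1, loss = _branch_expectations(model.tree, model.q, obs, leaf_names)
    # analytic exactness: a node with a present descendant leaf is forced
    # present (gains are impossible), so its posterior is exactly 1
    col = {name: j for j, name in enumerate(leaf_names)}
    has_present: dict[str, np.ndarray] = {}
    for node in model.tree.postorder():
        if node.is_leaf:
            has_present[node.id] = obs[:, col[node.name]] > 0
        else:
            flag = np.zeros(obs.shape[0], dtype=bool)
            for child in node.children:
                flag |= has_present[child.id]
            has_present[node.id] = flag
    for node_id, flag in has_present.items():
        post1[node_id] = np.where(flag, 1.0, post1[node_id])
    node_ids = [n.id for n in model.tree.preorder()]
    posteriors = pd.DataFrame(
        {nid: post1[nid] for nid in node_ids}, index=matrix.family_ids)
    branch_ids = [n.id for n in model.tree.preorder() if n.parent is not None]
    branch_losses = pd.DataFrame(
        {nid: loss[nid] for nid in branch_ids}, index=matrix.family_ids)
    e0 = _unobservable_prob(model.tree, model.q)
    with np.errstate(divide="ignore"):
        ll = np.log(L) - math.log1p(-e0)
    return PosteriorReconstruction(posteriors, branch_losses,
                                   pd.Series(ll, index=matrix.family_ids))


# ---------------------------------------------------------------------------
# loss propensity
# ---------------------------------------------------------------------------

def loss_propensity(reconstruction: PosteriorReconstruction,
                    mode: str = "expected") -> pd.Series:
    """Number of lineages that lost each family.

    ``expected``: sum over branches of P(present at parent, absent at
    child | data).  ``thresholded``: count of branches whose loss
    posterior exceeds 0.5.
    """
    if mode == "expected":
        return reconstruction.branch_losses.sum(axis=1)
    if mode == "thresholded":
        return (reconstruction.branch_losses > 0.5).sum(axis=1).astype(float)
    raise ValueError(f"unknown mode {mode!r}")


def complex_propensity(loss_counts: pd.Series,
                       family_groups: dict[str, list[str]]) -> dict[str, float]:
    """Mean loss-lineage count per functional group (e.g. a complex)."""
    out = {}
    for group, families in family_groups.items():
        if not families:
            raise ValueError(f"group {group!r} is empty")
        missing = [f for f in families if f not in loss_counts.index]
        if missing:
            raise ValueError(f"group {group!r}: unknown families {missing}")
        out[group] = float(loss_counts.loc[list(families)].mean())
    return out


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharacterHistory:
    character_id: str
    gain_node: str | None  # None for all-absent characters
    loss_branches: tuple[str, ...]
    states: dict[str, int]


@dataclass
class DolloScenario:
    tree: RootedTree
    characters: list[CharacterHistory]

    def n_losses(self) -> int:
        return sum(len(c.loss_branches) for c in self.characters)


def dollo_reconstruct(tree: RootedTree, matrix: PhyleticMatrix) -> DolloScenario:
    """Single-gain / minimal-loss reconstruction of binary characters.

    The gain is placed at the last common ancestor of the present
    leaves; an internal node is in state 1 iff it lies inside the gain
    clade and has at least one present descendant leaf.  Losses are the
    branches from a state-1 parent to a state-0 child.  All-absent
    characters get no gain and no losses (``gain_node`` is None).
    """
    obs, leaf_names = _observations(tree, matrix)
    histories: list[CharacterHistory] = []
    col = {name: j for j, name in enumerate(leaf_names)}
    for i, character_id in enumerate(matrix.family_ids):
        present = [name for name in leaf_names if obs[i, col[name]] > 0]
        if not present:
            histories.append(CharacterHistory(
                character_id, None, (),
                {n.id: 0 for n in tree.preorder()}))
            continue
        gain = tree.mrca(present)
        present_set = set(present)
        has_present: dict[str, bool] = {}
        for node in tree.postorder():
            if node.is_leaf:
                has_present[node.id] = node.name in present_set
            else:
                has_present[node.id] = any(has_present[c.id] for c in node.children)
        in_gain_clade: dict[str, bool] = {}
        states: dict[str, int] = {}
        for node in tree.preorder():
            inside = (node is gain) or (
                node.parent is not None and in_gain_clade.get(node.parent.id, False))
            in_gain_clade[node.id] = inside
            states[node.id] = 1 if inside and has_present[node.id] else 0
        losses = tuple(sorted(
            node.id for node in tree.preorder()
            if node.parent is not None
            and states[node.parent.id] == 1 and states[node.id] == 0))
        histories.append(CharacterHistory(character_id, gain.id, losses, states))
    return DolloScenario(tree, histories)


def branch_event_table(scenario: DolloScenario) -> pd.DataFrame:
    """Per-branch totals of gains and losses across characters.

    Indexed by node id (the branch above that node); gains at the root
    are recorded on the root's row.
    """
    node_ids = [n.id for n in scenario.tree.preorder()]
    table = pd.DataFrame(0, index=node_ids, columns=["gains", "losses"])
    for ch in scenario.characters:
        if ch.gain_node is not None:
            table.loc[ch.gain_node, "gains"] += 1
        for b in ch.loss_branches:
            table.loc[b, "losses"] += 1
    return table
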