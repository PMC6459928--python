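"""Per-patient sample phylogenies from binary mutation presence.

Each patient's mutations are converted to a binary presence table
(VAF >= 2% and >= 2 supporting reads), and a rooted sample tree is
inferred by exhaustive maximum parsimony under an asymmetric binary
character model: a 0->1 gain costs 1, a 1->0 reversal costs 10
(somatic point mutations are effectively irreversible).  The root is
the germline with an all-zero profile.  On perfect-phylogeny input
the optimal score equals the number of mutations and every mutation
has a unique gain edge.

Timing follows the presence pattern: trunk = present in every tumor
sample, private = present in exactly one, shared branch = the rest.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import MutationRecord, SampleType

log = logging.getLogger(__name__)

MAX_EXHAUSTIVE_LEAVES = 9
GAIN_COST = 1.0
REVERSAL_COST = 10.0
_INF = 1e18


# ---------------------------------------------------------------- presence

@dataclass
class PresenceMatrix:
    """Binary mutation x sample presence table with VAFs alongside."""

    presence: pd.DataFrame  # bool, rows = mutation ids, cols = sample ids
    vaf: pd.DataFrame

    @property
    def samples(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.presence.index)


def build_presence_matrix(
    records: list[MutationRecord],
    samples: list[str],
    vaf_min: float = 0.02,
    min_alt: int = 2,
) -> PresenceMatrix:
    """Binary table: present iff VAF >= vaf_min and alt reads >= min_alt.

    Rows that are absent everywhere are dropped with a warning.
    """
    if len(samples) < 2:
        raise ValueError("need >= 2 tumor samples to build a presence matrix")
    pres = np.zeros((len(records), len(samples)), dtype=bool)
    vafs = np.zeros((len(records), len(samples)))
    for i, rec in enumerate(records):
        for j, s in enumerate(samples):
            counts = rec.per_sample_counts.get(s)
            if counts is None:
                continue
            vafs[i, j] = counts.vaf
            pres[i, j] = counts.vaf >= vaf_min and counts.alt >= min_alt
    ids = [r.mutation_id for r in records]
    presence = pd.DataFrame(pres, index=ids, columns=samples)
    vaf = pd.DataFrame(vafs, index=ids, columns=samples)
    empty = ~presence.any(axis=1)
    if empty.any():
        log.warning("dropping %d mutations unsupported in every sample",
                    int(empty.sum()))
        presence, vaf = presence[~empty], vaf[~empty]
    return PresenceMatrix(presence, vaf)


# ---------------------------------------------------------------- topology

def _insertions(tree, leaf):
    yield (tree, leaf)
    if isinstance(tree, tuple):
        left, right = tree
        for t in _insertions(left, leaf):
            yield (t, right)
        for t in _insertions(right, leaf):
            yield (left, t)


def enumerate_topologies(leaves: list[str]):
    """All rooted binary leaf topologies as nested 2-tuples ((2n-3)!! trees)."""
    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t for base in trees for t in _insertions(base, leaf)]
    return trees


def _leafset(tree) -> frozenset:
    if not isinstance(tree, tuple):
        return frozenset([tree])
    return _leafset(tree[0]) | _leafset(tree[1])


def tree_clades(tree) -> list[frozenset]:
    """Clades (leaf sets below each edge) of a nested-tuple topology,
    including the trunk clade (all leaves)."""
    out = []

    def walk(node):
        ls = _leafset(node)
        out.append(ls)
        if isinstance(node, tuple):
            walk(node[0])
            walk(node[1])
        return ls

    walk(tree)
    return out


def _canonical_newick(tree) -> str:
    if not isinstance(tree, tuple):
        return tree
    parts = sorted([_canonical_newick(tree[0]), _canonical_newick(tree[1])])
    return f"({parts[0]},{parts[1]})"


# ---------------------------------------------------------------- parsimony

def _sankoff_costs(tree, col_of: dict, matrix: np.ndarray, cache: dict):
    """Bottom-up Sankoff cost arrays, shape (m, 2) per node."""
    if not isinstance(tree, tuple):
        m = matrix.shape[0]
        c = np.full((m, 2), _INF)
        obs = matrix[:, col_of[tree]].astype(int)
        c[np.arange(m), obs] = 0.0
        cache[id(tree)] = (tree, c)
        return c
    cl = _sankoff_costs(tree[0], col_of, matrix, cache)
    cr = _sankoff_costs(tree[1], col_of, matrix, cache)
    c = np.empty_like(cl)
    # parent state 0: child keeps 0 free or gains at GAIN_COST
    c[:, 0] = (np.minimum(cl[:, 0], cl[:, 1] + GAIN_COST)
               + np.minimum(cr[:, 0], cr[:, 1] + GAIN_COST))
    # parent state 1: child keeps 1 free or reverts at REVERSAL_COST
    c[:, 1] = (np.minimum(cl[:, 0] + REVERSAL_COST, cl[:, 1])
               + np.minimum(cr[:, 0] + REVERSAL_COST, cr[:, 1]))
    cache[id(tree)] = (tree, c)
    return c


def parsimony_score(tree, matrix: pd.DataFrame) -> float:
    """Total character-change cost of a topology rooted at germline (all-0)."""
    col_of = {s: j for j, s in enumerate(matrix.columns)}
    m = matrix.to_numpy().astype(bool)
    c = _sankoff_costs(tree, col_of, m, {})
    per_char = np.minimum(c[:, 0], c[:, 1] + GAIN_COST)
    return float(per_char.sum())


def _assign_states(tree, parent_state: np.ndarray, cache: dict,
                   states: dict) -> None:
    _, c = cache[id(tree)]
    m = c.shape[0]
    cost_same = c[np.arange(m), parent_state]
    switch_cost = np.where(parent_state == 0, GAIN_COST, REVERSAL_COST)
    cost_other = c[np.arange(m), 1 - parent_state] + switch_cost
    # prefer keeping the parent state on ties (fewest changes, gains latest)
    child_state = np.where(cost_other < cost_same, 1 - parent_state, parent_state)
    states[id(tree)] = (tree, child_state)
    if isinstance(tree, tuple):
        _assign_states(tree[0], child_state, cache, states)
        _assign_states(tree[1], child_state, cache, states)


@dataclass
class PhyloTree:
    """Rooted sample tree with per-edge mutation assignments.

    Edges are identified by their clade (the set of sample leaves
    below the edge); the trunk is the edge from the germline root to
    the first tree node, whose clade is the full sample set.
    """

    samples: list[str]
    topology: object  # nested 2-tuples of sample ids
    edge_mutations: dict[frozenset, list[str]]
    score: float
    n_co_optimal: int = 1
    multi_gain: set[str] = field(default_factory=set)

    @property
    def trunk_clade(self) -> frozenset:
        return frozenset(self.samples)

    @property
    def clades(self) -> list[frozenset]:
        return tree_clades(self.topology)

    def path_clades(self, sample: str) -> set[frozenset]:
        """Clades on the germline-to-leaf path of one sample."""
        return {c for c in self.clades if sample in c}

    def edge_length(self, clade: frozenset) -> int:
        return len(self.edge_mutations.get(clade, []))

    def to_newick(self, germline_label: str = "germline") -> str:
        def fmt(node):
            clade = _leafset(node)
            length = self.edge_length(clade)
            if not isinstance(node, tuple):
                return f"{node}:{length}"
            return f"({fmt(node[0])},{fmt(node[1])}):{length}"

        return f"({fmt(self.topology)}){germline_label};"


def _assign_mutations(tree, matrix: pd.DataFrame) -> tuple[dict, set]:
    """Map each mutation to the edge (clade) of its earliest gain."""
    col_of = {s: j for j, s in enumerate(matrix.columns)}
    m = matrix.to_numpy().astype(bool)
    cache: dict = {}
    _sankoff_costs(tree, col_of, m, cache)
    nmut = m.shape[0]
    states: dict = {}
    # germline parent state is all-zero; the top node's edge is the trunk
    _assign_states(tree, np.zeros(nmut, dtype=int), cache, states)

    gains: list[list[frozenset]] = [[] for _ in range(nmut)]

    def walk(node, parent_state):
        _, st = states[id(node)]
        gained = (st == 1) & (parent_state == 0)
        clade = _leafset(node)
        for i in np.where(gained)[0]:
            gains[i].append(clade)
        if isinstance(node, tuple):
            walk(node[0], st)
            walk(node[1], st)

    zero = np.zeros(nmut, dtype=int)
    # trunk edge: germline (0) -> top node
    walk(tree, zero)

    edge_mutations: dict[frozenset, list[str]] = {}
    multi = set()
    for i, mut_id in enumerate(matrix.index):
        if not gains[i]:
            continue  # never gained (all-absent row)
        # earliest (largest-clade) gain; parallel gains flagged
        best = max(gains[i], key=len)
        if len(gains[i]) > 1:
            multi.add(mut_id)
        edge_mutations.setdefault(best, []).append(mut_id)
    return edge_mutations, multi


def infer_parsimony_tree(
    matrix: PresenceMatrix,
) -> tuple[PhyloTree, list]:
    """Exhaustive maximum-parsimony sample tree.

    Enumerates every rooted leaf topology (feasible up to 9 samples),
    scores each under the asymmetric gain/reversal model, and returns
    the reported optimum plus the full co-optimal topology list.  Ties
    are broken by longest trunk, then lexicographic canonical form.
    """
    samples = matrix.samples
    if len(samples) > MAX_EXHAUSTIVE_LEAVES:
        raise ValueError(
            f"{len(samples)} samples exceeds the exhaustive-search bound "
            f"({MAX_EXHAUSTIVE_LEAVES}); heuristic search is not provided"
        )
    if len(samples) < 2:
        raise ValueError("need >= 2 samples")
    pres = matrix.presence
    best_score, co_optimal = np.inf, []
    for topo in enumerate_topologies(sorted(samples)):
        s = parsimony_score(topo, pres)
        if s < best_score - 1e-9:
            best_score, co_optimal = s, [topo]
        elif s <= best_score + 1e-9:
            co_optimal.append(topo)

    def report_key(topo):
        edge_muts, _ = _assign_mutations(topo, pres)
        trunk_len = len(edge_muts.get(frozenset(samples), []))
        return (-trunk_len, _canonical_newick(topo))

    chosen = min(co_optimal, key=report_key)
    edge_mutations, multi = _assign_mutations(chosen, pres)
    tree = PhyloTree(
        samples=sorted(samples),
        topology=chosen,
        edge_mutations=edge_mutations,
        score=best_score,
        n_co_optimal=len(co_optimal),
        multi_gain=multi,
    )
    return tree, co_optimal


# ---------------------------------------------------------------- timing

@dataclass
class TimingSummary:
    n_trunk: int
    n_shared: int
    n_private: int

    @property
    def total(self) -> int:
        return self.n_trunk + self.n_shared + self.n_private

    @property
    def proportions(self) -> tuple[float, float, float]:
        t = self.total
        if t == 0:
            return (0.0, 0.0, 0.0)
        return (self.n_trunk / t, self.n_shared / t, self.n_private / t)

    @property
    def heterogeneous_fraction(self) -> float:
        """Fraction of mutations not on the trunk (shared + private)."""
        t = self.total
        return (self.n_shared + self.n_private) / t if t else 0.0


def classify_timing(
    matrix: PresenceMatrix, tree: PhyloTree | None = None
) -> tuple[TimingSummary, dict[str, str]]:
    """Label each mutation trunk / shared / private by presence pattern."""
    n_samples = len(matrix.samples)
    labels: dict[str, str] = {}
    counts = {"trunk": 0, "shared": 0, "private": 0}
    n_present = matrix.presence.sum(axis=1)
    for mut_id, k in n_present.items():
        if k == n_samples:
            lab = "trunk"
        elif k == 1:
            lab = "private"
        else:
            lab = "shared"
        labels[mut_id] = lab
        counts[lab] += 1
    return TimingSummary(counts["trunk"], counts["shared"], counts["private"]), labels


# ---------------------------------------------------------------- intermixing

def detect_intermixing(
    tree: PhyloTree,
    matrix: PresenceMatrix,
    ccf_table: pd.DataFrame,
    ccf_min: float = 0.1,
    clonal_min: float = 0.6,
    min_block: int = 3,
) -> list[dict]:
    """Samples carrying another lineage's mutation block subclonally.

    For every non-trunk edge block of at least ``min_block`` mutations,
    each sample's median block CCF is computed.  A sample is an
    intermixed carrier of the block when it holds the block at a
    subclonal level (``ccf_min`` <= median CCF < ``clonal_min``) while
    at least one other sample carries it clonally (median CCF >=
    ``clonal_min``): the sample contains a minority cell population
    from that clade's evolutionary history.
    """
    out: list[dict] = []
    samples = [s for s in matrix.samples if s in ccf_table.columns]
    for clade in sorted(tree.edge_mutations, key=lambda c: sorted(c)):
        if clade == tree.trunk_clade:
            continue
        muts = [m for m in tree.edge_mutations[clade] if m in ccf_table.index]
        if len(muts) < min_block:
            continue
        med = {s: float(np.median(ccf_table.loc[muts, s])) for s in samples}
        clonal_carriers = {s for s, v in med.items() if v >= clonal_min}
        if not clonal_carriers:
            continue
        for s in samples:
            if s in clonal_carriers:
                continue
            if ccf_min <= med[s] < clonal_min:
                out.append({
                    "sample": s,
                    "foreign_clade": set(clonal_carriers),
                    "mutations": sorted(muts),
                    "median_ccf": med[s],
                })
    return out


# ---------------------------------------------------------------- seeding

def classify_seeding(tree: PhyloTree, sample_meta: dict[str, SampleType]) -> str:
    """Metastatic seeding pattern from the sample tree.

    - ``monoclonal_precursor``: all lymph-node samples form one
      met-only clade attached at the first branching node, with a
      mutated stem edge (metastasis-to-metastasis dissemination).
    - ``linear``: all mets form a met-only clade nested inside a
      subclade that also contains primaries.
    - ``explosive``: two or more met lineages attach independently at
      the first branching node.
    """
    mets = {s for s in tree.samples
            if sample_meta.get(s) == SampleType.LYMPH_NODE_MET}
    if not mets:
        raise ValueError("no_metastasis")
    topo = tree.topology
    if not isinstance(topo, tuple):
        return "unclassified"
    top_children = [topo[0], topo[1]]
    met_set = frozenset(mets)

    if met_set in set(tree.clades) and tree.edge_length(met_set) >= 1:
        sisters = [c for c in top_children if _leafset(c) == met_set]
        if sisters:
            return "monoclonal_precursor"
        return "linear"

    # met-only subtrees hanging directly off the first branching node
    independent = 0
    for child in top_children:
        ls = _leafset(child)
        if ls <= met_set:
            independent += 1
        elif isinstance(child, tuple):
            # one level deeper: met-only lineages stemming near the trunk
            for grand in child:
                if _leafset(grand) <= met_set:
                    independent += 1
    if independent >= 2:
        return "explosive"
    return "unclassified"
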