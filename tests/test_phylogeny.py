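"""Presence matrix, exhaustive parsimony, timing, intermixing, seeding."""

import itertools

import numpy as np
import pandas as pd
import pytest

from escc_ith import phylogeny, synthetic
from escc_ith.phylogeny import (
    GAIN_COST,
    REVERSAL_COST,
    PresenceMatrix,
    build_presence_matrix,
    classify_seeding,
    classify_timing,
    detect_intermixing,
    enumerate_topologies,
    infer_parsimony_tree,
    parsimony_score,
    tree_clades,
)
from escc_ith.records import (
    Consequence,
    MutationRecord,
    ReadCounts,
    SampleType,
    VariantType,
)


def _rec(counts_by_sample, pos=100):
    rec = MutationRecord("P", "chr1", pos, "C", "T", VariantType.SNV,
                        consequence=Consequence.MISSENSE)
    rec.per_sample_counts = {s: ReadCounts(a, r)
                             for s, (a, r) in counts_by_sample.items()}
    return rec


# ---------------------------------------------------------------- presence

def test_presence_boundaries():
    recs = [
        _rec({"T1": (3, 147), "T2": (10, 90)}, pos=1),  # T1: VAF 0.02 exactly
        _rec({"T1": (1, 19), "T2": (0, 100)}, pos=2),   # alt=1 fails min_alt
    ]
    m = build_presence_matrix(recs, ["T1", "T2"])
    assert m.presence.loc["chr1:1:C>T", "T1"]          # VAF >= 2% boundary
    assert m.presence.loc["chr1:1:C>T", "T2"]
    # row 2 fails everywhere (min_alt guard / no reads) and is dropped
    assert "chr1:2:C>T" not in m.presence.index


def test_presence_min_alt_guard():
    recs = [_rec({"T1": (1, 19), "T2": (5, 95)})]
    m = build_presence_matrix(recs, ["T1", "T2"])
    assert not m.presence.loc["chr1:100:C>T", "T1"]
    assert m.presence.loc["chr1:100:C>T", "T2"]


def test_presence_matches_bruteforce(rng):
    samples = ["T1", "T2", "T3"]
    recs = []
    for i in range(2000):
        counts = {s: (int(rng.integers(0, 10)), int(rng.integers(0, 300)))
                  for s in samples}
        recs.append(_rec(counts, pos=i + 1))
    m = build_presence_matrix(recs, samples)
    for rec in recs:
        expected = {s: (c.vaf >= 0.02 and c.alt >= 2)
                    for s, c in rec.per_sample_counts.items()}
        if not any(expected.values()):
            assert rec.mutation_id not in m.presence.index
            continue
        for s in samples:
            assert m.presence.loc[rec.mutation_id, s] == expected[s]


def test_presence_needs_two_samples():
    with pytest.raises(ValueError):
        build_presence_matrix([_rec({"T1": (5, 95)})], ["T1"])


# ---------------------------------------------------------------- parsimony

def _matrix(rows, samples):
    pres = pd.DataFrame(np.array(rows, dtype=bool),
                        index=[f"m{i}" for i in range(len(rows))],
                        columns=samples)
    return PresenceMatrix(pres, pres.astype(float) * 0.4)


def test_three_sample_exhaustive():
    # m0 everywhere, m1 in {T1,T2}, m2 in {T3}
    m = _matrix([[1, 1, 1], [1, 1, 0], [0, 0, 1]], ["T1", "T2", "T3"])
    tree, co = infer_parsimony_tree(m)
    assert tree.score == 3  # perfect phylogeny: one gain per mutation
    assert frozenset({"T1", "T2"}) in tree.clades
    assert tree.edge_mutations[frozenset({"T1", "T2", "T3"})] == ["m0"]
    assert tree.edge_mutations[frozenset({"T1", "T2"})] == ["m1"]
    assert tree.edge_mutations[frozenset({"T3"})] == ["m2"]


def test_all_ubiquitous_star_tree():
    m = _matrix([[1, 1, 1]] * 5, ["T1", "T2", "T3"])
    tree, co = infer_parsimony_tree(m)
    assert tree.score == 5
    assert len(tree.edge_mutations) == 1
    assert set(tree.edge_mutations) == {frozenset({"T1", "T2", "T3"})}
    # every resolution is co-optimal for an all-trunk matrix
    assert len(co) == 3


def test_enumeration_counts():
    # number of rooted binary leaf topologies is (2n-3)!!
    assert len(enumerate_topologies(list("AB"))) == 1
    assert len(enumerate_topologies(list("ABC"))) == 3
    assert len(enumerate_topologies(list("ABCD"))) == 15
    assert len(enumerate_topologies(list("ABCDE"))) == 105


def _bruteforce_score(topology, matrix: pd.DataFrame) -> float:
    """Independent re-scorer: minimize over all internal-state labelings."""
    nodes = []

    def collect(node):
        nodes.append(node)
        if isinstance(node, tuple):
            collect(node[0])
            collect(node[1])

    collect(topology)
    internals = [n for n in nodes if isinstance(n, tuple)]
    leaves = {n: matrix[n].to_numpy().astype(int) for n in nodes
              if not isinstance(n, tuple)}
    total = 0.0
    for char_idx in range(len(matrix)):
        best = np.inf
        for states in itertools.product([0, 1], repeat=len(internals)):
            assign = {id(n): s for n, s in zip(internals, states)}
            for leaf, col in leaves.items():
                assign[id(leaf)] = int(col[char_idx])
            cost = 0.0

            def edge_cost(parent_state, node):
                s = assign[id(node)]
                c = (0.0 if s == parent_state
                     else GAIN_COST if s == 1 else REVERSAL_COST)
                if isinstance(node, tuple):
                    c += edge_cost(s, node[0]) + edge_cost(s, node[1])
                return c

            cost = edge_cost(0, topology)  # germline root state 0
            best = min(best, cost)
        total += best
    return total


def test_parsimony_matches_bruteforce(rng):
    """Sankoff scoring equals exhaustive labeling enumeration on all
    topologies for up to 5 leaves."""
    for n_leaves in (3, 4, 5):
        samples = [f"T{i}" for i in range(n_leaves)]
        pres = pd.DataFrame(rng.integers(0, 2, size=(12, n_leaves)).astype(bool),
                            columns=samples,
                            index=[f"m{i}" for i in range(12)])
        keep = pres.any(axis=1)
        pres = pres[keep]
        for topo in enumerate_topologies(samples):
            assert parsimony_score(topo, pres) == pytest.approx(
                _bruteforce_score(topo, pres))


def test_zero_homoplasy_score_equals_mutation_count():
    recs, metas, truth = synthetic.simulate_patient(
        n_regions=5, n_clones=5, muts_per_clone=10, seed=11, noiseless=True)
    samples = [m.sample_id for m in metas if m.is_tumor]
    matrix = build_presence_matrix(recs, samples)
    tree, _ = infer_parsimony_tree(matrix)
    assert tree.score == len(matrix.mutation_ids)
    assert not tree.multi_gain


def test_planted_topology_and_labels_recovered_exactly():
    """Noiseless simulation: inferred clades, edge assignments and timing
    labels all match the planted clone structure."""
    recs, metas, truth = synthetic.simulate_patient(
        n_regions=5, n_clones=4, muts_per_clone=20, seed=3, noiseless=True)
    samples = [m.sample_id for m in metas if m.is_tumor]
    matrix = build_presence_matrix(recs, samples)
    tree, _ = infer_parsimony_tree(matrix)
    expected = truth.expected_clades()
    for clade, muts in tree.edge_mutations.items():
        assert clade in expected
        for mid in muts:
            clone = truth.clone_of_mutation(mid)
            carrying = frozenset(s for s in samples if truth.ccf(clone, s) >= 0.5)
            assert clade == carrying
    _, labels = classify_timing(matrix, tree)
    assert labels == {m: truth.timing_labels[m] for m in labels}


def test_too_many_samples_error():
    m = _matrix([[1] * 10], [f"T{i}" for i in range(10)])
    with pytest.raises(ValueError, match="exhaustive"):
        infer_parsimony_tree(m)


# ---------------------------------------------------------------- timing

def test_timing_definitions():
    m = _matrix([[1, 1, 1, 1, 1], [1, 0, 0, 0, 0], [1, 1, 0, 0, 0]],
                [f"T{i}" for i in range(5)])
    summary, labels = classify_timing(m)
    assert labels == {"m0": "trunk", "m1": "private", "m2": "shared"}
    assert summary.total == 3
    assert summary.proportions == pytest.approx((1 / 3, 1 / 3, 1 / 3))
    assert summary.heterogeneous_fraction == pytest.approx(2 / 3)


def test_timing_invariant_to_column_order(rng):
    samples = [f"T{i}" for i in range(5)]
    rows = rng.integers(0, 2, size=(50, 5)).astype(bool)
    rows[~rows.any(axis=1), 0] = True
    m1 = _matrix(rows.tolist(), samples)
    perm = ["T3", "T0", "T4", "T2", "T1"]
    m2 = PresenceMatrix(m1.presence[perm], m1.vaf[perm])
    s1, _ = classify_timing(m1)
    s2, _ = classify_timing(m2)
    assert s1 == s2


# ---------------------------------------------------------------- intermixing

def _intermix_setup(spill_frac):
    recs, metas, truth = synthetic.simulate_patient(
        n_regions=5, n_clones=3, muts_per_clone=15, seed=21, noiseless=True,
        spill=("T3", 1, spill_frac) if spill_frac else None)
    samples = [m.sample_id for m in metas if m.is_tumor]
    matrix = build_presence_matrix(recs, samples)
    tree, _ = infer_parsimony_tree(matrix)
    rows = {}
    for rec in recs:
        clone = truth.clone_of_mutation(rec.mutation_id)
        rows[rec.mutation_id] = {s: truth.ccf(clone, s) for s in samples}
    ccf_table = pd.DataFrame(rows).T
    return tree, matrix, ccf_table


def test_planted_intermixing_detected():
    tree, matrix, ccf_table = _intermix_setup(0.2)
    hits = detect_intermixing(tree, matrix, ccf_table, ccf_min=0.1)
    assert any(h["sample"] == "T3" for h in hits)


def test_clean_simulation_no_intermixing():
    tree, matrix, ccf_table = _intermix_setup(0.0)
    assert detect_intermixing(tree, matrix, ccf_table, ccf_min=0.1) == []


def test_intermixing_threshold_limit():
    tree, matrix, ccf_table = _intermix_setup(0.2)
    assert detect_intermixing(tree, matrix, ccf_table, ccf_min=1.1) == []


# ---------------------------------------------------------------- seeding

def _seeding_tree(pattern, n_mets=3):
    recs, metas, truth = synthetic.simulate_patient(
        n_regions=4, n_mets=n_mets, muts_per_clone=10, seed=5,
        noiseless=True, seeding=pattern)
    samples = [m.sample_id for m in metas if m.is_tumor]
    matrix = build_presence_matrix(recs, samples)
    tree, _ = infer_parsimony_tree(matrix)
    types = {m.sample_id: m.sample_type for m in metas}
    return tree, types


def test_monoclonal_precursor_seeding():
    tree, types = _seeding_tree("monoclonal", n_mets=2)
    assert classify_seeding(tree, types) == "monoclonal_precursor"


def test_explosive_seeding():
    tree, types = _seeding_tree("explosive", n_mets=3)
    assert classify_seeding(tree, types) == "explosive"


def test_linear_seeding():
    tree, types = _seeding_tree("linear", n_mets=2)
    assert classify_seeding(tree, types) == "linear"


def test_no_metastasis_error():
    recs, metas, _ = synthetic.simulate_patient(
        n_regions=3, muts_per_clone=10, seed=5, noiseless=True)
    samples = [m.sample_id for m in metas if m.is_tumor]
    tree, _ = infer_parsimony_tree(build_presence_matrix(recs, samples))
    with pytest.raises(ValueError, match="no_metastasis"):
        classify_seeding(tree, {s: SampleType.PRIMARY_REGION for s in samples})
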