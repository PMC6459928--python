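"""Repertoire preprocessing, diversity, distances, NJ, and concordance."""

import numpy as np
import pandas as pd
import pytest

from escc_ith import synthetic, tcr
from escc_ith.records import Chain, TcrCloneRecord
from escc_ith.synthetic import TcrTruth
from escc_ith.tcr import (
    TcrRepertoire,
    build_nj_tree,
    count_overlap,
    diversity,
    jaccard_index,
    pairwise_distance,
    preprocess,
    tree_concordance,
)


def _clone(sample, cdr3, count, chain=Chain.TRA, productive=True):
    return TcrCloneRecord(sample, chain, cdr3, "TRV1", "TRJ1", count,
                          productive)


def _rep(freqs, sample="S", chain=Chain.TRA, total=10_000):
    counts = {(f"c{i}", "TRV1", "TRJ1"): int(round(fr * total))
              for i, fr in enumerate(freqs)}
    tot = sum(counts.values())
    return TcrRepertoire(sample, chain, {c: n / tot for c, n in counts.items()},
                         counts, tot)


# ---------------------------------------------------------------- preprocess

def test_low_frequency_filter_per_million():
    # 2 reads per million removed, 3 per million kept
    recs = [_clone("S", "CAAAF", 999_995), _clone("S", "CBBBF", 2),
            _clone("S", "CCCCF", 3)]
    rep = preprocess(recs, "S", Chain.TRA, downsample_to=None)
    kept = {c[0] for c in rep.clones}
    assert "CBBBF" not in kept and "CCCCF" in kept


def test_nonproductive_dropped_and_empty_errors():
    recs = [_clone("S", "CAAAF", 10), _clone("S", "CBBBF", 5, productive=False)]
    rep = preprocess(recs, "S", Chain.TRA)
    assert rep.unique_clones == 1
    with pytest.raises(ValueError):
        preprocess([_clone("S", "CBBBF", 5, productive=False)], "S", Chain.TRA)


def test_downsampling_seeded_and_skipped_when_small():
    recs = [_clone("S", f"C{i:04d}F", 2000) for i in range(1000)]
    rep1 = preprocess(recs, "S", Chain.TRA, downsample_to=1_000_000, seed=5)
    rep2 = preprocess(recs, "S", Chain.TRA, downsample_to=1_000_000, seed=5)
    assert rep1.counts == rep2.counts
    assert rep1.total_reads == 1_000_000
    small = preprocess(recs[:10], "S", Chain.TRA, downsample_to=1_000_000)
    assert small.total_reads == 20_000  # below a million: untouched


def test_frequencies_sum_to_one():
    recs = [_clone("S", f"C{i}F", i + 1) for i in range(20)]
    rep = preprocess(recs, "S", Chain.TRA)
    assert sum(rep.clones.values()) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------- diversity

def test_uniform_eight_clones():
    d = diversity(_rep([0.125] * 8))
    assert d.shannon == pytest.approx(3.0)
    assert d.evenness == pytest.approx(1.0)
    assert d.clonality == pytest.approx(0.0)
    assert d.cr4 == pytest.approx(0.5)


def test_two_clone_shannon():
    d = diversity(_rep([0.75, 0.25]))
    assert d.shannon == pytest.approx(0.8113, abs=1e-4)
    assert d.evenness == pytest.approx(0.8113, abs=1e-4)


def test_cr4_top_four():
    d = diversity(_rep([0.4, 0.3, 0.2, 0.05, 0.05]))
    assert d.cr4 == pytest.approx(0.95)


def test_single_clone_evenness_zero():
    d = diversity(_rep([1.0]))
    assert d.evenness == 0.0 and d.clonality == 1.0


def test_high_frequency_count_threshold():
    rep = _rep([0.5] + [0.5 / 9999] * 9999, total=1_000_000)
    d = diversity(rep, high_freq_threshold=1e-4)
    # 0.5/9999 ~ 5e-5 < 1e-4: only the dominant clone counts
    assert d.high_freq_count == 1


def test_diversity_matches_oracle(rng):
    """Entropy/evenness/CR4 agree with direct one-line recomputation."""
    for _ in range(1000):
        k = int(rng.integers(2, 30))
        w = rng.dirichlet(np.ones(k))
        d = diversity(_rep(w, total=1_000_000))
        freqs = np.array(list(_rep(w, total=1_000_000).clones.values()))
        shannon = -(freqs * np.log2(freqs)).sum()
        assert d.shannon == pytest.approx(shannon, abs=1e-9)
        assert d.evenness == pytest.approx(shannon / np.log2(len(freqs)),
                                           abs=1e-9)
        assert d.cr4 == pytest.approx(np.sort(freqs)[::-1][:4].sum(), abs=1e-9)


# ---------------------------------------------------------------- distances

def _pair(freqs_a, freqs_b, clones_a, clones_b):
    def make(sample, clones, freqs):
        counts = {(c, "V", "J"): int(f * 1000) for c, f in zip(clones, freqs)}
        tot = sum(counts.values())
        reps = {}
        for ch in (Chain.TRA, Chain.TRB):
            reps[ch] = TcrRepertoire(sample, ch,
                                     {c: n / tot for c, n in counts.items()},
                                     dict(counts), tot)
        return reps
    return (make("A", clones_a, freqs_a), make("B", clones_b, freqs_b))


def test_identical_repertoires_zero_distance():
    a, b = _pair([0.5, 0.3, 0.2], [0.5, 0.3, 0.2],
                 "c1 c2 c3".split(), "c1 c2 c3".split())
    d = pairwise_distance(a, b)
    assert d.jaccard["TRA"] == 1.0 and d.overlap["TRB"] == 1.0
    assert d.distance_jaccard == pytest.approx(0.0)
    assert d.distance_overlap == pytest.approx(0.0)


def test_jaccard_distance_formula():
    # {c1,c2,c3} vs {c2,c3,c4}: Jaccard 0.5 per chain -> distance 1.0
    a, b = _pair([1 / 3] * 3, [1 / 3] * 3,
                 "c1 c2 c3".split(), "c2 c3 c4".split())
    d = pairwise_distance(a, b)
    assert d.jaccard["TRA"] == pytest.approx(0.5)
    assert d.distance_jaccard == pytest.approx(1.0)


def test_overlap_distance_formula():
    # shared counts a=(10,5) of 30, b=(20,5) of 50 -> overlap 40/80 = 0.5
    def make(sample, counts):
        tot = sum(counts.values())
        reps = {}
        for ch in (Chain.TRA, Chain.TRB):
            reps[ch] = TcrRepertoire(sample, ch,
                                     {c: n / tot for c, n in counts.items()},
                                     dict(counts), tot)
        return reps
    a = make("A", {("s1", "V", "J"): 10, ("s2", "V", "J"): 5,
                   ("p1", "V", "J"): 15})
    b = make("B", {("s1", "V", "J"): 20, ("s2", "V", "J"): 5,
                   ("p2", "V", "J"): 25})
    d = pairwise_distance(a, b)
    assert d.overlap["TRA"] == pytest.approx(0.5)
    assert d.distance_overlap == pytest.approx(1.0)


def test_disjoint_repertoires_capped():
    a, b = _pair([0.5, 0.5], [0.5, 0.5], "c1 c2".split(), "c3 c4".split())
    d = pairwise_distance(a, b)
    assert d.capped and d.distance_jaccard >= tcr.DISTANCE_CAP / 2


def test_distance_oracle_equivalence(rng):
    """Jaccard/overlap distances match independent recomputation on 1000
    random repertoire pairs."""
    for _ in range(1000):
        pool = [f"c{i}" for i in range(12)]
        ca = sorted(rng.choice(pool, size=rng.integers(2, 10), replace=False))
        cb = sorted(rng.choice(pool, size=rng.integers(2, 10), replace=False))
        a, b = _pair(rng.dirichlet(np.ones(len(ca))),
                     rng.dirichlet(np.ones(len(cb))), ca, cb)
        jac = len(set(ca) & set(cb)) / len(set(ca) | set(cb))
        if jac == 0:
            continue
        d = pairwise_distance(a, b)
        assert d.jaccard["TRA"] == pytest.approx(jac, abs=1e-9)
        expected = 0.5 * (1 / jac - 1) + 0.5 * (1 / jac - 1)
        assert d.distance_jaccard == pytest.approx(expected, abs=1e-9)
        ra, rb = a[Chain.TRA], b[Chain.TRA]
        shared = set(ra.counts) & set(rb.counts)
        ov = (sum(ra.counts[c] + rb.counts[c] for c in shared)
              / (sum(ra.counts.values()) + sum(rb.counts.values())))
        assert d.overlap["TRA"] == pytest.approx(ov, abs=1e-9)


# ---------------------------------------------------------------- NJ tree

def test_nj_recovers_additive_split():
    # additive 4-taxon matrix with split AB|CD
    dm = pd.DataFrame(
        [[0, 2, 7, 7], [2, 0, 7, 7], [7, 7, 0, 2], [7, 7, 2, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float)
    tree = build_nj_tree(dm)
    # the AB|CD split exists: A and B share their nearest internal node
    tips = {t.name: t for t in tree.tips()}
    assert tips["A"].parent is tips["B"].parent or \
        tips["C"].parent is tips["D"].parent


def test_nj_equidistant_star():
    n = 4
    dm = pd.DataFrame(np.ones((n, n)) - np.eye(n),
                      index=list("ABCD"), columns=list("ABCD"))
    tree = build_nj_tree(dm)
    internal = [n for n in tree.non_tips()]
    assert all(abs(e.length or 0) < 1e-9 for e in internal)


def test_nj_input_validation():
    dm2 = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"))
    with pytest.raises(ValueError):
        build_nj_tree(dm2)
    bad = pd.DataFrame([[0, 1, 2], [5, 0, 1], [2, 1, 0]],
                       index=list("ABC"), columns=list("ABC"), dtype=float)
    with pytest.raises(ValueError, match="symmetric"):
        build_nj_tree(bad)


# ---------------------------------------------------------------- concordance

class _FakeTree:
    """Minimal genetic-tree stand-in exposing clades and edge lengths."""

    def __init__(self, clades, lengths):
        self.clades = clades
        self._lengths = lengths

    def edge_length(self, clade):
        return self._lengths.get(clade, 0)

    def path_clades(self, sample):
        return {c for c in self.clades if sample in c}


def _genetic_tree():
    s = ["T1", "T2", "T3", "T4"]
    clades = [frozenset(s), frozenset({"T1", "T2"}), frozenset({"T3", "T4"})] \
        + [frozenset({x}) for x in s]
    lengths = {c: 5 for c in clades}
    return _FakeTree(clades, lengths)


def test_concordant_distances_score_one():
    tree = _genetic_tree()
    d = np.array([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]],
                 dtype=float)
    tcr_dist = pd.DataFrame(d, index=["T1", "T2", "T3", "T4"],
                            columns=["T1", "T2", "T3", "T4"])
    score, flags, rho = tree_concordance(tree, tcr_dist,
                                         ["T1", "T2", "T3", "T4"])
    assert score == 1.0
    assert rho > 0.9


def test_discordant_distances_score_zero():
    tree = _genetic_tree()
    d = np.array([[0, 9, 1, 1], [9, 0, 1, 1], [1, 1, 0, 9], [1, 1, 9, 0]],
                 dtype=float)
    tcr_dist = pd.DataFrame(d, index=["T1", "T2", "T3", "T4"],
                            columns=["T1", "T2", "T3", "T4"])
    score, flags, rho = tree_concordance(tree, tcr_dist,
                                         ["T1", "T2", "T3", "T4"])
    assert score == 0.0


def test_concordance_needs_four_shared_leaves():
    tree = _genetic_tree()
    tcr_dist = pd.DataFrame(np.zeros((2, 2)), index=["T1", "T2"],
                            columns=["T1", "T2"])
    with pytest.raises(ValueError):
        tree_concordance(tree, tcr_dist, ["T1", "T2"])


def test_permutation_null_concordance(rng):
    """Randomly permuted TCR distances give a mean score near the
    exchangeable expectation (two symmetric clades -> 0.5)."""
    tree = _genetic_tree()
    samples = ["T1", "T2", "T3", "T4"]
    base = np.array([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 1], [9, 9, 1, 0]],
                    dtype=float)
    scores = []
    for _ in range(300):
        perm = rng.permutation(4)
        d = base[np.ix_(perm, perm)]
        tcr_dist = pd.DataFrame(d, index=samples, columns=samples)
        score, _, _ = tree_concordance(tree, tcr_dist, samples)
        scores.append(score)
    # 4 labels over the AB|CD structure: 1/3 of pairings match (score 1),
    # 2/3 mismatch (score 0) -> mean 1/3
    assert np.mean(scores) == pytest.approx(1 / 3, abs=0.1)


def test_planted_concordant_simulation(rng):
    """TCR distance = genetic distance + small noise scores >= 0.8."""
    tree = _genetic_tree()
    samples = ["T1", "T2", "T3", "T4"]
    gd = np.array([[0, 10, 20, 20], [10, 0, 20, 20],
                   [20, 20, 0, 10], [20, 20, 10, 0]], dtype=float)
    hits = []
    for _ in range(50):
        noise = rng.normal(0, 1, size=(4, 4))
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d = pd.DataFrame(np.abs(gd + noise), index=samples, columns=samples)
        score, _, _ = tree_concordance(tree, d, samples)
        hits.append(score)
    assert np.mean(hits) >= 0.8
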