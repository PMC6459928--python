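"""TCR repertoire diversity, overlap, distances, and NJ trees.

Clone identity is (CDR3 amino-acid sequence, V gene, J gene).  After
dropping non-productive clones and low-frequency sequences (<= 2
reads per million), a repertoire exceeding one million reads is
down-sampled to exactly one million reads (seeded, without
replacement) before diversity metrics are computed.

Diversity: Shannon index in bits; evenness (Pielou) =
Shannon / log2(unique clone number); clonality = 1 - evenness; CR4 =
summed frequency of the top four clones.

Between-sample measures per chain: Jaccard index on clone identity
sets and count overlap = sum of shared-clone reads in both samples
over the two totals.  Two distances, each averaging the TRA and TRB
terms with equal weight:

    D_jaccard = 0.5*(1/J_TRA - 1) + 0.5*(1/J_TRB - 1)
    D_overlap = 0.5*(1/ov_TRA - 1) + 0.5*(1/ov_TRB - 1)

Sample trees are built from the distance matrix by neighbor joining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .records import Chain, TcrCloneRecord

log = logging.getLogger(__name__)

LOW_FREQ_PER_MILLION = 2
DOWNSAMPLE_READS = 1_000_000
HIGH_FREQ_DEFAULT = 1e-4  # "high-frequency clone" threshold (0.01%)
DISTANCE_CAP = 1e6  # reported distance when Jaccard/overlap is zero

CloneId = tuple[str, str, str]


@dataclass
class TcrRepertoire:
    sample_id: str
    chain: Chain
    clones: dict[CloneId, float]  # clone -> frequency (sums to 1)
    counts: dict[CloneId, int]
    total_reads: int
    vj_pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def unique_clones(self) -> int:
        return len(self.clones)

    def frequencies(self) -> np.ndarray:
        return np.array(list(self.clones.values()))


def preprocess(
    records: list[TcrCloneRecord],
    sample_id: str,
    chain: Chain,
    downsample_to: int = DOWNSAMPLE_READS,
    seed: int | None = None,
) -> TcrRepertoire:
    """Productive-clone filtering, low-frequency removal, normalization.

    Clones at <= 2 reads per million of the sample+chain total are
    removed; repertoires larger than ``downsample_to`` reads are
    down-sampled to exactly that many reads (multivariate
    hypergeometric, i.e. without replacement) before frequencies are
    formed.
    """
    counts: dict[CloneId, int] = {}
    for rec in records:
        if rec.sample_id != sample_id or rec.chain != chain or not rec.productive:
            continue
        counts[rec.clone_id] = counts.get(rec.clone_id, 0) + rec.count
    if not counts:
        raise ValueError(f"no productive clones for {sample_id}/{chain.value}")

    total = sum(counts.values())
    cutoff = LOW_FREQ_PER_MILLION * total / 1_000_000
    counts = {c: n for c, n in counts.items() if n > cutoff}
    if not counts:
        raise ValueError(f"all clones below the frequency filter in {sample_id}")
    total = sum(counts.values())

    if downsample_to and total > downsample_to:
        rng = np.random.default_rng(seed)
        ids = list(counts)
        drawn = rng.multivariate_hypergeometric(
            [counts[c] for c in ids], downsample_to
        )
        counts = {c: int(n) for c, n in zip(ids, drawn) if n > 0}
        total = downsample_to

    freqs = {c: n / total for c, n in sorted(counts.items())}
    vj: dict[tuple[str, str], float] = {}
    for (cdr3, v, j), fr in freqs.items():
        vj[(v, j)] = vj.get((v, j), 0.0) + fr
    return TcrRepertoire(sample_id, chain, freqs, counts, total, vj)


@dataclass
class DiversityMetrics:
    unique_clones: int
    shannon: float
    evenness: float
    clonality: float
    cr4: float
    high_freq_count: int


def diversity(
    rep: TcrRepertoire, high_freq_threshold: float = HIGH_FREQ_DEFAULT
) -> DiversityMetrics:
    """Shannon (bits), Pielou evenness, clonality, CR4, high-freq clones.

    A single-clone repertoire has evenness defined as 0 (log2(1)=0).
    """
    freqs = rep.frequencies()
    shannon = float(-np.sum(freqs * np.log2(freqs)))
    n = rep.unique_clones
    evenness = shannon / np.log2(n) if n > 1 else 0.0
    cr4 = float(np.sort(freqs)[::-1][:4].sum())
    high = int(np.sum(freqs > high_freq_threshold))
    return DiversityMetrics(n, shannon, float(evenness), float(1.0 - evenness),
                            cr4, high)


@dataclass
class RepertoireDistance:
    sample_a: str
    sample_b: str
    jaccard: dict[str, float]      # chain name -> Jaccard index
    overlap: dict[str, float]      # chain name -> count overlap
    distance_jaccard: float
    distance_overlap: float
    capped: bool = False
    missing_chains: list[str] = field(default_factory=list)


def jaccard_index(a: TcrRepertoire, b: TcrRepertoire) -> float:
    sa, sb = set(a.clones), set(b.clones)
    union = len(sa | sb)
    return len(sa & sb) / union if union else 0.0


def count_overlap(a: TcrRepertoire, b: TcrRepertoire) -> float:
    """Shared-clone read mass: sum_i (a_i + b_i) / (sum A + sum B)."""
    shared = set(a.counts) & set(b.counts)
    num = sum(a.counts[c] + b.counts[c] for c in shared)
    denom = sum(a.counts.values()) + sum(b.counts.values())
    return num / denom if denom else 0.0


def _inverse_distance(per_chain: dict[str, float]) -> tuple[float, bool]:
    """Equal-weight sum of 0.5*(1/x - 1) terms, capped when any x is 0."""
    if not per_chain:
        raise ValueError("no chains available for distance")
    weight = 1.0 / (2 * len(per_chain) / 2)  # 0.5 for two chains, 1.0 for one
    capped = False
    total = 0.0
    for x in per_chain.values():
        if x <= 0:
            total += weight * DISTANCE_CAP
            capped = True
        else:
            total += weight * (1.0 / x - 1.0)
    return total, capped


def pairwise_distance(
    reps_a: dict[Chain, TcrRepertoire], reps_b: dict[Chain, TcrRepertoire]
) -> RepertoireDistance:
    """Jaccard and count-overlap distances between two samples.

    A chain present in only one sample is dropped from the average
    with the remaining chain reweighted, and the pair is flagged.
    """
    chains = [c for c in (Chain.TRA, Chain.TRB) if c in reps_a and c in reps_b]
    missing = [c.value for c in (Chain.TRA, Chain.TRB) if c not in chains]
    if not chains:
        raise ValueError("no chain shared between the two samples")
    jac = {c.value: jaccard_index(reps_a[c], reps_b[c]) for c in chains}
    ov = {c.value: count_overlap(reps_a[c], reps_b[c]) for c in chains}
    d_jac, cap1 = _inverse_distance(jac)
    d_ov, cap2 = _inverse_distance(ov)
    if missing:
        log.warning("chains %s missing in one sample; reweighted", missing)
    a_id = next(iter(reps_a.values())).sample_id
    b_id = next(iter(reps_b.values())).sample_id
    return RepertoireDistance(a_id, b_id, jac, ov, d_jac, d_ov,
                              capped=cap1 or cap2, missing_chains=missing)


def distance_matrix(
    repertoires: dict[str, dict[Chain, TcrRepertoire]],
    metric: str = "overlap",
) -> pd.DataFrame:
    """Symmetric sample-by-sample distance matrix (zero diagonal)."""
    ids = sorted(repertoires)
    mat = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            d = pairwise_distance(repertoires[a], repertoires[ids[j]])
            val = d.distance_overlap if metric == "overlap" else d.distance_jaccard
            mat[i, j] = mat[j, i] = val
    return pd.DataFrame(mat, index=ids, columns=ids)


def build_nj_tree(dist: pd.DataFrame) -> skbio.TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Negative branch lengths produced by NJ are clamped to zero.
    """
    mat = dist.to_numpy()
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 samples")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    dm = skbio.DistanceMatrix(mat, ids=list(dist.index))
    return skbio.tree.nj(dm, neg_as_zero=True)


def cophenetic_distances(tree: skbio.TreeNode, ids: list[str]) -> pd.DataFrame:
    tip_dm = tree.tip_tip_distances(endpoints=list(ids))
    return pd.DataFrame(tip_dm.data, index=list(tip_dm.ids), columns=list(tip_dm.ids))


def tree_concordance(
    genetic_tree,
    tcr_dist: pd.DataFrame,
    primary_samples: list[str],
) -> tuple[float, list[dict], float]:
    """Agreement between genetic clades and TCR-repertoire proximity.

    For each nontrivial genetic clade among the primary regions, the
    clade is concordant when its members' mean pairwise TCR distance
    is smaller than the mean member-to-non-member distance.  Returns
    (fraction of concordant clades, per-clade flags, Spearman
    correlation between genetic cophenetic distance and TCR distance).
    """
    shared = [s for s in primary_samples if s in tcr_dist.index]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared primary-region leaves")
    shared_set = set(shared)
    flags = []
    for clade in genetic_tree.clades:
        members = sorted(clade & shared_set)
        others = sorted(shared_set - clade)
        if len(members) < 2 or not others:
            continue
        within = np.mean([tcr_dist.at[a, b] for i, a in enumerate(members)
                          for b in members[i + 1:]])
        between = np.mean([tcr_dist.at[a, b] for a in members for b in others])
        flags.append({"clade": set(members), "within": float(within),
                      "between": float(between),
                      "concordant": bool(within < between)})
    score = float(np.mean([f["concordant"] for f in flags])) if flags else 0.0

    # cophenetic Spearman: genetic tree edge lengths vs TCR distances
    import scipy.stats
    gdist = _genetic_cophenetic(genetic_tree, shared)
    pairs = [(gdist.at[a, b], tcr_dist.at[a, b])
             for i, a in enumerate(shared) for b in shared[i + 1:]]
    rho = scipy.stats.spearmanr([p[0] for p in pairs], [p[1] for p in pairs]).statistic
    return score, flags, float(rho)


def _genetic_cophenetic(tree, samples: list[str]) -> pd.DataFrame:
    """Pairwise path lengths (mutation counts) between leaves of a PhyloTree."""
    n = len(samples)
    mat = pd.DataFrame(np.zeros((n, n)), index=samples, columns=samples)
    for i, a in enumerate(samples):
        pa = tree.path_clades(a)
        for b in samples[i + 1:]:
            pb = tree.path_clades(b)
            d = sum(tree.edge_length(c) for c in pa ^ pb)
            mat.at[a, b] = mat.at[b, a] = d
    return mat
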