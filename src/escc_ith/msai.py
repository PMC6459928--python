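"""Mirrored subclonal allelic imbalance (MSAI) between tumor samples.

MSAI is parallel copy-number evolution: the same segment is
imbalanced in two samples of a patient, but in favor of opposite
parental haplotypes.  Detection works on heterozygous-SNP B-allele
fractions over a patient-specific consensus segmentation:

1. breakpoints of all samples are pooled into consensus segments;
2. on an imbalanced segment, each SNP's BAF is scored under two
   truncated-normal densities centered at the theoretical BAF of the
   major and of the minor copy number, giving a per-SNP log-likelihood
   ratio (LLR) for "B allele sits on the major haplotype";
3. mirroring means the favored haplotype flips between samples, so
   per-SNP LLRs anti-correlate: the reversal statistic
   r_i = -LLR_A(i) * LLR_B(i) is positive under mirroring and is
   tested against zero with a one-tailed one-sample t-test.

The product form makes the test exactly symmetric in sample order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .records import SegmentRecord, SnpBafRecord

MIN_SNPS = 10
SIGMA_FLOOR = 0.01


def expected_baf(purity: float, n_major: int, n_minor: int, major: bool = True) -> float:
    """Theoretical BAF when the B allele lies on the major (or minor) haplotype.

    expected_baf(major) + expected_baf(minor) = 1 for any valid state.
    """
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    if n_major < n_minor or n_minor < 0 or (n_major == n_minor == 0):
        raise ValueError(f"invalid copy state ({n_major},{n_minor})")
    n = n_major if major else n_minor
    return (purity * n + (1 - purity)) / (purity * (n_major + n_minor) + 2 * (1 - purity))


@dataclass
class ConsensusSegment:
    chrom: str
    start: int
    end: int
    states: dict[str, tuple[int, int]]  # sample -> (n_major, n_minor)
    purities: dict[str, float] = field(default_factory=dict)


def build_consensus_segments(
    segments: list[SegmentRecord],
    purities: dict[str, float] | None = None,
) -> list[ConsensusSegment]:
    """Overlap-partition of all samples' segments by pooled breakpoints.

    Each output interval carries every sample's copy state there.
    Intervals not covered in a sample omit that sample from ``states``.
    """
    by_sample: dict[str, list[SegmentRecord]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    if len(by_sample) < 2:
        raise ValueError("need segments from >= 2 samples")
    for sid, segs in by_sample.items():
        segs.sort(key=lambda s: (s.chrom, s.start))
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start <= a.end:
                raise ValueError(f"overlapping segments within sample {sid}")

    out: list[ConsensusSegment] = []
    chroms = sorted({s.chrom for s in segments})
    for chrom in chroms:
        cuts = set()
        for seg in segments:
            if seg.chrom == chrom:
                cuts.add(seg.start)
                cuts.add(seg.end + 1)  # closed intervals: end+1 is the next start
        edges = sorted(cuts)
        for lo, hi in zip(edges, edges[1:]):
            start, end = lo, hi - 1
            states, purs = {}, {}
            for sid, segs in by_sample.items():
                for seg in segs:
                    if seg.chrom == chrom and seg.start <= start and end <= seg.end:
                        states[sid] = (seg.n_major, seg.n_minor)
                        if purities and sid in purities:
                            purs[sid] = purities[sid]
                        break
            if states:
                out.append(ConsensusSegment(chrom, start, end, states, purs))
    return out


@dataclass
class MsaiResult:
    chrom: str
    start: int
    end: int
    sample_a: str
    sample_b: str
    n_snps: int
    t_statistic: float
    p_value: float
    mirrored: bool
    skipped: str | None = None  # reason when the test could not run
    llr_a: np.ndarray | None = None
    llr_b: np.ndarray | None = None


def _segment_llrs(
    bafs: np.ndarray, purity: float, n_major: int, n_minor: int
) -> np.ndarray:
    """Per-SNP log-likelihood ratio: B allele on major vs minor haplotype.

    Densities are normals truncated to (0, 1) centered at the two
    theoretical BAFs; sigma is the MAD of BAFs folded about the nearer
    center (floored at 0.01), robust to the unknown assignment.
    """
    mu_major = expected_baf(purity, n_major, n_minor, major=True)
    mu_minor = 1.0 - mu_major
    dev = np.minimum(np.abs(bafs - mu_major), np.abs(bafs - mu_minor))
    sigma = max(1.4826 * float(np.median(dev)), SIGMA_FLOOR)

    def logpdf(x, mu):
        a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
        return scipy.stats.truncnorm.logpdf(x, a, b, loc=mu, scale=sigma)

    return logpdf(bafs, mu_major) - logpdf(bafs, mu_minor)


def test_msai(
    segment: ConsensusSegment,
    snps: list[SnpBafRecord],
    sample_a: str,
    sample_b: str,
    alpha: float = 0.05,
) -> MsaiResult:
    """Test one consensus segment for mirrored allelic imbalance.

    Requires both samples imbalanced on the segment and >= 10 shared
    heterozygous SNPs; otherwise the result is skipped with a reason.
    ``mirrored`` requires a significant reversal t-test AND the
    aggregate favored haplotype to flip between the samples.
    """
    base = dict(chrom=segment.chrom, start=segment.start, end=segment.end,
                sample_a=sample_a, sample_b=sample_b)
    for sid in (sample_a, sample_b):
        if sid not in segment.states:
            return MsaiResult(**base, n_snps=0, t_statistic=np.nan,
                              p_value=np.nan, mirrored=False, skipped="no_state")
        nmaj, nmin = segment.states[sid]
        if nmaj == nmin:
            return MsaiResult(**base, n_snps=0, t_statistic=np.nan,
                              p_value=np.nan, mirrored=False, skipped="no_imbalance")

    on_seg: dict[str, dict[int, float]] = {sample_a: {}, sample_b: {}}
    for snp in snps:
        if snp.sample_id in on_seg and snp.chrom == segment.chrom \
                and segment.start <= snp.pos <= segment.end:
            on_seg[snp.sample_id][snp.pos] = snp.baf
    shared = sorted(set(on_seg[sample_a]) & set(on_seg[sample_b]))
    if len(shared) < MIN_SNPS:
        return MsaiResult(**base, n_snps=len(shared), t_statistic=np.nan,
                          p_value=np.nan, mirrored=False, skipped="insufficient_snps")

    llrs = {}
    for sid in (sample_a, sample_b):
        nmaj, nmin = segment.states[sid]
        purity = segment.purities.get(sid, 1.0)
        bafs = np.array([on_seg[sid][p] for p in shared])
        llrs[sid] = _segment_llrs(bafs, purity, nmaj, nmin)

    reversal = -llrs[sample_a] * llrs[sample_b]
    t, p = scipy.stats.ttest_1samp(reversal, 0.0, alternative="greater")
    flipped = np.sign(np.sum(llrs[sample_a])) != np.sign(np.sum(llrs[sample_b]))
    return MsaiResult(**base, n_snps=len(shared), t_statistic=float(t),
                      p_value=float(p), mirrored=bool(p < alpha and flipped),
                      llr_a=llrs[sample_a], llr_b=llrs[sample_b])


def screen_patient(
    segments: list[SegmentRecord],
    snps: list[SnpBafRecord],
    purities: dict[str, float],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[MsaiResult]:
    """All (consensus segment, sample pair) MSAI tests for one patient.

    Raw p-values are reported; ``bh_correct`` adds Benjamini-Hochberg
    adjustment across the tested segments and re-derives the mirrored
    flag from the adjusted values.
    """
    consensus = build_consensus_segments(segments, purities)
    sample_ids = sorted({s.sample_id for s in segments})
    results = []
    for seg in consensus:
        for i, a in enumerate(sample_ids):
            for b in sample_ids[i + 1:]:
                results.append(test_msai(seg, snps, a, b, alpha=alpha))
    if bh_correct:
        tested = [r for r in results if r.skipped is None]
        if tested:
            rej, adj, *_ = multipletests([r.p_value for r in tested], alpha=alpha,
                                         method="fdr_bh")
            for r, pa, rj in zip(tested, adj, rej):
                flipped = np.sign(np.sum(r.llr_a)) != np.sign(np.sum(r.llr_b))
                r.p_value = float(pa)
                r.mirrored = bool(rj and flipped)
    return results
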