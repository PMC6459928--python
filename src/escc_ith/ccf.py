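"""Cancer cell fraction, clonality classification, and LOH calls.

The CCF of a mutation with variant allele frequency v, in a sample of
purity p with local tumor total copy number n_t (normal copy number
n_n, usually 2) and mutation multiplicity m, is the closed form

    CCF = v * (p*n_t + (1-p)*n_n) / (p * m)

The 95% CI is a Clopper-Pearson binomial interval on v pushed through
the same linear map; a mutation is subclonal when the CI's upper
bound is below 1.  Reported CCFs are capped at 1.2 rather than 1 so
that multiplicity misestimation stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

from statsmodels.stats.proportion import proportion_confint

log = logging.getLogger(__name__)

CCF_CAP = 1.2


@dataclass
class CcfEstimate:
    mutation_id: str
    sample_id: str
    vaf: float
    multiplicity: int
    ccf: float
    ci95: tuple[float, float]

    @property
    def clonality(self) -> str:
        """``subclonal`` iff the CCF 95% CI upper bound is < 1."""
        return "subclonal" if self.ci95[1] < 1.0 else "clonal"


def compute_ccf(
    alt: int,
    ref: int,
    purity: float,
    cn_tumor: int,
    cn_normal: int = 2,
    multiplicity: int | None = None,
    mutation_id: str = "",
    sample_id: str = "",
    n_major: int | None = None,
) -> CcfEstimate:
    """Closed-form CCF with a binomially propagated 95% CI.

    ``multiplicity=None`` selects it automatically as
    round(v*(p*n_t+(1-p)*n_n)/p) clipped to [1, n_major] (n_major
    defaults to cn_tumor).
    """
    if purity is None:
        raise ValueError("purity_required")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    depth = alt + ref
    if depth <= 0:
        raise ValueError("alt + ref must be positive")
    if cn_tumor < 0:
        raise ValueError("cn_tumor must be >= 0")
    if cn_tumor == 0 and alt > 0:
        log.warning("%s %s: alt reads on a zero-copy segment; multiplicity forced 1",
                    mutation_id, sample_id)
        multiplicity = 1

    vaf = alt / depth
    denom_cn = purity * cn_tumor + (1 - purity) * cn_normal
    if multiplicity is None:
        cap = n_major if n_major is not None else max(cn_tumor, 1)
        multiplicity = int(min(max(round(vaf * denom_cn / purity), 1), max(cap, 1)))

    scale = denom_cn / (purity * multiplicity)
    ccf = min(vaf * scale, CCF_CAP)
    lo, hi = proportion_confint(alt, depth, alpha=0.05, method="beta")
    ci = (min(lo * scale, CCF_CAP), min(hi * scale, CCF_CAP))
    return CcfEstimate(mutation_id, sample_id, vaf, multiplicity, ccf, ci)


def classify_clonality(estimate: CcfEstimate) -> str:
    return estimate.clonality


@dataclass
class LohCall:
    gene: str
    sample_id: str
    loh: bool
    alt_allele_loss: bool


ALT_LOSS_VAF = 0.7


def call_loh(
    segments,
    gene: str,
    chrom: str,
    pos: int,
    sample_id: str,
    variant_vaf: float | None = None,
) -> LohCall:
    """LOH at a gene locus: minor allele clonally lost, major retained.

    ``alt_allele_loss`` additionally requires the variant's read
    frequency to exceed 0.7 (the retained allele carries the variant).
    """
    overlapping = [s for s in segments
                   if s.sample_id == sample_id and s.overlaps(chrom, pos)]
    if not overlapping:
        raise ValueError(f"locus_uncovered: {gene} {chrom}:{pos} in {sample_id}")
    seg = overlapping[0]
    loh = seg.n_minor == 0 and seg.n_major >= 1
    alt_loss = bool(loh and variant_vaf is not None and variant_vaf > ALT_LOSS_VAF)
    return LohCall(gene, sample_id, loh, alt_loss)
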