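"""Synthetic multi-region cohorts with known ground truth.

The generator emulates the study design the pipeline targets: five
spatially separated primary-tumor regions plus optional lymph-node
metastases per patient, whole-exome read counts at ~290x tumor /
~187x normal depth, substitution contexts drawn from known signature
mixtures, BAF segments with optional mirrored imbalance, neutral
1/f-tail VAF spectra, and power-law TCR repertoires with planted
sharing.  Per-site coverage is Poisson around the mean depth and
alt-read noise is binomial — the simplest model consistent with WES
count data.  Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import CHANNELS_96, load_catalog
from .records import (
    Chain,
    Consequence,
    MutationRecord,
    ReadCounts,
    SampleMeta,
    SampleType,
    SegmentRecord,
    SnpBafRecord,
    TcrCloneRecord,
    VariantType,
)

TUMOR_DEPTH = 290.0
NORMAL_DEPTH = 187.0
DEFAULT_PURITY = 0.8


# ---------------------------------------------------------------- clone trees

@dataclass
class CloneTreeTruth:
    """Planted clone tree with per-sample composition.

    ``parents[c]`` is the parent clone of c (clone 0 is the founding
    clone, parented by the germline, -1).  ``region_composition[s][c]``
    is the fraction of sample s's tumor cells belonging to clone c's
    terminal population; a mutation in clone c has true CCF equal to
    the summed fraction of c and its descendants.
    """

    parents: list[int]
    mutations_per_clone: dict[int, list[str]]
    region_composition: dict[str, dict[int, float]]
    purity_per_sample: dict[str, float]
    timing_labels: dict[str, str] = field(default_factory=dict)

    def descendants(self, clone: int) -> set[int]:
        out = {clone}
        changed = True
        while changed:
            changed = False
            for c, p in enumerate(self.parents):
                if p in out and c not in out:
                    out.add(c)
                    changed = True
        return out

    def ccf(self, clone: int, sample: str) -> float:
        sub = self.descendants(clone)
        return sum(f for c, f in self.region_composition[sample].items() if c in sub)

    def clone_of_mutation(self, mutation_id: str) -> int:
        for c, muts in self.mutations_per_clone.items():
            if mutation_id in muts:
                return c
        raise KeyError(mutation_id)

    def expected_clades(self, min_ccf: float = 0.5) -> set[frozenset]:
        """Sample clades implied by clone carriage (CCF >= min_ccf)."""
        clades = set()
        for c in range(len(self.parents)):
            carrying = frozenset(
                s for s in self.region_composition if self.ccf(c, s) >= min_ccf
            )
            if len(carrying) >= 1:
                clades.add(carrying)
        return clades


def _draw_contexts(rng: np.random.Generator, n: int, signature_mix: np.ndarray,
                   catalog: pd.DataFrame) -> list[tuple[str, str, str]]:
    """(ref, alt, tri_context) per mutation, drawn from the mixed spectrum."""
    probs = catalog.to_numpy() @ signature_mix
    probs = probs / probs.sum()
    channels = rng.choice(96, size=n, p=probs)
    out = []
    for ch in channels:
        label = CHANNELS_96[ch]  # e.g. "A[C>T]G"
        five, mid, three = label[0], label[2:5], label[6]
        ref, alt = mid[0], mid[2]
        out.append((ref, alt, f"{five}{ref}{three}"))
    return out


def _clone_tree(rng: np.random.Generator, n_clones: int, sample_ids: list[str],
                mets: list[str], seeding: str | None) -> tuple[list[int], dict]:
    """Parent pointers plus sample -> terminal clone assignment."""
    primaries = [s for s in sample_ids if s not in mets]
    if seeding is None:
        parents = [-1]
        for c in range(1, n_clones):
            parents.append(int(rng.integers(0, c)))
        assignment = {}
        # spread samples over clones, guaranteeing trunk representation
        clones = list(range(n_clones))
        for i, s in enumerate(sample_ids):
            assignment[s] = clones[i % n_clones] if n_clones > 1 else 0
        return parents, assignment

    # deterministic seeding-pattern scaffolds (one clone per tracked lineage)
    parents = [-1]
    assignment: dict[str, int] = {}

    def new_clone(parent: int) -> int:
        parents.append(parent)
        return len(parents) - 1

    if seeding == "monoclonal":
        primary_clade = new_clone(0)
        precursor = new_clone(0)  # metastatic precursor, sister of primaries
        for s in primaries:
            assignment[s] = new_clone(primary_clade)
        for s in mets:
            assignment[s] = new_clone(precursor)
    elif seeding == "explosive":
        primary_clade = new_clone(0)
        for s in primaries:
            assignment[s] = new_clone(primary_clade)
        for s in mets:
            assignment[s] = new_clone(0)  # each met seeds from the trunk node
    elif seeding == "linear":
        half = max(1, len(primaries) // 2)
        clade_a = new_clone(0)
        clade_b = new_clone(0)
        for s in primaries[:half]:
            assignment[s] = new_clone(clade_a)
        inner = new_clone(clade_b)  # primary subclone that seeds the chain
        for s in primaries[half:]:
            assignment[s] = new_clone(inner)
        met_stem = new_clone(inner)
        for s in mets:
            assignment[s] = new_clone(met_stem)
    else:
        raise ValueError(f"unknown seeding pattern {seeding!r}")
    return parents, assignment


def simulate_patient(
    n_regions: int = 5,
    n_mets: int = 0,
    n_clones: int = 4,
    muts_per_clone: int = 30,
    depth: float = TUMOR_DEPTH,
    signature_mix: np.ndarray | None = None,
    seed: int = 0,
    purity: float = DEFAULT_PURITY,
    normal_depth: float = NORMAL_DEPTH,
    patient_id: str = "SIM001",
    noiseless: bool = False,
    seeding: str | None = None,
    spill: tuple[str, int, float] | None = None,
    catalog: pd.DataFrame | None = None,
    prefix_samples: bool = False,
) -> tuple[list[MutationRecord], list[SampleMeta], CloneTreeTruth]:
    """Simulate one multi-region patient with known clone structure.

    Samples are named T1..Tn (primary regions), L1..Lm (lymph-node
    mets) plus one matched normal N1.  Each sample's tumor cells are,
    by default, a pure population of one terminal clone, so every
    mutation on the sample's lineage has CCF 1 there.  ``spill =
    (sample, clone, fraction)`` mixes a foreign clone into a sample
    (clone intermixing); ``seeding`` in {"monoclonal", "linear",
    "explosive"} plants a metastatic-dissemination pattern.
    ``noiseless`` replaces Poisson/binomial sampling with expectations
    for exact ground-truth recovery tests.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    if catalog is None:
        catalog = load_catalog()
    if signature_mix is None:
        signature_mix = np.zeros(catalog.shape[1])
        signature_mix[0] = 1.0
    signature_mix = np.asarray(signature_mix, dtype=float)
    if signature_mix.min() < 0 or not np.isclose(signature_mix.sum(), 1.0):
        raise ValueError("signature_mix must be non-negative and sum to 1")

    pre = f"{patient_id}_" if prefix_samples else ""
    regions = [f"{pre}T{i + 1}" for i in range(n_regions)]
    mets = [f"{pre}L{i + 1}" for i in range(n_mets)]
    tumor_samples = regions + mets
    if spill is not None and prefix_samples and not spill[0].startswith(pre):
        spill = (f"{pre}{spill[0]}", spill[1], spill[2])
    parents, assignment = _clone_tree(rng, n_clones, tumor_samples, mets, seeding)
    n_clones_actual = len(parents)

    composition = {s: {assignment[s]: 1.0} for s in tumor_samples}
    if spill is not None:
        s, clone, frac = spill
        composition[s] = {assignment[s]: 1.0 - frac, clone: frac}

    truth = CloneTreeTruth(
        parents=parents,
        mutations_per_clone={c: [] for c in range(n_clones_actual)},
        region_composition=composition,
        purity_per_sample={s: purity for s in tumor_samples},
    )

    n_mut_total = n_clones_actual * muts_per_clone
    contexts = _draw_contexts(rng, n_mut_total, signature_mix, catalog)
    positions = np.array([], dtype=np.int64)
    while positions.size < n_mut_total:  # rejection-sample unique positions
        draw = rng.integers(1, 100_000_000, size=2 * n_mut_total)
        positions = np.unique(np.concatenate([positions, draw]))
    positions = rng.permutation(positions)[:n_mut_total]
    chroms = rng.integers(1, 23, size=n_mut_total)

    records: list[MutationRecord] = []
    k = 0
    for clone in range(n_clones_actual):
        for _ in range(muts_per_clone):
            ref, alt, ctx = contexts[k]
            rec = MutationRecord(
                patient_id=patient_id,
                chrom=f"chr{chroms[k]}",
                pos=int(positions[k]),
                ref=ref,
                alt=alt,
                variant_type=VariantType.SNV,
                gene=None,
                consequence=Consequence.MISSENSE,
                tri_context=ctx,
            )
            truth.mutations_per_clone[clone].append(rec.mutation_id)
            for s in tumor_samples:
                ccf = truth.ccf(clone, s)
                exp_vaf = purity * ccf / 2.0  # diploid, multiplicity 1
                if noiseless:
                    cov = int(round(depth))
                    alt_reads = int(round(cov * exp_vaf))
                else:
                    cov = int(rng.poisson(depth))
                    alt_reads = int(rng.binomial(cov, exp_vaf)) if cov else 0
                rec.per_sample_counts[s] = ReadCounts(alt_reads, cov - alt_reads)
            ncov = int(round(normal_depth)) if noiseless else int(rng.poisson(normal_depth))
            rec.per_sample_counts[f"{pre}N1"] = ReadCounts(0, ncov)
            records.append(rec)
            k += 1

    metas = [
        SampleMeta(patient_id, s, SampleType.PRIMARY_REGION, purity,
                   2.0, depth) for s in regions
    ] + [
        SampleMeta(patient_id, s, SampleType.LYMPH_NODE_MET, purity,
                   2.0, depth) for s in mets
    ] + [SampleMeta(patient_id, f"{pre}N1", SampleType.NORMAL_TISSUE, None,
                    2.0, normal_depth)]

    n_samples = len(tumor_samples)
    for clone in range(n_clones_actual):
        carrying = sum(1 for s in tumor_samples if truth.ccf(clone, s) >= 0.5)
        label = ("trunk" if carrying == n_samples
                 else "private" if carrying == 1 else "shared")
        for mut in truth.mutations_per_clone[clone]:
            truth.timing_labels[mut] = label
    return records, metas, truth


# ---------------------------------------------------------------- neutral VAFs

def neutral_true_slope(n_mut: int, f_min: float, f_max: float) -> float:
    """Implied mu/beta slope when n_mut draws fill the (f_min, f_max) tail."""
    return n_mut / (1.0 / f_min - f_min / f_max)


def simulate_neutral_vafs(
    mu_eff: float,
    f_max: float,
    n_mut: int,
    depth: float,
    seed: int = 0,
    f_min: float = 0.1,
    dilution: float = 0.0,
) -> list[tuple[int, int]]:
    """Read pairs whose underlying VAF tail follows the neutral model.

    VAFs are drawn so the expected cumulative count M(f) is
    proportional to 1/f - f/f_max on (f_min, f_max); the model's
    nonzero tail at f_max, M(f_max) = mu(1/f_max - 1), is realized as
    a clonal point mass at f_max.  Read counts are then binomially
    resampled at Poisson(depth) coverage.  ``dilution`` deflates every
    VAF by 1/(1+dilution) to emulate extra normal contamination.
    """
    if mu_eff <= 0:
        raise ValueError("mu_eff must be positive")
    if not 0 < f_max <= 0.5:
        raise ValueError("f_max must be in (0, 0.5]")
    if not 0 < f_min < f_max:
        raise ValueError("f_min must be in (0, f_max)")
    if n_mut == 0:
        return []
    rng = np.random.default_rng(seed)

    def x(f):
        return 1.0 / f - f / f_max

    # M(f) must be proportional to x(f) with no offset, so draws with
    # tail coordinate below x(f_max) form the clonal point mass at f_max
    target = rng.uniform(0.0, 1.0, size=n_mut) * x(f_min)
    target = np.maximum(target, x(f_max))
    # invert x(f) = t: f^2/f_max + t f - 1 = 0
    f = (-target + np.sqrt(target**2 + 4.0 / f_max)) / (2.0 / f_max)
    f = f / (1.0 + dilution)

    cov = rng.poisson(depth, size=n_mut)
    cov = np.maximum(cov, 1)
    alt = rng.binomial(cov, np.clip(f, 0.0, 1.0))
    return [(int(a), int(c)) for a, c in zip(alt, cov)]


def add_subclone(
    read_pairs: list[tuple[int, int]],
    ccf: float,
    n_mut: int,
    depth: float,
    purity: float = 1.0,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Append a subclonal mutation cluster at VAF = purity*ccf/2."""
    rng = np.random.default_rng(seed)
    vaf = purity * ccf / 2.0
    cov = np.maximum(rng.poisson(depth, size=n_mut), 1)
    alt = rng.binomial(cov, vaf)
    return read_pairs + [(int(a), int(c)) for a, c in zip(alt, cov)]


# ---------------------------------------------------------------- BAF segments

def simulate_baf_segments(
    n_snps: int,
    purity: float,
    states: dict[str, tuple[int, int]],
    mirrored: bool,
    seed: int = 0,
    depth: float = TUMOR_DEPTH,
    chrom: str = "chr1",
    start: int = 1,
    end: int = 50_000_000,
) -> tuple[list[SnpBafRecord], list[SegmentRecord]]:
    """Heterozygous-SNP BAFs on one segment across samples.

    Each SNP is phased onto haplotype A or B (shared phase across
    samples).  In the first sample haplotype A carries the major copy
    number; if ``mirrored``, every other sample favors haplotype B
    instead, otherwise all samples favor A.  B-reads are binomial
    around the theoretical BAF.
    """
    from .msai import expected_baf

    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    rng = np.random.default_rng(seed)
    positions = np.array([], dtype=np.int64)
    while positions.size < n_snps:  # rejection-sample unique positions
        draw = rng.integers(start, end, size=2 * n_snps)
        positions = np.unique(np.concatenate([positions, draw]))
    positions = np.sort(rng.permutation(positions)[:n_snps])
    hap_of_b = rng.integers(0, 2, size=n_snps)  # which haplotype the B allele is on

    snps: list[SnpBafRecord] = []
    segments: list[SegmentRecord] = []
    for idx, (sample_id, (n_major, n_minor)) in enumerate(sorted(states.items())):
        # haplotype A is major in the first sample; mirrored flips the rest
        a_is_major = True if idx == 0 else not mirrored
        baf_major = expected_baf(purity, n_major, n_minor, major=True)
        for i in range(n_snps):
            b_on_major = (hap_of_b[i] == 0) == a_is_major
            mu = baf_major if b_on_major else 1.0 - baf_major
            cov = max(int(rng.poisson(depth)), 1)
            b = int(rng.binomial(cov, mu))
            snps.append(SnpBafRecord(sample_id, chrom, int(positions[i]),
                                     cov - b, b, phase_id=f"hap{hap_of_b[i]}"))
        segments.append(SegmentRecord(sample_id, chrom, start, end,
                                      float(np.log2((n_major + n_minor) / 2.0))
                                      if n_major + n_minor > 0 else -3.0,
                                      n_major, n_minor))
    return snps, segments


# ---------------------------------------------------------------- TCR cohort

@dataclass
class TcrTruth:
    """Sharing design: which samples contain which clones.

    ``membership[sample]`` is the set of clone indices planted in that
    sample; expected Jaccard overlaps follow from set arithmetic.
    """

    membership: dict[str, set[int]]
    abundance_exponent: float = 2.0
    reads_per_sample: int = 20_000

    def jaccard(self, a: str, b: str) -> float:
        sa, sb = self.membership[a], self.membership[b]
        union = len(sa | sb)
        return len(sa & sb) / union if union else 0.0


_AA = "ACDEFGHIKLMNPQRSTVWY"


def _cdr3(rng: np.random.Generator, length: int = 12) -> str:
    inner = "".join(rng.choice(list(_AA), size=length - 2))
    return f"C{inner}F"


def simulate_tcr_cohort(
    design: TcrTruth,
    seed: int = 0,
    chains: tuple[Chain, ...] = (Chain.TRA, Chain.TRB),
) -> list[TcrCloneRecord]:
    """Clone tables realizing the planted sharing design exactly.

    Every clone in a sample's membership receives at least one read;
    counts follow a power law (Zipf-like, exponent
    ``abundance_exponent``) over the sample's clones.
    """
    all_clones = sorted(set().union(*design.membership.values())) \
        if design.membership else []
    if not all_clones:
        raise ValueError("empty shared clone pool")
    rng = np.random.default_rng(seed)

    records: list[TcrCloneRecord] = []
    v_genes = [f"TRV{i}" for i in range(1, 31)]
    j_genes = [f"TRJ{i}" for i in range(1, 13)]
    for chain in chains:
        identities = {
            c: (_cdr3(rng), str(rng.choice(v_genes)), str(rng.choice(j_genes)))
            for c in all_clones
        }
        for sample_id, members in sorted(design.membership.items()):
            clones = sorted(members)
            ranks = rng.permutation(len(clones)) + 1
            weights = ranks.astype(float) ** (-design.abundance_exponent)
            weights /= weights.sum()
            extra = max(design.reads_per_sample - len(clones), 0)
            counts = rng.multinomial(extra, weights) + 1  # floor realizes membership
            for c, n in zip(clones, counts):
                cdr3, v, j = identities[c]
                records.append(TcrCloneRecord(sample_id, chain, cdr3, v, j,
                                              int(n), productive=True))
    return records


# ---------------------------------------------------------------- BRCA cohort

def simulate_brca_cohort(
    n_pos: int,
    n_neg: int,
    sep: float,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Signature-3 activity scores for a labelled cohort.

    Negative (HR-proficient) patients score ~ N(0, sd); positive
    (BRCA1/2-deficient) patients ~ N(sep, sd), so the population AUC
    has the closed form Phi(sep / (sd*sqrt(2))).  Scores are logistic
    -transformed to [0, 1] (monotone, AUC-preserving) so they read as
    contribution levels.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one patient per class")
    if sep < 0:
        raise ValueError("sep must be >= 0")
    rng = np.random.default_rng(seed)
    neg = rng.normal(0.0, noise_sd, size=n_neg)
    pos = rng.normal(sep, noise_sd, size=n_pos)
    raw = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(n_pos, dtype=bool),
                             np.zeros(n_neg, dtype=bool)])
    scores = 1.0 / (1.0 + np.exp(-raw))
    return scores, labels


def brca_sep_for_auc(target_auc: float, noise_sd: float = 1.0) -> float:
    """Normal-shift separation giving a target population AUC."""
    import scipy.stats
    return float(scipy.stats.norm.ppf(target_auc) * noise_sd * np.sqrt(2.0))


# ---------------------------------------------------------------- demo cohort

def write_demo_cohort(outdir, seed: int = 0, n_patients: int = 3) -> dict:
    """Write a small synthetic cohort in every pipeline input format.

    Patient 1: five regions, mixed signatures, mirrored + non-mirrored
    BAF segments, and a TCR repertoire over its samples.  Patient 2:
    five regions plus two lymph-node mets seeded from a monoclonal
    precursor.  Patient 3: four regions with a planted intermixed
    clone.  A truth JSON accompanies the tables.
    """
    import json
    from pathlib import Path

    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cat = load_catalog()
    base = int(seed) % (2**31 - 10_000)

    mix1 = np.zeros(30); mix1[[0, 1, 12]] = (0.5, 0.3, 0.2)
    mix2 = np.zeros(30); mix2[[0, 2]] = (0.6, 0.4)
    specs = [
        dict(patient_id="SIM001", n_regions=5, n_mets=0, n_clones=4,
             muts_per_clone=25, signature_mix=mix1, seed=base + 1),
        dict(patient_id="SIM002", n_regions=5, n_mets=2, n_clones=4,
             muts_per_clone=25, signature_mix=mix2, seed=base + 2,
             seeding="monoclonal"),
        dict(patient_id="SIM003", n_regions=4, n_mets=0, n_clones=4,
             muts_per_clone=25, signature_mix=mix1, seed=base + 3,
             spill=("T3", 1, 0.25)),
    ][:n_patients]

    records, metas, truths = [], [], {}
    for sp in specs:
        r, m, t = simulate_patient(catalog=cat, prefix_samples=True, **sp)
        records += r
        metas += m
        truths[sp["patient_id"]] = {
            "parents": t.parents,
            "mutations_per_clone": {str(k): v for k, v in
                                    t.mutations_per_clone.items()},
            "timing_labels": t.timing_labels,
        }

    snps1, segs1 = simulate_baf_segments(
        80, 0.8, {"SIM001_T1": (2, 1), "SIM001_T2": (2, 1)}, mirrored=True,
        seed=base + 11, chrom="chr5")
    snps2, segs2 = simulate_baf_segments(
        80, 0.8, {"SIM001_T1": (2, 1), "SIM001_T2": (2, 1)}, mirrored=False,
        seed=base + 12, chrom="chr7")
    tcr_design = TcrTruth(membership={
        "SIM001_T1": set(range(0, 60)), "SIM001_T2": set(range(20, 80)),
        "SIM001_T3": set(range(40, 100)), "SIM001_N1": set(range(90, 140)),
    }, reads_per_sample=5_000)
    tcr_records = simulate_tcr_cohort(tcr_design, seed=base + 21)

    paths = {
        "mutations": outdir / "mutations.tsv",
        "samples": outdir / "samples.tsv",
        "segments": outdir / "segments.tsv",
        "snp_bafs": outdir / "snp_bafs.tsv",
        "tcr_clones": outdir / "tcr_clones.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    io.write_mutation_table(records, paths["mutations"])
    io.write_sample_table(metas, paths["samples"])
    io.write_segment_table(segs1 + segs2, paths["segments"])
    io.write_baf_table(snps1 + snps2, paths["snp_bafs"])
    io.write_tcr_table(tcr_records, paths["tcr_clones"])
    paths["truth"].write_text(json.dumps(truths, indent=2, sort_keys=True) + "\n")
    paths["config"].write_text(json.dumps({
        "mutations": str(paths["mutations"]),
        "samples": str(paths["samples"]),
        "segments": str(paths["segments"]),
        "snp_bafs": str(paths["snp_bafs"]),
        "tcr_clones": str(paths["tcr_clones"]),
        "seed": int(seed),
        "outdir": str(outdir / "results"),
    }, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
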