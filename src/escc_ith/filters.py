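"""Numeric post-calling filters, hypermutator flag, germline HR-gene
filters, driver annotation, and the neoantigen affinity cutoff.

All filters are pure functions: every input record lands in exactly
one of the passed/rejected partitions, and rejections carry the full
list of violated rules.  Upstream caller internals (false-positive
scripts, manual indel review) are not reproduced — only the numeric
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

from .records import (
    Consequence,
    GermlineVariant,
    MutationRecord,
    ReadCounts,
    TRUNCATING,
)

# SNV post-filter thresholds (tumor / matched normal)
SNV_MIN_TUMOR_ALT = 4
SNV_MAX_NORMAL_ALT = 2
SNV_MIN_TUMOR_COV = 14
SNV_MIN_NORMAL_COV = 10

# indel post-filter thresholds
INDEL_MIN_ALT = 6
INDEL_MIN_COV = 20
INDEL_MIN_VAF = 0.1

# hypermutator: burden at least this multiple of the cohort median
HYPERMUTATOR_FOLD = 10.0

# germline HR-gene filter
GERMLINE_MIN_COV = 30
GERMLINE_MIN_VAF = 0.08  # strict: VAF must exceed this
GERMLINE_MAX_POP_MAF = 0.01

# neoantigen candidate: MHC-I binding affinity strictly below this (nM)
NEOANTIGEN_MAX_AFFINITY_NM = 500.0

#: homologous-recombination pathway panel screened for germline variants
HR_GENES = frozenset({
    "BRCA1", "BRCA2", "MRE11A", "NBN", "RAD50", "RAD51C", "RAD51B",
    "RAD52", "XRCC2", "BLM", "EME1", "RPA1", "POLD1", "TOP3A", "RAD54B",
    "TOP3B", "BARD1", "BRIP1", "MLH1", "MSH2", "PALB2", "CHEK2",
    "FAM175A", "MSH6", "RAD51D",
})


@dataclass
class Rejection:
    record: object
    reasons: list[str]


def _snv_reasons(tumor: ReadCounts, normal: ReadCounts) -> list[str]:
    reasons = []
    if tumor.alt < SNV_MIN_TUMOR_ALT:
        reasons.append("tumor_support")
    if normal.alt > SNV_MAX_NORMAL_ALT:
        reasons.append("normal_support")
    if tumor.depth < SNV_MIN_TUMOR_COV:
        reasons.append("tumor_coverage")
    if normal.depth < SNV_MIN_NORMAL_COV:
        reasons.append("normal_coverage")
    return reasons


def filter_somatic_snvs(
    records: list[tuple[MutationRecord, str, str]] | list[tuple[ReadCounts, ReadCounts]],
) -> tuple[list, list[Rejection]]:
    """Apply SNV post-filters to (record, tumor_sample, normal_sample) triples.

    Each item is either ``(MutationRecord, tumor_sample_id, normal_sample_id)``
    or a bare ``(tumor ReadCounts, normal ReadCounts)`` pair.  Keeps
    records with tumor alt >= 4, normal alt <= 2, tumor coverage >= 14
    and normal coverage >= 10; rejections enumerate every violated rule.
    """
    passed, rejected = [], []
    for item in records:
        if isinstance(item[0], ReadCounts):
            tumor, normal = item
            rec = item
        else:
            rec, tumor_id, normal_id = item
            if normal_id not in rec.per_sample_counts:
                raise KeyError(f"missing normal counts for {rec.mutation_id}")
            tumor = rec.per_sample_counts[tumor_id]
            normal = rec.per_sample_counts[normal_id]
        reasons = _snv_reasons(tumor, normal)
        if reasons:
            rejected.append(Rejection(rec, reasons))
        else:
            passed.append(rec)
    return passed, rejected


def filter_somatic_indels(
    records: list[tuple[object, ReadCounts]],
) -> tuple[list, list[Rejection]]:
    """Keep indels with alt >= 6, coverage >= 20 and VAF >= 0.1."""
    passed, rejected = [], []
    for rec, counts in records:
        reasons = []
        if counts.depth == 0:
            reasons.append("no_coverage")
        else:
            if counts.alt < INDEL_MIN_ALT:
                reasons.append("indel_support")
            if counts.depth < INDEL_MIN_COV:
                reasons.append("indel_coverage")
            if counts.vaf < INDEL_MIN_VAF:
                reasons.append("indel_vaf")
        if reasons:
            rejected.append(Rejection(rec, reasons))
        else:
            passed.append(rec)
    return passed, rejected


def flag_hypermutator(per_patient_burden: dict[str, int]) -> set[str]:
    """Flag patients whose burden is >= 10x the cohort median burden."""
    if not per_patient_burden:
        raise ValueError("empty burden map")
    if len(per_patient_burden) < 3:
        raise ValueError("hypermutator flag needs >= 3 patients")
    cohort_median = median(per_patient_burden.values())
    return {
        p for p, burden in per_patient_burden.items()
        if burden >= HYPERMUTATOR_FOLD * cohort_median
    }


def filter_germline_hr(
    variants: list[GermlineVariant],
) -> tuple[list[GermlineVariant], list[Rejection]]:
    """Deleterious germline HR-gene variants.

    Kept when coverage >= 30, VAF > 8%, population MAF <= 1% (absent
    treated as 0, i.e. rare), and the variant is truncating (nonsense,
    frameshift, splice) or ClinVar-pathogenic.
    """
    passed, rejected = [], []
    for v in variants:
        reasons = []
        if v.gene not in HR_GENES:
            reasons.append("gene_panel")
        if v.coverage < GERMLINE_MIN_COV:
            reasons.append("coverage")
        if v.vaf <= GERMLINE_MIN_VAF:
            reasons.append("vaf")
        maf = 0.0 if v.population_maf is None else v.population_maf
        if maf > GERMLINE_MAX_POP_MAF:
            reasons.append("common_variant")
        if not (v.consequence in TRUNCATING or v.clinvar_pathogenic):
            reasons.append("not_deleterious")
        if reasons:
            rejected.append(Rejection(v, reasons))
        else:
            passed.append(v)
    return passed, rejected


@dataclass
class DriverCallConfig:
    """Configuration for putative-driver annotation.

    ``cosmic_index`` maps gene -> [(genomic position, recorded mutation
    count)], in genomic (not amino-acid) coordinates.
    """

    driver_gene_list: frozenset[str]
    cosmic_index: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    recessive_genes: frozenset[str] = frozenset()

    #: window (bp) for the recurrent-position criterion
    proximity_bp: int = 15
    #: recurrence needed inside the window
    proximity_min_count: int = 3
    sift_max: float = 0.05
    polyphen_min: float = 0.995


def default_driver_config() -> DriverCallConfig:
    """DriverCallConfig seeded from the packaged ESCC driver-gene list.

    The list covers recurrently mutated / amplified ESCC genes with a
    recessive (tumor-suppressor) flag; the mutation catalog index starts
    empty and should be supplied by the user.
    """
    import importlib.resources

    import pandas as pd

    ref = importlib.resources.files("escc_ith.data").joinpath(
        "driver_genes_default.tsv")
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    return DriverCallConfig(
        driver_gene_list=frozenset(df.gene),
        recessive_genes=frozenset(df.gene[df.recessive == 1]),
    )


def _cosmic_criterion(rec: MutationRecord, cfg: DriverCallConfig) -> bool:
    entries = cfg.cosmic_index.get(rec.gene, [])
    n_near = 0
    for pos, count in entries:
        if pos == rec.pos:
            return True
        if abs(pos - rec.pos) <= cfg.proximity_bp:
            n_near += count
    return n_near >= cfg.proximity_min_count


def _recessive_criterion(rec: MutationRecord, cfg: DriverCallConfig) -> bool:
    if rec.gene not in cfg.recessive_genes:
        return False
    if rec.consequence not in TRUNCATING:
        return False
    sift_ok = rec.sift is not None and rec.sift < cfg.sift_max
    polyphen_ok = rec.polyphen is not None and rec.polyphen > cfg.polyphen_min
    return sift_ok or polyphen_ok


def annotate_drivers(
    records: list[MutationRecord], config: DriverCallConfig
) -> list[MutationRecord]:
    """Flag putative driver mutations in place and return the records.

    A non-silent variant in a listed driver gene is a driver if it has
    an exact catalog match or >= 3 recorded mutations within 15 bp
    (criterion i), or lies in a recessive gene, is truncating, and has
    SIFT < 0.05 or PolyPhen > 0.995 (criterion ii).
    """
    for rec in records:
        rec.is_driver = False
        if rec.gene is None or rec.gene not in config.driver_gene_list:
            continue
        if rec.consequence == Consequence.SILENT:
            continue
        if _cosmic_criterion(rec, config) or _recessive_criterion(rec, config):
            rec.is_driver = True
    return records


def filter_neoantigens(peptides: list[tuple[object, float]]) -> list:
    """Keep candidate peptides with binding affinity strictly < 500 nM."""
    out = []
    for peptide, affinity in peptides:
        if affinity < 0:
            raise ValueError(f"negative affinity {affinity}")
        if affinity < NEOANTIGEN_MAX_AFFINITY_NM:
            out.append(peptide)
    return out
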