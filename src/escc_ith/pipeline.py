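"""End-to-end per-patient pipeline over the analysis stages.

Stages: variant filtering -> presence matrix / parsimony tree /
timing -> CCF table -> signature exposures (pooled and per phase) ->
MSAI screen -> neutral-evolution fits -> TCR metrics and trees.
A stage that cannot run (missing inputs, failed precondition) is
logged and skipped together with its downstream dependents only.

The run is deterministic given (inputs, config, seed): summaries are
byte-identical across repeat runs.  Log output intentionally carries
no timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ccf as ccf_mod
from . import filters, io, msai, neutral, phylogeny, signatures, tcr
from .catalog import load_catalog
from .records import Chain, SampleType

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration; threshold defaults are the published values."""

    mutations: str | None = None
    samples: str | None = None
    segments: str | None = None
    snp_bafs: str | None = None
    tcr_clones: str | None = None
    catalog: str | None = None
    outdir: str = "results"
    seed: int = 0

    stages: list[str] = field(default_factory=lambda: [
        "filter", "tree", "ccf", "signatures", "msai", "neutral", "tcr",
    ])

    presence_vaf_min: float = 0.02
    presence_min_alt: int = 2
    msai_alpha: float = 0.05
    tcr_high_freq: float = 1e-4
    tcr_distance_metric: str = "overlap"
    neutral_window: tuple[float, float] = (0.12, 0.24)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        cfg.neutral_window = tuple(cfg.neutral_window)
        return cfg


def _jsonable(obj):
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 10)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = [_jsonable(v) for v in obj]
        return sorted(items, key=str) if isinstance(obj, (set, frozenset)) else items
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all configured stages; write per-patient outputs and a summary.

    Returns the machine-readable summary that is also written to
    ``<outdir>/summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("thresholds: presence_vaf_min=%s presence_min_alt=%s msai_alpha=%s "
             "tcr_high_freq=%s neutral_window=%s seed=%s",
             config.presence_vaf_min, config.presence_min_alt,
             config.msai_alpha, config.tcr_high_freq, config.neutral_window,
             config.seed)

    mutations = io.read_mutation_table(config.mutations) if config.mutations else []
    metas = io.read_sample_table(config.samples) if config.samples else []
    segments = io.read_segment_table(config.segments) if config.segments else []
    snps = io.read_baf_table(config.snp_bafs) if config.snp_bafs else []
    tcr_records = io.read_tcr_table(config.tcr_clones) if config.tcr_clones else []
    catalog = load_catalog(config.catalog)

    meta_by_patient: dict[str, list] = {}
    for m in metas:
        meta_by_patient.setdefault(m.patient_id, []).append(m)

    summary: dict = {"patients": {}, "config": {
        "seed": config.seed, "stages": list(config.stages),
        "presence_vaf_min": config.presence_vaf_min,
        "presence_min_alt": config.presence_min_alt,
        "msai_alpha": config.msai_alpha,
    }}

    for patient_id in sorted(meta_by_patient):
        psummary = _run_patient(
            patient_id,
            [r for r in mutations if r.patient_id == patient_id],
            meta_by_patient[patient_id],
            segments, snps, catalog, config, outdir,
        )
        summary["patients"][patient_id] = psummary

    if tcr_records and "tcr" in config.stages:
        summary["tcr"] = _run_tcr(tcr_records, config, outdir)
    elif "tcr" not in config.stages:
        log.info("TCR stage disabled")

    text = json.dumps(_jsonable(summary), indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(text + "\n")
    return summary


def _run_patient(patient_id, muts, metas, segments, snps, catalog, config,
                 outdir) -> dict:
    psum: dict = {"n_mutations": len(muts)}
    pdir = outdir / patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    tumor = sorted(m.sample_id for m in metas if m.is_tumor)
    normal = next((m.sample_id for m in metas
                   if m.sample_type in (SampleType.NORMAL_TISSUE, SampleType.BLOOD)),
                  None)
    purities = {m.sample_id: m.purity for m in metas}
    sample_types = {m.sample_id: m.sample_type for m in metas}
    done: set[str] = set()

    # ---- filter
    if "filter" in config.stages and muts:
        if normal is None:
            log.warning("%s: no matched normal; filter stage skipped", patient_id)
        else:
            triples = [(r, s, normal) for r in muts for s in tumor
                       if s in r.per_sample_counts]
            passed, rejected = filters.filter_somatic_snvs(triples)
            keep_ids = {r.mutation_id for r in passed}
            muts = [r for r in muts if r.mutation_id in keep_ids]
            rej_rows = [{"mutation_id": r.record.mutation_id
                         if hasattr(r.record, "mutation_id") else str(r.record),
                         "reasons": ";".join(r.reasons)} for r in rejected]
            pd.DataFrame(rej_rows).to_csv(pdir / "rejected.tsv", sep="\t",
                                          index=False)
            psum["filter"] = {"n_pass": len(keep_ids), "n_reject": len(rej_rows)}
            done.add("filter")

    # ---- tree & timing
    matrix = tree = timing = labels = None
    if "tree" in config.stages and muts and len(tumor) >= 2:
        try:
            matrix = phylogeny.build_presence_matrix(
                muts, tumor, config.presence_vaf_min, config.presence_min_alt)
            tree, co = phylogeny.infer_parsimony_tree(matrix)
            timing, labels = phylogeny.classify_timing(matrix, tree)
            io.write_newick(tree, pdir / "tree.nwk")
            edge_rows = [{"clade": "|".join(sorted(clade)), "mutation_id": mid}
                         for clade, mids in sorted(
                             tree.edge_mutations.items(),
                             key=lambda kv: sorted(kv[0]))
                         for mid in sorted(mids)]
            pd.DataFrame(edge_rows).to_csv(pdir / "edges.tsv", sep="\t",
                                           index=False)
            psum["tree"] = {
                "newick": tree.to_newick(),
                "score": tree.score,
                "n_co_optimal": len(co),
                "timing": {"trunk": timing.n_trunk, "shared": timing.n_shared,
                           "private": timing.n_private,
                           "proportions": list(timing.proportions)},
            }
            done.add("tree")
        except ValueError as exc:
            log.warning("%s: tree stage failed (%s); dependents skipped",
                        patient_id, exc)

    # ---- CCF
    ccf_table = None
    if "ccf" in config.stages and muts:
        if any(purities.get(s) is None for s in tumor):
            log.warning("%s: purity missing for a tumor sample; CCF stage "
                        "skipped", patient_id)
        else:
            rows = []
            for rec in muts:
                for s in tumor:
                    counts = rec.per_sample_counts.get(s)
                    if counts is None or counts.depth == 0:
                        continue
                    cn = _local_cn(segments, s, rec.chrom, rec.pos)
                    est = ccf_mod.compute_ccf(
                        counts.alt, counts.ref, purities[s], cn_tumor=cn,
                        mutation_id=rec.mutation_id, sample_id=s)
                    rows.append({"mutation_id": est.mutation_id, "sample_id": s,
                                 "vaf": est.vaf, "multiplicity": est.multiplicity,
                                 "ccf": est.ccf, "ci_low": est.ci95[0],
                                 "ci_high": est.ci95[1],
                                 "clonality": est.clonality})
            df = pd.DataFrame(rows)
            df.to_csv(pdir / "ccf.tsv", sep="\t", index=False)
            if not df.empty:
                ccf_table = df.pivot_table(index="mutation_id",
                                           columns="sample_id", values="ccf")
                psum["ccf"] = {"n_estimates": len(df),
                               "n_subclonal": int((df.clonality ==
                                                   "subclonal").sum())}
                done.add("ccf")

    # ---- intermixing (needs tree + ccf)
    if tree is not None and ccf_table is not None and matrix is not None:
        inter = phylogeny.detect_intermixing(tree, matrix, ccf_table)
        psum["intermixing"] = [
            {"sample": h["sample"], "foreign_clade": sorted(h["foreign_clade"]),
             "n_mutations": len(h["mutations"])} for h in inter]
        mets_present = any(sample_types.get(s) == SampleType.LYMPH_NODE_MET
                           for s in tumor)
        if mets_present:
            psum["seeding"] = phylogeny.classify_seeding(tree, sample_types)

    # ---- signatures
    if "signatures" in config.stages and muts:
        pooled = signatures.fit_exposures(
            signatures.build_spectrum(muts), catalog, patient_id)
        psum["signatures"] = {
            "dominant": None if pooled.dominant is None
            else pooled.signature_names[pooled.dominant],
            "proportions": {n: p for n, p in zip(pooled.signature_names,
                                                 pooled.proportions)
                            if p > 1e-6},
            "low_confidence": pooled.low_confidence,
        }
        if labels is not None:
            trunk_exp, branch_exp = signatures.phase_exposures(
                muts, labels, catalog, patient_id)
            psum["signatures"]["trunk_dominant"] = (
                None if trunk_exp.dominant is None
                else trunk_exp.signature_names[trunk_exp.dominant])
            psum["signatures"]["branch_dominant"] = (
                None if branch_exp is None or branch_exp.dominant is None
                else branch_exp.signature_names[branch_exp.dominant])
        done.add("signatures")

    # ---- MSAI
    if "msai" in config.stages:
        pat_samples = set(tumor)
        pat_segs = [s for s in segments if s.sample_id in pat_samples]
        pat_snps = [s for s in snps if s.sample_id in pat_samples]
        if pat_segs and pat_snps and all(purities.get(s) for s in
                                         {x.sample_id for x in pat_segs}):
            results = msai.screen_patient(
                pat_segs, pat_snps,
                {s: purities[s] for s in pat_samples if purities.get(s)},
                alpha=config.msai_alpha)
            rows = [{"chrom": r.chrom, "start": r.start, "end": r.end,
                     "sample_a": r.sample_a, "sample_b": r.sample_b,
                     "n_snps": r.n_snps, "p_value": r.p_value,
                     "mirrored": r.mirrored, "skipped": r.skipped or ""}
                    for r in results]
            pd.DataFrame(rows).to_csv(pdir / "msai.tsv", sep="\t", index=False)
            psum["msai"] = {"n_tested": sum(1 for r in results if not r.skipped),
                            "n_mirrored": sum(r.mirrored for r in results)}
            done.add("msai")

    # ---- neutral evolution
    if "neutral" in config.stages and muts:
        fits = []
        for s in tumor:
            vafs = np.array([rec.per_sample_counts[s].vaf for rec in muts
                             if s in rec.per_sample_counts
                             and rec.per_sample_counts[s].depth > 0])
            vafs = vafs[(vafs > 0) & (vafs < 1)]
            fits.append(neutral.fit_sample(vafs, purities.get(s), s,
                                           window=config.neutral_window))
        pd.DataFrame([dataclasses.asdict(f) for f in fits]).to_csv(
            pdir / "neutral.tsv", sep="\t", index=False)
        psum["neutral"] = {
            "n_eligible": sum(f.eligible for f in fits),
            "n_neutral": sum(f.neutral for f in fits),
        }
        done.add("neutral")

    psum["stages_completed"] = sorted(done)
    return psum


def _local_cn(segments, sample_id, chrom, pos) -> int:
    for seg in segments:
        if seg.sample_id == sample_id and seg.overlaps(chrom, pos):
            return seg.n_major + seg.n_minor
    return 2


def _run_tcr(records, config, outdir) -> dict:
    tdir = outdir / "tcr"
    tdir.mkdir(parents=True, exist_ok=True)
    sample_ids = sorted({r.sample_id for r in records})
    reps: dict[str, dict[Chain, tcr.TcrRepertoire]] = {}
    metrics_rows = []
    for s in sample_ids:
        reps[s] = {}
        for chain in (Chain.TRA, Chain.TRB):
            try:
                rep = tcr.preprocess(records, s, chain, seed=config.seed)
            except ValueError:
                continue
            reps[s][chain] = rep
            d = tcr.diversity(rep, config.tcr_high_freq)
            metrics_rows.append({"sample_id": s, "chain": chain.value,
                                 **dataclasses.asdict(d)})
    pd.DataFrame(metrics_rows).to_csv(tdir / "diversity.tsv", sep="\t",
                                      index=False)
    out: dict = {"n_samples": len([s for s in reps if reps[s]])}
    usable = {s: r for s, r in reps.items() if r}
    if len(usable) >= 3:
        dist = tcr.distance_matrix(usable, metric=config.tcr_distance_metric)
        dist.to_csv(tdir / "distances.tsv", sep="\t")
        nj = tcr.build_nj_tree(dist)
        io.write_newick(nj, tdir / "nj_tree.nwk")
        out["nj_leaves"] = sorted(dist.index)
    return out
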