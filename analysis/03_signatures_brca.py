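"""Signature deconvolution, early-vs-late dynamics, and the HRD AUC.

Fits per-patient 30-signature exposures on the demo cohort and splits
them by trunk (early) vs branch (late) phase.  Then simulates a
labelled cohort whose signature-3 activity separates BRCA1/2-deficient
from proficient patients at a closed-form population AUC of 0.9 and
reports the empirical Mann-Whitney AUC — the predictive-value check.
"""

import json
from pathlib import Path

import numpy as np

from escc_ith import io, signatures, synthetic
from escc_ith.catalog import load_catalog
from escc_ith.phylogeny import build_presence_matrix, classify_timing
from escc_ith.records import SampleType

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    catalog = load_catalog()
    muts = io.read_mutation_table(ROOT / "cohort" / "mutations.tsv")
    metas = io.read_sample_table(ROOT / "cohort" / "samples.tsv")

    print("per-patient dominant signatures (pooled / trunk / branch):")
    rows = {}
    for pid in sorted({m.patient_id for m in metas}):
        pmuts = [r for r in muts if r.patient_id == pid]
        tumor = sorted(m.sample_id for m in metas
                       if m.patient_id == pid and m.is_tumor)
        matrix = build_presence_matrix(pmuts, tumor)
        _, labels = classify_timing(matrix)
        pooled = signatures.fit_exposures(
            signatures.build_spectrum(pmuts), catalog, pid)
        trunk, branch = signatures.phase_exposures(pmuts, labels, catalog, pid)

        def name(exp):
            return ("-" if exp is None or exp.dominant is None
                    else exp.signature_names[exp.dominant])

        print(f"  {pid}: {name(pooled)} / {name(trunk)} / {name(branch)}")
        rows[pid] = {"pooled": name(pooled), "trunk": name(trunk),
                     "branch": name(branch)}

    sep = synthetic.brca_sep_for_auc(0.9)
    scores, brca_labels = synthetic.simulate_brca_cohort(250, 250, sep, seed=7)
    auc, roc = signatures.auc_signature3(scores, brca_labels)
    print(f"signature-3 vs BRCA1/2 deficiency: empirical AUC {auc:.3f} "
          f"(closed-form target 0.900, n=500)")

    outdir = ROOT / "analysis"
    outdir.mkdir(parents=True, exist_ok=True)
    roc.to_csv(outdir / "brca_roc.tsv", sep="\t", index=False)
    (outdir / "signatures_summary.json").write_text(json.dumps(
        {"dominant": rows, "brca_auc": round(float(auc), 4)},
        indent=2, sort_keys=True))
    print(f"wrote {outdir / 'signatures_summary.json'}")
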