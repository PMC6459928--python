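"""Generate the synthetic multi-region demo cohort used by the later steps.

Three patients: five regions with mixed mutational signatures
(SIM001, plus mirrored/non-mirrored BAF segments and TCR
repertoires), five regions + two lymph-node mets seeded from a
monoclonal precursor (SIM002), and four regions with a planted
intermixed clone (SIM003).  All pipeline input tables plus the
ground-truth JSON land in results/cohort/.
"""

from pathlib import Path

from escc_ith.synthetic import write_demo_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

if __name__ == "__main__":
    paths = write_demo_cohort(OUT, seed=7)
    print("wrote synthetic cohort:")
    for name, path in sorted(paths.items()):
        print(f"  {name}: {path}")
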