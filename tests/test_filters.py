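"""Variant-filter rules against boundary cases and a brute-force oracle."""

import numpy as np
import pytest

from escc_ith.filters import (
    DriverCallConfig,
    annotate_drivers,
    filter_germline_hr,
    filter_neoantigens,
    filter_somatic_indels,
    filter_somatic_snvs,
    flag_hypermutator,
)
from escc_ith.records import (
    Consequence,
    GermlineVariant,
    MutationRecord,
    ReadCounts,
    VariantType,
)


@pytest.mark.parametrize(
    "t_alt,t_cov,n_alt,n_cov,ok",
    [
        (4, 14, 2, 10, True),    # all four thresholds exactly at the boundary
        (3, 14, 2, 10, False),   # tumor support one short
        (4, 13, 2, 10, False),
        (4, 14, 3, 10, False),
        (4, 14, 2, 9, False),
        (40, 100, 0, 50, True),
    ],
)
def test_snv_filter_boundaries(t_alt, t_cov, n_alt, n_cov, ok):
    pair = (ReadCounts(t_alt, t_cov - t_alt), ReadCounts(n_alt, n_cov - n_alt))
    passed, rejected = filter_somatic_snvs([pair])
    assert bool(passed) is ok
    if not ok:
        assert rejected[0].reasons


def test_snv_filter_reason_names():
    pair = (ReadCounts(3, 5), ReadCounts(3, 4))  # violates everything
    _, rejected = filter_somatic_snvs([pair])
    assert set(rejected[0].reasons) == {
        "tumor_support", "normal_support", "tumor_coverage", "normal_coverage"
    }


@pytest.mark.parametrize(
    "alt,cov,ok",
    [(6, 20, True), (6, 61, False), (5, 20, False), (6, 19, False),
     (30, 100, True)],
)
def test_indel_filter_boundaries(alt, cov, ok):
    # VAF = alt/cov; (6, 61) has VAF 0.098 < 0.1
    passed, _ = filter_somatic_indels([("x", ReadCounts(alt, cov - alt))])
    assert bool(passed) is ok


def test_indel_zero_coverage_reason():
    _, rejected = filter_somatic_indels([("x", ReadCounts(0, 0))])
    assert rejected[0].reasons == ["no_coverage"]


def test_snv_filter_matches_bruteforce(rng):
    """Partition agrees with independent per-row re-evaluation, and
    passed/rejected form an exact partition of the input."""
    rows = [(ReadCounts(int(a), int(r)), ReadCounts(int(na), int(nr)))
            for a, r, na, nr in zip(
                rng.integers(0, 12, 10_000), rng.integers(0, 30, 10_000),
                rng.integers(0, 6, 10_000), rng.integers(0, 20, 10_000))]
    passed, rejected = filter_somatic_snvs(rows)
    assert len(passed) + len(rejected) == len(rows)
    for t, n in rows:
        expect = (t.alt >= 4 and n.alt <= 2 and t.alt + t.ref >= 14
                  and n.alt + n.ref >= 10)
        assert ((t, n) in passed) is expect


def test_indel_filter_matches_bruteforce(rng):
    rows = [(i, ReadCounts(int(a), int(r)))
            for i, (a, r) in enumerate(zip(rng.integers(0, 15, 10_000),
                                           rng.integers(0, 40, 10_000)))]
    passed, rejected = filter_somatic_indels(rows)
    passed_ids = set(passed)
    for i, c in rows:
        cov = c.alt + c.ref
        expect = cov > 0 and c.alt >= 6 and cov >= 20 and c.alt / cov >= 0.1
        assert (i in passed_ids) is expect
    assert len(passed) + len(rejected) == len(rows)


def test_hypermutator_flagging():
    burdens = {f"P{i}": 189 for i in range(10)}
    burdens["P_hyper"] = 3095
    assert flag_hypermutator(burdens) == {"P_hyper"}
    # boundary: exactly 10x the median is flagged
    burdens["P_edge"] = 1890
    assert "P_edge" in flag_hypermutator(burdens)
    # all-equal cohort: nobody is 10x the median
    assert flag_hypermutator({"A": 5, "B": 5, "C": 5}) == set()
    with pytest.raises(ValueError):
        flag_hypermutator({})


def _gv(**kw):
    base = dict(gene="BRCA2", consequence=Consequence.FRAMESHIFT,
                clinvar_pathogenic=False, coverage=50, vaf=0.48,
                population_maf=0.0)
    base.update(kw)
    return GermlineVariant(**base)


def test_germline_hr_filter():
    kept, _ = filter_germline_hr([_gv()])
    assert len(kept) == 1
    # missense without ClinVar support is not deleterious
    _, rej = filter_germline_hr([_gv(consequence=Consequence.MISSENSE)])
    assert "not_deleterious" in rej[0].reasons
    # ClinVar-pathogenic missense qualifies
    kept, _ = filter_germline_hr(
        [_gv(consequence=Consequence.MISSENSE, clinvar_pathogenic=True)])
    assert len(kept) == 1
    # common variant
    _, rej = filter_germline_hr([_gv(population_maf=0.02)])
    assert "common_variant" in rej[0].reasons
    # absent MAF treated as rare
    kept, _ = filter_germline_hr([_gv(population_maf=None)])
    assert len(kept) == 1
    # VAF must strictly exceed 8%
    _, rej = filter_germline_hr([_gv(vaf=0.08)])
    assert "vaf" in rej[0].reasons
    # outside the 25-gene panel
    _, rej = filter_germline_hr([_gv(gene="TP53")])
    assert "gene_panel" in rej[0].reasons


def _mut(**kw):
    base = dict(patient_id="P", chrom="chr1", pos=1000, ref="C", alt="T",
                variant_type=VariantType.SNV, gene="TP53",
                consequence=Consequence.MISSENSE)
    base.update(kw)
    return MutationRecord(**base)


def test_driver_annotation_criteria():
    cfg = DriverCallConfig(
        driver_gene_list=frozenset({"TP53", "NOTCH1"}),
        cosmic_index={"TP53": [(1000, 1), (1010, 2)],
                      "NOTCH1": [(5005, 2)]},
        recessive_genes=frozenset({"NOTCH1"}),
    )
    # criterion i: exact position match
    assert annotate_drivers([_mut()], cfg)[0].is_driver
    # criterion i: needs >= 3 recorded mutations within 15 bp
    near = _mut(pos=1015)  # sees counts 1 + 2 = 3 within 15 bp
    assert annotate_drivers([near], cfg)[0].is_driver
    only_two = _mut(gene="NOTCH1", pos=5000, consequence=Consequence.MISSENSE)
    assert not annotate_drivers([only_two], cfg)[0].is_driver
    # criterion ii: truncating in a recessive gene with a damaging score
    rec = _mut(gene="NOTCH1", pos=9000, consequence=Consequence.NONSENSE,
               sift=0.01)
    assert annotate_drivers([rec], cfg)[0].is_driver
    # missing scores fail the score clause
    rec2 = _mut(gene="NOTCH1", pos=9000, consequence=Consequence.NONSENSE)
    assert not annotate_drivers([rec2], cfg)[0].is_driver
    # silent variants never qualify
    sil = _mut(consequence=Consequence.SILENT)
    assert not annotate_drivers([sil], cfg)[0].is_driver


def test_default_driver_config_fixture():
    from escc_ith.filters import default_driver_config

    cfg = default_driver_config()
    assert {"TP53", "NOTCH1", "ERBB4", "BRCA2"} <= cfg.driver_gene_list
    assert cfg.recessive_genes <= cfg.driver_gene_list
    assert "TP53" in cfg.recessive_genes and "PIK3CA" not in cfg.recessive_genes
    # an empty catalog index means criterion i never fires
    rec = _mut(gene="TP53", consequence=Consequence.MISSENSE)
    assert not annotate_drivers([rec], cfg)[0].is_driver


def test_neoantigen_affinity_strict_cutoff():
    kept = filter_neoantigens([("a", 499.9), ("b", 500.0), ("c", 10.0)])
    assert kept == ["a", "c"]
    assert filter_neoantigens([]) == []
    with pytest.raises(ValueError):
        filter_neoantigens([("d", -1.0)])
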