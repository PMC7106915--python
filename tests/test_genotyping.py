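"""DOC break point, allele validation, replicates, naming, copy number."""

import itertools
import math

import pytest
from hypothesis import given, settings, strategies as st

from amp_typer.amplicon import VariantTable, demultiplex, tally_variants
from amp_typer.genotyping import (AlleleRegistry, GenotypeCall, copy_number_summary,
                                  doc_breakpoint, name_alleles,
                                  replicate_concordance, validate_alleles)


def test_doc_worked_example():
    r = doc_breakpoint([5000, 4800, 4500, 4300, 120, 80])
    assert [round(x, 2) for x in r.doc] == [4.0, 6.25, 4.44, 97.21, 33.33]
    assert r.break_rank == 4


def test_doc_degenerate_and_ties():
    assert doc_breakpoint([100]).break_rank == 1
    assert doc_breakpoint([100]).doc == []
    r = doc_breakpoint([100, 100, 100])
    assert r.doc == [0.0, 0.0] and r.break_rank == 1


def test_doc_rejects_bad_input():
    with pytest.raises(ValueError):
        doc_breakpoint([100, 200])
    with pytest.raises(ValueError):
        doc_breakpoint([100, 0])
    with pytest.raises(ValueError):
        doc_breakpoint([])


def test_doc_matches_exhaustive_oracle_on_grid():
    # every non-increasing depth vector of length <= 8 over a fixed grid
    grid = [5000, 1200, 300, 90, 25]
    n_checked = 0
    for k in range(1, 9):
        for combo in itertools.combinations_with_replacement(grid, k):
            depths = sorted(combo, reverse=True)
            r = doc_breakpoint(depths)
            if k == 1:
                assert r.break_rank == 1
                continue
            oracle = [100.0 * (depths[i] - depths[i + 1]) / depths[i]
                      for i in range(k - 1)]
            best = 0
            for i, v in enumerate(oracle):
                if v > oracle[best]:
                    best = i
            assert r.doc == oracle
            assert r.break_rank == best + 1
            n_checked += 1
    assert n_checked > 1000


def _table(depths, amp="ind1|g"):
    seqs = [chr(ord("A") + i) * 10 for i in range(len(depths))]
    return VariantTable(amp, list(zip(seqs, depths)), sum(depths))


def test_validate_both_filters_worked_example():
    call = validate_alleles(_table([4000, 3000, 2500, 250, 200, 50]))
    assert call.status == "ok"
    assert len(call.alleles) == 3
    assert [d for _, d, _, _ in call.alleles] == [4000, 3000, 2500]


def test_validate_low_coverage_discarded():
    call = validate_alleles(_table([150, 100]))
    assert call.status == "discarded_low_reads"
    assert call.alleles == []


def test_validate_zero_noise_recovers_truth(zero_noise_run):
    z = zero_noise_run
    bins, _ = demultiplex(z["reads"], z["tags"])
    truth_map = dict(zip(z["truth"].amplicons.amplicon_id,
                         z["truth"].amplicons.alleles))
    for amp_id, b in sorted(bins.items()):
        call = validate_alleles(tally_variants(b))
        assert call.allele_set() == set(truth_map[amp_id].split(";"))


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.integers(min_value=1, max_value=5000), min_size=1,
                max_size=10))
def test_validate_monotonicity_and_order_invariance(depths):
    depths = sorted(depths, reverse=True)
    table = _table(depths)
    base = validate_alleles(table, min_reads=1)
    stricter = validate_alleles(table, min_reads=1, min_frac=0.10)
    no_doc = validate_alleles(table, min_reads=1, use_doc=False)
    assert stricter.allele_set() <= base.allele_set()
    assert base.allele_set() <= no_doc.allele_set()
    # row order must not matter (re-ranking is internal)
    shuffled = VariantTable(table.amplicon_id, table.variants[::-1],
                            table.total_reads)
    assert validate_alleles(shuffled, min_reads=1).allele_set() == \
        base.allele_set()


def test_chimera_flagged_but_kept():
    a = "AAAAAAAAAA"
    b = "TTTTTTTTTT"
    chim = a[:5] + b[5:]
    table = VariantTable("i|g", [(a, 5000), (b, 4000), (chim, 3000)], 12000)
    call = validate_alleles(table, min_reads=300, min_frac=0.03, use_doc=False)
    flags = {seq: fl for seq, _, _, fl in call.alleles}
    assert flags[chim] == "putative_chimera"
    assert len(call.alleles) == 3


def _call(amp, alleles, ind="i", gene="g"):
    return GenotypeCall(amp, ind, gene, "ok", 1000,
                        [(a, 100, 0.1, "") for a in alleles])


def test_replicate_concordance_sets():
    calls = {"x": _call("x", ["a", "b", "c"]), "x|rep": _call("x|rep", ["a", "b", "c"]),
             "y": _call("y", ["a", "b"]), "y|rep": _call("y|rep", ["a", "b", "c"])}
    rep = replicate_concordance(calls, {"x|rep": "x", "y|rep": "y"})
    assert [p.concordant for p in rep.pairs] == [True, False]
    assert rep.pairs[1].difference == {"c"}
    assert rep.fraction_concordant == 0.5
    with pytest.raises(ValueError):
        replicate_concordance(calls, {"z|rep": "z"})


def test_allele_naming_and_shared_species():
    calls = [
        GenotypeCall("Raar_P1_i1|Brevinin", "Raar_P1_i1", "Brevinin", "ok",
                     1000, [("AAA", 500, .5, ""), ("CCC", 300, .3, "")]),
        GenotypeCall("Rate_P2_i1|Brevinin", "Rate_P2_i1", "Brevinin", "ok",
                     1000, [("AAA", 600, .6, "")]),
    ]
    species_of = {"Raar_P1_i1": "Raar", "Rate_P2_i1": "Rate"}
    regs = name_alleles(calls, species_of, {"Brevinin": "Brev"})
    reg = regs["Brevinin"]
    # the shared allele keeps its number but carries both species codes
    assert reg.name_of("AAA") == "Raar_Rate_Brev*01"
    assert reg.name_of("CCC") == "Raar_Brev*02"
    assert calls[0].names["AAA"] == "Raar_Rate_Brev*01"
    regs2 = name_alleles(calls, species_of, {"Brevinin": "Brev"})
    assert regs2["Brevinin"].sidecar_frame().equals(reg.sidecar_frame())


def test_registry_gene_mismatch_fails():
    call = GenotypeCall("i|other", "i", "other", "ok", 1000,
                        [("AAA", 500, .5, "")])
    reg = AlleleRegistry(gene="Brevinin", gene_code="Brev")
    with pytest.raises(ValueError):
        name_alleles([call], {"i": "Raar"}, {}, {"other": reg})


def test_copy_number_summary():
    calls = [_call("a|g", [f"s{i}" for i in range(7)], ind="a"),
             _call("b|g", ["s1", "s2"], ind="b")]
    df = copy_number_summary(calls, {"a": "Raar", "b": "Raar"})
    row = df.iloc[0]
    assert row["max_alleles"] == 7
    assert row["min_loci"] == math.ceil(7 / 2)
    flat = copy_number_summary([_call("a|g", ["x", "y"], ind="a"),
                                _call("b|g", ["x", "z"], ind="b")],
                               {"a": "R", "b": "R"})
    r = flat.iloc[0]
    assert (r["min_loci"], r["mean_alleles"], r["sd_alleles"]) == (1, 2.0, 0.0)


def test_copy_number_bounded_by_simulated_loci(zero_noise_run):
    z = zero_noise_run
    bins, _ = demultiplex(z["reads"], z["tags"])
    calls = [validate_alleles(tally_variants(b)) for _, b in sorted(bins.items())
             if not b.amplicon_id.endswith("|rep")]
    species_of = {i.id: i.species for i in z["cohort"].individuals}
    df = copy_number_summary(calls, species_of)
    loci = dict(zip(z["cfg"].gene_names, z["cfg"].loci_per_gene))
    for _, row in df.iterrows():
        assert row["min_loci"] <= loci[row["gene"]]
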