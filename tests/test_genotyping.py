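"""SNP calling against the reference, ST assignment, combination
reports and the SNP-ST correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snptyper import datasets
from snptyper.assemble import LocusContig
from snptyper.errors import UsageError
from snptyper.genotyping import (
    SnpProfile,
    assign_sts,
    build_profiles,
    call_snps,
    diagnostic_sites,
    evaluate_combinations,
    pearson_snp_st,
    resolution_percent,
)


def contig_from(seq, sample="S", locus="L"):
    from snptyper._seq import HET_ALLELES

    het = tuple(i + 1 for i, b in enumerate(seq) if b in HET_ALLELES)
    return LocusContig(sample, locus, seq, het, ("both_strands",) * len(seq))


def truth_contigs(truth):
    """Noiseless shortcut: consensus == planted genotype."""
    return {
        locus: {
            s: contig_from(truth.sample_genotypes[s][locus], s, locus)
            for s in truth.sample_ids
        }
        for locus in truth.locus_ids
    }


def test_reference_sample_has_no_snps(default_truth):
    ref = default_truth.reference_sample
    for locus in default_truth.locus_ids:
        contig = contig_from(default_truth.sample_genotypes[ref][locus], ref, locus)
        assert call_snps(contig, default_truth.references[locus]) == []


def test_planted_substitutions_are_called(default_truth):
    by_sample = {}
    for s in default_truth.planted_snps:
        for carrier in s.carriers:
            by_sample.setdefault((carrier, s.locus_id), {})[s.position_1based] = s.alt_base
    for (sample, locus), expected in by_sample.items():
        contig = contig_from(default_truth.sample_genotypes[sample][locus], sample, locus)
        calls = {c.position_1based: c.sample_base for c in
                 call_snps(contig, default_truth.references[locus])}
        assert calls == expected


def test_iupac_symbol_counts_as_one_snp():
    ref = "ACGTACGT"
    contig = contig_from("ACRTACGT")
    calls = call_snps(contig, ref)
    assert [(c.position_1based, c.ref_base, c.sample_base) for c in calls] == [(3, "G", "R")]


def test_longer_contig_than_reference_is_unalignable():
    with pytest.raises(UsageError):
        call_snps(contig_from("A" * 10), "A" * 8)


def test_assign_sts_basic_counts():
    combo = ("L",)
    mk = lambda s, v: SnpProfile(s, combo, v)
    identical = [mk(f"s{i}", ("A", "C")) for i in range(5)]
    assert assign_sts(identical).n_sts == 1
    distinct = [mk(f"s{i}", ("A", str(i))) for i in range(5)]
    assert assign_sts(distinct).n_sts == 5


def test_assign_sts_numbering_by_first_occurrence():
    combo = ("L",)
    profiles = [
        SnpProfile("a", combo, ("A",)),
        SnpProfile("b", combo, ("G",)),
        SnpProfile("c", combo, ("A",)),
    ]
    reg = assign_sts(profiles)
    assert reg.st_of_sample == {"a": 1, "b": 2, "c": 1}


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.permutations(list(range(8))))
def test_assign_sts_partition_invariant_under_sample_order(perm):
    combo = ("L",)
    vecs = [("A",), ("A",), ("G",), ("T",), ("G",), ("A",), ("C",), ("T",)]
    base = [SnpProfile(f"s{i}", combo, vecs[i]) for i in range(8)]
    shuffled = [base[i] for i in perm]
    assert assign_sts(base).partition() == assign_sts(shuffled).partition()


def test_mixed_combinations_rejected():
    with pytest.raises(UsageError):
        assign_sts([SnpProfile("a", ("L1",), ("A",)), SnpProfile("b", ("L2",), ("A",))])


def test_resolution_percent_rounding():
    assert resolution_percent(19, 29) == 65.5
    assert resolution_percent(29, 29) == 100.0


def test_combination_report_snp_additivity(default_truth):
    contigs = truth_contigs(default_truth)
    refs = default_truth.references
    combos = [
        ("ITS",), ("LSU_D1-D3",), ("rbcL",), ("matK",),
        ("ITS", "LSU_D1-D3"), ("rbcL", "matK"),
        ("ITS", "LSU_D1-D3", "rbcL", "matK"),
    ]
    report = evaluate_combinations(
        {l: contigs[l] for l in ("ITS", "LSU_D1-D3", "rbcL", "matK")}, refs, combos
    )
    n = dict(zip(report["combination"], report["n_snps"]))
    assert n["ITS"] + n["LSU_D1-D3"] == n["ITS + LSU_D1-D3"] == 30
    assert n["rbcL"] + n["matK"] == n["rbcL + matK"] == 5
    assert n["ITS + LSU_D1-D3 + rbcL + matK"] == 35


def test_n_sts_monotone_under_adding_loci(default_truth):
    contigs = truth_contigs(default_truth)
    refs = default_truth.references
    chain = [("matK",), ("rbcL", "matK"), ("LSU_D1-D3", "rbcL", "matK"),
             ("ITS", "LSU_D1-D3", "rbcL", "matK")]
    report = evaluate_combinations(
        {l: contigs[l] for l in ("ITS", "LSU_D1-D3", "rbcL", "matK")}, refs, chain
    )
    sts = report["n_sts"].tolist()
    assert sts == sorted(sts)


def test_pearson_on_published_panel_counts():
    r, p = pearson_snp_st(datasets.discriminatory_power_table())
    assert round(r, 4) == 0.9182
    assert p < 1e-5


def test_pearson_perfectly_proportional():
    df = pd.DataFrame({"n_snps": [1, 2, 3, 4], "n_sts": [2, 4, 6, 8]})
    r, _ = pearson_snp_st(df)
    assert r == pytest.approx(1.0)


def test_pearson_matches_direct_formula_oracle():
    rng = np.random.default_rng(8)
    x = rng.integers(0, 40, size=15).astype(float)
    y = rng.integers(1, 25, size=15).astype(float)
    df = pd.DataFrame({"n_snps": x, "n_sts": y})
    r, _ = pearson_snp_st(df)
    expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert r == pytest.approx(expected, abs=1e-12)


def test_pearson_degenerate_inputs_rejected():
    with pytest.raises(UsageError):
        pearson_snp_st(pd.DataFrame({"n_snps": [1, 2], "n_sts": [1, 2]}))
    with pytest.raises(UsageError):
        pearson_snp_st(pd.DataFrame({"n_snps": [3, 3, 3], "n_sts": [1, 2, 3]}))


def test_diagnostic_sites_recover_planted_species_structure(default_truth):
    contigs = truth_contigs(default_truth)
    loci = ("ITS", "LSU_D1-D3", "rbcL", "matK")
    profiles, columns = build_profiles(
        {l: contigs[l] for l in loci}, default_truth.references, loci
    )
    diag = diagnostic_sites(profiles, columns, default_truth.species_labels)

    c_samples = {s for s, sp in default_truth.species_labels.items() if sp == "C"}
    b_samples = {s for s, sp in default_truth.species_labels.items() if sp == "B"}
    planted_c_cols, planted_all3_cols = set(), set()
    by_col = {}
    for s in default_truth.planted_snps:
        by_col.setdefault((s.locus_id, s.position_1based), []).append(s)
    for col, entries in by_col.items():
        carrier_sets = [set(e.carriers) for e in entries]
        if any(cs == c_samples for cs in carrier_sets):
            planted_c_cols.add(col)
            if any(cs == b_samples for cs in carrier_sets):
                planted_all3_cols.add(col)

    got_c = {(c.locus_id, c.position_1based) for c in diag["C_vs_rest"]}
    got_all = {(c.locus_id, c.position_1based) for c in diag["all_species"]}
    assert got_c == planted_c_cols
    assert got_all == planted_all3_cols
    # within-species variant columns are never diagnostic
    assert len(got_c) + len(got_all) < len(columns)


def test_shared_allele_is_not_diagnostic():
    combo = ("L",)
    profiles = [
        SnpProfile("a1", combo, ("A", "A")),
        SnpProfile("b1", combo, ("A", "G")),
        SnpProfile("c1", combo, ("G", "T")),
    ]
    from snptyper.genotyping import SnpColumn

    columns = [SnpColumn("L", 1, "A", frozenset("AG")), SnpColumn("L", 2, "A", frozenset("AGT"))]
    labels = {"a1": "A", "b1": "B", "c1": "C"}
    diag = diagnostic_sites(profiles, columns, labels)
    assert columns[0] not in diag["B_vs_rest"]  # shares A with species A
    assert columns[1] in diag["all_species"]  # three distinct alleles
    assert columns[1] in diag["C_vs_rest"]
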