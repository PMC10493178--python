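"""Summary tables: hand examples, conservation, brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from vcfcohort.annotate import FeatureCall
from vcfcohort.errors import ConfigError
from vcfcohort.records import make_record
from vcfcohort.summaries import (
    collapse_substitution,
    count_variants,
    driver_gene_tally,
    feature_distribution,
    gene_mutation_ranking,
    genome_distribution,
    indel_length_distribution,
    overlap_table,
    replicate_overlap,
    resolve_bins,
    substitution_spectrum,
)
from vcfcohort.vcf_io import Cohort


def _mini_cohort(records_by_sample, groups=None):
    groups = groups or {"g": list(records_by_sample)}
    return Cohort(groups=groups, variants=records_by_sample)


def _mk(pos, ref, alt, sample="s1", chrom="chr1"):
    return make_record(chrom, pos, ref, alt, sample)


def test_count_variants_by_class():
    c = _mini_cohort(
        {
            "s1": [
                _mk(10, "A", "G"),
                _mk(20, "C", "T"),
                _mk(30, "T", "A"),
                _mk(40, "A", "AT"),
            ],
            "s2": [],
        }
    )
    df = count_variants(c)
    s1 = df[df["sample"] == "s1"].set_index("category")["count"]
    assert s1["total"] == 4 and s1["SNV"] == 3 and s1["INSERTION"] == 1
    s2 = df[df["sample"] == "s2"].set_index("category")["count"]
    assert (s2 == 0).all()


def test_replicate_overlap_set_arithmetic():
    # A = {k1,k2,k3}, B = {k2,k3,k4}
    c = _mini_cohort(
        {
            "A": [_mk(1, "A", "G"), _mk(2, "A", "G"), _mk(3, "A", "G")],
            "B": [_mk(2, "A", "G"), _mk(3, "A", "G"), _mk(4, "A", "G")],
        }
    )
    regions = replicate_overlap(c, "g")
    assert regions[frozenset({"A"})] == 1
    assert regions[frozenset({"B"})] == 1
    assert regions[frozenset({"A", "B"})] == 2


def test_identical_replicates_only_full_intersection():
    recs = [_mk(p, "A", "G") for p in (1, 2, 3)]
    c = _mini_cohort({"A": list(recs), "B": list(recs), "C": list(recs)})
    regions = replicate_overlap(c, "g")
    for subset, n in regions.items():
        assert n == (3 if len(subset) == 3 else 0)


def test_overlap_brute_force_oracle():
    rng = np.random.default_rng(3)
    sets = {
        s: {int(p) for p in rng.integers(1, 400, size=200)} for s in ("r1", "r2", "r3")
    }
    c = _mini_cohort(
        {s: [_mk(p, "A", "G", s) for p in sorted(ps)] for s, ps in sets.items()}
    )
    regions = replicate_overlap(c, "g")
    universe = set().union(*sets.values())
    assert sum(regions.values()) == len(universe)
    for key in universe:
        membership = frozenset(s for s, ps in sets.items() if key in ps)
        # nested-loop check: each key counted in exactly its membership region
        assert regions[membership] >= 1
    # recompute regions by nested loop and compare exactly
    brute = {subset: 0 for subset in regions}
    for key in universe:
        membership = frozenset(s for s, ps in sets.items() if key in ps)
        brute[membership] += 1
    assert brute == regions


def test_overlap_unknown_group():
    c = _mini_cohort({"s1": []})
    with pytest.raises(ConfigError):
        replicate_overlap(c, "nope")


def test_overlap_matches_alleles_not_just_positions():
    c = _mini_cohort(
        {"A": [_mk(5, "A", "G")], "B": [_mk(5, "A", "T")]}
    )
    regions = replicate_overlap(c, "g")
    assert regions[frozenset({"A", "B"})] == 0
    assert regions[frozenset({"A"})] == regions[frozenset({"B"})] == 1


def test_spectrum_collapse_hand_tally():
    recs = (
        [_mk(p, "C", "A") for p in range(1, 4)]
        + [_mk(10, "G", "T")]
        + [_mk(p, "T", "C") for p in range(20, 24)]
    )
    c = _mini_cohort({"s1": recs})
    df = substitution_spectrum(c, collapse=True)
    s = df.set_index("category")
    assert s.loc["C>A", "frequency"] == 0.5  # G>T complements to C>A
    assert s.loc["T>C", "frequency"] == 0.5
    df12 = substitution_spectrum(c, collapse=False)
    s12 = df12.set_index("category")
    assert s12.loc["G>T", "count"] == 1 and s12.loc["C>A", "count"] == 3
    assert s12["count"].sum() == 8


def test_spectrum_collapse_consistency(cohort):
    six = substitution_spectrum(cohort, True)
    twelve = substitution_spectrum(cohort, False)
    twelve = twelve.assign(c6=twelve["category"].map(collapse_substitution))
    merged = (
        twelve.groupby(["sample", "c6"])["count"].sum().reset_index()
    )
    for _, row in merged.iterrows():
        got = six[(six["sample"] == row["sample"]) & (six["category"] == row["c6"])]
        assert got["count"].iloc[0] == row["count"]


def test_spectrum_no_snvs_emits_zero_frequencies():
    c = _mini_cohort({"s1": [_mk(10, "A", "AT")]})
    df = substitution_spectrum(c)
    assert (df["count"] == 0).all() and (df["frequency"] == 0).all()


def test_indel_bins_hand_example():
    recs = [
        _mk(10, "A", "AT"),
        _mk(20, "C", "CG"),
        _mk(30, "G", "GAA"),
        _mk(40, "T", "TAACCGGA"),  # insertion length 7 -> 6-10 bin
    ]
    c = _mini_cohort({"s1": recs})
    df = indel_length_distribution(c)
    ins = df[df["indel_type"] == "INSERTION"].set_index("category")
    assert ins.loc["1", "frequency"] == 0.5
    assert ins.loc["2", "frequency"] == 0.25
    assert ins.loc["6-10", "frequency"] == 0.25


def test_indel_open_bin_boundary():
    c = _mini_cohort({"s1": [_mk(10, "A" + "C" * 11, "A")]})  # deletion length 11
    df = indel_length_distribution(c)
    dele = df[df["indel_type"] == "DELETION"].set_index("category")
    assert dele.loc[">10", "count"] == 1


def test_indel_histogram_brute_force():
    rng = np.random.default_rng(8)
    lengths = rng.integers(1, 20, size=500)
    recs = [
        _mk(int(10 + 30 * i), "A", "A" + "C" * int(ln)) for i, ln in enumerate(lengths)
    ]
    c = _mini_cohort({"s1": recs})
    df = indel_length_distribution(c)
    ins = df[df["indel_type"] == "INSERTION"].set_index("category")["count"]
    bins = {"1": (1, 1), "2": (2, 2), "3": (3, 3), "4-5": (4, 5),
            "6-10": (6, 10), ">10": (11, 10**9)}
    for label, (lo, hi) in bins.items():
        assert ins[label] == int(((lengths >= lo) & (lengths <= hi)).sum())


def test_bad_bins_rejected():
    with pytest.raises(ConfigError):
        resolve_bins([3, 2])
    with pytest.raises(ConfigError):
        indel_length_distribution(_mini_cohort({"s": []}), [5, 5])


def test_window_tiling_and_conservation():
    recs = [_mk(p, "A", "G") for p in (1, 50, 100, 101, 250)] + [_mk(60, "A", "AT")]
    c = _mini_cohort({"s1": recs})
    df = genome_distribution(c, {"chr1": 250}, window_bp=100)
    w = df[df["sample"] == "s1"]
    assert list(zip(w["window_start"], w["window_end"])) == [
        (1, 100), (101, 200), (201, 250)
    ]
    assert list(w["snv_count"]) == [3, 1, 1]
    assert list(w["indel_count"]) == [1, 0, 0]
    assert w["snv_count"].sum() == 5 and w["indel_count"].sum() == 1


def test_window_unplaced_bucket():
    c = _mini_cohort({"s1": [_mk(10, "A", "G", chrom="chrZ")]})
    df = genome_distribution(c, {"chr1": 100}, window_bp=50)
    unp = df[df["chrom"] == "unplaced"]
    assert unp["snv_count"].sum() == 1


def _annotated_mini():
    recs = {
        "s1": [_mk(p, "A", "G") for p in range(1, 11)],
    }
    calls = [FeatureCall("exonic", ["GENE1"])] * 3 + [
        FeatureCall("exonic", ["GENE2"])
    ] + [FeatureCall("intergenic", [])] * 6
    return _mini_cohort(recs), {"s1": calls}


def test_feature_distribution_fractions():
    c, ann = _annotated_mini()
    df = feature_distribution(c, ann)
    s = df.set_index("category")
    assert s.loc["exonic", "frequency"] == pytest.approx(0.4)
    assert s.loc["intergenic", "frequency"] == pytest.approx(0.6)
    assert df["frequency"].sum() == pytest.approx(1.0)


def test_feature_distribution_requires_annotations():
    c, _ = _annotated_mini()
    with pytest.raises(ConfigError):
        feature_distribution(c, {})


def test_gene_ranking_and_tie_break():
    c, ann = _annotated_mini()
    df = gene_mutation_ranking(c, ann, top_n=5)
    assert list(df["gene"]) == ["GENE1", "GENE2"]
    assert list(df["count"]) == [3, 1]
    # tie: equal counts ordered lexicographically
    calls = [FeatureCall("exonic", ["GENEB"])] * 2 + [FeatureCall("exonic", ["GENEA"])] * 2
    c2 = _mini_cohort({"s1": [_mk(p, "A", "G") for p in range(1, 5)]})
    df2 = gene_mutation_ranking(c2, {"s1": calls}, top_n=2)
    assert list(df2["gene"]) == ["GENEA", "GENEB"]
    with pytest.raises(ConfigError):
        gene_mutation_ranking(c, ann, top_n=0)


def test_driver_tally():
    c, ann = _annotated_mini()
    per_gene, totals = driver_gene_tally(c, ann, ["GENE1", "OTHER"])
    assert per_gene.set_index("gene")["count"].to_dict() == {"GENE1": 3}
    assert totals["count"].iloc[0] == 3
    # no hits -> empty per-gene table, zero totals
    pg2, tot2 = driver_gene_tally(c, ann, ["NOPE"])
    assert pg2.empty and tot2["count"].iloc[0] == 0
    with pytest.raises(ConfigError):
        driver_gene_tally(c, ann, [])


def test_frequency_tables_sum_to_one(cohort, annotations):
    for df, keys in [
        (substitution_spectrum(cohort, True), ["sample"]),
        (substitution_spectrum(cohort, False), ["sample"]),
        (feature_distribution(cohort, annotations), ["sample"]),
        (indel_length_distribution(cohort), ["sample", "indel_type"]),
    ]:
        sums = df.groupby(keys)["frequency"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


def test_deterministic_tsv_output(tmp_path, cohort):
    from vcfcohort.summaries import write_tsv

    df = count_variants(cohort)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_tsv(df, p1)
    write_tsv(count_variants(cohort), p2)
    assert p1.read_bytes() == p2.read_bytes()
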