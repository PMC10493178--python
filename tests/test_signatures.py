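"""SBS96 channeling, NMF extraction, exposure refitting, catalog matching."""

import numpy as np
import pandas as pd
import pytest

from vcfcohort.errors import ConfigError, DegenerateInputError, FormatError
from vcfcohort.records import make_record
from vcfcohort.signatures import (
    CHANNELS,
    SBS96Matrix,
    _kl_divergence,
    build_sbs96,
    context_channel,
    cosine_similarity_matrix,
    extract_signatures,
    fit_exposures,
    match_to_catalog,
    read_signature_tsv,
    trinucleotide_context,
    write_signatures,
)
from vcfcohort.simulate import (
    make_exposures,
    make_signature_catalog,
    simulate_sbs96_counts,
)
from vcfcohort.summaries import count_variants


def test_channel_order_is_canonical():
    assert len(CHANNELS) == 96
    assert CHANNELS[0] == "A[C>A]A"
    assert CHANNELS[15] == "T[C>A]T"
    assert CHANNELS[16] == "A[C>G]A"
    assert CHANNELS[-1] == "T[T>G]T"


@pytest.mark.parametrize(
    "trinuc,ref,alt,expected",
    [
        ("ACA", "C", "T", "A[C>T]A"),  # pyrimidine ref, no collapse
        ("TGC", "G", "A", "G[C>T]A"),  # revcomp: TGC -> GCA, G>A -> C>T
        ("AAT", "A", "C", "A[T>G]T"),  # revcomp: AAT -> ATT, A>C -> T>G
        ("GTG", "T", "A", "G[T>A]G"),
    ],
)
def test_context_channel_hand_cases(trinuc, ref, alt, expected):
    assert context_channel(trinuc, ref, alt) == expected


def test_context_with_n_is_dropped():
    assert context_channel("NCA", "C", "T") is None


def test_chromosome_boundary_dropped(bundle):
    from pyfaidx import Fasta

    fa = Fasta(str(bundle["genome"].fasta_path))
    chrom = list(bundle["genome"].sizes)[0]
    base = str(fa[chrom][0]).upper()
    alt = "A" if base != "A" else "G"
    v = make_record(chrom, 1, base, alt, "s")
    assert trinucleotide_context(v, fa) is None


def test_build_sbs96_single_snv(tmp_path):
    from vcfcohort.vcf_io import Cohort

    fa_path = tmp_path / "g.fa"
    fa_path.write_text(">chr1\nAACAT\n")
    from pyfaidx import Faidx

    Faidx(str(fa_path))
    cohort = Cohort(
        groups={"g": ["s1"]},
        variants={"s1": [make_record("chr1", 3, "C", "T", "s1")]},
    )
    m = build_sbs96(cohort, fa_path)
    col = m.counts["s1"]
    assert col["A[C>T]A"] == 1 and col.sum() == 1


def test_build_sbs96_conservation_and_manifest(cohort, bundle, manifest):
    m = build_sbs96(cohort, bundle["genome"].fasta_path)
    totals = count_variants(cohort)
    for s in cohort.samples:
        snv_total = totals[
            (totals["sample"] == s) & (totals["category"] == "SNV")
        ]["count"].iloc[0]
        assert m.counts[s].sum() + m.dropped[s] == snv_total
        assert m.counts[s].to_dict() == manifest["samples"][s]["channel_counts"]


def test_build_sbs96_missing_chromosome(cohort):
    with pytest.raises((FormatError, KeyError, OSError)):
        build_sbs96(cohort, "/nonexistent/genome.fa")


def test_extract_rank1_recovery():
    sig = make_signature_catalog(seed=2, k=4).iloc[:, [0]]
    expo = pd.DataFrame(
        [[2000.0 + 100 * i for i in range(20)]],
        index=sig.columns, columns=[f"S{i}" for i in range(20)],
    )
    m = simulate_sbs96_counts(sig, expo, seed=3)
    W, H, err = extract_signatures(m, k=1, n_restarts=3, seed=4)
    cos = cosine_similarity_matrix(W, sig).iloc[0, 0]
    assert cos >= 0.99
    np.testing.assert_allclose(W.sum(axis=0), 1.0, atol=1e-9)


def test_extract_single_channel_unit_vector():
    counts = pd.DataFrame(0.0, index=list(CHANNELS), columns=["s1", "s2"])
    counts.loc["A[C>T]G"] = [50.0, 80.0]
    m = SBS96Matrix(counts, pd.Series(0, index=["s1", "s2"]))
    W, H, _ = extract_signatures(m, k=1, n_restarts=2, seed=0)
    assert W.loc["A[C>T]G"].iloc[0] == pytest.approx(1.0, abs=1e-6)


def test_reconstruction_error_nested_in_k():
    sigs = make_signature_catalog(seed=5, k=3)
    expo = make_exposures(12, sigs, 3000, seed=6)
    m = simulate_sbs96_counts(sigs, expo, seed=7)
    _, _, e1 = extract_signatures(m, k=1, n_restarts=3, seed=8)
    _, _, e2 = extract_signatures(m, k=2, n_restarts=3, seed=8)
    assert e2 <= e1


def test_extract_validation_errors():
    counts = pd.DataFrame(0.0, index=list(CHANNELS), columns=["s1", "s2"])
    m = SBS96Matrix(counts, pd.Series(0, index=["s1", "s2"]))
    with pytest.raises(DegenerateInputError):
        extract_signatures(m, k=1)
    counts2 = counts.copy()
    counts2.iloc[0] = 1.0
    m2 = SBS96Matrix(counts2, pd.Series(0, index=["s1", "s2"]))
    with pytest.raises(ConfigError):
        extract_signatures(m2, k=3)  # k > n_samples
    with pytest.raises(ConfigError):
        extract_signatures(m2, k=1, n_restarts=0)


def test_extract_seed_determinism():
    sigs = make_signature_catalog(seed=20, k=2)
    expo = make_exposures(8, sigs, 2000, seed=21)
    m = simulate_sbs96_counts(sigs, expo, seed=22)
    a = extract_signatures(m, k=2, n_restarts=4, seed=9)
    b = extract_signatures(m, k=2, n_restarts=4, seed=9)
    assert (a[0].values == b[0].values).all()
    assert (a[1].values == b[1].values).all()
    assert a[2] == b[2]


def test_fit_exposures_exact_recovery():
    sigs = make_signature_catalog(seed=30, k=4)
    expo = make_exposures(10, sigs, 4000, seed=31)
    m = simulate_sbs96_counts(sigs, expo, seed=0, poisson=False)
    fitted = fit_exposures(m, sigs)
    rel = np.abs(fitted.to_numpy() - expo.to_numpy()) / expo.to_numpy()
    assert rel.max() < 1e-6


def test_fit_exposures_zero_column():
    sigs = make_signature_catalog(seed=32, k=2)
    counts = pd.DataFrame(0.0, index=list(CHANNELS), columns=["s1"])
    m = SBS96Matrix(counts, pd.Series(0, index=["s1"]))
    fitted = fit_exposures(m, sigs)
    assert (fitted.to_numpy() == 0).all()


def test_fit_exposures_channel_order_check():
    sigs = make_signature_catalog(seed=33, k=2).iloc[::-1]
    counts = pd.DataFrame(1.0, index=list(CHANNELS), columns=["s1"])
    m = SBS96Matrix(counts, pd.Series(0, index=["s1"]))
    with pytest.raises(FormatError):
        fit_exposures(m, sigs)


def test_cosine_formula_oracle():
    rng = np.random.default_rng(40)
    a = pd.DataFrame(rng.random((96, 3)), index=list(CHANNELS), columns=list("abc"))
    b = pd.DataFrame(rng.random((96, 2)), index=list(CHANNELS), columns=list("xy"))
    sim = cosine_similarity_matrix(a, b)
    for i in a.columns:
        for j in b.columns:
            u, v = a[i].to_numpy(), b[j].to_numpy()
            direct = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            assert sim.loc[i, j] == pytest.approx(direct, abs=1e-12)


def test_match_to_catalog_self_and_orthogonal():
    cat = make_signature_catalog(seed=50, k=3)
    matches, sim = match_to_catalog(cat, cat)
    assert list(matches["best_match"]) == list(cat.columns)
    assert np.allclose(matches["cosine"], 1.0)
    e1 = pd.DataFrame(0.0, index=list(CHANNELS), columns=["u"])
    e2 = pd.DataFrame(0.0, index=list(CHANNELS), columns=["v"])
    e1.iloc[0, 0] = 1.0
    e2.iloc[1, 0] = 1.0
    assert cosine_similarity_matrix(e1, e2).iloc[0, 0] == pytest.approx(0.0)


def test_catalog_tsv_round_trip_and_reordering(tmp_path):
    cat = make_signature_catalog(seed=60, k=4)
    p = tmp_path / "cat.tsv"
    write_signatures(cat, p)
    back = read_signature_tsv(p)
    np.testing.assert_allclose(back.to_numpy(), cat.to_numpy(), atol=1e-9)
    # shuffled rows are restored to canonical order on load
    shuffled = cat.sample(frac=1.0, random_state=0)
    out = shuffled.copy()
    out.insert(0, "Type", out.index)
    out.to_csv(tmp_path / "shuf.tsv", sep="\t", index=False)
    back2 = read_signature_tsv(tmp_path / "shuf.tsv")
    np.testing.assert_allclose(back2.to_numpy(), cat.to_numpy(), atol=1e-9)
    with pytest.raises(FormatError):
        out.iloc[: 50].to_csv(tmp_path / "short.tsv", sep="\t", index=False)
        read_signature_tsv(tmp_path / "short.tsv")


def test_kl_objective_competitive_with_sklearn():
    """Independent cross-check: sklearn's KL-NMF on the same matrix.

    Both minimize the same generalized KL objective; our multi-restart best
    must land within a few percent of sklearn's solution (evaluated under
    our own objective function).
    """
    from sklearn.decomposition import NMF

    sigs = make_signature_catalog(seed=70, k=3)
    expo = make_exposures(15, sigs, 3000, seed=71)
    m = simulate_sbs96_counts(sigs, expo, seed=72)
    V = m.values()
    _, _, ours = extract_signatures(m, k=3, n_restarts=5, seed=73)
    sk = NMF(
        n_components=3, beta_loss="kullback-leibler", solver="mu",
        init="random", random_state=0, max_iter=2000, tol=1e-8,
    )
    Wsk = sk.fit_transform(V)
    theirs = _kl_divergence(V, np.maximum(Wsk @ sk.components_, 1e-12))
    assert ours <= theirs * 1.05
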