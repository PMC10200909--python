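import numpy as np
import pandas as pd
import pytest

from cfquad.fragmentomics import (
    ALL_MOTIFS,
    EM_DIM,
    FLEN_DIM,
    em_differential,
    em_first_base_summary,
    em_vector,
    extract_end_motifs,
    flen_distribution_test,
    flen_vector,
    revcomp,
    short_fragment_fraction,
)
from conftest import random_fragments


def _frame(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "strand_fwd_read",
                 "n_meth_cpg", "n_total_cpg", "end_motif"],
    )


# ------------------------------------------------------------------- Flen


def test_flen_all_167():
    df = _frame([("s", "c", 0, 167, "+", 0, 0, None)] * 4)
    v = flen_vector(df)
    assert len(v) == FLEN_DIM == 151
    assert v.loc[167] == pytest.approx(100.0)
    assert v.drop(167).sum() == 0


def test_flen_boundary_inclusive():
    df = _frame([
        ("s", "c", 0, 100, "+", 0, 0, None),
        ("s", "c", 0, 250, "+", 0, 0, None),
        ("s", "c", 0, 99, "+", 0, 0, None),    # below range: excluded
        ("s", "c", 0, 251, "+", 0, 0, None),   # above range: excluded
    ])
    v = flen_vector(df)
    assert v.loc[100] == pytest.approx(50.0)
    assert v.loc[250] == pytest.approx(50.0)
    assert v.sum() == pytest.approx(100.0)


def test_flen_matches_histogram_oracle(rng, small_model):
    df = random_fragments(rng, small_model, 1000)
    v = flen_vector(df)
    lengths = (df["end"] - df["start"]).to_numpy()
    lengths = lengths[(lengths >= 100) & (lengths <= 250)]
    hist, _ = np.histogram(lengths, bins=np.arange(100, 252))
    np.testing.assert_allclose(v.to_numpy(), 100 * hist / hist.sum())


def test_flen_no_inrange_fragments_flagged():
    df = _frame([("s", "c", 0, 50, "+", 0, 0, None)])
    assert flen_vector(df).isna().all()


def test_flen_group_test_identical_and_short_fraction():
    idx = pd.RangeIndex(100, 251)
    pmf = np.exp(-0.5 * ((np.asarray(idx) - 167) / 9) ** 2)
    profile = pd.Series(100 * pmf / pmf.sum(), index=idx)
    group = pd.DataFrame([profile, profile])
    res, med_a, med_b = flen_distribution_test(group, group.copy())
    assert res.pvalue > 0.99
    assert med_a == med_b == 167
    assert short_fragment_fraction(profile) < 0.05


def test_flen_hcc_short_excess_detected():
    from cfquad.fragmentomics import flen_matrix
    from cfquad.simulate import cohort_spec, generate_cohort

    spec = cohort_spec("hcc", n_cancer=6, n_control=6,
                       fragments_per_sample=30_000, seed=5,
                       tumor_fraction_mean=0.15)
    r = generate_cohort(spec)
    mat = flen_matrix(r.frames)
    cancer = mat[mat.index.str.startswith("cancer")]
    control = mat[mat.index.str.startswith("control")]
    res, _, _ = flen_distribution_test(cancer, control)
    short_c = short_fragment_fraction(cancer.mean(axis=0))
    short_h = short_fragment_fraction(control.mean(axis=0))
    assert short_c > short_h
    assert res.pvalue < 0.01


def test_flen_breast_preset_no_shift():
    from cfquad.fragmentomics import flen_matrix
    from cfquad.simulate import cohort_spec, generate_cohort

    spec = cohort_spec("breast", n_cancer=6, n_control=6,
                       fragments_per_sample=30_000, seed=6)
    r = generate_cohort(spec)
    mat = flen_matrix(r.frames)
    res, _, _ = flen_distribution_test(
        mat[mat.index.str.startswith("cancer")],
        mat[mat.index.str.startswith("control")],
    )
    assert res.pvalue > 0.05


# ------------------------------------------------------------------ motifs


def _write_fasta(path, seqs):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    return str(path)


def test_extract_plus_strand(tmp_path):
    ref = _write_fasta(tmp_path / "r.fa", {"c": "GGAGTT" + "A" * 200})
    df = _frame([("s", "c", 0, 150, "+", 0, 0, None)])
    assert extract_end_motifs(df, ref).iloc[0] == "GGAG"


def test_extract_minus_strand_revcomp(tmp_path):
    ref = _write_fasta(tmp_path / "r.fa", {"c": "C" * 146 + "AAAT" + "C" * 50})
    df = _frame([("s", "c", 0, 150, "-", 0, 0, None)])
    assert extract_end_motifs(df, ref).iloc[0] == "ATTT"


def test_extract_n_missing_and_short_error(tmp_path):
    ref = _write_fasta(tmp_path / "r.fa", {"c": "GGNG" + "A" * 200})
    df = _frame([("s", "c", 0, 150, "+", 0, 0, None)])
    assert extract_end_motifs(df, ref).isna().iloc[0]
    short = _frame([("s", "c", 0, 3, "+", 0, 0, None)])
    with pytest.raises(ValueError, match="4 bp"):
        extract_end_motifs(short, ref)


def test_strand_symmetry(tmp_path, rng):
    """Extracting from the reverse-complemented genome with flipped strand
    and mirrored coordinates yields the reverse-complemented... motif is
    preserved as the fragment's 5' template-strand end."""
    L = 400
    seq = "".join(rng.choice(list("ACGT"), size=L))
    fwd = _write_fasta(tmp_path / "f.fa", {"c": seq})
    rev = _write_fasta(tmp_path / "rv.fa", {"c": revcomp(seq)})
    start, end = 37, 199
    plus = _frame([("s", "c", start, end, "+", 0, 0, None)])
    # same physical fragment on the flipped assembly: coords mirror, strand flips
    mirrored = _frame([("s", "c", L - end, L - start, "-", 0, 0, None)])
    m1 = extract_end_motifs(plus, fwd).iloc[0]
    m2 = extract_end_motifs(mirrored, rev).iloc[0]
    assert m1 == m2


def test_em_vector_single_and_invariances(rng, small_model):
    single = _frame([("s", "c", 0, 150, "+", 0, 0, "AAAA")])
    v = em_vector(single)
    assert len(v) == EM_DIM == 256
    assert v.iloc[0] == 1.0 and v.iloc[1:].sum() == 0

    df = random_fragments(rng, small_model, 500)
    v1 = em_vector(df)
    assert v1.sum() == pytest.approx(1.0, abs=1e-9)
    # order invariance and duplication invariance
    pd.testing.assert_series_equal(v1, em_vector(df.sample(frac=1, random_state=3)))
    pd.testing.assert_series_equal(v1, em_vector(pd.concat([df, df])))


def test_em_vector_matches_tally_oracle(rng, small_model):
    df = random_fragments(rng, small_model, 800)
    v = em_vector(df)
    tally = df["end_motif"].value_counts()
    for motif in ALL_MOTIFS:
        expected = tally.get(motif, 0) / len(df)
        assert v[motif] == pytest.approx(expected)


def test_em_vector_requires_usable_motifs():
    df = _frame([("s", "c", 0, 150, "+", 0, 0, np.nan)])
    with pytest.raises(ValueError, match="usable"):
        em_vector(df)


def test_generator_extractor_consistency(tmp_path):
    """The synthetic reference is written so the extractor recovers every
    fragment's drawn motif."""
    from cfquad.simulate import cohort_spec, generate_cohort

    spec = cohort_spec("breast", n_cancer=2, n_control=2,
                       fragments_per_sample=2000, seed=9)
    r = generate_cohort(spec, outdir=tmp_path / "cohort", write_reference=True)
    from cfquad.fragments import read_fragment_table

    for sid in r.frames:
        rep = read_fragment_table(tmp_path / "cohort" / f"{sid}.fragments.tsv.gz")
        derived = extract_end_motifs(rep.frame, str(tmp_path / "cohort" / "reference.fa"))
        assert (derived == rep.frame["end_motif"]).all()


def test_em_differential_identical_groups(rng):
    base = rng.dirichlet(np.ones(256) * 50, size=12)
    cancer = pd.DataFrame(base[:6], columns=ALL_MOTIFS)
    control = pd.DataFrame(base[6:], columns=ALL_MOTIFS)
    table = em_differential(cancer, control)
    assert (table["category"] == "ns").all()
    summary = em_first_base_summary(table)
    assert list(summary.index) == ["A", "C", "G", "T"]
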