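import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cfquad.cna import (
    bin_read_counts,
    call_significant_bins,
    cna_zscores,
    gc_correct,
    normalize_and_smooth,
)
from cfquad.genome import locate_bin
from conftest import random_fragments


def test_empty_sample_zero_counts(small_model):
    empty = random_fragments(np.random.default_rng(0), small_model, 0)
    assert (bin_read_counts(empty, small_model) == 0).all()


def test_counts_single_bin(small_model):
    rng = np.random.default_rng(1)
    df = random_fragments(rng, small_model, 5)
    df["chrom"], df["start"], df["end"] = "chrA", 100, 300
    counts = bin_read_counts(df, small_model)
    assert counts.iloc[0] == 5 and counts.iloc[1:].sum() == 0


def test_counts_match_tally_oracle(rng, small_model):
    df = random_fragments(rng, small_model, 200)
    counts = bin_read_counts(df, small_model)
    tally = np.zeros(small_model.n_bins)
    for _, row in df.iterrows():
        tally[locate_bin(small_model, row["chrom"], row["start"])] += 1
    np.testing.assert_array_equal(counts.to_numpy(), tally)


# ---------------------------------------------------------------- GC trend


def test_gc_correct_flat_counts():
    gc = np.linspace(0.3, 0.6, 50)
    counts = pd.Series(np.full(50, 80.0))
    corrected = gc_correct(counts, gc)
    np.testing.assert_allclose(corrected, counts / counts.mean(), atol=1e-6)


def test_gc_correct_removes_linear_trend():
    gc = np.linspace(0.3, 0.6, 100)
    counts = pd.Series(100.0 * (1 + gc))
    corrected = gc_correct(counts, gc)
    inner = corrected.iloc[5:-5]  # lowess edge bins are less constrained
    assert inner.max() / inner.min() < 1.01


def test_gc_correct_removes_injected_logistic_bias(rng):
    from scipy.special import expit

    gc = rng.uniform(0.3, 0.7, 300)
    expected = np.full(300, 200.0)
    bias = 2 * expit(4 * (gc - 0.5))
    counts = pd.Series(rng.poisson(expected * bias).astype(float))
    assert np.corrcoef(counts, gc)[0, 1] > 0.5  # injected trend is strong
    corrected = gc_correct(counts, gc)
    assert abs(np.corrcoef(corrected, gc)[0, 1]) < 0.1


def test_gc_correct_too_few_bins():
    with pytest.raises(ValueError, match="20 bins"):
        gc_correct(pd.Series(np.ones(10)), np.linspace(0.3, 0.6, 10))


# ------------------------------------------------------- normalize / smooth


def test_normalize_constant_vector():
    out = normalize_and_smooth(pd.Series(np.full(30, 7.0)))
    np.testing.assert_allclose(out, 1.0)


def test_spike_replaced_by_local_median():
    v = np.ones(40)
    v[20] = 9.0
    out = normalize_and_smooth(pd.Series(v))
    assert out.iloc[20] == pytest.approx(1.0)
    np.testing.assert_allclose(out, 1.0)


def test_smoothing_idempotent():
    rng = np.random.default_rng(2)
    v = 1 + 0.05 * rng.standard_normal(200)
    v[[30, 90, 150]] = [4.0, 0.1, 6.0]
    once = normalize_and_smooth(pd.Series(v))
    twice = normalize_and_smooth(once)
    np.testing.assert_allclose(twice, once, rtol=1e-9)


def test_normalized_median_is_one(rng):
    v = pd.Series(rng.gamma(5, 20, 150))
    out = normalize_and_smooth(v)
    assert np.nanmedian(out) == pytest.approx(1.0, abs=0)


def test_zero_median_errors():
    with pytest.raises(ValueError, match="median"):
        normalize_and_smooth(pd.Series(np.zeros(30)))


# ---------------------------------------------------------------- Z-scores


def test_zscore_hand_computation():
    bins = ["b1"]
    control = pd.DataFrame({"b1": [1.0, 1.0, 1.0, 3.0]})  # mean 1.5, SD 1.0
    cancer = pd.DataFrame({"b1": [2.5]}, index=["c1"])
    z = cna_zscores(cancer, control)
    assert z.loc["c1", "b1"] == pytest.approx(1.0)
    assert z.loc["mean", "b1"] == pytest.approx(1.0)


def test_zscore_zero_at_control_mean():
    control = pd.DataFrame({"b1": [0.8, 1.0, 1.2]})
    cancer = pd.DataFrame({"b1": [1.0]}, index=["c1"])
    assert cna_zscores(cancer, control).loc["c1", "b1"] == pytest.approx(0.0)


def test_zscore_scale_invariance(rng):
    bins = [f"b{i}" for i in range(20)]
    control = pd.DataFrame(rng.normal(1, 0.1, (8, 20)), columns=bins)
    cancer = pd.DataFrame(rng.normal(1.2, 0.1, (5, 20)), columns=bins)
    z1 = cna_zscores(cancer, control)
    z2 = cna_zscores(cancer * 3.0, control * 3.0)
    pd.testing.assert_frame_equal(z1, z2, check_exact=False)


def test_zscore_zero_sd_flagged():
    control = pd.DataFrame({"b1": [1.0, 1.0, 1.0]})
    cancer = pd.DataFrame({"b1": [1.5]}, index=["c1"])
    assert cna_zscores(cancer, control)["b1"].isna().all()


# ----------------------------------------------------------- bin calling


def test_identical_groups_no_calls(rng):
    bins = [f"b{i}" for i in range(30)]
    base = rng.normal(1, 0.05, (10, 30))
    table = call_significant_bins(
        pd.DataFrame(base, columns=bins), pd.DataFrame(base.copy(), columns=bins)
    )
    assert (table["category"] == "ns").all()


def test_constructed_gain_called_increase(rng):
    bins = [f"b{i}" for i in range(30)]
    control = pd.DataFrame(rng.normal(1, 0.05, (20, 30)), columns=bins)
    cancer = pd.DataFrame(rng.normal(1, 0.05, (20, 30)), columns=bins)
    cancer["b7"] *= 1.5
    table = call_significant_bins(cancer, control).set_index("feature")
    assert table.loc["b7", "category"] == "increase"
    assert (table.drop(index="b7")["category"] == "ns").sum() >= 27


def wilcoxon_bh_oracle(cancer, control, alpha=0.05):
    """Rank-sum by explicit rank computation + BH by sorting, per bin."""
    stats, ps = [], []
    for col in cancer.columns:
        a, b = cancer[col].to_numpy(), control[col].to_numpy()
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        n1, n2 = len(a), len(b)
        r1 = ranks[:n1].sum()
        u1 = r1 - n1 * (n1 + 1) / 2
        mu = n1 * n2 / 2
        # tie-corrected variance + continuity correction (matches the
        # asymptotic Mann-Whitney convention)
        _, counts = np.unique(pooled, return_counts=True)
        tie = (counts**3 - counts).sum()
        n = n1 + n2
        var = n1 * n2 / 12 * ((n + 1) - tie / (n * (n - 1)))
        z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
        ps.append(min(1.0, 2 * sps.norm.sf(z)))
        stats.append(max(u1, n1 * n2 - u1))
    m = len(ps)
    order = np.argsort(ps, kind="mergesort")
    q_sorted = np.minimum.accumulate(
        (m * np.array(ps)[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1)
    return np.array(ps), q


def test_calls_match_bruteforce_on_small_fixture(rng):
    bins = [f"b{i}" for i in range(8)]
    control = pd.DataFrame(rng.normal(1, 0.1, (12, 8)), columns=bins)
    cancer = pd.DataFrame(rng.normal(1, 0.1, (12, 8)), columns=bins)
    cancer["b2"] += 0.4
    table = call_significant_bins(cancer, control)
    p_oracle, q_oracle = wilcoxon_bh_oracle(cancer, control)
    np.testing.assert_allclose(table["p"], p_oracle, rtol=1e-8)
    np.testing.assert_allclose(table["q"], q_oracle, rtol=1e-8)


def test_constant_bin_p_one():
    control = pd.DataFrame({"b1": [1.0] * 5, "b2": [1.0, 1.1, 0.9, 1.0, 1.2]})
    cancer = pd.DataFrame({"b1": [1.0] * 5, "b2": [1.0, 1.2, 1.1, 0.8, 1.0]})
    table = call_significant_bins(cancer, control).set_index("feature")
    assert table.loc["b1", "p"] == 1.0
    assert table.loc["b1", "category"] == "ns"
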