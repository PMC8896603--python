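import numpy as np
import pandas as pd
import pytest
import scipy.stats

from slidenorm import (
    EvalReport,
    SimConfig,
    ad_ksample,
    adjusted_rand_index,
    apply_transform,
    evaluate_method,
    marker_positive_accuracy,
    otsu_discordance,
    otsu_threshold,
    simulate_table,
    variance_proportion,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def ad_direct_formula(samples):
    """Direct scalar evaluation of the midrank k-sample AD statistic (unstandardized)."""
    pooled = sorted(v for s in samples for v in s)
    zstar = sorted(set(pooled))
    N = len(pooled)
    k = len(samples)
    a2 = 0.0
    for sample in samples:
        n_i = len(sample)
        inner = 0.0
        Bc = 0.0
        Mc = 0.0
        for z in zstar:
            l_j = sum(1 for v in pooled if v == z)
            f_ij = sum(1 for v in sample if v == z)
            Bc += l_j
            Mc += f_ij
            B = Bc - l_j / 2.0
            M = Mc - f_ij / 2.0
            denom = B * (N - B) - N * l_j / 4.0
            inner += (l_j / N) * (N * M - n_i * B) ** 2 / denom
        a2 += inner / n_i
    return (N - 1) / N * a2


def otsu_brute_force(values, nbins):
    """Exhaustive edge scan maximizing between-class variance."""
    values = np.asarray(values, dtype=float)
    edges = np.histogram_bin_edges(values, bins=nbins, range=(values.min(), values.max()))
    best_t, best_s = None, -1.0
    n = values.size
    for t in edges[1:-1]:
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            s = 0.0
        else:
            s = (lo.size / n) * (hi.size / n) * (lo.mean() - hi.mean()) ** 2
        if s > best_s:  # strict: ties keep the smallest edge
            best_t, best_s = t, s
    return best_t


# ---------------------------------------------------------------------------
# k-sample Anderson–Darling
# ---------------------------------------------------------------------------

def test_ad_matches_direct_formula_on_small_samples():
    rng = np.random.default_rng(0)
    cases = [
        [[1, 2, 3, 4, 5], [1, 2, 3, 4, 5]],
        [list(rng.integers(0, 10, 30)), list(rng.integers(0, 10, 25))],
        [list(rng.normal(size=40)), list(rng.normal(1, 1, 35)), list(rng.normal(size=20))],
    ]
    for samples in cases:
        mine = ad_ksample([np.asarray(s, float) for s in samples], standardized=False)
        assert mine == pytest.approx(ad_direct_formula(samples), rel=1e-10)


def test_ad_standardized_matches_scipy():
    rng = np.random.default_rng(1)
    samples = [rng.normal(size=60), rng.normal(0.5, 1.2, 45), rng.integers(0, 5, 50).astype(float)]
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = scipy.stats.anderson_ksamp(samples).statistic
    assert ad_ksample(samples) == pytest.approx(ref, rel=1e-9)


def test_ad_separation_increases_statistic():
    a = np.arange(1.0, 21.0)
    far = ad_ksample([a, a + 1000.0])
    near = ad_ksample([a, a + 0.5])
    assert far > near


def test_ad_is_rank_invariant_to_cell_order():
    rng = np.random.default_rng(2)
    s1, s2 = rng.normal(size=50), rng.normal(1, 1, 40)
    base = ad_ksample([s1, s2])
    assert ad_ksample([rng.permutation(s1), rng.permutation(s2)]) == pytest.approx(base)


def test_ad_input_validation():
    with pytest.raises(ValueError):
        ad_ksample([np.arange(5.0)])
    with pytest.raises(ValueError):
        ad_ksample([np.arange(5.0), np.array([])])


# ---------------------------------------------------------------------------
# Otsu
# ---------------------------------------------------------------------------

def test_otsu_separates_clean_bimodal():
    values = np.array([0.0] * 50 + [10.0] * 50)
    t = otsu_threshold(values)
    assert 0.0 < t <= 10.0
    assert np.array_equal(values > t, values == 10.0)


def test_otsu_equals_brute_force_scan():
    values = np.array([1, 2, 3, 4, 5, 6, 100, 101, 102], dtype=float)
    assert otsu_threshold(values, nbins=64) == pytest.approx(otsu_brute_force(values, 64))
    rng = np.random.default_rng(3)
    generators = [
        lambda: rng.integers(0, 256, 500).astype(float),
        lambda: rng.lognormal(3.0, 0.8, 400),
        lambda: np.round(rng.lognormal(3.0, 0.8, 300)),
    ]
    for _ in range(7):
        for gen in generators:
            v = gen()
            assert otsu_threshold(v, nbins=128) == pytest.approx(otsu_brute_force(v, 128))


def test_otsu_affine_equivariance():
    rng = np.random.default_rng(4)
    v = rng.lognormal(2.0, 0.7, 1000)
    t = otsu_threshold(v, nbins=256)
    a, b = 3.5, 11.0
    t2 = otsu_threshold(a * v + b, nbins=256)
    assert t2 == pytest.approx(a * t + b, rel=1e-9)


def test_otsu_degenerate_error():
    with pytest.raises(ValueError):
        otsu_threshold(np.full(10, 7.0))


def test_discordance_zero_when_slides_match_global():
    base = [0.0] * 20 + [10.0] * 20
    table = make_table({"m": {"s1": base, "s2": base}})
    per_slide, mean = otsu_discordance(table, "m")
    assert mean == 0.0
    assert per_slide.tolist() == [0.0, 0.0]


def test_discordance_hand_enumeration():
    # slide A {0,0,10,10}, slide B {0,0,4,10}
    table = make_table({"m": {"A": [0.0, 0.0, 10.0, 10.0], "B": [0.0, 0.0, 4.0, 10.0]}})
    per_slide, mean = otsu_discordance(table, "m", nbins=8)
    y = table.intensities("m")
    o_global = otsu_threshold(y, nbins=8)
    expected = {}
    for slide in ("A", "B"):
        yi = table.data.loc[table.data["slide_id"] == slide, "m"].to_numpy()
        o_slide = otsu_threshold(yi, nbins=8)
        expected[slide] = float(np.mean((yi > o_slide) != (yi > o_global)))
    assert per_slide.to_dict() == expected
    assert mean == pytest.approx(np.mean(list(expected.values())))


def test_discordance_invariant_to_duplicating_cells():
    rng = np.random.default_rng(5)
    vals = {f"s{i}": list(np.round(rng.lognormal(3, 0.6 + 0.1 * i, 200))) for i in range(3)}
    t1 = make_table({"m": vals})
    t2 = make_table({"m": {s: v + v for s, v in vals.items()}})
    p1, m1 = otsu_discordance(t1, "m")
    p2, m2 = otsu_discordance(t2, "m")
    assert m1 == pytest.approx(m2)
    assert p1.to_dict() == pytest.approx(p2.to_dict())


def test_marker_positive_accuracy_extremes():
    rng = np.random.default_rng(6)
    v = np.concatenate([rng.normal(10, 2, 100), rng.normal(100, 5, 100)])
    table = make_table({"m": {"s1": list(np.clip(v, 0, None))}})
    y = table.intensities("m")
    calls = y > otsu_threshold(y)
    assert marker_positive_accuracy(table, "m", labels=calls.astype(int)) == 1.0
    assert marker_positive_accuracy(table, "m", labels=(~calls).astype(int)) == 0.0
    mixed = calls.copy()
    mixed[:20] = ~mixed[:20]
    assert marker_positive_accuracy(table, "m", labels=mixed.astype(int)) == pytest.approx(0.9)


# ---------------------------------------------------------------------------
# variance proportion
# ---------------------------------------------------------------------------

def make_icc_data(icc, n_slides=20, n_cells=2000, seed=0):
    rng = np.random.default_rng(seed)
    s2_slide = icc
    s2_res = 1.0 - icc
    b = rng.normal(0, np.sqrt(s2_slide), n_slides)
    y = np.repeat(b, n_cells) + rng.normal(0, np.sqrt(s2_res), n_slides * n_cells)
    slides = np.repeat([f"s{i}" for i in range(n_slides)], n_cells)
    return y, slides


def test_variance_proportion_null_case():
    y, slides = make_icc_data(0.0, seed=1)
    assert variance_proportion(y, slides) < 0.01


def test_variance_proportion_saturates():
    rng = np.random.default_rng(2)
    b = rng.normal(0, 10.0, 10)
    y = np.repeat(b, 200) + rng.normal(0, 0.01, 2000)
    slides = np.repeat([f"s{i}" for i in range(10)], 200)
    assert variance_proportion(y, slides) > 0.99


def icc_fisher_se(icc, n_slides, n_cells):
    """Large-sample standard error of the one-way intraclass correlation."""
    n = n_cells
    return np.sqrt(
        2 * (1 - icc) ** 2 * (1 + (n - 1) * icc) ** 2 / (n * (n - 1) * (n_slides - 1))
    )


def test_variance_proportion_recovers_half():
    # 20 slides is few; the honest tolerance is the estimator's own
    # sampling error (dominated by the 20 slide draws), ~0.08 here
    y, slides = make_icc_data(0.5, seed=3)
    est = variance_proportion(y, slides)
    assert est == pytest.approx(0.5, abs=2 * icc_fisher_se(0.5, 20, 2000))


def test_variance_proportion_needs_two_slides():
    with pytest.raises(ValueError):
        variance_proportion(np.arange(10.0), ["s1"] * 10)


# ---------------------------------------------------------------------------
# ARI
# ---------------------------------------------------------------------------

def test_ari_identical_and_permuted_labelings():
    labels = ["a", "a", "b", "b", "c"]
    assert adjusted_rand_index(labels, labels) == 1.0
    renamed = ["x" if l == "a" else "y" if l == "b" else "z" for l in labels]
    assert adjusted_rand_index(labels, renamed) == 1.0


def test_ari_closed_form_hand_case():
    # partitions {12|34} vs {13|24} of 4 items: every pair statistic computable
    # by hand from the 2x2 contingency table [[1,1],[1,1]]:
    # index = 0, expected = 2*2/6 = 2/3, max = 2 -> ARI = (0 - 2/3)/(2 - 2/3) = -1/2
    a = [0, 0, 1, 1]
    b = [0, 1, 0, 1]
    assert adjusted_rand_index(a, b) == pytest.approx(-0.5)


def test_ari_random_labels_near_zero():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 2, 10_000)
    b = rng.integers(0, 2, 10_000)
    assert abs(adjusted_rand_index(a, b)) < 0.05


def test_ari_length_mismatch():
    with pytest.raises(ValueError):
        adjusted_rand_index([1, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# aggregated report
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def eval_tables():
    table, truth = simulate_table(SimConfig(n_slides=6, cells_per_slide=400, tau=0.5, seed=31))
    return table, truth


def test_report_self_consistency_and_round_trip(eval_tables, tmp_path):
    table, _ = eval_tables
    report = evaluate_method(table, table, method="None; None",
                             channels=["vimentin", "cd3"])
    assert report.method == "None; None"
    assert 0.0 <= report.mean_discordance <= 1.0
    assert 0.0 <= report.mean_variance_proportion <= 1.0
    assert set(report.accuracy) == {"cd3"}
    assert 0.0 <= report.accuracy["cd3"] <= 1.0
    p = tmp_path / "report.json"
    report.to_json(p)
    back = EvalReport.from_json(p)
    pd.testing.assert_frame_equal(back.per_channel, report.per_channel)
    assert back.accuracy == report.accuracy
    row = report.to_row()
    assert row["Method"] == "None; None"


def test_mean_division_lowers_variance_proportion(eval_tables):
    table, _ = eval_tables
    md = apply_transform(table, "mean_divide")
    raw_rep = evaluate_method(table, table, channels=["vimentin", "cd3"])
    md_rep = evaluate_method(table, md, channels=["vimentin", "cd3"])
    assert md_rep.mean_variance_proportion < raw_rep.mean_variance_proportion
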