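import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import betarebound as br
from betarebound.stats import StatsError, sign_flip_pvalues
from conftest import brute_force_rm_anova


# ---------------------------------------------------------------- FDR


def bh_oracle(p, q):
    """Hand-stepped Benjamini-Hochberg: largest k with p(k) <= k q / m."""
    p = np.asarray(p, float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    if k_star:
        reject[order[:k_star]] = True
    return reject


def test_fdr_worked_examples():
    assert br.fdr_correct([0.001, 0.02, 0.03, 0.04], q=0.05).all()
    assert not br.fdr_correct([1.0, 1.0, 1.0], q=0.05).any()
    assert br.fdr_correct([0.004], q=0.01).all()
    assert br.fdr_correct([], q=0.05).size == 0
    with pytest.raises(StatsError):
        br.fdr_correct([0.5, 1.5], q=0.05)


@settings(deadline=None, max_examples=50)
@given(
    p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
    q=st.sampled_from([0.01, 0.05, 0.1]),
)
def test_fdr_matches_hand_stepped_oracle(p, q):
    np.testing.assert_array_equal(br.fdr_correct(p, q), bh_oracle(p, q))


# ----------------------------------------------- permutation map contrast


def _subject_maps(rng, n_subjects=12, shape=(6, 8), offset=0.0, region=None):
    maps = []
    for _ in range(n_subjects):
        v = rng.standard_normal(shape)
        if region is not None:
            v[region] += offset
        maps.append(br.TimeFreqMap(
            v, np.arange(shape[0], dtype=float),
            np.arange(shape[1], dtype=float),
        ))
    return maps


def test_identical_maps_yield_no_significant_points():
    rng = np.random.default_rng(0)
    maps = _subject_maps(rng)
    res = br.compare_maps_permutation(maps, maps, n_perm=500, alpha=0.05,
                                      seed=1)
    assert not res.mask.any()
    assert (res.p_values == 1.0).all()


def test_permutation_p_invariant_to_common_offset():
    rng = np.random.default_rng(1)
    a = _subject_maps(rng)
    b = _subject_maps(rng)
    r1 = br.compare_maps_permutation(a, b, n_perm=300, alpha=0.05, seed=7)
    shift = [br.TimeFreqMap(m.values + 3.7, m.freqs_hz, m.times_ms) for m in a]
    shift_b = [br.TimeFreqMap(m.values + 3.7, m.freqs_hz, m.times_ms) for m in b]
    r2 = br.compare_maps_permutation(shift, shift_b, n_perm=300, alpha=0.05,
                                     seed=7)
    np.testing.assert_allclose(r1.p_values, r2.p_values)


def test_exhaustive_sign_flip_matches_enumeration_oracle():
    """n=4 subjects: compare against literal enumeration of all 16 patterns."""
    rng = np.random.default_rng(3)
    d = rng.standard_normal((4, 5))
    p = sign_flip_pvalues(d, n_perm=1 << 4, seed=0)

    def t_of(x):
        return x.mean(0) / (x.std(0, ddof=1) / np.sqrt(len(x)))

    t_obs = np.abs(t_of(d))
    count = np.zeros(5)
    for signs in itertools.product([-1.0, 1.0], repeat=4):
        t_perm = np.abs(t_of(d * np.array(signs)[:, None]))
        count += t_perm >= t_obs - 1e-12
    np.testing.assert_allclose(p, count / 16.0)


def test_injected_region_is_localized():
    rng = np.random.default_rng(5)
    region = (slice(2, 4), slice(4, 7))
    a = _subject_maps(rng, offset=2.5, region=region)
    b = _subject_maps(rng)
    res = br.compare_maps_permutation(a, b, n_perm=2000, alpha=0.05, seed=11)
    hits = np.argwhere(res.mask)
    assert len(hits) >= 4
    inside = [(2 <= i < 4) and (4 <= j < 7) for i, j in hits]
    assert np.mean(inside) >= 0.9


def test_mismatched_grids_rejected():
    rng = np.random.default_rng(0)
    a = _subject_maps(rng)
    b = _subject_maps(rng, shape=(6, 9))
    with pytest.raises(StatsError):
        br.compare_maps_permutation(a, b, n_perm=10)
    with pytest.raises(StatsError):
        br.compare_maps_permutation(a[:3], a[:4], n_perm=10)


# ------------------------------------------------- baseline bootstrap


def test_baseline_bootstrap_calibrated_on_stationary_noise():
    rng = np.random.default_rng(8)
    times = np.linspace(-1000, 1000, 101)
    power = rng.chisquare(10, size=(40, 20, 101))
    res = br.baseline_significance(power, times, alpha=0.05, n_boot=2000,
                                   seed=3)
    rate = res.mask.mean()
    assert 0.005 < rate < 0.12  # ~alpha within Monte-Carlo slack


def test_baseline_bootstrap_flags_injected_rebound():
    rng = np.random.default_rng(9)
    times = np.linspace(-1000, 1000, 101)
    power = rng.chisquare(10, size=(60, 10, 101)) / 10.0
    window = (times >= 500) & (times <= 800)
    power[:, 4, window] *= 2.0  # ~ +3 dB at one frequency row
    res = br.baseline_significance(power, times, alpha=0.01, n_boot=2000,
                                   seed=4)
    assert res.mask[4, window].mean() > 0.9
    assert res.mask[0].mean() < 0.1
    with pytest.raises(StatsError):
        br.baseline_significance(power, times, n_boot=0)


# ------------------------------------------------- band/window extraction


def test_band_window_means():
    freqs = np.arange(4.0, 41.0, 0.5)
    times = np.linspace(-1000, 1000, 501)
    const = br.TimeFreqMap(np.full((len(freqs), len(times)), 1.7), freqs, times)
    spec = br.canonical_band_windows()["beta_ers"]
    assert spec.band_hz == (13.0, 30.0)
    assert spec.window_ms == (600.0, 800.0)
    assert br.extract_band_window_means(const, spec) == pytest.approx(1.7)
    with pytest.raises(StatsError):
        br.extract_band_window_means(
            const, br.BandWindowSpec((13, 30), (900, 1100))
        )
    # closed intervals on the grid: exact edge rows/columns included
    ramp = br.TimeFreqMap(
        np.tile(freqs[:, None], (1, len(times))), freqs, times
    )
    got = br.extract_band_window_means(ramp, br.BandWindowSpec((8, 12), (0, 100)))
    assert got == pytest.approx(np.mean(freqs[(freqs >= 8) & (freqs <= 12)]))


# ------------------------------------------------------------- ANOVA


def _long_table(y, factors=("syllable", "stimulation", "window")):
    levels = {f: (f + "_a", f + "_b") for f in factors}
    rows = []
    for s in range(y.shape[0]):
        for i, j, k in itertools.product(range(2), repeat=3):
            rows.append({
                "subject": s,
                factors[0]: levels[factors[0]][i],
                factors[1]: levels[factors[1]][j],
                factors[2]: levels[factors[2]][k],
                "value": y[s, i, j, k],
            })
    return pd.DataFrame(rows)


def test_constant_cells_give_zero_f():
    y = np.ones((6, 2, 2, 2)) * 3.3
    res = br.rm_anova_2x2x2(_long_table(y))
    assert (res.effects["F"] == 0).all()
    assert (res.effects["df2"] == 5).all()


def test_f_equals_squared_paired_t_of_contrast():
    from scipy import stats as sp

    rng = np.random.default_rng(21)
    y = rng.normal(size=(12, 2, 2, 2))
    res = br.rm_anova_2x2x2(_long_table(y))
    # main effect of the first factor: paired t between its two level means
    t = sp.ttest_rel(y[:, 0].mean(axis=(1, 2)), y[:, 1].mean(axis=(1, 2)))
    row = res.effect("syllable")
    assert row["F"] == pytest.approx(t.statistic**2, rel=1e-10)
    assert row["p"] == pytest.approx(t.pvalue, rel=1e-10)
    # three-way: paired t on the per-subject interaction contrast halves
    c = (y[:, 0, 0, 0] - y[:, 0, 0, 1] - y[:, 0, 1, 0] + y[:, 0, 1, 1])
    d = (y[:, 1, 0, 0] - y[:, 1, 0, 1] - y[:, 1, 1, 0] + y[:, 1, 1, 1])
    t3 = sp.ttest_rel(c, d)
    assert res.effect("syllable*stimulation*window")["F"] == pytest.approx(
        t3.statistic**2, rel=1e-10
    )


def test_matches_sums_of_squares_oracle():
    rng = np.random.default_rng(22)
    y = rng.normal(size=(12, 2, 2, 2))
    res = br.rm_anova_2x2x2(_long_table(y))
    oracle = brute_force_rm_anova(y)
    name = {"syllable": (1,), "stimulation": (2,), "window": (3,),
            "syllable*stimulation": (1, 2), "syllable*window": (1, 3),
            "stimulation*window": (2, 3),
            "syllable*stimulation*window": (1, 2, 3)}
    for _, row in res.effects.iterrows():
        assert abs(row["F"] - oracle[name[row["effect"]]]) < 1e-8


@settings(deadline=None, max_examples=15)
@given(a=st.floats(0.1, 50.0), b=st.floats(-20.0, 20.0),
       flip=st.booleans())
def test_f_invariant_under_affine_rescaling(a, b, flip):
    rng = np.random.default_rng(23)
    y = rng.normal(size=(8, 2, 2, 2))
    base = br.rm_anova_2x2x2(_long_table(y)).effects["F"]
    scale = -a if flip else a
    scaled = br.rm_anova_2x2x2(_long_table(scale * y + b)).effects["F"]
    np.testing.assert_allclose(scaled, base, rtol=1e-8)


def test_engine_is_factor_label_agnostic():
    rng = np.random.default_rng(24)
    y = rng.normal(size=(10, 2, 2, 2))
    res1 = br.rm_anova_2x2x2(_long_table(y))
    res2 = br.rm_anova_2x2x2(
        _long_table(y, factors=("place", "stim", "phase")),
        within=("place", "stim", "phase"),
    )
    np.testing.assert_allclose(res1.effects["F"], res2.effects["F"])


def test_missing_cell_rejected():
    y = np.random.default_rng(0).normal(size=(5, 2, 2, 2))
    table = _long_table(y)
    with pytest.raises(StatsError):
        br.rm_anova_2x2x2(table.iloc[:-1])


# ----------------------------------------------------------- post-hocs


def test_bonferroni_thresholds():
    rng = np.random.default_rng(30)
    a, b = rng.normal(size=(2, 12))
    two = br.posthoc_bonferroni({"x": (a, b), "y": (a, b + 1)})
    assert (two["alpha_adj"] == 0.025).all()
    one = br.posthoc_bonferroni({"x": (a, b)})
    assert (one["alpha_adj"] == 0.05).all()


def test_degenerate_pair_warns_and_reports_p1():
    a = np.arange(5.0)
    with pytest.warns(UserWarning, match="degenerate"):
        res = br.posthoc_bonferroni({"same": (a, a)})
    assert res.loc[0, "t"] == 0.0
    assert res.loc[0, "p"] == 1.0
    assert not res.loc[0, "significant"]
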