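"""Inferential statistics for ERSP maps and band/window summaries.

Map-level condition contrasts use paired t statistics across subjects with a
sign-flip permutation null (each subject's paired difference is randomly
negated; exchangeable under the null of no condition difference), two-tailed
permutation p-values and Benjamini-Hochberg FDR across all time-frequency
points.  Baseline significance of a single map uses a bootstrap that
re-draws baseline time points across trials.  Band/window scalar summaries
feed a fully within-subject 2x2x2 ANOVA computed from +/-1 contrast scores
(each F with (1, n-1) df equals the squared paired t of its contrast), with
Bonferroni-corrected paired t post-hocs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from betarebound.tfr import TimeFreqMap


class StatsError(ValueError):
    """Raised for invalid statistical requests."""


# --------------------------------------------------------------------------
# band / window specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BandWindowSpec:
    band_hz: tuple[float, float]
    window_ms: tuple[float, float]
    label: str = ""


def canonical_band_windows() -> dict[str, BandWindowSpec]:
    """The standard mu/beta x ERD/ERS analysis regions.

    ERD is read at 200-400 ms in both bands; the rebound (ERS) is read at
    400-600 ms for mu and 600-800 ms for beta.
    """
    return {
        "mu_erd": BandWindowSpec((8.0, 12.0), (200.0, 400.0), "mu_erd"),
        "mu_ers": BandWindowSpec((8.0, 12.0), (400.0, 600.0), "mu_ers"),
        "beta_erd": BandWindowSpec((13.0, 30.0), (200.0, 400.0), "beta_erd"),
        "beta_ers": BandWindowSpec((13.0, 30.0), (600.0, 800.0), "beta_ers"),
    }


def extract_band_window_means(
    tfmap: TimeFreqMap, spec: BandWindowSpec
) -> float:
    """Mean of the map cells with frequency in band and time in window.

    Both intervals are closed on the grid.  A region that does not fit
    inside the map grids is an error.
    """
    f0, f1 = spec.band_hz
    t0, t1 = spec.window_ms
    if (f0 < tfmap.freqs_hz[0] - 1e-9 or f1 > tfmap.freqs_hz[-1] + 1e-9
            or t0 < tfmap.times_ms[0] - 1e-9 or t1 > tfmap.times_ms[-1] + 1e-9):
        raise StatsError(
            f"band/window region {spec} lies outside the map grids"
        )
    frows = (tfmap.freqs_hz >= f0 - 1e-9) & (tfmap.freqs_hz <= f1 + 1e-9)
    tcols = (tfmap.times_ms >= t0 - 1e-9) & (tfmap.times_ms <= t1 + 1e-9)
    if not frows.any() or not tcols.any():
        raise StatsError("band/window region contains no grid points")
    return float(tfmap.values[np.ix_(frows, tcols)].mean())


# --------------------------------------------------------------------------
# FDR
# --------------------------------------------------------------------------

def fdr_correct(p_values: Sequence[float], q: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level ``q``.

    Rejects all p <= p(k*) where k* is the largest rank k with
    p(k) <= (k/m) q.  Empty input yields an empty flag array.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)):
        raise StatsError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


# --------------------------------------------------------------------------
# map-level permutation contrast
# --------------------------------------------------------------------------

@dataclass
class SignificanceMask:
    mask: np.ndarray  # boolean, (n_freqs, n_times)
    p_values: np.ndarray
    alpha: float
    n_permutations: int
    correction: str  # "fdr" or "none"
    freqs_hz: np.ndarray = field(default_factory=lambda: np.zeros(0))
    times_ms: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Paired t over axis 0 of (n_subjects, ...) differences."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _stack_maps(maps: Sequence[TimeFreqMap]) -> np.ndarray:
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise StatsError("maps have mismatched grids")
    return np.stack([m.values for m in maps])


def sign_flip_pvalues(
    diffs: np.ndarray, n_perm: int, seed: int | None = None
) -> np.ndarray:
    """Two-tailed sign-flip permutation p-values for paired differences.

    ``diffs`` has shape (n_subjects, ...).  Because negating a difference
    leaves its square unchanged, only the permuted mean varies, so the
    permuted t is computed from the means alone.  When ``n_perm`` covers the
    2**n possible sign patterns the null is enumerated exactly (the identity
    pattern makes the p-values strictly positive); otherwise ``n_perm``
    random patterns are drawn and the add-one estimator
    ``p = (1 + #exceedances) / (n_perm + 1)`` keeps p >= 1/(n_perm+1).
    """
    n = diffs.shape[0]
    if n_perm < 1:
        raise StatsError("n_perm must be >= 1")
    point_shape = diffs.shape[1:]
    flat = diffs.reshape(n, -1)
    ss = (flat**2).sum(axis=0)  # invariant under sign flips
    t_obs = np.abs(_paired_t(flat))

    def t_from_means(m: np.ndarray) -> np.ndarray:
        var = (ss[None, :] - n * m**2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / np.sqrt(var / n)
        return np.where(var == 0, np.where(m == 0, 0.0, np.inf), t)

    exhaustive = n_perm >= 2**n
    if exhaustive:
        codes = np.arange(2**n, dtype=np.uint32)
        total = 2**n
    else:
        rng = np.random.default_rng(seed)
        total = n_perm
    count = np.zeros(flat.shape[1])
    block = max(1, int(2**22 // max(flat.shape[1], 1)))
    done = 0
    while done < total:
        b = min(block, total - done)
        if exhaustive:
            bits = (codes[done:done + b, None] >> np.arange(n)[None, :]) & 1
            signs = bits.astype(float) * 2 - 1
        else:
            signs = rng.integers(0, 2, size=(b, n)).astype(float) * 2 - 1
        means = signs @ flat / n
        t_perm = np.abs(t_from_means(means))
        count += (t_perm >= t_obs[None, :] - 1e-12).sum(axis=0)
        done += b
    if exhaustive:
        p = count / total
    else:
        p = (1.0 + count) / (n_perm + 1.0)
    return p.reshape(point_shape)


def compare_maps_permutation(
    maps_a: Sequence[TimeFreqMap],
    maps_b: Sequence[TimeFreqMap],
    n_perm: int = 10000,
    alpha: float = 0.01,
    correction: str = "fdr",
    seed: int | None = None,
) -> SignificanceMask:
    """Point-wise paired contrast of two per-subject map sets.

    ``maps_a`` and ``maps_b`` are paired by position (subject).  The
    statistic per (f, t) point is the paired t across subjects; its null is
    built by sign-flipping each subject's difference map.  With ``fdr``
    correction the rejection threshold is Benjamini-Hochberg at level
    ``alpha`` across all points.
    """
    if len(maps_a) != len(maps_b) or len(maps_a) < 2:
        raise StatsError("need >= 2 paired subjects")
    if correction not in ("fdr", "none"):
        raise StatsError(f"unknown correction: {correction!r}")
    a = _stack_maps(list(maps_a))
    b = _stack_maps(list(maps_b))
    if a.shape != b.shape:
        raise StatsError("map sets have mismatched grids")
    if not maps_a[0].same_grid(maps_b[0]):
        raise StatsError("map sets have mismatched grids")
    diffs = a - b
    p = sign_flip_pvalues(diffs, n_perm=n_perm, seed=seed)
    if correction == "fdr":
        mask = fdr_correct(p.ravel(), q=alpha).reshape(p.shape)
    else:
        mask = p <= alpha
    return SignificanceMask(
        mask=mask, p_values=p, alpha=alpha, n_permutations=n_perm,
        correction=correction, freqs_hz=maps_a[0].freqs_hz,
        times_ms=maps_a[0].times_ms,
    )


def compare_trials_permutation(
    power_a: np.ndarray,
    power_b: np.ndarray,
    n_perm: int = 10000,
    alpha: float = 0.01,
    correction: str = "fdr",
    seed: int | None = None,
) -> SignificanceMask:
    """Trial-level alternative to the subject-level contrast.

    Conditions are compared with an unpaired t across trials and a null
    built by shuffling trial condition labels.  Provided for designs where
    subject-level pairing is unavailable.
    """
    a = np.asarray(power_a, float)
    b = np.asarray(power_b, float)
    if a.ndim != 3 or b.ndim != 3 or a.shape[1:] != b.shape[1:]:
        raise StatsError("power arrays must be (n_trials, n_freqs, n_times)")
    na, nb = a.shape[0], b.shape[0]
    pooled = np.concatenate([a, b]).reshape(na + nb, -1)
    rng = np.random.default_rng(seed)

    def t_stat(x, y):
        return sp_stats.ttest_ind(x, y, axis=0, equal_var=False).statistic

    t_obs = np.abs(t_stat(pooled[:na], pooled[na:]))
    count = np.zeros(pooled.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        t_p = np.abs(t_stat(pooled[perm[:na]], pooled[perm[na:]]))
        count += t_p >= t_obs - 1e-12
    p = ((1.0 + count) / (n_perm + 1.0)).reshape(a.shape[1:])
    if correction == "fdr":
        mask = fdr_correct(p.ravel(), q=alpha).reshape(p.shape)
    else:
        mask = p <= alpha
    return SignificanceMask(mask, p, alpha, n_perm, correction)


# --------------------------------------------------------------------------
# baseline significance bootstrap
# --------------------------------------------------------------------------

def baseline_significance(
    trial_power: np.ndarray,
    times_ms: np.ndarray,
    baseline_ms: tuple[float, float] = (-1000.0, -150.0),
    alpha: float = 0.01,
    n_boot: int = 10000,
    seed: int | None = None,
) -> SignificanceMask:
    """Two-tailed bootstrap mask of where a map differs from its baseline.

    For every bootstrap iteration one baseline time point is drawn per trial
    and the map statistic (trial-mean power in dB relative to the common
    baseline level) is recomputed, giving a per-frequency null distribution
    of baseline-only ERSP values; the observed map is flagged outside the
    (alpha/2, 1 - alpha/2) percentile band.
    """
    if n_boot < 1:
        raise StatsError("n_boot must be >= 1")
    power = np.asarray(trial_power, float)
    if power.ndim != 3 or power.shape[0] < 2:
        raise StatsError("trial_power must be (n_trials, n_freqs, n_times), >= 2 trials")
    times_ms = np.asarray(times_ms, float)
    cols = np.flatnonzero(
        (times_ms >= baseline_ms[0] - 1e-9) & (times_ms <= baseline_ms[1] + 1e-9)
    )
    if cols.size == 0:
        raise StatsError("baseline window contains no time points")
    n_trials, n_freqs, _ = power.shape
    base = power[:, :, cols]  # (n_trials, n_freqs, n_base)
    p0 = base.mean(axis=(0, 2))
    if np.any(p0 <= 0):
        raise StatsError("zero baseline power: degenerate input")
    ersp = 10.0 * np.log10(power.mean(axis=0) / p0[:, None])

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, cols.size, size=(n_boot, n_trials))
    null = np.empty((n_boot, n_freqs))
    trial_ix = np.arange(n_trials)
    for b in range(n_boot):
        null[b] = base[trial_ix, :, idx[b]].mean(axis=0)
    null_db = 10.0 * np.log10(null / p0[None, :])
    lo = np.percentile(null_db, 100 * alpha / 2, axis=0)
    hi = np.percentile(null_db, 100 * (1 - alpha / 2), axis=0)
    mask = (ersp < lo[:, None]) | (ersp > hi[:, None])
    p = np.full_like(ersp, np.nan)
    return SignificanceMask(mask, p, alpha, n_boot, "none",
                            times_ms=times_ms)


# --------------------------------------------------------------------------
# 2x2x2 fully within-subject ANOVA
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    effects: pd.DataFrame  # effect, F, df1, df2, p
    cell_stats: pd.DataFrame  # factor levels, mean, se
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        row = self.effects.loc[self.effects["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def rm_anova_2x2x2(
    table: pd.DataFrame,
    dv: str = "value",
    within: Sequence[str] = ("syllable", "stimulation", "window"),
    subject: str = "subject",
) -> AnovaResult:
    """Fully within-subject 2x2x2 ANOVA from per-subject cell values.

    ``table`` holds one value per subject x cell (extra rows per cell are
    averaged first).  Factor names are arbitrary; each factor must have
    exactly two levels and every subject must have all 8 cells.  For every
    effect (3 main, 3 two-way, 1 three-way) a per-subject contrast score is
    computed from the +/-1 design vector; ``F = (mean / SE)^2`` of those
    scores with df (1, n-1), identical to the classical sums-of-squares
    decomposition and to the squared paired t of the contrast.
    """
    if len(within) != 3:
        raise StatsError("exactly three within factors are required")
    for col in (*within, subject, dv):
        if col not in table.columns:
            raise StatsError(f"missing column: {col}")
    levels = {}
    for f in within:
        lv = sorted(table[f].unique())
        if len(lv) != 2:
            raise StatsError(f"factor {f!r} must have exactly 2 levels, got {lv}")
        levels[f] = lv
    cells = table.groupby([subject, *within], sort=True)[dv].mean().unstack(
        list(within)
    )
    expected = list(itertools.product(*[levels[f] for f in within]))
    missing = [c for c in expected if c not in cells.columns]
    if missing or cells.isna().any().any():
        raise StatsError(f"incomplete cells for some subject: {missing or 'NaN'}")
    cells = cells[expected]
    n = len(cells)
    if n < 2:
        raise StatsError("need >= 2 subjects")
    y = cells.to_numpy(float)  # (n_subjects, 8)

    codes = {
        f: {levels[f][0]: 1.0, levels[f][1]: -1.0} for f in within
    }
    rows = []
    for r in range(1, 4):
        for combo in itertools.combinations(range(3), r):
            name = "*".join(within[i] for i in combo)
            w = np.array([
                np.prod([codes[within[i]][cell[i]] for i in combo])
                for cell in expected
            ])
            scores = y @ w / len(expected)
            m = scores.mean()
            se = scores.std(ddof=1) / np.sqrt(n)
            F = 0.0 if se == 0 else (m / se) ** 2
            p = float(sp_stats.f.sf(F, 1, n - 1))
            rows.append((name, float(F), 1, n - 1, p))
    effects = pd.DataFrame(rows, columns=["effect", "F", "df1", "df2", "p"])

    cell_stats = pd.DataFrame(
        [
            (*cell, y[:, j].mean(), y[:, j].std(ddof=1) / np.sqrt(n))
            for j, cell in enumerate(expected)
        ],
        columns=[*within, "mean", "se"],
    )
    return AnovaResult(effects, cell_stats, n)


def posthoc_bonferroni(
    pairs: Mapping[str, tuple[np.ndarray, np.ndarray]],
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-tailed paired t per comparison at alpha ``family_alpha / n_pairs``.

    A degenerate pair (zero variance of the differences) is reported with
    p = 1 and a warning.
    """
    n_pairs = len(pairs)
    if n_pairs == 0:
        raise StatsError("no comparisons supplied")
    alpha_adj = family_alpha / n_pairs
    rows = []
    for label, (a, b) in pairs.items():
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if a.shape != b.shape or a.size < 2:
            raise StatsError(f"pair {label!r} must have equal lengths >= 2")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            warnings.warn(f"degenerate pair {label!r}: zero-variance differences")
            t, p = 0.0, 1.0
        else:
            res = sp_stats.ttest_rel(a, b)
            t, p = float(res.statistic), float(res.pvalue)
        rows.append((label, t, a.size - 1, p, alpha_adj, p < alpha_adj))
    return pd.DataFrame(
        rows, columns=["comparison", "t", "df", "p", "alpha_adj", "significant"]
    )
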