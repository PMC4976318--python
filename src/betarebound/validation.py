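"""Simulation studies that characterize the pipeline's statistical behaviour.

Three studies are provided: a parameter-recovery study (does the full
pipeline detect the injected beta-rebound attenuation as the syllable x
stimulation x window interaction, and only where it was injected?), a
point-wise false-positive calibration of the sign-flip permutation test
under the null, and an empirical-FDR check of the Benjamini-Hochberg
procedure on a null/alternative mixture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from betarebound.design import DesignConfig
from betarebound.pipeline import PipelineConfig, run_pipeline
from betarebound.simulate import SimConfig, derive_seed
from betarebound.stats import fdr_correct, rm_anova_2x2x2, sign_flip_pvalues


def scaled_design_config() -> DesignConfig:
    """Reduced-size session used for repeated simulation studies.

    4 speakers x 2 syllables x 4 repetitions x 2 stimulation levels =
    64 trials (16 per factor cell) with shortened inter-trial intervals;
    everything else (epoching, spectral analysis, statistics) runs exactly
    as for a full-size session.
    """
    return DesignConfig(
        n_speakers=4, repetitions_per_audio=4, iti_range_s=(1.0, 1.5)
    )


def interaction_recovery(
    n_datasets: int,
    base_seed: int,
    design_cfg: DesignConfig | None = None,
    sim_cfg: SimConfig | None = None,
) -> pd.DataFrame:
    """Run the full pipeline on repeated simulated studies.

    Returns one row per dataset with the p-values of the beta-band
    syllable x stimulation x window interaction in the left ROI (where the
    effect is injected), the same interaction in the mu band and in the
    right ROI (where nothing is injected), the no-stimulation syllable
    post-hoc (the classical control contrast), and the trial discard rate.
    """
    design_cfg = design_cfg or scaled_design_config()
    sim_cfg = sim_cfg or SimConfig()
    rows = []
    for k in range(n_datasets):
        cfg = PipelineConfig(
            design=design_cfg, sim=sim_cfg, map_stats=False,
            seed=derive_seed(base_seed, k, 2),
        )
        res = run_pipeline(cfg)
        beta = res["anovas"]["beta"]
        mu = res["anovas"]["mu"]
        right = rm_anova_2x2x2(
            res["band_table"].query("band == 'beta' and roi == 'right'"),
            dv="value", within=("syllable", "stimulation", "window"),
            subject="subject",
        )
        post = res["posthocs"]["beta"].set_index("comparison")
        rows.append({
            "dataset": k,
            "p_beta_left": beta.effect("syllable*stimulation*window")["p"],
            "F_beta_left": beta.effect("syllable*stimulation*window")["F"],
            "p_mu_left": mu.effect("syllable*stimulation*window")["p"],
            "p_beta_right": right.effect("syllable*stimulation*window")["p"],
            "p_nostim_posthoc": post.loc["dental_vs_bilabial_nostim", "p"],
            "p_stim_posthoc": post.loc["dental_vs_bilabial_stim", "p"],
            "discard_rate": res["manifest"]["discard_rate"],
        })
    return pd.DataFrame(rows)


def null_map_fpr(
    n_datasets: int = 200,
    n_subjects: int = 12,
    shape: tuple[int, int] = (8, 8),
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> float:
    """Point-wise false-positive rate of the sign-flip test under the null.

    Both conditions are drawn from the same generator (the paired
    differences are exchangeable zero-mean Gaussians), so every rejection
    at uncorrected ``alpha`` is a false positive.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    for k in range(n_datasets):
        diffs = rng.standard_normal((n_subjects, *shape))
        p = sign_flip_pvalues(diffs, n_perm=n_perm,
                              seed=derive_seed(seed, k, 3))
        hits += int((p <= alpha).sum())
        total += p.size
    return hits / total


def fdr_mixture_empirical_fdr(
    n_sim: int = 300,
    m: int = 500,
    pi0: float = 0.8,
    q: float = 0.05,
    effect: float = 3.0,
    seed: int = 0,
) -> float:
    """Mean false-discovery proportion of BH on an 80/20 null mixture.

    Null p-values are uniform; alternatives come from a one-sided normal
    shift of size ``effect``.  Benjamini-Hochberg guarantees the expectation
    is at most ``pi0 * q``.
    """
    rng = np.random.default_rng(seed)
    from scipy.stats import norm

    n_null = int(round(m * pi0))
    fdps = []
    for _ in range(n_sim):
        p_null = rng.uniform(size=n_null)
        z = rng.standard_normal(m - n_null) + effect
        p_alt = norm.sf(z)
        p = np.concatenate([p_null, p_alt])
        reject = fdr_correct(p, q=q)
        n_rej = int(reject.sum())
        false_rej = int(reject[:n_null].sum())
        fdps.append(false_rej / n_rej if n_rej else 0.0)
    return float(np.mean(fdps))
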