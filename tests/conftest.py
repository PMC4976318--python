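import numpy as np
import pytest

import betarebound as br
from betarebound.simulate import subject_response_sides


@pytest.fixture(scope="session")
def small_design_cfg():
    """Compact design (16 trials) with short ITIs for fast simulation."""
    return br.DesignConfig(
        n_speakers=2, repetitions_per_audio=2, iti_range_s=(1.0, 1.2)
    )


@pytest.fixture(scope="session")
def small_design(small_design_cfg):
    return br.build_design(small_design_cfg, seed=3)


@pytest.fixture(scope="session")
def sim_cfg():
    return br.SimConfig()


@pytest.fixture(scope="session")
def simulated_subject(small_design, sim_cfg):
    """One simulated recording plus its ground-truth behaviour."""
    truth = {}
    raw = br.simulate_recording(
        small_design, sim_cfg, subject_seed=11, behavior_out=truth
    )
    return raw, small_design, truth


@pytest.fixture(scope="session")
def preprocessed(simulated_subject):
    raw, design, _ = simulated_subject
    cfg = br.PreprocConfig()
    rawp = br.preprocess_continuous(raw, cfg)
    epochs = br.epoch_and_baseline(rawp, design, cfg)
    return rawp, epochs, cfg


@pytest.fixture(scope="session")
def behavior_table(preprocessed, simulated_subject):
    rawp, _, _ = preprocessed
    _, design, _ = simulated_subject
    return br.score_behavior(rawp, design, subject_response_sides(0))


def brute_force_rm_anova(y: np.ndarray) -> dict:
    """Sums-of-squares within-subject 2x2x2 ANOVA oracle.

    ``y`` has shape (n_subjects, 2, 2, 2); axis 0 is subjects, axes 1-3 the
    factors.  Each effect's F uses its own effect-by-subject error term
    (classical fully within-subject decomposition, built by
    inclusion-exclusion of marginal means).  Returns {factor-axes: F}, e.g.
    ``(1,)`` for the first main effect, ``(1, 2, 3)`` for the three-way.
    """
    from itertools import chain, combinations

    y = np.asarray(y, float)
    n = y.shape[0]

    def effect_term(subset):
        eff = np.zeros_like(y)
        subs = chain.from_iterable(
            combinations(subset, r) for r in range(len(subset) + 1)
        )
        for kept in subs:
            collapse = tuple(i for i in range(4) if i not in kept)
            marg = y.mean(axis=collapse, keepdims=True)
            eff = eff + (-1) ** (len(subset) - len(kept)) * marg
        return eff

    out = {}
    for axes in [(1,), (2,), (3,), (1, 2), (1, 3), (2, 3), (1, 2, 3)]:
        ss_effect = (effect_term(axes) ** 2).sum()
        ss_error = (effect_term((0, *axes)) ** 2).sum()
        ms_error = ss_error / (n - 1)
        out[axes] = float(ss_effect / ms_error) if ms_error > 0 else 0.0
    return out
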