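"""Experimental design: factorial trial tables for the syllable x stimulation task.

The task crosses place of articulation of an auditory CV syllable (bilabial
vs dental, each uttered by several speakers) with somatosensory stimulation
of the lower lip (present vs absent).  Each audio file is repeated a fixed
number of times per stimulation level, trials are presented in pseudo-random
order, and an identification question follows each syllable after a fixed
delay; the correct answer (yes/no) is balanced across the session and is
given with a lateral saccade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Fixed column order of the trial table (also the CSV schema).
TRIAL_COLUMNS = [
    "trial_id",
    "syllable",
    "speaker",
    "stimulation",
    "vowel_onset_s",
    "question_onset_s",
    "question_polarity",
    "true_response_side",
]


class DesignError(ValueError):
    """Raised for invalid design configurations."""


@dataclass
class DesignConfig:
    """Parameters of the factorial design.

    Defaults give 6 speakers x 2 syllables = 12 audio files, each repeated
    8 times per stimulation level: 192 trials, 96 with stimulation.
    """

    n_speakers: int = 6
    syllables: tuple[str, ...] = ("bilabial", "dental")
    repetitions_per_audio: int = 8
    stimulation_levels: tuple[str, ...] = ("present", "absent")
    iti_range_s: tuple[float, float] = (7.0, 8.0)
    question_delay_s: float = 1.5
    #: time allotted for the saccadic response after question onset
    response_window_s: float = 3.0
    #: silence before the first vowel onset (must cover the epoch pre-stimulus)
    lead_in_s: float = 5.0
    response_sides: Mapping[str, str] = field(
        default_factory=lambda: {"yes": "right", "no": "left"}
    )

    def __post_init__(self) -> None:
        if self.n_speakers < 1 or self.repetitions_per_audio < 1:
            raise DesignError("counts must be >= 1")
        if not self.syllables or not self.stimulation_levels:
            raise DesignError("syllable and stimulation sets must be non-empty")
        if len(set(self.syllables)) != len(self.syllables):
            raise DesignError("duplicate syllable labels")
        if len(set(self.stimulation_levels)) != len(self.stimulation_levels):
            raise DesignError("duplicate stimulation labels")
        lo, hi = self.iti_range_s
        if not (0 <= lo <= hi):
            raise DesignError("invalid ITI range")
        if self.question_delay_s < 0 or self.response_window_s <= 0:
            raise DesignError("invalid timing parameters")
        sides = set(self.response_sides.values())
        if set(self.response_sides) != {"yes", "no"} or not sides <= {"left", "right"}:
            raise DesignError("response_sides must map yes/no to left/right")
        if len(sides) != len(self.response_sides):
            raise DesignError("yes and no must map to different sides")

    @property
    def n_audio_files(self) -> int:
        return self.n_speakers * len(self.syllables)

    @property
    def n_trials(self) -> int:
        return (
            self.n_audio_files
            * self.repetitions_per_audio
            * len(self.stimulation_levels)
        )

    @property
    def trial_span_s(self) -> float:
        """Active portion of a trial, from vowel onset to end of response window."""
        return self.question_delay_s + self.response_window_s


def build_design(cfg: DesignConfig, seed: int) -> pd.DataFrame:
    """Build a pseudo-randomized trial table.

    Every audio file (speaker x syllable) appears exactly
    ``repetitions_per_audio`` times at each stimulation level; question
    polarity is balanced (counts differ by at most 1) and shuffled; vowel
    onsets are laid out sequentially with a uniform inter-trial interval
    drawn from ``iti_range_s``.

    Returns a DataFrame with columns :data:`TRIAL_COLUMNS`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for speaker in range(cfg.n_speakers):
        for syllable in cfg.syllables:
            for stimulation in cfg.stimulation_levels:
                for _ in range(cfg.repetitions_per_audio):
                    rows.append((syllable, f"spk{speaker:02d}", stimulation))
    table = pd.DataFrame(rows, columns=["syllable", "speaker", "stimulation"])

    # pseudo-randomized presentation order
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)

    # question polarity balanced within every syllable x stimulation cell
    # (hence globally: counts differ by at most 1), shuffled within cells
    n = len(table)
    polarity = np.empty(n, object)
    spare = 0  # alternate the extra polarity of odd-sized cells
    for _, idx in table.groupby(["syllable", "stimulation"]).groups.items():
        idx = np.asarray(idx)
        n_pos = len(idx) // 2
        if len(idx) % 2 == 1:
            n_pos += spare
            spare = 1 - spare
        cell = np.array(["positive"] * n_pos + ["negative"] * (len(idx) - n_pos))
        rng.shuffle(cell)
        polarity[idx] = cell
    table["question_polarity"] = polarity
    answers = np.where(polarity == "positive", "yes", "no")
    table["true_response_side"] = [cfg.response_sides[a] for a in answers]

    itis = rng.uniform(cfg.iti_range_s[0], cfg.iti_range_s[1], size=n)
    # vowel onset k+1 = onset k + trial span + ITI k
    onsets = cfg.lead_in_s + np.concatenate(
        [[0.0], np.cumsum(cfg.trial_span_s + itis[:-1])]
    )
    table["vowel_onset_s"] = onsets
    table["question_onset_s"] = onsets + cfg.question_delay_s
    table.insert(0, "trial_id", np.arange(n))
    return table[TRIAL_COLUMNS]
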