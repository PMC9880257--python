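"""Cohort- and trial-level statistics.

Covers the two small tabulations the pipeline reports: which side's
motor neuron starts oscillating first across a cohort of embryos
(onset-laterality dominance), and the distribution of behavioural
responses to unilateral photostimulation (left contraction, right
contraction, continuous swimming, no response) per stimulated side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

RESPONSE_CATEGORIES = ("left_contraction", "right_contraction",
                       "continuous_swimming", "no_response")
SIDES = ("L", "R")


@dataclass(frozen=True)
class LateralityResult:
    """Right-first onset dominance over a cohort."""

    n_right: int
    n_left: int
    n_indeterminate: int
    fraction_right: float
    percent_right: int

    @property
    def n_determinate(self) -> int:
        return self.n_right + self.n_left


def laterality_dominance(onset_table: pd.DataFrame) -> LateralityResult:
    """Fraction and rounded percentage of embryos whose right channel fires first.

    ``onset_table`` needs a ``first_onset`` column with values in
    ``{"L", "R", "indeterminate"}``; indeterminate rows are excluded from
    the fraction but counted.
    """
    if onset_table.empty:
        raise ValueError("empty onset table")
    col = onset_table["first_onset"].astype(str)
    n_right = int((col == "R").sum())
    n_left = int((col == "L").sum())
    n_ind = int((col == "indeterminate").sum())
    unknown = len(col) - n_right - n_left - n_ind
    if unknown:
        raise ValueError("first_onset values must be 'L', 'R' or 'indeterminate'")
    total = n_right + n_left
    if total == 0:
        raise ValueError("no determinate onsets in table")
    frac = n_right / total
    return LateralityResult(n_right=n_right, n_left=n_left,
                            n_indeterminate=n_ind, fraction_right=frac,
                            percent_right=int(round(100.0 * frac)))


def format_percentage(value: float) -> str:
    """Render a percentage at mixed precision: integers from 10% up, one
    decimal below 10% (e.g. 85, 2.9, 5.9)."""
    return f"{value:.0f}" if value >= 10.0 else f"{value:.1f}"


def stim_response_percentages(trials: pd.DataFrame, side: str
                              ) -> tuple[dict[str, float], dict[str, str], int]:
    """Per-category response percentages for one stimulated side.

    ``trials`` has ``stimulated_side`` in ``{"L", "R"}`` and ``response``
    in :data:`RESPONSE_CATEGORIES`.  Returns ``(exact, formatted, n)``:
    exact percentages per observed category, their mixed-precision string
    renderings, and the trial count.  Categories with zero trials are
    omitted (matching how such tables are reported).
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}")
    sub = trials[trials["stimulated_side"] == side]
    n = len(sub)
    if n == 0:
        raise ValueError(f"no trials for side {side!r}")
    bad = set(sub["response"]) - set(RESPONSE_CATEGORIES)
    if bad:
        raise ValueError(f"unknown response categories: {sorted(bad)}")
    exact: dict[str, float] = {}
    formatted: dict[str, str] = {}
    for cat in RESPONSE_CATEGORIES:
        count = int((sub["response"] == cat).sum())
        if count == 0:
            continue
        pct = 100.0 * count / n
        exact[cat] = pct
        formatted[cat] = format_percentage(pct)
    return exact, formatted, n


def make_trial_table(counts_by_side: dict[str, dict[str, int]]) -> pd.DataFrame:
    """Expand per-side response counts into a long trial table."""
    rows = []
    for side, counts in counts_by_side.items():
        for cat, k in counts.items():
            if cat not in RESPONSE_CATEGORIES:
                raise ValueError(f"unknown response category {cat!r}")
            rows.extend({"stimulated_side": side, "response": cat}
                        for _ in range(int(k)))
    return pd.DataFrame(rows, columns=["stimulated_side", "response"])
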