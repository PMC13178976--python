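"""Published posterior summaries from the original 11-team badge study.

The study that this pipeline operationalises fitted the hierarchical
coordination model to one week of infrared badge data from 11 R&D teams in
three organisational contexts and reported posterior medians, 95%
equal-tailed credible intervals and probabilities of direction per context.
The raw sensor data were not deposited, so these printed summaries are the
reference points for the interpretation layer: probability ratios and
cross-context contrasts are deterministic transforms of the medians.

Values are stored exactly as printed (two decimals).
"""

from __future__ import annotations

import pandas as pd

# effect -> context -> (median, ci_low, ci_high, pd)
_ROWS = [
    # effect, context, median, ci_low, ci_high, pd
    ("inertia", "uni", -0.52, -0.92, -0.15, 0.99),
    ("inertia", "lab", -0.37, -0.79, 0.05, 0.96),
    ("inertia", "bus", -0.65, -1.12, -0.08, 0.99),
    ("degree", "uni", 1.30, 0.84, 1.76, 1.00),
    ("degree", "lab", 1.05, 0.73, 1.37, 1.00),
    ("degree", "bus", 0.49, -0.40, 1.37, 0.86),
    ("recency", "uni", 1.41, 1.24, 1.58, 1.00),
    ("recency", "lab", 1.10, 0.99, 1.20, 1.00),
    ("recency", "bus", 1.99, 1.66, 2.32, 1.00),
    ("man_man", "uni", 0.25, -0.12, 0.55, 0.90),
    ("man_man", "lab", -0.21, -0.45, 0.03, 0.96),
    ("man_man", "bus", -0.80, -1.28, -0.34, 1.00),
    ("woman_woman", "uni", -0.35, -0.66, -0.06, 0.99),
    ("woman_woman", "lab", -0.54, -0.75, -0.33, 1.00),
    ("woman_woman", "bus", 0.17, -1.18, 1.21, 0.61),
    ("friendship", "uni", 0.71, 0.27, 1.18, 1.00),
    ("friendship", "lab", 0.00, -0.19, 0.19, 0.51),
    ("friendship", "bus", 1.01, 0.47, 1.54, 1.00),
    ("advice", "uni", 0.20, -0.06, 0.46, 0.93),
    ("advice", "lab", 0.30, 0.16, 0.43, 1.00),
    ("advice", "bus", 1.52, 0.95, 2.15, 1.00),
    ("colocation", "uni", 0.15, -0.01, 0.32, 0.97),
    ("colocation", "lab", 0.09, -0.02, 0.20, 0.95),
    ("colocation", "bus", -0.35, -0.96, 0.28, 0.86),
    ("junior_junior", "uni", -0.19, -0.45, 0.07, 0.93),
    ("junior_junior", "lab", -0.13, -0.27, 0.02, 0.96),
    ("junior_junior", "bus", 0.41, -0.28, 1.06, 0.88),
    ("senior_senior", "uni", 0.19, -0.06, 0.44, 0.93),
    ("senior_senior", "lab", -0.05, -0.23, 0.12, 0.72),
    ("senior_senior", "bus", -0.50, -0.90, -0.12, 1.00),
    ("ww_senior", "uni", -0.05, -0.88, 0.60, 0.56),
    ("ww_senior", "lab", 0.22, -0.02, 0.45, 0.96),
    ("ww_senior", "bus", 1.43, 0.65, 2.30, 1.00),
    ("ww_junior", "uni", 0.33, -0.16, 0.70, 0.91),
    ("ww_junior", "lab", 0.46, 0.28, 0.63, 1.00),
    ("ww_junior", "bus", -0.00, -8.10, 8.08, 0.50),
    ("same_age", "uni", -0.10, -0.27, 0.07, 0.87),
    ("same_age", "lab", 0.10, 0.01, 0.19, 0.99),
    ("same_age", "bus", -0.02, -0.23, 0.21, 0.57),
    ("same_tenure", "uni", -0.07, -0.20, 0.05, 0.88),
    ("same_tenure", "lab", 0.05, -0.05, 0.16, 0.86),
    ("same_tenure", "bus", -0.22, -0.54, 0.09, 0.91),
]

#: Published probability ratios for the four single-effect pairings.
#: effect -> context -> printed PR median.
PUBLISHED_PR = {
    "woman_woman": {"uni": 0.50, "lab": 0.34, "bus": 1.40},
    "man_man": {"uni": 1.66, "lab": 0.66, "bus": 0.20},
    "junior_junior": {"uni": 0.68, "lab": 0.78, "bus": 2.27},
    "senior_senior": {"uni": 1.46, "lab": 0.90, "bus": 0.37},
}

#: Published cross-context coefficient contrasts (median of c1 - c2).
#: (effect, c1, c2) -> printed Delta-beta.
PUBLISHED_CONTRASTS = {
    ("woman_woman", "bus", "uni"): 0.52,
    ("man_man", "bus", "uni"): -1.05,
    ("junior_junior", "bus", "uni"): 0.60,
    ("senior_senior", "bus", "uni"): -0.69,
    ("ww_junior", "lab", "uni"): 0.13,
    ("ww_senior", "bus", "lab"): 1.21,
}

#: Published SD of the team-level inertia random effect.
PUBLISHED_SIGMA_INERTIA = (0.14, 0.05, 0.32)


def published_summaries() -> pd.DataFrame:
    """The printed coefficient table as a tidy DataFrame."""
    return pd.DataFrame(
        _ROWS, columns=["effect", "context", "median", "ci_low", "ci_high", "pd"]
    )


def published_medians(context: str) -> dict[str, float]:
    """effect -> printed posterior median for one context."""
    df = published_summaries()
    sub = df[df["context"] == context]
    return dict(zip(sub["effect"], sub["median"]))
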