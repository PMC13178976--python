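"""Prototypical-dyad probability ratios.

Coefficients of the coordination model are translated into relative
interaction probabilities by comparing two hypothetical ("prototypical")
dyads that differ only in the attribute of interest.  For such dyads the
endogenous statistics are zeroed (prototypes carry no event history) and

    PR = exp(2 * (eta_num - eta_den)),

where eta is the exogenous part of the linear predictor and the factor 2
reflects the mutual-agreement mechanism: an effect enters both i's
proposal to j and j's proposal to i.  The PR relies on the numerator of
the multinomial logit only, i.e. it is ceteris paribus with respect to the
opportunity structure (the denominator over alternative partners).

The model's baseline dyad has mixed gender, mixed seniority and no advice,
friendship or co-location ties.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .covariates import EXOGENOUS_EFFECTS
from .inference import PosteriorDraws, probability_of_direction

GENDER_PAIRS = ("mixed", "woman_woman", "man_man")
SENIORITY_PAIRS = ("mixed", "junior_junior", "senior_senior")


class ComparisonError(ValueError):
    """Prototypical dyads that cannot be compared."""


@dataclass(frozen=True)
class PrototypicalDyad:
    """Attribute bundle of a hypothetical dyad in a given context.

    Interaction indicators (woman-woman x seniority) are derived, never
    set directly, so they always equal the product of their parents.
    """

    context: str
    gender_pair: str = "mixed"
    seniority_pair: str = "mixed"
    friendship: int = 0
    advice: int = 0
    colocation: int = 0
    same_age: int = 0
    same_tenure: int = 0

    def __post_init__(self) -> None:
        if self.gender_pair not in GENDER_PAIRS:
            raise ComparisonError(f"gender_pair must be one of {GENDER_PAIRS}")
        if self.seniority_pair not in SENIORITY_PAIRS:
            raise ComparisonError(
                f"seniority_pair must be one of {SENIORITY_PAIRS}"
            )

    def exogenous_vector(self) -> np.ndarray:
        """Indicator values in :data:`EXOGENOUS_EFFECTS` order."""
        ww = float(self.gender_pair == "woman_woman")
        mm = float(self.gender_pair == "man_man")
        jj = float(self.seniority_pair == "junior_junior")
        ss = float(self.seniority_pair == "senior_senior")
        values = {
            "man_man": mm,
            "woman_woman": ww,
            "friendship": float(self.friendship),
            "advice": float(self.advice),
            "colocation": float(self.colocation),
            "junior_junior": jj,
            "senior_senior": ss,
            "ww_senior": ww * ss,
            "ww_junior": ww * jj,
            "same_age": float(self.same_age),
            "same_tenure": float(self.same_tenure),
        }
        return np.array([values[k] for k in EXOGENOUS_EFFECTS])


def baseline_dyad(context: str, **overrides) -> PrototypicalDyad:
    """The reference dyad: mixed seniority, no advice/friendship ties."""
    return replace(PrototypicalDyad(context=context), **overrides)


def _coefficient_matrix(post: PosteriorDraws, context: str) -> np.ndarray:
    """(draws, K_exo) matrix of exogenous coefficients for one context."""
    cols = []
    for eff in EXOGENOUS_EFFECTS:
        if eff not in post.spec.effects:
            raise ComparisonError(f"effect {eff!r} absent from the fitted model")
        cols.append(post.beta(eff, context))
    return np.column_stack(cols)


def prototype_predictor(
    dyad: PrototypicalDyad, coefficients: dict[str, float]
) -> float:
    """Exogenous linear predictor eta for one coefficient assignment.

    ``coefficients`` maps exogenous effect names to values (a single
    posterior draw, or a table of posterior medians); missing effects
    count as zero.
    """
    s = dyad.exogenous_vector()
    beta = np.array([coefficients.get(k, 0.0) for k in EXOGENOUS_EFFECTS])
    return float(beta @ s)


@dataclass(frozen=True)
class PRResult:
    numerator: PrototypicalDyad
    denominator: PrototypicalDyad
    values: np.ndarray
    median: float
    ci_low: float
    ci_high: float
    pd: float
    note: str = (
        "ceteris paribus: assumes comparable opportunity structures "
        "for the actors involved"
    )


def _summarise_pr(num: PrototypicalDyad, den: PrototypicalDyad,
                  values: np.ndarray) -> PRResult:
    lo, med, hi = np.percentile(values, [2.5, 50.0, 97.5])
    return PRResult(
        numerator=num,
        denominator=den,
        values=values,
        median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        pd=probability_of_direction(values, reference=1.0),
    )


def probability_ratio(
    num: PrototypicalDyad, den: PrototypicalDyad, post: PosteriorDraws
) -> PRResult:
    """Posterior of PR = exp(2 (eta_num - eta_den)), draw-wise.

    The PR is computed per draw and then summarised; pd is taken relative
    to the reference value 1.  Shared attributes of the two dyads cancel
    exactly in the difference of predictors.
    """
    if num.context != den.context:
        raise ComparisonError(
            f"context mismatch: {num.context!r} vs {den.context!r}"
        )
    coef = _coefficient_matrix(post, num.context)
    ds = num.exogenous_vector() - den.exogenous_vector()
    values = np.exp(2.0 * (coef @ ds))
    return _summarise_pr(num, den, values)


def probability_ratio_from_point(
    num: PrototypicalDyad,
    den: PrototypicalDyad,
    coefficients: dict[str, float],
) -> float:
    """PR evaluated at a single coefficient assignment (e.g. medians).

    Because exp(2x) is strictly increasing, the posterior median PR equals
    the PR at the posterior median of the predictor difference, so printed
    coefficient medians reproduce printed PRs for single-effect contrasts.
    """
    if num.context != den.context:
        raise ComparisonError(
            f"context mismatch: {num.context!r} vs {den.context!r}"
        )
    d_eta = prototype_predictor(num, coefficients) - prototype_predictor(
        den, coefficients
    )
    return float(np.exp(2.0 * d_eta))
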