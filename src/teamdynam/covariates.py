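"""Actor- and dyad-level exogenous covariates.

Gender and professional seniority enter the model as dyadic pairing
indicators (man-man, woman-woman, junior-junior, senior-senior) against a
mixed-pair reference, plus the woman-woman x seniority interaction
indicators that operationalise gender-based status cues.  Survey networks
(advice seeking, friendship) are dichotomised at rating > 3 and
symmetrised; age and team tenure are discretised into bands and enter as
same-band indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .defaults import (
    AGE_BAND_EDGES,
    CONTEXTS,
    RATING_THRESHOLD,
    TENURE_BAND_EDGES,
)

#: Order of the exogenous dyadic statistics everywhere downstream.
EXOGENOUS_EFFECTS = (
    "man_man",
    "woman_woman",
    "friendship",
    "advice",
    "colocation",
    "junior_junior",
    "senior_senior",
    "ww_senior",
    "ww_junior",
    "same_age",
    "same_tenure",
)

#: Role -> seniority lookup: leaders, senior researchers and postdocs count
#: as senior; assistants, PhD/MA students and administrative staff as junior.
SENIOR_ROLES = frozenset({"team leader", "senior researcher", "postdoc"})
JUNIOR_ROLES = frozenset(
    {
        "research assistant",
        "lab assistant",
        "technician",
        "phd student",
        "ma student",
        "administrative assistant",
    }
)

GENDERS = ("woman", "man")
SENIORITIES = ("junior", "senior")


class DesignError(ValueError):
    """Inconsistent covariate inputs."""


@dataclass
class ActorTable:
    """Per-actor attributes for all teams.

    Columns: ``actor_id, team_id, context, gender, seniority,
    tenure_months, age_years``; tenure and age may be missing (NaN),
    gender and seniority never are.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {
            "actor_id", "team_id", "context", "gender",
            "seniority", "tenure_months", "age_years",
        }
        missing = required - set(t.columns)
        if missing:
            raise DesignError(f"actor table missing columns {sorted(missing)}")
        bad_gender = ~t["gender"].isin(GENDERS)
        if bad_gender.any():
            raise DesignError(
                f"unsupported gender value {t['gender'][bad_gender].iloc[0]!r}; "
                f"expected one of {GENDERS}"
            )
        if (~t["seniority"].isin(SENIORITIES)).any():
            raise DesignError(f"seniority must be one of {SENIORITIES}")
        if (~t["context"].isin(CONTEXTS)).any():
            raise DesignError(f"context must be one of {CONTEXTS}")
        per_team = t.groupby("team_id")["context"].nunique()
        if (per_team > 1).any():
            raise DesignError("context must be constant within team")
        sizes = t.groupby("team_id").size()
        if (sizes < 2).any():
            raise DesignError("team sizes must be >= 2")
        if t["actor_id"].duplicated().any():
            raise DesignError("duplicate actor ids")

    @property
    def teams(self) -> list[str]:
        return sorted(self.table["team_id"].unique())

    def team_members(self, team: str) -> pd.DataFrame:
        sub = self.table[self.table["team_id"] == team]
        return sub.sort_values("actor_id").reset_index(drop=True)

    def context_of(self, team: str) -> str:
        return str(self.team_members(team)["context"].iloc[0])


def seniority_from_role(role: str) -> str:
    """Map a survey role to the senior/junior status binary."""
    key = role.strip().lower()
    if key in SENIOR_ROLES:
        return "senior"
    if key in JUNIOR_ROLES:
        return "junior"
    raise DesignError(f"unknown role {role!r}")


def read_actor_table(path) -> ActorTable:
    """Read ``actor_id,team_id,context,gender,role,tenure_months,age_years``."""
    df = pd.read_csv(path, dtype={"actor_id": str, "team_id": str})
    if "seniority" not in df.columns:
        df["seniority"] = df["role"].map(seniority_from_role)
    df["tenure_months"] = pd.to_numeric(df["tenure_months"], errors="coerce")
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    return ActorTable(df)


def band_age(age_years: float) -> str:
    """Discretise age into young (<=30), middle (31-45), elderly (>=46)."""
    if not age_years > 0:
        raise DesignError(f"age must be positive, got {age_years}")
    lo, hi = AGE_BAND_EDGES
    if age_years <= lo:
        return "young"
    if age_years <= hi:
        return "middle"
    return "elderly"


def band_tenure(tenure_months: float) -> str:
    """Discretise tenure into newcomer (<=12 mo), consolidated (<=72), long_term."""
    if tenure_months < 0:
        raise DesignError(f"tenure must be non-negative, got {tenure_months}")
    lo, hi = TENURE_BAND_EDGES
    if tenure_months <= lo:
        return "newcomer"
    if tenure_months <= hi:
        return "consolidated"
    return "long_term"


def dichotomize_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Binarise a directed 1-5 rating matrix at rating > 3.

    Missing ratings propagate as NaN (imputed downstream); the diagonal is
    ignored and returned as NaN.
    """
    vals = ratings.to_numpy(dtype=float)
    off_diag = ~np.eye(len(ratings), dtype=bool)
    observed = ~np.isnan(vals) & off_diag
    legal = np.isin(vals[observed], [1, 2, 3, 4, 5])
    if not legal.all():
        bad = vals[observed][~legal][0]
        raise DesignError(f"rating {bad} outside 1-5")
    out = np.where(vals > RATING_THRESHOLD, 1.0, 0.0)
    out[~observed] = np.nan
    return pd.DataFrame(out, index=ratings.index, columns=ratings.columns)


@dataclass
class DyadDesign:
    """Exogenous dyadic indicators for one team.

    ``matrix`` is an ``(n, n, K)`` array over :data:`EXOGENOUS_EFFECTS`,
    symmetric in the first two axes with a zeroed diagonal; ``actors`` is
    the sorted actor-id list defining the axes.
    """

    actors: list[str]
    matrix: np.ndarray
    team: str
    context: str

    def dyad_table(self) -> pd.DataFrame:
        """Long-format indicator table over unordered dyads (i < j)."""
        rows = []
        n = len(self.actors)
        for a in range(n):
            for b in range(a + 1, n):
                rows.append(
                    {
                        "i": self.actors[a],
                        "j": self.actors[b],
                        **dict(zip(EXOGENOUS_EFFECTS, self.matrix[a, b])),
                    }
                )
        return pd.DataFrame(rows)

    def row(self, i: str, j: str) -> np.ndarray:
        return self.matrix[self.actors.index(i), self.actors.index(j)]


def _symmetrize_either(net: np.ndarray) -> np.ndarray:
    """Undirected tie present if a directed tie exists in either direction."""
    return np.maximum(net, net.T)


def build_dyad_design(
    actors: ActorTable,
    advice: dict[str, pd.DataFrame],
    friendship: dict[str, pd.DataFrame],
    colocation: dict[str, pd.DataFrame],
) -> dict[str, DyadDesign]:
    """Assemble the full dyadic indicator design, one DyadDesign per team.

    ``advice``/``friendship`` are complete (post-imputation) binary directed
    matrices per team, ``colocation`` binary symmetric; all indexed by
    actor id.  Advice and friendship are symmetrised to
    either-direction indicators.  The mixed-gender and mixed-seniority
    dyads form the reference category and get no indicator of their own.
    """
    designs: dict[str, DyadDesign] = {}
    for team in actors.teams:
        members = actors.team_members(team)
        ids = members["actor_id"].tolist()
        n = len(ids)
        for name, nets in (("advice", advice), ("friendship", friendship),
                           ("colocation", colocation)):
            mat = nets[team]
            if list(mat.index) != ids or list(mat.columns) != ids:
                raise DesignError(
                    f"{name} matrix for team {team} not conformable with roster"
                )
            if np.isnan(mat.to_numpy()[~np.eye(n, dtype=bool)]).any():
                raise DesignError(
                    f"{name} matrix for team {team} has missing entries; "
                    "impute before building the design"
                )
        woman = (members["gender"] == "woman").to_numpy()
        senior = (members["seniority"] == "senior").to_numpy()
        age_band = members["age_years"].map(band_age).to_numpy()
        tenure_band = members["tenure_months"].map(band_tenure).to_numpy()

        mm = np.outer(~woman, ~woman).astype(float)
        ww = np.outer(woman, woman).astype(float)
        jj = np.outer(~senior, ~senior).astype(float)
        ss = np.outer(senior, senior).astype(float)
        adv = _symmetrize_either(np.nan_to_num(advice[team].to_numpy(dtype=float)))
        fri = _symmetrize_either(np.nan_to_num(friendship[team].to_numpy(dtype=float)))
        col = colocation[team].to_numpy(dtype=float)
        same_age = (age_band[:, None] == age_band[None, :]).astype(float)
        same_tenure = (tenure_band[:, None] == tenure_band[None, :]).astype(float)

        stack = np.stack(
            [mm, ww, fri, adv, col, jj, ss, ww * ss, ww * jj, same_age, same_tenure],
            axis=-1,
        )
        diag = np.eye(n, dtype=bool)
        stack[diag] = 0.0
        designs[team] = DyadDesign(
            actors=ids,
            matrix=stack,
            team=team,
            context=actors.context_of(team),
        )
    return designs


def read_long_matrix(path, value_col: str) -> dict[str, pd.DataFrame]:
    """Read long-format ``team,from,to,<value>`` CSV into per-team matrices."""
    df = pd.read_csv(path, dtype={"team": str, "from": str, "to": str})
    out: dict[str, pd.DataFrame] = {}
    for team, grp in df.groupby("team"):
        ids = sorted(set(grp["from"]) | set(grp["to"]))
        mat = pd.DataFrame(np.nan, index=ids, columns=ids)
        for _, r in grp.iterrows():
            mat.loc[r["from"], r["to"]] = r[value_col]
        out[team] = mat
    return out
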