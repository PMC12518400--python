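"""Statistical models for post-fledging parental care.

Model objects follow the statsmodels convention: construct from data,
``fit()`` returns a results object carrying estimates, uncertainties and
fit statistics, with a ``summary()``.  The layer covers

* feeding-observation models: Poisson regression of per-age-class feeding
  counts on 10-day age class (one randomly selected observation per
  chick), and an ordinary linear model of feeding distance on continuous
  age;
* contact models: binomial GLMMs for the daily proportion of linked fixes
  in contact (overall / while begging / while foraging) and a Gamma
  log-link GLMM for the distance to the nest during contact, each with
  correlated random intercept and age slope among chicks;
* AICc-based model selection (most parsimonious model within 2 dAICc of
  the best) over all subsets of {age, chick sex, parent sex} with year
  always included and no interactions;
* the first-year survival comparison against a mark-recapture reference.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .glmm import MixedGLM, MixedGLMResults
from .morpho import bin_age

logger = logging.getLogger(__name__)

Response = Literal[
    "feeding_count", "feeding_distance",
    "p_contact", "p_contact_beg", "p_contact_forage", "nest_distance_contact",
]

#: (successes, trials) columns per binomial response
_BINOMIAL_COLS = {
    "p_contact": ("n_contact", "n_linked"),
    "p_contact_beg": ("n_contact_beg", "n_linked_with_acc"),
    "p_contact_forage": ("n_contact_forage", "n_linked_with_acc"),
}

NEST_DISTANCE_FLOOR_KM = 0.001  # 1 m; Gamma support is the positive reals


# ----------------------------------------------------------------------
# closed-form pieces

def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction:
    -2 logLik + 2k + 2k(k+1)/(n-k-1).  Requires n > k + 1."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def select_model(results: Sequence) -> object:
    """Most parsimonious model: among candidates within 2 dAICc of the
    best-supported (inclusive), the one with fewest parameters; ties on
    parameter count broken by lower AICc.  Unconverged fits are excluded."""
    usable = [r for r in results if getattr(r, "converged", True)]
    if not usable:
        raise ValueError("no converged model fits to select from")
    best = min(r.aicc for r in usable)
    candidates = [r for r in usable if r.aicc <= best + 2.0]
    return min(candidates, key=lambda r: (r.k, r.aicc))


@dataclass(frozen=True)
class SurvivalComparison:
    rate: float
    se: float
    z: float
    p_value: float
    n_tagged: int
    n_died: int
    ref_rate: float
    ref_se: float

    def summary(self) -> str:
        return (f"first-year survival {self.rate:.2f} ± {self.se:.2f} "
                f"(n={self.n_tagged}, died={self.n_died}); reference "
                f"{self.ref_rate:.2f} ± {self.ref_se:.2f}; "
                f"Z={self.z:.2f}, p={self.p_value:.2f}")


def survival_comparison(n_tagged: int, n_died: int,
                        ref_rate: float, ref_se: float) -> SurvivalComparison:
    """Binomial first-year survival of the tagged cohort vs a mark-recapture
    reference estimate; two-sided Z test combining both standard errors."""
    from scipy.stats import norm

    if n_tagged <= 0 or not (0 <= n_died <= n_tagged):
        raise ValueError(f"invalid counts: n_tagged={n_tagged}, n_died={n_died}")
    rate = (n_tagged - n_died) / n_tagged
    se = float(np.sqrt(rate * (1.0 - rate) / n_tagged))
    z = (rate - ref_rate) / float(np.sqrt(se ** 2 + ref_se ** 2))
    p = 2.0 * float(norm.sf(abs(z)))
    return SurvivalComparison(rate, se, z, p, n_tagged, n_died, ref_rate, ref_se)


# ----------------------------------------------------------------------
# feeding-observation models

def subsample_one_per_chick(records: pd.DataFrame, seed: int,
                            chick_col: str = "chick_id") -> pd.DataFrame:
    """Randomly select one feeding observation per chick (seeded)."""
    rng = np.random.default_rng(seed)
    idx = records.groupby(chick_col, sort=True).indices
    keep = [values[rng.integers(len(values))] for _, values in sorted(idx.items())]
    return records.iloc[sorted(keep)].reset_index(drop=True)


class FeedingCountModel:
    """Poisson regression of feeding-observation counts on 10-day age class.

    One observation per known-age chick is selected at random (seeded),
    ages are binned (40 = 35-44 d, ...), the observations per class are
    counted and regressed on the class midpoint with a log link.
    """

    def __init__(self, records: pd.DataFrame, age_col: str = "age_days"):
        self.records = records
        self.age_col = age_col

    def fit(self, seed: int = 0) -> "FeedingCountResults":
        sub = subsample_one_per_chick(self.records, seed)
        ages = sub[self.age_col].map(bin_age)
        counts = ages.value_counts().sort_index()
        if len(counts) < 2:
            raise ValueError("need observations in at least 2 age classes")
        X = sm.add_constant(counts.index.to_numpy(dtype=float))
        res = sm.GLM(counts.to_numpy(dtype=float), X,
                     family=sm.families.Poisson()).fit()
        return FeedingCountResults(res, counts, seed)


@dataclass
class FeedingCountResults:
    _res: object
    class_counts: pd.Series
    seed: int

    @property
    def slope(self) -> float:
        return float(self._res.params[1])

    @property
    def slope_se(self) -> float:
        return float(self._res.bse[1])

    @property
    def zvalue(self) -> float:
        return float(self._res.tvalues[1])

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = self._res.conf_int(alpha)[1]
        return float(lo), float(hi)

    def summary(self) -> str:
        return (f"Poisson feeding-count model: slope per day of age "
                f"{self.slope:+.4f} (SE {self.slope_se:.4f}, z={self.zvalue:.2f}); "
                f"{int(self.class_counts.sum())} observations in "
                f"{len(self.class_counts)} age classes")


class FeedingDistanceModel:
    """Ordinary linear model of feeding distance from the colony (km) on
    continuous (unbinned) chick age."""

    def __init__(self, records: pd.DataFrame, age_col: str = "age_days",
                 distance_col: str = "distance_km"):
        if len(records) < 3:
            raise ValueError("feeding-distance model needs n >= 3")
        if (records[distance_col] < 0).any():
            raise ValueError("distances must be non-negative")
        self.records = records
        self.age_col, self.distance_col = age_col, distance_col

    def fit(self) -> "FeedingDistanceResults":
        X = sm.add_constant(self.records[self.age_col].to_numpy(dtype=float))
        res = sm.OLS(self.records[self.distance_col].to_numpy(dtype=float), X).fit()
        return FeedingDistanceResults(res)


@dataclass
class FeedingDistanceResults:
    _res: object

    @property
    def slope(self) -> float:
        return float(self._res.params[1])

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def fvalue(self) -> float:
        return float(self._res.fvalue)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = self._res.conf_int(alpha)[1]
        return float(lo), float(hi)

    def summary(self) -> str:
        return (f"linear feeding-distance model: {self.slope:+.4f} km/day, "
                f"R^2 = {self.rsquared:.3f}, F = {self.fvalue:.2f}")


# ----------------------------------------------------------------------
# contact GLMMs

@dataclass(frozen=True)
class ModelSpec:
    """One candidate model: response, fixed terms, error family, random
    structure.  Interactions are never considered; year is always a fixed
    effect in the contact and nest-distance models."""

    response: Response
    fixed: tuple[str, ...] = ("age",)
    family: str = "binomial"
    random: str = "chick"  # chick | pair | none

    def __post_init__(self) -> None:
        allowed = {"age", "chick_sex", "parent_sex"}
        extra = set(self.fixed) - allowed
        if extra:
            raise ValueError(f"unknown fixed terms {sorted(extra)}")

    @property
    def label(self) -> str:
        return " + ".join(self.fixed) + " + year" if self.fixed else "year"


class ContactModel:
    """Mixed model for one daily contact (or nest-distance) response.

    Built from a table of daily contact summaries (one row per
    chick-parent pair per day).  Chick age is z-standardized internally;
    year enters as fixed-effect dummies; the random structure is a
    correlated intercept + standardized-age slope per chick (or per
    chick-parent pair).
    """

    def __init__(self, summaries: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        df = summaries.copy()
        if spec.response in _BINOMIAL_COLS:
            succ, tri = _BINOMIAL_COLS[spec.response]
            ok_col = "ok_overall" if spec.response == "p_contact" else "ok_behaviour"
            if ok_col in df.columns:
                df = df[df[ok_col].astype(bool)]
            df = df[df[tri] > 0]
            self.family = "binomial"
        elif spec.response == "nest_distance_contact":
            if "ok_overall" in df.columns:
                df = df[df["ok_overall"].astype(bool)]
            df = df[df["mean_dist_nest_contact_km"].notna()]
            self.family = "gamma-log"
        else:
            raise ValueError(f"unsupported contact response {spec.response!r}")
        if df.empty:
            raise ValueError("no usable rows for this response")
        self.data = df.reset_index(drop=True)
        self.age_mean = float(self.data["chick_age"].mean())
        self.age_sd = float(self.data["chick_age"].std(ddof=0)) or 1.0

    def _design(self) -> pd.DataFrame:
        df = self.data
        X = pd.DataFrame({"const": np.ones(len(df))})
        X["age_std"] = (df["chick_age"] - self.age_mean) / self.age_sd
        if "chick_sex" in self.spec.fixed:
            X["chick_sex_male"] = (df["chick_sex"] == "male").astype(float)
        if "parent_sex" in self.spec.fixed:
            X["parent_sex_male"] = (df["parent_sex"] == "male").astype(float)
        years = sorted(df["year"].unique())
        for y in years[1:]:
            X[f"year_{y}"] = (df["year"] == y).astype(float)
        return X

    def fit(self, **fit_kwargs) -> "ContactModelResults":
        df = self.data
        X = self._design()
        age_std = X["age_std"].to_numpy()
        if "age" not in self.spec.fixed:
            X = X.drop(columns=["age_std"])
        exog_re = np.column_stack([np.ones(len(df)), age_std])
        groups = df["chick_id"] if self.spec.random == "chick" else df["pair_id"]
        if self.family == "binomial":
            succ, tri = _BINOMIAL_COLS[self.spec.response]
            endog, trials = df[succ].to_numpy(float), df[tri].to_numpy(float)
            if endog.sum() == 0 or (endog == trials).all():
                raise ValueError("degenerate binomial response: no variation in contact")
            mm = MixedGLM(endog, X, groups, exog_re=exog_re,
                          family="binomial", trials=trials)
        else:
            endog = np.maximum(df["mean_dist_nest_contact_km"].to_numpy(float),
                               NEST_DISTANCE_FLOOR_KM)
            mm = MixedGLM(endog, X, groups, exog_re=exog_re, family="gamma-log")
        res = mm.fit(**fit_kwargs)
        return ContactModelResults(self, res)


@dataclass
class ContactModelResults:
    """Fit of one candidate contact model: coefficients on the
    standardized-age scale, random-effect SDs, log-likelihood and AICc."""

    model: ContactModel
    _res: MixedGLMResults

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def fe_params(self) -> pd.Series:
        return self._res.fe_params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self._res.conf_int(alpha)

    @property
    def re_sd(self) -> pd.Series:
        return self._res.re_sd

    @property
    def llf(self) -> float:
        return self._res.llf

    @property
    def k(self) -> int:
        return self._res.k_params

    @property
    def nobs(self) -> int:
        return self._res.nobs

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k, self.nobs)

    @property
    def converged(self) -> bool:
        return self._res.converged

    def age_slope_per_day(self) -> tuple[float, float]:
        """Fixed age effect back-transformed to per-day log-odds (or
        log-distance) units: (estimate, SE)."""
        if "age_std" not in self.fe_params.index:
            raise ValueError("model has no fixed age term")
        return (self.fe_params["age_std"] / self.model.age_sd,
                self.bse["age_std"] / self.model.age_sd)

    def summary(self) -> str:
        head = (f"ContactModel[{self.spec.response}] ~ {self.spec.label} "
                f"(random: {self.spec.random})\n"
                f"AICc {self.aicc:.2f} (k={self.k}, n={self.nobs})\n")
        return head + self._res.summary()


def candidate_contact_models(
    summaries: pd.DataFrame,
    response: Response,
    random: str = "chick",
    **fit_kwargs,
) -> list[ContactModelResults]:
    """Fit the full candidate set: every subset of {age, chick_sex,
    parent_sex} as fixed effects, year always included, no interactions.
    Non-converging candidates are logged and returned flagged."""
    family = "binomial" if response in _BINOMIAL_COLS else "gamma-log"
    out: list[ContactModelResults] = []
    terms = ("age", "chick_sex", "parent_sex")
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            spec = ModelSpec(response=response, fixed=combo,
                             family=family, random=random)
            try:
                res = ContactModel(summaries, spec).fit(**fit_kwargs)
            except Exception as exc:  # degenerate data for this candidate
                logger.warning("candidate %s failed: %s", spec.label, exc)
                continue
            if not res.converged:
                logger.warning("candidate %s did not converge; excluded from selection",
                               spec.label)
            out.append(res)
    return out


def model_selection_table(results: Iterable[ContactModelResults]) -> pd.DataFrame:
    """AICc model-selection table: spec, k, logLik, AICc, dAICc, weight."""
    rows = [{"model": r.spec.label, "k": r.k, "logLik": r.llf,
             "AICc": r.aicc, "converged": r.converged} for r in results]
    tab = pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)
    tab["dAICc"] = tab["AICc"] - tab["AICc"].min()
    w = np.exp(-0.5 * tab["dAICc"])
    tab["weight"] = w / w.sum()
    return tab
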