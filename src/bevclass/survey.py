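"""Design-based weighted regression and group comparisons.

Implements the statistical layer for stratified, clustered, weighted survey
samples:

* :class:`SurveyWLS` -- weighted least squares with a Taylor-series
  (linearization) covariance computed from primary-sampling-unit (PSU) score
  totals within strata, the with-replacement first-stage approximation used
  by the standard survey procedures.  Residual degrees of freedom are
  ``#PSUs - #strata``.
* a residual-normalization ladder (power transforms and log) selected by
  weighted residual skewness;
* least-squares means (LSMs): model predictions per consumer group at the
  survey-weighted covariate profile, with delta-method standard errors;
* Tukey-Kramer adjusted pairwise comparisons via the studentized-range
  distribution, with compact letter displays.

Outcome models follow the published analysis: Model 1 adjusts for age, sex,
race/ethnicity, income, physical activity, and BMI percentile; Model 2 adds
total energy intake.  LSMs and their standard errors are reported on the
untransformed scale, while pairwise comparisons use the transformed scale.

Notes
-----
No general-purpose Python library provides design-based survey regression,
so the estimator is implemented here from first principles; under a
simple-random-sample design (one stratum, each observation its own PSU) the
coefficients collapse to textbook WLS and the covariance to a centered
sandwich (heteroskedasticity-robust) form.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .recall import ConsumerGroup

__all__ = [
    "SurveyDesign",
    "SurveyWLS",
    "SingularDesignError",
    "ModelSpec",
    "OutcomeModel",
    "LsmResult",
    "fit_survey_wls",
    "weighted_skewness",
    "choose_transform",
    "normalize_residuals",
    "build_design_matrix",
    "lsm",
    "tukey_pairwise",
    "letter_display",
    "TRANSFORM_LADDER",
    "MODEL1_COVARIATES",
    "OUTCOMES",
]

OUTCOMES = ("energy_kcal", "carbohydrate_g", "total_sugar_g", "added_sugar_g")

MODEL1_COVARIATES = {
    "continuous": ("age_years", "bmi_percentile"),
    "categorical": ("sex", "race_ethnicity", "income", "physical_activity"),
}


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient; names the aliased columns."""


@dataclass(frozen=True)
class SurveyDesign:
    """Per-observation stratum/PSU identifiers and sampling weights."""

    strata: np.ndarray
    psu: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        strata = np.asarray(self.strata)
        psu = np.asarray(self.psu)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "strata", strata)
        object.__setattr__(self, "psu", psu)
        object.__setattr__(self, "weights", weights)
        n = len(weights)
        if len(strata) != n or len(psu) != n:
            raise ValueError("strata, psu, and weights must have equal length")
        if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
            raise ValueError("weights must be finite and strictly positive")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurveyDesign":
        return cls(
            strata=df["stratum_id"].to_numpy(),
            psu=df["psu_id"].to_numpy(),
            weights=df["weight"].to_numpy(dtype=float),
        )


class SurveyWLS:
    """Survey-weighted least squares with linearized covariance.

    Parameters
    ----------
    lonely_psu : {"grand_mean", "error"}
        How to handle strata containing a single PSU.  ``"grand_mean"``
        (default) centers the lonely PSU's score total at the grand mean of
        all PSU totals (its squared deviation enters the variance with unit
        factor); ``"error"`` raises.

    Attributes (after :meth:`fit`)
    ------------------------------
    params_ : ndarray of shape (p,)
        Weighted least-squares coefficients.
    cov_params_ : ndarray of shape (p, p)
        Taylor-linearization covariance over strata/PSUs.
    df_resid_ : int
        Design degrees of freedom, ``n_psu_ - n_strata_``.
    lonely_strata_ : list
        Strata that contained a single PSU.
    """

    def __init__(self, lonely_psu: str = "grand_mean"):
        if lonely_psu not in ("grand_mean", "error"):
            raise ValueError(f"unknown lonely_psu rule {lonely_psu!r}")
        self.lonely_psu = lonely_psu

    def get_params(self) -> dict:
        return {"lonely_psu": self.lonely_psu}

    def set_params(self, **params) -> "SurveyWLS":
        for k, v in params.items():
            if k not in ("lonely_psu",):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        design: SurveyDesign,
        colnames: Sequence[str] | None = None,
    ) -> "SurveyWLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one row per observation of y")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
            raise ValueError("X and y must be finite")
        n, p = X.shape
        w = design.weights
        if len(w) != n:
            raise ValueError("design length does not match X")
        names = list(colnames) if colnames is not None else [f"x{j}" for j in range(p)]

        Xw = X * np.sqrt(w)[:, None]
        A = X.T @ (w[:, None] * X)
        rank = np.linalg.matrix_rank(Xw)
        if rank < p:
            aliased = _aliased_columns(Xw, names)
            raise SingularDesignError(
                f"design matrix is singular; aliased column(s): {aliased}"
            )
        beta = np.linalg.solve(A, X.T @ (w * y))
        resid = y - X @ beta
        scores = (w * resid)[:, None] * X  # per-observation score contributions

        G, n_psu, n_strata, lonely = _linearized_score_cov(
            scores, design.strata, design.psu, self.lonely_psu
        )
        A_inv = np.linalg.inv(A)
        cov = A_inv @ G @ A_inv

        self.params_ = beta
        self.cov_params_ = cov
        self.bse_ = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        self.df_resid_ = n_psu - n_strata
        self.n_psu_ = n_psu
        self.n_strata_ = n_strata
        self.lonely_strata_ = lonely
        self.nobs_ = n
        self.colnames_ = names
        self.resid_ = resid
        self.weights_ = w
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.params_


def _aliased_columns(Xw: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns made redundant by earlier ones (greedy QR-style scan)."""
    aliased = []
    kept: list[int] = []
    for j in range(Xw.shape[1]):
        cand = Xw[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


def _linearized_score_cov(
    scores: np.ndarray,
    strata: np.ndarray,
    psu: np.ndarray,
    lonely_psu: str,
) -> tuple[np.ndarray, int, int, list]:
    """Between-PSU covariance of score totals, stratum by stratum."""
    strata = np.asarray(strata)
    psu = np.asarray(psu)
    p = scores.shape[1]
    # PSU totals, keyed by (stratum, psu)
    df = pd.DataFrame(scores)
    df["_stratum"] = strata
    df["_psu"] = psu
    totals = df.groupby(["_stratum", "_psu"], sort=True).sum()
    z = totals.to_numpy()
    stratum_of_psu = totals.index.get_level_values(0).to_numpy()

    uniq_strata = pd.unique(stratum_of_psu)
    n_psu = z.shape[0]
    n_strata = len(uniq_strata)
    grand_mean = z.mean(axis=0)

    G = np.zeros((p, p))
    lonely = []
    for h in uniq_strata:
        zh = z[stratum_of_psu == h]
        nh = zh.shape[0]
        if nh == 1:
            if lonely_psu == "error":
                raise ValueError(f"stratum {h!r} has a single PSU")
            lonely.append(h)
            d = zh[0] - grand_mean
            G += np.outer(d, d)
            continue
        dev = zh - zh.mean(axis=0)
        G += (nh / (nh - 1)) * (dev.T @ dev)
    return G, n_psu, n_strata, lonely


def fit_survey_wls(
    y: np.ndarray,
    X: np.ndarray,
    design: SurveyDesign,
    colnames: Sequence[str] | None = None,
    lonely_psu: str = "grand_mean",
) -> SurveyWLS:
    """Functional wrapper over :class:`SurveyWLS`."""
    return SurveyWLS(lonely_psu=lonely_psu).fit(X, y, design, colnames)


# ---------------------------------------------------------------------------
# residual-normalization ladder


def weighted_skewness(x: np.ndarray, w: np.ndarray) -> float:
    """Weight-standardized third moment; 0 for (near-)degenerate samples."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    wsum = w.sum()
    m = (w * x).sum() / wsum
    d = x - m
    m2 = (w * d**2).sum() / wsum
    if m2 <= 1e-12 * max(1.0, m**2):
        return 0.0
    m3 = (w * d**3).sum() / wsum
    return float(m3 / m2**1.5)


def _identity(y):
    return y


def _sqrt(y):
    return np.sqrt(y)


def _log(y):
    return np.log(y)


def _invsqrt(y):
    return -1.0 / np.sqrt(y)


def _inv(y):
    return -1.0 / y


#: (name, transform, requires_positive).  Negative powers carry a sign flip
#: so every rung is monotone increasing.
TRANSFORM_LADDER: tuple[tuple[str, Callable, bool], ...] = (
    ("identity", _identity, False),
    ("sqrt", _sqrt, False),
    ("log", _log, True),
    ("inverse_sqrt", _invsqrt, True),
    ("inverse", _inv, True),
)


def choose_transform(
    y: np.ndarray,
    X: np.ndarray,
    design: SurveyDesign,
    skew_threshold: float = 0.5,
    ladder=TRANSFORM_LADDER,
) -> tuple[str, SurveyWLS]:
    """Walk the transform ladder until model residuals look normal.

    Each rung refits the model on the transformed outcome and accepts the
    first fit whose weighted residual skewness has magnitude below
    `skew_threshold` (identity is tried first, so an already-normal outcome
    stays untransformed).  Rungs whose domain excludes the observed outcome
    values (log and negative powers need ``y > 0``, the square root needs
    ``y >= 0``) are rejected rather than shifted.  If no rung passes, the one
    with the smallest absolute skewness is used.
    """
    y = np.asarray(y, dtype=float)
    best: tuple[float, str, SurveyWLS] | None = None
    for name, func, needs_pos in ladder:
        if needs_pos and np.any(y <= 0):
            continue
        if name == "sqrt" and np.any(y < 0):
            continue
        fit = SurveyWLS().fit(X, func(y), design)
        skew = abs(weighted_skewness(fit.resid_, design.weights))
        if skew < skew_threshold:
            return name, fit
        if best is None or skew < best[0]:
            best = (skew, name, fit)
    assert best is not None
    return best[1], best[2]


def normalize_residuals(
    y: np.ndarray,
    X: np.ndarray,
    design: SurveyDesign,
    skew_threshold: float = 0.5,
) -> str:
    """Name of the ladder transform selected for this outcome/model."""
    name, _ = choose_transform(y, X, design, skew_threshold)
    return name


# ---------------------------------------------------------------------------
# design matrices and least-squares means


@dataclass(frozen=True)
class ColumnInfo:
    name: str
    kind: str  # "intercept" | "continuous" | "dummy"
    var: str | None = None
    level: str | None = None


def build_design_matrix(
    df: pd.DataFrame,
    continuous: Sequence[str],
    categorical: Sequence[str],
) -> tuple[np.ndarray, list[ColumnInfo]]:
    """Intercept + treatment-coded dummies (first level dropped, levels
    sorted) + continuous columns, with per-column metadata."""
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    info: list[ColumnInfo] = [ColumnInfo("Intercept", "intercept")]
    for var in categorical:
        levels = sorted(df[var].astype(str).unique())
        vals = df[var].astype(str).to_numpy()
        for level in levels[1:]:
            cols.append((vals == level).astype(float))
            info.append(ColumnInfo(f"{var}[T.{level}]", "dummy", var, level))
    for var in continuous:
        cols.append(df[var].to_numpy(dtype=float))
        info.append(ColumnInfo(var, "continuous", var))
    return np.column_stack(cols), info


def _lsm_profiles(
    info: Sequence[ColumnInfo],
    df: pd.DataFrame,
    weights: np.ndarray,
    group_var: str,
    groups: Sequence[str],
) -> np.ndarray:
    """Profile matrix L (one row per group) for LSM prediction.

    The group's own dummies are set to the group indicator; other categorical
    dummies take their survey-weighted proportions and continuous covariates
    their survey-weighted means (the covariate profile of the weighted
    population).
    """
    wsum = weights.sum()
    L = np.zeros((len(groups), len(info)))
    for j, ci in enumerate(info):
        if ci.kind == "intercept":
            L[:, j] = 1.0
        elif ci.kind == "continuous":
            L[:, j] = (weights * df[ci.var].to_numpy(dtype=float)).sum() / wsum
        elif ci.var == group_var:
            L[:, j] = [1.0 if g == ci.level else 0.0 for g in groups]
        else:
            mask = (df[ci.var].astype(str) == ci.level).to_numpy()
            L[:, j] = (weights * mask).sum() / wsum
    return L


@dataclass
class LsmResult:
    """Least-squares means with adjusted pairwise comparisons.

    Means and standard errors are on the untransformed scale; pairwise
    adjusted p-values come from the transformed-scale fit.  Groups sharing a
    letter are not significantly different at `alpha`.
    """

    groups: list[str]
    lsm: dict[str, float]
    se: dict[str, float]
    n: dict[str, int]
    pairwise: pd.DataFrame
    letters: dict[str, str]
    transform: str
    df_resid: int
    alpha: float = 0.05


def lsm(
    fit: SurveyWLS,
    info: Sequence[ColumnInfo],
    df: pd.DataFrame,
    weights: np.ndarray,
    group_var: str = "group",
    groups: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group LSM vector and its covariance matrix.

    Raises if a requested group is absent from the data.
    """
    present = set(df[group_var].astype(str))
    if groups is None:
        groups = sorted(present)
    missing = [g for g in groups if g not in present]
    if missing:
        raise ValueError(f"group(s) absent from data: {missing}")
    L = _lsm_profiles(info, df, weights, group_var, groups)
    means = L @ fit.params_
    cov = L @ fit.cov_params_ @ L.T
    return means, cov


# ---------------------------------------------------------------------------
# Tukey-Kramer pairwise comparisons and letters


def tukey_pairwise(
    means: np.ndarray,
    cov: np.ndarray,
    df_resid: int,
    groups: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise group contrasts with Tukey-Kramer adjusted p-values.

    The adjustment uses the studentized-range distribution with the design
    degrees of freedom: ``p_adj = P(Q_{k, df} > sqrt(2) |t|)``.  For k = 2
    this reduces to the two-sided t-test.  Degenerate contrasts (zero
    standard error) get p = 1 when the difference is also zero, else p = 0.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("pairwise comparisons need at least 2 groups")
    if df_resid < 1:
        raise ValueError(f"design degrees of freedom {df_resid} < 1")
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
        se = math.sqrt(max(var, 0.0))
        if se == 0.0:
            t = np.inf if diff != 0 else 0.0
            p_adj = p_unadj = 0.0 if diff != 0 else 1.0
        else:
            t = diff / se
            p_adj = float(stats.studentized_range.sf(math.sqrt(2.0) * abs(t), k, df_resid))
            p_unadj = float(2 * stats.t.sf(abs(t), df_resid))
        rows.append(
            {
                "group_a": groups[i],
                "group_b": groups[j],
                "estimate": diff,
                "se": se,
                "t": t,
                "p_unadj": p_unadj,
                "p_adj": min(p_adj, 1.0),
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def letter_display(
    groups: Sequence[str],
    means: Mapping[str, float],
    pairwise: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different.

    Letters label the maximal cliques of the non-significance graph (groups
    ordered by ascending mean), the standard presentation for adjusted
    all-pairs comparisons.  Feasible directly because the number of groups is
    small.
    """
    order = sorted(groups, key=lambda g: means[g])
    sig = {
        frozenset((r["group_a"], r["group_b"]))
        for _, r in pairwise.iterrows()
        if r["p_adj"] < alpha
    }

    def is_clique(subset: tuple[str, ...]) -> bool:
        return all(
            frozenset((a, b)) not in sig for a, b in itertools.combinations(subset, 2)
        )

    cliques: list[tuple[str, ...]] = []
    for size in range(len(order), 0, -1):
        for subset in itertools.combinations(order, size):
            if not is_clique(subset):
                continue
            if any(set(subset) <= set(c) for c in cliques):
                continue
            cliques.append(subset)
    cliques.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in groups}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    return letters


# ---------------------------------------------------------------------------
# outcome models


@dataclass(frozen=True)
class ModelSpec:
    """Outcome and adjustment set of one published model."""

    outcome: str
    model: int = 1  # 1: demographics; 2: demographics + energy

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}; expected one of {OUTCOMES}")
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.model == 2 and self.outcome == "energy_kcal":
            raise ValueError("Model 2 adjusts for energy; energy itself is a Model 1 outcome")

    @property
    def continuous(self) -> tuple[str, ...]:
        base = MODEL1_COVARIATES["continuous"]
        return base + ("energy_kcal",) if self.model == 2 else base

    @property
    def categorical(self) -> tuple[str, ...]:
        return ("group",) + MODEL1_COVARIATES["categorical"]


class OutcomeModel:
    """Estimator for one outcome under one adjustment model.

    ``fit`` expects a frame carrying the outcome, ``group``, the model
    covariates, and ``weight`` / ``stratum_id`` / ``psu_id``.  Ungrouped
    participants and rows with missing values in used columns are dropped
    (counts recorded).  Fitted attributes: ``lsm_``, ``lsm_se_`` (raw scale),
    ``pairwise_``, ``letters_`` (transformed scale), ``transform_``,
    ``df_resid_``, ``n_per_group_``.
    """

    def __init__(
        self,
        outcome: str,
        model: int = 1,
        alpha: float = 0.05,
        skew_threshold: float = 0.5,
        lonely_psu: str = "grand_mean",
    ):
        self.outcome = outcome
        self.model = model
        self.alpha = alpha
        self.skew_threshold = skew_threshold
        self.lonely_psu = lonely_psu

    def get_params(self) -> dict:
        return {
            "outcome": self.outcome,
            "model": self.model,
            "alpha": self.alpha,
            "skew_threshold": self.skew_threshold,
            "lonely_psu": self.lonely_psu,
        }

    def set_params(self, **params) -> "OutcomeModel":
        valid = self.get_params()
        for k, v in params.items():
            if k not in valid:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, df: pd.DataFrame) -> "OutcomeModel":
        spec = ModelSpec(self.outcome, self.model)
        used = (
            [self.outcome, "group", "weight", "stratum_id", "psu_id"]
            + list(spec.continuous)
            + list(MODEL1_COVARIATES["categorical"])
        )
        used = list(dict.fromkeys(used))
        missing_cols = [c for c in used if c not in df.columns]
        if missing_cols:
            raise ValueError(f"missing column(s) for {spec}: {missing_cols}")
        data = df[used].copy()
        n0 = len(data)
        data = data[data["group"] != ConsumerGroup.UNGROUPED.value]
        self.n_ungrouped_ = n0 - len(data)
        n1 = len(data)
        data = data.dropna()
        self.n_dropped_missing_ = n1 - len(data)
        if data["group"].nunique() < 2:
            raise ValueError("outcome model needs at least 2 consumer groups present")

        design = SurveyDesign.from_frame(data)
        X, info = build_design_matrix(data, spec.continuous, spec.categorical)
        names = [ci.name for ci in info]
        y = data[self.outcome].to_numpy(dtype=float)

        raw = SurveyWLS(lonely_psu=self.lonely_psu).fit(X, y, design, names)
        groups = sorted(data["group"].astype(str).unique())
        means_raw, cov_raw = lsm(raw, info, data, design.weights, "group", groups)

        self.transform_, tfit = choose_transform(
            y, X, design, self.skew_threshold
        )
        means_t, cov_t = lsm(tfit, info, data, design.weights, "group", groups)
        pairwise = tukey_pairwise(means_t, cov_t, tfit.df_resid_, groups, self.alpha)

        self.groups_ = groups
        self.n_per_group_ = data.groupby("group").size().to_dict()
        self.lsm_ = {g: float(m) for g, m in zip(groups, means_raw)}
        self.lsm_se_ = {
            g: float(math.sqrt(max(cov_raw[i, i], 0.0))) for i, g in enumerate(groups)
        }
        self.pairwise_ = pairwise
        self.letters_ = letter_display(groups, self.lsm_, pairwise, self.alpha)
        self.df_resid_ = raw.df_resid_
        self.fit_raw_ = raw
        self.fit_transformed_ = tfit
        self.column_info_ = info
        return self

    def result(self) -> LsmResult:
        return LsmResult(
            groups=self.groups_,
            lsm=self.lsm_,
            se=self.lsm_se_,
            n=self.n_per_group_,
            pairwise=self.pairwise_,
            letters=self.letters_,
            transform=self.transform_,
            df_resid=self.df_resid_,
            alpha=self.alpha,
        )

    def summary(self) -> dict:
        return {
            "outcome": self.outcome,
            "model": self.model,
            "transform": self.transform_,
            "df_resid": self.df_resid_,
            "groups": self.groups_,
            "n": self.n_per_group_,
            "lsm": self.lsm_,
            "se": self.lsm_se_,
            "letters": self.letters_,
            "p_adj": {
                f"{r['group_a']}|{r['group_b']}": float(r["p_adj"])
                for _, r in self.pairwise_.iterrows()
            },
        }
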