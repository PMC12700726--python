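"""Inferential models: collinearity screen, count GLMM, weather GAM,
and the behavior-rhythm Friedman test.

The count model is a Poisson GLMM with log link — per-individual
vocal-event counts against rank (David's Score), sex, age, network
centrality and number of relatives, with a random intercept per
individual.  The weather model is a Gaussian GAM of hourly acoustic
complexity on eight environmental covariates (thin-plate smooths, a
cyclic smooth for wind direction) with candidate tensor-product
interaction terms (temperature x humidity, temperature x precipitation);
the candidate with the lowest AIC is reduced by backward removal of
non-significant smooths.  Both mixed/additive fits run on the lme4 and
mgcv engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from ._rbackend import run_r_json

__all__ = [
    "GLMM_PREDICTORS",
    "GAM_SMOOTH_TERMS",
    "GAM_TENSOR_TERMS",
    "vif",
    "GlmmResult",
    "fit_count_glmm",
    "fit_count_glmm_batch",
    "GamResult",
    "fit_aci_gam",
    "fit_aci_gam_batch",
    "friedman_behavior_test",
]

#: fixed effects of the count model, in reporting order
GLMM_PREDICTORS = ("rank", "sex", "age", "centrality", "relatives")
#: continuous predictors standardized before fitting (sex stays 0/1)
_STANDARDIZED = ("rank", "age", "centrality", "relatives")

#: environmental covariates entering the weather GAM as univariate smooths
GAM_SMOOTH_TERMS: tuple[dict, ...] = (
    {"term": "temperature", "k": 8, "bs": "tp"},
    {"term": "humidity", "k": 8, "bs": "tp"},
    {"term": "precipitation", "k": 8, "bs": "tp"},
    {"term": "zonal_wind", "k": 8, "bs": "tp"},
    {"term": "meridional_wind", "k": 8, "bs": "tp"},
    {"term": "surface_wind_speed", "k": 8, "bs": "tp"},
    {"term": "wind_direction", "k": 8, "bs": "cc", "knots": [0.0, 360.0]},
    {"term": "surface_radiation", "k": 8, "bs": "tp"},
)
#: candidate tensor-product interactions
GAM_TENSOR_TERMS: tuple[dict, ...] = (
    {"vars": ["temperature", "humidity"], "k": 5},
    {"vars": ["temperature", "precipitation"], "k": 5},
)
#: the four candidate models: which tensor terms each includes
GAM_CANDIDATES: tuple[tuple[int, ...], ...] = ((), (0,), (1,), (0, 1))


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor, VIF_j = 1 / (1 - R²_j).

    Categorical (non-numeric) columns are expanded to 0/1 indicators with
    a dropped reference level.  Perfect collinearity yields ``inf`` for
    the columns involved, with a warning naming them.
    """
    x = pd.get_dummies(design, drop_first=True).astype(float)
    if x.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if x.shape[0] <= x.shape[1]:
        raise ValueError("VIF needs more observations than predictors")
    out = {}
    arr = x.to_numpy()
    n = arr.shape[1]
    for j in range(n):
        y = arr[:, j]
        others = np.column_stack([np.ones(arr.shape[0]), np.delete(arr, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            out[x.columns[j]] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        if r2 > 1 - 1e-12:
            warnings.warn(f"perfect collinearity involving {x.columns[j]!r}", stacklevel=2)
            out[x.columns[j]] = np.inf
        else:
            out[x.columns[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class GlmmResult:
    """Fixed-effect table plus random-intercept spread of the count model."""

    table: pd.DataFrame
    random_sd: float
    converged: bool
    method: str  # "glmm" or "glm" fallback
    vifs: pd.Series | None = None


def _prepare_glmm_frame(
    data: pd.DataFrame,
    predictors: Sequence[str],
    response: str,
    group: str,
    offset: str | None,
    standardize: bool,
) -> pd.DataFrame:
    d = data.copy()
    counts = np.asarray(d[response], dtype=float)
    if np.any(counts < 0) or np.any(counts % 1 != 0):
        raise ValueError("response must be nonnegative integer counts")
    if d["sex"].dtype == object:
        # female coded 1, male reference
        d["sex"] = (d["sex"].str.lower().str[0] == "f").astype(int)
    if standardize:
        for col in _STANDARDIZED:
            if col in predictors:
                v = np.asarray(d[col], dtype=float)
                sd = v.std(ddof=0)
                d[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    keep = [response, group, *predictors]
    if offset:
        keep.append(offset)
    return d[keep]


def fit_count_glmm(
    data: pd.DataFrame,
    predictors: Sequence[str] = GLMM_PREDICTORS,
    response: str = "count",
    group: str = "id",
    offset: str | None = None,
    standardize: bool = True,
    compute_vif: bool = True,
) -> GlmmResult:
    """Poisson GLMM of vocal counts on individual attributes.

    One row per observation period (individual-night by default); random
    intercept on ``group``; sex coded female = 1 against a male
    reference; continuous predictors z-scored by default.  Rank may be
    supplied as the continuous David's Score (default ``rank``) or as a
    categorical tier column named in ``predictors``, which the engine
    dummy-codes.  When fewer
    than two observations per individual are available the random
    intercept is not estimable and the fit degrades to a plain Poisson
    GLM with a warning.
    """
    d = _prepare_glmm_frame(data, predictors, response, group, offset, standardize)
    vifs = vif(d[list(predictors)]) if compute_vif and len(predictors) >= 2 else None
    if d.groupby(group).size().max() < 2:
        warnings.warn(
            "fewer than 2 observations per individual; fitting a Poisson GLM "
            "without the random intercept",
            stacklevel=2,
        )
        x = sm.add_constant(d[list(predictors)].astype(float))
        off = np.asarray(d[offset], dtype=float) if offset else None
        fit = sm.GLM(d[response], x, family=sm.families.Poisson(), offset=off).fit()
        ci = fit.conf_int()
        table = pd.DataFrame(
            {
                "term": ["(Intercept)", *predictors],
                "estimate": fit.params.to_numpy(),
                "se": fit.bse.to_numpy(),
                "z": fit.tvalues.to_numpy(),
                "p": fit.pvalues.to_numpy(),
                "ci_lo": ci[0].to_numpy(),
                "ci_hi": ci[1].to_numpy(),
            }
        )
        return GlmmResult(table=table, random_sd=np.nan, converged=True,
                          method="glm", vifs=vifs)

    cfg = {
        "response": response,
        "fixed": list(predictors),
        "group": group,
        "offset": offset,
        "ci_level": 0.95,
    }
    res = run_r_json("glmm_fit.R", d, cfg)[0]
    if "error" in res:
        raise RuntimeError(f"GLMM did not converge: {res['error']}")
    table = pd.DataFrame(res["terms"])
    return GlmmResult(
        table=table,
        random_sd=float(res["random_sd"]),
        converged=bool(res["converged"]),
        method="glmm",
        vifs=vifs,
    )


def fit_count_glmm_batch(
    data: pd.DataFrame,
    predictors: Sequence[str] = GLMM_PREDICTORS,
    response: str = "count",
    group: str = "id",
    offset: str | None = None,
    standardize: bool = True,
) -> list[GlmmResult | None]:
    """Fit the count GLMM once per ``replicate`` value, in one R session.

    Intended for simulation studies; returns None for replicates whose
    fit failed.
    """
    frames = []
    for rep, sub in data.groupby("replicate"):
        f = _prepare_glmm_frame(sub, predictors, response, group, offset, standardize)
        f.insert(0, "replicate", rep)
        frames.append(f)
    allf = pd.concat(frames, ignore_index=True)
    cfg = {
        "response": response,
        "fixed": list(predictors),
        "group": group,
        "offset": offset,
        "ci_level": 0.95,
    }
    results = run_r_json("glmm_fit.R", allf, cfg)
    out: list[GlmmResult | None] = []
    for res in results:
        if "error" in res:
            out.append(None)
            continue
        out.append(
            GlmmResult(
                table=pd.DataFrame(res["terms"]),
                random_sd=float(res["random_sd"]),
                converged=bool(res["converged"]),
                method="glmm",
            )
        )
    return out


@dataclass
class GamResult:
    """Final weather-GAM summary after candidate choice and backward removal."""

    table: pd.DataFrame  # term, edf, ref_df, statistic, p
    adj_r2: float
    candidate_aics: list[float]
    chosen_candidate: int
    removal_trace: list[dict]
    grid_effects: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def retained_terms(self) -> list[str]:
        return list(self.table["term"]) if len(self.table) else []


def _gam_config(
    alpha: float, grid: dict[str, Sequence[float]] | None, multiplicity: str
) -> dict:
    cfg = {
        "response": "aci",
        "family": "gaussian",
        "alpha": alpha,
        "multiplicity": multiplicity,
        "smooths": [dict(s) for s in GAM_SMOOTH_TERMS],
        "tensors": [dict(t) for t in GAM_TENSOR_TERMS],
        "candidates": [list(c) for c in GAM_CANDIDATES],
        "stepwise": True,
    }
    if grid:
        cfg["grid"] = {k: list(map(float, v)) for k, v in grid.items()}
    return cfg


def _parse_gam(res: dict) -> GamResult:
    terms = res.get("terms") or []
    table = pd.DataFrame(terms, columns=["term", "edf", "ref_df", "statistic", "p"])
    grid_effects = {
        k: np.asarray(v, dtype=float) for k, v in (res.get("grid_effects") or {}).items()
    }
    return GamResult(
        table=table,
        adj_r2=float(res["adj_r2"]) if res.get("adj_r2") is not None else np.nan,
        candidate_aics=[np.nan if a is None else float(a) for a in res["candidate_aics"]],
        chosen_candidate=int(res["chosen_candidate"]),
        removal_trace=list(res.get("removal_trace") or []),
        grid_effects=grid_effects,
    )


def fit_aci_gam(
    data: pd.DataFrame,
    alpha: float = 0.05,
    grid: dict[str, Sequence[float]] | None = None,
    multiplicity: str = "bonferroni",
) -> GamResult:
    """Fit the weather GAM of hourly ACI and reduce it stepwise.

    ``data`` needs an ``aci`` column plus the eight weather covariates.
    Four candidates are fitted (main effects; + temperature x humidity;
    + temperature x precipitation; + both), the lowest-AIC candidate is
    selected, then non-significant smooths are removed one at a time
    (largest p first, ties broken by term order) until every retained
    term is significant.  "Significant" is family-wise across the
    candidate's smooth terms (Bonferroni, threshold ``alpha / m0``), so
    the whole selection keeps its false-retention rate at ``alpha``;
    ``multiplicity="none"`` uses the plain per-term threshold instead.
    ``grid`` maps covariate names to grids on which the retained partial
    effects are evaluated (for recovery checks or plotting).
    """
    required = {"aci", *(s["term"] for s in GAM_SMOOTH_TERMS)}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    n_terms = len(GAM_SMOOTH_TERMS) + len(GAM_TENSOR_TERMS)
    if data.shape[0] < 10 * n_terms:
        raise ValueError(f"need at least {10 * n_terms} rows for {n_terms} smooth terms")
    res = run_r_json(
        "gam_fit.R", data[sorted(required)], _gam_config(alpha, grid, multiplicity)
    )[0]
    return _parse_gam(res)


def fit_aci_gam_batch(
    data: pd.DataFrame,
    alpha: float = 0.05,
    grid: dict[str, Sequence[float]] | None = None,
    multiplicity: str = "bonferroni",
) -> list[GamResult]:
    """Run the full candidate + stepwise procedure per ``replicate``."""
    required = ["replicate", "aci", *sorted(s["term"] for s in GAM_SMOOTH_TERMS)]
    res = run_r_json("gam_fit.R", data[required], _gam_config(alpha, grid, multiplicity))
    return [_parse_gam(r) for r in res]


def friedman_behavior_test(
    table: pd.DataFrame,
    categories: Sequence[str] = ("aggression", "social", "other"),
) -> tuple[float, int, float]:
    """Friedman test of behavior-category counts across night hours.

    Hours are the blocks and behavior categories the treatments; counts
    are ranked within each hour with average ranks for ties.  Sleep is
    excluded from the default three-way comparison but can be included
    by passing the category list.  A constant table carries no rank
    information and returns (0, k-1, 1).
    Returns (chi-square statistic, degrees of freedom, p-value).
    """
    cols = [c for c in categories if c in table.columns]
    if len(cols) < 3:
        raise ValueError("Friedman test needs at least 3 categories")
    if table.shape[0] < 2:
        raise ValueError("Friedman test needs at least 2 hours (blocks)")
    sub = table[cols].to_numpy(dtype=float)
    dfree = len(cols) - 1
    if np.all(sub == sub[:, :1]):
        return 0.0, dfree, 1.0
    stat, p = stats.friedmanchisquare(*[sub[:, j] for j in range(sub.shape[1])])
    return float(stat), dfree, float(p)
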