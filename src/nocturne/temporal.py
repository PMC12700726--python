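"""Temporal pattern description and validation of the acoustic index.

Hourly series are labeled descriptively by the quartile rule (above Q3 =
peak, below Q1 = trough, otherwise normal — not a formal bimodality
test); the acoustic index is validated against manual counts by Spearman
rank correlation (with a Shapiro–Wilk normality check reported); and the
hour-of-night effect is tested with a Poisson GAM smooth over the
wrapped hour axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rbackend import run_r_json

__all__ = [
    "quartile_classify",
    "AciValidation",
    "validate_aci",
    "SmoothTestResult",
    "hour_smooth_test",
    "hours_since_night_start",
]


def quartile_classify(values: np.ndarray) -> list[str]:
    """Label each value peak / normal / trough against the series quartiles.

    Q1 and Q3 use linear-interpolation quantiles.  Values strictly above
    Q3 are peaks and strictly below Q1 are troughs; boundary values are
    normal.  Labels are therefore invariant under any strictly monotone
    transform of the series.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("series too short: quartile labels need at least 4 values")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    return [
        "peak" if v > q3 else "trough" if v < q1 else "normal" for v in values
    ]


@dataclass(frozen=True)
class AciValidation:
    rho: float
    p: float
    shapiro_p_counts: float
    shapiro_p_aci: float

    @property
    def nonnormal(self) -> bool:
        """True when either series fails the normality gate at 0.05."""
        return self.shapiro_p_counts < 0.05 or self.shapiro_p_aci < 0.05


def validate_aci(counts: np.ndarray, aci: np.ndarray) -> AciValidation:
    """Spearman correlation between hourly counts and hourly ACI.

    Matched hourly series only.  The Shapiro–Wilk p-values are reported
    so the rank-based choice is auditable; Spearman's rho is returned
    regardless of the gate outcome.
    """
    counts = np.asarray(counts, dtype=float)
    aci = np.asarray(aci, dtype=float)
    if counts.shape != aci.shape:
        raise ValueError("counts and ACI series must be matched by hour")
    if counts.size < 4:
        raise ValueError("need at least 4 matched hours")
    sw_c = stats.shapiro(counts).pvalue if np.ptp(counts) > 0 else 0.0
    sw_a = stats.shapiro(aci).pvalue if np.ptp(aci) > 0 else 0.0
    rho, p = stats.spearmanr(counts, aci)
    return AciValidation(rho=float(rho), p=float(p), shapiro_p_counts=float(sw_c),
                         shapiro_p_aci=float(sw_a))


@dataclass(frozen=True)
class SmoothTestResult:
    edf: float
    statistic: float
    p: float


def hours_since_night_start(hour: np.ndarray, night_start: int = 17) -> np.ndarray:
    """Map clock hours to a wrapped 0-based night axis (17 -> 0, 0 -> 7...)."""
    return (np.asarray(hour, dtype=int) - night_start) % 24


def hour_smooth_test(
    data: pd.DataFrame,
    count_col: str = "count",
    hour_col: str = "hour",
    night_start: int = 17,
    k: int = 8,
) -> SmoothTestResult:
    """Test for a non-linear hour-of-night effect on vocal counts.

    Fits ``count ~ s(hours-since-night-start, k=k)`` with a Poisson GAM
    (thin-plate basis on the wrapped hour index, pooled over nights) and
    returns the smooth's effective degrees of freedom, chi-square
    statistic and p-value.
    """
    if data.shape[0] < 12:
        raise ValueError("insufficient data for the hour-of-night smooth")
    d = pd.DataFrame(
        {
            "count": np.asarray(data[count_col], dtype=float),
            "night_hour": hours_since_night_start(np.asarray(data[hour_col]), night_start),
        }
    )
    if np.any(d["count"] % 1 != 0) or np.any(d["count"] < 0):
        raise ValueError("counts must be nonnegative integers")
    cfg = {
        "response": "count",
        "family": "poisson",
        "smooths": [{"term": "night_hour", "k": k, "bs": "tp"}],
        "tensors": [],
        "candidates": [[]],
        "stepwise": False,
    }
    res = run_r_json("gam_fit.R", d, cfg)[0]
    if not res["terms"]:
        raise RuntimeError("smooth term missing from fitted model")
    t = res["terms"][0]
    return SmoothTestResult(edf=float(t["edf"]), statistic=float(t["statistic"]),
                            p=float(t["p"]))
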