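"""Nonparametric richness extrapolation for MOTU inventories.

Three standard estimators of total richness from an under-sampled,
singleton-heavy inventory:

* Chao1 (abundance-based): S_obs + F1^2 / (2 F2), where F1 and F2 count
  MOTUs seen exactly once and twice; bias-corrected form
  S_obs + F1(F1-1) / (2(F2+1)) when F2 = 0.
* Chao2 (incidence-based): same form on Q1/Q2, MOTUs present in exactly
  one and two samples.
* First-order jackknife: S_obs + Q1 (m-1)/m over m samples.

Chao estimators are lower bounds on true richness; their standard
deviations use the classical variance formulas.  "Registration" is the
percentage of the extrapolated richness actually observed,
100 * S_obs / estimate, the survey-completeness figure of merit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RichnessEstimate",
    "chao1",
    "chao2",
    "jackknife1",
    "registration",
]


@dataclass
class RichnessEstimate:
    estimator: str
    s_obs: int
    estimate: float
    sd: float | None = None
    n: int | None = None  # total individuals (abundance estimators)
    m: int | None = None  # number of samples (incidence estimators)
    f1: int | None = None
    f2: int | None = None
    q1: int | None = None
    q2: int | None = None

    def __post_init__(self) -> None:
        if self.estimate < self.s_obs - 1e-9:
            warnings.warn(
                f"{self.estimator}: estimate {self.estimate} below S_obs {self.s_obs}"
            )


def _chao_sd(f1: int, f2: int, estimate: float, s_obs: int) -> float:
    """Classical Chao variance, classic or bias-corrected branch."""
    if f1 == 0:
        return 0.0
    if f2 > 0:
        r = f1 / f2
        var = f2 * (r**2 / 2 + r**3 + r**4 / 4)
    else:
        var = (
            f1 * (f1 - 1) / 2
            + f1 * (2 * f1 - 1) ** 2 / 4
            - f1**4 / (4 * estimate)
        )
    return math.sqrt(max(var, 0.0))


def chao1(abundances: Sequence[int]) -> RichnessEstimate:
    """Chao1 richness from per-MOTU abundances (zeros ignored)."""
    counts = np.asarray(abundances, dtype=int)
    if np.any(counts < 0):
        raise ValueError("negative abundances")
    counts = counts[counts > 0]
    s_obs = int(counts.size)
    if s_obs < 1:
        raise ValueError("no observed MOTUs")
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        est = s_obs + f1**2 / (2 * f2)
    else:
        est = s_obs + f1 * (f1 - 1) / 2  # bias-corrected with F2 = 0
    return RichnessEstimate(
        estimator="chao1",
        s_obs=s_obs,
        estimate=float(est),
        sd=_chao_sd(f1, f2, float(est), s_obs),
        n=int(counts.sum()),
        f1=f1,
        f2=f2,
    )


def _incidence_counts(incidence: pd.DataFrame) -> tuple[int, int, int, int]:
    """(S_obs, Q1, Q2, m) from a MOTU x sample presence table."""
    inc = (incidence.to_numpy() > 0).astype(int)
    m = inc.shape[1]
    per_motu = inc.sum(axis=1)
    observed = per_motu > 0
    s_obs = int(observed.sum())
    q1 = int((per_motu == 1).sum())
    q2 = int((per_motu == 2).sum())
    return s_obs, q1, q2, m


def chao2(incidence: pd.DataFrame) -> RichnessEstimate:
    """Chao2 richness from a MOTU x sample incidence (presence) table."""
    s_obs, q1, q2, m = _incidence_counts(incidence)
    if m < 2:
        raise ValueError("Chao2 needs at least 2 samples")
    if s_obs < 1:
        raise ValueError("no observed MOTUs")
    if q2 > 0:
        est = s_obs + q1**2 / (2 * q2)
    else:
        est = s_obs + q1 * (q1 - 1) / 2
    return RichnessEstimate(
        estimator="chao2",
        s_obs=s_obs,
        estimate=float(est),
        sd=_chao_sd(q1, q2, float(est), s_obs),
        m=m,
        q1=q1,
        q2=q2,
    )


def jackknife1(incidence: pd.DataFrame) -> RichnessEstimate:
    """First-order jackknife: S_obs + Q1 (m-1)/m.  No SD is reported."""
    s_obs, q1, q2, m = _incidence_counts(incidence)
    if m < 2:
        raise ValueError("jackknife1 needs at least 2 samples")
    est = s_obs + q1 * (m - 1) / m
    return RichnessEstimate(
        estimator="jackknife1",
        s_obs=s_obs,
        estimate=float(est),
        sd=None,
        m=m,
        q1=q1,
        q2=q2,
    )


def registration(s_obs: int | float, estimate: float) -> float:
    """Percent of the extrapolated richness observed, 100*S_obs/estimate.

    Rounded half-up to one decimal.  An estimate below S_obs is
    theoretically impossible and triggers a warning (upstream bug).
    """
    if estimate <= 0:
        raise ValueError("estimate must be positive")
    if estimate < s_obs:
        warnings.warn(f"estimate {estimate} < S_obs {s_obs}: registration > 100%")
    pct = Decimal(100 * s_obs / estimate).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(pct)
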