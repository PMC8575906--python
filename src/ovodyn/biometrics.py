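"""Allometric length–weight fit and derived condition / gonadosomatic indices.

The pooled length–weight relationship W = a·TL^b is fitted by ordinary least
squares on log10-transformed data. The exponent b feeds two derived indices:

* relative condition K_n = W_obs / (a·TL^b) — preferred over Fulton's K when
  b deviates from 3, as it self-centres around 1 on the fitting sample;
* the length-based gonadosomatic index GSI_TL = 10⁴ · OW / TL^b, which tracks
  spawning drawdown of the ovary without the body-weight noise of classic GSI.

Lengths are in cm and weights in g throughout; no silent unit absorption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_ALLOMETRIC_B",
    "LengthWeightFit",
    "fit_length_weight",
    "relative_condition",
    "gsi_tl",
    "biometrics_table",
]

#: pooled allometric exponent for NEA mackerel used as the GSI_TL default
DEFAULT_ALLOMETRIC_B = 3.13


@dataclass
class LengthWeightFit:
    a: float  # intercept coefficient, g · cm^-b
    b: float  # allometric exponent
    b_ci95: float  # half-width of the slope's 95% t-interval
    r_squared: float
    n: int

    def predict(self, total_length: float) -> float:
        """Expected weight (g) at a given total length (cm)."""
        return self.a * total_length**self.b


def fit_length_weight(
    total_lengths: Sequence[float], body_weights: Sequence[float]
) -> LengthWeightFit:
    """OLS power fit W = a·TL^b on log10–log10 axes.

    No back-transform bias correction is applied: the ratio convention of
    K_n expects the raw geometric-mean regression line.
    """
    tl = np.asarray(total_lengths, dtype=float)
    w = np.asarray(body_weights, dtype=float)
    if tl.size != w.size:
        raise ValueError("length and weight vectors differ in size")
    if tl.size < 3:
        raise ValueError("need at least 3 females for a length-weight fit")
    if np.any(tl <= 0) or np.any(w <= 0):
        raise ValueError("lengths and weights must be positive")
    if np.allclose(tl, tl[0]):
        raise ValueError("degenerate fit: all total lengths equal")
    res = stats.linregress(np.log10(tl), np.log10(w))
    half = float(stats.t.ppf(0.975, tl.size - 2)) * res.stderr
    return LengthWeightFit(
        a=float(10.0**res.intercept),
        b=float(res.slope),
        b_ci95=float(half),
        r_squared=float(res.rvalue**2),
        n=int(tl.size),
    )


def relative_condition(
    body_weight: float, total_length: float, fit: LengthWeightFit
) -> float:
    """K_n = observed weight over length-predicted weight (dimensionless)."""
    if not total_length > 0:
        raise ValueError("total length must be > 0 cm")
    return body_weight / fit.predict(total_length)


def gsi_tl(
    ovary_weight: float, total_length: float, b: float = DEFAULT_ALLOMETRIC_B
) -> float:
    """Length-based gonadosomatic index 10⁴ · OW / TL^b."""
    if not total_length > 0:
        raise ValueError("total length must be > 0 cm")
    if ovary_weight < 0:
        raise ValueError("ovary weight must be >= 0 g")
    return 1e4 * ovary_weight / total_length**b


def biometrics_table(
    females: pd.DataFrame, b_override: float | None = None
) -> tuple[pd.DataFrame, LengthWeightFit]:
    """Per-female K_n and GSI_TL from the biometry table.

    The length–weight fit pools every female in the table; ``b_override``
    replaces the fitted exponent inside GSI_TL (K_n always uses the fit
    itself, as the index is defined relative to the fitted line).
    """
    fit = fit_length_weight(
        females["total_length_cm"].to_numpy(), females["body_weight_g"].to_numpy()
    )
    b = fit.b if b_override is None else float(b_override)
    rows = [
        (
            str(r.female_id),
            relative_condition(float(r.body_weight_g), float(r.total_length_cm), fit),
            gsi_tl(float(r.ovary_weight_g), float(r.total_length_cm), b),
        )
        for r in females.itertuples(index=False)
    ]
    return pd.DataFrame(rows, columns=["female_id", "K_n", "GSI_TL"]), fit
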