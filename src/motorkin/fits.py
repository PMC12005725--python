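"""Shared statistical layer: Michaelis-Menten and exponential dwell fits.

Dwell-time rate estimation supports three estimators:

``inverse_mean``
    1 / mean of the uncensored dwells at or above ``min_dwell`` (the
    convention behind single-molecule detachment-rate estimates).
``mle_censored``
    maximum likelihood for a left-truncated exponential with
    right-censored dwells contributing survival terms; by memorylessness
    the uncensored closed form is ``n_unc / sum(d - min_dwell)``.
``histogram_ls``
    least-squares single-exponential fit to the binned dwell histogram
    (kept for fidelity with histogram-based reports).

Reported rates are conventionally rounded to 2 significant figures in
text outputs; JSON keeps full precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    FitError,
    InsufficientDataError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "MMFit",
    "DwellRateResult",
    "RateSet",
    "fit_michaelis_menten",
    "fit_dwell_exponential",
    "derive_kd",
    "fold_change",
    "round_sig",
    "build_rate_table",
]


@dataclass(frozen=True)
class MMFit:
    kcat: float        # s^-1 (or vmax in the caller's units)
    km: float          # uM
    se_kcat: float
    se_km: float
    residual_norm: float

    def predict(self, x):
        x = np.asarray(x, float)
        return self.kcat * x / (self.km + x)


@dataclass(frozen=True)
class DwellRateResult:
    rate: float      # s^-1
    se: float
    method: str      # "histogram_ls" | "mle_censored" | "inverse_mean"
    n_used: int
    min_dwell: float  # s, left-truncation actually applied


@dataclass
class RateSet:
    """Kinetic rate constants for one construct/condition."""

    construct: str
    condition: str = "n/a"  # "reduced" | "oxidized" | "n/a"
    k_plus1: float | None = None   # uM^-1 s^-1
    k_minus1: float | None = None  # s^-1
    k2: float | None = None        # s^-1
    k2_smf: float | None = None    # s^-1
    kcat: float | None = None      # s^-1
    km: float | None = None        # uM
    kd: float | None = None        # uM

    def derived_kd(self) -> float | None:
        if self.k_plus1 and self.k_minus1 is not None:
            return derive_kd(self.k_minus1, self.k_plus1)
        return None


def _mm_model(x, kcat, km):
    return kcat * x / (km + x)


def fit_michaelis_menten(x: np.ndarray, y: np.ndarray) -> MMFit:
    """Least-squares fit of ``y = kcat * x / (Km + x)``.

    Initialized from a Lineweaver-Burk double-reciprocal line; SEs come
    from the Jacobian.  Warns when the concentrations do not straddle the
    fitted Km.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise InvalidInputError("x and y have unequal lengths")
    if len(np.unique(x)) < 3:
        raise InvalidInputError("need >= 3 distinct concentrations")
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidInputError("concentrations and rates must be non-negative")

    pos = (x > 0) & (y > 0)
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / x[pos], 1.0 / y[pos], 1)
        if intercept > 0:
            kcat0 = 1.0 / intercept
            km0 = max(slope * kcat0, 1e-12)
        else:
            kcat0, km0 = float(np.max(y)), float(np.median(x[pos]))
    else:
        kcat0, km0 = float(np.max(y)) or 1.0, float(np.median(x)) or 1.0

    try:
        popt, pcov = curve_fit(
            _mm_model, x, y, p0=(kcat0, km0),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Michaelis-Menten fit did not converge "
                       f"(init kcat={kcat0:.4g}, Km={km0:.4g}): {exc}") from exc
    kcat, km = (float(v) for v in popt)
    se = np.sqrt(np.diag(pcov))
    if not (np.min(x[x > 0], initial=np.inf) < km < np.max(x, initial=0.0)):
        warnings.warn(
            f"concentrations do not straddle the fitted Km ({km:.3g} uM); "
            "parameters may be poorly constrained",
            stacklevel=2,
        )
    resid = y - _mm_model(x, *popt)
    return MMFit(kcat, km, float(se[0]), float(se[1]), float(np.linalg.norm(resid)))


def fit_dwell_exponential(
    dwells: np.ndarray,
    censored: np.ndarray | None = None,
    min_dwell: float = 0.0,
    method: str = "mle_censored",
    bin_width: float | None = None,
) -> DwellRateResult:
    """Single-rate estimate from dwell times with truncation/censoring.

    Only dwells ``>= min_dwell`` enter; at least 20 uncensored ones are
    required.  See module docstring for the three estimators.
    """
    d = np.asarray(dwells, float)
    if censored is None:
        cens = np.zeros(len(d), bool)
    else:
        cens = np.asarray(censored, bool)
        if len(cens) != len(d):
            raise InvalidInputError("censored mask length mismatch")
    keep = d >= min_dwell
    d, cens = d[keep], cens[keep]
    n_unc = int((~cens).sum())
    if n_unc < 20:
        raise InsufficientDataError(
            f"need >= 20 uncensored dwells >= {min_dwell} s, got {n_unc}"
        )

    if method == "inverse_mean":
        mean = float(np.mean(d[~cens]))
        rate = 1.0 / mean
        return DwellRateResult(rate, rate / math.sqrt(n_unc), method, n_unc, min_dwell)

    if method == "mle_censored":
        # L = prod_unc r e^{-r(d-m)} * prod_cens e^{-r(d-m)}
        total = float(np.sum(d - min_dwell))
        if total <= 0:
            raise InvalidInputError("all dwells equal the truncation point")
        rate = n_unc / total
        return DwellRateResult(rate, rate / math.sqrt(n_unc), method, n_unc, min_dwell)

    if method == "histogram_ls":
        du = d[~cens]
        rng = float(np.ptp(du))
        if rng <= 0:
            raise InvalidInputError("degenerate dwell distribution for histogram fit")
        bw = bin_width if bin_width is not None else rng / 30.0
        nbins = max(5, int(math.ceil(rng / bw)))
        counts, edges = np.histogram(du, bins=nbins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        rate0 = 1.0 / max(float(np.mean(du - min_dwell)), 1e-12)
        try:
            popt, pcov = curve_fit(
                lambda t, a, r: a * np.exp(-r * t),
                centers, counts.astype(float),
                p0=(float(counts.max()), rate0), maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            raise FitError(f"histogram exponential fit failed: {exc}") from exc
        rate = float(popt[1])
        se = float(np.sqrt(np.diag(pcov))[1])
        return DwellRateResult(rate, se, method, n_unc, min_dwell)

    raise InvalidParameterError(f"unknown method {method!r}")


def derive_kd(k_minus1: float, k_plus1: float) -> float:
    """Dissociation constant ``Kd = k_minus1 / k_plus1`` in uM."""
    if k_plus1 <= 0:
        raise InvalidParameterError(f"k_plus1 must be > 0, got {k_plus1}")
    if k_minus1 < 0:
        raise InvalidParameterError(f"k_minus1 must be >= 0, got {k_minus1}")
    return k_minus1 / k_plus1


def round_sig(value: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures."""
    if value == 0 or not math.isfinite(value):
        return value
    ndigits = sig_figs - 1 - int(math.floor(math.log10(abs(value))))
    return round(value, ndigits)


def fold_change(a: float, b: float, sig_figs: int = 2) -> float:
    """Ratio ``a / b`` rounded to significant figures."""
    if b <= 0:
        raise InvalidParameterError(f"denominator must be > 0, got {b}")
    return round_sig(a / b, sig_figs)


_RATE_COLUMNS = ["construct", "condition", "kcat_per_s", "km_uM", "k_plus1_per_uM_s",
                 "k_minus1_per_s", "k2_per_s", "k2_smf_per_s", "kd_uM",
                 "kd_derived_uM", "kd_inconsistent"]


def build_rate_table(rate_sets: list[RateSet], kd_rtol: float = 0.10) -> pd.DataFrame:
    """Assemble per-construct, per-condition rate constants into a table.

    Adds a derived ``Kd = k_minus1 / k_plus1`` column and flags rows whose
    stored Kd disagrees with the derived one by more than ``kd_rtol``
    relative.  Duplicate (construct, condition) keys are an error.
    """
    seen = set()
    rows = []
    for rs in rate_sets:
        key = (rs.construct, rs.condition)
        if key in seen:
            raise InvalidInputError(f"duplicate rate-set key {key}")
        seen.add(key)
        kd_derived = rs.derived_kd()
        inconsistent = False
        if rs.kd is not None and kd_derived is not None and kd_derived > 0:
            inconsistent = abs(rs.kd - kd_derived) / kd_derived > kd_rtol
        rows.append({
            "construct": rs.construct,
            "condition": rs.condition,
            "kcat_per_s": rs.kcat,
            "km_uM": rs.km,
            "k_plus1_per_uM_s": rs.k_plus1,
            "k_minus1_per_s": rs.k_minus1,
            "k2_per_s": rs.k2,
            "k2_smf_per_s": rs.k2_smf,
            "kd_uM": rs.kd if rs.kd is not None else kd_derived,
            "kd_derived_uM": kd_derived,
            "kd_inconsistent": inconsistent,
        })
    return pd.DataFrame(rows, columns=_RATE_COLUMNS)
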