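"""Ensemble stopped-flow transient fitting.

Averaged fluorescence transients are fit with a single exponential
``y = A exp(-kobs t) + C`` and turbidity transients with the burst form
``y = A exp(-kobs t) + kss t + C``.  Observed rates collected over a
ligand-concentration series are fit with a line ``kobs = k1 [S] + k-1``
whose slope is the second-order on-rate and intercept the off-rate
(reported as-is even when negative).

Fits start at the first recorded point; instrument dead time is not
modeled.  Initialization is deterministic: the offset from the trace end,
the amplitude from the endpoints, and the rate from the time at which the
signal has covered ``1 - 1/e`` of its span.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InvalidInputError

__all__ = [
    "Trace",
    "ExpFit",
    "BurstFit",
    "KobsSeries",
    "LineFit",
    "average_traces",
    "fit_single_exponential",
    "fit_burst",
    "fit_kobs_linear",
]


@dataclass
class Trace:
    """One stopped-flow time course (time from mix)."""

    t: np.ndarray
    y: np.ndarray
    kind: str = "fluorescence"  # "fluorescence" | "turbidity"
    ligand_conc: float = math.nan  # uM

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.y = np.asarray(self.y, float)
        if len(self.t) != len(self.y):
            raise InvalidInputError("trace t and y have unequal lengths")
        if len(self.t) and self.t[0] < 0:
            raise InvalidInputError("trace time must be non-negative")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise InvalidInputError("trace time must be strictly increasing")
        if self.kind not in ("fluorescence", "turbidity"):
            raise InvalidInputError(f"unknown trace kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ExpFit:
    A: float
    k_obs: float
    C: float
    se_A: float
    se_k: float
    se_C: float
    residual_norm: float
    short_window: bool = False  # trace covers < 3/k_obs of the relaxation


@dataclass(frozen=True)
class BurstFit:
    A: float
    k_obs: float
    k_ss: float
    C: float
    se_A: float
    se_k: float
    se_kss: float
    se_C: float
    residual_norm: float


@dataclass
class KobsSeries:
    """(concentration, k_obs, SE) points for one construct/condition."""

    conc: np.ndarray     # uM
    k_obs: np.ndarray    # s^-1
    se: np.ndarray | None = None
    tag: str = ""

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, float)
        self.k_obs = np.asarray(self.k_obs, float)
        if self.se is not None:
            self.se = np.asarray(self.se, float)
        if len(np.unique(self.conc)) != len(self.conc):
            raise InvalidInputError("concentrations in a kobs series must be distinct")


@dataclass(frozen=True)
class LineFit:
    k_plus1: float    # uM^-1 s^-1 (slope)
    k_minus1: float   # s^-1 (intercept; may be negative)
    se_k_plus1: float
    se_k_minus1: float
    weighted: bool


def average_traces(traces: list[Trace]) -> Trace:
    """Pointwise mean of replicate traces.

    Traces must share kind and ligand concentration.  Differing time grids
    are linearly resampled onto the densest grid first.
    """
    if not traces:
        raise InvalidInputError("no traces to average")
    kind = traces[0].kind
    conc = traces[0].ligand_conc
    for tr in traces[1:]:
        if tr.kind != kind:
            raise InvalidInputError("cannot average traces of different kinds")
        same_conc = (tr.ligand_conc == conc) or (
            math.isnan(tr.ligand_conc) and math.isnan(conc)
        )
        if not same_conc:
            raise InvalidInputError(
                f"cannot average traces at different ligand concentrations "
                f"({tr.ligand_conc} vs {conc} uM)"
            )
    grid = max((tr.t for tr in traces), key=len)
    ys = [
        tr.y if len(tr.t) == len(grid) and np.array_equal(tr.t, grid)
        else np.interp(grid, tr.t, tr.y)
        for tr in traces
    ]
    return Trace(grid.copy(), np.mean(ys, axis=0), kind=kind, ligand_conc=conc)


def _exp_model(t, A, k, C):
    return A * np.exp(-k * t) + C


def _init_exp(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    C0 = float(y[-1])
    A0 = float(y[0] - y[-1])
    span = t[-1] - t[0]
    k0 = 3.0 / span if span > 0 else 1.0
    if A0 != 0:
        frac = (y - C0) / A0
        idx = np.flatnonzero(frac <= 1.0 / math.e)
        if len(idx) and t[idx[0]] > t[0]:
            k0 = 1.0 / (t[idx[0]] - t[0])
    return A0, k0, C0


def fit_single_exponential(trace: Trace) -> ExpFit:
    """Nonlinear least squares of ``y = A exp(-kobs t) + C``."""
    t, y = trace.t, trace.y
    if len(t) < 10:
        raise InvalidInputError(f"trace too short to fit ({len(t)} points, need >= 10)")
    if np.ptp(y) == 0:
        raise FitError("cannot fit an exponential to a constant trace")
    p0 = _init_exp(t, y)
    try:
        popt, pcov = curve_fit(
            _exp_model, t, y, p0=p0,
            bounds=([-np.inf, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"exponential fit did not converge (init A={p0[0]:.4g}, "
            f"k={p0[1]:.4g}, C={p0[2]:.4g}; bounds k in (0, inf)): {exc}"
        ) from exc
    A, k, C = (float(v) for v in popt)
    se = np.sqrt(np.diag(pcov))
    resid = y - _exp_model(t, *popt)
    short = (t[-1] - t[0]) < 3.0 / k
    if short:
        warnings.warn(
            f"trace covers only {(t[-1] - t[0]) * k:.2f}/3 relaxation times; "
            "k_obs may be poorly constrained",
            stacklevel=2,
        )
    return ExpFit(A, k, C, float(se[0]), float(se[1]), float(se[2]),
                  float(np.linalg.norm(resid)), short_window=short)


def _burst_model(t, A, k, kss, C):
    return A * np.exp(-k * t) + kss * t + C


def fit_burst(trace: Trace) -> BurstFit:
    """Least squares of the exponential-plus-line burst form.

    For turbidity traces the decaying burst-phase rate ``k_obs`` is the
    track-dissociation rate; ``k_ss`` captures the steady-state linear drift.
    """
    t, y = trace.t, trace.y
    if len(t) < 10:
        raise InvalidInputError(f"trace too short to fit ({len(t)} points, need >= 10)")
    # tail line estimate over the last 30%
    ntail = max(int(0.3 * len(t)), 2)
    kss0, c_tail = np.polyfit(t[-ntail:], y[-ntail:], 1)
    resid0 = y - (kss0 * t + c_tail)
    A0, k0, C_extra = _init_exp(t, resid0)
    p0 = (A0, k0, float(kss0), float(c_tail + C_extra))
    try:
        popt, pcov = curve_fit(
            _burst_model, t, y, p0=p0,
            bounds=([-np.inf, 1e-12, -np.inf, -np.inf], np.inf),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"burst fit did not converge (init {p0}): {exc}"
        ) from exc
    A, k, kss, C = (float(v) for v in popt)
    se = np.sqrt(np.diag(pcov))
    resid = y - _burst_model(t, *popt)
    return BurstFit(A, k, kss, C, float(se[0]), float(se[1]), float(se[2]),
                    float(se[3]), float(np.linalg.norm(resid)))


def fit_kobs_linear(series: KobsSeries) -> LineFit:
    """Weighted least-squares line through (conc, k_obs) points.

    Weights are inverse-variance from the per-point SEs when all are
    available and positive, unweighted otherwise.  Slope is the on-rate in
    uM^-1 s^-1, intercept the off-rate in s^-1 (negative values are
    reported as-is with their SE).
    """
    if len(series.conc) < 3:
        raise InvalidInputError(
            f"need >= 3 concentrations for a line fit, got {len(series.conc)}"
        )
    x, y = series.conc, series.k_obs
    use_weights = (
        series.se is not None
        and np.all(np.isfinite(series.se))
        and np.all(series.se > 0)
    )
    if use_weights:
        w = 1.0 / series.se
        coef, cov = np.polyfit(x, y, 1, w=w, cov="unscaled")
    else:
        coef, cov = np.polyfit(x, y, 1, cov=True)
    se = np.sqrt(np.diag(cov))
    return LineFit(
        k_plus1=float(coef[0]),
        k_minus1=float(coef[1]),
        se_k_plus1=float(se[0]),
        se_k_minus1=float(se[1]),
        weighted=bool(use_weights),
    )
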