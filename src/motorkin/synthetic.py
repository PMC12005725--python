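"""Synthetic data generators with known ground truth.

Every generator draws from the same three-step scheme — second-order
nucleotide binding (``k_plus1 * [S]``), reversible nucleotide release
(``k_minus1``), and irreversible track detachment (``k2``) — so that each
analysis stage of the package can be validated by parameter recovery.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream per
call; identical parameters and seed give bit-identical output.  Continuous
event times are snapped to frame boundaries by flooring the start and
ceiling the end, which reproduces the short-dwell censoring of real
camera-limited recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .fret import FRETTrace
from .segmentation import (
    BOUND,
    UNBOUND,
    Dwell,
    StateSegmentation,
    Trajectory2D,
)
from .stoppedflow import Trace

__all__ = [
    "SchemeParams",
    "TwoStateTrajParams",
    "FretSimParams",
    "MMDwellSimParams",
    "FretEvent",
    "simulate_two_state_trajectory",
    "simulate_stopped_flow_transient",
    "three_state_occupancy",
    "simulate_fret_trace",
    "simulate_bound_dwells_mm",
    "simulate_gfp_dwells",
]


@dataclass(frozen=True)
class SchemeParams:
    """Rates of the three-step binding/detachment scheme."""

    k_plus1: float       # uM^-1 s^-1
    k_minus1: float      # s^-1
    k2: float            # s^-1
    ligand_conc: float   # uM

    def __post_init__(self) -> None:
        for name in ("k_plus1", "k_minus1", "k2", "ligand_conc"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @property
    def kd(self) -> float:
        if self.k_plus1 == 0:
            return math.inf
        return self.k_minus1 / self.k_plus1


@dataclass(frozen=True)
class TwoStateTrajParams:
    """Parameters of the alternating bound/unbound probe-trajectory model.

    ``mean_bound_dwell`` may be ``inf`` to emulate an absorbing bound
    state (rate 0: no transitions ever).  The detection contrast the
    segmentation relies on requires ``noise_unbound > noise_bound``.
    """

    frame_rate: float                # Hz
    mean_bound_dwell: float          # s (may be inf)
    mean_unbound_dwell: float        # s
    n_frames: int
    noise_bound: float = 4.0         # nm per axis
    noise_unbound: float = 12.0      # nm per axis
    unbound_on_axis_offset: float = -8.0  # nm; negative = toward minus end
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InvalidParameterError("frame_rate must be > 0")
        if not (self.mean_bound_dwell > 0) or not (self.mean_unbound_dwell > 0):
            raise InvalidParameterError("dwell means must be > 0")
        if self.noise_bound < 0 or self.noise_unbound < 0:
            raise InvalidParameterError("noise amplitudes must be >= 0")
        if self.noise_unbound < self.noise_bound:
            raise InvalidParameterError(
                "noise_unbound must be >= noise_bound (detection contrast)"
            )
        if self.n_frames < 2:
            raise InvalidParameterError("n_frames must be >= 2")


@dataclass(frozen=True)
class FretSimParams:
    scheme: SchemeParams
    frame_interval: float        # s
    duration: float              # s
    donor_mean: float = 1000.0   # a.u.
    acceptor_mean: float = 1000.0
    intensity_sd: float = 50.0
    fret_bound: float = 0.9
    fret_unbound: float = 0.05
    donor_bleach_rate: float = 0.0    # s^-1
    acceptor_bleach_rate: float = 0.0  # s^-1 (per binding event)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise InvalidParameterError("frame_interval must be > 0")
        if not (0 <= self.fret_unbound < self.fret_bound <= 1):
            raise InvalidParameterError(
                "require 0 <= fret_unbound < fret_bound <= 1"
            )
        if self.donor_bleach_rate < 0 or self.acceptor_bleach_rate < 0:
            raise InvalidParameterError("bleach rates must be >= 0")
        if self.duration <= 0:
            raise InvalidParameterError("duration must be > 0")


@dataclass(frozen=True)
class MMDwellSimParams:
    kcat: float                  # s^-1
    km: float                    # uM
    atp_concs: tuple             # uM
    n_per_conc: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise InvalidParameterError("kcat must be > 0")
        if self.km <= 0:
            raise InvalidParameterError("Km must be > 0")
        if len(self.atp_concs) == 0:
            raise InvalidParameterError("atp_concs must not be empty")
        if self.n_per_conc < 1:
            raise InvalidParameterError("n_per_conc must be >= 1")


@dataclass(frozen=True)
class FretEvent:
    """Ground-truth binding event of the FRET simulator."""

    start_s: float
    end_s: float
    end_type: str  # "dissociation" | "detachment" | "donor_bleach" | "censored"
    acceptor_bleached: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# gold-probe trajectory


def simulate_two_state_trajectory(
    params: TwoStateTrajParams,
) -> tuple[Trajectory2D, StateSegmentation]:
    """Alternating exponential bound/unbound dwells with per-state noise.

    Returns the trajectory and a ground-truth segmentation whose
    ``source_events`` hold the continuous (pre-discretization) dwell
    draws, ``[(state, duration_s), ...]``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    dt = 1.0 / params.frame_rate
    total_t = n * dt

    states: list[str] = []
    durs: list[float] = []
    t = 0.0
    state = "bound"
    while t < total_t:
        mean = (params.mean_bound_dwell if state == "bound"
                else params.mean_unbound_dwell)
        d = math.inf if math.isinf(mean) else float(rng.exponential(mean))
        states.append(state)
        durs.append(d)
        t += d
        state = "unbound" if state == "bound" else "bound"

    boundaries = np.cumsum(durs)
    frame_times = np.arange(n) * dt
    seg_idx = np.searchsorted(boundaries, frame_times, side="right")
    is_bound = (seg_idx % 2) == 0  # even segments are bound (starts bound)

    on = np.where(is_bound, 0.0, params.unbound_on_axis_offset)
    off = np.zeros(n)
    noise = np.where(is_bound, params.noise_bound, params.noise_unbound)
    on = on + rng.standard_normal(n) * noise
    off = off + rng.standard_normal(n) * noise

    labels = np.where(is_bound, BOUND, UNBOUND).astype(np.int8)
    traj = Trajectory2D.from_positions(on, off, params.frame_rate)

    dwells: list[Dwell] = []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        dwells.append(Dwell(
            state="bound" if labels[s] == BOUND else "unbound",
            start_frame=int(s), end_frame=int(e),
            duration_s=(e - s) * dt,
        ))
    if dwells:
        dwells[0].censored = True
        dwells[-1].censored = True
    transitions = []
    for prev, nxt in zip(dwells, dwells[1:]):
        direction = "bound_to_unbound" if prev.state == "bound" else "unbound_to_bound"
        transitions.append((nxt.start_frame, direction))

    truth = StateSegmentation(
        labels=labels,
        frame_rate=params.frame_rate,
        transitions=transitions,
        dwells=dwells,
        source_events=list(zip(states, durs)),
    )
    return traj, truth


# ---------------------------------------------------------------------------
# stopped-flow transient


def three_state_occupancy(scheme: SchemeParams, t_grid: np.ndarray) -> np.ndarray:
    """Occupancies [empty, bound, detached] of the linear three-state scheme.

    Solved exactly by eigendecomposition of the 2x2 generator acting on
    (empty, bound); the detached probability is the complement.
    """
    a = scheme.k_plus1 * scheme.ligand_conc
    b = scheme.k_minus1
    c = scheme.k2
    M = np.array([[-a, b], [a, -(b + c)]])
    vals, vecs = np.linalg.eig(M)
    coef = np.linalg.solve(vecs, np.array([1.0, 0.0]))
    t = np.asarray(t_grid, float)
    eb = (vecs @ (coef[:, None] * np.exp(np.outer(vals, t)))).real
    out = np.empty((len(t), 3))
    out[:, 0] = eb[0]
    out[:, 1] = eb[1]
    out[:, 2] = 1.0 - eb[0] - eb[1]
    return out


def simulate_stopped_flow_transient(
    scheme: SchemeParams,
    t_grid: np.ndarray,
    baseline: float = 0.0,
    amplitude: float = 1.0,
    binding_only: bool = False,
    observable: str = "bound",
    noise_sd: float = 0.0,
    seed: int | None = None,
    kind: str = "fluorescence",
) -> Trace:
    """Deterministic occupancy-proportional stopped-flow signal.

    ``binding_only`` forces k2 = 0, for which the bound fraction has the
    closed form ``[S]/([S]+Kd) * (1 - exp(-(k1[S]+k-1) t))``.  Otherwise
    the three-state scheme is solved exactly.  ``observable`` selects the
    bound fraction ("bound", fluorescence-like) or the attached fraction
    ("attached" = empty+bound, turbidity-like).  Optional Gaussian noise.
    """
    t = np.asarray(t_grid, float)
    if len(t) == 0:
        raise InvalidParameterError("t_grid must not be empty")
    if t[0] < 0 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
        raise InvalidParameterError("t_grid must be strictly increasing from 0")
    if observable not in ("bound", "attached"):
        raise InvalidParameterError(f"unknown observable {observable!r}")

    if binding_only:
        kobs = scheme.k_plus1 * scheme.ligand_conc + scheme.k_minus1
        if kobs == 0:
            bound = np.zeros_like(t)
        else:
            binf = scheme.k_plus1 * scheme.ligand_conc / kobs
            bound = binf * (1.0 - np.exp(-kobs * t))
        frac = bound if observable == "bound" else np.ones_like(t)
    else:
        occ = three_state_occupancy(scheme, t)
        frac = occ[:, 1] if observable == "bound" else occ[:, 0] + occ[:, 1]

    y = baseline + amplitude * frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.standard_normal(len(t)) * noise_sd
    return Trace(t, y, kind=kind, ligand_conc=scheme.ligand_conc)


# ---------------------------------------------------------------------------
# smFRET trace


def simulate_fret_trace(
    params: FretSimParams,
) -> tuple[FRETTrace, list[FretEvent]]:
    """Markov-jump FRET trace with competing exits and photobleaching.

    The molecule alternates empty <-> nucleotide-bound (rates
    ``k_plus1*[S]`` and ``k_minus1``) with a competing ``k2`` exit from
    the bound state that detaches it and drops both channels to
    background for the rest of the trace.  A global donor-bleach clock
    also drops both channels (the acceptor is excited via the donor); an
    acceptor-bleach clock runs per binding event (each nucleotide carries
    a fresh acceptor) and truncates only that event's high-FRET signal.
    Intensities are time-weighted frame averages plus Gaussian noise.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    r_on = p.scheme.k_plus1 * p.scheme.ligand_conc
    r_off = p.scheme.k_minus1
    r_det = p.scheme.k2

    t_donor_bleach = (math.inf if p.donor_bleach_rate == 0
                      else float(rng.exponential(1.0 / p.donor_bleach_rate)))

    # piecewise-constant efficiency segments while signal is alive
    segments: list[tuple[float, float, float]] = []  # (t0, t1, efficiency)
    events: list[FretEvent] = []
    t = 0.0
    alive_until = min(p.duration, t_donor_bleach)
    detach_time = math.inf
    while t < p.duration:
        # empty (unbound nucleotide pocket)
        w = math.inf if r_on == 0 else float(rng.exponential(1.0 / r_on))
        t0, t = t, t + w
        segments.append((t0, min(t, p.duration), p.fret_unbound))
        if t >= p.duration or t >= t_donor_bleach:
            break
        # bound: competing exits
        w_off = math.inf if r_off == 0 else float(rng.exponential(1.0 / r_off))
        w_det = math.inf if r_det == 0 else float(rng.exponential(1.0 / r_det))
        w = min(w_off, w_det)
        start = t
        end = t + w
        t_acc = (math.inf if p.acceptor_bleach_rate == 0
                 else float(rng.exponential(1.0 / p.acceptor_bleach_rate)))
        acc_bleached = t_acc < w
        if end > p.duration or not math.isfinite(end):
            end_clip = p.duration
            end_type = "censored"
        elif w_det <= w_off:
            end_clip = end
            end_type = "detachment"
            detach_time = end
        else:
            end_clip = end
            end_type = "dissociation"
        if start < t_donor_bleach <= end_clip:
            end_type = "donor_bleach"
            end_clip = min(end_clip, t_donor_bleach)
        hi_end = min(start + t_acc, end_clip)
        segments.append((start, hi_end, p.fret_bound))
        if acc_bleached and hi_end < end_clip:
            segments.append((hi_end, end_clip, p.fret_unbound))
        events.append(FretEvent(start, end_clip, end_type,
                                acceptor_bleached=acc_bleached))
        t = end
        if end_type in ("detachment", "donor_bleach", "censored"):
            break
        if t >= t_donor_bleach:
            break
    alive_until = min(alive_until, detach_time)

    n_frames = max(1, int(round(p.duration / p.frame_interval)))
    dt = p.frame_interval
    donor = np.zeros(n_frames)
    acceptor = np.zeros(n_frames)
    for t0, t1, eff in segments:
        t1 = min(t1, alive_until)
        if t1 <= t0:
            continue
        i0 = int(t0 / dt)
        i1 = min(int(math.ceil(t1 / dt)), n_frames)
        idx = np.arange(i0, i1)
        lo = np.maximum(idx * dt, t0)
        hi = np.minimum((idx + 1) * dt, t1)
        wfrac = np.clip(hi - lo, 0.0, None) / dt
        donor[idx] += wfrac * p.donor_mean * (1.0 - eff)
        acceptor[idx] += wfrac * p.acceptor_mean * eff

    if p.intensity_sd > 0:
        donor = donor + rng.standard_normal(n_frames) * p.intensity_sd
        acceptor = acceptor + rng.standard_normal(n_frames) * p.intensity_sd

    trace = FRETTrace(
        t=np.arange(n_frames) * dt,
        donor=donor,
        acceptor=acceptor,
        frame_interval=dt,
    )
    return trace, events


# ---------------------------------------------------------------------------
# dwell samplers


def simulate_bound_dwells_mm(params: MMDwellSimParams) -> pd.DataFrame:
    """Two-step bound dwells whose inverse mean follows Michaelis-Menten.

    Each dwell is an exponential wait at rate ``(kcat/Km)*[ATP]`` (binding)
    plus one at rate ``kcat`` (catalysis/exit), so the population mean is
    ``Km/(kcat*[ATP]) + 1/kcat`` exactly.
    """
    rng = np.random.default_rng(params.seed)
    frames = []
    for conc in params.atp_concs:
        if conc <= 0:
            raise InvalidParameterError("ATP concentrations must be > 0")
        r_bind = (params.kcat / params.km) * conc
        d = (rng.exponential(1.0 / r_bind, params.n_per_conc)
             + rng.exponential(1.0 / params.kcat, params.n_per_conc))
        frames.append(pd.DataFrame({"atp_uM": conc, "dwell_s": d}))
    return pd.concat(frames, ignore_index=True)


def simulate_gfp_dwells(
    rate: float,
    frame_interval: float,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Exponential dwells discretized by ceiling to the frame grid.

    The ``dwelled more than two frames`` inclusion rule is applied
    downstream (pass ``min_dwell = 2*frame_interval`` to the fitters).
    """
    if rate <= 0:
        raise InvalidParameterError(f"rate must be > 0, got {rate}")
    if frame_interval <= 0:
        raise InvalidParameterError("frame_interval must be > 0")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.exponential(1.0 / rate, n)
    return np.ceil(x / frame_interval) * frame_interval
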