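"""Two-state segmentation of high-speed probe trajectories.

A gold-probe centroid trajectory (on-axis / off-axis positions at a fixed
frame rate) is classified frame-by-frame into microtubule-*bound* and
*unbound* states from the rolling two-dimensional standard deviation of the
position: the unbound head fluctuates more, so windows whose s.d. exceeds a
noise-floor threshold ``mu + k*sigma`` for a persistent run of frames mark
an unbound excursion.  Transition frames are then refined with a two-level
step fit to the raw positions, short flanked excursions can be merged into
composite unbound events, and dwell times are extracted per state with
boundary censoring.

Conventions: frames are 0-based, dwell intervals are half-open
``[start_frame, end_frame)``, durations are seconds, positions nanometres.
The rolling s.d. uses the sample (n-1) variance and is defined as
``sqrt(var(on) + var(off))`` so that it is rotation invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import InvalidInputError, InvalidParameterError, FitError

__all__ = [
    "BOUND",
    "UNBOUND",
    "EDGE_UNDEFINED",
    "LABEL_NAMES",
    "Trajectory2D",
    "SegmentationParams",
    "NoiseFloor",
    "Dwell",
    "StateSegmentation",
    "compute_rolling_sd",
    "fit_noise_floor",
    "detect_transitions",
    "refine_transition_stepfit",
    "apply_g0_merge_rule",
    "extract_dwells",
    "classify_detachment_origin",
    "median_filter_trace",
    "segment_trajectory",
]

# Integer label codes used in StateSegmentation.labels.
BOUND = 0
UNBOUND = 1
EDGE_UNDEFINED = -1
LABEL_NAMES = {BOUND: "bound", UNBOUND: "unbound", EDGE_UNDEFINED: "edge_undefined"}

_T_ATOL = 1e-9  # s; allowed |t - frame/frame_rate|


@dataclass
class Trajectory2D:
    """A 2D centroid trajectory of a single labeled head.

    Attributes
    ----------
    frame : ndarray of int
        Consecutive 0-based frame indices.
    t : ndarray of float
        Time in seconds; must equal ``frame / frame_rate`` to 1e-9 s.
    on_axis, off_axis : ndarray of float
        Position (nm) parallel / perpendicular to the filament long axis;
        positive on-axis is the plus-end direction.
    frame_rate : float
        Frames per second.
    """

    frame: np.ndarray
    t: np.ndarray
    on_axis: np.ndarray
    off_axis: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.on_axis = np.asarray(self.on_axis, dtype=float)
        self.off_axis = np.asarray(self.off_axis, dtype=float)
        n = len(self.frame)
        if not (len(self.t) == len(self.on_axis) == len(self.off_axis) == n):
            raise InvalidInputError("trajectory columns have unequal lengths")
        if self.frame_rate <= 0:
            raise InvalidParameterError(f"frame_rate must be > 0, got {self.frame_rate}")
        if n > 1 and not np.all(np.diff(self.frame) == 1):
            raise InvalidInputError("frame indices must be consecutive")
        if not np.all(np.isfinite(self.on_axis)) or not np.all(np.isfinite(self.off_axis)):
            raise InvalidInputError("non-finite coordinates in trajectory")
        expected = self.frame / self.frame_rate
        if n and np.max(np.abs(self.t - expected)) > _T_ATOL:
            bad = int(np.argmax(np.abs(self.t - expected) > _T_ATOL))
            raise InvalidInputError(
                f"t inconsistent with frame/frame_rate at row {bad} "
                f"(t={self.t[bad]!r}, expected {expected[bad]!r})"
            )

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_positions(cls, on_axis, off_axis, frame_rate: float) -> "Trajectory2D":
        frame = np.arange(len(on_axis), dtype=np.int64)
        return cls(frame, frame / frame_rate, np.asarray(on_axis, float),
                   np.asarray(off_axis, float), frame_rate)


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning parameters of the segmentation pipeline (defaults as used
    for 20 kHz gold-probe recordings)."""

    half_window: int = 20           # rolling s.d. window is [t-hw, t+hw]
    persistence: int = 10           # consecutive frames to commit a transition
    threshold_multiplier: float = 4.0
    median_window: int = 51         # display median filter
    merge_gap: float = 0.050        # s; flanked-excursion merge rule
    sd_hist_bin: float | None = None  # nm; None = Freedman-Diaconis
    step_halfwidth: int = 40        # frames; step-fit search half width
    merge_min_separation: float = 4.0  # nm; floor of the merge displacement criterion
    origin_criterion: float = 4.0   # nm; leading/trailing displacement criterion

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise InvalidParameterError("half_window must be >= 1")
        if self.persistence < 1:
            raise InvalidParameterError("persistence must be >= 1")
        if self.threshold_multiplier <= 0:
            raise InvalidParameterError("threshold_multiplier must be > 0")
        if self.median_window % 2 == 0:
            raise InvalidParameterError("median_window must be odd")


@dataclass(frozen=True)
class NoiseFloor:
    """Bound-state rolling-s.d. distribution and the derived threshold."""

    mu: float          # nm, center of the primary (bound) mode
    sigma: float       # nm, its spread
    threshold: float   # nm, mu + multiplier * sigma
    multiplier: float = 4.0
    degenerate: bool = False


@dataclass
class Dwell:
    state: str                 # "bound" | "unbound"
    start_frame: int
    end_frame: int             # half-open
    duration_s: float
    censored: bool = False
    mean_on: float = float("nan")
    mean_off: float = float("nan")
    origin: str | None = None  # "leading" | "trailing" | "ambiguous" | None


@dataclass
class StateSegmentation:
    """Per-frame labels plus derived transitions and dwells."""

    labels: np.ndarray                       # int8 codes, see LABEL_NAMES
    frame_rate: float
    transitions: list[tuple[int, str]] = field(default_factory=list)
    dwells: list[Dwell] = field(default_factory=list)
    merged_groups: list[tuple[int, int, int]] = field(default_factory=list)
    noise_floor: NoiseFloor | None = None
    params: SegmentationParams | None = None
    source_events: list[tuple[str, float]] | None = None  # simulator ground truth

    def label_names(self) -> np.ndarray:
        return np.array([LABEL_NAMES[int(c)] for c in self.labels])

    def validate(self) -> None:
        """Check the structural invariants (dwell tiling, alternation)."""
        prev_end = None
        prev_state = None
        for d in self.dwells:
            if prev_end is not None and d.start_frame != prev_end:
                raise InvalidInputError("dwells do not tile the labeled region")
            if prev_state is not None and d.state == prev_state:
                raise InvalidInputError("adjacent dwells share a state")
            if abs(d.duration_s - (d.end_frame - d.start_frame) / self.frame_rate) > 1e-12:
                raise InvalidInputError("dwell duration inconsistent with frames")
            prev_end, prev_state = d.end_frame, d.state
        dirs = [direction for _, direction in self.transitions]
        for a, b in zip(dirs, dirs[1:]):
            if a == b:
                raise InvalidInputError("transitions do not alternate")


# ---------------------------------------------------------------------------
# rolling statistics


def compute_rolling_sd(traj: Trajectory2D, half_window: int = 20) -> np.ndarray:
    """Rolling 2D standard deviation, ``sqrt(var(on) + var(off))``.

    For each frame ``t`` the sample variance of both axes is taken over the
    window ``[t - half_window, t + half_window]``.  The first and last
    ``half_window`` frames are NaN (undefined).
    """
    if half_window < 1:
        raise InvalidParameterError("half_window must be >= 1")
    w = 2 * half_window + 1
    n = len(traj)
    if n < w:
        raise InvalidInputError(
            f"trajectory too short for rolling s.d.: {n} frames < window {w}"
        )

    def _rolling_var(x: np.ndarray) -> np.ndarray:
        # center first so the cumulative sums stay well conditioned
        xc = x - x.mean()
        c1 = np.concatenate(([0.0], np.cumsum(xc)))
        c2 = np.concatenate(([0.0], np.cumsum(xc * xc)))
        s1 = c1[w:] - c1[:-w]
        s2 = c2[w:] - c2[:-w]
        return np.maximum(s2 - s1 * s1 / w, 0.0) / (w - 1)

    sd = np.full(n, np.nan)
    sd[half_window:n - half_window] = np.sqrt(
        _rolling_var(traj.on_axis) + _rolling_var(traj.off_axis)
    )
    return sd


# ---------------------------------------------------------------------------
# noise floor


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_noise_floor(
    sd_series: np.ndarray,
    params: SegmentationParams | None = None,
) -> NoiseFloor:
    """Fit a Gaussian to the primary (lowest) mode of the s.d. histogram.

    The fit window runs from the left edge to the first clear local minimum
    after the primary mode (a smoothed bin count below 25% of the peak),
    which keeps the unbound-state tail from dragging the fit; if no such
    minimum exists the whole histogram is used.
    """
    params = params or SegmentationParams()
    vals = np.asarray(sd_series, float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 1000:
        raise InvalidInputError(
            f"need >= 1000 defined s.d. values to fit the noise floor, got {len(vals)}"
        )
    k = params.threshold_multiplier
    if np.ptp(vals) == 0:
        v = float(vals[0])
        warnings.warn("degenerate s.d. histogram (all values identical)", stacklevel=2)
        return NoiseFloor(mu=v, sigma=0.0, threshold=v, multiplier=k, degenerate=True)

    if params.sd_hist_bin is not None:
        bw = params.sd_hist_bin
    else:
        iqr = np.subtract(*np.percentile(vals, [75, 25]))
        bw = 2 * iqr / len(vals) ** (1 / 3) if iqr > 0 else np.ptp(vals) / 100
    nbins = max(10, int(np.ceil(np.ptp(vals) / bw)))
    counts, edges = np.histogram(vals, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    smooth = np.convolve(counts, np.ones(3) / 3, mode="same")
    mode = int(np.argmax(smooth))
    end = len(counts)
    for i in range(mode + 1, len(smooth) - 1):
        if (smooth[i] <= smooth[i - 1] and smooth[i] <= smooth[i + 1]
                and smooth[i] < 0.25 * smooth[mode]):
            end = i + 1
            break

    x, y = centers[:end], counts[:end].astype(float)
    sigma0 = max(np.sqrt(np.average((x - centers[mode]) ** 2, weights=y + 1e-12)),
                 0.5 * (edges[1] - edges[0]))
    try:
        popt, _ = curve_fit(
            _gauss, x, y, p0=(float(counts[mode]), float(centers[mode]), sigma0),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            f"noise-floor Gaussian fit failed on histogram range "
            f"[{edges[0]:.3g}, {edges[-1]:.3g}] nm: {exc}"
        ) from exc
    mu, sigma = float(popt[1]), abs(float(popt[2]))
    return NoiseFloor(mu=mu, sigma=sigma, threshold=mu + k * sigma, multiplier=k)


# ---------------------------------------------------------------------------
# transition detection


def detect_transitions(
    sd_series: np.ndarray,
    floor: NoiseFloor,
    persistence: int = 10,
) -> tuple[str, list[tuple[int, str]]]:
    """Hysteresis state machine on the rolling s.d. series.

    A bound-to-unbound transition is placed at the first frame of a run of
    ``persistence`` consecutive frames above ``floor.threshold``; the
    reverse at the first frame of an equally long run below it.  Returns
    ``(initial_state, transitions)`` where each transition is
    ``(frame, "bound_to_unbound" | "unbound_to_bound")``.
    """
    if persistence < 1:
        raise InvalidParameterError("persistence must be >= 1")
    sd = np.asarray(sd_series, float)
    defined = np.flatnonzero(np.isfinite(sd))
    if len(defined) == 0:
        return "bound", []
    lo, hi = int(defined[0]), int(defined[-1]) + 1
    above = sd[lo:hi] > floor.threshold

    state = UNBOUND if above[0] else BOUND
    initial_state = LABEL_NAMES[state]
    transitions: list[tuple[int, str]] = []

    # run-length encode `above`
    change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(above)]))
    for s, e in zip(starts, ends):
        run_above = bool(above[s])
        if e - s < persistence:
            continue
        if state == BOUND and run_above:
            transitions.append((lo + int(s), "bound_to_unbound"))
            state = UNBOUND
        elif state == UNBOUND and not run_above:
            transitions.append((lo + int(s), "unbound_to_bound"))
            state = BOUND
    return initial_state, transitions


def refine_transition_stepfit(
    traj: Trajectory2D,
    approx_frame: int,
    search_halfwidth: int = 40,
) -> int:
    """Refine a transition frame with a two-level step fit.

    Over ``[approx - hw, approx + hw]`` every candidate split is scored by
    the total residual sum of squares of a piecewise-constant (one level
    left, one level right) model fitted jointly to the on- and off-axis
    positions; the minimizing split frame (first frame of the new level) is
    returned, ties broken toward ``approx_frame``.
    """
    n = len(traj)
    lo = approx_frame - search_halfwidth
    hi = approx_frame + search_halfwidth + 1
    if lo < 0 or hi > n:
        warnings.warn(
            f"step-fit window [{lo}, {hi}) clipped to trajectory bounds [0, {n})",
            stacklevel=2,
        )
        lo, hi = max(lo, 0), min(hi, n)
    if hi - lo < 2:
        return int(np.clip(approx_frame, 0, n - 1))

    splits = np.arange(lo + 1, hi)
    rss = np.zeros(len(splits))
    for x in (traj.on_axis[lo:hi], traj.off_axis[lo:hi]):
        c1 = np.concatenate(([0.0], np.cumsum(x - x.mean())))
        c2 = np.concatenate(([0.0], np.cumsum((x - x.mean()) ** 2)))
        m = len(x)
        k = splits - lo  # left segment length
        sl, s2l = c1[k], c2[k]
        sr, s2r = c1[m] - c1[k], c2[m] - c2[k]
        rss += (s2l - sl * sl / k) + (s2r - sr * sr / (m - k))
    # tie-break toward approx_frame among RSS minima (within float noise)
    tol = 1e-9 * max(1.0, float(np.max(rss)))
    candidates = splits[rss <= np.min(rss) + tol]
    best = int(candidates[np.argmin(np.abs(candidates - approx_frame))])
    return best


# ---------------------------------------------------------------------------
# segmentation assembly


def _dwells_from_labels(
    labels: np.ndarray, traj: Trajectory2D | None, frame_rate: float
) -> list[Dwell]:
    dwells: list[Dwell] = []
    idx = np.flatnonzero(labels != EDGE_UNDEFINED)
    if len(idx) == 0:
        return dwells
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    seg = labels[lo:hi]
    change = np.flatnonzero(np.diff(seg)) + 1
    starts = np.concatenate(([0], change)) + lo
    ends = np.concatenate((change, [hi - lo])) + lo
    for s, e in zip(starts, ends):
        state = LABEL_NAMES[int(labels[s])]
        d = Dwell(
            state=state,
            start_frame=int(s),
            end_frame=int(e),
            duration_s=(e - s) / frame_rate,
        )
        if traj is not None:
            d.mean_on = float(np.mean(traj.on_axis[s:e]))
            d.mean_off = float(np.mean(traj.off_axis[s:e]))
        dwells.append(d)
    if dwells:
        dwells[0].censored = True
        dwells[-1].censored = True
    return dwells


def _transitions_from_dwells(dwells: list[Dwell]) -> list[tuple[int, str]]:
    out = []
    for prev, nxt in zip(dwells, dwells[1:]):
        direction = ("bound_to_unbound" if prev.state == "bound" else "unbound_to_bound")
        out.append((nxt.start_frame, direction))
    return out


def extract_dwells(seg: StateSegmentation, frame_rate: float | None = None) -> pd.DataFrame:
    """Dwell table with durations in seconds and boundary-censor flags.

    The first and last dwells of the labeled region are flagged censored
    (truncated by the trace edges) and should be excluded from rate fits.
    """
    frame_rate = frame_rate or seg.frame_rate
    rows = [
        {
            "state": d.state,
            "start_frame": d.start_frame,
            "end_frame": d.end_frame,
            "duration_s": d.duration_s,
            "censored": d.censored,
            "origin_label": d.origin if d.origin is not None else "",
            "mean_on_nm": d.mean_on,
            "mean_off_nm": d.mean_off,
        }
        for d in seg.dwells
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "state", "start_frame", "end_frame", "duration_s", "censored",
            "origin_label", "mean_on_nm", "mean_off_nm",
        ],
    )


def apply_g0_merge_rule(
    seg: StateSegmentation,
    traj: Trajectory2D,
    merge_gap: float = 0.050,
    min_separation: float | None = None,
) -> StateSegmentation:
    """Merge short flanked excursion triplets into composite unbound events.

    If two unbound dwells are separated by less than ``merge_gap`` seconds
    and the intervening bound dwell's mean on-axis position is displaced
    from the flanking bound dwells by more than a separation criterion,
    the unbound-bound-unbound triplet is relabeled as a single unbound
    event.  The criterion is ``max(min_separation, 2 * sd_est/sqrt(m))``
    where ``sd_est`` is the per-axis bound noise inferred from the noise
    floor and ``m`` the intervening dwell's frame count.
    """
    if min_separation is None:
        min_separation = (seg.params.merge_min_separation if seg.params is not None
                          else 4.0)
    labels = seg.labels.copy()
    merged_groups = list(seg.merged_groups)
    changed = True
    while changed:
        changed = False
        dwells = _dwells_from_labels(labels, traj, seg.frame_rate)
        for i in range(len(dwells) - 2):
            u1, b, u2 = dwells[i], dwells[i + 1], dwells[i + 2]
            if not (u1.state == "unbound" and b.state == "bound" and u2.state == "unbound"):
                continue
            if b.duration_s >= merge_gap:
                continue
            flank_means = []
            if i - 1 >= 0 and dwells[i - 1].state == "bound":
                flank_means.append(dwells[i - 1].mean_on)
            if i + 3 < len(dwells) and dwells[i + 3].state == "bound":
                flank_means.append(dwells[i + 3].mean_on)
            if not flank_means:
                continue
            crit = min_separation
            if seg.noise_floor is not None and not seg.noise_floor.degenerate:
                per_axis = seg.noise_floor.mu / np.sqrt(2.0)
                m = b.end_frame - b.start_frame
                crit = max(min_separation, 2.0 * per_axis / np.sqrt(m))
            if abs(b.mean_on - float(np.mean(flank_means))) > crit:
                labels[u1.start_frame:u2.end_frame] = UNBOUND
                merged_groups.append((i, i + 1, i + 2))
                changed = True
                break

    dwells = _dwells_from_labels(labels, traj, seg.frame_rate)
    return StateSegmentation(
        labels=labels,
        frame_rate=seg.frame_rate,
        transitions=_transitions_from_dwells(dwells),
        dwells=dwells,
        merged_groups=merged_groups,
        noise_floor=seg.noise_floor,
        params=seg.params,
        source_events=seg.source_events,
    )


def classify_detachment_origin(
    traj: Trajectory2D,
    seg: StateSegmentation,
    displacement_criterion: float = 4.0,
) -> list[str | None]:
    """Label each unbound dwell as coming from the leading or trailing position.

    A detached head that sits *backward* (negative on-axis displacement
    relative to the preceding bound dwell, beyond the criterion) was leading
    before detachment; forward displacement marks a trailing head; anything
    in between is ambiguous.  The first dwell has no predecessor and stays
    unlabeled.  Labels are written onto ``seg.dwells`` and returned in dwell
    order (``None`` for bound dwells and the unlabeled first dwell).
    """
    out: list[str | None] = []
    prev_bound: Dwell | None = None
    for i, d in enumerate(seg.dwells):
        if d.state == "bound":
            prev_bound = d
            out.append(None)
            continue
        if prev_bound is None:
            d.origin = None
            out.append(None)
            continue
        delta = d.mean_on - prev_bound.mean_on
        if delta < -displacement_criterion:
            d.origin = "leading"
        elif delta > displacement_criterion:
            d.origin = "trailing"
        else:
            d.origin = "ambiguous"
        out.append(d.origin)
    return out


def median_filter_trace(
    traj: Trajectory2D,
    seg: StateSegmentation | None = None,
    window: int = 51,
) -> Trajectory2D:
    """Per-axis running median for display, filtered per dwell segment.

    Each dwell segment is filtered independently (bound and unbound
    stretches do not bleed into each other); window shrinks at segment
    edges.  Without a segmentation the whole trace is one segment.
    """
    if window % 2 == 0:
        raise InvalidParameterError(f"median window must be odd, got {window}")

    def _med(x: np.ndarray) -> np.ndarray:
        return (
            pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
        )

    on = traj.on_axis.copy()
    off = traj.off_axis.copy()
    if seg is None or not seg.dwells:
        spans = [(0, len(traj))]
    else:
        spans = [(d.start_frame, d.end_frame) for d in seg.dwells]
    for s, e in spans:
        on[s:e] = _med(traj.on_axis[s:e])
        off[s:e] = _med(traj.off_axis[s:e])
    return Trajectory2D(traj.frame, traj.t, on, off, traj.frame_rate)


# ---------------------------------------------------------------------------
# full pipeline


def segment_trajectory(
    traj: Trajectory2D,
    params: SegmentationParams | None = None,
    merge: bool = True,
    classify_origin: bool = True,
) -> StateSegmentation:
    """Run the full segmentation pipeline on one trajectory.

    Steps: rolling s.d. -> noise-floor Gaussian fit -> hysteresis
    transition detection -> per-transition step-fit refinement -> (optional)
    flanked-excursion merge -> dwell extraction with boundary censoring ->
    (optional) leading/trailing classification.
    """
    params = params or SegmentationParams()
    sd = compute_rolling_sd(traj, params.half_window)
    floor = fit_noise_floor(sd, params)
    initial_state, provisional = detect_transitions(sd, floor, params.persistence)

    refined: list[int] = []
    for f, _direction in provisional:
        r = refine_transition_stepfit(traj, f, params.step_halfwidth)
        if refined and r <= refined[-1]:
            r = refined[-1] + 1
        refined.append(r)

    n = len(traj)
    labels = np.full(n, EDGE_UNDEFINED, dtype=np.int8)
    lo = params.half_window
    hi = n - params.half_window
    state = BOUND if initial_state == "bound" else UNBOUND
    pos = lo
    for r, (_f, _d) in zip(refined, provisional):
        r = int(np.clip(r, lo, hi))
        labels[pos:r] = state
        state = UNBOUND if state == BOUND else BOUND
        pos = max(r, pos)
    labels[pos:hi] = state

    dwells = _dwells_from_labels(labels, traj, traj.frame_rate)
    seg = StateSegmentation(
        labels=labels,
        frame_rate=traj.frame_rate,
        transitions=_transitions_from_dwells(dwells),
        dwells=dwells,
        noise_floor=floor,
        params=params,
    )
    if merge:
        seg = apply_g0_merge_rule(seg, traj, params.merge_gap)
    if classify_origin:
        classify_detachment_origin(traj, seg, params.origin_criterion)
    return seg
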