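"""smFRET trace analysis: efficiency, binding-dwell detection, end typing.

A two-channel (donor/acceptor) intensity trace is converted to a FRET
efficiency series using the background-subtracted proximity ratio
``E = A / (A + D)`` (no gamma or bleed-through correction; a gamma factor
can be supplied for completeness).  Nucleotide-binding events are maximal
runs of frames with ``E`` above a threshold (default 0.5), and each event
end is classified from the channel behaviour just after the event:

* donor recovers, acceptor gone  -> ``atp_dissociation`` (reversible release)
* both channels at background    -> ``detachment`` (head left the track)
* donor gone, acceptor persists  -> ``donor_bleach``
* anything else                  -> ``censored`` with a reason

Off-rates are the inverse mean of uncensored dwell durations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError

__all__ = [
    "FRETTrace",
    "BindingEvent",
    "DwellRate",
    "compute_fret_efficiency",
    "detect_binding_events",
    "classify_event_end",
    "rate_from_mean_dwell",
    "analyze_fret_trace",
]

END_TYPES = ("atp_dissociation", "detachment", "donor_bleach", "censored")


@dataclass
class FRETTrace:
    """Synchronized donor/acceptor intensity series."""

    t: np.ndarray
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    background_donor: float = 0.0
    background_acceptor: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.donor = np.asarray(self.donor, float)
        self.acceptor = np.asarray(self.acceptor, float)
        if not (len(self.t) == len(self.donor) == len(self.acceptor)):
            raise InvalidInputError("FRET trace channels have unequal lengths")
        if self.frame_interval <= 0:
            raise InvalidParameterError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class BindingEvent:
    start_frame: int
    end_frame: int  # half-open
    duration_s: float
    censored: bool = False
    end_type: str | None = None
    reason: str = ""


class DwellRate(NamedTuple):
    rate: float  # s^-1
    se: float
    n: int


def compute_fret_efficiency(
    trace: FRETTrace,
    min_total: float | None = None,
    gamma: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame proximity-ratio efficiency and a validity mask.

    ``E = (A - bgA) / ((A - bgA) + gamma * (D - bgD))`` clipped to [0, 1].
    Frames whose total corrected intensity falls below ``min_total`` are
    invalid (NaN).  The default floor is half the 99.5th percentile of the
    corrected total, which tracks the fluorophore-on level even when most
    of the trace is post-detachment/post-bleach background.
    """
    d = trace.donor - trace.background_donor
    a = trace.acceptor - trace.background_acceptor
    total = a + gamma * d
    if min_total is None:
        hi = float(np.percentile(total, 99.5))
        min_total = 0.5 * hi if hi > 0 else np.inf
    valid = total >= max(min_total, 1e-300)
    if not valid.any():
        warnings.warn("no valid frames: total corrected intensity at/below floor",
                      stacklevel=2)
    E = np.full(len(trace), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        E[valid] = np.clip(a[valid] / total[valid], 0.0, 1.0)
    return E, valid


def detect_binding_events(
    E_series: np.ndarray,
    frame_interval: float,
    threshold: float = 0.5,
    min_frames: int = 2,
    valid: np.ndarray | None = None,
) -> list[BindingEvent]:
    """Maximal supra-threshold runs of length >= ``min_frames``.

    Runs touching either end of the trace are censored (their true duration
    is unknown).
    """
    E = np.asarray(E_series, float)
    if valid is None:
        valid = np.isfinite(E)
    mask = np.zeros(len(E), bool)
    mask[valid] = E[valid] > threshold
    if not mask.any():
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    edges = np.concatenate(([0], change, [len(E)]))
    events = []
    for s, e in zip(edges[:-1], edges[1:]):
        if not mask[s] or e - s < min_frames:
            continue
        ev = BindingEvent(
            start_frame=int(s),
            end_frame=int(e),
            duration_s=(e - s) * frame_interval,
        )
        if s == 0 or e == len(E):
            ev.censored = True
            ev.end_type = "censored"
            ev.reason = "run touches trace boundary"
        events.append(ev)
    return events


def classify_event_end(
    trace: FRETTrace,
    event: BindingEvent,
    window: int = 10,
    recovery_fraction: float = 0.5,
    limit_frame: int | None = None,
) -> str:
    """Classify how a binding event ended from the post-event channels.

    Channel means over the ``window`` frames after the event (clipped to
    ``limit_frame``, e.g. the start of the next event) are compared against
    ``recovery_fraction`` of the event's mean total intensity.
    Precedence: donor up & acceptor down -> ``atp_dissociation``; donor
    down & acceptor up -> ``donor_bleach``; both down -> ``detachment``;
    both up -> ``censored`` ("ambiguous", efficiency dropped with both
    dyes alive).  The result is written onto ``event.end_type``.
    """
    if event.censored:
        raise InvalidInputError("cannot classify a censored event end")
    s, e = event.start_frame, event.end_frame
    stop = min(e + window, len(trace))
    if limit_frame is not None:
        stop = min(stop, limit_frame)
    if stop <= e:
        event.end_type = "censored"
        event.reason = "no post-event frames before the next event"
        return event.end_type
    d = trace.donor - trace.background_donor
    a = trace.acceptor - trace.background_acceptor
    ref = float(np.mean(d[s:e] + a[s:e]))
    hi = recovery_fraction * ref
    w = slice(e, stop)
    mean_d = float(np.mean(d[w]))
    mean_a = float(np.mean(a[w]))
    if mean_d > hi and mean_a <= hi:
        event.end_type = "atp_dissociation"
    elif mean_d <= hi and mean_a > hi:
        event.end_type = "donor_bleach"
    elif mean_d <= hi and mean_a <= hi:
        event.end_type = "detachment"
    else:
        event.end_type = "censored"
        event.reason = "ambiguous: both channels above recovery level"
    return event.end_type


def rate_from_mean_dwell(
    durations: np.ndarray,
    censored: np.ndarray | None = None,
) -> DwellRate:
    """Rate = 1 / mean(uncensored dwells); SE = rate / sqrt(n)."""
    d = np.asarray(durations, float)
    if censored is not None:
        d = d[~np.asarray(censored, bool)]
    if len(d) == 0:
        raise InsufficientDataError("no uncensored dwells to estimate a rate from")
    mean = float(np.mean(d))
    if mean <= 0:
        raise InvalidInputError("mean dwell must be positive")
    rate = 1.0 / mean
    return DwellRate(rate=rate, se=rate / np.sqrt(len(d)), n=len(d))


def analyze_fret_trace(
    trace: FRETTrace,
    threshold: float = 0.5,
    min_frames: int = 2,
    window: int = 10,
    min_total: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full per-trace analysis: events table plus a summary dict.

    The summary flags the rate as a lower bound when the frame interval is
    short enough (<= 10 ms) that brief dwells are lost to time resolution.
    """
    E, valid = compute_fret_efficiency(trace, min_total=min_total)
    events = detect_binding_events(E, trace.frame_interval, threshold, min_frames, valid)
    for i, ev in enumerate(events):
        if not ev.censored:
            nxt = events[i + 1].start_frame if i + 1 < len(events) else None
            classify_event_end(trace, ev, window=window, limit_frame=nxt)
    rows = [
        {
            "start_s": ev.start_frame * trace.frame_interval,
            "duration_s": ev.duration_s,
            "end_type": ev.end_type or "",
            "censored": ev.censored,
        }
        for ev in events
    ]
    df = pd.DataFrame(rows, columns=["start_s", "duration_s", "end_type", "censored"])
    summary: dict = {
        "n_events": len(events),
        "n_by_end_type": {
            k: int(sum(1 for ev in events if ev.end_type == k)) for k in END_TYPES
        },
    }
    usable = df[~df["censored"]]
    if len(usable):
        r = rate_from_mean_dwell(usable["duration_s"].to_numpy())
        summary.update(
            mean_dwell_s=float(usable["duration_s"].mean()),
            rate_per_s=r.rate,
            rate_se=r.se,
            n_used=r.n,
            rate_is_lower_bound=bool(trace.frame_interval <= 0.010),
        )
    return df, summary
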