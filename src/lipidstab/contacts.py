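"""Per-residue and per-site lipid contact statistics.

Coarse-grained simulations of membrane proteins are commonly summarised by
two quantities per residue or binding site: *occupancy*, the fraction of
trajectory frames in which a lipid is in contact, and *residence time*, the
duration of an uninterrupted bound interval.  Long residence distinguishes
structural lipids at defined sites from annular boundary lipids.  This
module computes both from distance or binary contact series, using the
dual-cutoff convention to suppress boundary flicker: a contact begins when
the distance drops to ``r_on`` and persists until it exceeds ``r_off``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DistanceTrace",
    "ContactTrace",
    "SiteDefinition",
    "ResidenceEvent",
    "ContactStats",
    "dual_cutoff_contacts",
    "occupancy",
    "residence_events",
    "mean_residence",
    "contact_stats",
    "site_stats",
    "pool_replicates",
]

#: default dual-cutoff radii (nm), the usual coarse-grained convention
DEFAULT_R_ON = 0.475
DEFAULT_R_OFF = 0.8


@dataclass(frozen=True)
class DistanceTrace:
    """Lipid–residue minimum distance per frame, in nm."""

    residue_label: str
    dt: float
    distances: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        if self.dt <= 0:
            raise ValueError("frame spacing dt must be positive")
        if d.ndim != 1 or d.size == 0:
            raise ValueError("distances must be a non-empty 1-D series")
        if np.any(d < 0) or not np.all(np.isfinite(d)):
            raise ValueError("distances must be finite and non-negative")


@dataclass(frozen=True)
class ContactTrace:
    """Binary bound/unbound indicator per frame."""

    residue_label: str
    dt: float
    bound: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.bound)
        if b.ndim != 1 or b.size == 0:
            raise ValueError("bound must be a non-empty 1-D series")
        if not np.isin(b, (0, 1)).all():
            raise ValueError("bound series must contain only 0 and 1")
        object.__setattr__(self, "bound", b.astype(np.int8))
        if self.dt <= 0:
            raise ValueError("frame spacing dt must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.bound.size)


@dataclass(frozen=True)
class SiteDefinition:
    """A named binding site: the residues whose contacts it unions."""

    site_id: str
    residue_labels: tuple

    def __post_init__(self):
        labels = tuple(self.residue_labels)
        if not labels:
            raise ValueError("a site needs at least one residue label")
        if len(set(labels)) != len(labels):
            raise ValueError("site residue labels must be unique")
        object.__setattr__(self, "residue_labels", labels)


@dataclass(frozen=True)
class ResidenceEvent:
    """One maximal bound interval. Durations are in ns.

    Events touching either end of the trace are censored: their true
    duration is only bounded below by what was observed.
    """

    duration: float
    censored_left: bool = False
    censored_right: bool = False

    @property
    def censored(self) -> bool:
        return self.censored_left or self.censored_right


@dataclass(frozen=True)
class ContactStats:
    """Summary statistics for one residue or site.

    ``mean_residence`` is the arithmetic mean of uncensored event durations
    (NaN when there is none); ``k_off`` the rate from a single-exponential
    survival fit when determinable.
    """

    label: str
    occupancy: float
    n_events: int
    mean_residence: float
    n_frames: int
    dt: float
    events: tuple = field(default_factory=tuple)
    k_off: float | None = None

    def summary(self) -> str:
        res = f"{self.mean_residence:.3g} ns" if np.isfinite(self.mean_residence) else "undefined"
        koff = f"{self.k_off:.3g}/ns" if self.k_off is not None else "n/a"
        return (f"{self.label}: occupancy {100 * self.occupancy:.1f}%, "
                f"{self.n_events} events, mean residence {res}, k_off {koff}")


def dual_cutoff_contacts(trace: DistanceTrace,
                         r_on: float = DEFAULT_R_ON,
                         r_off: float = DEFAULT_R_OFF) -> ContactTrace:
    """Binarize a distance series with on/off hysteresis.

    The state becomes bound when distance <= ``r_on`` and stays bound until
    distance > ``r_off``.  With ``r_on == r_off`` this reduces to a single
    cutoff.  The initial state is bound iff the first distance <= ``r_on``.
    """
    if not 0 < r_on <= r_off:
        raise ValueError(f"need 0 < r_on <= r_off, got r_on={r_on}, r_off={r_off}")
    d = trace.distances
    # +1 where binding is (re)triggered, -1 where it must release; forward-fill
    code = np.zeros(d.size, dtype=np.int8)
    code[d <= r_on] = 1
    code[d > r_off] = -1
    idx = np.where(code != 0, np.arange(d.size), -1)
    last = np.maximum.accumulate(idx)
    bound = np.where(last >= 0, code[np.maximum(last, 0)] == 1, False)
    return ContactTrace(trace.residue_label, trace.dt, bound.astype(np.int8))


def occupancy(trace: ContactTrace) -> float:
    """Fraction of frames in the bound state."""
    return float(trace.bound.mean())


def _runs(bound: np.ndarray):
    """(start, stop) index pairs of maximal runs of ones; stop exclusive."""
    padded = np.concatenate(([0], bound, [0]))
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return starts, stops


def residence_events(trace: ContactTrace) -> list[ResidenceEvent]:
    """Maximal bound intervals, each of duration run_length * dt.

    Runs touching the first or last frame are flagged censored on that side.
    """
    starts, stops = _runs(trace.bound)
    n = trace.n_frames
    return [
        ResidenceEvent(duration=float((b - a) * trace.dt),
                       censored_left=(a == 0),
                       censored_right=(b == n))
        for a, b in zip(starts, stops)
    ]


def _survival_rate(durations: np.ndarray) -> float | None:
    """k from least-squares exp(-k t) fit to the event-survival curve.

    Returns None when under-determined (fewer than 2 distinct durations).
    """
    t = np.sort(durations)
    if np.unique(t).size < 2:
        return None
    # survival S(t) = fraction of events with duration >= t
    surv = 1.0 - (np.arange(t.size)) / t.size
    k0 = 1.0 / max(float(t.mean()), 1e-12)
    try:
        popt, _ = curve_fit(lambda x, k: np.exp(-k * x), t, surv,
                            p0=[k0], bounds=(1e-12, np.inf), maxfev=2000)
    except RuntimeError:
        return None
    return float(popt[0])


def mean_residence(events: Iterable[ResidenceEvent],
                   method: Literal["mean", "survival_exponential"] = "mean") -> float:
    """Mean residence time in ns.

    ``mean``: arithmetic mean of uncensored durations (censored intervals
    are excluded — their observed length is only a lower bound — so the
    estimate is not biased downward by truncation). ``survival_exponential``:
    1/k from a least-squares single-exponential fit to the normalized
    survival curve of all event durations. NaN flags an undefined or
    under-determined estimate.
    """
    events = list(events)
    if method == "mean":
        durations = [e.duration for e in events if not e.censored]
        if not durations:
            return float("nan")
        return float(np.mean(durations))
    if method == "survival_exponential":
        if not events:
            return float("nan")
        k = _survival_rate(np.array([e.duration for e in events]))
        return float("nan") if k is None else 1.0 / k
    raise ValueError(f"unknown method: {method!r}")


def contact_stats(trace: ContactTrace, fit_koff: bool = True) -> ContactStats:
    """Full per-trace summary: occupancy, events, mean residence, k_off."""
    events = residence_events(trace)
    k_off = None
    if fit_koff and events:
        k = _survival_rate(np.array([e.duration for e in events]))
        if k is not None:
            k_off = k
    return ContactStats(
        label=trace.residue_label,
        occupancy=occupancy(trace),
        n_events=len(events),
        mean_residence=mean_residence(events),
        n_frames=trace.n_frames,
        dt=trace.dt,
        events=tuple(events),
        k_off=k_off,
    )


def site_stats(traces: Mapping[str, ContactTrace],
               site: SiteDefinition) -> tuple[ContactStats, dict[str, ContactStats]]:
    """Site-level and per-residue statistics.

    The site is bound at a frame iff any member residue is bound (union of
    the member contact series).
    """
    missing = [r for r in site.residue_labels if r not in traces]
    if missing:
        raise KeyError(f"site {site.site_id!r} references absent residues: {missing}")
    members = [traces[r] for r in site.residue_labels]
    n = members[0].n_frames
    dt = members[0].dt
    for m in members[1:]:
        if m.n_frames != n or m.dt != dt:
            raise ValueError("all member traces must share n_frames and dt")
    union = np.zeros(n, dtype=np.int8)
    for m in members:
        union |= m.bound
    site_trace = ContactTrace(site.site_id, dt, union)
    per_residue = {r: contact_stats(traces[r]) for r in site.residue_labels}
    return contact_stats(site_trace), per_residue


def pool_replicates(stats: Sequence[ContactStats]) -> ContactStats:
    """Pool statistics across replicate trajectories.

    Occupancy is the frame-weighted mean; residence events are concatenated
    (never merged across replicate boundaries).
    """
    if not stats:
        raise ValueError("no replicate statistics to pool")
    dts = {s.dt for s in stats}
    if len(dts) > 1:
        raise ValueError(f"replicates have mixed frame spacings: {sorted(dts)}")
    total_frames = sum(s.n_frames for s in stats)
    occ = sum(s.occupancy * s.n_frames for s in stats) / total_frames
    events = tuple(e for s in stats for e in s.events)
    k_off = None
    if events:
        k = _survival_rate(np.array([e.duration for e in events]))
        if k is not None:
            k_off = k
    return ContactStats(
        label=stats[0].label,
        occupancy=float(occ),
        n_events=len(events),
        mean_residence=mean_residence(events),
        n_frames=total_frames,
        dt=stats[0].dt,
        events=events,
        k_off=k_off,
    )
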