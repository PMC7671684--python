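"""Single-channel analysis: all-point histograms, two-Gaussian level fits,
half-amplitude threshold idealization with dead-time imposition, open
probability and conductance.

The workflow mirrors standard patch-clamp practice: build the all-point
amplitude histogram of the trace, fit a double Gaussian to locate the closed
and open levels (their separation is the single-channel current amplitude i),
idealize by 50%-amplitude threshold crossing, impose a dead time (0.3 ms by
default) by merging unresolvable events into the enclosing level, and read
Po as the open fraction of total time.
"""

from __future__ import annotations

import heapq
import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .channel import Recording
from .errors import DegenerateFitError, FitError, ParameterError

DEFAULT_DEAD_TIME_MS = 0.3

CLOSED, OPEN = 0, 1


@dataclass(frozen=True)
class AmplitudeHistogram:
    """All-point histogram: counts per current bin; counts sum to n_samples."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class LevelFit:
    """Two-Gaussian decomposition of the amplitude histogram.

    ``weights`` are the closed/open area fractions (sum to 1); the
    single-channel current amplitude is ``open_mean - closed_mean``.
    """

    closed_mean: float
    open_mean: float
    closed_sd: float
    open_sd: float
    weights: tuple

    @property
    def amplitude_pA(self) -> float:
        return self.open_mean - self.closed_mean

    @property
    def threshold(self) -> float:
        """Half-amplitude threshold: arithmetic midpoint of the level means."""
        return 0.5 * (self.closed_mean + self.open_mean)

    @property
    def open_weight(self) -> float:
        return self.weights[1]


def freedman_diaconis_bins(x: np.ndarray, max_bins: int = 512) -> int:
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        return 20
    h = 2.0 * iqr / x.size ** (1.0 / 3.0)
    return int(np.clip(np.ceil((x.max() - x.min()) / h), 20, max_bins))


def _double_gauss(x, mu1, mu2, s1, s2, a1, a2):
    return (a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))


class TwoGaussianModel:
    """Least-squares double-Gaussian model of an all-point histogram.

    Initial guesses are moment-based: samples are split at the midpoint of
    the data range and each half supplies the mean/SD of one component.
    """

    def __init__(self, rec: Recording | np.ndarray, n_bins: int | None = None):
        samples = rec.current_pA if isinstance(rec, Recording) else np.asarray(rec, float)
        if samples.size < 10:
            raise ParameterError("too few samples for an amplitude histogram")
        if n_bins is None:
            n_bins = freedman_diaconis_bins(samples)
        if n_bins < 20:
            raise ParameterError("n_bins must be at least 20")
        self.samples = samples
        counts, edges = np.histogram(samples, bins=n_bins)
        self.histogram = AmplitudeHistogram(edges, counts)

    def fit(self) -> tuple[AmplitudeHistogram, LevelFit]:
        x = self.histogram.centers
        y = self.histogram.counts.astype(float)
        s = self.samples
        mid = 0.5 * (s.min() + s.max())
        lo, hi = s[s <= mid], s[s > mid]
        if lo.size == 0 or hi.size == 0:
            raise DegenerateFitError("unimodal data: only one level present")
        mu1, mu2 = float(lo.mean()), float(hi.mean())
        sd1_raw, sd2_raw = float(lo.std()), float(hi.std())

        # Delta-like peaks (noise-free traces): report empirical moments; a
        # nonlinear fit on two one-bin spikes is ill-posed.
        span = s.max() - s.min()
        if max(sd1_raw, sd2_raw) < 1e-9 * max(span, 1.0):
            w_open = hi.size / s.size
            fit = LevelFit(mu1, mu2, sd1_raw, sd2_raw, (1.0 - w_open, w_open))
            self._check_separation(fit)
            return self.histogram, fit
        sd1 = sd1_raw or self.histogram.bin_width
        sd2 = sd2_raw or self.histogram.bin_width

        a1 = lo.size * self.histogram.bin_width / (np.sqrt(2 * np.pi) * sd1)
        a2 = hi.size * self.histogram.bin_width / (np.sqrt(2 * np.pi) * sd2)

        def resid(theta):
            return _double_gauss(x, *theta) - y

        eps = 1e-6 * max(span, 1.0)
        sol = least_squares(
            resid, [mu1, mu2, sd1, sd2, a1, a2],
            bounds=([s.min(), s.min(), eps, eps, 0, 0],
                    [s.max(), s.max(), span, span, np.inf, np.inf]),
        )
        if not sol.success:
            raise FitError(f"double-Gaussian fit failed: {sol.message}")
        mu1, mu2, sd1, sd2, a1, a2 = sol.x
        if mu1 > mu2:  # keep closed = lower level for outward current
            mu1, mu2, sd1, sd2, a1, a2 = mu2, mu1, sd2, sd1, a2, a1
        area1, area2 = a1 * sd1, a2 * sd2
        tot = area1 + area2
        fit = LevelFit(mu1, mu2, sd1, sd2, (area1 / tot, area2 / tot))
        self._check_separation(fit)
        return self.histogram, fit

    @staticmethod
    def _check_separation(fit: LevelFit):
        if abs(fit.amplitude_pA) < 2.0 * max(fit.closed_sd, fit.open_sd):
            raise DegenerateFitError(
                "fit collapsed: level separation below 2 SD — data appear "
                "unimodal (single level)"
            )


def amplitude_histogram_fit(rec: Recording,
                            n_bins: int | None = None
                            ) -> tuple[AmplitudeHistogram, LevelFit]:
    """All-point histogram plus double-Gaussian level fit of a recording."""
    return TwoGaussianModel(rec, n_bins).fit()


@dataclass
class EventList:
    """Idealized alternating closed/open events.

    Events are contiguous (start[k+1] = start[k] + duration[k]), levels
    alternate, and every duration is at least the dead time.
    """

    starts_ms: np.ndarray
    durations_ms: np.ndarray
    levels: np.ndarray
    dead_time_ms: float
    total_time_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.starts_ms = np.asarray(self.starts_ms, float)
        self.durations_ms = np.asarray(self.durations_ms, float)
        self.levels = np.asarray(self.levels, np.int8)

    def __len__(self):
        return self.levels.size

    @property
    def n_events(self) -> int:
        return self.levels.size

    def open_time_ms(self) -> float:
        return float(self.durations_ms[self.levels == OPEN].sum())

    def to_tsv(self, path_or_buf=None):
        df = pd.DataFrame({
            "start_ms": self.starts_ms,
            "duration_ms": self.durations_ms,
            "level": np.where(self.levels == OPEN, "open", "closed"),
        })
        return df.to_csv(path_or_buf, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path_or_buf, dead_time_ms=DEFAULT_DEAD_TIME_MS) -> "EventList":
        df = pd.read_csv(path_or_buf, sep="\t")
        levels = (df["level"] == "open").to_numpy().astype(np.int8)
        starts = df["start_ms"].to_numpy()
        durs = df["duration_ms"].to_numpy()
        total = float(starts[-1] + durs[-1]) if len(df) else 0.0
        return cls(starts, durs, levels, dead_time_ms, total)

    def summary_json(self, voltage_mV: float | None = None,
                     e_rev_mV: float = 0.0,
                     amplitude_pA: float | None = None) -> str:
        d = {
            "Po": open_probability(self),
            "n_events": int(self.n_events),
            "dead_time_ms": self.dead_time_ms,
            "total_time_ms": self.total_time_ms,
        }
        if amplitude_pA is not None:
            d["i_pA"] = amplitude_pA
            if voltage_mV is not None:
                d["g_pS"] = conductance(amplitude_pA, voltage_mV, e_rev_mV)
        return json.dumps(d, indent=2)


def _merge_dead_time(durations: np.ndarray, levels: np.ndarray,
                     dead_time: float) -> tuple[np.ndarray, np.ndarray]:
    """Remove events shorter than the dead time, shortest first.

    Each unresolvable event is absorbed into its enclosing level: an interior
    short event merges with both (same-level) neighbours; a short event at
    either edge merges into its single neighbour. Re-scanned to a fixed point
    so the result is deterministic and idempotent. Implemented as a doubly
    linked list with a lazy min-heap, O(n log n).
    """
    n = durations.size
    if n <= 1:
        return durations.copy(), levels.copy()
    dur = durations.astype(float).copy()
    lev = levels.copy()
    prev = np.arange(-1, n - 1)
    nxt = np.arange(1, n + 1)
    nxt[-1] = -1
    alive = np.ones(n, bool)
    version = np.zeros(n, np.int64)
    heap = [(dur[i], i, 0) for i in range(n) if dur[i] < dead_time]
    heapq.heapify(heap)

    def push(i):
        if dur[i] < dead_time:
            version[i] += 1
            heapq.heappush(heap, (dur[i], i, version[i]))

    n_alive = n
    while heap and n_alive > 1:
        d, i, ver = heapq.heappop(heap)
        if not alive[i] or ver != version[i] or dur[i] != d:
            continue
        p, q = prev[i], nxt[i]
        if p >= 0 and q >= 0:
            # interior: neighbours share the enclosing level
            dur[p] += dur[i] + dur[q]
            nxt[p] = nxt[q]
            if nxt[q] >= 0:
                prev[nxt[q]] = p
            alive[i] = alive[q] = False
            n_alive -= 2
            push(p)
        elif q >= 0:  # first event
            dur[q] += dur[i]
            prev[q] = -1
            alive[i] = False
            n_alive -= 1
            push(q)
        else:  # last event
            dur[p] += dur[i]
            nxt[p] = -1
            alive[i] = False
            n_alive -= 1
            push(p)
    keep = np.nonzero(alive)[0]
    return dur[keep], lev[keep]


def idealize_events(rec: Recording, levels: LevelFit,
                    dead_time_ms: float = DEFAULT_DEAD_TIME_MS) -> EventList:
    """Threshold-crossing idealization with dead-time imposition.

    The threshold is the midpoint of the fitted level means (the 50%-amplitude
    rule); samples above it are open. Events shorter than ``dead_time_ms``
    are merged into the enclosing level, shortest first, until none remain.
    """
    if dead_time_ms < 0:
        raise ParameterError("dead time must be non-negative")
    total = rec.duration_ms
    if dead_time_ms >= total / 2.0:
        raise ParameterError(
            f"dead time {dead_time_ms} ms is at least half the trace "
            f"({total} ms): no events are resolvable"
        )
    above = rec.current_pA > levels.threshold
    if above.size == 0:
        raise ParameterError("empty recording")
    # run-length encode the threshold comparison
    change = np.nonzero(np.diff(above))[0] + 1
    bounds = np.concatenate([[0], change, [above.size]])
    run_lengths = np.diff(bounds) * rec.dt_ms
    run_levels = above[bounds[:-1]].astype(np.int8)
    durs, levs = _merge_dead_time(run_lengths, run_levels, dead_time_ms)
    starts = np.concatenate([[0.0], np.cumsum(durs)[:-1]])
    return EventList(starts, durs, levs, dead_time_ms, float(durs.sum()),
                     meta={"threshold_pA": levels.threshold})


def open_probability(events: EventList) -> float:
    """Open probability: total open time over total time."""
    if events.n_events == 0 or events.total_time_ms <= 0:
        raise ParameterError("empty event list")
    return events.open_time_ms() / float(events.durations_ms.sum())


def conductance(i_pA: float, voltage_mV: float, e_rev_mV: float = 0.0) -> float:
    """Chord conductance g = i / (V - E_rev) in pS (i in pA, V in mV)."""
    if voltage_mV == e_rev_mV:
        raise ParameterError("V equals E_rev: conductance undefined")
    return 1e3 * i_pA / (voltage_mV - e_rev_mV)


def aggregate_po(po_values, method: str = "mean") -> tuple[float, float]:
    """Aggregate per-patch Po values: mean ± SEM (default) or pooled.

    ``pooled`` expects (open_time, total_time) pairs and returns the
    time-weighted Po with SE 0 (no between-patch variance estimate).
    """
    if method == "mean":
        v = np.asarray(list(po_values), float)
        sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
        return float(v.mean()), float(sem)
    if method == "pooled":
        pairs = np.asarray(list(po_values), float)
        return float(pairs[:, 0].sum() / pairs[:, 1].sum()), 0.0
    raise ParameterError(f"unknown aggregation {method!r}")
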