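"""Tethered Particle Motion (TPM) folding analysis.

A bead tethered to the surface by a single DNA molecule explores a disc whose
size tracks the effective tether length. When protamine folds the DNA, the
windowed standard deviation of the bead position, sigma_x, drops. The pipeline
here mirrors the real-time analysis of that signal:

    remove_drift -> qc_tether -> rolling_sigma -> detect_states
                                               -> detect_transitions
                                               -> pool_peaks

Conventions (all configurable): 5 Hz sampling, 50-frame rolling window,
1-nm histogram bins anchored at 0, peaks must exceed the window size in count,
pooled peak histograms use 3-nm bins, and the instrument detection limit is the
end of the second pooled bin (6 nm).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: whole-trace sigma cutoffs (nm) by tether length (nm); beads whose excursion
#: falls below the cutoff are assumed to be stuck or mis-tethered.
SIGMA_CUTOFFS_NM: dict[float, float] = {25.0: 18.0, 50.0: 25.0, 105.0: 40.0}

ECCENTRICITY_CUT = 0.45


def detection_limit(pool_bin_nm: float = 3.0, n_bins: int = 2) -> float:
    """Instrument detection limit: the end of the *n_bins*-th pooled bin.

    Stuck-bead control traces have sigma of 3 +/- 1 nm, which sets the pooled
    bin width; the limit is placed conservatively at the end of the second bin.
    """
    return pool_bin_nm * n_bins


@dataclass
class BeadTrace:
    """Planar bead positions for one tether.

    time_s is uniformly sampled (5 Hz nominal); condition holds a per-frame
    label for the protamine condition active at that time.
    """

    time_s: np.ndarray
    x_nm: np.ndarray
    y_nm: np.ndarray
    condition: np.ndarray
    tether_length_nm: float = np.nan

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.x_nm = np.asarray(self.x_nm, dtype=float)
        self.y_nm = np.asarray(self.y_nm, dtype=float)
        self.condition = np.asarray(self.condition)
        n = len(self.time_s)
        if not (len(self.x_nm) == len(self.y_nm) == len(self.condition) == n):
            raise ValueError("time, x, y and condition must have equal length")
        if n >= 3:
            dt = np.diff(self.time_s)
            if dt.min() <= 0 or (dt.max() - dt.min()) > 0.01 * np.median(dt):
                raise ValueError("trace must be uniformly sampled within 1%")
        if not (np.isfinite(self.x_nm).all() and np.isfinite(self.y_nm).all()):
            raise ValueError("positions must be finite")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def segments(self):
        """Yield (label, slice) for each contiguous condition segment."""
        labels = self.condition
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                yield labels[start], slice(start, i)
                start = i

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time_s, "x_nm": self.x_nm,
                             "y_nm": self.y_nm, "condition_label": self.condition})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, tether_length_nm: float = np.nan) -> "BeadTrace":
        return cls(df["time_s"].to_numpy(), df["x_nm"].to_numpy(),
                   df["y_nm"].to_numpy(), df["condition_label"].to_numpy(),
                   tether_length_nm)


@dataclass
class TetherQC:
    eccentricity: float
    sigma_x_nm: float
    sigma_y_nm: float
    whole_trace_sigma_nm: float
    sigma_cutoff_nm: float
    pass_eccentricity: bool
    pass_sigma: bool
    reason: str = ""

    @property
    def passed(self) -> bool:
        return self.pass_eccentricity and self.pass_sigma


@dataclass
class RollingSigma:
    """Trailing-window sample standard deviation of x, advanced one frame."""

    time_s: np.ndarray
    sigma_nm: np.ndarray
    window: int

    def __post_init__(self):
        if (self.sigma_nm < 0).any():
            raise ValueError("sigma must be non-negative")


@dataclass
class Peak:
    sigma_nm: float
    count: int
    reliable: bool  # False when at or below the detection limit


@dataclass
class StateModel:
    bin_edges: np.ndarray
    counts: np.ndarray
    peaks: list[Peak]
    window: int
    detection_limit_nm: float = 6.0

    @property
    def peak_locations(self) -> np.ndarray:
        return np.array([p.sigma_nm for p in self.peaks])


@dataclass
class Transition:
    """A move of sigma_x from one histogram peak to another.

    duration_s is the time from the last frame inside the start peak's band
    to the first frame inside the end peak's band. On a sigma trace computed
    with a rolling window this includes the window's own ~window-length
    response, so durations of fast transitions on real or simulated bead
    traces are upper bounds.
    """

    start_peak_nm: float
    end_peak_nm: float
    leave_time_s: float
    arrive_time_s: float

    @property
    def duration_s(self) -> float:
        return self.arrive_time_s - self.leave_time_s

    @property
    def direction(self) -> str:
        return "forward" if self.end_peak_nm < self.start_peak_nm else "reverse"

    @property
    def transition_class(self) -> str:
        if self.duration_s <= 2.0:
            return "discrete"
        if self.duration_s > 10.0:
            return "gradual"
        return "intermediate"


def remove_drift(trace: BeadTrace, min_segment: int = 10) -> BeadTrace:
    """Subtract a per-axis least-squares line within each condition segment.

    Removes low-frequency instrumental drift. Segments shorter than
    *min_segment* frames are passed through unchanged with a warning.
    """
    x = trace.x_nm.copy()
    y = trace.y_nm.copy()
    for label, sl in trace.segments():
        n = sl.stop - sl.start
        if n < 2:
            raise ValueError(f"segment {label!r} has fewer than 2 frames")
        if n < min_segment:
            warnings.warn(f"segment {label!r} has {n} frames (<{min_segment}); "
                          "drift not removed", stacklevel=2)
            continue
        t = trace.time_s[sl]
        for arr in (x, y):
            coeff = np.polynomial.polynomial.polyfit(t, arr[sl], 1)
            arr[sl] -= np.polynomial.polynomial.polyval(t, coeff)
    return BeadTrace(trace.time_s.copy(), x, y, trace.condition.copy(),
                     trace.tether_length_nm)


def qc_tether(trace: BeadTrace, reference_label=None,
              sigma_cutoff_nm: float | None = None,
              sigma_axis: str = "x",
              sigma_scope: str = "reference",
              use_variance_ratio: bool = False) -> TetherQC:
    """Single-tether quality control on the protamine-free segment.

    Eccentricity e = sqrt(|1 - sigma_x/sigma_y|) must be < 0.45 (a larger value
    indicates a bead held by more than one tether) and the whole-trace standard
    deviation must exceed a tether-length-specific cutoff, confirming the bead
    hangs from DNA of the right length. Both statistics are evaluated on the
    protamine-free segment by default (a folded tether legitimately has a
    small sigma later on); ``sigma_scope="full"`` applies the cutoff to the
    entire recording instead. The eccentricity ratio uses standard deviations
    as printed; *use_variance_ratio* switches to variances for sensitivity
    analysis.
    """
    if reference_label is None:
        reference_label = trace.condition[0]
    sel = trace.condition == reference_label
    if not sel.any():
        raise ValueError(f"no frames with condition {reference_label!r}")
    sx = float(np.std(trace.x_nm[sel], ddof=1))
    sy = float(np.std(trace.y_nm[sel], ddof=1))
    if sy == 0:
        return TetherQC(np.inf, sx, sy, sx, np.nan, False, False,
                        reason="sigma_y is zero")
    ratio = (sx / sy) ** 2 if use_variance_ratio else sx / sy
    ecc = float(np.sqrt(abs(1.0 - ratio)))

    if sigma_cutoff_nm is None:
        key = trace.tether_length_nm
        match = [v for k, v in SIGMA_CUTOFFS_NM.items() if abs(k - key) <= 1.0]
        if not match:
            raise ValueError(
                f"no default sigma cutoff for tether length {key} nm; "
                "pass sigma_cutoff_nm explicitly")
        sigma_cutoff_nm = match[0]

    scope = sel if sigma_scope == "reference" else np.ones(len(sel), bool)
    if sigma_axis == "x":
        whole = float(np.std(trace.x_nm[scope], ddof=1))
    elif sigma_axis == "y":
        whole = float(np.std(trace.y_nm[scope], ddof=1))
    else:  # pooled over both axes
        whole = float(np.std(np.concatenate([trace.x_nm[scope],
                                             trace.y_nm[scope]]), ddof=1))

    pass_ecc = ecc < ECCENTRICITY_CUT
    pass_sigma = whole > sigma_cutoff_nm
    reason = "" if (pass_ecc and pass_sigma) else \
        ("eccentricity" if not pass_ecc else "whole-trace sigma below cutoff")
    return TetherQC(ecc, sx, sy, whole, sigma_cutoff_nm, pass_ecc, pass_sigma,
                    reason)


def rolling_sigma(trace: BeadTrace, window: int = 50) -> RollingSigma:
    """Sample standard deviation (n-1 denominator) of x over a trailing window.

    The window advances one frame at a time; the output has
    ``len(trace) - window + 1`` values, timestamped at the window's last frame.
    """
    n = len(trace.time_s)
    if n < window:
        raise ValueError(f"trace length {n} shorter than window {window}")
    s = pd.Series(trace.x_nm).rolling(window).std(ddof=1).to_numpy()[window - 1:]
    return RollingSigma(trace.time_s[window - 1:], s, window)


def sigma_resolution(sigma_nm: float, window: int) -> float:
    """Sampling standard deviation of a window-*window* sigma estimate.

    The rolling sigma of a true state of size sigma fluctuates with SD of
    about sigma / sqrt(2 (window - 1)); states closer than a few times this
    cannot be resolved by the histogram.
    """
    return sigma_nm / math.sqrt(2.0 * (window - 1))


def detect_states(rs: RollingSigma, bin_nm: float = 1.0,
                  min_count: int | None = None,
                  detection_limit_nm: float | None = None,
                  merge_nm: float = 3.0,
                  merge_scale: float = 1.2,
                  valley_ratio: float = 0.4) -> StateModel:
    """Call folding states as peaks of the sigma_x histogram.

    The histogram uses *bin_nm* bins anchored at 0. A candidate peak is a bin
    strictly taller than both neighbours with a count greater than the rolling
    window size (so a state must last at least one window); runs of
    equal-count bins count once, at their centroid. Because consecutive
    rolling-sigma values share most of their window, a single state produces a
    ragged cluster of candidate bins spanning a few times the sigma sampling
    SD rather than one smooth mode. Adjacent candidates are therefore merged
    when either (i) they are closer than
    ``max(merge_nm, merge_scale * sigma_resolution(sigma, window))``
    (*merge_nm* is the 3-nm instrument noise floor that also sets the pooled
    histogram bin) or (ii) the histogram valley between them stays above
    *valley_ratio* of the smaller candidate — i.e. there is no real dip, only
    raggedness; genuinely distinct states are separated by near-empty valleys
    and are never merged by this rule. Each merged state is located at the
    count-weighted centroid of all histogram bins in its territory. Peaks at
    or below the detection limit are kept but flagged unreliable.
    """
    if len(rs.sigma_nm) == 0:
        raise ValueError("empty rolling-sigma input")
    if min_count is None:
        min_count = rs.window
    if detection_limit_nm is None:
        detection_limit_nm = detection_limit()
    top = float(np.nanmax(rs.sigma_nm))
    edges = np.arange(0.0, (np.floor(top / bin_nm) + 2) * bin_nm, bin_nm)
    counts, _ = np.histogram(rs.sigma_nm[np.isfinite(rs.sigma_nm)], bins=edges)

    candidates: list[tuple[float, int, int, int]] = []
    i = 0
    nb = len(counts)
    while i < nb:
        j = i
        while j + 1 < nb and counts[j + 1] == counts[i]:
            j += 1
        left = counts[i - 1] if i > 0 else 0
        right = counts[j + 1] if j + 1 < nb else 0
        c = int(counts[i])
        if c > left and c > right and c > min_count:
            candidates.append((0.5 * (edges[i] + edges[j + 1]), c, i, j))
        i = j + 1

    clusters: list[list[tuple[float, int, int, int]]] = []
    for loc, c, i, j in candidates:
        if clusters:
            ploc, pc, pi, pj = clusters[-1][-1]
            radius = max(merge_nm, merge_scale *
                         sigma_resolution(0.5 * (loc + ploc), rs.window))
            valley = counts[pj + 1:i].min() if i > pj + 1 else min(c, pc)
            if (loc - ploc < radius) or (valley > valley_ratio * min(c, pc)):
                clusters[-1].append((loc, c, i, j))
                continue
        clusters.append([(loc, c, i, j)])

    # Each cluster's location is the count-weighted centroid of all histogram
    # bins in its territory (bounded by midpoints between adjacent clusters),
    # i.e. the mean sigma of the frames assigned to that state - a far more
    # stable estimate than the single tallest ragged bin.
    centres = 0.5 * (edges[:-1] + edges[1:])
    spans = [(cl[0][0], cl[-1][0]) for cl in clusters]
    bounds = [-np.inf]
    for (lo_a, hi_a), (lo_b, hi_b) in zip(spans, spans[1:]):
        bounds.append(0.5 * (hi_a + lo_b))
    bounds.append(np.inf)
    peaks = []
    for cl, lo, hi in zip(clusters, bounds, bounds[1:]):
        sel = (centres >= lo) & (centres < hi) & (counts > 0)
        total = int(counts[sel].sum())
        centre = float((centres[sel] * counts[sel]).sum() / total)
        peaks.append(Peak(centre, total, centre > detection_limit_nm))
    return StateModel(edges, counts, peaks, rs.window, detection_limit_nm)


def detect_transitions(rs: RollingSigma, model: StateModel,
                       band_nm: float = 1.5,
                       persistence_s: float = 5.0) -> list[Transition]:
    """Call transitions of sigma_x between histogram peaks.

    A frame is assigned to a peak when sigma_x lies within +/-*band_nm* of it
    (half the 3-nm pooled bin, the control-trace noise floor). A transition is
    emitted when the assignment moves to a different peak and stays off the
    other peaks for *persistence_s* seconds; its duration runs from the last
    frame in the start band to the first frame in the end band.
    """
    locs = model.peak_locations
    if len(locs) < 2:
        return []
    sig = rs.sigma_nm
    t = rs.time_s
    nearest = np.argmin(np.abs(sig[:, None] - locs[None, :]), axis=1)
    inband = np.abs(sig - locs[nearest]) <= band_nm
    assign = np.where(inband, nearest, -1)

    idx = np.flatnonzero(assign >= 0)
    transitions: list[Transition] = []
    if idx.size == 0:
        return transitions
    current = assign[idx[0]]
    last_in_current = idx[0]
    k = 1
    while k < idx.size:
        i = idx[k]
        if assign[i] == current:
            last_in_current = i
            k += 1
            continue
        cand = assign[i]
        horizon = t[i] + persistence_s
        future = idx[(idx > i) & (t[idx] <= horizon)]
        if np.all(assign[future] == cand):
            transitions.append(Transition(
                start_peak_nm=float(locs[current]),
                end_peak_nm=float(locs[cand]),
                leave_time_s=float(t[last_in_current]),
                arrive_time_s=float(t[i])))
            current = cand
            last_in_current = i
        k += 1
    return transitions


def pool_peaks(models: list[StateModel], condition_labels=None,
               bin_nm: float = 3.0) -> pd.DataFrame:
    """Stack per-tether sigma_x peaks into a pooled histogram.

    Returns a tidy DataFrame with one row per (condition, bin): columns
    bin_left, bin_right, count and below_detection_limit (bins ending at or
    below 6 nm). An empty model list yields an empty histogram.
    """
    if condition_labels is None:
        condition_labels = ["all"] * len(models)
    rows = []
    all_peaks = [(lab, p) for lab, m in zip(condition_labels, models)
                 for p in m.peak_locations]
    if not all_peaks:
        return pd.DataFrame(columns=["condition", "bin_left", "bin_right",
                                     "count", "below_detection_limit"])
    top = max(p for _, p in all_peaks)
    edges = np.arange(0.0, (np.floor(top / bin_nm) + 2) * bin_nm, bin_nm)
    limit = detection_limit(bin_nm)
    for lab in dict.fromkeys(condition_labels):
        vals = [p for label, p in all_peaks if label == lab]
        counts, _ = np.histogram(vals, bins=edges)
        for left, right, c in zip(edges[:-1], edges[1:], counts):
            rows.append({"condition": lab, "bin_left": left, "bin_right": right,
                         "count": int(c),
                         "below_detection_limit": bool(right <= limit)})
    return pd.DataFrame(rows)
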