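"""Polymer statistics for traced DNA contours.

Two competing pictures for a folded molecule are fitted to the same pooled
statistics:

* a flexible (worm-like) polymer, whose tangent-tangent correlation decays as
  ``<cos theta> = exp(-l / (s Lp))`` and whose contour mean-squared
  displacement follows ``MSD(l) = 2 s Lp l (1 - (s Lp / l)(1 - exp(-l/(s Lp))))``
  with s the dimensionality (s = 2 for molecules equilibrated on a surface);

* a contour bent along a circle of radius R, for which
  ``<cos theta> = cos(l / R)`` and ``MSD(l) = 4 R^2 sin^2(l / (2R))`` — the
  correlation crosses zero and goes negative, and the MSD turns over, which no
  exponential decay can do.

Which model fits better (by residual norm) distinguishes entropic softening
(a shorter persistence length) from enthalpic bending (a preferred radius of
curvature). A local curvature histogram at the nearest-neighbour scale
(~4 nm) provides the per-point view of the same question.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from . import geometry

DEFAULT_BIN_NM = 4.0
BP_PER_TURN = 10.5
_R_HUGE = 1e6  # circle radii above this mean "effectively straight"


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

def wlc_correlation_model(ell: np.ndarray, lp: float, s: float = 2.0) -> np.ndarray:
    """Exponential tangent-correlation decay of a worm-like chain."""
    return np.exp(-np.asarray(ell, dtype=float) / (s * lp))


def circle_correlation_model(ell: np.ndarray, radius: float) -> np.ndarray:
    """Tangent correlation of a contour bent along a circle."""
    return np.cos(np.asarray(ell, dtype=float) / radius)


def wlc_msd_model(ell: np.ndarray, lp: float, s: float = 2.0) -> np.ndarray:
    """Contour MSD of a worm-like chain (numerically stable at small l)."""
    ell = np.asarray(ell, dtype=float)
    x = ell / (s * lp)
    with np.errstate(divide="ignore", invalid="ignore"):
        bracket = 1.0 + np.expm1(-x) / x
    small = x < 1e-8
    if np.any(small):  # series limit: MSD -> l^2
        bracket = np.where(small, x / 2.0, bracket)
    return 2.0 * s * lp * ell * bracket


def circle_msd_model(radius: float, ell: np.ndarray) -> np.ndarray:
    """Chord-squared along a circle: 4 R^2 sin^2(l / 2R)."""
    return 4.0 * radius ** 2 * np.sin(np.asarray(ell, dtype=float)
                                      / (2.0 * radius)) ** 2


# ---------------------------------------------------------------------------
# pooled statistics
# ---------------------------------------------------------------------------

@dataclass
class TangentCorrelation:
    ell_nm: np.ndarray
    mean_cos: np.ndarray
    n_pairs: np.ndarray
    bin_nm: float
    median_contour_nm: float

    def __post_init__(self):
        if np.any(self.mean_cos < -1 - 1e-9) or np.any(self.mean_cos > 1 + 1e-9):
            raise ValueError("mean cos theta outside [-1, 1]")


@dataclass
class MSDProfile:
    ell_nm: np.ndarray
    msd_nm2: np.ndarray
    n_pairs: np.ndarray
    bin_nm: float
    median_contour_nm: float


@dataclass
class WLCFit:
    persistence_nm: float
    dimension: float
    residual_norm: float
    fit_range_nm: tuple[float, float]


@dataclass
class CircleFit:
    radius_nm: float
    residual_norm: float
    poor_fit: bool = False


@dataclass
class CurvatureProfile:
    radii_nm: np.ndarray
    bin_edges_nm: np.ndarray
    counts: np.ndarray
    mode_nm: float
    fwhm_nm: float
    cap_nm: float


def _pool_pairs(centerlines, bin_nm, values_fn):
    """Pool all point pairs of all centerlines into contour-separation bins.

    Each bin reports the mean separation of the pairs it holds (not the bin
    centre), so that regular sampling grids do not bias the abscissa.
    """
    sums: dict[int, float] = {}
    sep_sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    lengths = []
    for cl in centerlines:
        cl = np.asarray(cl, dtype=float)
        if len(cl) < 3:
            raise ValueError("each centerline needs at least 3 points")
        s = geometry.arc_positions(cl)
        lengths.append(s[-1])
        vals, seps = values_fn(cl, s)
        bins = np.rint(seps / bin_nm).astype(int)
        ok = bins >= 1
        for b, v, sep in zip(bins[ok], vals[ok], seps[ok]):
            sums[b] = sums.get(b, 0.0) + v
            sep_sums[b] = sep_sums.get(b, 0.0) + sep
            counts[b] = counts.get(b, 0) + 1
    keys = sorted(sums)
    ell = np.array([sep_sums[k] / counts[k] for k in keys])
    mean = np.array([sums[k] / counts[k] for k in keys])
    n = np.array([counts[k] for k in keys])
    return ell, mean, n, float(np.median(lengths))


def tangent_correlation(centerlines, bin_nm: float = DEFAULT_BIN_NM
                        ) -> TangentCorrelation:
    """Pooled mean cos(theta) between tangents separated by contour length l.

    Tangents are the unit directions of consecutive segments, located at the
    segment midpoints (this finite-difference estimator is exactly unbiased
    for both the exponential and the circular null model, unlike a centred
    difference, which smooths the tangent over two segments). All segment
    pairs of all molecules are pooled into *bin_nm* separation bins before
    any fitting (one ensemble curve, not per-molecule fits).
    """
    def values(cl, s):
        seg = np.diff(cl, axis=0)
        t = seg / np.linalg.norm(seg, axis=1, keepdims=True)
        mid = 0.5 * (s[:-1] + s[1:])
        i, j = np.triu_indices(len(t), k=1)
        return (t[i] * t[j]).sum(axis=1), mid[j] - mid[i]

    ell, mean, n, med = _pool_pairs(centerlines, bin_nm, values)
    return TangentCorrelation(ell, np.clip(mean, -1.0, 1.0), n, bin_nm, med)


def msd_profile(centerlines, bin_nm: float = DEFAULT_BIN_NM) -> MSDProfile:
    """Pooled mean squared displacement between contour points at separation l."""
    def values(cl, s):
        i, j = np.triu_indices(len(cl), k=1)
        d = cl[j] - cl[i]
        return (d ** 2).sum(axis=1), s[j] - s[i]

    ell, mean, n, med = _pool_pairs(centerlines, bin_nm, values)
    return MSDProfile(ell, mean, n, bin_nm, med)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def _fit_window(ell, lo, hi):
    sel = (ell >= lo - 1e-9) & (ell <= hi + 1e-9)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 bins in the fit range")
    return sel


def _range(profile, ell_range):
    if ell_range is not None:
        return ell_range
    return (profile.bin_nm, 0.9 * profile.median_contour_nm)


def fit_wlc_correlation(tc: TangentCorrelation, s: float = 2.0,
                        ell_range: tuple[float, float] | None = None) -> WLCFit:
    """Least-squares fit of the exponential decay; returns the persistence length.

    Negative-correlation bins are kept — they penalize the exponential, which
    is exactly what distinguishes it from circular bending.
    """
    lo, hi = _range(tc, ell_range)
    sel = _fit_window(tc.ell_nm, lo, hi)
    x, y = tc.ell_nm[sel], tc.mean_cos[sel]
    pos = y > 0.05
    if pos.sum() >= 2:  # log-linear seed
        slope = np.polyfit(x[pos], np.log(y[pos]), 1)[0]
        p0 = -1.0 / (s * slope) if slope < 0 else hi
    else:
        p0 = hi
    p0 = float(np.clip(p0, 1e-2, 1e7))
    try:
        popt, _ = optimize.curve_fit(
            lambda e, lp: wlc_correlation_model(e, lp, s), x, y,
            p0=[p0], bounds=(1e-3, 1e9), maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"worm-like-chain correlation fit failed to converge "
            f"(seed Lp={p0:.3g}, {sel.sum()} bins): {exc}") from exc
    resid = float(np.linalg.norm(y - wlc_correlation_model(x, popt[0], s)))
    return WLCFit(float(popt[0]), s, resid, (lo, hi))


def fit_circle_correlation(tc: TangentCorrelation,
                           ell_range: tuple[float, float] | None = None
                           ) -> CircleFit:
    """Least-squares fit of cos(l/R); captures the zero crossing of bent contours.

    Straight or nearly straight data drives R to an effectively infinite
    value; such fits are returned with ``poor_fit`` set.
    """
    lo, hi = _range(tc, ell_range)
    sel = _fit_window(tc.ell_nm, lo, hi)
    x, y = tc.ell_nm[sel], tc.mean_cos[sel]
    below = x[y <= 0]
    p0 = 2.0 * below.min() / math.pi if below.size else float(x.max())
    try:
        popt, _ = optimize.curve_fit(circle_correlation_model, x, y,
                                     p0=[p0], bounds=(1e-3, 10 * _R_HUGE),
                                     maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"circle correlation fit failed to converge "
            f"(seed R={p0:.3g}): {exc}") from exc
    radius = float(popt[0])
    resid = float(np.linalg.norm(y - circle_correlation_model(x, radius)))
    # a radius far beyond the probed separations is indistinguishable from a
    # straight contour: the data carry no curvature signal
    return CircleFit(radius, resid, poor_fit=radius > 5 * hi)


def fit_wlc_msd(msd: MSDProfile, s: float = 2.0,
                ell_range: tuple[float, float] | None = None) -> WLCFit:
    """Least-squares fit of the worm-like-chain MSD; returns persistence length."""
    lo, hi = _range(msd, ell_range)
    sel = _fit_window(msd.ell_nm, lo, hi)
    x, y = msd.ell_nm[sel], msd.msd_nm2[sel]
    slope_end = y[-1] / x[-1] if x[-1] > 0 else 1.0
    p0 = float(np.clip(slope_end / (2 * s), 1e-2, 1e7))
    try:
        popt, _ = optimize.curve_fit(lambda e, lp: wlc_msd_model(e, lp, s),
                                     x, y, p0=[p0], bounds=(1e-3, 1e9),
                                     maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"worm-like-chain MSD fit failed to converge: "
                           f"{exc}") from exc
    resid = float(np.linalg.norm(y - wlc_msd_model(x, popt[0], s)))
    return WLCFit(float(popt[0]), s, resid, (lo, hi))


def fit_circle_msd(msd: MSDProfile,
                   ell_range: tuple[float, float] | None = None) -> CircleFit:
    """Least-squares fit of the circular-arc MSD 4 R^2 sin^2(l/2R)."""
    lo, hi = _range(msd, ell_range)
    sel = _fit_window(msd.ell_nm, lo, hi)
    x, y = msd.ell_nm[sel], msd.msd_nm2[sel]
    p0 = float(max(math.sqrt(y.max()) / 2.0, 1.0))
    try:
        popt, _ = optimize.curve_fit(lambda e, r: circle_msd_model(r, e),
                                     x, y, p0=[p0], bounds=(1e-3, 10 * _R_HUGE),
                                     maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"circle MSD fit failed to converge: {exc}") from exc
    radius = float(popt[0])
    resid = float(np.linalg.norm(y - circle_msd_model(radius, x)))
    return CircleFit(radius, resid, poor_fit=radius > _R_HUGE)


# ---------------------------------------------------------------------------
# curvature profile
# ---------------------------------------------------------------------------

def curvature_profile(centerlines, scale_nm: float = DEFAULT_BIN_NM,
                      cap_nm: float = 100.0,
                      bin_nm: float = 2.0) -> CurvatureProfile:
    """Histogram of the local radius of curvature at the nearest-neighbour scale.

    Each centerline is resampled at *scale_nm* spacing and the radius of the
    circumscribed circle of every consecutive point triplet is recorded
    (collinear triplets count as the cap). The histogram mode and its full
    width at half maximum (linear interpolation at half the modal count)
    summarize whether curvature is broad (flexible polymer) or concentrated
    at a preferred radius (bent contour).
    """
    if isinstance(centerlines, np.ndarray) and centerlines.ndim == 2:
        centerlines = [centerlines]
    radii = []
    for cl in centerlines:
        cl = np.asarray(cl, dtype=float)
        seg = geometry.segment_lengths(cl)
        if abs(np.median(seg) - scale_nm) > 0.05 * scale_nm:
            cl = geometry.resample_polyline(cl, scale_nm)
        for a, b, c in zip(cl[:-2], cl[1:-1], cl[2:]):
            radii.append(geometry.circumradius(a, b, c, cap=cap_nm))
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0:
        raise ValueError("no interior triplets; centerlines too short")
    edges = np.arange(0.0, cap_nm + bin_nm, bin_nm)
    counts, _ = np.histogram(radii, bins=edges)
    mode_i = int(np.argmax(counts))
    mode = 0.5 * (edges[mode_i] + edges[mode_i + 1])
    fwhm = _fwhm(edges, counts, mode_i)
    return CurvatureProfile(radii, edges, counts, mode, fwhm, cap_nm)


def _fwhm(edges, counts, mode_i) -> float:
    half = counts[mode_i] / 2.0
    centres = 0.5 * (edges[:-1] + edges[1:])
    left = centres[0]
    for i in range(mode_i, 0, -1):
        if counts[i - 1] < half:
            left = np.interp(half, [counts[i - 1], counts[i]],
                             [centres[i - 1], centres[i]])
            break
    right = centres[-1]
    for i in range(mode_i, len(counts) - 1):
        if counts[i + 1] < half:
            right = np.interp(half, [counts[i + 1], counts[i]],
                              [centres[i + 1], centres[i]])
            break
    return float(max(right - left, edges[1] - edges[0]))


# ---------------------------------------------------------------------------
# bend-angle arithmetic
# ---------------------------------------------------------------------------

def round_to_sig_figs(value: float, n: int = 1) -> float:
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    factor = 10.0 ** (exponent - n + 1)
    return round(value / factor) * factor


@dataclass
class BendAngle:
    degrees: float
    one_sig_fig: float


def bend_angle_per_protein(arc_bp: float, radius_bp: float) -> BendAngle:
    """Bend angle subtended per bound protein: arc length / radius (radians).

    With one binding site per ~11 bp of arc and a radius of curvature of
    30 bp, each bound protein subtends ~20 degrees.
    """
    if radius_bp <= 0:
        raise ValueError("radius must be positive")
    deg = math.degrees(arc_bp / radius_bp)
    return BendAngle(deg, round_to_sig_figs(deg, 1))


def helical_turn_count(length_bp: float, bp_per_turn: float = BP_PER_TURN) -> int:
    """Complete helical turns in a duplex, hence maximum protein sites."""
    if length_bp <= 0:
        raise ValueError("length must be positive")
    return int(math.floor(length_bp / bp_per_turn))
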