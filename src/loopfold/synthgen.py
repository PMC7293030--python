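"""Synthetic bead traces and AFM images with known ground truth.

Every downstream stage (tpm, afm, polymer) is verifiable against these
generators without any external dataset. The generators' defaults emulate the
study conditions: 5-Hz bead traces with multi-state Gaussian excursions and
linear drift, and 1 um x 1 um, 256 x 256 px height maps (3.90625 nm/px) on
which DNA contours are stamped as ~0.5-nm-tall ridges of 2.5-px width.

Contours are built by a tangent-walk: equal chord steps with a prescribed
per-step turn. For a worm-like chain the turn is a Gaussian increment of
variance step/Lp, so the ensemble tangent correlation decays exactly as
exp(-l/(2 Lp)) at the step level; for arcs and loops the turn is the constant
step/R, so the tangent correlation of a polygonal circle is exactly cos(l/R).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .afm import AFMImage
from .geometry import transform
from .tpm import BeadTrace

DEFAULT_PIXEL_NM = 1000.0 / 256  # 3.90625 nm/px


# ---------------------------------------------------------------------------
# TPM traces
# ---------------------------------------------------------------------------

@dataclass
class TPMState:
    sigma_x_nm: float
    sigma_y_nm: float
    dwell_s: float
    label: str | None = None


@dataclass
class TPMSimSpec:
    """Multi-state Gaussian bead trace specification.

    states are visited in order for their dwell times. ramp_s > 0 turns the
    instantaneous sigma steps into linear ramps of that duration (starting at
    each transition). ou_tau_s > 0 switches the per-frame white noise to an
    Ornstein-Uhlenbeck process with that relaxation time (stress-test mode;
    the default is white noise, which is all the windowed-sigma analysis
    assumes).
    """

    states: list[TPMState]
    frame_rate_hz: float = 5.0
    n_frames: int | None = None
    ramp_s: float = 0.0
    drift_nm_per_s: tuple[float, float] = (0.0, 0.0)
    ou_tau_s: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.states:
            raise ValueError("at least one state required")
        for st in self.states:
            if st.sigma_x_nm <= 0 or st.sigma_y_nm <= 0:
                raise ValueError("state sigmas must be positive")
            if st.dwell_s < 1.0 / self.frame_rate_hz:
                raise ValueError(
                    f"dwell {st.dwell_s}s shorter than one frame "
                    f"({1.0 / self.frame_rate_hz}s)")
        total = sum(st.dwell_s for st in self.states)
        frames = int(round(total * self.frame_rate_hz))
        if self.n_frames is None:
            self.n_frames = frames
        elif abs(self.n_frames - frames) > 1:
            raise ValueError(
                f"dwells sum to {frames} frames but n_frames={self.n_frames}")


def simulate_tpm_trace(spec: TPMSimSpec) -> tuple[BeadTrace, np.ndarray]:
    """Simulate a bead trace; returns (trace, ground-truth state index per frame)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    dt = 1.0 / spec.frame_rate_hz
    t = np.arange(n) * dt

    # per-frame state track from the dwell ladder
    frames_per = [int(round(st.dwell_s * spec.frame_rate_hz)) for st in spec.states]
    track = np.repeat(np.arange(len(spec.states)), frames_per)[:n]
    if len(track) < n:  # rounding shortfall goes to the final state
        track = np.concatenate([track, np.full(n - len(track),
                                               len(spec.states) - 1)])

    sig_x = np.array([spec.states[k].sigma_x_nm for k in track], dtype=float)
    sig_y = np.array([spec.states[k].sigma_y_nm for k in track], dtype=float)
    if spec.ramp_s > 0:
        ramp_frames = max(int(round(spec.ramp_s * spec.frame_rate_hz)), 1)
        boundaries = np.flatnonzero(np.diff(track)) + 1
        for b in boundaries:
            for sig in (sig_x, sig_y):
                lo, hi = sig[b - 1], sig[min(b + ramp_frames, n) - 1]
                m = min(ramp_frames, n - b)
                sig[b:b + m] = lo + (hi - lo) * (np.arange(1, m + 1) / ramp_frames)

    if spec.ou_tau_s > 0:
        a = math.exp(-dt / spec.ou_tau_s)
        innov = math.sqrt(1.0 - a * a)
        zx = np.empty(n)
        zy = np.empty(n)
        zx[0], zy[0] = rng.standard_normal(2)
        ex = rng.standard_normal(n - 1) * innov
        ey = rng.standard_normal(n - 1) * innov
        for i in range(1, n):
            zx[i] = a * zx[i - 1] + ex[i - 1]
            zy[i] = a * zy[i - 1] + ey[i - 1]
    else:
        zx = rng.standard_normal(n)
        zy = rng.standard_normal(n)

    x = sig_x * zx + spec.drift_nm_per_s[0] * t
    y = sig_y * zy + spec.drift_nm_per_s[1] * t
    labels = np.array([spec.states[k].label or f"state{k}" for k in track])
    trace = BeadTrace(t, x, y, labels)
    return trace, track


# ---------------------------------------------------------------------------
# DNA contours
# ---------------------------------------------------------------------------

CONTOUR_KINDS = ("wlc", "arc_c", "arc_s", "loop", "pseudo_loop")


@dataclass
class ContourSpec:
    """Ground-truth parameters for one simulated DNA contour.

    kind selects the geometry: a 2D worm-like chain of persistence length
    persistence_nm, a single circular arc (arc_c), two opposite-curvature arcs
    (arc_s), or an "alpha" glyph — a circular head of centreline radius
    radius_nm whose two tails cross below it. With a head large enough to
    enclose a hole after rasterization this is a loop; with a small head whose
    hole fills in, a pseudo_loop. length_nm is the total contour length; the
    effective step is length_nm / round(length_nm / step_nm) so that all chord
    segments are exactly equal.
    """

    kind: str
    length_nm: float
    persistence_nm: float | None = None
    radius_nm: float | None = None
    step_nm: float = 4.0
    alpha_beta_rad: float = 0.8  # tail half-angle at the loop-tail crossing
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CONTOUR_KINDS:
            raise ValueError(f"unknown contour kind {self.kind!r}")
        if self.length_nm <= 0:
            raise ValueError("contour length must be positive")
        if self.step_nm <= 0 or self.step_nm >= self.length_nm:
            raise ValueError("step must satisfy 0 < step < length")
        if self.kind == "wlc":
            if not self.persistence_nm or self.persistence_nm <= 0:
                raise ValueError("wlc contours need persistence_nm > 0")
        else:
            if not self.radius_nm or self.radius_nm <= 0:
                raise ValueError(f"{self.kind} contours need radius_nm > 0")
        if self.kind == "loop" and \
                self.length_nm < 2 * math.pi * self.radius_nm - 1e-9:
            raise ValueError("loop needs length >= 2*pi*radius")
        if self.kind == "pseudo_loop":
            arc = self.radius_nm * (2 * math.pi - 2 * self.alpha_beta_rad)
            if self.length_nm <= arc:
                raise ValueError("pseudo_loop needs length > loop arc "
                                 f"({arc:.1f} nm) to leave crossing tails")

    @property
    def n_steps(self) -> int:
        return max(int(round(self.length_nm / self.step_nm)), 2)

    @property
    def effective_step_nm(self) -> float:
        return self.length_nm / self.n_steps


def _walk(turns: np.ndarray, step: float, psi0: float = 0.0) -> np.ndarray:
    """Tangent-walk: heading psi0 for step 1, then turning by turns[k] before
    each subsequent step. Returns (n_steps+1, 2) vertices starting at 0."""
    psi = psi0 + np.concatenate([[0.0], np.cumsum(turns)])
    steps = step * np.column_stack([np.cos(psi), np.sin(psi)])
    return np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])


def simulate_wlc_contour(spec: ContourSpec,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """2D worm-like chain: Gaussian tangent-angle walk, variance step/Lp per step.

    The ensemble mean tangent correlation at separation l is exp(-l/(2 Lp)),
    i.e. the 2D (s=2) form of the exponential-decay law.
    """
    if spec.kind != "wlc":
        raise ValueError("spec.kind must be 'wlc'")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h = spec.effective_step_nm
    turns = rng.normal(0.0, math.sqrt(h / spec.persistence_nm), spec.n_steps - 1)
    return _walk(turns, h)


def simulate_shape_contour(spec: ContourSpec) -> np.ndarray:
    """Deterministic arc / loop / pseudo-loop centerline polyline.

    arc_c: one circular arc of radius R subtending L/R radians.
    arc_s: two consecutive arcs of radius R with opposite curvature sign.
    loop: closed regular-polygon circle of radius R, remaining length split
          between two collinear tails tangent at the closure point.
    pseudo_loop: "alpha" glyph - tails entering at +beta and leaving at -beta
          with a left turn of 2*pi - 2*beta between them, so the tails cross
          transversally below a loop head of radius R.
    """
    h = spec.effective_step_nm
    n = spec.n_steps
    R = spec.radius_nm

    if spec.kind == "arc_c":
        dpsi = (spec.length_nm / R) / n
        return _walk(np.full(n - 1, dpsi), h)

    if spec.kind == "arc_s":
        n1 = n // 2
        dpsi = h / R
        turns = np.concatenate([np.full(n1 - 1, dpsi), [0.0],
                                np.full(n - n1 - 1, -dpsi)])
        return _walk(turns[:n - 1], h)

    if spec.kind in ("loop", "pseudo_loop"):
        # "alpha" glyph: tail in at +beta, left turn of 2*pi - 2*beta, tail
        # out at -beta; the outgoing tail crosses the incoming one
        # transversally below a circular head of radius R — the geometry of
        # an imaged DNA loop. The two kinds share the construction and
        # differ only in R: a loop's head encloses a resolvable hole after
        # rasterization, a pseudo-loop's does not. Length too short for
        # tails yields a pure closed polygon circle instead.
        beta = spec.alpha_beta_rad
        total_turn = 2 * math.pi - 2 * beta
        arc_len = R * total_turn
        if spec.length_nm - arc_len < 2 * h:
            if spec.kind == "pseudo_loop":
                raise ValueError(
                    "pseudo_loop needs length > loop arc to leave "
                    "crossing tails")
            dpsi = 2 * math.pi / n  # pure circle of circumference L
            return _walk(np.full(n - 1, dpsi), h)
        n_arc = max(int(round(arc_len / h)), 3)
        n_tail1 = max((n - n_arc) // 2, 1)
        dpsi = total_turn / n_arc
        turns = np.zeros(n - 1)
        turns[n_tail1 - 1:n_tail1 - 1 + n_arc] = dpsi
        return _walk(turns, h, psi0=beta)

    raise ValueError(f"spec.kind must be a shape kind, got {spec.kind!r}")


def circle_polyline(radius_nm: float, step_nm: float = 4.0) -> np.ndarray:
    """Closed regular-polygon circle at ~*step_nm* arc spacing.

    Built by the same tangent-walk as the other shapes, so the correlation
    between its segment tangents at arc separation l is exactly cos(l / R).
    """
    length = 2 * math.pi * radius_nm
    n = max(int(round(length / step_nm)), 3)
    h = length / n
    return _walk(np.full(n - 1, 2 * math.pi / n), h)


def simulate_contour(spec: ContourSpec,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    if spec.kind == "wlc":
        return simulate_wlc_contour(spec, rng)
    return simulate_shape_contour(spec)


# ---------------------------------------------------------------------------
# AFM images
# ---------------------------------------------------------------------------

@dataclass
class PlacedMolecule:
    contour: ContourSpec
    offset_nm: tuple[float, float]  # final centroid position in the field
    rotation_rad: float = 0.0


@dataclass
class AFMImageSpec:
    """Rasterized AFM field specification.

    Contours are stamped as ridges of Gaussian cross-section (peak
    ridge_height_nm, FWHM ridge_width_px) onto a zero background, then
    optional per-row polynomial offsets (scan-line bow) and white pixel noise
    are added. Molecules must lie fully inside the field unless
    allow_clipping is set (for border-rejection tests).
    """

    molecules: list[PlacedMolecule] = field(default_factory=list)
    image_px: int = 256
    pixel_size_nm: float = DEFAULT_PIXEL_NM
    ridge_height_nm: float = 0.5
    ridge_width_px: float = 2.5
    noise_sigma_nm: float = 0.0
    row_offsets: np.ndarray | None = None  # (rows, k) polynomial coefficients
    allow_clipping: bool = False
    seed: int = 0

    @property
    def field_of_view_nm(self) -> float:
        return self.image_px * self.pixel_size_nm


def _stamp_ridge(heights: np.ndarray, poly_px: np.ndarray, fwhm_px: float,
                 peak: float) -> np.ndarray:
    """Stamp one polyline ridge; returns this molecule's height field.

    Along a smooth contour the nearest-segment Gaussian profile applies, but
    where the contour crosses itself the two strands stack: the contribution
    of the far-away part of the contour (more than ~2 widths along the arc)
    is added on top, so a self-crossing shows up at about twice the ridge
    height — as it does in a real topograph.
    """
    npx = heights.shape[0]
    sigma = fwhm_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    margin = int(math.ceil(4 * sigma)) + 1
    r0 = max(int(np.floor(poly_px[:, 1].min())) - margin, 0)
    r1 = min(int(np.ceil(poly_px[:, 1].max())) + margin + 1, npx)
    c0 = max(int(np.floor(poly_px[:, 0].min())) - margin, 0)
    c1 = min(int(np.ceil(poly_px[:, 0].max())) + margin + 1, npx)
    if r0 >= r1 or c0 >= c1:
        return np.zeros_like(heights)
    rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
    pts = np.column_stack([cc.ravel() + 0.5, rr.ravel() + 0.5])  # pixel centres

    a = poly_px[:-1]
    ab = np.diff(poly_px, axis=0)
    nseg = len(a)
    l2 = np.maximum((ab ** 2).sum(axis=1), 1e-300)
    seg_len = float(np.mean(np.sqrt(l2)))
    min_sep = max(int(math.ceil(2.5 * fwhm_px / max(seg_len, 1e-9))), 2)
    seg_idx = np.arange(nseg)

    h = np.empty(len(pts))
    chunk = max(int(2e6 / max(nseg, 1)), 1)
    for s in range(0, len(pts), chunk):
        p = pts[s:s + chunk]
        t = np.clip(((p[:, None, :] - a[None]) * ab[None]).sum(-1) / l2[None],
                    0.0, 1.0)
        diff = p[:, None, :] - (a[None] + t[..., None] * ab[None])
        d2 = (diff ** 2).sum(-1)
        near = np.argmin(d2, axis=1)
        h1 = peak * np.exp(-d2[np.arange(len(p)), near] / (2.0 * sigma ** 2))
        far = np.abs(seg_idx[None, :] - near[:, None]) >= min_sep
        d2_far = np.where(far, d2, np.inf).min(axis=1)
        h2 = peak * np.exp(-d2_far / (2.0 * sigma ** 2))
        h[s:s + chunk] = h1 + np.where(h2 > 0.02 * peak, h2, 0.0)

    out = np.zeros_like(heights)
    out[r0:r1, c0:c1] = h.reshape(rr.shape)
    return out


def rasterize_afm_image(spec: AFMImageSpec) -> tuple[AFMImage, list[dict]]:
    """Render the field; returns (image, per-molecule ground truth).

    Ground-truth entries carry the molecule kind, its transformed centerline
    polyline (nm, image coordinates: x right, y down), its contour parameters
    and an overlap flag set when the molecule's rasterized footprint touches
    another molecule's (selection-filter tests use this).
    """
    rng = np.random.default_rng(spec.seed)
    npx = spec.image_px
    heights = np.zeros((npx, npx))
    fov = spec.field_of_view_nm
    half_w_nm = 0.5 * spec.ridge_width_px * spec.pixel_size_nm

    fields = []
    truth: list[dict] = []
    for mol in spec.molecules:
        poly = simulate_contour(mol.contour, rng=None)
        poly = transform(poly, mol.rotation_rad, mol.offset_nm)
        if not spec.allow_clipping:
            lo = poly.min() - half_w_nm
            hi = poly.max() + half_w_nm
            if lo < 0 or hi > fov:
                raise ValueError(
                    "molecule extends outside the field of view "
                    f"([{lo:.1f}, {hi:.1f}] nm vs [0, {fov:.1f}]); "
                    "set allow_clipping=True to permit this")
        f = _stamp_ridge(heights, poly / spec.pixel_size_nm,
                         spec.ridge_width_px, spec.ridge_height_nm)
        fields.append(f)
        truth.append({
            "kind": mol.contour.kind,
            "polyline_nm": poly,
            "length_nm": mol.contour.length_nm,
            "radius_nm": mol.contour.radius_nm,
            "persistence_nm": mol.contour.persistence_nm,
            "overlaps": False,
        })
        heights = np.maximum(heights, f)

    # overlap flags from thresholded per-molecule footprints
    thr = 0.5 * spec.ridge_height_nm
    masks = [f > thr for f in fields]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                truth[i]["overlaps"] = truth[j]["overlaps"] = True

    if spec.row_offsets is not None:
        coeffs = np.atleast_2d(np.asarray(spec.row_offsets, dtype=float))
        if coeffs.shape[0] not in (1, npx):
            raise ValueError("row_offsets must have 1 or image_px rows")
        u = np.arange(npx) / (npx - 1)
        rows = np.vstack([np.polynomial.polynomial.polyval(u, c)
                          for c in coeffs])
        heights += rows if rows.shape[0] == npx else np.tile(rows, (npx, 1))

    if spec.noise_sigma_nm > 0:
        heights = heights + rng.normal(0.0, spec.noise_sigma_nm, heights.shape)

    return AFMImage(heights, spec.pixel_size_nm), truth
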