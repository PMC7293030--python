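"""AFM height-map analysis: single-DNA segmentation, tracing, classification.

The pipeline mirrors a standard single-molecule AFM workflow on 1 um x 1 um,
256 x 256 px topographs of surface-deposited DNA:

    level_rows        per-row polynomial background alignment (degree 5)
    segment_molecules threshold, 8-connected components, selection filters
    find_endpoints    k-cosine boundary-curvature maxima (skeleton fallback)
    trace_centerline  boundary averaged on either side of the endpoints
    classify_shape    loop / linear / c-shape / s-shape / pseudo-loop
    measure_loop_diameter  d = 2*sqrt(A/pi) + molecule width

Coordinates: image origin top-left, x = column * pixel_size, y = row *
pixel_size with y increasing downward; all lengths in nanometres.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from . import geometry

DEFAULT_PIXEL_NM = 1000.0 / 256
DEFAULT_WIDTH_PX = 2.5          # imaged DNA molecule width in the thresholded mask
DEFAULT_THRESHOLD_NM = 0.25     # half the ~0.5 nm expected DNA ridge height
HEIGHT_RANGE_NM = (0.3, 0.8)    # plausible median ridge height for flat-lying DNA
EXTENSION_CUT = 0.6             # fractional extension below which a molecule is
                                # in an intermediate folding state
MIN_LENGTH_FRACTION = 0.8       # traced/expected contour length for selection
BP_PER_NM = 1.0 / 0.34


def expected_length_nm(n_bp: float) -> float:
    """Contour length of B-form DNA at 0.34 nm/bp."""
    return 0.34 * n_bp


def intermediate_extension_threshold(contour_length_nm: float,
                                     fraction: float = EXTENSION_CUT) -> float:
    """Extension below which a molecule counts as an intermediate folding state."""
    return fraction * contour_length_nm


def loop_diameter_from_area(hole_area_nm2: float,
                            width_px: float = DEFAULT_WIDTH_PX,
                            pixel_size_nm: float = DEFAULT_PIXEL_NM) -> float:
    """Loop diameter: equivalent-circle diameter of the unfilled area plus the
    imaged molecule width. Because tip broadening shrinks the hole by about one
    molecule width, this estimates the centerline diameter of the DNA loop."""
    return 2.0 * math.sqrt(hole_area_nm2 / math.pi) + width_px * pixel_size_nm


@dataclass
class AFMImage:
    """Topograph: per-pixel heights in nm, square field."""

    heights: np.ndarray
    pixel_size_nm: float = DEFAULT_PIXEL_NM

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or self.heights.shape[0] != self.heights.shape[1]:
            raise ValueError("AFM image must be square")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class MoleculeRecord:
    """One segmented molecule with its trace and selection flags."""

    label: int
    mask: np.ndarray                 # component mask in a padded bounding box
    heights: np.ndarray              # matching height crop
    origin_px: tuple[int, int]       # (row, col) of mask[0, 0] in the image
    pixel_size_nm: float
    expected_length_nm: float
    crop_mask: np.ndarray | None = None   # 200 nm x 200 nm display crop
    centerline_nm: np.ndarray | None = None  # image coordinates
    endpoints_nm: np.ndarray | None = None
    contour_length_nm: float = np.nan
    extension_nm: float = np.nan
    has_hole: bool = False
    hole_area_px: int = 0
    has_crossing: bool = False   # stacked-strand pixels at ~2x ridge height
    n_junctions: int = 0
    flags: dict = field(default_factory=dict)
    trace_flags: list[str] = field(default_factory=list)
    reasons: list[str] = field(default_factory=list)

    @property
    def accepted(self) -> bool:
        return not self.reasons

    @property
    def fractional_extension(self) -> float:
        return self.extension_nm / self.contour_length_nm


@dataclass
class ShapeCall:
    shape: str                       # loop | linear | c_shape | s_shape | pseudo_loop
    fractional_extension: float
    hole_area_nm2: float | None = None
    diameter_nm: float | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# leveling
# ---------------------------------------------------------------------------

def level_rows(img: AFMImage, degree: int = 5,
               fg_threshold_nm: float = DEFAULT_THRESHOLD_NM) -> AFMImage:
    """Align scan rows by fitting and subtracting a per-row polynomial.

    Each row's polynomial (default degree 5) is fitted to background pixels
    only, estimated in two passes: a sigma-clipped fit to the raw row followed
    by a refit that excludes pixels more than *fg_threshold_nm* above the
    first-pass background. Rows left with too few background pixels fall back
    to an all-pixel fit with a warning.
    """
    h = img.heights
    if h.shape[1] < degree + 2:
        raise ValueError("image width must exceed polynomial degree + 1")
    u = np.linspace(-1.0, 1.0, h.shape[1])
    out = np.empty_like(h)
    for r in range(h.shape[0]):
        row = h[r]
        keep = np.ones(len(row), dtype=bool)
        fit = np.zeros_like(row)
        for _ in range(3):  # sigma-clipped first pass
            coeff = np.polynomial.polynomial.polyfit(u[keep], row[keep], degree)
            fit = np.polynomial.polynomial.polyval(u, coeff)
            resid = row - fit
            scale = np.std(resid[keep])
            if scale == 0:
                break
            keep = resid < 2.5 * scale
            if keep.sum() < degree + 2:
                keep = np.ones(len(row), dtype=bool)
                break
        background = row - fit < fg_threshold_nm
        if background.sum() < degree + 2:
            warnings.warn(f"row {r} is almost entirely foreground; "
                          "using all-pixel fit", stacklevel=2)
            background = np.ones(len(row), dtype=bool)
        coeff = np.polynomial.polynomial.polyfit(u[background], row[background],
                                                 degree)
        out[r] = row - np.polynomial.polynomial.polyval(u, coeff)
    return AFMImage(out, img.pixel_size_nm)


# ---------------------------------------------------------------------------
# skeleton graph helpers
# ---------------------------------------------------------------------------

_NEIGHBOURS = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
               if (dr, dc) != (0, 0)]


def _skeleton_graph(mask: np.ndarray) -> nx.Graph:
    skel = morphology.skeletonize(mask)
    g = nx.Graph()
    rows, cols = np.nonzero(skel)
    pix = set(zip(rows.tolist(), cols.tolist()))
    g.add_nodes_from(pix)
    for (r, c) in pix:
        for dr, dc in _NEIGHBOURS:
            q = (r + dr, c + dc)
            if q in pix:
                g.add_edge((r, c), q, weight=math.hypot(dr, dc))
    # drop redundant diagonal shortcuts where an L-shaped path exists
    for (p, q) in list(g.edges):
        if abs(p[0] - q[0]) + abs(p[1] - q[1]) == 2:
            if g.has_edge(p, (p[0], q[1])) and g.has_edge((p[0], q[1]), q):
                g.remove_edge(p, q)
            elif g.has_edge(p, (q[0], p[1])) and g.has_edge((q[0], p[1]), q):
                g.remove_edge(p, q)
    return g


def _prune_spurs(g: nx.Graph, min_len: float = 3.0) -> nx.Graph:
    """Remove tip branches shorter than *min_len* px that end at a junction."""
    g = g.copy()
    changed = True
    while changed:
        changed = False
        tips = [n for n in g if g.degree(n) == 1]
        for tip in tips:
            if tip not in g or g.degree(tip) != 1:
                continue
            path = [tip]
            length = 0.0
            node = tip
            while True:
                nbrs = [m for m in g.neighbors(node) if m not in path]
                if not nbrs or g.degree(node) > 2:
                    break
                nxt = nbrs[0]
                length += g.edges[node, nxt]["weight"]
                path.append(nxt)
                node = nxt
                if g.degree(node) != 2 or length >= min_len:
                    break
            if length < min_len and g.degree(node) > 2:
                g.remove_nodes_from(path[:-1])
                changed = True
    return g


def _graph_length(g: nx.Graph) -> float:
    return sum(d["weight"] for _, _, d in g.edges(data=True))


def _junction_clusters(junctions, radius_px: int = 2) -> int:
    """Count distinct crossings: junction pixels within *radius_px* are one."""
    remaining = list(junctions)
    clusters = 0
    while remaining:
        seed = remaining.pop()
        clusters += 1
        group = [seed]
        while group:
            p = group.pop()
            near = [q for q in remaining
                    if max(abs(p[0] - q[0]), abs(p[1] - q[1])) <= radius_px]
            for q in near:
                remaining.remove(q)
                group.append(q)
    return clusters


def _longest_tip_path(g: nx.Graph) -> list | None:
    tips = [n for n in g if g.degree(n) == 1]
    if len(tips) < 2:
        return None
    best, best_len = None, -1.0
    lengths = dict(nx.all_pairs_dijkstra_path_length(g)) if len(tips) > 6 else None
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            try:
                if lengths is not None:
                    d = lengths[tips[i]][tips[j]]
                else:
                    d = nx.dijkstra_path_length(g, tips[i], tips[j])
            except (nx.NetworkXNoPath, KeyError):
                continue
            if d > best_len:
                best_len = d
                best = (tips[i], tips[j])
    if best is None:
        return None
    return nx.dijkstra_path(g, *best)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _holes(mask: np.ndarray) -> tuple[bool, int]:
    """Background regions (4-connected) fully enclosed by the mask."""
    bg = ~mask
    lbl, n = ndimage.label(bg, structure=np.array([[0, 1, 0], [1, 1, 1],
                                                   [0, 1, 0]]))
    border = np.unique(np.concatenate([lbl[0], lbl[-1], lbl[:, 0], lbl[:, -1]]))
    areas = ndimage.sum_labels(bg, lbl, index=np.arange(1, n + 1))
    hole_px = sum(int(a) for k, a in enumerate(areas, start=1)
                  if k not in border and a >= 1)
    return hole_px > 0, hole_px


def segment_molecules(img: AFMImage, expected_length: float,
                      threshold_nm: float = DEFAULT_THRESHOLD_NM,
                      height_range_nm: tuple[float, float] = HEIGHT_RANGE_NM,
                      min_length_fraction: float = MIN_LENGTH_FRACTION,
                      isolation_px: int = 1,
                      crop_nm: float = 200.0) -> list[MoleculeRecord]:
    """Threshold, label and select single DNA molecules.

    Components are kept when they (i) keep at least *isolation_px* background
    pixels to any other component, (ii) do not touch the image border,
    (iii) trace to a contour length of at least *min_length_fraction* of the
    expected value (molecules lying flat on the surface), and (iv) have a
    median ridge height inside *height_range_nm*. All components are returned;
    rejected ones carry their reasons and ``accepted`` is False.
    """
    heights = img.heights
    ps = img.pixel_size_nm
    mask = heights > threshold_nm
    lbl = measure.label(mask, connectivity=2)
    n_labels = lbl.max()
    crop_px = int(round(crop_nm / ps))
    records: list[MoleculeRecord] = []
    for k in range(1, n_labels + 1):
        comp = lbl == k
        rows, cols = np.nonzero(comp)
        pad = 3
        r0, r1 = rows.min() - pad, rows.max() + pad + 1
        c0, c1 = cols.min() - pad, cols.max() + pad + 1
        r0c, c0c = max(r0, 0), max(c0, 0)
        r1c, c1c = min(r1, lbl.shape[0]), min(c1, lbl.shape[1])
        sub = comp[r0c:r1c, c0c:c1c]
        rec = MoleculeRecord(
            label=k, mask=sub, heights=heights[r0c:r1c, c0c:c1c],
            origin_px=(r0c, c0c), pixel_size_nm=ps,
            expected_length_nm=expected_length)

        in_field = rows.min() > 0 and cols.min() > 0 and \
            rows.max() < lbl.shape[0] - 1 and cols.max() < lbl.shape[1] - 1
        rec.flags["in_field"] = in_field
        if not in_field:
            rec.reasons.append("in-field")

        grown = ndimage.binary_dilation(comp, iterations=isolation_px)
        isolated = not np.any(grown & mask & ~comp)
        rec.flags["isolated"] = isolated
        if not isolated:
            rec.reasons.append("isolation")

        # the ridge crest height (90th percentile of the thresholded
        # footprint; the footprint median sits on the ridge flank and is
        # insensitive to how tall the object actually is)
        crest = float(np.percentile(heights[comp], 90))
        height_ok = height_range_nm[0] <= crest <= height_range_nm[1]
        rec.flags["height_ok"] = height_ok
        rec.flags["ridge_height_nm"] = crest
        if not height_ok:
            rec.reasons.append("height")

        # two stacked strands image at about twice the single-strand ridge
        # height (the threshold is half of it); a couple of such pixels mark
        # a self-crossing
        rec.has_crossing = int((heights[comp] >= 3.0 * threshold_nm).sum()) >= 2

        rec.has_hole, rec.hole_area_px = _holes(sub)
        try:
            find_endpoints(rec)
            trace_centerline(rec)
        except Exception as exc:  # tracing failed outright
            rec.trace_flags.append(f"trace-error:{exc}")
        length_ok = (np.isfinite(rec.contour_length_nm) and
                     rec.contour_length_nm >= min_length_fraction * expected_length)
        rec.flags["length_ok"] = length_ok
        if not length_ok:
            rec.reasons.append("length")

        # 200 nm x 200 nm display crop centred on the component centroid
        cr, cc_ = int(round(rows.mean())), int(round(cols.mean()))
        half = crop_px // 2
        rr0, cc0 = max(cr - half, 0), max(cc_ - half, 0)
        rec.crop_mask = comp[rr0:rr0 + crop_px, cc0:cc0 + crop_px]
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# endpoints and centerline
# ---------------------------------------------------------------------------

def _ridge_length_estimate(record: MoleculeRecord,
                           ridge_height_nm: float = 0.5,
                           width_px: float = DEFAULT_WIDTH_PX) -> float:
    """Contour length from the integrated ridge height.

    A Gaussian ridge of peak h and cross-section sigma carries a height
    integral of h * sigma * sqrt(2*pi) per unit length, and stacked strands
    at a self-crossing simply count twice, so the total height in the
    molecule's neighbourhood divided by that factor estimates the contour
    length independently of the mask topology.
    """
    ps = record.pixel_size_nm
    sigma_px = width_px / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    # sum over the whole neighbourhood: zero-mean background noise cancels
    region = ndimage.binary_dilation(record.mask, iterations=3)
    total = float(record.heights[region].sum())  # nm * px^2
    per_px = ridge_height_nm * sigma_px * math.sqrt(2.0 * math.pi)
    return total / per_px * ps


def _boundary(mask: np.ndarray) -> np.ndarray:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    b = max(contours, key=len)
    if np.allclose(b[0], b[-1]):
        b = b[:-1]
    return b  # (M, 2) of (row, col), sub-pixel


def find_endpoints(record: MoleculeRecord, k: int = 5,
                   percentile: float = 90.0,
                   min_separation_fraction: float = 0.25):
    """Locate the two free DNA ends as boundary-curvature maxima.

    Boundary curvature uses the k-cosine measure: the cosine of the angle at
    point i between the chords to points i-k and i+k; a free end is a sharp
    boundary spike where that cosine approaches 1. The two highest local
    maxima above the 90th percentile, separated by at least a quarter of the
    boundary, are the endpoints. With no qualifying maxima and an enclosed
    hole, the record is flagged endpoint-free (a closed loop); otherwise the
    farthest pair of skeleton tips is used and flagged as a fallback.

    Stores endpoints (nm) and the boundary/indices on the record; returns the
    endpoint array or None for endpoint-free masks.
    """
    b = _boundary(record.mask)
    m = len(b)
    k = min(k, max(m // 8, 1))
    idx = np.arange(m)
    prev = b[(idx - k) % m]
    nxt = b[(idx + k) % m]
    v1 = prev - b
    v2 = nxt - b
    dot = (v1 * v2).sum(axis=1)
    norm = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    cosang = np.where(norm > 0, dot / norm, -1.0)

    # a free DNA end is a *convex* spike: the chord midpoint between the two
    # flanking boundary points lies inside the mask. Concave notches (e.g. at
    # a self-crossing) score the same k-cosine but their midpoint falls in the
    # background, so they are excluded here.
    mid = np.rint(0.5 * (prev + nxt)).astype(int)
    mid[:, 0] = np.clip(mid[:, 0], 0, record.mask.shape[0] - 1)
    mid[:, 1] = np.clip(mid[:, 1], 0, record.mask.shape[1] - 1)
    convex = record.mask[mid[:, 0], mid[:, 1]]

    is_max = (cosang >= np.roll(cosang, 1)) & (cosang > np.roll(cosang, -1))
    cut = np.percentile(cosang, percentile)
    cand = np.flatnonzero(is_max & convex & (cosang > cut))
    record._boundary = b  # cached for trace_centerline

    endpoints_idx = None
    if cand.size >= 2:
        order = cand[np.argsort(cosang[cand])[::-1]]
        first = order[0]
        min_sep = min_separation_fraction * m
        for second in order[1:]:
            sep = abs(second - first)
            if min(sep, m - sep) >= min_sep:
                endpoints_idx = (min(first, second), max(first, second))
                break

    if endpoints_idx is None:
        g = _prune_spurs(_skeleton_graph(record.mask))
        tips = [n for n in g if g.degree(n) == 1]
        if len(tips) < 2:
            if record.has_hole or len(tips) == 0:
                record.trace_flags.append("endpoint_free")
                record.endpoints_nm = None
                return None
        if len(tips) >= 2:
            # farthest pair of skeleton tips, mapped to the nearest boundary pts
            best, best_d = None, -1.0
            for i in range(len(tips)):
                for j in range(i + 1, len(tips)):
                    d = math.dist(tips[i], tips[j])
                    if d > best_d:
                        best_d, best = d, (tips[i], tips[j])
            record.trace_flags.append("auto_fallback")
            pts = np.array(best, dtype=float)
            endpoints_idx = tuple(sorted(
                int(np.argmin(((b - p) ** 2).sum(axis=1))) for p in pts))
        else:
            record.trace_flags.append("endpoint_free")
            record.endpoints_nm = None
            return None

    record._endpoint_idx = endpoints_idx
    ep_px = b[list(endpoints_idx)]
    record.endpoints_nm = _px_to_nm(ep_px, record)
    return record.endpoints_nm


def _px_to_nm(points_rc: np.ndarray, record: MoleculeRecord) -> np.ndarray:
    """(row, col) crop pixels -> (x, y) nm in full-image coordinates."""
    r0, c0 = record.origin_px
    pts = np.atleast_2d(points_rc)
    return np.column_stack([(pts[:, 1] + c0) * record.pixel_size_nm,
                            (pts[:, 0] + r0) * record.pixel_size_nm])


def trace_centerline(record: MoleculeRecord) -> np.ndarray | None:
    """Trace the molecule's longitudinal axis.

    For a simple open molecule the boundary is split at the two endpoints and
    the two arcs are resampled to matching point counts and averaged
    pointwise. Masks with enclosed holes or skeleton junctions (self-crossing
    molecules) fall back to the skeleton: the centerline is the longest
    tip-to-tip geodesic and the contour length is the total skeleton length;
    such records are flagged. The centerline is resampled at 1-px arc spacing;
    contour length and end-to-end extension are stored on the record.
    """
    ps = record.pixel_size_nm
    g = _prune_spurs(_skeleton_graph(record.mask))
    junctions = [n for n in g if g.degree(n) > 2]
    has_cycle = g.number_of_edges() >= g.number_of_nodes() and \
        g.number_of_nodes() > 0
    record.n_junctions = len(junctions)

    use_skeleton = record.has_hole or record.has_crossing or junctions or \
        has_cycle or getattr(record, "_endpoint_idx", None) is None

    if not use_skeleton:
        b = record._boundary
        i, j = record._endpoint_idx
        arc1 = b[i:j + 1]
        arc2 = np.concatenate([b[j:], b[:i + 1]])[::-1]
        if len(arc1) < 2 or len(arc2) < 2:
            use_skeleton = True
        else:
            npts = max(len(arc1), len(arc2))
            a1 = geometry.resample_to_count(arc1, npts)
            a2 = geometry.resample_to_count(arc2, npts)
            centre = 0.5 * (a1 + a2)
            cl = _px_to_nm(centre, record)
            # the mask's rounded end caps extend half a molecule width past
            # the true contour ends; trim that overhang from both ends
            trim = 0.5 * DEFAULT_WIDTH_PX * ps
            total = geometry.polyline_length(cl)
            if total > 3 * trim:
                cl = geometry.sub_polyline(cl, trim, total - trim)
            cl = geometry.resample_polyline(cl, ps)
            record.centerline_nm = cl
            record.contour_length_nm = geometry.polyline_length(cl)
            record.extension_nm = float(np.hypot(*(cl[-1] - cl[0])))
            record.endpoints_nm = np.vstack([cl[0], cl[-1]])
            return cl

    # skeleton route
    if g.number_of_nodes() == 0:
        record.contour_length_nm = 0.0
        record.extension_nm = 0.0
        return None
    record.trace_flags.append("skeleton_centerline")
    # at each strand crossing the skeleton collapses about one molecule
    # width of contour into a single node; compensate per junction cluster.
    # The height-integral estimate below is immune to crossings altogether
    # (stacked strands count twice), so take the larger of the two.
    n_crossings = _junction_clusters(junctions)
    total = _graph_length(g) * ps + n_crossings * DEFAULT_WIDTH_PX * ps
    total = max(total, _ridge_length_estimate(record))
    path = _longest_tip_path(g)
    if path is not None and len(path) >= 2:
        pts = np.array(path, dtype=float)
        if len(pts) >= 5:  # light smoothing against pixel staircase
            kern = np.ones(3) / 3.0
            inner = np.column_stack([
                np.convolve(pts[:, 0], kern, mode="valid"),
                np.convolve(pts[:, 1], kern, mode="valid")])
            pts = np.vstack([pts[0], inner, pts[-1]])
        cl = geometry.resample_polyline(_px_to_nm(pts, record), ps)
        record.centerline_nm = cl
        record.extension_nm = float(np.hypot(*(cl[-1] - cl[0])))
        record.endpoints_nm = np.vstack([cl[0], cl[-1]])
    else:  # closed loop without free ends
        record.centerline_nm = None
        record.extension_nm = 0.0
    record.contour_length_nm = max(
        total, geometry.polyline_length(record.centerline_nm)
        if record.centerline_nm is not None else 0.0)
    return record.centerline_nm


# ---------------------------------------------------------------------------
# classification and loop measurement
# ---------------------------------------------------------------------------

def classify_shape(record: MoleculeRecord,
                   extension_cut: float = EXTENSION_CUT,
                   smooth_nm: float = 10.0) -> ShapeCall:
    """Classify a traced molecule.

    Order of evidence: an enclosed hole makes a loop (a hole plus extended
    tails is still a loop, flagged); fractional extension >= 0.6 makes the
    molecule linear; a robust skeleton junction or a self-crossing centerline
    without a hole makes a pseudo-loop; otherwise the smoothed signed
    curvature decides c-shape (single sign; excursions shorter than
    *smooth_nm* of arc are ignored) versus s-shape (sign change).
    """
    frac = record.fractional_extension
    flags: list[str] = []
    if record.has_hole:
        if np.isfinite(frac) and frac >= extension_cut:
            flags.append("hole_with_extended_tails")
        call = ShapeCall("loop", float(frac), flags=flags)
        area = record.hole_area_px * record.pixel_size_nm ** 2
        call.hole_area_nm2 = area
        call.diameter_nm = loop_diameter_from_area(
            area, pixel_size_nm=record.pixel_size_nm)
        return call
    if not np.isfinite(frac):
        raise ValueError("record has no traced centerline")
    if frac >= extension_cut:
        return ShapeCall("linear", float(frac), flags=flags)
    crossing = record.has_crossing or record.n_junctions > 0
    if not crossing and record.centerline_nm is not None:
        crossing = geometry.self_intersects(record.centerline_nm)
    if crossing:
        return ShapeCall("pseudo_loop", float(frac), flags=flags)

    cl = record.centerline_nm
    spacing = 2.0 * record.pixel_size_nm
    cl_s = geometry.resample_polyline(cl, spacing)
    kappa = geometry.signed_curvature(cl_s)
    win = max(int(round(smooth_nm / spacing)), 1)
    if len(kappa) >= win:
        kappa = np.convolve(kappa, np.ones(win) / win, mode="valid")
    sign = np.sign(kappa)
    sign[np.abs(kappa) < 1e-3 * np.abs(kappa).max()] = 0.0
    # runs of constant non-zero sign, measured in arc length
    runs = []
    for s in sign:
        if s == 0:
            continue
        if runs and runs[-1][0] == s:
            runs[-1][1] += spacing
        else:
            runs.append([s, spacing])
    robust = [r[0] for r in runs if r[1] >= smooth_nm]
    changes = sum(1 for a, b in zip(robust, robust[1:]) if a != b)
    shape = "c_shape" if changes == 0 else "s_shape"
    return ShapeCall(shape, float(frac), flags=flags)


def measure_loop_diameter(record: MoleculeRecord,
                          width_px: float = DEFAULT_WIDTH_PX) -> float:
    """Loop diameter d = 2*sqrt(A/pi) + width, A = enclosed unfilled area."""
    if not record.has_hole or record.hole_area_px < 1:
        raise ValueError("not a loop: mask encloses no unfilled area")
    area_nm2 = record.hole_area_px * record.pixel_size_nm ** 2
    return loop_diameter_from_area(area_nm2, width_px, record.pixel_size_nm)
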