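"""Whole-bone mechanical properties from load-displacement records.

Covers the three test types used for murine bone fragility work:

* three-point bending of the femur mid-diaphysis (structural
  properties: stiffness, yield, ultimate, post-yield displacement,
  work-to-fracture);
* compression of a vertebral body (ultimate load);
* three-point bending of a micro-notched femur (crack-initiation
  toughness K_c from peak load and notch geometry, using the
  thin-walled-pipe circumferential through-crack geometry factor).

Yield is located by the 0.9-secant criterion (the displacement at which
the secant stiffness from the toe-corrected origin falls to 90% of the
elastic stiffness); an offset-yield criterion is available by flag.
Work terms are N*mm = mJ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .phantoms import LoadDisplacementCurve

__all__ = [
    "MechanicalProperties",
    "NotchGeometry",
    "analyze_curve",
    "analyze_vb_compression",
    "measure_notch_geometry",
    "compute_crack_initiation_toughness",
    "takahashi_bending_factor",
    "NotchNotDetectedError",
]


class NotchNotDetectedError(ValueError):
    """No contiguous missing arc found at the notch plane."""


@dataclass
class MechanicalProperties:
    stiffness: float       # N/mm
    yield_force: float     # N
    yield_displacement: float  # mm (from corrected origin)
    ultimate_force: float  # N
    pyd: float             # mm
    w_f: float             # mJ
    py_wf: float           # mJ
    failure_displacement: float  # mm
    origin: float          # toe-corrected zero-displacement, mm (raw axis)
    k_c: float | None = None  # MPa*sqrt(m), notched tests only
    yield_criterion: str = "secant90"
    flags: dict | None = None


@dataclass(frozen=True)
class NotchGeometry:
    """Annular section with a through-wall circumferential notch."""

    r_o: float   # outer radius, mm
    r_i: float   # inner radius, mm
    theta: float  # notch half-angle, rad

    def __post_init__(self):
        if not (0 < self.r_i < self.r_o):
            raise ValueError("need 0 < r_i < r_o")
        if not (0 < self.theta < np.pi):
            raise ValueError("theta must be in (0, pi)")

    @property
    def r_m(self) -> float:
        return 0.5 * (self.r_o + self.r_i)

    @property
    def t(self) -> float:
        return self.r_o - self.r_i


def _fit_r2(dd, ff):
    a, b_ = np.polyfit(dd, ff, 1)
    resid = ff - (a * dd + b_)
    ss_tot = np.sum((ff - ff.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return a, b_, r2


def _stiffest_window_fit(d, f, f_lo, f_hi, min_points=8):
    """Linear fit of the elastic limb restricted to forces in [f_lo, f_hi].

    Fast path: one regression over the whole band (noise-robust).  If
    that fit is poor (R^2 < 0.99, e.g. a toe region intrudes into the
    band), sliding windows of a quarter of the band are scanned and the
    stiffest fit with R^2 >= 0.99 wins (falling back to the best R^2).
    """
    i_ult = int(np.argmax(f))
    sel = np.nonzero((f[: i_ult + 1] >= f_lo) & (f[: i_ult + 1] <= f_hi))[0]
    if len(sel) < min_points:
        sel = np.arange(max(0, i_ult - min_points), i_ult + 1)
    lo, hi = sel[0], sel[-1] + 1
    slope, intercept, r2 = _fit_r2(d[lo:hi], f[lo:hi])
    if r2 >= 0.99:
        return slope, intercept, r2
    n_win = max(min_points, (hi - lo) // 4)
    best = None
    for start in range(lo, hi - n_win + 1, max(1, n_win // 4)):
        a, b_, r2w = _fit_r2(d[start:start + n_win], f[start:start + n_win])
        key = (r2w >= 0.99, a if r2w >= 0.99 else r2w)
        if best is None or key > best[0]:
            best = (key, a, b_, r2w)
    _, slope, intercept, r2 = best
    return slope, intercept, r2


def analyze_curve(
    curve: LoadDisplacementCurve,
    *,
    fit_range: tuple[float, float] = (0.2, 0.8),
    secant_fraction: float = 0.9,
    failure_fraction: float = 0.1,
    yield_criterion: str = "secant90",
    offset_mm: float = 0.01,
    toe_correction: bool = True,
    smooth_window: int = 0,
) -> MechanicalProperties:
    """Structural properties of a bending / monotonic failure test.

    The elastic stiffness is the slope of the best sliding-window linear
    fit between ``fit_range`` fractions of the ultimate force on the
    ascending limb; the toe-corrected origin back-extrapolates that fit
    to zero force.  Yield is the first point where the secant stiffness
    from the corrected origin drops below ``secant_fraction`` of the
    elastic stiffness (or the ``offset`` criterion by flag).  Failure is
    the first post-ultimate sample below ``failure_fraction`` of
    ultimate (else the last sample).  W_f integrates force over
    displacement from the corrected origin to failure; post-yield W_f
    from yield to failure.
    """
    d = curve.displacement
    f = curve.force
    flags = {}
    f_ult = float(f.max())
    # sample-to-sample differences estimate the noise sd without being
    # inflated by the curve's own trend
    noise_floor = 8.0 * float(np.std(np.diff(f)) / np.sqrt(2.0))
    if f_ult <= noise_floor or f_ult <= 0:
        raise ValueError("force never exceeds the noise floor")

    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        f_s = np.convolve(f, kernel, mode="same")
    else:
        f_s = f

    slope, intercept, r2 = _stiffest_window_fit(
        d, f_s, fit_range[0] * f_ult, fit_range[1] * f_ult)
    if r2 < 0.99:
        flags["poor_linear_fit"] = r2
        warnings.warn(f"no linear segment with R^2 >= 0.99 (best {r2:.4f}); "
                      "best-effort stiffness")
    origin = -intercept / slope if toe_correction else 0.0

    i_ult = int(np.argmax(f_s))
    dc = d - origin

    if yield_criterion == "secant90":
        with np.errstate(divide="ignore", invalid="ignore"):
            secant = np.where(dc > 0, f_s / dc, np.inf)
        # search above the elastic fit band and require the secant drop
        # to persist, so single noise dips cannot fake a yield point
        below = ((secant[: i_ult + 1] < secant_fraction * slope)
                 & (dc[: i_ult + 1] > 0)
                 & (f_s[: i_ult + 1] > fit_range[1] * f_ult))
        run = max(3, smooth_window)
        ok = np.convolve(below.astype(int), np.ones(run, dtype=int),
                         mode="valid") == run
        hits = np.nonzero(ok)[0]
        i_yield = int(hits[0]) if len(hits) else i_ult
    elif yield_criterion == "offset":
        line = slope * (dc - offset_mm)
        cand = np.nonzero((f_s[: i_ult + 1] <= line[: i_ult + 1]) & (dc[: i_ult + 1] > offset_mm))[0]
        i_yield = int(cand[0]) if len(cand) else i_ult
    else:
        raise ValueError(f"unknown yield_criterion {yield_criterion!r}")

    post = np.nonzero(f_s[i_ult:] < failure_fraction * f_ult)[0]
    if len(post):
        i_fail = i_ult + int(post[0])
    else:
        i_fail = len(f) - 1
        flags["no_failure_drop"] = True

    w_f = float(np.trapezoid(np.clip(f[: i_fail + 1], 0, None),
                             dc[: i_fail + 1])
                - 0.0)
    py_wf = float(np.trapezoid(np.clip(f[i_yield: i_fail + 1], 0, None),
                               dc[i_yield: i_fail + 1]))

    return MechanicalProperties(
        stiffness=float(slope),
        yield_force=float(f_s[i_yield]),
        yield_displacement=float(dc[i_yield]),
        ultimate_force=f_ult,
        pyd=float(dc[i_fail] - dc[i_yield]),
        w_f=w_f,
        py_wf=py_wf,
        failure_displacement=float(dc[i_fail]),
        origin=float(origin),
        yield_criterion=yield_criterion,
        flags=flags,
    )


def analyze_vb_compression(curve: LoadDisplacementCurve, *,
                           drop_fraction: float = 0.2,
                           convention: str = "first_failure") -> tuple[float, dict]:
    """Ultimate load of a vertebral-body compression test, N.

    ``first_failure`` (default): the running maximum before the first
    force drop exceeding ``drop_fraction`` of the running maximum.
    ``global_max``: plain maximum force.  A curve with no qualifying
    drop returns the global maximum with a truncation warning flag.
    """
    if curve.test_kind != "vb_compression":
        raise ValueError("curve.test_kind must be 'vb_compression'")
    f = curve.force
    flags = {}
    if convention == "global_max":
        return float(f.max()), flags
    running = np.maximum.accumulate(f)
    dropped = np.nonzero(running - f > drop_fraction * running)[0]
    if len(dropped):
        return float(running[dropped[0]]), flags
    flags["no_failure_drop"] = True
    warnings.warn("no force drop detected; reporting maximum force "
                  "(possibly truncated test)")
    return float(f.max()), flags


# ---------------------------------------------------------------------------
# notch geometry and crack-initiation toughness
# ---------------------------------------------------------------------------

def measure_notch_geometry(mask_stack: np.ndarray, voxel_size_mm: float,
                           *, n_angle_bins: int = 360) -> NotchGeometry:
    """Notch geometry from the uCT mask of a notched diaphyseal segment.

    The notch plane is the slice of minimal bone area.  Around the bone
    centroid of that slice, an angular sweep finds the contiguous arc
    with no bone (the machined notch); theta is half the subtended
    angle.  r_o and r_i are equivalent-area fits: mean periosteal and
    endosteal radii over the bins that do contain bone.
    """
    m = np.asarray(mask_stack, dtype=bool)
    if m.ndim != 3:
        raise ValueError("expected a 3D mask stack")
    areas = m.sum(axis=(1, 2))
    if not areas.any():
        raise NotchNotDetectedError("empty mask stack")
    z = int(np.argmin(np.where(areas > 0, areas, np.inf)))
    s = m[z]
    ys, xs = np.nonzero(s)
    cy, cx = ys.mean(), xs.mean()  # seed center: bone centroid
    # refine center by a Kasa circle fit to the periosteal boundary
    # (the centroid is biased away from the notch)
    for _ in range(2):
        ang = np.arctan2(ys - cy, xs - cx)
        rad = np.hypot(ys - cy, xs - cx)
        bins = ((ang + np.pi) / (2 * np.pi) * n_angle_bins).astype(int) % n_angle_bins
        r_out = np.zeros(n_angle_bins)
        np.maximum.at(r_out, bins, rad)
        occ = r_out > 0
        sel = occ[bins] & (rad >= r_out[bins] - 0.51)
        by, bx = ys[sel], xs[sel]
        a = np.column_stack([by, bx, np.ones(len(by))])
        b = by.astype(float) ** 2 + bx.astype(float) ** 2
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        cy, cx = sol[0] / 2.0, sol[1] / 2.0

    ang = np.arctan2(ys - cy, xs - cx)
    rad = np.hypot(ys - cy, xs - cx) * voxel_size_mm
    bins = ((ang + np.pi) / (2 * np.pi) * n_angle_bins).astype(int) % n_angle_bins
    occupied = np.zeros(n_angle_bins, dtype=bool)
    r_out = np.zeros(n_angle_bins)
    r_in = np.full(n_angle_bins, np.inf)
    np.maximum.at(r_out, bins, rad)
    np.minimum.at(r_in, bins, rad)
    occupied[bins] = True
    if occupied.all():
        raise NotchNotDetectedError("notch not detected: full annulus")
    # longest contiguous run of empty bins (circular), plus half a bin of
    # partial blockage at each edge
    empty = ~occupied
    doubled = np.concatenate([empty, empty])
    best = run = 0
    for v in doubled:
        run = run + 1 if v else 0
        best = max(best, run)
    best = min(best, n_angle_bins)
    missing_angle = (best + 1) * 2 * np.pi / n_angle_bins
    theta = missing_angle / 2.0
    half_pixel = 0.5 * voxel_size_mm
    r_o = float(r_out[occupied].mean()) + half_pixel
    r_i = float(r_in[occupied].mean()) - half_pixel
    return NotchGeometry(r_o=r_o, r_i=max(r_i, 1e-6), theta=float(theta))


# Geometry factor for a circumferential through-wall crack in a pipe
# under bending (Takahashi, Int J Pressure Vessels & Piping 79 (2002)
# 385-392, as used in rodent-femur notched-bending protocols):
#   F_b = 1 + A * (4.5967 (theta/pi)^1.5 + 2.6422 (theta/pi)^4.24)
#   A = (0.125 r_m/t - 0.25)^0.25   for  5 <= r_m/t <= 10
#   A = (0.4   r_m/t - 3.0 )^0.25   for 10 <  r_m/t <= 20
# valid for theta/pi <= 0.611.
_TAKAHASHI_C1, _TAKAHASHI_E1 = 4.5967, 1.5
_TAKAHASHI_C2, _TAKAHASHI_E2 = 2.6422, 4.24
_THETA_OVER_PI_MAX = 0.611


def takahashi_bending_factor(theta: float, rm_over_t: float) -> float:
    """F_b(theta/pi, r_m/t) for the pipe-bending through-crack geometry."""
    x = theta / np.pi
    if not (0 < x <= _THETA_OVER_PI_MAX):
        raise ValueError(f"theta/pi = {x:.3f} outside validity range "
                         f"(0, {_THETA_OVER_PI_MAX}]")
    tol = 1e-9
    if 5.0 - tol <= rm_over_t <= 10.0:
        a = (0.125 * rm_over_t - 0.25) ** 0.25
    elif 10.0 < rm_over_t <= 20.0 + tol:
        a = (0.4 * rm_over_t - 3.0) ** 0.25
    else:
        raise ValueError(f"r_m/t = {rm_over_t:.2f} outside validity range "
                         "[5, 20]")
    return 1.0 + a * (_TAKAHASHI_C1 * x**_TAKAHASHI_E1
                      + _TAKAHASHI_C2 * x**_TAKAHASHI_E2)


def compute_crack_initiation_toughness(
    curve: LoadDisplacementCurve,
    geom: NotchGeometry,
    *,
    force_N: float | None = None,
) -> float:
    """Crack-initiation toughness K_c in MPa*sqrt(m).

    The midspan three-point bending moment at peak load is
    M = F_ult * S / 4; the nominal bending stress at the notch section
    is sigma = M r_o / I with I the intact-annulus second moment; and

        K_c = F_b(theta/pi, r_m/t) * sigma * sqrt(pi r_m theta)

    with F_b the pipe-bending geometry factor above.  ``force_N``
    overrides the peak force read from the curve.
    """
    if curve.test_kind != "bend_notched":
        raise ValueError("curve.test_kind must be 'bend_notched'")
    f_ult = float(curve.force.max()) if force_N is None else float(force_N)
    moment = f_ult * curve.span / 4.0           # N*mm
    i_sect = np.pi / 4.0 * (geom.r_o**4 - geom.r_i**4)  # mm^4
    sigma = moment * geom.r_o / i_sect          # MPa
    fb = takahashi_bending_factor(geom.theta, geom.r_m / geom.t)
    # sqrt(pi * r_m * theta): r_m in mm -> convert to m for MPa*sqrt(m)
    return float(fb * sigma * np.sqrt(np.pi * geom.r_m * 1e-3 * geom.theta))
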