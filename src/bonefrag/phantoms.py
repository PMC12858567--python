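"""Synthetic inputs with analytically known ground truth.

Every generator in this module returns both the synthetic measurement
(a voxel volume, a load-displacement curve, a CPMG echo train, or a
cohort table) and a ground-truth record describing the quantities the
downstream analysis is supposed to recover.  Downstream modules are
validated against these records, never against hand-entered numbers.

Conventions
-----------
* Voxel arrays are indexed ``(z, y, x)``; z is the scan axis and the
  loading axis of the compression model.
* A voxel belongs to a solid iff its *center* lies inside the analytic
  solid (unambiguous and convergent under refinement).
* Physical lengths are micrometres inside :class:`VoxelVolume`, and
  millimetres in the geometry specs and ground-truth records.
* All random draws come from a per-operation stream derived from
  ``(seed, operation tag)`` so adding one generator never perturbs the
  draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelVolume",
    "Calibration",
    "CPMGSignal",
    "CurveSpec",
    "LoadDisplacementCurve",
    "CohortSpec",
    "make_cortical_tube_phantom",
    "make_trabecular_lattice_phantom",
    "make_vertebral_phantom",
    "simulate_cpmg_signal",
    "simulate_bending_curve",
    "simulate_cohort_table",
]

# stable per-operation stream tags (never reorder; append only)
_STREAM = {
    "tube": 101,
    "lattice": 102,
    "vertebral": 103,
    "cpmg": 104,
    "curve": 105,
    "cohort": 106,
}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAM[op]])


class InvalidGeometryError(ValueError):
    """Phantom dimensions are inconsistent (e.g. inner radius >= outer)."""


@dataclass(frozen=True)
class Calibration:
    """Affine map from raw attenuation to mg HA/cm^3."""

    slope: float = 1.0
    intercept: float = 0.0

    def __post_init__(self):
        if not (self.slope > 0):
            raise ValueError("calibration slope must be > 0")


@dataclass
class VoxelVolume:
    """Calibrated density image.

    data : 3D float array, mg HA/cm^3, indexed (z, y, x)
    voxel_size : isotropic voxel edge, micrometres
    origin : physical offset of voxel (0,0,0) center, micrometres
    """

    data: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    calibration: Calibration = field(default_factory=Calibration)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("data must be a 3D array")
        if not (self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("density data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return (self.voxel_size * 1e-3) ** 3


def _centered_grid(n: int, voxel_um: float) -> np.ndarray:
    """Physical coordinates (um) of voxel centers, centered on 0."""
    return (np.arange(n) - (n - 1) / 2.0) * voxel_um


# ---------------------------------------------------------------------------
# cortical tube
# ---------------------------------------------------------------------------

def make_cortical_tube_phantom(
    outer_radius_mm: float,
    inner_radius_mm: float,
    length_mm: float,
    *,
    voxel_size_um: float = 12.0,
    tmd_mean: float = 1200.0,
    tmd_sd: float = 0.0,
    noise_sd: float = 0.0,
    porosity: float = 0.0,
    margin_mm: float = 0.1,
    seed: int = 0,
):
    """Hollow-cylinder phantom of a mid-diaphyseal cortical segment.

    Returns ``(VoxelVolume, ground_truth)`` where the ground truth holds
    the closed-form section properties of the annulus:

    * ``ct_ar``  = pi (r_o^2 - r_i^2)      cortical area, mm^2
    * ``tt_ar``  = pi r_o^2                total area, mm^2
    * ``ct_th``  = r_o - r_i               wall thickness, mm
    * ``i_min``  = pi/4 (r_o^4 - r_i^4)    min. second moment, mm^4
    * ``z_min``  = i_min / r_o             section modulus, mm^3
    * ``ct_po``  = requested porosity (voxel-exact count also recorded)

    ``porosity`` sets the fraction of annulus voxels whose density is set
    to background (simple intracortical pores, one voxel each).
    """
    r_o, r_i = float(outer_radius_mm), float(inner_radius_mm)
    if not (0 <= r_i < r_o):
        raise InvalidGeometryError(f"need 0 <= r_i < r_o, got r_i={r_i}, r_o={r_o}")
    if not (0.0 <= porosity < 1.0):
        raise ValueError("porosity must be in [0, 1)")
    under_resolved = voxel_size_um * 1e-3 > (r_o - r_i)
    if under_resolved:
        import warnings

        warnings.warn("voxel size exceeds wall thickness; annulus under-resolved")

    rng = _rng(seed, "tube")
    half_um = (r_o + margin_mm) * 1e3
    n_xy = int(np.ceil(2 * half_um / voxel_size_um))
    n_z = max(1, int(round(length_mm * 1e3 / voxel_size_um)))
    x = _centered_grid(n_xy, voxel_size_um)
    yy, xx = np.meshgrid(x, x, indexing="ij")
    rr = np.hypot(yy, xx) * 1e-3  # mm
    ring2d = (rr >= r_i) & (rr < r_o)
    mask = np.broadcast_to(ring2d, (n_z, n_xy, n_xy)).copy()

    n_bone = int(mask.sum())
    pore_mask = np.zeros_like(mask)
    if porosity > 0 and n_bone:
        idx = np.flatnonzero(mask.ravel())
        n_pores = int(round(porosity * n_bone))
        chosen = rng.choice(idx, size=n_pores, replace=False)
        pore_flat = np.zeros(mask.size, dtype=bool)
        pore_flat[chosen] = True
        pore_mask = pore_flat.reshape(mask.shape)
        mask = mask & ~pore_mask

    data = np.zeros((n_z, n_xy, n_xy), dtype=np.float32)
    if tmd_sd > 0:
        data[mask] = rng.normal(tmd_mean, tmd_sd, size=int(mask.sum()))
    else:
        data[mask] = tmd_mean
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)

    vol = VoxelVolume(data, voxel_size_um)
    gt = {
        "mask": mask,
        "pore_mask": pore_mask,
        "ct_ar": math.pi * (r_o**2 - r_i**2),
        "tt_ar": math.pi * r_o**2,
        "ct_th": r_o - r_i,
        "i_min": math.pi / 4.0 * (r_o**4 - r_i**4),
        "z_min": math.pi / 4.0 * (r_o**4 - r_i**4) / r_o,
        "ct_po": porosity,
        "ct_po_voxel": (pore_mask.sum() / n_bone) if n_bone else 0.0,
        "tmd_mean": tmd_mean,
        "under_resolved": under_resolved,
    }
    return vol, gt


# ---------------------------------------------------------------------------
# trabecular lattice
# ---------------------------------------------------------------------------

def _grid_graph_betti1(n_nodes: tuple[int, int, int]) -> int:
    """First Betti number of the full 3D grid graph (closed form E-V+1)."""
    nx_, ny_, nz_ = n_nodes
    v = nx_ * ny_ * nz_
    e = (nx_ - 1) * ny_ * nz_ + nx_ * (ny_ - 1) * nz_ + nx_ * ny_ * (nz_ - 1)
    return e - v + 1  # grid graph is connected


def make_trabecular_lattice_phantom(
    rod_diameter_mm: float,
    pitch_mm: float,
    n_cells: int = 3,
    *,
    style: str = "rods",
    voxel_size_um: float = 12.0,
    tmd_mean: float = 900.0,
    tmd_sd: float = 0.0,
    noise_sd: float = 0.0,
    margin_mm: float = 0.06,
    seed: int = 0,
):
    """Regular trabecular phantom with closed-form architecture.

    Two styles:

    ``"rods"``
        Orthogonal lattice of cylindrical rods of diameter ``d`` along
        all three axes, with axes on a cubic grid of pitch ``s``
        (``n_cells`` cells per side).  Ground truth: exact voxel-count
        BV/TV, ``tb_th = d`` (largest inscribed sphere in a rod), and
        connectivity from the rod graph's first Betti number
        (``conn_d = b1 / TV``).  Note the sphere-fitting *separation* of
        this geometry is set by the diagonal gaps between rod axes, so
        ``tb_sp``/``tb_n`` are recorded as the nominal ``s - d`` and
        ``1/s`` only.
    ``"plates"``
        Stack of parallel plates normal to z, thickness ``d``, pitch
        ``s``.  For this geometry the sphere-fitting metrics are exact
        closed forms: ``tb_th = d``, ``tb_sp = s - d``, ``tb_n = 1/s``.

    Returns ``(VoxelVolume, ground_truth)``.
    """
    d, s = float(rod_diameter_mm), float(pitch_mm)
    if not (0 < d < s):
        raise InvalidGeometryError(f"need 0 < d < s, got d={d}, s={s}")
    if style not in ("rods", "plates"):
        raise ValueError("style must be 'rods' or 'plates'")

    rng = _rng(seed, "lattice")
    extent_mm = n_cells * s + 2 * margin_mm
    n = int(np.ceil(extent_mm * 1e3 / voxel_size_um))
    c = _centered_grid(n, voxel_size_um) * 1e-3  # mm
    # lattice node coordinates (n_cells+1 per axis), centered
    nodes = (np.arange(n_cells + 1) - n_cells / 2.0) * s

    if style == "plates":
        dist_z = np.min(np.abs(c[:, None] - nodes[None, :]), axis=1)
        mask = np.broadcast_to((dist_z <= d / 2.0)[:, None, None], (n, n, n)).copy()
        b1 = 0
        n_components = n_cells + 1
    else:
        r = d / 2.0
        dmin = np.min(np.abs(c[:, None] - nodes[None, :]), axis=1)  # per-axis distance to nearest grid plane
        # rods along x: distance in (z, y); along y: (z, x); along z: (y, x)
        dz = dmin[:, None]
        dy = dmin[None, :]
        in_perp = np.hypot(dz, dy) <= r  # 2D template reused per orientation
        mask = np.zeros((n, n, n), dtype=bool)
        mask |= in_perp[:, :, None]  # x-rods: (z,y) template
        mask |= in_perp[:, None, :]  # y-rods: (z,x)
        mask |= in_perp[None, :, :]  # z-rods: (y,x)
        # clip rods to the lattice extent so end caps are flush
        half = n_cells * s / 2.0
        inside = (np.abs(c) <= half + d / 2.0)
        mask &= inside[:, None, None] & inside[None, :, None] & inside[None, None, :]
        b1 = _grid_graph_betti1((n_cells + 1,) * 3)
        n_components = 1

    data = np.zeros((n, n, n), dtype=np.float32)
    if tmd_sd > 0:
        data[mask] = rng.normal(tmd_mean, tmd_sd, size=int(mask.sum()))
    else:
        data[mask] = tmd_mean
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)

    vol = VoxelVolume(data, voxel_size_um)
    tv_mm3 = mask.size * (voxel_size_um * 1e-3) ** 3
    euler = n_components - b1
    gt = {
        "mask": mask,
        "bvtv": mask.sum() / mask.size,
        "tb_th": d,
        "tb_sp": s - d,
        "tb_n": 1.0 / s,
        "betti1": b1,
        "euler": euler,
        "conn_d": (1 - euler) / tv_mm3,
        "tv_mm3": tv_mm3,
        "tmd_mean": tmd_mean,
        "style": style,
    }
    return vol, gt


# ---------------------------------------------------------------------------
# vertebral body
# ---------------------------------------------------------------------------

def make_vertebral_phantom(
    *,
    height_mm: float = 1.2,
    semiaxis_y_mm: float = 0.9,
    semiaxis_x_mm: float = 0.7,
    shell_thickness_mm: float = 0.1,
    endplate_thickness_mm: float = 0.06,
    rod_diameter_mm: float = 0.08,
    pitch_mm: float = 0.3,
    voxel_size_um: float = 12.0,
    shell_tmd: float = 1100.0,
    rod_tmd: float = 800.0,
    tmd_sd: float = 0.0,
    noise_sd: float = 0.0,
    margin_mm: float = 0.06,
    seed: int = 0,
):
    """Idealized vertebral-body phantom: elliptical cortical shell with
    flat cranial/caudal end plates enclosing an orthogonal rod lattice.

    Shell and end plates take ``shell_tmd``; interior rods take
    ``rod_tmd``, giving a two-material volume whose per-bin voxel counts
    are known exactly for any mineral-density binning.  Returns
    ``(VoxelVolume, ground_truth)`` with per-material voxel counts and
    total bone voxel count.
    """
    t = float(shell_thickness_mm)
    if t < voxel_size_um * 1e-3:
        import warnings

        warnings.warn("shell thickness below voxel size; shell under-resolved")

    rng = _rng(seed, "vertebral")
    a_y, a_x = float(semiaxis_y_mm), float(semiaxis_x_mm)
    n_xy_y = int(np.ceil(2 * (a_y + margin_mm) * 1e3 / voxel_size_um))
    n_xy_x = int(np.ceil(2 * (a_x + margin_mm) * 1e3 / voxel_size_um))
    n_z = int(round(height_mm * 1e3 / voxel_size_um))
    cy = _centered_grid(n_xy_y, voxel_size_um) * 1e-3
    cx = _centered_grid(n_xy_x, voxel_size_um) * 1e-3
    cz = _centered_grid(n_z, voxel_size_um) * 1e-3
    yy, xx = np.meshgrid(cy, cx, indexing="ij")
    r_out = (yy / a_y) ** 2 + (xx / a_x) ** 2
    r_in = (yy / (a_y - t)) ** 2 + (xx / (a_x - t)) ** 2
    inside = r_out <= 1.0
    shell2d = inside & (r_in > 1.0)

    shell = np.broadcast_to(shell2d, (n_z, n_xy_y, n_xy_x)).copy()
    endplate = np.zeros((n_z, n_xy_y, n_xy_x), dtype=bool)
    n_plate = max(1, int(round(endplate_thickness_mm * 1e3 / voxel_size_um)))
    endplate[:n_plate] = inside
    endplate[-n_plate:] = inside

    # interior rod lattice clipped to the endosteal ellipse
    d, s = float(rod_diameter_mm), float(pitch_mm)
    nodes_y = np.arange(-a_y, a_y + 1e-9, s)
    nodes_y -= nodes_y.mean()
    nodes_x = np.arange(-a_x, a_x + 1e-9, s)
    nodes_x -= nodes_x.mean()
    nodes_z = np.arange(-height_mm / 2, height_mm / 2 + 1e-9, s)
    nodes_z -= nodes_z.mean()

    def _dmin(c, nodes):
        return np.min(np.abs(c[:, None] - nodes[None, :]), axis=1)

    dz = _dmin(cz, nodes_z)
    dy = _dmin(cy, nodes_y)
    dx = _dmin(cx, nodes_x)
    r = d / 2.0
    rods = np.zeros((n_z, n_xy_y, n_xy_x), dtype=bool)
    rods |= (np.hypot(dz[:, None], dy[None, :]) <= r)[:, :, None]  # x-rods
    rods |= (np.hypot(dz[:, None], dx[None, :]) <= r)[:, None, :]  # y-rods
    rods |= (np.hypot(dy[:, None], dx[None, :]) <= r)[None, :, :]  # z-rods
    rods &= np.broadcast_to(r_in <= 1.0, rods.shape)

    cortical = shell | endplate
    rods &= ~cortical
    mask = cortical | rods

    data = np.zeros(mask.shape, dtype=np.float32)
    for region, tmd in ((cortical, shell_tmd), (rods, rod_tmd)):
        nvox = int(region.sum())
        if tmd_sd > 0:
            data[region] = rng.normal(tmd, tmd_sd, size=nvox)
        else:
            data[region] = tmd
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)

    vol = VoxelVolume(data, voxel_size_um)
    gt = {
        "mask": mask,
        "cortical_mask": cortical,
        "rod_mask": rods,
        "n_bone_voxels": int(mask.sum()),
        "material_voxel_counts": {shell_tmd: int(cortical.sum()), rod_tmd: int(rods.sum())},
        "n_slices": n_z,
        "height_mm": height_mm,
    }
    return vol, gt


# ---------------------------------------------------------------------------
# CPMG echo train
# ---------------------------------------------------------------------------

@dataclass
class CPMGSignal:
    """A CPMG echo train: echo times (s, constant spacing) and amplitudes."""

    echo_times: np.ndarray
    amplitudes: np.ndarray
    echo_spacing: float

    def __post_init__(self):
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.echo_times.shape != self.amplitudes.shape:
            raise ValueError("echo_times and amplitudes must have equal length")
        if len(self.echo_times) >= 2:
            dt = np.diff(self.echo_times)
            if not np.allclose(dt, self.echo_spacing, rtol=1e-6):
                raise ValueError("echo times must be uniform at echo_spacing")
            if np.any(dt <= 0):
                raise ValueError("echo times must be strictly increasing")

    @property
    def n_echoes(self) -> int:
        return len(self.echo_times)


def simulate_cpmg_signal(
    compartments: list[tuple[float, float]],
    *,
    echo_spacing: float = 100e-6,
    n_echoes: int = 10_000,
    noise_sd: float = 0.0,
    signal_per_ul: float = 1.0,
    noise_family: str = "gaussian",
    seed: int = 0,
) -> tuple[CPMGSignal, dict]:
    """Multi-exponential CPMG decay.

    ``compartments`` is a list of ``(volume_ul, t2_s)`` pairs; the
    noiseless amplitude at echo k is ``sum_j c * v_j * exp(-t_k/T2_j)``
    with ``c = signal_per_ul``, so the t=0 extrapolation is ``c * sum v``.
    Default acquisition: 10,000 echoes at 100 us spacing.  Noise is
    additive Gaussian by default; ``noise_family="rician"`` applies
    magnitude (Rician) noise instead.
    """
    if n_echoes < 2:
        raise ValueError("n_echoes must be >= 2")
    if echo_spacing <= 0:
        raise ValueError("echo_spacing must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for v, t2 in compartments:
        if v < 0 or t2 <= 0:
            raise ValueError("compartment volumes must be >= 0 and T2 > 0")

    rng = _rng(seed, "cpmg")
    t = echo_spacing * np.arange(1, n_echoes + 1)
    sig = np.zeros_like(t)
    for v, t2 in compartments:
        sig += signal_per_ul * v * np.exp(-t / t2)
    if noise_sd > 0:
        if noise_family == "gaussian":
            sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
        elif noise_family == "rician":
            sig = np.hypot(sig + rng.normal(0.0, noise_sd, size=sig.shape),
                           rng.normal(0.0, noise_sd, size=sig.shape))
        else:
            raise ValueError(f"unknown noise_family {noise_family!r}")
    gt = {
        "compartments": [(float(v), float(t2)) for v, t2 in compartments],
        "total_volume_ul": float(sum(v for v, _ in compartments)),
        "signal_per_ul": signal_per_ul,
        "noise_sd": noise_sd,
    }
    return CPMGSignal(t, sig, echo_spacing), gt


# ---------------------------------------------------------------------------
# bending curves
# ---------------------------------------------------------------------------

@dataclass
class CurveSpec:
    """Piecewise-linear whole-bone test curve parameters.

    ``post_yield_displacement`` is measured from the yield knee to the
    onset of the terminal force drop.  ``failure_drop_fraction`` is the
    force fraction of ultimate below which the analysis declares
    failure.
    """

    stiffness: float = 112.0          # N/mm  (typical healthy mouse femur)
    yield_force: float = 14.2         # N
    ultimate_force: float = 15.7      # N
    post_yield_displacement: float = 0.2  # mm
    failure_drop_fraction: float = 0.1
    hardening_fraction: float = 0.4   # fraction of PYD spent rising to ultimate
    softening_level: float = 0.85     # force/ultimate at drop onset
    sampling_rate: float = 2000.0     # samples per mm
    noise_sd: float = 0.0             # N, added to force
    toe_displacement: float = 0.0     # mm of compliant toe before the elastic ramp
    seed: int = 0

    def __post_init__(self):
        if not (self.ultimate_force >= self.yield_force > 0):
            raise ValueError("need ultimate_force >= yield_force > 0")
        if self.stiffness <= 0:
            raise ValueError("stiffness must be > 0")
        if self.post_yield_displacement < 0:
            raise ValueError("post_yield_displacement must be >= 0")


@dataclass
class LoadDisplacementCurve:
    displacement: np.ndarray  # mm, monotone non-decreasing
    force: np.ndarray         # N
    test_kind: str = "bend_3pt"  # bend_3pt | bend_notched | vb_compression
    span: float = 8.0         # mm
    loading_rate: float = 3.0  # mm/min

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must have equal length")
        if len(self.displacement) < 50:
            raise ValueError("need at least 50 samples")
        if np.any(np.diff(self.displacement) < 0):
            raise ValueError("displacement must be monotone non-decreasing")
        if self.test_kind in ("bend_3pt", "bend_notched") and not (self.span > 0):
            raise ValueError("bending tests require span > 0")


def _polyline_area(xs, ys, x0, x1):
    """Area under a piecewise-linear curve between x0 and x1 (trapezoids)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    grid = np.unique(np.clip(np.concatenate([xs, [x0, x1]]), x0, x1))
    yg = np.interp(grid, xs, ys)
    return float(np.trapezoid(yg, grid))


def simulate_bending_curve(spec: CurveSpec) -> tuple[LoadDisplacementCurve, dict]:
    """Piecewise-linear bending curve with closed-form ground truth.

    Segments: linear ramp at ``stiffness`` to the yield knee; linear
    work-hardening to ultimate; linear softening to the drop onset at
    knee + PYD; steep terminal drop to near zero.  The ground-truth
    record carries the analytic values of every property the curve
    analyzer reports, including the 0.9-secant yield point evaluated in
    closed form on the noiseless polyline (so the analyzer can be
    checked without running the analyzer).
    """
    k = spec.stiffness
    d_knee = spec.yield_force / k
    pyd = spec.post_yield_displacement
    if pyd > 0:
        d_ult = d_knee + spec.hardening_fraction * pyd
        d_drop = d_knee + pyd
        f_soft = spec.softening_level * spec.ultimate_force
        xs = [0.0, d_knee, d_ult, d_drop]
        ys = [0.0, spec.yield_force, spec.ultimate_force, f_soft]
    else:
        d_ult = d_drop = d_knee
        xs = [0.0, d_knee]
        ys = [0.0, spec.ultimate_force if spec.ultimate_force == spec.yield_force else spec.yield_force]
    # terminal drop: steep, a couple of samples wide
    drop_w = 2.0 / spec.sampling_rate
    f_end = 0.02 * spec.ultimate_force
    xs = np.array(xs + [d_drop + drop_w])
    ys = np.array(ys + [f_end])

    n = int(np.ceil((xs[-1]) * spec.sampling_rate)) + 1
    if n < 50:
        raise ValueError("sampling_rate too coarse to resolve the curve")
    d = np.linspace(0.0, xs[-1], n)
    if (d[1] - d[0]) > 0.5 * d_knee:
        raise ValueError("sampling too coarse to place the yield point")
    f = np.interp(d, xs, ys)

    toe = spec.toe_displacement
    toe_origin = toe / 2.0
    if toe > 0:
        # quadratic toe f = k d^2 / (2 toe): meets the elastic line
        # k (d - toe/2) with matching value and slope at d = toe, so the
        # corrected origin is toe/2 and the post-toe curve is unchanged
        d_toe = np.arange(0.0, toe, 1.0 / spec.sampling_rate)
        f_toe = k * d_toe**2 / (2.0 * toe)
        keep = d + toe_origin >= toe
        d = np.concatenate([d_toe, d[keep] + toe_origin])
        f = np.concatenate([f_toe, f[keep]])

    if spec.noise_sd > 0:
        rng = _rng(spec.seed, "curve")
        f = f + rng.normal(0.0, spec.noise_sd, size=f.shape)

    # --- closed-form 0.9-secant yield on the noiseless polyline (pre-toe) ---
    d_y, f_y = d_knee, spec.yield_force
    for i in range(len(xs) - 1):
        x0, x1, y0, y1 = xs[i], xs[i + 1], ys[i], ys[i + 1]
        if x1 <= x0:
            continue
        m = (y1 - y0) / (x1 - x0)
        denom = 0.9 * k - m
        if abs(denom) < 1e-12:
            continue
        d_cross = (y0 - m * x0) / denom
        if x0 - 1e-12 <= d_cross <= x1 + 1e-12 and d_cross > 0:
            d_y, f_y = d_cross, y0 + m * (d_cross - x0)
            break

    # analytic failure point: first crossing below failure_drop_fraction*ultimate
    f_fail_level = spec.failure_drop_fraction * spec.ultimate_force
    d_fail = xs[-1]
    if ys[-1] < f_fail_level:
        m = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        d_fail = xs[-2] + (f_fail_level - ys[-2]) / m

    w_f = _polyline_area(xs, ys, 0.0, d_fail)
    py_wf = _polyline_area(xs, ys, d_y, d_fail)
    if toe > 0:
        # toe blend carries k toe^2/24 of extra area above the
        # back-extrapolated elastic line
        w_f += k * toe**2 / 24.0

    gt = {
        "stiffness": k,
        "yield_force": f_y,
        "yield_displacement": d_y,
        "knee_force": spec.yield_force,
        "knee_displacement": d_knee,
        "ultimate_force": spec.ultimate_force,
        "ultimate_displacement": d_ult,
        "failure_displacement": d_fail,
        "pyd": d_fail - d_y,
        "w_f": w_f,
        "py_wf": py_wf,
        "toe_displacement": toe,
        "origin": toe_origin,
    }
    curve = LoadDisplacementCurve(d, f, test_kind="bend_3pt", span=8.0)
    return curve, gt


# ---------------------------------------------------------------------------
# two-factor cohorts
# ---------------------------------------------------------------------------

CANA_LEVELS = ("NoCana", "Cana")
GROUP_LEVELS = ("ND-Palm", "T1D-Palm", "T1D-Ins")

#: End-point blood glucose medians (mg/dl) by (cana, group), used as the
#: default cell locations for cohort simulations.
DEFAULT_BG_LOCATIONS = {
    ("NoCana", "ND-Palm"): 176.0,
    ("NoCana", "T1D-Palm"): 723.0,
    ("NoCana", "T1D-Ins"): 280.0,
    ("Cana", "ND-Palm"): 174.0,
    ("Cana", "T1D-Palm"): 727.0,
    ("Cana", "T1D-Ins"): 324.0,
}


@dataclass
class CohortSpec:
    """Two-factor (pretreatment x glucose group) cohort design.

    ``cell_location`` / ``cell_scale`` / ``n_per_cell`` may be scalars or
    dicts keyed by ``(cana, group)``.  Noise families: ``gaussian``
    (location = mean = median), ``lognormal`` (location = median, scale =
    log-sd, right-skewed), ``scaled-t`` (heavy tails, df=3).
    """

    n_per_cell: object = 10
    cell_location: object = None  # defaults to DEFAULT_BG_LOCATIONS
    cell_scale: object = 1.0
    noise_family: str = "gaussian"
    outcome_name: str = "outcome"
    seed: int = 0

    def cells(self):
        return [(c, g) for c in CANA_LEVELS for g in GROUP_LEVELS]

    def _per_cell(self, value, cell, default=None):
        if value is None:
            value = default
        if isinstance(value, dict):
            return value[cell]
        return value


def simulate_cohort_table(spec: CohortSpec):
    """Long-format cohort table: one row per specimen.

    Columns: ``specimen_id``, ``cana``, ``group``, and the outcome.  Per
    cell, the sample median converges to ``cell_location`` as n grows
    for every noise family.
    """
    import pandas as pd

    if spec.noise_family not in ("gaussian", "lognormal", "scaled-t"):
        raise ValueError(f"unknown noise_family {spec.noise_family!r}")
    rng = _rng(spec.seed, "cohort")
    rows = []
    sid = 0
    for cell in spec.cells():
        cana, group = cell
        n = int(spec._per_cell(spec.n_per_cell, cell))
        if n < 2:
            raise ValueError("n_per_cell must be >= 2")
        loc = float(spec._per_cell(spec.cell_location, cell, DEFAULT_BG_LOCATIONS))
        scale = float(spec._per_cell(spec.cell_scale, cell))
        if scale < 0:
            raise ValueError("cell_scale must be >= 0")
        if spec.noise_family == "gaussian":
            vals = loc + scale * rng.standard_normal(n)
        elif spec.noise_family == "lognormal":
            vals = loc * np.exp(scale * rng.standard_normal(n))
        else:  # scaled-t, df=3
            vals = loc + scale * rng.standard_t(3, size=n)
        for v in vals:
            rows.append((f"m{sid:04d}", cana, group, float(v)))
            sid += 1
    return pd.DataFrame(rows, columns=["specimen_id", "cana", "group", spec.outcome_name])
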