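"""Synthetic volumes with analytically known properties.

Every phantom is generated on the voxel lattice by the centre-inclusion
rule: a voxel belongs to the solid iff its centre satisfies the implicit
inequality of the shape (no antialiasing), which makes voxel-count oracles
exact to enumerate.  Each generator returns the volume together with a
ground-truth record (analytic volume, surface, Euler characteristic, fabric
axis, plate-model indices — whatever applies), so tests never recompute
ground truth by hand.

Randomised phantoms (Boolean ball models, ellipsoid fields, gray-level
noise) draw from one ``numpy`` generator seeded per spec; identical spec +
seed is bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .volumes import BinaryVolume, GrayVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "generate_binary_phantom",
    "generate_gray_phantom",
    "BINARY_KINDS",
    "GRAY_KINDS",
]

BINARY_KINDS = (
    "ball",
    "balls",
    "shell",
    "torus",
    "cylinder",
    "cylinder_bundle",
    "slab_stack",
    "boolean_balls",
    "ellipsoid_field",
    "grain_pack",
)
GRAY_KINDS = ("bimodal_gray", "multiphase_gray")


@dataclass(frozen=True)
class PhantomSpec:
    kind: str
    shape: tuple[int, int, int]
    voxel_size: float = 1.0  # um
    seed: int = 0
    params: dict = field(default_factory=dict)


@dataclass
class PhantomResult:
    """Generated volume plus its analytic ground-truth sidecar record."""

    volume: Any  # BinaryVolume or GrayVolume
    truth: dict
    labels: LabelVolume | None = None  # phase labels for gray phantoms


def _grids(shape):
    ax = [np.arange(n, dtype=np.float64) for n in shape]
    return np.meshgrid(*ax, indexing="ij")


def _ball_mask(shape, center, r):
    x, y, z = _grids(shape)
    return (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2 <= r**2


def _default_center(shape):
    return tuple((n - 1) / 2.0 for n in shape)


def _make_ball(spec):
    r = float(spec.params["r"])
    c = spec.params.get("center", _default_center(spec.shape))
    if r <= 0:
        raise ValueError("ball radius must be positive")
    mask = _ball_mask(spec.shape, c, r)
    return mask, {
        "analytic_volume_vox": 4.0 / 3.0 * np.pi * r**3,
        "analytic_surface_vox2": 4.0 * np.pi * r**2,
        "analytic_mean_curvature_vox": 4.0 * np.pi * r,
        "euler_number": 1,
        "radius_vox": r,
    }


def _make_balls(spec):
    centers = spec.params["centers"]
    radii = spec.params["radii"]
    if len(centers) != len(radii) or not centers:
        raise ValueError("centers and radii must be equal-length, nonempty")
    mask = np.zeros(spec.shape, dtype=bool)
    for c, r in zip(centers, radii):
        mask |= _ball_mask(spec.shape, c, float(r))
    disjoint = all(
        np.linalg.norm(np.subtract(centers[i], centers[j])) > radii[i] + radii[j] + 1
        for i in range(len(centers))
        for j in range(i + 1, len(centers))
    )
    truth = {"n_balls": len(centers), "disjoint": disjoint}
    if disjoint:
        truth["euler_number"] = len(centers)
    return mask, truth


def _make_shell(spec):
    r_out = float(spec.params["r_out"])
    r_in = float(spec.params["r_in"])
    if not 0 < r_in < r_out:
        raise ValueError("shell needs 0 < r_in < r_out")
    c = spec.params.get("center", _default_center(spec.shape))
    x, y, z = _grids(spec.shape)
    d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    mask = (d2 <= r_out**2) & (d2 > r_in**2)
    return mask, {"euler_number": 2, "r_out_vox": r_out, "r_in_vox": r_in}


def _make_torus(spec):
    R = float(spec.params["R"])
    r = float(spec.params["r"])
    if not 0 < r < R:
        raise ValueError("torus needs 0 < r < R")
    c = spec.params.get("center", _default_center(spec.shape))
    x, y, z = _grids(spec.shape)
    rho = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2)
    mask = (rho - R) ** 2 + (z - c[2]) ** 2 <= r**2
    return mask, {"euler_number": 0, "ring_radius_vox": R, "tube_radius_vox": r}


_AXIS = {"x": 0, "y": 1, "z": 2}


def _cylinder_mask(shape, r, axis, center, length):
    x, y, z = _grids(shape)
    coords = [x, y, z]
    a = _AXIS[axis]
    trans = [coords[i] - center[i] for i in range(3) if i != a]
    mask = trans[0] ** 2 + trans[1] ** 2 <= r**2
    if length is not None:
        mask &= np.abs(coords[a] - center[a]) <= length / 2.0
    return mask


def _make_cylinder(spec):
    r = float(spec.params["r"])
    axis = spec.params.get("axis", "z")
    length = spec.params.get("length")
    c = spec.params.get("center", _default_center(spec.shape))
    mask = _cylinder_mask(spec.shape, r, axis, c, length)
    return mask, {"euler_number": 1, "fabric_axis": axis, "radius_vox": r}


def _make_cylinder_bundle(spec):
    r = float(spec.params["r"])
    axis = spec.params.get("axis", "z")
    pitch = float(spec.params.get("pitch", 4 * r))
    a = _AXIS[axis]
    mask = np.zeros(spec.shape, dtype=bool)
    other = [i for i in range(3) if i != a]
    n0 = spec.shape[other[0]]
    n1 = spec.shape[other[1]]
    count = 0
    for c0 in np.arange(pitch / 2, n0, pitch):
        for c1 in np.arange(pitch / 2, n1, pitch):
            center = [0.0, 0.0, 0.0]
            center[a] = (spec.shape[a] - 1) / 2.0
            center[other[0]] = c0
            center[other[1]] = c1
            mask |= _cylinder_mask(spec.shape, r, axis, center, None)
            count += 1
    return mask, {"fabric_axis": axis, "n_cylinders": count, "radius_vox": r}


def _make_slab_stack(spec):
    t = int(spec.params["thickness"])
    period = int(spec.params["period"])
    axis = spec.params.get("axis", "z")
    if not 0 < t < period:
        raise ValueError("slab stack needs 0 < thickness < period")
    a = _AXIS[axis]
    # offset keeps plate faces interior to the volume (a face on the border
    # would be invisible to surface estimation)
    offset = int(spec.params.get("offset", (period - t) // 2))
    pos = np.arange(spec.shape[a])
    solid_1d = ((pos - offset) % period) < t
    shape_b = [1, 1, 1]
    shape_b[a] = spec.shape[a]
    mask = np.broadcast_to(solid_1d.reshape(shape_b), spec.shape).copy()
    vs_mm = spec.voxel_size / 1000.0
    return mask, {
        "thickness_vox": t,
        "period_vox": period,
        "BvTv": t / period,
        "TbTh_mm": t * vs_mm,
        "TbSp_mm": (period - t) * vs_mm,
        "TbN_per_mm": 1.0 / (period * vs_mm),
    }


def _make_boolean_balls(spec):
    r = float(spec.params["r"])
    fraction = float(spec.params["fraction"])
    if not 0 < fraction < 1:
        raise ValueError("target fraction must be in (0, 1)")
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape, dtype=np.float64)
    # stationary Boolean model: centres Poisson in the r-dilated domain
    lo = -r
    hi = shape - 1 + r
    extent = hi - lo
    grain_vol = 4.0 / 3.0 * np.pi * r**3
    lam = -np.log(1.0 - fraction) / grain_vol  # coverage 1 - exp(-lam*v)
    n = rng.poisson(lam * np.prod(extent))
    centers = lo + rng.random((n, 3)) * extent
    mask = np.zeros(spec.shape, dtype=bool)
    for c in centers:
        mask |= _ball_mask(spec.shape, c, r)
    return mask, {
        "expected_VV": fraction,
        "intensity_per_vox3": lam,
        "n_grains_drawn": int(n),
        "isotropic": True,
    }


def _rotation_from_vectors(rng, align_axis=None, concentration=0.0):
    """Random rotation; with alignment, the grain's long axis is drawn close
    to ``align_axis`` (simple von-Mises-Fisher-like jitter of strength
    ``concentration`` in [0, 1], 1 = perfectly aligned)."""
    if align_axis is None or concentration <= 0:
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        return q
    a = np.zeros(3)
    a[_AXIS[align_axis]] = 1.0
    w = a + (1.0 - concentration) * rng.standard_normal(3)
    w /= np.linalg.norm(w)
    helper = np.array([1.0, 0, 0]) if abs(w[0]) < 0.9 else np.array([0.0, 1, 0])
    u = np.cross(w, helper)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.column_stack([u, v, w])


def _make_ellipsoid_field(spec):
    semi = np.asarray(spec.params["semi_axes"], dtype=np.float64)  # (a, b, c_long)
    count = int(spec.params["count"])
    align = spec.params.get("align_axis")
    conc = float(spec.params.get("concentration", 0.0))
    if np.any(semi <= 0) or count < 1:
        raise ValueError("ellipsoid field needs positive semi-axes and count >= 1")
    rng = np.random.default_rng(spec.seed)
    shape = np.array(spec.shape, dtype=np.float64)
    x, y, z = _grids(spec.shape)
    pts = np.stack([x, y, z], axis=-1)
    mask = np.zeros(spec.shape, dtype=bool)
    for _ in range(count):
        c = rng.random(3) * (shape - 1)
        rot = _rotation_from_vectors(rng, align, conc)
        local = (pts - c) @ rot  # grain frame; columns of rot = grain axes
        mask |= np.sum((local / semi) ** 2, axis=-1) <= 1.0
    return mask, {
        "n_grains": count,
        "fabric_axis": align,
        "isotropic": align is None or conc == 0.0,
    }


def _make_grain_pack(spec):
    """Known number of ball grains on a jittered lattice, optionally touching."""
    r = float(spec.params["r"])
    pitch = float(spec.params["pitch"])
    jitter = float(spec.params.get("jitter", 0.0))
    rng = np.random.default_rng(spec.seed)
    centers = []
    margin = r * 0.9
    for cx in np.arange(margin + pitch / 2, spec.shape[0] - margin, pitch):
        for cy in np.arange(margin + pitch / 2, spec.shape[1] - margin, pitch):
            for cz in np.arange(margin + pitch / 2, spec.shape[2] - margin, pitch):
                c = np.array([cx, cy, cz]) + rng.uniform(-jitter, jitter, 3)
                centers.append(c)
    mask = np.zeros(spec.shape, dtype=bool)
    for c in centers:
        mask |= _ball_mask(spec.shape, c, r)
    return mask, {
        "n_grains": len(centers),
        "touching": pitch < 2 * r,
        "radius_vox": r,
        "centers": [tuple(float(v) for v in c) for c in centers],
    }


_BINARY_MAKERS = {
    "ball": _make_ball,
    "balls": _make_balls,
    "shell": _make_shell,
    "torus": _make_torus,
    "cylinder": _make_cylinder,
    "cylinder_bundle": _make_cylinder_bundle,
    "slab_stack": _make_slab_stack,
    "boolean_balls": _make_boolean_balls,
    "ellipsoid_field": _make_ellipsoid_field,
    "grain_pack": _make_grain_pack,
}


def generate_binary_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate a binary phantom; see ``BINARY_KINDS`` for available shapes."""
    if spec.kind not in _BINARY_MAKERS:
        raise ValueError(f"unknown binary phantom kind {spec.kind!r}")
    mask, truth = _BINARY_MAKERS[spec.kind](spec)
    truth = {"kind": spec.kind, "voxel_count": int(np.count_nonzero(mask)), **truth}
    return PhantomResult(volume=BinaryVolume(mask, spec.voxel_size), truth=truth)


def generate_gray_phantom(spec: PhantomSpec) -> PhantomResult:
    """Gray-level phantom: per-phase mean gray values plus Gaussian noise.

    ``bimodal_gray`` draws the object phase from a nested binary phantom
    (``params['geometry']``, default a Boolean ball model) and assigns
    ``means = (background, object)``; ``multiphase_gray`` takes an explicit
    label geometry with one mean per phase (emulating e.g. air/brine/grain
    contrast).  Noise sigma in gray levels; values clipped to the dtype.
    """
    if spec.kind not in GRAY_KINDS:
        raise ValueError(f"unknown gray phantom kind {spec.kind!r}")
    dtype = np.dtype(spec.params.get("dtype", np.uint8))
    if dtype not in (np.dtype(np.uint8), np.dtype(np.uint16)):
        raise ValueError("gray phantoms are uint8 or uint16")
    sigma = float(spec.params.get("sigma", 0.0))
    means = [float(m) for m in spec.params["means"]]
    dmax = float(np.iinfo(dtype).max)
    if any(not 0 <= m <= dmax for m in means):
        raise ValueError(f"phase means must lie within [0, {dmax}]")

    if spec.kind == "bimodal_gray":
        geom = spec.params.get(
            "geometry", {"kind": "boolean_balls", "params": {"r": 6.0, "fraction": 0.4}}
        )
        sub = PhantomSpec(
            kind=geom["kind"],
            shape=spec.shape,
            voxel_size=spec.voxel_size,
            seed=spec.seed,
            params=geom.get("params", {}),
        )
        base = generate_binary_phantom(sub)
        labels = LabelVolume(base.volume.data.astype(np.int32), spec.voxel_size)
        phase_truth = base.truth
        if len(means) != 2:
            raise ValueError("bimodal_gray needs exactly 2 means")
    else:
        label_data = np.asarray(spec.params["label_data"], dtype=np.int32)
        if label_data.shape != tuple(spec.shape):
            raise ValueError("label_data shape mismatch")
        labels = LabelVolume(label_data, spec.voxel_size)
        phase_truth = {"n_phases": int(label_data.max()) + 1}
        if len(means) != int(label_data.max()) + 1:
            raise ValueError("need one mean per phase")

    rng = np.random.default_rng(spec.seed + 1)  # decorrelated from geometry draw
    mean_map = np.asarray(means)[labels.data]
    noisy = mean_map + (sigma * rng.standard_normal(labels.data.shape) if sigma else 0.0)
    gray = np.clip(np.rint(noisy), 0, dmax).astype(dtype)
    truth = {
        "kind": spec.kind,
        "means": means,
        "sigma": sigma,
        **phase_truth,
    }
    return PhantomResult(
        volume=GrayVolume(gray, spec.voxel_size), truth=truth, labels=labels
    )
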