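"""Basic Analysis: Minkowski functionals and MIL fabric anisotropy.

The four additive morphological measures of a voxelised body — volume,
surface area, integral of mean curvature, Euler characteristic — are
estimated from local counts on the voxel grid:

* volume density ``VV``: object-voxel fraction;
* surface via the discrete Cauchy–Crofton formula, ``S_V = 2 <P_L>``, with
  phase transitions counted along the 13 lattice directions and the
  spherical average taken with spherical-Voronoi direction weights;
* integral of mean curvature via the section formula ``M_V = 2 pi <chi_A>``,
  the mean planar Euler-characteristic density over the three axis-aligned
  section stacks;
* Euler characteristic, exactly, as ``chi = V - E + F - C`` of the cubical
  complex of closed voxels (object adjacency 26, background 6); solid ball
  -> 1, solid torus -> 0, hollow shell -> 2.

Fabric anisotropy follows the mean-intercept-length (MIL) method: the MIL
ellipsoid is fitted to directional intercept lengths and the Benn indices
are read off its sorted semi-axes — isotropy ``I = m3/m1`` and elongation
``EA = 1 - m2/m1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial import SphericalVoronoi

from .volumes import BinaryVolume

__all__ = [
    "BasicAnalysisResult",
    "FabricTensor",
    "MinkowskiFunctionals",
    "volume_density",
    "euler_number_3d",
    "minkowski_functionals",
    "mil_fabric",
    "anisotropy_indices",
    "basic_analysis",
]


@dataclass
class MinkowskiFunctionals:
    """Raw totals and specific (per-VOI-volume) Minkowski measures."""

    surface_area_mm2: float
    mean_curvature_mm: float  # integral of mean curvature
    euler_number: int
    SV: float  # mm^-1
    MV: float  # mm^-2
    chi_v: float  # mm^-3


@dataclass
class FabricTensor:
    """MIL ellipsoid: quadratic form ``1/MIL(w)^2 = w' H w`` and its axes."""

    H: np.ndarray  # 3x3 symmetric positive-definite
    mil_axes: np.ndarray  # semi-axes m1 >= m2 >= m3, mm
    axes_directions: np.ndarray  # unit eigenvectors, columns match mil_axes
    directions_used: int


@dataclass
class BasicAnalysisResult:
    VV: float
    SV: float
    MV: float
    chi_v: float
    I: float
    EA: float


def volume_density(bin: BinaryVolume) -> float:
    """Object-voxel fraction of the VOI (porosity when the object is the pore phase)."""
    return float(np.count_nonzero(bin.data)) / bin.data.size


def _cells_touched(occ: np.ndarray, axes: tuple[int, ...]) -> int:
    """Count lattice cells (vertex/edge/face grid) touched by >= 1 voxel.

    A k-cell orthogonal to ``axes`` at grid position g is touched iff any of
    the 2^len(axes) voxels sharing it is object.
    """
    pad = [(1, 1) if a in axes else (0, 0) for a in range(3)]
    p = np.pad(occ, pad)
    out = p
    for a in axes:
        n = out.shape[a]
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[a] = slice(0, n - 1)
        sl_hi[a] = slice(1, n)
        out = out[tuple(sl_lo)] | out[tuple(sl_hi)]
    return int(np.count_nonzero(out))


def euler_number_3d(bin_or_array) -> int:
    """Euler characteristic of the closed-voxel cubical complex.

    chi = V - E + F - C over vertices, edges, faces and cubes of the union of
    closed unit cubes, which realises 26-connectivity for the object and
    6-connectivity for the background.
    """
    occ = bin_or_array.data if isinstance(bin_or_array, BinaryVolume) else bin_or_array
    occ = np.asarray(occ, dtype=bool)
    C = int(np.count_nonzero(occ))
    if C == 0:
        return 0
    V = _cells_touched(occ, (0, 1, 2))
    E = sum(_cells_touched(occ, axes) for axes in ((0, 1), (0, 2), (1, 2)))
    F = sum(_cells_touched(occ, (a,)) for a in (0, 1, 2))
    return V - E + F - C


def _euler_2d_total(occ: np.ndarray, plane_axes: tuple[int, int]) -> int:
    """Sum of per-slice 2D Euler characteristics over the stack of sections
    spanned by ``plane_axes`` (closed-pixel complex, 8-connectivity object)."""
    a, b = plane_axes
    F = int(np.count_nonzero(occ))
    if F == 0:
        return 0
    V = _cells_touched(occ, (a, b))
    E = _cells_touched(occ, (a,)) + _cells_touched(occ, (b,))
    return V - E + F


# the 13 lattice directions: 3 axes, 6 face diagonals, 4 body diagonals
_DIRECTIONS_13 = np.array(
    [
        (1, 0, 0), (0, 1, 0), (0, 0, 1),
        (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
        (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
    ],
    dtype=np.int64,
)


@lru_cache(maxsize=1)
def _crofton_weights() -> np.ndarray:
    """Spherical-Voronoi solid-angle weights of the 13 direction pairs.

    Computed on the 26 signed unit directions; each antipodal pair's weight
    is the fraction of the sphere closest to it, so the weights sum to 1 and
    the weighted sum of directional P_L values is a quadrature of the
    spherical mean.
    """
    dirs = _DIRECTIONS_13.astype(np.float64)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    pts = np.concatenate([dirs, -dirs])
    sv = SphericalVoronoi(pts, radius=1.0)
    areas = sv.calculate_areas()
    return (areas[:13] + areas[13:]) / (4.0 * np.pi)


def _transitions(occ: np.ndarray, d: np.ndarray) -> tuple[int, int]:
    """(phase transitions, valid pairs) between voxels p and p+d inside the VOI."""
    sl_a = [slice(None)] * 3
    sl_b = [slice(None)] * 3
    for axis in range(3):
        step = int(d[axis])
        if step == 1:
            sl_a[axis] = slice(0, occ.shape[axis] - 1)
            sl_b[axis] = slice(1, occ.shape[axis])
        elif step == -1:
            sl_a[axis] = slice(1, occ.shape[axis])
            sl_b[axis] = slice(0, occ.shape[axis] - 1)
    a = occ[tuple(sl_a)]
    b = occ[tuple(sl_b)]
    return int(np.count_nonzero(a != b)), a.size


def minkowski_functionals(bin: BinaryVolume) -> MinkowskiFunctionals:
    """Surface, integral mean curvature and Euler number with specific values."""
    occ = np.asarray(bin.data, dtype=bool)
    a_mm = bin.voxel_size_mm
    voi_mm3 = occ.size * a_mm**3

    weights = _crofton_weights()
    p_l = 0.0  # transitions per unit length, spherical mean, voxel^-1
    for w, d in zip(weights, _DIRECTIONS_13):
        count, n_pairs = _transitions(occ, d)
        h = float(np.linalg.norm(d))
        if n_pairs:
            p_l += w * count / (n_pairs * h)
    sv_vox = 2.0 * p_l  # voxel^-1
    SV = sv_vox / a_mm
    surface = SV * voi_mm3

    chi_a_total = sum(
        _euler_2d_total(occ, axes) for axes in ((0, 1), (0, 2), (1, 2))
    )
    mv_vox = 2.0 * np.pi * chi_a_total / (3.0 * occ.size)  # voxel^-2
    MV = mv_vox / a_mm**2
    mean_curv = MV * voi_mm3

    chi = euler_number_3d(occ)
    chi_v = chi / voi_mm3

    return MinkowskiFunctionals(
        surface_area_mm2=float(surface),
        mean_curvature_mm=float(mean_curv),
        euler_number=int(chi),
        SV=float(SV),
        MV=float(MV),
        chi_v=float(chi_v),
    )


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit directions (spherical Fibonacci lattice)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def mil_fabric(
    bin: BinaryVolume,
    n_directions: int = 512,
    line_spacing: float = 2.0,
    seed: int = 0,
) -> FabricTensor:
    """Mean-intercept-length fabric tensor.

    For each of ``n_directions`` quasi-uniform directions, parallel test
    lines ``line_spacing`` voxels apart are traced through the VOI with a
    1-voxel sampling step; ``MIL(w)`` is the line length inside the VOI per
    object<->background crossing.  The MIL ellipsoid ``1/MIL^2 = w' H w`` is
    fitted by least squares and its semi-axes returned in mm, sorted
    descending.  ``seed`` randomises the global rotation of the direction
    set (sampling design only; the underlying quantity is deterministic).
    """
    occ = np.asarray(bin.data, dtype=bool)
    if not occ.any() or occ.all():
        raise ValueError("MIL needs both object and background voxels")
    if n_directions < 9:
        raise ValueError("need at least 9 directions for the tensor fit")
    shape = np.array(occ.shape, dtype=np.float64)
    center = (shape - 1) / 2.0
    radius = float(np.linalg.norm(shape)) / 2.0
    step = 1.0

    dirs = _fibonacci_sphere(n_directions) @ _random_rotation(seed).T

    n_off = max(1, int(np.ceil(2 * radius / line_spacing)))
    offs = (np.arange(n_off) - (n_off - 1) / 2.0) * line_spacing
    ou, ov = np.meshgrid(offs, offs, indexing="ij")
    ou = ou.ravel()
    ov = ov.ravel()
    s = np.arange(-radius, radius + step, step)

    mils = []
    used_dirs = []
    dropped = 0
    for w in dirs:
        # orthonormal frame (u, v, w)
        helper = np.array([1.0, 0.0, 0.0])
        if abs(w[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        u = np.cross(w, helper)
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        # sample points: (lines, steps, 3)
        origins = center + ou[:, None] * u + ov[:, None] * v
        pts = origins[:, None, :] + s[None, :, None] * w
        idx = np.rint(pts).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.array(occ.shape)), axis=2)
        idx_c = np.clip(idx, 0, np.array(occ.shape) - 1)
        vals = occ[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]]
        pair_ok = inside[:, :-1] & inside[:, 1:]
        crossings = int(np.count_nonzero(pair_ok & (vals[:, :-1] != vals[:, 1:])))
        length = float(np.count_nonzero(pair_ok)) * step
        if crossings == 0:
            dropped += 1
            continue
        mils.append(length / crossings)
        used_dirs.append(w)
    if dropped:
        warnings.warn(
            f"{dropped} MIL directions had no object/background crossings and were dropped",
            stacklevel=2,
        )
    if len(used_dirs) < 9:
        raise ValueError(
            f"only {len(used_dirs)} usable MIL directions; tensor fit underdetermined"
        )

    W = np.asarray(used_dirs)
    mil_vox = np.asarray(mils)
    # design matrix for the symmetric quadratic form
    A = np.column_stack(
        [
            W[:, 0] ** 2,
            W[:, 1] ** 2,
            W[:, 2] ** 2,
            2 * W[:, 0] * W[:, 1],
            2 * W[:, 0] * W[:, 2],
            2 * W[:, 1] * W[:, 2],
        ]
    )
    y = 1.0 / mil_vox**2
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    H = np.array(
        [
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ]
    )
    evals, evecs = np.linalg.eigh(H)
    if np.any(evals <= 0):
        raise ValueError("MIL tensor is not positive definite (degenerate fabric)")
    axes_vox = 1.0 / np.sqrt(evals)  # largest eigenvalue -> shortest axis
    order = np.argsort(axes_vox)[::-1]
    axes_vox = axes_vox[order]
    evecs = evecs[:, order]
    return FabricTensor(
        H=H,
        mil_axes=axes_vox * bin.voxel_size_mm,
        axes_directions=evecs,
        directions_used=len(used_dirs),
    )


def anisotropy_indices(fab: FabricTensor) -> tuple[float, float]:
    """Benn indices on sorted MIL semi-axes: I = m3/m1, EA = 1 - m2/m1."""
    m1, m2, m3 = fab.mil_axes
    if not (m1 > 0 and m2 > 0 and m3 > 0):
        raise ValueError("degenerate fabric tensor")
    return float(m3 / m1), float(1.0 - m2 / m1)


def basic_analysis(
    bin: BinaryVolume,
    n_directions: int = 512,
    line_spacing: float = 2.0,
    seed: int = 0,
) -> BasicAnalysisResult:
    """The full Basic Analysis report: VV, SV, MV, chi_v, I, EA."""
    vv = volume_density(bin)
    mink = minkowski_functionals(bin)
    fab = mil_fabric(bin, n_directions=n_directions, line_spacing=line_spacing, seed=seed)
    i_idx, ea = anisotropy_indices(fab)
    return BasicAnalysisResult(
        VV=vv, SV=mink.SV, MV=mink.MV, chi_v=mink.chi_v, I=i_idx, EA=ea
    )
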