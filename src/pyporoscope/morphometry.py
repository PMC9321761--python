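"""Trabecular morphometry: BV/TV, BS/BV and the plate-model indices.

The indirect (plate-model) histomorphometric identities are used: assuming
plate-like trabeculae,

    Tb.Th = 2 / BsBv          [mm]
    Tb.N  = BvTv / Tb.Th      [mm^-1]
    Tb.Sp = 1/Tb.N - Tb.Th    [mm]

``BvTv`` is the solid-phase voxel fraction and ``BsBv`` the solid-phase
surface area (Crofton estimate) over solid-phase volume.  The identities
hold to machine precision by construction; accuracy on real structures is
governed by how plate-like the trabeculae are and by the surface estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basic import minkowski_functionals, volume_density
from .volumes import BinaryVolume

__all__ = ["MorphometryResult", "bone_morphometry", "morphometry_from_scalars"]


@dataclass
class MorphometryResult:
    BvTv: float  # dimensionless bone volume fraction
    BsBv: float  # mm^-1
    TbTh: float  # mm
    TbN: float  # mm^-1
    TbSp: float  # mm

    def as_dict(self) -> dict[str, float]:
        return {
            "BvTv": self.BvTv,
            "BsBv_per_mm": self.BsBv,
            "TbTh_mm": self.TbTh,
            "TbN_per_mm": self.TbN,
            "TbSp_mm": self.TbSp,
        }


def morphometry_from_scalars(BvTv: float, BsBv: float) -> MorphometryResult:
    """Plate-model indices from the two measured scalars."""
    if not (0.0 < BvTv <= 1.0):
        raise ValueError(f"BvTv must be in (0, 1], got {BvTv}")
    if not BsBv > 0.0:
        raise ValueError(f"BsBv must be positive, got {BsBv}")
    tbth = 2.0 / BsBv
    tbn = BvTv / tbth
    tbsp = 1.0 / tbn - tbth
    return MorphometryResult(
        BvTv=float(BvTv), BsBv=float(BsBv), TbTh=tbth, TbN=tbn, TbSp=tbsp
    )


def bone_morphometry(bin: BinaryVolume) -> MorphometryResult:
    """Morphometric indices of a binary bone mask (object = solid phase)."""
    n_solid = int(np.count_nonzero(bin.data))
    if n_solid == 0:
        raise ValueError("empty solid phase: morphometry undefined")
    bvtv = volume_density(bin)
    mink = minkowski_functionals(bin)
    bone_volume_mm3 = n_solid * bin.voxel_size_mm**3
    bsbv = mink.surface_area_mm2 / bone_volume_mm3
    if bsbv == 0.0:
        # no measurable internal surface (e.g. a fully solid VOI): the plate
        # model degenerates — infinitely thick plates, zero trabecular number
        return MorphometryResult(
            BvTv=bvtv,
            BsBv=0.0,
            TbTh=float("inf"),
            TbN=0.0,
            TbSp=0.0 if bvtv == 1.0 else float("inf"),
        )
    return morphometry_from_scalars(bvtv, bsbv)
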