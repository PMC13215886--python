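"""End-to-end STV generation pipeline.

SCART (stereotactic centralized ablative radiation therapy) prescribes a
single ablative core — the SCART treatment volume, STV — centered inside
the gross tumor volume, while a protection dose of about 5 Gy per
fraction is enforced at the GTV border.  The STV is obtained from the
GTV by a dose-dependent radial shrink applied per axial slice in polar
coordinates about a refined center, followed by two safety rules:

* any STV slice whose equivalent circular radius falls below 2 cm is
  removed (narrow slices cannot support an adequate dose fall-off);
* a 5-15 mm gap is trimmed at the superior and inferior ends of the STV
  to accommodate tumor motion along the inferior-superior direction.

The shrink factor applied to slice radii is the STV/GTV diameter ratio:
either the tabulated clinical recommendation (0.36, 0.27, 0.24, 0.21 for
15, 18, 21, 24 Gy with a 5 Gy border) or the analytic fallback
border_dose / scart_dose.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .contour import ContourSlice, Structure, polygon_area
from .errors import (
    DegenerateContourError,
    InvalidGapError,
    InvalidWidthError,
    StvEmptyError,
    UnsupportedDoseError,
)
from .polar import RefineParams, from_polar, refine_center, to_polar

__all__ = [
    "SHRINK_TABLE",
    "ShrinkMode",
    "StvParams",
    "shrink_ratio",
    "shrink_slice",
    "filter_min_radius",
    "apply_is_gap",
    "generate_stv",
    "make_control_ring",
    "ControlRing",
]

logger = logging.getLogger(__name__)

ShrinkMode = Literal["table", "formula"]

#: Clinical recommendation: (scart_dose Gy, border_dose Gy) -> STV/GTV diameter ratio.
SHRINK_TABLE: dict[tuple[float, float], float] = {
    (15.0, 5.0): 0.36,
    (18.0, 5.0): 0.27,
    (21.0, 5.0): 0.24,
    (24.0, 5.0): 0.21,
}

RadiusRule = Literal["equivalent", "max", "min"]


def shrink_ratio(scart_dose: float, border_dose: float = 5.0, mode: ShrinkMode = "table") -> float:
    """STV/GTV diameter ratio for a given prescription.

    Parameters
    ----------
    scart_dose
        Ablative dose per fraction prescribed to the STV (Gy).
    border_dose
        Protection dose enforced at the GTV border (Gy), default 5.
    mode
        ``"formula"`` returns border_dose / scart_dose.  ``"table"``
        returns the tabulated clinical ratio at 15/18/21/24 Gy with a
        5 Gy border, linearly interpolated in scart_dose in between;
        doses outside [15, 24] Gy or a non-5 Gy border are rejected.
    """
    if not scart_dose > border_dose > 0:
        raise UnsupportedDoseError(
            f"require scart_dose > border_dose > 0, got {scart_dose} and {border_dose} Gy"
        )
    if mode == "formula":
        return border_dose / scart_dose
    if mode != "table":
        raise ValueError(f"mode must be 'table' or 'formula', got {mode!r}")
    if border_dose != 5.0:
        raise UnsupportedDoseError(
            f"tabulated ratios assume a 5 Gy border dose, got {border_dose} Gy"
        )
    doses = np.array(sorted(d for d, _ in SHRINK_TABLE))
    ratios = np.array([SHRINK_TABLE[(d, 5.0)] for d in doses])
    if not doses[0] <= scart_dose <= doses[-1]:
        raise UnsupportedDoseError(
            f"table mode covers {doses[0]:g}-{doses[-1]:g} Gy; got {scart_dose} Gy "
            "(use mode='formula' for other prescriptions)"
        )
    return float(np.interp(scart_dose, doses, ratios))


@dataclass(frozen=True)
class StvParams:
    """Configuration of the STV generation pipeline.

    gap is the superior-inferior trim (mm, clinically 5-15); min_radius
    is the slice-removal threshold (mm) applied to the equivalent
    circular radius sqrt(area/pi) by default.
    """

    scart_dose: float
    border_dose: float = 5.0
    mode: ShrinkMode = "table"
    min_radius: float = 20.0
    gap: float = 10.0
    refine: RefineParams = field(default_factory=RefineParams)
    trim_enabled: bool = True
    radius_rule: RadiusRule = "equivalent"

    def __post_init__(self) -> None:
        if not 5.0 <= self.gap <= 15.0:
            raise InvalidGapError(f"IS gap must be within 5-15 mm, got {self.gap} mm")
        if self.min_radius < 0:
            raise ValueError("min_radius must be >= 0")
        if not self.scart_dose > self.border_dose > 0:
            raise UnsupportedDoseError(
                f"require scart_dose > border_dose > 0, "
                f"got {self.scart_dose} and {self.border_dose} Gy"
            )


def shrink_slice(
    contour: ContourSlice, ratio: float, refine: RefineParams | None = None
) -> ContourSlice:
    """Radially shrink one slice by ``ratio`` about its refined center.

    The slice is resampled in polar form (nearest-crossing radii) about
    the refined center and every radius is multiplied by ``ratio``; the
    output polygon is therefore contained in the input polygon.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"shrink ratio must be in (0, 1), got {ratio}")
    if refine is None:
        refine = RefineParams()
    center = refine_center(contour, refine)
    polar = to_polar(contour, center, refine.n_angles)
    return from_polar(polar.scaled(ratio))


def _slice_radius(contour: ContourSlice, rule: RadiusRule, center=None) -> float:
    if rule == "equivalent":
        return math.sqrt(polygon_area(contour) / math.pi)
    c = np.asarray(center if center is not None else np.mean(contour.vertices, axis=0))
    d = np.linalg.norm(contour.vertices - c, axis=1)
    return float(d.max() if rule == "max" else d.min())


def filter_min_radius(
    slices: list[ContourSlice],
    min_radius: float,
    rule: RadiusRule = "equivalent",
) -> list[ContourSlice]:
    """Remove slices thinner than ``min_radius`` (mm), preserving order.

    A slice is kept when its radius under ``rule`` — by default the
    equivalent circular radius sqrt(area/pi), which is robust to radial
    spikes — is at least the threshold.  The clinical rule removes STV
    slices with radius below 2 cm to prevent high-dose leakage through
    insufficient lateral dose fall-off.
    """
    if min_radius < 0:
        raise ValueError("min_radius must be >= 0")
    kept = [s for s in slices if _slice_radius(s, rule) >= min_radius]
    logger.info("min-radius rule removed %d of %d slices", len(slices) - len(kept), len(slices))
    return kept


def apply_is_gap(
    stv_slices: list[ContourSlice], gtv_z_min: float, gtv_z_max: float, gap: float
) -> list[ContourSlice]:
    """Trim STV slices within ``gap`` mm of the GTV's axial extremes.

    Slices with z < gtv_z_min + gap or z > gtv_z_max - gap are removed;
    the gap accommodates respiratory/positional tumor motion along the
    inferior-superior direction.  Valid gaps are 5-15 mm.
    """
    if not 5.0 <= gap <= 15.0:
        raise InvalidGapError(f"IS gap must be within 5-15 mm, got {gap} mm")
    if not gtv_z_min < gtv_z_max:
        raise ValueError("gtv_z_min must be below gtv_z_max")
    kept = [s for s in stv_slices if gtv_z_min + gap <= s.z <= gtv_z_max - gap]
    logger.info("IS gap removed %d of %d slices", len(stv_slices) - len(kept), len(stv_slices))
    return kept


def generate_stv(gtv: Structure, params: StvParams) -> Structure:
    """Generate the SCART treatment volume from a GTV structure.

    Per slice: refine the center, resample in polar form, scale radii by
    the dose-dependent shrink ratio; then drop slices below the minimum
    radius and (when trimming is enabled) those within the
    superior-inferior gap.  STV slices keep the axial positions of their
    GTV slices.

    Raises
    ------
    StvEmptyError
        When every slice is removed — the tumor is too small for SCART
        at this prescription; consider a lower dose or, clinically,
        conventional SBRT.
    """
    if len(gtv.slices) < 3:
        raise DegenerateContourError(
            f"GTV {gtv.name!r} has {len(gtv.slices)} slices; need >= 3 for STV generation"
        )
    ratio = shrink_ratio(params.scart_dose, params.border_dose, params.mode)
    shrunk = [shrink_slice(s, ratio, params.refine) for s in gtv.slices]
    kept = filter_min_radius(shrunk, params.min_radius, params.radius_rule)
    if params.trim_enabled:
        kept = apply_is_gap(kept, gtv.z_min, gtv.z_max, params.gap)
    if not kept:
        raise StvEmptyError(
            f"no STV slices remain for {gtv.name!r} at {params.scart_dose:g} Gy: "
            "the tumor is too small for SCART at this dose (every shrunken slice "
            "fell below the minimum radius or inside the superior-inferior gap)"
        )
    name = f"STV_{params.scart_dose:g}Gy"
    return Structure(name, kept, declared_spacing=gtv.slice_spacing)


@dataclass(frozen=True)
class ControlRing:
    """Paired-contour ring around a PTV: expanded outer boundary + inner PTV.

    The outer boundary is a radial expansion of each PTV slice by the
    ring width about its refined center — an approximation to a true
    uniform (Minkowski) margin that is exact for circles and within
    width*(1 - cos(max edge angle)) elsewhere.
    """

    outer: Structure
    inner: Structure
    width: float


def make_control_ring(
    ptv: Structure, width: float = 3.0, refine: RefineParams | None = None
) -> ControlRing:
    """Build the peripheral control ring used to cap the border dose.

    Clinically a 3 mm shell around the PTV (= GTV with zero margin) is
    constrained to the 5 Gy/fraction protection dose to force a steep
    fall-off outside the ablative core.
    """
    if not width > 0:
        raise InvalidWidthError(f"ring width must be positive, got {width} mm")
    if refine is None:
        refine = RefineParams()
    outer_slices = []
    for s in ptv.slices:
        center = refine_center(s, refine)
        polar = to_polar(s, center, refine.n_angles)
        outer_slices.append(from_polar(polar.expanded(width)))
    outer = Structure(f"Ring_{width:g}mm", outer_slices, declared_spacing=ptv.declared_spacing)
    return ControlRing(outer=outer, inner=ptv, width=width)
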