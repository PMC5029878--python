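"""ROI and compartment summaries on fat-fraction maps.

Per-muscle mean fat fraction, cross-sectional areas, the CSA-weighted
total compartment fat fraction, the remaining (non-fat) muscle area and
analysis-slice selection.  Follow-up scans reuse the baseline label mask
verbatim, so no registration is involved here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dixon import FatFractionMap
from .labels import DORSAL_LABELS, VOLAR_LABELS

__all__ = [
    "LabelMask",
    "SliceGeometry",
    "CompartmentSummary",
    "roi_mean_ff",
    "roi_csa",
    "compartment_summary",
    "select_slices",
]

DEFAULT_PIXEL_AREA = 0.56 * 0.56  # mm^2


class EmptyROIError(ValueError):
    """Raised when an ROI holds no (defined) pixels."""


@dataclass
class LabelMask:
    """Integer ROI image: 0 background, 1..10 muscle groups."""

    labels: np.ndarray
    pixel_area: float = DEFAULT_PIXEL_AREA

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer image")
        if self.labels.min() < 0 or self.labels.max() > 10:
            raise ValueError("labels must lie in {0..10}")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")

    def present_labels(self) -> set[int]:
        return set(np.unique(self.labels)) - {0}


@dataclass
class SliceGeometry:
    """Axial slice stack geometry.

    ``central_index`` is the analysis reference slice (anatomically, the
    first slice distal to the supinator; chosen by the user since it cannot
    be inferred from a synthetic stack).  Slice centres are spaced by
    thickness + gap.
    """

    n_slices: int = 9
    slice_thickness: float = 6.0  # mm
    slice_gap: float = 12.0  # mm
    central_index: int = 4

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.slice_thickness <= 0 or self.slice_gap < 0:
            raise ValueError("slice spacing must be positive")
        if not 0 <= self.central_index < self.n_slices:
            raise ValueError("central_index out of range")

    @property
    def center_spacing(self) -> float:
        return self.slice_thickness + self.slice_gap


@dataclass
class CompartmentSummary:
    """Summary measures for one analysis slice.

    ``total_ff`` is the CSA-weighted mean of per-muscle mean fat fractions;
    ``remaining_area`` = total_csa * (100 - total_ff)/100, i.e. the
    compartment area attributed to non-fat tissue.
    """

    per_roi_ff: dict[int, float]
    per_roi_csa: dict[int, float]
    total_ff: float
    total_csa: float
    remaining_area: float
    dorsal_ff: float
    volar_ff: float
    slice_level: str | None = None
    per_roi_undefined: dict[int, int] = field(default_factory=dict)


def _roi_ff_stats(
    ff: FatFractionMap, mask: LabelMask, label: int
) -> tuple[float, int, int]:
    """(mean ff, n defined, n undefined) for one label."""
    if ff.ff.shape != mask.labels.shape:
        raise ValueError("fat-fraction map and label mask must share a grid")
    sel = mask.labels == label
    n_total = int(sel.sum())
    if n_total == 0:
        raise EmptyROIError(f"label {label} has no pixels")
    defined = sel & ff.mask
    n_def = int(defined.sum())
    if n_def == 0:
        raise EmptyROIError(f"label {label} has no defined fat-fraction pixels")
    # averaged on the signed values when available (unbiased at low f.f.),
    # then clamped back to the percent range
    mean = float(np.clip(ff.ff_for_stats[defined].mean(), 0.0, 100.0))
    return mean, n_def, n_total - n_def


def roi_mean_ff(ff: FatFractionMap, mask: LabelMask, label: int) -> float:
    """Arithmetic mean percent fat fraction over the defined pixels of one ROI.

    Undefined (masked-out) pixels are excluded, not imputed; a warning
    reports their count for QC.
    """
    mean, _, n_undef = _roi_ff_stats(ff, mask, label)
    if n_undef:
        warnings.warn(
            f"label {label}: {n_undef} undefined pixel(s) excluded from mean",
            stacklevel=2,
        )
    return mean


def roi_csa(mask: LabelMask, label: int) -> float:
    """Cross-sectional area of one ROI in mm^2 (pixel count x pixel area)."""
    n = int((mask.labels == label).sum())
    if n == 0:
        warnings.warn(f"label {label} is empty; CSA = 0", stacklevel=2)
    return n * mask.pixel_area


def compartment_summary(
    ff: FatFractionMap,
    mask: LabelMask,
    dorsal_labels: tuple[int, ...] = DORSAL_LABELS,
    volar_labels: tuple[int, ...] = VOLAR_LABELS,
    slice_level: str | None = None,
) -> CompartmentSummary:
    """Slice-level summary over the union of dorsal and volar muscle ROIs."""
    labels = tuple(dorsal_labels) + tuple(volar_labels)
    if len(set(labels)) != len(labels):
        raise ValueError("dorsal and volar label sets overlap")
    missing = set(labels) - mask.present_labels()
    if missing:
        raise EmptyROIError(f"labels missing from mask: {sorted(missing)}")

    per_ff: dict[int, float] = {}
    per_csa: dict[int, float] = {}
    per_undef: dict[int, int] = {}
    for lab in labels:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, _, n_undef = _roi_ff_stats(ff, mask, lab)
        per_ff[lab] = mean
        per_csa[lab] = roi_csa(mask, lab)
        per_undef[lab] = n_undef

    def weighted(subset: tuple[int, ...]) -> float:
        csa = sum(per_csa[l] for l in subset)
        return sum(per_ff[l] * per_csa[l] for l in subset) / csa

    total_csa = sum(per_csa.values())
    total_ff = weighted(labels)
    return CompartmentSummary(
        per_roi_ff=per_ff,
        per_roi_csa=per_csa,
        total_ff=total_ff,
        total_csa=total_csa,
        remaining_area=total_csa * (100.0 - total_ff) / 100.0,
        dorsal_ff=weighted(tuple(dorsal_labels)),
        volar_ff=weighted(tuple(volar_labels)),
        slice_level=slice_level,
        per_roi_undefined=per_undef,
    )


def select_slices(
    geometry: SliceGeometry, offset_mm: float = 74.0
) -> tuple[int, int, int]:
    """(distal, central, proximal) slice indices for the analysis levels.

    The distal and proximal levels are the slices whose centres lie nearest
    to -/+ ``offset_mm`` from the central slice centre.  The requested
    offset rarely falls on the centre lattice (spacing = thickness + gap),
    so nearest-centre selection is used.  Offsets reaching beyond the stack
    (further than half a spacing past the outermost centre) raise an error
    naming the reachable range.
    """
    if offset_mm < 0:
        raise ValueError("offset_mm must be nonnegative")
    sp = geometry.center_spacing
    c = geometry.central_index
    centers = np.arange(geometry.n_slices) * sp
    out = []
    for sign, name in ((-1, "distal"), (+1, "proximal")):
        target = centers[c] + sign * offset_mm
        if target < centers[0] - sp / 2 or target > centers[-1] + sp / 2:
            reach = (c if sign < 0 else geometry.n_slices - 1 - c) * sp + sp / 2
            raise ValueError(
                f"no {name} slice at offset {offset_mm} mm from slice {c}; "
                f"reachable {name} offsets are <= {reach:g} mm"
            )
        out.append(int(np.argmin(np.abs(centers - target))))
    distal, proximal = out
    return distal, c, proximal
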