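"""Ipsilateral/contralateral ratio quantification.

The unit of quantification is the per-animal, per-ion ratio of
baseline-subtracted peak areas between the lesioned (ipsilateral) ROI and
its mirror image on the intact (contralateral) hemisphere.  Because both
ROIs come from the same section, per-section multiplicative factors —
matrix application, tissue heterogeneity, ion suppression — cancel in the
ratio, which is what makes cross-animal comparison defensible for MALDI
imaging data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem import IonSpecies
from .msi_io import RoiPolygon, SpectralImage
from .processing import (
    BaselineParams,
    ProcessingError,
    average_spectrum,
    estimate_baseline,
    integrate_peak,
    roi_mask,
    subtract_baseline,
)

__all__ = [
    "BELOW_DETECTION",
    "RatioRecord",
    "RoiPair",
    "detection_filter",
    "estimate_detection_floor",
    "mirror_roi",
    "quantify_section",
    "records_to_frame",
]

BELOW_DETECTION = "below_detection"

#: default signal-free m/z region used to estimate the detection floor; the
#: default panel has no channel between the GM3 and GM2 clusters.
QUIET_REGION = (1250.0, 1360.0)


@dataclass(frozen=True)
class RoiPair:
    """Ipsilateral ROI and its reflection about the sagittal midline."""

    ipsi: RoiPolygon
    contra: RoiPolygon
    midline_x: float


@dataclass(frozen=True)
class RatioRecord:
    """Per-animal, per-ion ipsi/contra AUC ratio with its metadata."""

    animal_id: str
    group: str
    timepoint_days: int
    ion: IonSpecies
    ratio: float
    ipsi_area: float
    contra_area: float
    flags: str = ""


def mirror_roi(ipsi: RoiPolygon, midline_x: float, grid_shape: tuple[int, int] | None = None) -> RoiPolygon:
    """Reflect a polygon about the vertical line x = midline_x.

    On a symmetric grid with the midline on an integer or half-integer
    coordinate, the reflected mask has exactly as many pixels as the
    original.  The operation is an involution: mirroring twice returns the
    original vertices.
    """
    vertices = ipsi.vertices.copy()
    vertices[:, 0] = 2.0 * midline_x - vertices[:, 0]
    if grid_shape is not None:
        nx = grid_shape[0]
        if vertices[:, 0].max() < 0 or vertices[:, 0].min() > nx - 1:
            raise ProcessingError(
                f"mirrored ROI falls entirely off the {nx}-pixel-wide grid "
                f"(midline_x={midline_x})"
            )
    label = "contralateral" if ipsi.label == "ipsilateral" else f"{ipsi.label}_mirrored"
    return RoiPolygon(label=label, vertices=vertices)


def estimate_detection_floor(
    image: SpectralImage,
    pair: RoiPair,
    params: BaselineParams | None = None,
    quiet_region: tuple[float, float] = QUIET_REGION,
    window: float = 0.5,
) -> float:
    """Detection floor for peak areas: 3x the noise MAD scaled to a window.

    The median absolute deviation of the baseline-subtracted residual is
    measured in a signal-free m/z region of the contralateral ROI-averaged
    spectrum, then scaled by the integration window width so the floor is
    comparable with trapezoidal areas.
    """
    params = params or BaselineParams()
    spec = average_spectrum(image, roi_mask(image, pair.contra))
    lo, hi = quiet_region
    sel = (spec.mz >= lo) & (spec.mz <= hi)
    if sel.sum() < 10:
        return 0.0
    residual = (spec.intensities - estimate_baseline(spec, params))[sel]
    mad = float(np.median(np.abs(residual - np.median(residual))))
    return 3.0 * mad * 2.0 * window


def quantify_section(
    image: SpectralImage,
    pair: RoiPair,
    panel: list[IonSpecies],
    params: BaselineParams | None = None,
    detection_floor: float | None = None,
) -> list[RatioRecord]:
    """Per-ion ipsi/contra AUC ratios for one section.

    Each hemisphere's ROI pixels are averaged into one spectrum, the baseline
    is subtracted, and each panel ion is integrated over its window; the
    record stores ratio = ipsi area / contra area.  Ions whose ipsi or
    contra area falls below the detection floor are flagged
    ``below_detection`` and carry ``ratio = nan``.
    """
    params = params or BaselineParams()
    if detection_floor is None:
        detection_floor = estimate_detection_floor(image, pair, params, window=panel[0].window if panel else 0.5)

    records: list[RatioRecord] = []
    ipsi_spec = subtract_baseline(average_spectrum(image, roi_mask(image, pair.ipsi)), params)
    contra_spec = subtract_baseline(average_spectrum(image, roi_mask(image, pair.contra)), params)
    for ion in panel:
        ipsi_area = integrate_peak(ipsi_spec, ion, roi_label="ipsilateral").area
        contra_area = integrate_peak(contra_spec, ion, roi_label="contralateral").area
        flags = ""
        if ipsi_area < detection_floor or contra_area < detection_floor:
            flags = BELOW_DETECTION
            ratio = float("nan")
        else:
            ratio = ipsi_area / contra_area
        records.append(
            RatioRecord(
                animal_id=image.animal_id,
                group=image.group,
                timepoint_days=image.timepoint_days if image.timepoint_days is not None else -1,
                ion=ion,
                ratio=ratio,
                ipsi_area=ipsi_area,
                contra_area=contra_area,
                flags=flags,
            )
        )
    return records


def detection_filter(records: list[RatioRecord], floor: float | None = None) -> list[RatioRecord]:
    """Drop ion channels that fall below the detection floor in any animal.

    A channel is removed cohort-wide as soon as one animal's ipsi or contra
    area is below ``floor`` (or carries a ``below_detection`` flag from
    quantification): a ratio cannot be trusted when its denominator sits in
    the noise, and a channel with missing animals cannot enter the group
    statistics.  Emits a warning naming the removed channels.
    """
    if floor is not None and floor < 0:
        raise ValueError("detection floor must be non-negative")

    undetected: set[str] = set()
    for rec in records:
        below = BELOW_DETECTION in rec.flags
        if floor is not None:
            below = below or rec.ipsi_area < floor or rec.contra_area < floor
        if below:
            undetected.add(rec.ion.label)

    kept = [rec for rec in records if rec.ion.label not in undetected]
    if undetected:
        warnings.warn(
            "channels below the detection threshold were excluded: "
            + ", ".join(sorted(undetected)),
            stacklevel=2,
        )
    if records and not kept:
        warnings.warn("all ion channels fell below the detection threshold", stacklevel=2)
    return kept


def records_to_frame(records: list[RatioRecord]) -> pd.DataFrame:
    """Tidy table of ratio records (one row per animal x ion)."""
    return pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "group": [r.group for r in records],
            "timepoint_days": [r.timepoint_days for r in records],
            "ion_name": [r.ion.species.name for r in records],
            "ceramide": [r.ion.species.ceramide.base_label for r in records],
            "adduct": [r.ion.adduct.value for r in records],
            "ion_label": [r.ion.label for r in records],
            "ratio": [r.ratio for r in records],
            "ipsi_area": [r.ipsi_area for r in records],
            "contra_area": [r.contra_area for r in records],
            "flags": [r.flags for r in records],
        }
    )
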