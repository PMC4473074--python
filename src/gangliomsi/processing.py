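"""ROI averaging, baseline subtraction and windowed peak-area integration.

The quantification scheme: pixels inside a polygonal ROI are averaged into
one spectrum, a slowly varying chemical baseline is estimated and removed,
and the area under the curve is integrated over a fixed window around each
panel ion's theoretical m/z.  No peak fitting, centroiding or TIC
normalization is applied — the downstream ipsilateral/contralateral ratio
cancels section-wide scale factors by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.ndimage import percentile_filter, uniform_filter1d
from shapely.geometry import Polygon as _ShapelyPolygon

from .chem import IonSpecies
from .msi_io import MassSpectrum, RoiPolygon, SpectralImage

__all__ = [
    "BaselineParams",
    "PeakArea",
    "ProcessingError",
    "average_spectrum",
    "integrate_peak",
    "ion_image",
    "roi_mask",
    "subtract_baseline",
]


class ProcessingError(ValueError):
    pass


@dataclass(frozen=True)
class BaselineParams:
    """Moving low-percentile baseline estimator parameters.

    The baseline at each m/z bin is the ``percentile`` quantile of the
    intensities within a ``window_width`` Da window, smoothed once with a
    moving average of the same width.  Defaults (10th percentile, 5 Da) track
    the slowly varying MALDI matrix/chemical baseline while ignoring peaks,
    whose widths are two orders of magnitude narrower.
    """

    method: str = "rolling_minimum_percentile"
    window_width: float = 5.0
    percentile: float = 0.10

    def __post_init__(self) -> None:
        if self.window_width <= 0:
            raise ProcessingError("baseline window_width must be positive")
        if not 0.0 <= self.percentile <= 0.5:
            raise ProcessingError("baseline percentile must lie in [0, 0.5]")


@dataclass(frozen=True)
class PeakArea:
    """Baseline-subtracted area under the curve for one ion channel."""

    ion: IonSpecies
    area: float
    roi_label: str = ""


def roi_mask(image: SpectralImage, polygon: RoiPolygon) -> np.ndarray:
    """Indices of pixels whose centers fall strictly inside the polygon.

    Containment follows the even-odd rule on pixel centers; pixels whose
    center lies exactly on the boundary are excluded.
    """
    poly = _ShapelyPolygon(polygon.vertices)
    if not poly.is_valid:
        raise ProcessingError(f"ROI polygon {polygon.label!r} is self-intersecting or degenerate")
    xs = image.coordinates[:, 0].astype(float)
    ys = image.coordinates[:, 1].astype(float)
    inside = shapely.contains_xy(poly, xs, ys)
    mask = np.flatnonzero(inside)
    if mask.size == 0:
        raise ProcessingError(
            f"ROI polygon {polygon.label!r} contains no pixel centers "
            "(is it outside the image grid?)"
        )
    return mask


def average_spectrum(image: SpectralImage, mask: np.ndarray) -> MassSpectrum:
    """Arithmetic mean spectrum over the masked pixels (continuous mode only)."""
    mask = np.asarray(mask, dtype=int)
    if mask.size == 0:
        raise ProcessingError("cannot average over an empty pixel mask")
    if not image.is_continuous:
        raise ProcessingError(
            "image pixels carry heterogeneous m/z axes; resample to a shared "
            "axis before ROI averaging"
        )
    return MassSpectrum(image.mz_axis, image.intensities[mask].mean(axis=0))


def _window_bins(mz: np.ndarray, width_da: float) -> int:
    spacing = float(np.median(np.diff(mz)))
    bins = int(round(width_da / spacing))
    # symmetric odd-sized window
    return max(3, bins | 1)


def estimate_baseline(spectrum: MassSpectrum, params: BaselineParams) -> np.ndarray:
    """Moving low-percentile baseline, smoothed once with the same window."""
    bins = _window_bins(spectrum.mz, params.window_width)
    if spectrum.mz.size < 3 or bins > spectrum.mz.size:
        raise ProcessingError(
            f"baseline window of {bins} bins does not fit a spectrum of "
            f"{spectrum.mz.size} bins"
        )
    low = percentile_filter(
        spectrum.intensities, percentile=100.0 * params.percentile, size=bins, mode="nearest"
    )
    return uniform_filter1d(low, size=bins, mode="nearest")


def subtract_baseline(spectrum: MassSpectrum, params: BaselineParams | None = None) -> MassSpectrum:
    """Baseline-subtracted spectrum, clipped at zero.

    Never increases any intensity and never produces negative values.
    """
    params = params or BaselineParams()
    baseline = estimate_baseline(spectrum, params)
    return MassSpectrum(spectrum.mz, np.maximum(spectrum.intensities - baseline, 0.0))


def integrate_peak(spectrum: MassSpectrum, ion: IonSpecies, roi_label: str = "") -> PeakArea:
    """Trapezoidal area under the curve over the ion's integration window.

    The spectrum is expected to be baseline-subtracted already; integration
    is a plain trapezoid on the native axis over [mz - window, mz + window].
    """
    lo, hi = ion.window_bounds
    if lo < spectrum.mz[0] or hi > spectrum.mz[-1]:
        raise ProcessingError(
            f"integration window [{lo:.3f}, {hi:.3f}] for {ion.label} falls "
            f"outside the spectrum axis [{spectrum.mz[0]:.3f}, {spectrum.mz[-1]:.3f}]"
        )
    sel = (spectrum.mz >= lo) & (spectrum.mz <= hi)
    if sel.sum() < 2:
        raise ProcessingError(
            f"integration window for {ion.label} covers fewer than 2 axis bins"
        )
    area = float(np.trapezoid(spectrum.intensities[sel], spectrum.mz[sel]))
    return PeakArea(ion=ion, area=max(area, 0.0), roi_label=roi_label)


def ion_image(
    image: SpectralImage,
    ion: IonSpecies,
    params: BaselineParams | None = None,
) -> np.ndarray:
    """Per-pixel baseline-subtracted window area as a 2D (ny, nx) map.

    Pixels absent from the image grid are NaN.  Rendering convention is
    low -> dark, high -> light (matplotlib "gray" colormap with an intensity
    bar); see :func:`gangliomsi.pipeline.render_ion_image`.
    """
    if not image.is_continuous:
        raise ProcessingError("ion images require a continuous-mode image")
    params = params or BaselineParams()
    mz = image.mz_axis
    bins = _window_bins(mz, params.window_width)
    low = percentile_filter(
        image.intensities, percentile=100.0 * params.percentile, size=(1, bins), mode="nearest"
    )
    corrected = np.maximum(image.intensities - uniform_filter1d(low, size=bins, axis=1, mode="nearest"), 0.0)

    lo, hi = ion.window_bounds
    if lo < mz[0] or hi > mz[-1]:
        raise ProcessingError(
            f"integration window for {ion.label} falls outside the image axis"
        )
    sel = (mz >= lo) & (mz <= hi)
    areas = np.trapezoid(corrected[:, sel], mz[sel], axis=1)

    nx, ny = image.grid_shape
    out = np.full((ny, nx), np.nan)
    out[image.coordinates[:, 1], image.coordinates[:, 0]] = areas
    return out
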