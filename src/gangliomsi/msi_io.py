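"""Spectral-image I/O: imzML read/write plus ROI and study-design tables.

Images follow the imzML convention: 0-based integer pixel coordinates with x
increasing rightward and y downward.  Continuous-mode images share a single
m/z axis across pixels; processed-mode images carry one sorted axis per
pixel.  Study metadata (animal, surgical group, timepoint) travels in the
design table, not inside imzML, which has no standard slot for it.
"""

from __future__ import annotations

import uuid as _uuid
from contextlib import contextmanager
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter
import pyimzml.ImzMLWriter as _writer_mod

__all__ = [
    "DesignError",
    "FormatError",
    "GROUPS",
    "MassSpectrum",
    "RoiPolygon",
    "SpectralImage",
    "TIMEPOINTS",
    "read_design",
    "read_imzml",
    "read_rois",
    "write_imzml",
    "write_rois",
]

GROUPS = ("control", "sham", "abeta", "et1", "abeta_et1")
TIMEPOINTS = (3, 21)


class FormatError(ValueError):
    """Malformed or inconsistent spectral-image file."""


class DesignError(ValueError):
    """Invalid study-design or ROI table."""


@dataclass
class MassSpectrum:
    """One mass spectrum: ascending m/z axis with non-negative intensities."""

    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz.shape != self.intensities.shape:
            raise FormatError(
                f"axis length {self.mz.size} != intensity length {self.intensities.size}"
            )
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise FormatError("m/z axis must be strictly increasing")
        if np.any(self.intensities < 0):
            raise FormatError("intensities must be non-negative")


@dataclass
class RoiPolygon:
    """Polygonal region of interest in pixel-space coordinates."""

    label: str
    vertices: np.ndarray  # (n, 2) ordered (x, y)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise DesignError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise DesignError("a polygon needs at least 3 vertices")


@dataclass
class SpectralImage:
    """Pixel grid of mass spectra with physical pitch and section metadata.

    Continuous mode: ``mz_axis`` is the shared axis and ``intensities`` is an
    (n_pixels, n_bins) matrix aligned with ``coordinates``.  Processed mode:
    ``spectra`` holds one :class:`MassSpectrum` per pixel and the shared
    fields are ``None``.
    """

    coordinates: np.ndarray  # (n, 2) int pixel coords (x, y)
    mz_axis: np.ndarray | None = None
    intensities: np.ndarray | None = None
    spectra: list[MassSpectrum] | None = None
    pitch_um: float = 100.0
    polarity: str = "negative"
    section_id: str = ""
    animal_id: str = ""
    group: str = ""
    timepoint_days: int | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        if self.pitch_um <= 0:
            raise FormatError("pixel pitch must be positive")
        n = len(self.coordinates)
        if len(np.unique(self.coordinates, axis=0)) != n:
            raise FormatError("pixel coordinates must be unique")
        if self.is_continuous:
            self.mz_axis = np.asarray(self.mz_axis, dtype=float)
            self.intensities = np.asarray(self.intensities, dtype=float)
            if self.intensities.shape != (n, self.mz_axis.size):
                raise FormatError(
                    f"intensity matrix shape {self.intensities.shape} does not match "
                    f"{n} pixels x {self.mz_axis.size} bins"
                )
            if self.mz_axis.size > 1 and not np.all(np.diff(self.mz_axis) > 0):
                raise FormatError("shared m/z axis must be strictly increasing")
        elif self.spectra is None or len(self.spectra) != n:
            raise FormatError("processed-mode image needs one spectrum per pixel")

    @property
    def is_continuous(self) -> bool:
        return self.mz_axis is not None

    @property
    def n_pixels(self) -> int:
        return len(self.coordinates)

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(nx, ny) extent of the pixel grid."""
        return (int(self.coordinates[:, 0].max()) + 1, int(self.coordinates[:, 1].max()) + 1)

    def spectrum_at(self, index: int) -> MassSpectrum:
        if self.is_continuous:
            return MassSpectrum(self.mz_axis, self.intensities[index])
        return self.spectra[index]

    def pixel_index(self) -> dict[tuple[int, int], int]:
        return {(int(x), int(y)): i for i, (x, y) in enumerate(self.coordinates)}


@contextmanager
def _deterministic_uuid(seed_material: str):
    """Scope a deterministic UUID into pyimzml's writer for reproducible bytes."""
    fixed = _uuid.uuid5(_uuid.NAMESPACE_URL, "gangliomsi:" + seed_material)
    original = _writer_mod.uuid.uuid4
    _writer_mod.uuid.uuid4 = lambda: fixed
    try:
        yield
    finally:
        _writer_mod.uuid.uuid4 = original


def write_imzml(image: SpectralImage, path: str | Path) -> Path:
    """Write a continuous-mode imzML file pair (.imzML + .ibd).

    Output bytes are deterministic for a fixed image: the imzML UUID is
    derived from the section id and pixel content rather than drawn randomly.
    """
    if not image.is_continuous:
        raise FormatError(
            "continuous-mode imzML requested but the image has per-pixel axes; "
            "resample to a shared axis first"
        )
    path = Path(path)
    if path.suffix == ".imzML":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)
    digest = f"{image.section_id}:{image.n_pixels}:{float(image.intensities.sum()):.6e}"
    with _deterministic_uuid(digest):
        with ImzMLWriter(
            str(path),
            mode="continuous",
            mz_dtype=np.float64,
            intensity_dtype=np.float64,
            spec_type="profile",
            polarity=image.polarity,
        ) as writer:
            for i, (x, y) in enumerate(image.coordinates):
                # imzML coordinates are 1-based
                writer.addSpectrum(image.mz_axis, image.intensities[i], (int(x) + 1, int(y) + 1, 1))
    xml_path = path.with_suffix(".imzML")
    # the writer stamps the absolute path into the run id; normalize to the
    # stem so identical images give identical bytes wherever they are written
    xml = xml_path.read_text()
    xml_path.write_text(xml.replace(f'id="{path}"', f'id="{path.name}"'))
    return xml_path


def read_imzml(path: str | Path, pitch_um: float = 100.0, polarity: str = "negative") -> SpectralImage:
    """Read an imzML file (continuous or processed mode) into a SpectralImage."""
    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not path.exists():
        raise FormatError(f"missing imzML index file: {path}")
    if not ibd.exists():
        raise FormatError(f"missing binary data file: {ibd}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # malformed XML or truncated binary
        raise FormatError(f"could not parse {path}: {exc}") from exc

    coords = np.array([(x - 1, y - 1) for x, y, *_ in parser.coordinates], dtype=int)
    n = len(coords)
    spectra = []
    for i in range(n):
        try:
            mz, intens = parser.getspectrum(i)
        except Exception as exc:
            raise FormatError(
                f"could not read spectrum for pixel {tuple(coords[i])} in {path}: {exc}"
            ) from exc
        if len(mz) != len(intens):
            raise FormatError(
                f"axis/intensity length mismatch at pixel {tuple(coords[i])} in {path}"
            )
        spectra.append((np.asarray(mz, dtype=float), np.asarray(intens, dtype=float)))

    shared = n > 0 and all(
        s[0].size == spectra[0][0].size and np.array_equal(s[0], spectra[0][0]) for s in spectra
    )
    if shared:
        return SpectralImage(
            coordinates=coords,
            mz_axis=spectra[0][0],
            intensities=np.vstack([s[1] for s in spectra]),
            pitch_um=pitch_um,
            polarity=polarity,
            section_id=path.stem,
        )
    return SpectralImage(
        coordinates=coords,
        spectra=[MassSpectrum(mz, np.maximum(i, 0.0)) for mz, i in spectra],
        pitch_um=pitch_um,
        polarity=polarity,
        section_id=path.stem,
    )


DESIGN_COLUMNS = ("animal_id", "group", "timepoint_days", "imzml_path")


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate the study-design table.

    Columns: animal_id, group (control/sham/abeta/et1/abeta_et1),
    timepoint_days (3 or 21), imzml_path (section file reference).
    """
    path = Path(path)
    try:
        design = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DesignError(f"design table {path} is empty") from None
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise DesignError(f"design table {path} is missing columns: {missing}")
    if design.empty:
        raise DesignError(f"design table {path} has no rows")

    bad_groups = sorted(set(design["group"]) - set(GROUPS))
    if bad_groups:
        raise DesignError(
            f"unknown group labels {bad_groups}; allowed labels are {list(GROUPS)}"
        )
    bad_tp = sorted(set(design["timepoint_days"].astype(int)) - set(TIMEPOINTS))
    if bad_tp:
        raise DesignError(f"unknown timepoints {bad_tp}; allowed: {list(TIMEPOINTS)}")
    dupes = design.duplicated(subset=["animal_id", "imzml_path"])
    if dupes.any():
        raise DesignError(
            f"duplicated animal/section rows in {path}: "
            f"{design.loc[dupes, 'animal_id'].tolist()}"
        )
    design = design.copy()
    design["timepoint_days"] = design["timepoint_days"].astype(int)
    design["animal_id"] = design["animal_id"].astype(str)
    return design


ROI_COLUMNS = ("section_id", "label", "x", "y")
ROI_LABELS = ("ipsilateral", "contralateral", "other", "midline")


def read_rois(path: str | Path) -> dict[str, dict[str, object]]:
    """Read the ROI polygon table.

    One row per vertex, ordered within each (section_id, label).  The special
    label ``midline`` carries a single row whose x gives the sagittal axis of
    that section.  Returns ``{section_id: {"polygons": {label: RoiPolygon},
    "midline_x": float | None}}``.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise DesignError(f"ROI table {path} is empty") from None
    missing = [c for c in ROI_COLUMNS if c not in table.columns]
    if missing:
        raise DesignError(f"ROI table {path} is missing columns: {missing}")
    bad = sorted(set(table["label"]) - set(ROI_LABELS))
    if bad:
        raise DesignError(f"unknown ROI labels {bad}; allowed: {list(ROI_LABELS)}")

    out: dict[str, dict[str, object]] = {}
    for section_id, section_rows in table.groupby("section_id", sort=False):
        entry: dict[str, object] = {"polygons": {}, "midline_x": None}
        for label, rows in section_rows.groupby("label", sort=False):
            if label == "midline":
                entry["midline_x"] = float(rows["x"].iloc[0])
            else:
                entry["polygons"][label] = RoiPolygon(
                    label=label, vertices=rows[["x", "y"]].to_numpy(dtype=float)
                )
        out[str(section_id)] = entry
    return out


def write_rois(rois: dict[str, dict[str, object]], path: str | Path) -> Path:
    """Write ROI polygons (inverse of :func:`read_rois`)."""
    records = []
    for section_id, entry in rois.items():
        for label, poly in entry.get("polygons", {}).items():
            for x, y in poly.vertices:
                records.append((section_id, label, x, y))
        if entry.get("midline_x") is not None:
            records.append((section_id, "midline", float(entry["midline_x"]), 0.0))
    path = Path(path)
    pd.DataFrame(records, columns=list(ROI_COLUMNS)).to_csv(path, index=False)
    return path
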