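"""Synthetic spectral-image and cell-count generator with known ground truth.

Emulates negative-mode MALDI imaging of 10 um coronal rat brain sections
acquired at 100 um pixel pitch, with a unilateral striatal lesion: panel
ganglioside peaks ride on a smooth chemical baseline, each section carries
a log-normal multiplicative gain (tissue heterogeneity, matrix application,
ion suppression — the factors the ipsi/contra ratio is designed to cancel),
and additive Gaussian detector noise is applied per bin.  Inside the lesion
region each ion's amplitude is multiplied by a configurable fold change;
the contralateral hemisphere is always the fold-1 anchor.

The shipped default effect table encodes the qualitative group x timepoint
findings this pipeline is built to detect (which channels rise or fall, in
which surgical groups, at 3 vs 21 days).  The fold-change magnitudes
(1.8 up, 0.6 down) and all noise levels are implementer defaults chosen to
be realistic — the underlying study reports directions and significance,
not effect magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .chem import IonSpecies, build_panel
from .msi_io import GROUPS, RoiPolygon, SpectralImage, write_imzml, write_rois
from .ratios import mirror_roi

__all__ = [
    "CellCountConfig",
    "EffectConfig",
    "default_amplitudes",
    "default_effect_table",
    "ellipse_polygon",
    "make_design",
    "simulate_cellcounts",
    "simulate_cohort",
    "simulate_section",
]

ELEVATED = 1.8
REDUCED = 0.6


def default_effect_table() -> dict[tuple[str, str, int], float]:
    """Ipsilateral fold change per (ion label, group, timepoint_days).

    Entries absent from the map default to 1 (no change); control, sham and
    abeta-alone groups carry no entries.  Directions follow the reported
    group x timepoint pattern; magnitudes are generator defaults.
    """
    up, down = ELEVATED, REDUCED
    table: dict[tuple[str, str, int], float] = {}

    for cer in ("d18:1", "d20:1"):
        # GM2 rises with stroke at 3 d, persists only with combined Abeta
        table[(f"GM2 {cer} [M-H]-", "et1", 3)] = up
        table[(f"GM2 {cer} [M-H]-", "abeta_et1", 3)] = up
        table[(f"GM2 {cer} [M-H]-", "abeta_et1", 21)] = up
        # GM3 rises with the combined insult at 3 d, and in both stroke
        # groups by 21 d (the d20:1 channel sits below detection regardless)
        table[(f"GM3 {cer} [M-H]-", "abeta_et1", 3)] = up
        table[(f"GM3 {cer} [M-H]-", "et1", 21)] = up
        table[(f"GM3 {cer} [M-H]-", "abeta_et1", 21)] = up
        # GD1a potassium adduct dips at 3 d after stroke alone, recovers
        table[(f"GD1a {cer} [M-2H+K]-", "et1", 3)] = down

    # GM1: combined-group elevation; persistent only for d20:1
    table[("GM1 d18:1 [M-H]-", "abeta_et1", 3)] = up
    table[("GM1 d20:1 [M-H]-", "abeta_et1", 3)] = up
    table[("GM1 d20:1 [M-H]-", "abeta_et1", 21)] = up
    # GD1a sodium adduct: transient combined-group elevation (d18:1 only)
    table[("GD1a d18:1 [M-2H+Na]-", "abeta_et1", 3)] = up
    return table


def default_amplitudes() -> dict[str, float]:
    """Peak amplitudes (arbitrary intensity units) per ion channel.

    Relative scale follows brain ganglioside abundance (GM1 > GM3, GM2,
    GD1a); the GM3 d20:1 channel is set well below the detection floor, the
    one channel the quantification is expected to discard.
    """
    return {
        "GM3 d18:1 [M-H]-": 60.0,
        "GM3 d20:1 [M-H]-": 0.2,
        "GM2 d18:1 [M-H]-": 40.0,
        "GM2 d20:1 [M-H]-": 25.0,
        "GM1 d18:1 [M-H]-": 100.0,
        "GM1 d20:1 [M-H]-": 60.0,
        "GD1a d18:1 [M-2H+Na]-": 50.0,
        "GD1a d20:1 [M-2H+Na]-": 30.0,
        "GD1a d18:1 [M-2H+K]-": 45.0,
        "GD1a d20:1 [M-2H+K]-": 28.0,
    }


@dataclass(frozen=True)
class EffectConfig:
    """Generator configuration: geometry, signal model, effects and noise."""

    grid_shape: tuple[int, int] = (26, 18)       # (nx, ny) pixels
    pitch_um: float = 100.0
    mz_start: float = 1150.0
    mz_stop: float = 1930.0
    mz_step: float = 0.1
    peak_sigma: float = 0.15                     # Gaussian peak width, Da
    baseline_coeffs: tuple[float, ...] = (25.0, -15.0, 5.0)  # polynomial in (mz-start)/(stop-start)
    noise_sigma: float = 4.0                     # additive Gaussian, intensity units
    gain_sigma: float = 0.2                      # log-normal per-section gain
    lesion_center: tuple[float, float] = (19.0, 8.5)
    lesion_axes: tuple[float, float] = (5.0, 5.5)
    midline_x: float = 12.5
    fold_changes: Mapping[tuple[str, str, int], float] = field(default_factory=default_effect_table)
    amplitudes: Mapping[str, float] = field(default_factory=default_amplitudes)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fold_changes.values()):
            raise ValueError("fold changes must be positive")
        if self.noise_sigma < 0 or self.gain_sigma < 0:
            raise ValueError("noise parameters must be non-negative")
        cx, cy = self.lesion_center
        ax, ay = self.lesion_axes
        nx, ny = self.grid_shape
        if not (0 <= cx - ax and cx + ax <= nx - 1 and 0 <= cy - ay and cy + ay <= ny - 1):
            raise ValueError("lesion ellipse extends outside the pixel grid")

    @property
    def mz_axis(self) -> np.ndarray:
        n = int(round((self.mz_stop - self.mz_start) / self.mz_step)) + 1
        return self.mz_start + self.mz_step * np.arange(n)

    def fold(self, ion_label: str, group: str, timepoint_days: int) -> float:
        return float(self.fold_changes.get((ion_label, group, timepoint_days), 1.0))

    def baseline(self, mz: np.ndarray) -> np.ndarray:
        u = (mz - self.mz_start) / (self.mz_stop - self.mz_start)
        return np.polynomial.polynomial.polyval(u, self.baseline_coeffs)


def ellipse_polygon(center: tuple[float, float], axes: tuple[float, float], n_vertices: int = 32) -> np.ndarray:
    """Polygonal approximation of an ellipse, counter-clockwise."""
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    return np.column_stack(
        [center[0] + axes[0] * np.cos(theta), center[1] + axes[1] * np.sin(theta)]
    )


def lesion_roi(config: EffectConfig) -> RoiPolygon:
    """The lesion outline, which doubles as the ipsilateral ROI.

    The lesion region is *defined* as the set of pixel centers inside this
    polygon, so the quantification ROI and the simulated effect region
    coincide exactly — parameter recovery is then a property of the spectral
    processing, not of ROI placement error.
    """
    return RoiPolygon(
        label="ipsilateral",
        vertices=ellipse_polygon(config.lesion_center, config.lesion_axes),
    )


def _gaussian_peaks(
    mz: np.ndarray,
    panel: list[IonSpecies],
    config: EffectConfig,
    folds: Mapping[str, float],
) -> np.ndarray:
    out = np.zeros_like(mz)
    sigma = config.peak_sigma
    for ion in panel:
        amp = float(config.amplitudes.get(ion.label, 0.0)) * folds.get(ion.label, 1.0)
        if amp == 0.0:
            continue
        sel = np.abs(mz - ion.mz) < 6.0 * sigma
        out[sel] += amp * np.exp(-0.5 * ((mz[sel] - ion.mz) / sigma) ** 2)
    return out


def simulate_section(
    config: EffectConfig,
    animal_id: str,
    group: str,
    timepoint_days: int,
    seed: int | np.random.SeedSequence | None = None,
    panel: list[IonSpecies] | None = None,
) -> tuple[SpectralImage, dict]:
    """One synthetic section for one animal, with its ground truth.

    Per-pixel spectrum: gain x [baseline(mz) + sum_i amplitude_i x
    fold_i^(pixel in lesion) x N(mz; mz_i, sigma)] + noise, clipped at zero.
    The per-section gain is a single log-normal draw shared by every pixel.
    Returns the image and a ground-truth dict (fold map, lesion pixel
    indices, ROI polygon, gain).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; allowed: {list(GROUPS)}")
    panel = panel if panel is not None else build_panel()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    nx, ny = config.grid_shape
    mz = config.mz_axis

    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny))
    coords = np.column_stack([xs.ravel(), ys.ravel()])

    roi = lesion_roi(config)
    from .processing import roi_mask  # local import to avoid a cycle

    folds = {ion.label: config.fold(ion.label, group, timepoint_days) for ion in panel}
    baseline = config.baseline(mz)
    profile_intact = baseline + _gaussian_peaks(mz, panel, config, {})
    profile_lesion = baseline + _gaussian_peaks(mz, panel, config, folds)

    intensities = np.tile(profile_intact, (len(coords), 1))
    # lesion membership evaluated on the same polygon the ROI file will carry
    probe = SpectralImage(
        coordinates=coords,
        mz_axis=mz[:2],
        intensities=np.zeros((len(coords), 2)),
        pitch_um=config.pitch_um,
    )
    lesion_idx = roi_mask(probe, roi)
    intensities[lesion_idx] = profile_lesion

    gain = float(rng.lognormal(mean=0.0, sigma=config.gain_sigma)) if config.gain_sigma > 0 else 1.0
    intensities *= gain
    if config.noise_sigma > 0:
        intensities += rng.normal(0.0, config.noise_sigma, size=intensities.shape)
    np.maximum(intensities, 0.0, out=intensities)

    section_id = f"{animal_id}_{timepoint_days}d"
    image = SpectralImage(
        coordinates=coords,
        mz_axis=mz,
        intensities=intensities,
        pitch_um=config.pitch_um,
        polarity="negative",
        section_id=section_id,
        animal_id=animal_id,
        group=group,
        timepoint_days=timepoint_days,
    )
    truth = {
        "fold_changes": folds,
        "lesion_pixels": lesion_idx,
        "roi": roi,
        "midline_x": config.midline_x,
        "gain": gain,
    }
    return image, truth


def make_design(
    groups: tuple[str, ...] = GROUPS,
    n_per_group: int = 4,
    timepoints: tuple[int, ...] = (3,),
) -> pd.DataFrame:
    """Balanced design table: one section per animal per timepoint."""
    rows = []
    counter = 0
    for group in groups:
        for _ in range(n_per_group):
            counter += 1
            animal = f"a{counter:02d}"
            for tp in timepoints:
                rows.append((animal, group, tp, f"{animal}_{tp}d.imzML"))
    return pd.DataFrame(rows, columns=["animal_id", "group", "timepoint_days", "imzml_path"])


def simulate_cohort(
    config: EffectConfig,
    design: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    panel: list[IonSpecies] | None = None,
) -> tuple[list[tuple[SpectralImage, dict]], pd.DataFrame, dict]:
    """Simulate one section per design row, with per-animal derived seeds.

    Returns (sections, design, rois).  When ``out_dir`` is given, also
    writes the imzML files, the design CSV, the ROI CSV and a ground-truth
    YAML there.
    """
    if design is None:
        design = make_design()
    panel = panel if panel is not None else build_panel()
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(design))

    sections: list[tuple[SpectralImage, dict]] = []
    rois: dict[str, dict] = {}
    roi = lesion_roi(config)
    contra = mirror_roi(roi, config.midline_x, grid_shape=config.grid_shape)
    for (row, child) in zip(design.itertuples(index=False), children):
        image, truth = simulate_section(
            config, str(row.animal_id), row.group, int(row.timepoint_days),
            seed=child, panel=panel,
        )
        sections.append((image, truth))
        rois[image.section_id] = {
            "polygons": {"ipsilateral": roi, "contralateral": contra},
            "midline_x": config.midline_x,
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for image, _ in sections:
            write_imzml(image, out_dir / image.section_id)
        design.to_csv(out_dir / "design.csv", index=False)
        write_rois(rois, out_dir / "rois.csv")
        truth_dump = {
            image.section_id: {
                "group": image.group,
                "timepoint_days": int(image.timepoint_days),
                "gain": truth["gain"],
                "fold_changes": {k: float(v) for k, v in truth["fold_changes"].items()},
            }
            for image, truth in sections
        }
        with open(out_dir / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(truth_dump, fh, sort_keys=True)
    return sections, design, rois


# ---------------------------------------------------------------------------
# cell counts


def _default_count_means() -> dict[tuple[str, str, int], float]:
    # FJB (degenerating cells): both stroke groups start equal at 3 d; by
    # 21 d the stroke-alone count falls by 65% and the combined group by
    # only 35%.  NeuN (surviving neurons): equal at 3 d, lower in the
    # combined group by 21 d.  Absolute means are generator defaults.
    return {
        ("et1", "FJB", 3): 300.0,
        ("et1", "FJB", 21): 105.0,
        ("abeta_et1", "FJB", 3): 300.0,
        ("abeta_et1", "FJB", 21): 195.0,
        ("et1", "NeuN", 3): 200.0,
        ("et1", "NeuN", 21): 180.0,
        ("abeta_et1", "NeuN", 3): 200.0,
        ("abeta_et1", "NeuN", 21): 130.0,
    }


@dataclass(frozen=True)
class CellCountConfig:
    """Negative-binomial cell-count model per (group, stain, timepoint).

    ``dispersion`` is the NB shape parameter k (variance = mu + mu^2/k);
    ``numpy.inf`` gives the Poisson limit and ``None`` the zero-variance
    degenerate mode in which every draw equals its configured mean exactly.
    """

    means: Mapping[tuple[str, str, int], float] = field(default_factory=_default_count_means)
    dispersion: float | None = 50.0
    n_per_group: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.means.values()):
            raise ValueError("configured mean counts must be positive")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive, inf, or None for degenerate mode")


def simulate_cellcounts(
    config: CellCountConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Draw a cell-count table (animal_id, group, timepoint_days, stain, count)."""
    config = config or CellCountConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows = []
    animal_ids: dict[tuple[str, int], list[str]] = {}
    counter = 0
    for (group, stain, tp), mu in sorted(config.means.items()):
        key = (group, tp)
        if key not in animal_ids:
            animal_ids[key] = []
            for _ in range(config.n_per_group):
                counter += 1
                animal_ids[key].append(f"c{counter:02d}")
        for animal in animal_ids[key]:
            if config.dispersion is None:
                count = mu
            elif np.isinf(config.dispersion):
                count = float(rng.poisson(mu))
            else:
                k = config.dispersion
                count = float(rng.negative_binomial(k, k / (k + mu)))
            rows.append((animal, group, tp, stain, count))
    return pd.DataFrame(
        rows, columns=["animal_id", "group", "timepoint_days", "stain", "count"]
    )
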