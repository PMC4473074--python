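"""End-to-end orchestration: simulate -> quantify -> stats -> render."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import build_panel, default_panel_config
from .msi_io import DesignError, read_design, read_imzml, read_rois
from .processing import BaselineParams, ion_image
from .ratios import RoiPair, detection_filter, mirror_roi, quantify_section, records_to_frame
from .stats import AnovaResult, anova_tukey_by

__all__ = [
    "PipelineConfig",
    "render_ion_image",
    "render_ratio_bars",
    "results_to_frame",
    "run_quantify",
    "run_stats",
]

log = logging.getLogger("gangliomsi")

_KNOWN_KEYS = {
    "panel", "baseline", "detection_floor", "alpha", "log_scale",
    "design_path", "roi_path", "data_dir", "output_dir", "seed",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``docs/methods.md`` for units)."""

    panel: dict = field(default_factory=default_panel_config)
    baseline: BaselineParams = field(default_factory=BaselineParams)
    detection_floor: float | None = None   # None -> estimated per section
    alpha: float = 0.05
    log_scale: bool = False
    design_path: str = "design.csv"
    roi_path: str = "rois.csv"
    data_dir: str = "."
    output_dir: str = "out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise DesignError(f"unknown config keys: {sorted(unknown)}")
        if "baseline" in raw:
            raw["baseline"] = BaselineParams(**raw["baseline"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_quantify(config: PipelineConfig, sections=None, rois=None, design=None) -> pd.DataFrame:
    """Quantify every section in the design into the tidy ratio table.

    ``sections`` may be pre-loaded (in-memory) images; otherwise each
    section's imzML is read from ``data_dir``.  Output is deterministic for
    fixed inputs.
    """
    panel = build_panel(config.panel)
    if design is None:
        design = read_design(Path(config.data_dir) / config.design_path)
    if rois is None:
        rois = read_rois(Path(config.data_dir) / config.roi_path)
    by_id = None
    if sections is not None:
        by_id = {img.section_id: img for img in sections}

    all_records = []
    for row in design.itertuples(index=False):
        section_id = Path(str(row.imzml_path)).stem
        try:
            if by_id is not None:
                image = by_id[section_id]
            else:
                image = read_imzml(Path(config.data_dir) / str(row.imzml_path))
            image.animal_id = str(row.animal_id)
            image.group = row.group
            image.timepoint_days = int(row.timepoint_days)
            entry = rois[section_id]
            ipsi = entry["polygons"]["ipsilateral"]
            midline = entry["midline_x"]
            if midline is None:
                raise DesignError(f"section {section_id} has no midline row in the ROI table")
            contra = entry["polygons"].get("contralateral")
            if contra is None:
                contra = mirror_roi(ipsi, midline, grid_shape=image.grid_shape)
            pair = RoiPair(ipsi=ipsi, contra=contra, midline_x=midline)
            log.info("quantifying section %s (%s, %s d)", section_id, row.group, row.timepoint_days)
            records = quantify_section(
                image, pair, panel, params=config.baseline,
                detection_floor=config.detection_floor,
            )
        except KeyError as exc:
            raise DesignError(f"section {section_id}: missing input {exc}") from exc
        except Exception as exc:
            raise type(exc)(f"section {section_id}: {exc}") from exc
        all_records.extend(records)

    all_records = detection_filter(all_records)
    table = records_to_frame(all_records)
    table.attrs["gangliomsi_version"] = __version__
    table.attrs["config_hash"] = config.config_hash()
    log.info(
        "quantified %d sections -> %d ratio records (gangliomsi %s, config %s)",
        len(design), len(table), __version__, table.attrs["config_hash"],
    )
    return table


def run_stats(
    ratio_table: pd.DataFrame,
    alpha: float = 0.05,
    log_scale: bool = False,
) -> dict[tuple, AnovaResult]:
    """Per-ion, per-timepoint one-way ANOVA with Tukey post-hoc."""
    if ratio_table.empty:
        raise DesignError("ratio table is empty")
    return anova_tukey_by(
        ratio_table, by=("ion_label", "timepoint_days"), alpha=alpha, log_scale=log_scale
    )


def results_to_frame(results: dict[tuple, AnovaResult]) -> pd.DataFrame:
    rows = []
    for (ion_label, timepoint), res in results.items():
        for comp in res.comparisons:
            rows.append(
                {
                    "ion_label": ion_label,
                    "timepoint_days": timepoint,
                    "anova_F": res.f_statistic,
                    "anova_p": res.p_value,
                    "group_a": comp.group_a,
                    "group_b": comp.group_b,
                    "mean_difference": comp.mean_difference,
                    "p_adjusted": comp.p_adjusted,
                    "significant": comp.significant,
                }
            )
    return pd.DataFrame(rows)


def render_ion_image(image, ion, path: str | Path, params: BaselineParams | None = None) -> Path:
    """Render an ion intensity map: low -> dark, high -> light, with a bar."""
    area_map = ion_image(image, ion, params=params)
    fig, ax = plt.subplots(figsize=(5, 4))
    shown = ax.imshow(area_map, cmap="gray", origin="upper", interpolation="nearest")
    fig.colorbar(shown, ax=ax, label="peak area (intensity x Da)")
    ax.set_title(f"{ion.label}  m/z {ion.mz:.2f}")
    ax.set_xlabel("x (pixels)")
    ax.set_ylabel("y (pixels)")
    path = Path(path)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def render_ratio_bars(
    ratio_table: pd.DataFrame,
    results: dict[tuple, AnovaResult],
    out_dir: str | Path,
    alpha: float = 0.05,
    reference_groups: tuple[str, ...] = ("control", "sham"),
) -> list[Path]:
    """Bar charts of mean ipsi/contra ratio per group, starred when a group
    differs significantly from every reference group (Tukey-adjusted)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (ion_label, timepoint), cell in ratio_table.groupby(["ion_label", "timepoint_days"]):
        summary = cell.groupby("group")["ratio"].agg(["mean", "sem"])
        res = results.get((ion_label, timepoint))
        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        xpos = np.arange(len(summary))
        ax.bar(xpos, summary["mean"], yerr=summary["sem"], capsize=3, color="0.6")
        ax.axhline(1.0, color="k", lw=0.8, ls=":")
        ax.set_xticks(xpos)
        ax.set_xticklabels(summary.index, rotation=30, ha="right")
        ax.set_ylabel("ipsi / contra ratio")
        ax.set_title(f"{ion_label}, {timepoint} d")
        if res is not None:
            refs = [g for g in reference_groups if g in summary.index]
            for i, group in enumerate(summary.index):
                if group in reference_groups or not refs:
                    continue
                try:
                    starred = all(
                        res.comparison(group, ref).p_adjusted < alpha for ref in refs
                    )
                except KeyError:
                    starred = False
                if starred:
                    y = summary.loc[group, "mean"] + 1.5 * (summary.loc[group, "sem"] or 0)
                    ax.text(i, y, "*", ha="center", fontsize=14)
        safe = ion_label.replace(" ", "_").replace("/", "-").replace("[", "").replace("]", "").replace(":", "")
        path = out_dir / f"ratios_{safe}_{timepoint}d.png"
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
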