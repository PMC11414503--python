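"""End-to-end orchestration: volume -> masks -> meshes -> metrics -> report.

``run_subject`` performs the per-subject imaging pipeline (threshold
segmentation of the soft and calcified windows, Boolean union, connected
components, 1 mm^3 filter, surface reconstruction, morphometry);
``run_cohort`` aggregates subject outputs, or generates a synthetic cohort,
and runs the full consistency analysis. Fixed seeds reproduce byte-identical
CSV outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import segmentation as seg
from .cohort import CohortSpec, make_cohort
from .image import BinaryMask, CALC_WINDOW, HuWindow, ImageVolume, SOFT_WINDOW
from .morphometry import (
    METRIC_COLUMNS,
    Centreline,
    compute_centreline,
    measure_plaque,
)
from .reconstruction import extract_surface
from .stats import SUMMARY_FIELDS, FitResult, consistency_report, subject_summary

logger = logging.getLogger("plaquemorph")

__all__ = ["RunConfig", "run_subject", "run_cohort", "report_from_tables"]

CALC_COLUMNS = ["plaque_id", "volume_mm3", "surface_area_mm2"]


@dataclass
class RunConfig:
    """Configuration of one subject-level pipeline run."""

    volume: ImageVolume | str | Path
    axis: np.ndarray | str | Path | None = None  # centreline polyline (mm)
    soft_window: HuWindow = field(default_factory=lambda: SOFT_WINDOW)
    calc_window: HuWindow = field(default_factory=lambda: CALC_WINDOW)
    min_volume: float = 1.0  # mm^3 exclusion for plaques and calcifications
    connectivity: int = 26
    cross_section_step: float = 0.5  # mm
    roi: tuple[slice, slice, slice] | None = None
    out_dir: str | Path | None = None
    subject_id: int = 0
    seed: int = 0

    def load_volume(self) -> ImageVolume:
        if isinstance(self.volume, ImageVolume):
            return self.volume
        return ImageVolume.load(self.volume)

    def load_axis(self) -> np.ndarray | None:
        if self.axis is None:
            return None
        if isinstance(self.axis, (str, Path)):
            p = Path(self.axis)
            if p.suffix == ".json":
                return np.asarray(json.loads(p.read_text()), dtype=float)
            return pd.read_csv(p).to_numpy(dtype=float)[:, :3]
        return np.asarray(self.axis, dtype=float)


def _centreline_for(cfg: RunConfig, vol: ImageVolume) -> Centreline:
    axis = cfg.load_axis()
    if axis is not None:
        return compute_centreline(axis=axis, step=cfg.cross_section_step)
    # no axis supplied: treat contrast-filled voxels above the calcified
    # window as lumen and extract a skeleton ridge path
    lumen = vol.intensities > cfg.calc_window.high
    if not lumen.any():
        raise ValueError(
            "no axis supplied and no voxels above the calcified window to "
            "serve as lumen; provide an axis polyline"
        )
    mask = BinaryMask(lumen, vol.spacing, vol.origin)
    return compute_centreline(lumen_mask=mask, step=cfg.cross_section_step)


def run_subject(cfg: RunConfig):
    """Segment, reconstruct and measure every surviving plaque component.

    Returns ``(plaque_df, calc_df, summary)`` where *summary* is None when
    no component survives the 1 mm^3 filter (the caller decides how to
    surface the empty result; the CLI exits with a dedicated code).
    Calcified components are assigned to the plaque whose unioned mask
    contains them.
    """
    vol = cfg.load_volume()
    soft = seg.threshold_mask(vol, cfg.soft_window, cfg.roi)
    calc = seg.threshold_mask(vol, cfg.calc_window, cfg.roi)
    union = seg.revise_mask(seg.union_masks(soft, calc))
    labels = seg.label_components(union, cfg.connectivity)
    logger.info("subject %s: %d raw components", cfg.subject_id, labels.n_components)
    labels = seg.filter_by_volume(labels, cfg.min_volume)
    logger.info(
        "subject %s: %d components survive the %.2f mm^3 filter",
        cfg.subject_id, labels.n_components, cfg.min_volume,
    )
    plaque_rows, calc_rows = [], []
    if labels.n_components > 0:
        centreline = _centreline_for(cfg, vol)
        calc_labels = seg.label_components(calc, cfg.connectivity)
        for lab in range(1, labels.n_components + 1):
            comp = labels.component_mask(lab)
            mesh = extract_surface(comp)
            # calcified components whose voxels lie inside this plaque mask
            calc_meshes = []
            for cl in range(1, calc_labels.n_components + 1):
                cmask = calc_labels.labels == cl
                inside = comp.voxels[cmask]
                if inside.size and inside.mean() > 0.5:
                    calc_meshes.append(
                        extract_surface(
                            BinaryMask(cmask, vol.spacing, vol.origin)
                        )
                    )
            metrics, calcs = measure_plaque(
                mesh,
                calc_meshes,
                centreline,
                step=cfg.cross_section_step,
                min_calc_volume=cfg.min_volume,
                plaque_id=lab,
            )
            row = {"subject_id": cfg.subject_id, "plaque_id": lab}
            row.update(metrics.as_row())
            row["calc_volume_mm3"] = sum(c.volume for c in calcs)
            row["calc_surface_area_mm2"] = sum(c.surface_area for c in calcs)
            plaque_rows.append(row)
            logger.debug("plaque %d metrics: %s", lab, row)
            for c in calcs:
                calc_rows.append(
                    {
                        "subject_id": cfg.subject_id,
                        "plaque_id": c.parent_plaque_id,
                        "volume_mm3": c.volume,
                        "surface_area_mm2": c.surface_area,
                    }
                )
    plaque_df = pd.DataFrame(
        plaque_rows, columns=["subject_id", "plaque_id", *METRIC_COLUMNS,
                              "calc_volume_mm3", "calc_surface_area_mm2"]
    )
    calc_df = pd.DataFrame(
        calc_rows, columns=["subject_id", *CALC_COLUMNS]
    )
    summary = subject_summary(plaque_df, calc_df) if len(plaque_df) else None
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        plaque_df.to_csv(out / "plaques.csv", index=False, float_format="%.9g")
        calc_df.to_csv(out / "calcifications.csv", index=False, float_format="%.9g")
        if summary is not None:
            pd.DataFrame([{"subject_id": cfg.subject_id, **summary.as_row()}]).to_csv(
                out / "subject_summary.csv", index=False, float_format="%.9g"
            )
    return plaque_df, calc_df, summary


def subject_table_from_plaques(plaque_df: pd.DataFrame,
                               calc_df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate a per-plaque table to the 12 subject-level summary fields."""
    rows = []
    for sid, grp in plaque_df.groupby("subject_id"):
        if calc_df is not None and len(calc_df):
            calcs = calc_df[calc_df["subject_id"] == sid]
        elif "calc_volume_mm3" in plaque_df.columns:
            calcs = pd.DataFrame(
                {
                    "volume_mm3": grp["calc_volume_mm3"],
                    "surface_area_mm2": grp["calc_surface_area_mm2"],
                }
            )
        else:
            calcs = None
        rows.append({"subject_id": sid, **subject_summary(grp, calcs).as_row()})
    return pd.DataFrame(rows)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _markdown_report(report: dict) -> str:
    lines = ["# Geometric consistency report", ""]
    lines.append("## Pairwise fits between plaque geometric parameters")
    lines.append("")
    lines.append("| x | y | linear R² | linear p | power b | power R² | label |")
    lines.append("|---|---|-----------|----------|---------|----------|-------|")
    for e in report.get("pairwise_fits", []):
        lin: FitResult = e["linear"]
        pw: FitResult = e["power"]
        label = "strong" if e["strong"] else ("significant" if e["significant"] else "-")
        lines.append(
            f"| {e['x']} | {e['y']} | {lin.r_squared:.3f} | {lin.p_value:.3g} "
            f"| {pw.b:.3f} | {pw.r_squared:.3f} | {label} |"
        )
    if "calcification_fits" in report:
        lines += ["", "## Plaque vs calcification fits", ""]
        lines.append("| subset | x | y | linear R² | linear p |")
        lines.append("|--------|---|---|-----------|----------|")
        for e in report["calcification_fits"]:
            lin = e["linear"]
            if lin is None:
                continue
            lines.append(
                f"| {e['subset']} | {e['x']} | {e['y']} | {lin.r_squared:.3f} "
                f"| {lin.p_value:.3g} |"
            )
    if "covariate_spearman" in report:
        lines += ["", "## Subject-level Spearman (covariates × summary parameters)", ""]
        header = "| covariate | " + " | ".join(SUMMARY_FIELDS) + " |"
        lines.append(header)
        lines.append("|" + "---|" * (len(SUMMARY_FIELDS) + 1))
        for cov, row in report["covariate_spearman"].items():
            cells = []
            for f in SUMMARY_FIELDS:
                r = row.get(f)
                cells.append(f"{r.rho:.2f}{'*' if r.label != 'none' else ''}" if r else "")
            lines.append(f"| {cov} | " + " | ".join(cells) + " |")
    if "srh" in report:
        srh = report["srh"]
        lines += ["", "## Plaque volume by subject and side", ""]
        lines.append(f"Levene p (side) = {report['levene_p_side']:.4g}; "
                     f"variance {'homogeneous' if report['variance_homogeneous'] else 'heterogeneous'}")
        lines.append("")
        lines.append("| term | H | df | p |")
        lines.append("|------|---|----|---|")
        lines.append(f"| subject | {srh.H_A:.3f} | {srh.df_A} | {srh.p_A:.4g} |")
        lines.append(f"| side | {srh.H_B:.3f} | {srh.df_B} | {srh.p_B:.4g} |")
        lines.append(
            f"| interaction | {srh.H_interaction:.3f} | {srh.df_interaction} "
            f"| {srh.p_interaction:.4g} |"
        )
    lines.append("")
    lines.append(f"Tests performed (no multiplicity correction): {report.get('n_tests', 0)}")
    lines.append("")
    return "\n".join(lines)


def report_from_tables(
    plaque_df: pd.DataFrame,
    subject_df: pd.DataFrame | None = None,
    covariate_df: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    figures: bool = False,
) -> dict:
    """Run the consistency analysis on ready-made tables and emit outputs."""
    if subject_df is None:
        subject_df = subject_table_from_plaques(plaque_df)
    report = consistency_report(plaque_df, subject_df, covariate_df)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        serializable = {k: v for k, v in report.items() if k != "anova"}
        (out / "report.json").write_text(json.dumps(_jsonable(serializable), indent=2))
        (out / "report.md").write_text(_markdown_report(report))
        if figures:
            from .plots import plot_fit_grid

            plot_fit_grid(plaque_df, report["pairwise_fits"], out / "pairwise_fits.png")
    return report


def run_cohort(
    source: CohortSpec | list[RunConfig],
    out_dir: str | Path | None = None,
    figures: bool = False,
) -> dict:
    """Cohort-level analysis from a synthetic spec or per-subject configs."""
    if isinstance(source, CohortSpec):
        plaque_df, covariate_df, _ = make_cohort(source)
        calc_df = None
    else:
        if len(source) < 2:
            raise ValueError("cohort analysis needs at least 2 subjects")
        pls, cls = [], []
        for cfg in source:
            p, c, _ = run_subject(cfg)
            pls.append(p)
            cls.append(c)
        ref = list(pls[0].columns)
        for p in pls[1:]:
            if list(p.columns) != ref:
                raise ValueError("subject outputs have mismatched schemas")
        plaque_df = pd.concat(pls, ignore_index=True)
        calc_df = pd.concat(cls, ignore_index=True)
        covariate_df = None
    subject_df = subject_table_from_plaques(plaque_df, calc_df)
    report = report_from_tables(
        plaque_df, subject_df, covariate_df, out_dir=out_dir, figures=figures
    )
    if out_dir is not None:
        out = Path(out_dir)
        plaque_df.to_csv(out / "plaques.csv", index=False, float_format="%.9g")
        subject_df.to_csv(out / "subjects.csv", index=False, float_format="%.9g")
        if covariate_df is not None:
            covariate_df.to_csv(out / "covariates.csv", index=False, float_format="%.9g")
    return report
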