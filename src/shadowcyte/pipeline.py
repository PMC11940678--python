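"""End-to-end processing: frame -> per-cell table -> cohort analysis -> QC.

This is the glue the command-line interface and the reproduction scripts
drive: detection + profiling of whole frames into tidy per-cell tables,
cohort aggregation with LAP and pairwise Mann-Whitney comparisons, and
the four-channel reproducibility check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activation import (ReferenceStats, attach_lap, aggregate_cells,
                         normalize_cohorts)
from .detection import DetectionConfig, detect_patterns
from .optics import (ChannelPerturbation, OpticsConfig, ShadowImage,
                     leukocyte_phantom, random_scene, render_shadow_image,
                     simulate_channel_run)
from .profiling import ProfilingConfig, extract_params
from .stats import StatResult, cov_percent, mann_whitney_u

__all__ = [
    "process_image",
    "simulate_cohort_cells",
    "analyze_cohorts",
    "CohortAnalysis",
    "qc_channel_cov",
    "QCReport",
]


def process_image(image: ShadowImage, image_id: str = "img",
                  detection: DetectionConfig | None = None,
                  profiling: ProfilingConfig | None = None) -> pd.DataFrame:
    """Detect every pattern in a frame and extract its shadow parameters.

    Returns the per-cell table (one row per accepted ROI, including
    invalid cells with their flags; downstream aggregation excludes
    NaN parameters listwise per parameter).
    """
    detection = detection or DetectionConfig()
    profiling = profiling or ProfilingConfig()
    rows = []
    for k, roi in enumerate(detect_patterns(image, detection)):
        params = extract_params(roi, profiling)
        rows.append({
            "image_id": image_id,
            "cell_id": k,
            "row": roi.center[0],
            "col": roi.center[1],
            "score": roi.score,
            "ppd_um": params.ppd,
            "mmd_mean_um": params.mmd_mean,
            "mmd_sd_um": params.mmd_sd,
            "sharpness": params.sharpness,
            "n_valid_angles": params.n_valid_angles,
            "flags": ";".join(params.flags) if params.flags else "",
        })
    return pd.DataFrame(rows, columns=[
        "image_id", "cell_id", "row", "col", "score", "ppd_um",
        "mmd_mean_um", "mmd_sd_um", "sharpness", "n_valid_angles", "flags"])


def simulate_cohort_cells(groups: dict[str, float], n_cells_target: int,
                          cfg: OpticsConfig | None = None, seed: int = 0,
                          cells_per_image: int = 25,
                          detection: DetectionConfig | None = None,
                          profiling: ProfilingConfig | None = None
                          ) -> pd.DataFrame:
    """Simulate leukocyte cohorts and measure them end to end.

    ``groups`` maps a label to the activated fraction of its cells (0 for
    a vehicle control, 1 for fully stimulated).  Frames are rendered and
    measured until at least ``n_cells_target`` valid cells per group are
    collected.  Returns the concatenated per-cell table with ``group``
    and the measurement columns renamed to the analysis schema
    (ppd, mmd_sd, ...).
    """
    cfg = cfg or OpticsConfig()
    rng = np.random.default_rng(seed)
    frames = []
    for label, frac in groups.items():
        got = 0
        img_idx = 0
        while got < n_cells_target:
            def factory(center, index, prng, f=frac):
                return leukocyte_phantom(center, rng=prng,
                                         activated=bool(prng.random() < f))
            scene = random_scene(cells_per_image, cfg,
                                 seed=int(rng.integers(2 ** 31)),
                                 phantom_factory=factory)
            image, _ = render_shadow_image(scene, cfg,
                                           seed=int(rng.integers(2 ** 31)))
            tab = process_image(image, image_id=f"{label}_{img_idx}",
                                detection=detection, profiling=profiling)
            tab["group"] = label
            frames.append(tab)
            got += int(tab["ppd_um"].notna().sum())
            img_idx += 1
    cells = pd.concat(frames, ignore_index=True)
    return cells.rename(columns={"ppd_um": "ppd", "mmd_sd_um": "mmd_sd",
                                 "mmd_mean_um": "mmd_mean"})


@dataclass
class CohortAnalysis:
    """Cohort-level outcome bundle."""

    cells: pd.DataFrame                  # per-cell with lap attached
    reference: ReferenceStats
    summaries: list                      # CohortSummary, normalized
    comparisons: dict[tuple[str, str, str], StatResult]


def analyze_cohorts(cells: pd.DataFrame, control_label: str,
                    lap_variant: str = "ratio",
                    grouping: str = "group") -> CohortAnalysis:
    """LAP, normalized summaries and control-vs-group tests for a
    per-cell table with ``ppd``/``mmd_sd`` columns."""
    ctrl = cells[cells[grouping] == control_label]
    if len(ctrl) == 0:
        raise ValueError(f"control group {control_label!r} missing")
    ref = ReferenceStats.from_cells(ctrl)
    cells = attach_lap(cells, ref, lap_variant)
    summaries = aggregate_cells(cells, grouping)
    summaries = normalize_cohorts(summaries, control_label)
    comparisons: dict[tuple[str, str, str], StatResult] = {}
    labels = [s.label for s in summaries if s.label != control_label]
    for label in labels:
        grp = cells[cells[grouping] == label]
        for par in ("ppd", "mmd_sd", "lap"):
            a = np.asarray(cells.loc[cells[grouping] == control_label, par],
                           dtype=float)
            b = np.asarray(grp[par], dtype=float)
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if len(a) and len(b):
                comparisons[(control_label, label, par)] = mann_whitney_u(a, b)
    return CohortAnalysis(cells=cells, reference=ref,
                          summaries=summaries, comparisons=comparisons)


@dataclass
class QCReport:
    """Inter-channel reproducibility outcome."""

    channel_means: dict[int, float]      # mean PPD per channel, um
    channel_n: dict[int, int]
    cov_percent: float
    threshold_percent: float
    passed: bool


def qc_channel_cov(cfg: OpticsConfig | None = None,
                   bead_diameter: float = 20.0, n_beads: int = 50,
                   n_replicates: int = 3, seed: int = 1,
                   perturbation: ChannelPerturbation | None = None,
                   threshold_percent: float = 10.0,
                   detection: DetectionConfig | None = None,
                   profiling: ProfilingConfig | None = None) -> QCReport:
    """Four-channel bead run -> per-channel mean PPD -> CoV pass/fail.

    Mirrors the instrument's reproducibility check: 20 um beads imaged in
    all four channels in triplicate; the coefficient of variation of the
    per-channel mean PPD must stay below the threshold (default 10 %).
    """
    cfg = cfg or OpticsConfig()
    detection = detection or DetectionConfig()
    profiling = profiling or ProfilingConfig()
    records = simulate_channel_run(bead_diameter, n_beads, n_replicates,
                                   cfg=cfg, perturbation=perturbation,
                                   seed=seed)
    ppd_by_channel: dict[int, list[float]] = {}
    for ch, image, _truth in records:
        tab = process_image(image, image_id=f"ch{ch}", detection=detection,
                            profiling=profiling)
        good = tab["ppd_um"].dropna()
        ppd_by_channel.setdefault(ch, []).extend(good.tolist())
    means = {ch: float(np.mean(v)) for ch, v in sorted(ppd_by_channel.items())}
    cov = cov_percent(list(means.values()))
    return QCReport(channel_means=means,
                    channel_n={ch: len(v) for ch, v in ppd_by_channel.items()},
                    cov_percent=cov, threshold_percent=threshold_percent,
                    passed=bool(cov < threshold_percent))
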