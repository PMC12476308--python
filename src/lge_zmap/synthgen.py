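"""Synthetic cohorts with the enhancement geography of non-ischemic
cardiomyopathy.

The generator emulates a two-group LGE-CMR cohort at segment-layer
granularity so every downstream stage (standardization, regression,
classification) is testable without patient data:

* **DCM-like** patients carry a linear mid-wall stripe in the basal septum:
  an additive enhancement offset in segments 2 and 3 at depths 0.4–0.6.
* **CS-like** patients carry patchy septal enhancement: each of the five
  septal segments is independently hit with probability ``cs_patch_rate``;
  within a hit segment the enhancement weight grows with transmural depth
  (maximal at 0.9, the RV-side sub-endocardium), and a random half of hit
  segments are transmural (full weight at every depth).

Lesion magnitude is parameterized in units of the baseline noise SD
(``effect_size``), so the induced septal RV-band group difference on the
z-score scale is directly controllable.  Device-artifact exclusions are
drawn per segment (all nine layers flagged), mimicking ICD artifact.

Image-level mode draws concentric-contour short-axis stacks whose
intensity is a known analytic function of (angle, depth) plus noise, so
ground-truth segment-layer means are computable in closed form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import isfinite
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, GeometryError
from .geometry import (
    ContourStack,
    LAYER_GRID,
    LGEImageStack,
    SEGMENTS,
    SEGMENTS_OF_WALL,
    SliceContour,
    WALL_OF_SEGMENT,
    band_of_layer,
    TABLE_COLUMNS,
)

DCM_LABEL = 0
CS_LABEL = 1

#: DCM stripe: basal septal segments, mid-wall depths.
DCM_SEGMENTS = (2, 3)
DCM_LAYERS = (0.4, 0.5, 0.6)

SEPTAL_SEGMENTS = SEGMENTS_OF_WALL["septal"]
RV_BAND_LAYERS = (0.7, 0.8, 0.9)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic cohort generator.

    ``effect_size`` is the peak additive enhancement in units of
    ``base_sd``; ``cs_patch_rate`` is the per-septal-segment lesion
    probability for CS patients; ``artifact_rate`` the per-segment
    probability that a segment's nine cells are flagged as device artifact.
    """

    n_dcm: int = 13
    n_cs: int = 9
    seed: int = 0
    # signed PSIR-like baseline: healthy myocardium sits low relative to
    # enhancement, so the 40%/60%-of-max tissue classes are all populated
    base_mean: float = 10.0
    base_sd: float = 10.0
    effect_size: float = 1.0
    cs_patch_rate: float = 0.6
    artifact_rate: float = 0.0
    noise_model: str = "gaussian"
    cs_transmural_rate: float = 0.5
    cs_anterior_trend: float = 0.0

    def __post_init__(self):
        for name in ("base_mean", "base_sd", "effect_size", "cs_patch_rate",
                     "artifact_rate", "cs_transmural_rate", "cs_anterior_trend"):
            v = getattr(self, name)
            if not isfinite(float(v)):
                raise ConfigurationError(f"{name} must be finite, got {v!r}")
        if self.n_dcm < 0 or self.n_cs < 0:
            raise ConfigurationError("cohort sizes must be non-negative")
        if self.base_sd <= 0:
            raise ConfigurationError(f"base_sd must be > 0, got {self.base_sd}")
        for name in ("cs_patch_rate", "artifact_rate", "cs_transmural_rate"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.noise_model not in ("gaussian", "rician"):
            raise ConfigurationError(
                f"noise_model must be 'gaussian' or 'rician', got {self.noise_model!r}"
            )


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests.

    ``offsets`` maps patient_id -> {(segment, layer_depth): additive
    enhancement offset in intensity units}; offsets are zero (absent)
    outside designated lesion cells.  ``septal_rv_band_delta_z`` is the
    implied CS-minus-DCM difference in mean septal RV-band z-score, on the
    z scale, accounting for the attenuation that per-patient
    standardization applies to localized offsets.
    """

    labels: dict[str, int]
    offsets: dict[str, dict[tuple[int, float], float]]
    base_sd: float
    septal_rv_band_delta_z: float = 0.0


@dataclass
class CohortDataset:
    """A cohort: concatenated segment-layer tables plus binary labels."""

    table: pd.DataFrame
    labels: pd.Series  # patient_id -> 0 (DCM) / 1 (CS)

    @property
    def n_patients(self) -> int:
        return len(self.labels)


# --------------------------------------------------------------------------
# z-scale calibration
# --------------------------------------------------------------------------

_N_CELLS = len(SEGMENTS) * len(LAYER_GRID)  # 153
_N_RV_BAND = len(SEPTAL_SEGMENTS) * len(RV_BAND_LAYERS)  # 15


def _expected_band_z(offsets_sd: np.ndarray, band_mask: np.ndarray) -> float:
    """Expected mean z over a band given per-cell offsets in SD units.

    Standardization subtracts the patient mean and divides by the patient
    SD; with unit baseline noise the expected sample variance is
    1 + Var_cells(offset), so a localized offset is attenuated on the z
    scale.  Noise-free first-order approximation, exact as n -> infinity.
    """
    mu = offsets_sd.mean()
    sigma = np.sqrt(1.0 + offsets_sd.var(ddof=0))
    return float((offsets_sd[band_mask] - mu).mean() / sigma)


def rv_band_offset_for_delta_z(delta_z: float) -> float:
    """Invert the standardization attenuation for a uniform RV-band lesion.

    Returns the offset c (in units of base_sd) to add to all 15 septal
    RV-band cells so that the expected mean septal RV-band z-score of a
    lesioned patient exceeds a lesion-free patient's by ``delta_z``.
    """
    if delta_z == 0:
        return 0.0
    p = _N_RV_BAND / _N_CELLS

    def gap(c):
        return c * (1 - p) / np.sqrt(1.0 + c * c * p * (1 - p)) - delta_z

    hi = 10.0 * max(1.0, abs(delta_z))
    # monotone in c; bracket and solve
    return float(brentq(gap, -hi, hi, xtol=1e-12))


def _delta_z_from_truth(gt: GroundTruth) -> float:
    """True CS-minus-DCM septal RV-band difference implied by the offsets."""
    band_cells = {(s, d) for s in SEPTAL_SEGMENTS for d in RV_BAND_LAYERS}
    all_cells = [(s, round(d, 1)) for s in SEGMENTS for d in LAYER_GRID]
    band_mask = np.array([c in band_cells for c in all_cells])
    per_group: dict[int, list[float]] = {DCM_LABEL: [], CS_LABEL: []}
    for pid, label in gt.labels.items():
        off = gt.offsets.get(pid, {})
        vec = np.array([off.get(c, 0.0) for c in all_cells]) / gt.base_sd
        per_group[label].append(_expected_band_z(vec, band_mask))
    if not per_group[DCM_LABEL] or not per_group[CS_LABEL]:
        return 0.0
    return float(np.mean(per_group[CS_LABEL]) - np.mean(per_group[DCM_LABEL]))


# --------------------------------------------------------------------------
# Table-level cohort generation
# --------------------------------------------------------------------------


def _noise(rng: np.random.Generator, mean, sd: float, model: str) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if model == "gaussian":
        return rng.normal(mean, sd)
    # Rician magnitude: |(nu + g1*sd) + i*(g2*sd)|
    re = mean + rng.normal(0.0, sd, size=mean.shape)
    im = rng.normal(0.0, sd, size=mean.shape)
    return np.hypot(re, im)


def _cs_offsets(rng: np.random.Generator, cfg: SyntheticConfig):
    """Patchy CS lesion: per-septal-segment Bernoulli, depth-weighted."""
    cells: dict[tuple[int, float], float] = {}
    peak = cfg.effect_size * cfg.base_sd
    for seg in SEPTAL_SEGMENTS:
        if rng.random() >= cfg.cs_patch_rate:
            continue
        transmural = rng.random() < cfg.cs_transmural_rate
        for d in LAYER_GRID:
            w = 1.0 if transmural else d / LAYER_GRID[-1]  # max at 0.9
            cells[(seg, round(d, 1))] = peak * w
    if cfg.cs_anterior_trend > 0:
        for seg in SEGMENTS_OF_WALL["anterior"]:
            for d in LAYER_GRID:
                cells[(seg, round(d, 1))] = cells.get((seg, round(d, 1)), 0.0) + (
                    cfg.cs_anterior_trend * cfg.base_sd
                )
    return cells


def _dcm_offsets(cfg: SyntheticConfig):
    peak = cfg.effect_size * cfg.base_sd
    return {
        (seg, round(d, 1)): peak for seg in DCM_SEGMENTS for d in DCM_LAYERS
    }


def _patient_table(
    pid: str,
    rng: np.random.Generator,
    cfg: SyntheticConfig,
    offsets: dict[tuple[int, float], float],
) -> pd.DataFrame:
    rows = []
    base = np.full(_N_CELLS, cfg.base_mean, dtype=float)
    cell_ids = [(s, round(d, 1)) for s in SEGMENTS for d in LAYER_GRID]
    for i, cell in enumerate(cell_ids):
        base[i] += offsets.get(cell, 0.0)
    vals = _noise(rng, base, cfg.base_sd, cfg.noise_model)
    flagged_segments = {
        s for s in SEGMENTS if rng.random() < cfg.artifact_rate
    }
    for (seg, d), v in zip(cell_ids, vals):
        rows.append(
            (
                pid,
                seg,
                d,
                WALL_OF_SEGMENT[seg],
                band_of_layer(d),
                float(v),
                seg in flagged_segments,
            )
        )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def generate_cohort(config: SyntheticConfig) -> tuple[CohortDataset, GroundTruth]:
    """Generate a synthetic two-group cohort of segment-layer tables.

    One 153-row SegmentLayerTable per patient (before exclusions), DCM
    patients labelled 0 and CS patients 1.  Reproducible under fixed
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    labels: dict[str, int] = {}
    offsets: dict[str, dict[tuple[int, float], float]] = {}
    tables = []
    for i in range(config.n_dcm):
        pid = f"DCM{i + 1:03d}"
        labels[pid] = DCM_LABEL
        off = _dcm_offsets(config) if config.effect_size != 0 else {}
        offsets[pid] = off
        tables.append(_patient_table(pid, rng, config, off))
    for i in range(config.n_cs):
        pid = f"CS{i + 1:03d}"
        labels[pid] = CS_LABEL
        off = _cs_offsets(rng, config) if config.effect_size != 0 else {}
        offsets[pid] = off
        tables.append(_patient_table(pid, rng, config, off))
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=list(TABLE_COLUMNS))
    )
    gt = GroundTruth(labels=labels, offsets=offsets, base_sd=config.base_sd)
    gt.septal_rv_band_delta_z = _delta_z_from_truth(gt)
    cohort = CohortDataset(
        table=table, labels=pd.Series(labels, name="label", dtype=int)
    )
    return cohort, gt


def generate_calibrated_cohort(
    n_dcm: int,
    n_cs: int,
    delta_z: float,
    seed: int,
    base_mean: float = 10.0,
    base_sd: float = 10.0,
    artifact_rate: float = 0.0,
) -> tuple[CohortDataset, GroundTruth]:
    """Cohort with an exactly calibrated septal RV-band z difference.

    Every CS patient receives a uniform offset over all 15 septal RV-band
    cells, sized (via :func:`rv_band_offset_for_delta_z`) so the expected
    CS-minus-DCM difference in mean septal RV-band z equals ``delta_z``.
    This is the designed condition for parameter-recovery experiments:
    the estimand of the mixed model is known by construction.
    """
    c = rv_band_offset_for_delta_z(delta_z)
    cfg = SyntheticConfig(
        n_dcm=n_dcm,
        n_cs=n_cs,
        seed=seed,
        base_mean=base_mean,
        base_sd=base_sd,
        effect_size=0.0,
        artifact_rate=artifact_rate,
    )
    rng = np.random.default_rng(seed)
    band_offsets = {
        (s, round(d, 1)): c * base_sd
        for s in SEPTAL_SEGMENTS
        for d in RV_BAND_LAYERS
    }
    labels: dict[str, int] = {}
    offsets: dict[str, dict[tuple[int, float], float]] = {}
    tables = []
    for i in range(n_dcm):
        pid = f"DCM{i + 1:03d}"
        labels[pid] = DCM_LABEL
        offsets[pid] = {}
        tables.append(_patient_table(pid, rng, cfg, {}))
    for i in range(n_cs):
        pid = f"CS{i + 1:03d}"
        labels[pid] = CS_LABEL
        offsets[pid] = dict(band_offsets)
        tables.append(_patient_table(pid, rng, cfg, band_offsets))
    table = pd.concat(tables, ignore_index=True)
    gt = GroundTruth(
        labels=labels,
        offsets=offsets,
        base_sd=base_sd,
        septal_rv_band_delta_z=float(delta_z),
    )
    return CohortDataset(table=table, labels=pd.Series(labels, dtype=int)), gt


def inject_artifact(
    table: pd.DataFrame, cells: list[tuple[int, float]]
) -> pd.DataFrame:
    """Flag the listed (segment, layer_depth) cells as excluded.

    Intensities are retained but ignored by all downstream statistics.
    Applies to every patient present in the table.
    """
    t = table.copy()
    valid = {(s, round(d, 1)) for s in SEGMENTS for d in LAYER_GRID}
    for cell in cells:
        seg, d = int(cell[0]), round(float(cell[1]), 1)
        if (seg, d) not in valid or abs(d - float(cell[1])) > 1e-9:
            raise IndexError(
                f"unknown cell (segment={cell[0]}, layer_depth={cell[1]})"
            )
        mask = (t["segment"] == seg) & (
            np.round(t["layer_depth"].astype(float), 1) == d
        )
        t.loc[mask, "artifact_flag"] = True
    return t


# --------------------------------------------------------------------------
# Image-level generation
# --------------------------------------------------------------------------


def generate_image_stack(
    config: SyntheticConfig,
    patient_label: int = DCM_LABEL,
    intensity_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    n_slices: int = 9,
    n_apex: int = 1,
    image_shape: tuple[int, int] = (96, 96),
    endo_radius: float = 15.0,
    epi_radius: float = 30.0,
    rv_insertion_angle: float = 60.0,
    noise_sd: float | None = None,
) -> tuple[LGEImageStack, ContourStack, GroundTruth]:
    """Draw a synthetic short-axis LGE stack with concentric contours.

    The image intensity is ``intensity_field(rel_angle_deg, depth)`` plus
    Gaussian noise, where ``rel_angle_deg`` is measured counterclockwise
    from the RV-insertion ray and ``depth`` is the transmural fraction.
    With the default field (constant ``base_mean``) every segment-layer
    mean equals ``base_mean``.  Contour radii shrink linearly toward the
    apex; the final ``n_apex`` slices are apex caps without a blood pool.
    """
    if epi_radius <= endo_radius:
        raise GeometryError(
            f"epi radius ({epi_radius}) must exceed endo radius ({endo_radius})"
        )
    if intensity_field is None:
        intensity_field = lambda ang, depth: np.full_like(depth, config.base_mean)
    if noise_sd is None:
        noise_sd = 0.0
    rng = np.random.default_rng(config.seed)
    ny, nx = image_shape
    cx, cy = nx / 2.0, ny / 2.0  # centre in pixel units; spacing 1 mm
    spacing = (1.0, 1.0)
    theta = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)

    frames, slices = [], []
    total = n_slices + n_apex
    for s in range(total):
        shrink = 1.0 - 0.3 * s / max(total - 1, 1)
        r_epi = epi_radius * shrink
        r_endo = endo_radius * shrink
        is_apex = s >= n_slices
        epi_poly = np.column_stack(
            [cx + r_epi * np.cos(theta), cy + r_epi * np.sin(theta)]
        )
        endo_poly = (
            None
            if is_apex
            else np.column_stack(
                [cx + r_endo * np.cos(theta), cy + r_endo * np.sin(theta)]
            )
        )
        ii, jj = np.mgrid[0:ny, 0:nx]
        x = (jj + 0.5) * spacing[1]
        y = (ii + 0.5) * spacing[0]
        r = np.hypot(x - cx, y - cy)
        if is_apex:
            depth = np.clip(r / r_epi, 0.0, 1.0)
        else:
            depth = np.clip((r - r_endo) / (r_epi - r_endo), 0.0, 1.0)
        ang = np.mod(
            np.degrees(np.arctan2(y - cy, x - cx)) - rv_insertion_angle, 360.0
        )
        frame = intensity_field(ang, depth)
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=frame.shape)
        frames.append(np.asarray(frame, dtype=float))
        slices.append(
            SliceContour(
                epi=epi_poly,
                endo=endo_poly,
                z_position=-10.0 * s,
                rv_insertion_angle=rv_insertion_angle,
            )
        )

    stack = LGEImageStack(frames=frames, pixel_spacing=spacing)
    contours = ContourStack(slices=slices, pixel_spacing=spacing)
    pid = "IMG0"
    gt = GroundTruth(
        labels={pid: int(patient_label)}, offsets={pid: {}}, base_sd=config.base_sd
    )
    return stack, contours, gt
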