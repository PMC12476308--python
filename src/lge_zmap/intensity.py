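"""Tissue characterization and per-patient z-score standardization.

Tissue classes follow the conventional LGE thresholds relative to each
patient's maximal myocardial signal intensity: healthy below 40% of the
maximum, border zone between 40% and 60% (boundaries inclusive), core
above 60%.

Z-scores standardize each patient's segment-layer intensities with that
patient's whole-LV mean and standard deviation, z = (x - mu) / sigma,
pooling all non-excluded cells across the 17 segments and 9 layers.  This
makes intensity maps comparable across scanners, contrast dose and coil
settings: any per-patient affine rescaling x -> a*x + b (a > 0) leaves
every z-score, and hence all downstream statistics, unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DegenerateVarianceError,
    EmptyRegionError,
    InsufficientDataError,
)
from .geometry import LAYERS_OF_BAND, SEGMENTS_OF_WALL, validate_table

TISSUE_CLASSES = ("healthy", "border_zone", "core")


@dataclass(frozen=True)
class TissueThresholds:
    """Tissue-class cut points as fractions of maximal signal intensity."""

    healthy_max: float = 0.40
    core_min: float = 0.60

    def __post_init__(self):
        if not (0 < self.healthy_max <= self.core_min < 1):
            raise ConfigurationError(
                f"need 0 < healthy_max <= core_min < 1, got "
                f"({self.healthy_max}, {self.core_min})"
            )


def classify_tissue(
    intensity, max_si: float, thresholds: TissueThresholds | None = None
):
    """Classify intensities as 'healthy', 'border_zone' or 'core'.

    The ratio r = intensity / max_si is compared against the thresholds;
    both boundary values (r exactly at healthy_max or core_min) fall in the
    border zone.  Accepts scalars or arrays.
    """
    if thresholds is None:
        thresholds = TissueThresholds()
    if not np.isfinite(max_si) or max_si <= 0:
        raise ValueError(f"max_si must be positive and finite, got {max_si}")
    r = np.asarray(intensity, dtype=float) / float(max_si)
    out = np.where(
        r < thresholds.healthy_max,
        "healthy",
        np.where(r > thresholds.core_min, "core", "border_zone"),
    )
    if out.ndim == 0:
        return str(out)
    return out


@dataclass(frozen=True)
class RegionalComposition:
    """Tissue-class percentages of a myocardial region."""

    region: str
    bz_pct: float
    core_pct: float

    @property
    def bz_plus_core_pct(self) -> float:
        return self.bz_pct + self.core_pct

    @property
    def healthy_pct(self) -> float:
        return 100.0 - self.bz_plus_core_pct


def regional_composition(
    intensities,
    max_si: float,
    thresholds: TissueThresholds | None = None,
    region: str = "region",
) -> RegionalComposition:
    """Percentage of units (pixels or cells) in each tissue class.

    In image mode the units are pixels; in table mode each segment-layer
    cell counts once.  healthy% + BZ% + core% = 100 by construction.
    """
    vals = np.asarray(intensities, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyRegionError(f"region {region!r} has no usable units")
    classes = classify_tissue(vals, max_si, thresholds)
    n = vals.size
    return RegionalComposition(
        region=region,
        bz_pct=100.0 * float(np.sum(classes == "border_zone")) / n,
        core_pct=100.0 * float(np.sum(classes == "core")) / n,
    )


def patient_max_si(table: pd.DataFrame) -> float:
    """Per-patient maximal signal intensity over non-excluded LV cells."""
    ok = table.loc[~table["artifact_flag"], "intensity"].dropna()
    if ok.empty:
        raise EmptyRegionError("no non-excluded cells")
    return float(ok.max())


def zscore_standardize(table: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Standardize segment-layer intensities patient by patient.

    For each patient, mu and sigma are computed over all non-excluded cells
    of the whole LV (17 segments x 9 layers, joint pooling) and
    z = (x - mu) / sigma is attached per cell.  Excluded cells carry NaN z.
    Sigma uses the sample convention (ddof=1) by default.

    Returns the table with added columns ``z``, ``patient_mu`` and
    ``patient_sigma``.

    Raises
    ------
    InsufficientDataError
        if a patient has fewer than 2 non-excluded cells.
    DegenerateVarianceError
        if a patient's non-excluded intensities are constant.
    """
    t = validate_table(table)
    t["z"] = np.nan
    t["patient_mu"] = np.nan
    t["patient_sigma"] = np.nan
    for pid, sub in t.groupby("patient_id", sort=False):
        ok = sub.loc[~sub["artifact_flag"] & sub["intensity"].notna()]
        if len(ok) < 2:
            raise InsufficientDataError(
                f"patient {pid!r}: need >= 2 non-excluded cells, got {len(ok)}"
            )
        mu = float(ok["intensity"].mean())
        sigma = float(ok["intensity"].std(ddof=ddof))
        if not np.isfinite(sigma) or sigma <= 0:
            raise DegenerateVarianceError(
                f"patient {pid!r}: zero intensity variance, z-scores undefined"
            )
        t.loc[sub.index, "patient_mu"] = mu
        t.loc[sub.index, "patient_sigma"] = sigma
        t.loc[ok.index, "z"] = (ok["intensity"] - mu) / sigma
    return t


def band_feature(ztable: pd.DataFrame, wall: str = "septal", band: str = "sub_epi"):
    """Mean z over one (wall, band) region, per patient.

    The classifier feature is the default: the septal sub-epicardial band,
    i.e. the endocardial third of the RV side of the septum (segments
    2, 3, 8, 9, 14 at depths 0.7–0.9).

    Returns a :class:`pandas.Series` indexed by patient_id.
    """
    if wall not in SEGMENTS_OF_WALL:
        raise ValueError(f"unknown wall {wall!r}")
    if band not in LAYERS_OF_BAND:
        raise ValueError(f"unknown band {band!r}")
    if "z" not in ztable.columns:
        raise ValueError("expected a z-scored table (column 'z' missing)")
    sel = ztable[
        ztable["segment"].isin(SEGMENTS_OF_WALL[wall])
        & np.isin(np.round(ztable["layer_depth"].astype(float), 1), LAYERS_OF_BAND[band])
        & ~ztable["artifact_flag"]
        & ztable["z"].notna()
    ]
    if sel.empty:
        raise EmptyRegionError(f"no non-excluded cells in ({wall}, {band})")
    return sel.groupby("patient_id", sort=False)["z"].mean()
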