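"""Hierarchical group comparison of z-scores and tissue percentages, plus
LOWESS transmural depth profiles.

The central model is a linear mixed model

    y_ijk = alpha + beta * I(CS)_i + u_i + v_k + e_ijk

with crossed random intercepts for patient (u_i) and transmural layer
(v_k), fit by REML.  ``beta`` is the CS-minus-DCM difference (DCM is the
reference level), reported with a Wald 95% CI and p-value.  Outcomes are
either the cell z-score or tissue-class percentages per cell.

If the crossed fit is singular or fails to converge, the model falls back
to a patient-only random intercept and finally to OLS, with a logged
warning — never silently.

LOWESS profiles summarize how z varies with transmural depth per group:
tricube-weighted local linear regression of cell z on layer depth,
evaluated on the nine-point depth grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import EmptyRegionError, InsufficientDataError
from .geometry import (
    BANDS,
    LAYERS_OF_BAND,
    SEGMENTS_OF_WALL,
    WALLS,
)
from .intensity import TissueThresholds, classify_tissue, patient_max_si
from .synthgen import CohortDataset

logger = logging.getLogger("lge_zmap")

OUTCOMES = ("z", "bz_pct", "core_pct", "bz_core_pct")


@dataclass(frozen=True)
class ModelFit:
    """One fitted group contrast (CS vs. DCM reference)."""

    outcome: str
    region: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_obs: int
    grouping: str  # which random-effects structure was actually used

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "region": self.region,
            "beta": self.beta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_obs": self.n_obs,
            "grouping": self.grouping,
        }


def _region_mask(df: pd.DataFrame, wall: str, band: str | None) -> pd.Series:
    mask = df["segment"].isin(SEGMENTS_OF_WALL[wall])
    if band is not None:
        mask &= np.isin(
            np.round(df["layer_depth"].astype(float), 1), LAYERS_OF_BAND[band]
        )
    return mask


def attach_outcomes(
    cohort: CohortDataset,
    thresholds: TissueThresholds | None = None,
    with_tissue: bool = True,
) -> pd.DataFrame:
    """Analysis frame: one row per non-excluded cell with all outcomes.

    Adds the group label, layer index (1..9) and, when ``with_tissue``,
    per-cell tissue-class percentage outcomes (0/100 indicators at cell
    granularity — a cell is wholly in one class; regional percentages are
    their means).  Tissue classes need a positive per-patient maximum
    signal intensity; z-only analyses do not.
    """
    t = cohort.table
    df = t.loc[~t["artifact_flag"] & t["intensity"].notna()].copy()
    if "z" not in df.columns:
        raise ValueError("cohort table must be z-scored first")
    df = df.loc[df["z"].notna()]
    df["group"] = df["patient_id"].map(cohort.labels).astype(int)
    df["layer_index"] = np.round(df["layer_depth"].astype(float) * 10).astype(int)
    if with_tissue:
        classes = np.empty(len(df), dtype=object)
        for pid, sub in df.groupby("patient_id", sort=False):
            max_si = float(sub["intensity"].max())
            classes[df.index.get_indexer(sub.index)] = classify_tissue(
                sub["intensity"].to_numpy(), max_si, thresholds
            )
        df["tissue_class"] = classes
        df["bz_pct"] = 100.0 * (df["tissue_class"] == "border_zone")
        df["core_pct"] = 100.0 * (df["tissue_class"] == "core")
        df["bz_core_pct"] = df["bz_pct"] + df["core_pct"]
    return df


def _wald(fitres, term: str, n_obs: int, outcome: str, region: str, grouping: str):
    beta = float(fitres.params[term])
    se = float(fitres.bse[term])
    ci = fitres.conf_int()
    ci_low, ci_high = float(ci.loc[term, 0]), float(ci.loc[term, 1])
    p = float(fitres.pvalues[term])
    # guard against p rounding to exactly 0
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return ModelFit(
        outcome=outcome,
        region=region,
        beta=beta,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        n_obs=n_obs,
        grouping=grouping,
    )


def fit_group_model(
    cohort_or_frame,
    outcome: str = "z",
    wall: str = "septal",
    band: str | None = None,
    thresholds: TissueThresholds | None = None,
) -> ModelFit:
    """Fit the mixed model for one outcome over one region.

    Parameters
    ----------
    cohort_or_frame : CohortDataset (z-scored) or a frame from
        :func:`attach_outcomes`.
    outcome : 'z', 'bz_pct', 'core_pct' or 'bz_core_pct'.
    wall, band : region selector; ``band=None`` means the whole wall.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    df = (
        attach_outcomes(cohort_or_frame, thresholds, with_tissue=outcome != "z")
        if isinstance(cohort_or_frame, CohortDataset)
        else cohort_or_frame
    )
    region = wall if band is None else f"{wall}:{band}"
    sub = df.loc[_region_mask(df, wall, band)]
    if sub.empty:
        raise EmptyRegionError(f"region {region!r} has no usable cells")
    n_per_group = sub.groupby("group")["patient_id"].nunique()
    if len(n_per_group) < 2 or (n_per_group < 2).any():
        raise InsufficientDataError(
            f"need >= 2 patients per group in region {region!r}; got {dict(n_per_group)}"
        )
    sub = sub.rename(columns={outcome: "y"})[
        ["y", "group", "patient_id", "layer_index"]
    ].copy()
    n_obs = len(sub)

    if sub["y"].nunique() == 1:
        # constant outcome (e.g. a tissue class absent everywhere): the
        # group contrast is identically zero and no inference is possible
        logger.warning("constant outcome for %s/%s; contrast fixed at 0",
                       outcome, region)
        return ModelFit(outcome=outcome, region=region, beta=0.0,
                        ci_low=0.0, ci_high=0.0, p_value=1.0,
                        n_obs=n_obs, grouping="constant-outcome")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # crossed random intercepts: a single super-group with two variance
        # components (patient, layer)
        try:
            md = smf.mixedlm(
                "y ~ group",
                sub,
                groups=np.ones(n_obs),
                vc_formula={
                    "patient": "0 + C(patient_id)",
                    "layer": "0 + C(layer_index)",
                },
            )
            res = md.fit(reml=True, method="powell", maxiter=500)
            if not res.converged:
                res = md.fit(reml=True, method="lbfgs", maxiter=500)
            if res.converged and np.isfinite(res.bse["group"]):
                return _wald(res, "group", n_obs, outcome, region,
                             "crossed(patient, layer)")
        except Exception as exc:  # singular / numeric failure
            logger.warning("crossed mixed fit failed for %s/%s: %s",
                           outcome, region, exc)
        logger.warning(
            "falling back to patient-only random intercept for %s/%s",
            outcome, region,
        )
        try:
            md = smf.mixedlm("y ~ group", sub, groups=sub["patient_id"])
            res = md.fit(reml=True)
            if res.converged and np.isfinite(res.bse["group"]):
                return _wald(res, "group", n_obs, outcome, region, "patient")
        except Exception as exc:
            logger.warning("patient-level mixed fit failed for %s/%s: %s",
                           outcome, region, exc)
        logger.warning("falling back to OLS for %s/%s", outcome, region)
        res = smf.ols("y ~ group", sub).fit()
        return _wald(res, "group", n_obs, outcome, region, "ols")


def analysis_battery(
    cohort: CohortDataset, thresholds: TissueThresholds | None = None
) -> pd.DataFrame:
    """The full regression battery over walls and bands.

    Fits, for each of the four walls, the group model on z, BZ%, core% and
    BZ+core%, and additionally the z model within each wall x band.  With
    22 patients and no exclusions the reported n_obs are the familiar
    denominators: 990 for the 5-segment walls (5 x 9 x 22), 594 for the
    inferior wall, 330/198 per band.  P-values are raw (28 tests, no
    multiplicity correction).
    """
    df = attach_outcomes(cohort, thresholds)
    fits: list[ModelFit] = []
    for wall in WALLS:
        for outcome in OUTCOMES:
            fits.append(fit_group_model(df, outcome=outcome, wall=wall))
    for wall in WALLS:
        for band in BANDS:
            fits.append(fit_group_model(df, outcome="z", wall=wall, band=band))
    return pd.DataFrame([f.as_dict() for f in fits])


# --------------------------------------------------------------------------
# LOWESS depth profiles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LowessCurve:
    """Smoothed z-vs-depth profiles, one curve per group."""

    grid: np.ndarray
    fitted: dict[int, np.ndarray]  # group label -> fitted z on grid
    bandwidth: float


def _tricube_local_linear(
    x: np.ndarray, y: np.ndarray, grid: np.ndarray, frac: float
) -> np.ndarray:
    """Tricube-weighted local linear regression evaluated on ``grid``.

    The window at each grid point spans the ceil(frac * n) nearest data
    points; weights are tricube in scaled distance.  Exactly reproduces
    polynomials of degree <= 1.
    """
    n = len(x)
    r = int(np.ceil(frac * n))
    if n < 2 or r < 2:
        raise ValueError(
            f"local window of {r} points over {n} observations is too small"
        )
    out = np.empty(len(grid))
    for i, x0 in enumerate(grid):
        d = np.abs(x - x0)
        h = np.partition(d, r - 1)[r - 1]
        if h <= 0:
            out[i] = y[d == 0].mean()
            continue
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sw = w.sum()
        xb = (w * x).sum() / sw
        yb = (w * y).sum() / sw
        sxx = (w * (x - xb) ** 2).sum()
        if sxx <= 1e-14 * sw:
            out[i] = yb
        else:
            slope = (w * (x - xb) * (y - yb)).sum() / sxx
            out[i] = yb + slope * (x0 - xb)
    return out


def lowess_profile(
    cohort: CohortDataset, wall: str = "septal", bandwidth: float = 0.6
) -> LowessCurve:
    """Per-group LOWESS profile of z against transmural depth in one wall.

    Depth runs from 0.1 (LV endocardium) to 0.9 (epicardium; RV-side
    endocardium in the septum).
    """
    if not 0 < bandwidth <= 1:
        raise ValueError(f"bandwidth must be in (0, 1], got {bandwidth}")
    if wall not in SEGMENTS_OF_WALL:
        raise ValueError(f"unknown wall {wall!r}")
    t = cohort.table
    if "z" not in t.columns:
        raise ValueError("cohort table must be z-scored first")
    sel = t.loc[
        t["segment"].isin(SEGMENTS_OF_WALL[wall])
        & ~t["artifact_flag"]
        & t["z"].notna()
    ].copy()
    if sel.empty:
        raise EmptyRegionError(f"wall {wall!r} has no usable cells")
    sel["group"] = sel["patient_id"].map(cohort.labels).astype(int)
    grid = np.round(np.arange(1, 10) * 0.1, 1)
    fitted: dict[int, np.ndarray] = {}
    for g, sub in sel.groupby("group"):
        fitted[int(g)] = _tricube_local_linear(
            sub["layer_depth"].to_numpy(dtype=float),
            sub["z"].to_numpy(dtype=float),
            grid,
            bandwidth,
        )
    return LowessCurve(grid=grid, fitted=fitted, bandwidth=bandwidth)
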