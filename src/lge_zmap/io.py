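"""File formats, cohort summaries, configuration and the pipeline driver.

Canonical on-disk formats are plain text: SegmentLayerTables as CSV
(columns patient_id, segment, layer_depth, wall, band, intensity,
artifact_flag), patient labels and configuration as JSON, contours as
JSON polygon lists, image stacks as NIfTI.  Every file the pipeline
writes is re-readable by the readers here.

``run_pipeline`` chains simulate/segment -> zscore -> analyze -> classify
and writes a manifest (package version, seed, config hash, per-file
checksums) so that identical configuration and seed yield identical
result checksums for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import cv_evaluate, predictive_values
from .errors import SchemaError, StageError
from .geometry import (
    ContourStack,
    LGEImageStack,
    SliceContour,
    TABLE_COLUMNS,
    aggregate,
    validate_table,
)
from .intensity import TissueThresholds, band_feature, zscore_standardize
from .stats import analysis_battery, lowess_profile
from .synthgen import CohortDataset, SyntheticConfig, generate_cohort

logger = logging.getLogger("lge_zmap")


# --------------------------------------------------------------------------
# Tables and labels
# --------------------------------------------------------------------------


def write_segment_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in table.columns if c in TABLE_COLUMNS or c in ("z", "patient_mu", "patient_sigma")]
    table[cols].to_csv(path, index=False)


def read_segment_table(path) -> pd.DataFrame:
    """Read and validate a SegmentLayerTable CSV.

    Wall/band columns are recomputed from segment/layer and checked
    against the file's contents; contradictions raise a schema error.
    """
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot read table {path}: {exc}")
    return validate_table(raw)


def write_labels(labels: pd.Series | dict, path) -> None:
    d = labels.to_dict() if isinstance(labels, pd.Series) else dict(labels)
    Path(path).write_text(json.dumps({str(k): int(v) for k, v in d.items()}, indent=1))


def read_labels(path) -> pd.Series:
    try:
        d = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read labels {path}: {exc}")
    if not isinstance(d, dict) or not d:
        raise SchemaError("labels file must be a non-empty JSON object")
    s = pd.Series({str(k): int(v) for k, v in d.items()}, name="label")
    if not s.isin([0, 1]).all():
        raise SchemaError("labels must be 0 (DCM) or 1 (CS)")
    return s


# --------------------------------------------------------------------------
# Contours and images
# --------------------------------------------------------------------------


def write_contours(contours: ContourStack, path) -> None:
    doc = {
        "spacing": list(contours.pixel_spacing),
        "slices": [
            {
                "epi": np.asarray(s.epi, dtype=float).tolist(),
                "endo": None if s.endo is None else np.asarray(s.endo, dtype=float).tolist(),
                "z": float(s.z_position),
                "rv_angle": float(s.rv_insertion_angle),
            }
            for s in contours.slices
        ],
    }
    Path(path).write_text(json.dumps(doc))


def read_contours(path) -> ContourStack:
    try:
        doc = json.loads(Path(path).read_text())
        slices = [
            SliceContour(
                epi=np.asarray(s["epi"], dtype=float),
                endo=None if s.get("endo") is None else np.asarray(s["endo"], dtype=float),
                z_position=float(s["z"]),
                rv_insertion_angle=float(s["rv_angle"]),
            )
            for s in doc["slices"]
        ]
        return ContourStack(slices=slices, pixel_spacing=tuple(doc["spacing"]))
    except (OSError, KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read contours {path}: {exc}")


def write_image_stack(stack: LGEImageStack, path) -> None:
    import nibabel as nib

    vol = np.stack([np.asarray(f, dtype=np.float32) for f in stack.frames], axis=-1)
    affine = np.diag([stack.pixel_spacing[1], stack.pixel_spacing[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def read_image_stack(path, pixel_spacing=None) -> LGEImageStack:
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if pixel_spacing is None:
        z = img.header.get_zooms()
        pixel_spacing = (float(z[1]), float(z[0]))
    frames = [vol[..., k] for k in range(vol.shape[-1])]
    return LGEImageStack(frames=frames, pixel_spacing=tuple(pixel_spacing))


# --------------------------------------------------------------------------
# Cohort summaries
# --------------------------------------------------------------------------


def round_pct(value: float, ndigits: int = 1) -> float:
    """Round half-up to ``ndigits`` decimals (presentation convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CohortSummary:
    """Per-group counts and percentages of binary characteristics."""

    group_sizes: dict[str, int]
    rows: pd.DataFrame  # characteristic x group -> "count (pct%)"

    def percentage(self, characteristic: str, group: str) -> float:
        return float(self.rows.loc[characteristic, f"{group}_pct"])


def summarize_cohort(
    labels: pd.Series, characteristics: pd.DataFrame,
    group_names: dict[int, str] | None = None,
) -> CohortSummary:
    """Count (percentage) of each binary characteristic per group.

    ``characteristics`` is indexed by patient_id with 0/1 columns.
    Percentages are 100 * count / group size, rounded half-up to one
    decimal.
    """
    if group_names is None:
        group_names = {0: "DCM", 1: "CS"}
    sizes = {group_names[g]: int((labels == g).sum()) for g in sorted(labels.unique())}
    for name, n in sizes.items():
        if n < 1:
            raise ValueError(f"group {name!r} is empty")
    out = {}
    for g in sorted(labels.unique()):
        name = group_names[g]
        members = labels.index[labels == g]
        sub = characteristics.reindex(members)
        counts = sub.sum(axis=0).astype(int)
        out[f"{name}_count"] = counts
        out[f"{name}_pct"] = counts.apply(
            lambda c: round_pct(100.0 * c / sizes[name])
        )
    return CohortSummary(group_sizes=sizes, rows=pd.DataFrame(out))


# --------------------------------------------------------------------------
# Pipeline configuration and driver
# --------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; serializable to/from JSON.

    Defaults are the conventional analysis settings: 40%/60% tissue
    thresholds, nine layers, five CV folds.
    """

    thresholds: TissueThresholds = field(default_factory=TissueThresholds)
    cv_folds: int = 5
    cv_seed: int = 7
    threshold_mode: str = "full"
    prevalence: float | None = None  # None -> cohort prevalence
    lowess_bandwidth: float = 0.6
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def to_json(self) -> str:
        d = {
            "thresholds": asdict(self.thresholds),
            "cv_folds": self.cv_folds,
            "cv_seed": self.cv_seed,
            "threshold_mode": self.threshold_mode,
            "prevalence": self.prevalence,
            "lowess_bandwidth": self.lowess_bandwidth,
            "synthetic": asdict(self.synthetic),
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        return cls(
            thresholds=TissueThresholds(**d.get("thresholds", {})),
            cv_folds=int(d.get("cv_folds", 5)),
            cv_seed=int(d.get("cv_seed", 7)),
            threshold_mode=d.get("threshold_mode", "full"),
            prevalence=d.get("prevalence"),
            lowess_bandwidth=float(d.get("lowess_bandwidth", 0.6)),
            synthetic=SyntheticConfig(**d.get("synthetic", {})),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir, cohort: CohortDataset | None = None) -> dict:
    """Run simulate -> zscore -> analyze -> classify and write all artifacts.

    If ``cohort`` is None a synthetic cohort is generated from
    ``config.synthetic``.  Returns the results bundle (paths, battery
    frame, CV report, manifest).  Any stage failure aborts with a
    stage-tagged :class:`~lge_zmap.errors.StageError`; artifacts from
    earlier stages remain on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    t_start = time.time()

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        logger.info("stage %-9s done in %.2f s", name, time.time() - t0)
        return result

    def _simulate():
        nonlocal cohort
        if cohort is None:
            cohort, _ = generate_cohort(config.synthetic)
        write_segment_table(cohort.table, out / "table.csv")
        write_labels(cohort.labels, out / "labels.json")
        logger.info(
            "cohort: %d patients, %d cells (%d excluded)",
            cohort.n_patients,
            len(cohort.table),
            int(cohort.table["artifact_flag"].sum()),
        )
        return cohort

    def _zscore():
        z = zscore_standardize(cohort.table)
        zcohort = CohortDataset(table=z, labels=cohort.labels)
        write_segment_table(z, out / "ztable.csv")
        return zcohort

    def _analyze():
        battery = analysis_battery(zcohort, config.thresholds)
        battery.to_csv(out / "regression_battery.csv", index=False)
        curve = lowess_profile(zcohort, "septal", config.lowess_bandwidth)
        rows = []
        for g, fitted in curve.fitted.items():
            for d, v in zip(curve.grid, fitted):
                rows.append({"group": g, "layer_depth": d, "z_fitted": v})
        pd.DataFrame(rows).to_csv(out / "lowess_septal.csv", index=False)
        return battery

    def _classify():
        feats = band_feature(zcohort.table, "septal", "sub_epi")
        labels = zcohort.labels.reindex(feats.index)
        report = cv_evaluate(
            feats.to_numpy(),
            labels.to_numpy(),
            k=config.cv_folds,
            seed=config.cv_seed,
            threshold_mode=config.threshold_mode,
        )
        prev = (
            config.prevalence
            if config.prevalence is not None
            else float((labels == 1).mean())
        )
        pv = predictive_values(
            report.mean_sensitivity, report.mean_specificity, prev
        )
        doc = report.as_dict()
        doc["predictive_values"] = {
            "ppv": pv.ppv, "npv": pv.npv, "prevalence": pv.prevalence,
        }
        (out / "cv_report.json").write_text(json.dumps(doc, indent=1))
        return report, pv

    cohort = stage("simulate", _simulate)
    zcohort = stage("zscore", _zscore)
    battery = stage("analyze", _analyze)
    report, pv = stage("classify", _classify)

    files = sorted(p for p in out.iterdir() if p.is_file() and p.name != "manifest.json")
    manifest = {
        "package": "lge-zmap",
        "version": __version__,
        "seed": config.synthetic.seed,
        "cv_seed": config.cv_seed,
        "config_hash": config.config_hash(),
        "config": json.loads(config.to_json()),
        "checksums": {p.name: _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline finished in %.2f s", time.time() - t_start)

    bundle.update(
        cohort=cohort,
        zcohort=zcohort,
        battery=battery,
        cv_report=report,
        predictive_values=pv,
        manifest=manifest,
        out_dir=out,
    )
    return bundle
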