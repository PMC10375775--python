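"""Table I/O, configuration and run manifests.

All tables are comma-separated UTF-8 with a header row and '.' decimals;
model artifacts are JSON.  Every pipeline stage writes a manifest (config
echo, seed, package version) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .qcei_model import Boundary, PlattCalibration, SvmGradeModel
from .synthdata import INDEX_ORDER, SyntheticDataset

__all__ = [
    "PipelineConfig",
    "load_config",
    "read_feature_table",
    "read_dataset",
    "save_model",
    "load_model",
    "write_manifest",
]

logger = logging.getLogger("licograde")

REQUIRED_FEATURE_COLUMNS = ("batch_id",) + INDEX_ORDER


@dataclass
class PipelineConfig:
    """Single flat configuration shared by all CLI stages."""

    outdir: str = "out"
    data_dir: str | None = None  # defaults to outdir
    seed: int = 0
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    screening: dict = field(default_factory=dict)  # ScreeningRules overrides
    model: dict = field(default_factory=dict)  # run_full_pipeline overrides
    compliance: dict = field(default_factory=dict)  # filter thresholds

    def resolved_data_dir(self) -> Path:
        return Path(self.data_dir or self.outdir)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML (or JSON, a YAML subset) config file; missing file or
    ``None`` gives the defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a batches x 21-index feature table, validating columns and types.

    Unknown columns are preserved (and logged); missing required columns or
    non-numeric index cells raise with the offending name/position.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"feature table {path} is empty") from None
    if df.empty:
        raise ValueError(f"feature table {path} has a header but no rows")
    missing = [c for c in REQUIRED_FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} is missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_FEATURE_COLUMNS]
    if extra:
        logger.info("feature table %s: preserving non-index column(s) %s", path.name, extra)
    for col in INDEX_ORDER:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column '{col}', row {row}"
            )
        df[col] = coerced
    return df


def read_dataset(data_dir: str | Path) -> SyntheticDataset:
    """Load the six study tables written by the simulate stage."""
    data_dir = Path(data_dir)
    tables = {}
    for name in ("batches", "peaks_250", "peaks_330", "absorbance", "contents", "extracts"):
        path = data_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table: {path} (run 'simulate' first?)")
        tables[name] = pd.read_csv(path)
    return SyntheticDataset(**tables)


# ---------------------------------------------------------------------------
# Model artifact (JSON)
# ---------------------------------------------------------------------------


def save_model(result, path: str | Path) -> None:
    """Serialize the trained grading model (SVM duals, scaler, boundary and
    Platt sigmoid) to JSON."""
    m: SvmGradeModel = result.model
    b: Boundary = result.boundary
    cal: PlattCalibration = result.calibration
    payload = {
        "C": m.C,
        "gamma": m.gamma,
        "b": m.b,
        "alphas": m.alphas.tolist(),
        "y": m.y.tolist(),
        "support": m.support.tolist(),
        "X_train": m.X_train.tolist(),
        "feature_subset": list(m.feature_subset),
        "scaler_mean": m.scaler_mean.tolist(),
        "scaler_sd": m.scaler_sd.tolist(),
        "platt": {"A": cal.A, "B": cal.B},
        "boundary": {
            "center": b.center.tolist(),
            "covariance": b.covariance.tolist(),
            "cutoff": b.cutoff,
            "quantile": b.quantile,
            "ridge": b.ridge,
            "feature_columns": list(getattr(result, "boundary_columns", INDEX_ORDER)),
        },
        "cv_report": result.cv_report,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path) -> tuple[SvmGradeModel, Boundary, PlattCalibration, dict]:
    """Inverse of :func:`save_model`."""
    from scipy import linalg

    payload = json.loads(Path(path).read_text())
    model = SvmGradeModel(
        C=payload["C"],
        gamma=payload["gamma"],
        alphas=np.array(payload["alphas"]),
        y=np.array(payload["y"]),
        b=payload["b"],
        support=np.array(payload["support"], dtype=int),
        X_train=np.array(payload["X_train"]),
        feature_subset=tuple(payload["feature_subset"]),
        scaler_mean=np.array(payload["scaler_mean"]),
        scaler_sd=np.array(payload["scaler_sd"]),
    )
    bd = payload["boundary"]
    boundary = Boundary(
        center=np.array(bd["center"]),
        covariance=np.array(bd["covariance"]),
        cutoff=bd["cutoff"],
        quantile=bd["quantile"],
        ridge=bd.get("ridge", 0.0),
    )
    boundary._chol = linalg.cholesky(boundary.covariance, lower=True)
    boundary.feature_columns = tuple(bd.get("feature_columns", INDEX_ORDER))
    cal = PlattCalibration(A=payload["platt"]["A"], B=payload["platt"]["B"])
    return model, boundary, cal, payload.get("cv_report", {})


def write_manifest(outdir: str | Path, stage: str, config: PipelineConfig, seed: int) -> Path:
    """Record everything needed to re-run a stage bit-for-bit."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "licograde_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": asdict(config),
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path
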