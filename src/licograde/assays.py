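"""Content-type quality indices.

Covers the wet-chemistry arithmetic of the workflow: ordinary-least-squares
calibration curves, total flavonoids by UV at 337 nm against a liquiritin
standard series (22.53 µg/mL stock diluted 0.2/0.5/1/2/3/4/5 mL into 10 mL),
compound contents from chromatographic peak areas, the pharmacological-
activity quality index (sum of the liquiritin apioside, liquiritigenin,
glycyrrhizic acid and isoliquiritin apioside contents), and assembly of the
21-component quality-index vector per batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import chromatography as chrom
from .synthdata import COMPOUNDS, INDEX_ORDER

__all__ = [
    "CalibrationCurve",
    "fit_calibration",
    "standard_series",
    "total_flavonoids",
    "quantify_compound",
    "pharm_activity_index",
    "assemble_index_vector",
    "build_feature_table",
    "PHARM_COMPONENTS",
]

#: The four contents summed into the pharmacological-activity quality index.
PHARM_COMPONENTS: tuple[str, ...] = (
    "liquiritin_apioside",
    "liquiritigenin",
    "glycyrrhizic_acid",
    "isoliquiritin_apioside",
)


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS calibration line: response = slope * concentration + intercept."""

    slope: float  # response per (µg/mL)
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]  # µg/mL

    def invert(self, response: float) -> tuple[float, bool]:
        """Concentration (µg/mL) for a response; second element flags
        readings outside the calibrated range."""
        c = (response - self.intercept) / self.slope
        in_range = self.conc_range[0] <= c <= self.conc_range[1]
        return float(c), bool(in_range)


def standard_series(stock_ug_ml: float = 22.53,
                    volumes_ml=(0.2, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0),
                    final_ml: float = 10.0) -> np.ndarray:
    """Concentrations (µg/mL) of the standard series: each stock volume
    developed to ``final_ml``."""
    return np.asarray(volumes_ml, dtype=float) * stock_ug_ml / final_ml


def fit_calibration(points) -> CalibrationCurve:
    """Fit an OLS calibration line to (concentration µg/mL, response) pairs.

    Requires >= 3 points with >= 2 distinct concentrations.
    """
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (concentration, response) pairs")
    if len(arr) < 3:
        raise ValueError("calibration needs at least 3 points")
    conc, resp = arr[:, 0], arr[:, 1]
    if np.unique(conc).size < 2:
        raise ValueError("all concentrations equal; cannot fit a line")
    fit = stats.linregress(conc, resp)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def total_flavonoids(
    absorbance: float,
    curve: CalibrationCurve,
    aliquot_ml: float = 0.1,
    final_ml: float = 10.0,
    extract_ml: float = 10.0,
    mass_g: float = 0.2,
) -> tuple[float, bool]:
    """Total flavonoid content in mg per g dry weight from one 337-nm reading.

    The cuvette concentration c = (A - intercept)/slope (µg/mL) is scaled by
    the colour-development dilution (final/aliquot) and the extract volume,
    then normalized by the sample mass:

        content = c * (final_ml / aliquot_ml) * extract_ml / (mass_g * 1000)

    Returns (content, in_range); an out-of-range absorbance is flagged rather
    than rejected.
    """
    if mass_g <= 0:
        raise ValueError("mass_g must be > 0")
    c, in_range = curve.invert(absorbance)
    content = c * (final_ml / aliquot_ml) * extract_ml / (mass_g * 1000.0)
    return float(content), in_range


def quantify_compound(
    peak_area: float,
    curve: CalibrationCurve,
    extract_ml: float = 50.0,
    dilution: float = 1.0,
    mass_g: float = 1.0,
) -> tuple[float, bool]:
    """Compound content (mg/g dry weight) from an HPLC peak area.

    Same inversion arithmetic as the UV assay with the peak area as the
    response: c = (area - intercept)/slope µg/mL in the injected solution,
    scaled by any dilution and the extraction volume, normalized by mass.
    """
    if mass_g <= 0:
        raise ValueError("mass_g must be > 0")
    c, in_range = curve.invert(peak_area)
    content = c * dilution * extract_ml / (mass_g * 1000.0)
    return float(content), in_range


def pharm_activity_index(
    liquiritin_apioside: float,
    liquiritigenin: float,
    glycyrrhizic_acid: float,
    isoliquiritin_apioside: float,
) -> float:
    """Pharmacological-activity quality index: the plain sum (mg/g) of the
    four anti-inflammatory marker contents."""
    parts = (liquiritin_apioside, liquiritigenin, glycyrrhizic_acid, isoliquiritin_apioside)
    for name, v in zip(PHARM_COMPONENTS, parts):
        if v is None or not np.isfinite(v):
            raise ValueError(f"pharmacological index undefined: missing {name}")
        if v < 0:
            raise ValueError(f"negative content for {name}")
    return float(sum(parts))


def assemble_index_vector(measurements: dict) -> pd.Series:
    """Order one batch's measurements into the fixed 21-index vector.

    ``measurements`` maps index names to values; every one of the 21 indices
    must be present.  Returns a Series in the canonical reporting order.
    """
    missing = [name for name in INDEX_ORDER if name not in measurements]
    if missing:
        raise ValueError(f"missing quality indices: {missing}")
    return pd.Series({name: float(measurements[name]) for name in INDEX_ORDER})


def build_feature_table(dataset, flavonoid_curve: CalibrationCurve | None = None) -> pd.DataFrame:
    """Compute the full 21-index feature table for a simulated (or loaded)
    dataset.

    Pipeline: fit the UV calibration curve from the standard series in the
    absorbance table (unless one is supplied), invert each batch's 337-nm
    reading into a total-flavonoid content, compute fingerprint cosine
    similarities at 250 and 330 nm from the peak tables, sum the
    pharmacological-activity index from the compound contents, and join the
    appearance/extract/content columns.  Returns one row per batch:
    ``batch_id`` + 21 index columns (+ ``true_grade`` when present).
    """
    std = dataset.absorbance.query("role == 'standard'")
    if flavonoid_curve is None:
        if std.empty:
            raise ValueError("absorbance table contains no standard series")
        flavonoid_curve = fit_calibration(
            std[["concentration_ug_ml", "absorbance_337"]].to_numpy()
        )
    samples = dataset.absorbance.query("role == 'sample'").set_index("sample_id")

    rows = dataset.batches.set_index("batch_id")
    contents = dataset.contents.set_index("batch_id")
    extracts = dataset.extracts.set_index("batch_id")
    sim250 = chrom.similarity_table(dataset.peaks_250, 250)
    sim330 = chrom.similarity_table(dataset.peaks_330, 330)

    records = []
    for batch_id in rows.index:
        m = {name: contents.loc[batch_id, name] for name in COMPOUNDS if name in INDEX_ORDER}
        m["alcohol_extract"] = extracts.loc[batch_id, "alcohol_extract"]
        m["diameter"] = rows.loc[batch_id, "diameter"]
        m["pharm_activity_index"] = pharm_activity_index(
            *(contents.loc[batch_id, c] for c in PHARM_COMPONENTS)
        )
        flav, _ = total_flavonoids(samples.loc[batch_id, "absorbance_337"], flavonoid_curve)
        m["total_flavonoids"] = flav
        m["sim_250"] = sim250.loc[batch_id]
        m["sim_330"] = sim330.loc[batch_id]
        rec = assemble_index_vector(m)
        rec["batch_id"] = batch_id
        records.append(rec)
    table = pd.DataFrame(records).set_index("batch_id").reset_index()
    if "true_grade" in rows.columns:
        table["true_grade"] = rows["true_grade"].to_numpy()
    # auxiliary columns used by screening (not part of the 21)
    for extra in ("length", "weight"):
        if extra in rows.columns:
            table[extra] = rows[extra].to_numpy()
    if "water_extract" in extracts.columns:
        table["water_extract"] = extracts["water_extract"].to_numpy()
    return table
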