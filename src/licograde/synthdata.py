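"""Synthetic licorice batch datasets with the study's factor and grade structure.

The generator emulates a licorice (*Glycyrrhiza uralensis*) quality-grading
study: 282 batches from three production regions (two traditional genuine
areas and one non-genuine area), grown 2-5 years, harvested in spring or
autumn.  A latent quality score built from those three provenance factors
orders the batches into four latent classes -- premium (52), first-class (92),
second-class (45) and non-compliant (93) -- and every raw measurement needed
to compute the 21 candidate quality indices is then drawn conditional on the
latent class: appearance traits, HPLC peak tables at 250 and 330 nm, UV
absorbances at 337 nm with a liquiritin standard series, 17 compound contents
and water/alcohol-soluble extract contents.

Non-compliant batches are sampled from content distributions truncated below
the pharmacopoeia monograph minima (glycyrrhizic acid >= 2.0 % and liquiritin
>= 0.50 % of dry weight), compliant classes from distributions truncated
above them, so the compliance filter passes exactly the 189 compliant batches
at the default configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import stats

__all__ = [
    "INDEX_ORDER",
    "KEY_INDICES",
    "COMPOUNDS",
    "PEAK_PATTERNS",
    "GRADE_ORDER",
    "GeneratorConfig",
    "SyntheticDataset",
    "simulate_batches",
    "simulate_peak_table",
    "apply_compliance_filter",
]

# ---------------------------------------------------------------------------
# Index catalogue
# ---------------------------------------------------------------------------

#: The 21 candidate quality indices, in the fixed reporting order used
#: throughout the package (contents first, then extract, appearance,
#: pharmacological index, total flavonoids and the two fingerprint
#: similarities).
INDEX_ORDER: tuple[str, ...] = (
    "licorice_saponin_g2",
    "glycyrrhizic_acid",
    "formononetin",
    "semilicoisoflavone_b",
    "licoisoflavone_b",
    "liquiritin_apioside",
    "liquiritin",
    "liquiritigenin",
    "violanthin",
    "isoliquiritin_apioside",
    "isoliquiritin_isomer",
    "isoliquiritin",
    "neoisoliquiritin",
    "glycyrol",
    "licoflavonol",
    "alcohol_extract",
    "diameter",
    "pharm_activity_index",
    "total_flavonoids",
    "sim_250",
    "sim_330",
)

#: The nine key indices reported as carrying essentially all of the grading
#: signal; the generator's informative set defaults to these.
KEY_INDICES: tuple[str, ...] = (
    "diameter",
    "total_flavonoids",
    "sim_250",
    "sim_330",
    "liquiritin_apioside",
    "liquiritin",
    "glycyrrhizic_acid",
    "liquiritigenin",
    "pharm_activity_index",
)

#: The 17 compounds quantified per batch (the 15 chemical indices plus two
#: compounds that are measured but screened out upstream).
COMPOUNDS: tuple[str, ...] = (
    "licorice_saponin_g2",
    "glycyrrhizic_acid",
    "formononetin",
    "semilicoisoflavone_b",
    "licoisoflavone_b",
    "liquiritin_apioside",
    "liquiritin",
    "liquiritigenin",
    "violanthin",
    "isoliquiritin_apioside",
    "isoliquiritin_isomer",
    "isoliquiritin",
    "neoisoliquiritin",
    "glycyrol",
    "licoflavonol",
    "isoliquiritigenin",
    "glycycoumarin",
)

#: Latent grades in increasing quality order (numeric codes -1..2).
GRADE_ORDER: tuple[str, ...] = ("noncompliant", "second", "first", "premium")
GRADE_CODE: dict[str, int] = {g: i - 1 for i, g in enumerate(GRADE_ORDER)}

# ---------------------------------------------------------------------------
# Canonical common-peak patterns (Fig.-1-style: 13 peaks at 250 nm with the
# licoricesaponin G2 reference, 14 at 330 nm with the isoliquiritin
# reference).  Retention times span the 75-min gradient; areas are a
# plausible relative absorbance profile in mAU*s.
# ---------------------------------------------------------------------------


def _rt(peak_number: int) -> float:
    return round(5.0 + 1.35 * peak_number, 2)


PEAK_PATTERNS: dict[int, dict] = {
    250: {
        "reference": "licorice_saponin_g2",
        "peaks": [
            # (peak id, analyte, canonical rt [min], canonical area)
            (6, "liquiritin_apioside", _rt(6), 920.0),
            (7, "liquiritin", _rt(7), 1250.0),
            (10, "isoliquiritin_apioside", _rt(10), 310.0),
            (12, "isoliquiritin", _rt(12), 420.0),
            (13, "neoisoliquiritin", _rt(13), 160.0),
            (17, "liquiritigenin", _rt(17), 240.0),
            (25, "licorice_saponin_g2", _rt(25), 680.0),
            (27, "isoliquiritigenin", _rt(27), 130.0),
            (28, "formononetin", _rt(28), 95.0),
            (30, "glycycoumarin", _rt(30), 70.0),
            (32, "semilicoisoflavone_b", _rt(32), 55.0),
            (34, "licoisoflavone_a", _rt(34), 60.0),
            (38, "licoisoflavone_b", _rt(38), 48.0),
        ],
    },
    330: {
        "reference": "isoliquiritin",
        "peaks": [
            (6, "violanthin", _rt(6), 140.0),
            (8, "liquiritin_apioside", _rt(8), 520.0),
            (10, "liquiritin", _rt(10), 690.0),
            (15, "isoliquiritin_apioside", _rt(15), 360.0),
            (17, "isoliquiritin", _rt(17), 830.0),
            (18, "neoisoliquiritin", _rt(18), 270.0),
            (20, "liquiritigenin", _rt(20), 190.0),
            (22, "isoliquiritigenin", _rt(22), 310.0),
            (23, "glycycoumarin", _rt(23), 85.0),
            (24, "semilicoisoflavone_b", _rt(24), 70.0),
            (27, "licoisoflavone_a", _rt(27), 75.0),
            (28, "glycyrol", _rt(28), 40.0),
            (30, "licoflavonol", _rt(30), 35.0),
            (31, "licoisoflavone_b", _rt(31), 55.0),
        ],
    },
}

# ---------------------------------------------------------------------------
# Baseline means and CVs for the raw measurements
# ---------------------------------------------------------------------------

# Compound contents in mg per g dry weight: baselines sit in the ranges
# typical of pharmacopoeia-compliant G. uralensis roots.
_CONTENT_BASE: dict[str, float] = {
    "licorice_saponin_g2": 2.0,
    "glycyrrhizic_acid": 32.0,
    "formononetin": 0.40,
    "semilicoisoflavone_b": 0.15,
    "licoisoflavone_b": 0.20,
    "liquiritin_apioside": 8.0,
    "liquiritin": 12.0,
    "liquiritigenin": 1.2,
    "violanthin": 0.50,
    "isoliquiritin_apioside": 2.5,
    "isoliquiritin_isomer": 0.60,
    "isoliquiritin": 1.8,
    "neoisoliquiritin": 0.70,
    "glycyrol": 0.30,
    "licoflavonol": 0.10,
    "isoliquiritigenin": 0.35,
    "glycycoumarin": 0.25,
}

# grading-informative indices carry an adjacent-grade shift of 1.5 pooled SD;
# every other index is pure noise (no grade effect)
_DEFAULT_EFFECTS: dict[str, float] = {name: 0.0 for name in COMPOUNDS}
_DEFAULT_EFFECTS.update({name: 1.5 for name in KEY_INDICES})
_DEFAULT_EFFECTS.update({"alcohol_extract": 0.0, "water_extract": 0.0})


def _default_effects() -> dict[str, float]:
    return dict(_DEFAULT_EFFECTS)


def _default_region_weights() -> dict[str, float]:
    return {"genuine_A": 0.40, "genuine_B": 0.40, "nongenuine": 0.20}


def _default_grade_counts() -> dict[str, int]:
    return {"premium": 52, "first": 92, "second": 45}


def _default_fingerprint_log_sd() -> dict[str, float]:
    # per-grade multiplicative peak-area noise SD on the log scale; lower
    # grades have more distorted fingerprints, hence lower cosine similarity
    return {"premium": 0.05, "first": 0.12, "second": 0.22, "noncompliant": 0.35}


def _scaled_fingerprint_sd(table: Mapping[str, float], effect: float) -> dict[str, float]:
    """Shrink the per-grade fingerprint-noise spread toward the first-class
    level as the similarity effect size drops; ``effect`` = 1.5 reproduces the
    table, 0 flattens it (similarity becomes grade-uninformative)."""
    ref = table.get("first", 0.0)
    if ref <= 0:
        return dict(table)
    power = max(effect, 0.0) / 1.5
    return {g: ref * (sd / ref) ** power for g, sd in table.items()}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the study conditions: 282 batches, latent grade counts
    52/92/45 compliant plus 93 non-compliant, nine informative indices with a
    standardized adjacent-grade mean shift of 1.5 pooled SD, lognormal noise
    on strictly positive contents and normal noise elsewhere.
    """

    n_batches: int = 282
    region_weights: dict[str, float] = field(default_factory=_default_region_weights)
    growth_years_range: tuple[int, int] = (2, 5)
    seasons: tuple[str, str] = ("spring", "autumn")
    grade_counts: dict[str, int] = field(default_factory=_default_grade_counts)
    effect_sizes: dict[str, float] = field(default_factory=_default_effects)
    content_cv: float = 0.20  # lognormal CV of compound contents
    # appearance traits
    diameter_mean_mm: float = 12.0
    diameter_cv: float = 0.15
    weight_mean_g: float = 25.0
    weight_diameter_r: float = 0.90
    length_base_cm: float = 36.0
    length_per_year_cm: float = 2.2
    length_sd_cm: float = 3.5
    # total flavonoids (mg/g) read out through the UV assay
    flavonoid_mean_mg_g: float = 15.0
    flavonoid_cv: float = 0.18
    # extracts (% of dry weight)
    water_extract_mean_pct: float = 28.0
    water_extract_cv: float = 0.10
    alcohol_extract_mean_pct: float = 14.0
    alcohol_extract_cv: float = 0.12
    # chromatography noise
    rt_jitter_sd_min: float = 0.05
    fingerprint_log_sd: dict[str, float] = field(
        default_factory=_default_fingerprint_log_sd
    )
    # UV calibration truth (absorbance units per ug/mL at 337 nm)
    uv_slope: float = 0.053
    uv_intercept: float = 0.002
    uv_noise_sd: float = 0.002
    stock_ug_ml: float = 22.53
    standard_volumes_ml: tuple[float, ...] = (0.2, 0.5, 1.0, 2.0, 3.0, 4.0, 5.0)
    # pharmacopoeia compliance thresholds, mg/g dry weight
    glycyrrhizic_acid_min_mg_g: float = 20.0
    liquiritin_min_mg_g: float = 5.0
    # latent quality score: weights of the three provenance factors
    latent_weight_genuine: float = 1.0
    latent_weight_years: float = 1.0
    latent_weight_autumn: float = 0.5
    latent_noise_sd: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_batches < 1:
            raise ValueError("n_batches must be positive")
        if sum(self.grade_counts.values()) > self.n_batches:
            raise ValueError(
                "grade_counts sum exceeds n_batches "
                f"({sum(self.grade_counts.values())} > {self.n_batches})"
            )
        unknown = set(self.grade_counts) - {"premium", "first", "second"}
        if unknown:
            raise ValueError(f"unknown grade names in grade_counts: {sorted(unknown)}")
        for cv_name in (
            "content_cv",
            "diameter_cv",
            "flavonoid_cv",
            "water_extract_cv",
            "alcohol_extract_cv",
        ):
            if getattr(self, cv_name) <= 0:
                raise ValueError(f"{cv_name} must be > 0")
        if not all(np.isfinite(list(self.effect_sizes.values()))):
            raise ValueError("effect sizes must be finite")
        if abs(sum(self.region_weights.values()) - 1.0) > 1e-9:
            raise ValueError("region_weights must sum to 1")


@dataclass
class SyntheticDataset:
    """Container for one simulated study: six tidy tables.

    ``batches`` carries one row per batch (provenance factors, appearance
    traits and the latent grade); the remaining tables hold the raw assay
    measurements keyed by ``batch_id``.
    """

    batches: pd.DataFrame
    peaks_250: pd.DataFrame
    peaks_330: pd.DataFrame
    absorbance: pd.DataFrame
    contents: pd.DataFrame
    extracts: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all six tables as UTF-8 CSV files; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in (
            "batches",
            "peaks_250",
            "peaks_330",
            "absorbance",
            "contents",
            "extracts",
        ):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = path
        return paths


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    mu = float(np.log(mean) - 0.5 * sigma * sigma)
    return mu, sigma


def _trunc_lognormal(
    rng: Generator,
    mean: np.ndarray,
    cv: float,
    lo: np.ndarray | float = 0.0,
    hi: np.ndarray | float = np.inf,
) -> np.ndarray:
    """Inverse-CDF sample of a lognormal truncated to [lo, hi], elementwise."""
    mean = np.asarray(mean, dtype=float)
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = np.log(mean) - 0.5 * sigma**2
    a = np.where(np.asarray(lo) <= 0, -np.inf, (np.log(np.maximum(lo, 1e-300)) - mu) / sigma)
    b = np.where(np.isinf(hi), np.inf, (np.log(np.maximum(hi, 1e-300)) - mu) / sigma)
    u_lo, u_hi = stats.norm.cdf(a), stats.norm.cdf(b)
    u = rng.uniform(u_lo, u_hi)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _grade_mean(base: float, cv: float, effect: float, grade_code: np.ndarray) -> np.ndarray:
    """Grade-conditional mean: baseline shifted by ``effect`` pooled SDs per
    grade step, centred on first-class (code 1); floored at 15 % of baseline."""
    factor = 1.0 + (grade_code - 1) * effect * cv
    return base * np.maximum(factor, 0.15)


# ---------------------------------------------------------------------------
# Peak-table simulation
# ---------------------------------------------------------------------------


def simulate_peak_table(
    batch: Mapping,
    wavelength: int,
    seed: int | SeedSequence,
    rt_jitter_sd: float = 0.05,
    area_log_sd: float | None = None,
    fingerprint_log_sd: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate one batch's common-peak table at a detection wavelength.

    Retention times are jittered around the canonical pattern; peak areas are
    the canonical profile under multiplicative lognormal noise whose SD grows
    as the latent grade drops, which is what degrades the fingerprint cosine
    similarity of lower grades.  The reference peak (licoricesaponin G2 at
    250 nm, isoliquiritin at 330 nm) is always present.

    Parameters
    ----------
    batch
        Mapping with at least ``batch_id`` and ``true_grade``.
    wavelength
        Detection wavelength in nm; 250 or 330.
    seed
        Integer or SeedSequence; identical seed and grade give identical
        tables.
    rt_jitter_sd
        SD of the retention-time jitter in minutes (0 disables).
    area_log_sd
        Log-scale SD of the area noise; overrides the per-grade default.
    """
    if wavelength not in PEAK_PATTERNS:
        raise ValueError(f"unknown wavelength {wavelength}; expected 250 or 330")
    pattern = PEAK_PATTERNS[wavelength]
    rng = default_rng(seed)
    grade = str(batch.get("true_grade", "first"))
    if area_log_sd is None:
        table = fingerprint_log_sd or _default_fingerprint_log_sd()
        area_log_sd = table[grade]
    rows = []
    for peak_id, analyte, rt, area in pattern["peaks"]:
        rt_obs = rt + (rng.normal(0.0, rt_jitter_sd) if rt_jitter_sd > 0 else 0.0)
        area_obs = area * (np.exp(rng.normal(0.0, area_log_sd)) if area_log_sd > 0 else 1.0)
        rows.append(
            {
                "batch_id": batch["batch_id"],
                "wavelength": wavelength,
                "peak_id": peak_id,
                "analyte": analyte,
                "rt_min": rt_obs,
                "area": area_obs,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full-study simulation
# ---------------------------------------------------------------------------


def _assign_latent_grades(config: GeneratorConfig, rng: Generator, batches: pd.DataFrame) -> pd.Series:
    """Latent quality score from the three provenance factors, cut into the
    configured grade counts by rank (worst batches are non-compliant)."""
    year_quality = batches["growth_years"].map({2: 0.0, 3: 0.5, 4: 1.0, 5: 1.0})
    score = (
        config.latent_weight_genuine * batches["genuine_area"].astype(float)
        + config.latent_weight_years * year_quality
        + config.latent_weight_autumn * (batches["season"] == "autumn").astype(float)
        + rng.normal(0.0, config.latent_noise_sd, len(batches))
    )
    order = np.argsort(score.to_numpy(), kind="stable")
    n = len(batches)
    n_second = config.grade_counts.get("second", 0)
    n_first = config.grade_counts.get("first", 0)
    n_premium = config.grade_counts.get("premium", 0)
    n_noncompliant = n - n_second - n_first - n_premium
    grades = np.empty(n, dtype=object)
    bounds = np.cumsum([n_noncompliant, n_second, n_first, n_premium])
    grades[order[: bounds[0]]] = "noncompliant"
    grades[order[bounds[0] : bounds[1]]] = "second"
    grades[order[bounds[1] : bounds[2]]] = "first"
    grades[order[bounds[2] : bounds[3]]] = "premium"
    return pd.Series(grades, index=batches.index, name="true_grade")


def simulate_batches(config: GeneratorConfig | None = None) -> SyntheticDataset:
    """Simulate a full study: batch records plus every raw assay table.

    Deterministic given ``config.seed``.  Latent grade counts match
    ``config.grade_counts`` exactly, grade-conditional index means follow
    ``config.effect_sizes``, and compound contents respect the monograph
    compliance split by construction (compliant classes above the
    glycyrrhizic-acid/liquiritin minima, the non-compliant class below the
    glycyrrhizic-acid minimum).
    """
    config = config or GeneratorConfig()
    config.validate()
    root = SeedSequence(config.seed)
    ss_factors, ss_grades, ss_traits, ss_contents, ss_uv, ss_extracts, ss_peaks = root.spawn(7)
    rng = default_rng(ss_factors)
    n = config.n_batches

    # --- provenance factors -------------------------------------------------
    regions = list(config.region_weights)
    weights = np.array([config.region_weights[r] for r in regions])
    region = rng.choice(regions, size=n, p=weights / weights.sum())
    lo, hi = config.growth_years_range
    growth_years = rng.integers(lo, hi + 1, size=n)
    season = rng.choice(list(config.seasons), size=n)
    batches = pd.DataFrame(
        {
            "batch_id": [f"S{i + 1}" for i in range(n)],
            "region": region,
            "genuine_area": [not str(r).startswith("nongenuine") for r in region],
            "growth_years": growth_years,
            "season": season,
        }
    )
    batches["true_grade"] = _assign_latent_grades(config, default_rng(ss_grades), batches)
    gcode = batches["true_grade"].map(GRADE_CODE).to_numpy()

    # --- appearance traits --------------------------------------------------
    rng_t = default_rng(ss_traits)
    d_mean = _grade_mean(config.diameter_mean_mm, config.diameter_cv, config.effect_sizes.get("diameter", 0.0), gcode)
    d_sd = config.diameter_mean_mm * config.diameter_cv
    diameter = np.maximum(rng_t.normal(d_mean, d_sd), 1.0)
    w_slope = config.weight_mean_g / config.diameter_mean_mm
    r = config.weight_diameter_r
    w_sd = w_slope * d_sd * np.sqrt(max(1.0 / r**2 - 1.0, 0.0))
    weight = np.maximum(w_slope * diameter + rng_t.normal(0.0, w_sd, n), 0.5)
    length = np.maximum(
        config.length_base_cm
        + config.length_per_year_cm * growth_years
        + rng_t.normal(0.0, config.length_sd_cm, n),
        5.0,
    )
    batches["length"] = length
    batches["diameter"] = diameter
    batches["weight"] = weight

    # --- compound contents (mg/g dry weight) --------------------------------
    rng_c = default_rng(ss_contents)
    contents = pd.DataFrame({"batch_id": batches["batch_id"]})
    ga_min = config.glycyrrhizic_acid_min_mg_g
    lq_min = config.liquiritin_min_mg_g
    compliant = gcode >= 0
    for name in COMPOUNDS:
        base = _CONTENT_BASE[name]
        mean = _grade_mean(base, config.content_cv, config.effect_sizes.get(name, 0.0), gcode)
        if name == "glycyrrhizic_acid":
            # compliance split is built in: compliant batches truncated above
            # the monograph minimum, non-compliant strictly below it
            lo_b = np.where(compliant, ga_min * 1.02, 0.0)
            hi_b = np.where(compliant, np.inf, ga_min * 0.98)
            vals = _trunc_lognormal(rng_c, mean, config.content_cv, lo_b, hi_b)
        elif name == "liquiritin":
            lo_b = np.where(compliant, lq_min * 1.02, 0.0)
            vals = _trunc_lognormal(rng_c, mean, config.content_cv, lo_b, np.inf)
        else:
            vals = _trunc_lognormal(rng_c, mean, config.content_cv)
        contents[name] = vals

    # --- UV absorbance table (standard series + samples) --------------------
    rng_u = default_rng(ss_uv)
    std_conc = np.array(config.standard_volumes_ml) * config.stock_ug_ml / 10.0
    std_abs = config.uv_slope * std_conc + config.uv_intercept + rng_u.normal(
        0.0, config.uv_noise_sd, len(std_conc)
    )
    flav_mean = _grade_mean(
        config.flavonoid_mean_mg_g, config.flavonoid_cv, config.effect_sizes.get("total_flavonoids", 0.0), gcode
    )
    flav_true = _trunc_lognormal(rng_u, flav_mean, config.flavonoid_cv)
    # 0.2 g extracted into 10 mL, 0.1 mL aliquot developed to 10 mL:
    # cuvette concentration in ug/mL is content * 0.2*1000 / (100 * 10)
    cuvette = flav_true * 0.2 * 1000.0 / (100.0 * 10.0)
    sample_abs = config.uv_slope * cuvette + config.uv_intercept + rng_u.normal(
        0.0, config.uv_noise_sd, n
    )
    absorbance = pd.concat(
        [
            pd.DataFrame(
                {
                    "sample_id": [f"STD{i + 1}" for i in range(len(std_conc))],
                    "role": "standard",
                    "concentration_ug_ml": std_conc,
                    "absorbance_337": std_abs,
                }
            ),
            pd.DataFrame(
                {
                    "sample_id": batches["batch_id"],
                    "role": "sample",
                    "concentration_ug_ml": np.nan,
                    "absorbance_337": sample_abs,
                }
            ),
        ],
        ignore_index=True,
    )

    # --- extract contents (% dry weight) ------------------------------------
    rng_e = default_rng(ss_extracts)
    water_mean = _grade_mean(
        config.water_extract_mean_pct, config.water_extract_cv, config.effect_sizes.get("water_extract", 0.0), gcode
    )
    alcohol_mean = _grade_mean(
        config.alcohol_extract_mean_pct,
        config.alcohol_extract_cv,
        config.effect_sizes.get("alcohol_extract", 0.0),
        gcode,
    )
    extracts = pd.DataFrame(
        {
            "batch_id": batches["batch_id"],
            "water_extract": _trunc_lognormal(rng_e, water_mean, config.water_extract_cv),
            "alcohol_extract": _trunc_lognormal(rng_e, alcohol_mean, config.alcohol_extract_cv),
        }
    )

    # --- peak tables ---------------------------------------------------------
    peak_seeds = ss_peaks.spawn(n)
    peak_frames = {250: [], 330: []}
    sd_tables = {
        wl: _scaled_fingerprint_sd(
            config.fingerprint_log_sd, config.effect_sizes.get(f"sim_{wl}", 1.5)
        )
        for wl in (250, 330)
    }
    for i, (_, row) in enumerate(batches.iterrows()):
        child = peak_seeds[i].spawn(2)
        for j, wl in enumerate((250, 330)):
            peak_frames[wl].append(
                simulate_peak_table(
                    row,
                    wl,
                    child[j],
                    rt_jitter_sd=config.rt_jitter_sd_min,
                    fingerprint_log_sd=sd_tables[wl],
                )
            )
    peaks_250 = pd.concat(peak_frames[250], ignore_index=True)
    peaks_330 = pd.concat(peak_frames[330], ignore_index=True)

    return SyntheticDataset(
        batches=batches,
        peaks_250=peaks_250,
        peaks_330=peaks_330,
        absorbance=absorbance,
        contents=contents,
        extracts=extracts,
    )


# ---------------------------------------------------------------------------
# Compliance filter
# ---------------------------------------------------------------------------


def apply_compliance_filter(
    batches: pd.DataFrame,
    contents: pd.DataFrame,
    glycyrrhizic_acid_min: float = 20.0,
    liquiritin_min: float = 5.0,
) -> pd.DataFrame:
    """Return the batches meeting the monograph content minima.

    Thresholds are in mg/g dry weight (defaults: glycyrrhizic acid 20 mg/g =
    2.0 %, liquiritin 5 mg/g = 0.50 %).
    """
    for col in ("glycyrrhizic_acid", "liquiritin"):
        if col not in contents.columns:
            raise ValueError(f"contents table is missing required column '{col}'")
    merged = batches.merge(
        contents[["batch_id", "glycyrrhizic_acid", "liquiritin"]], on="batch_id", how="left"
    )
    ok = (merged["glycyrrhizic_acid"] >= glycyrrhizic_acid_min) & (
        merged["liquiritin"] >= liquiritin_min
    )
    return batches.loc[ok.to_numpy()].reset_index(drop=True)


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A configuration with every grade effect removed (all indices pure
    noise); used for permutation and type-I-error calibration checks."""
    cfg = GeneratorConfig(seed=seed, **overrides)
    cfg.effect_sizes = {k: 0.0 for k in cfg.effect_sizes}
    return cfg
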