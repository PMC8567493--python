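"""Categorised FTIR feature assembly and the cohort modelling table.

Every scanned 6 μm × 6 μm bone area contributes four band-ratio parameters
(MMR, CPR, crystallinity, XLR).  Each parameter is split into *low / medium /
high* categories by cohort-level thresholds: the low threshold is the mean of
the lower half of the pooled values minus one SD of that half, the high
threshold is the mean of the upper half plus one SD of that half, and values
strictly below / above those cut values are low / high (boundary values are
medium).

Per sample, the category statistics are area-weighted: each category's area
is its pixel count times 36 μm², its area fraction is that area over the
total scanned bone area, and the category mean and SD are multiplied by the
area fraction ("area-normalised").  The canonical infrared feature vector has
exactly 44 entries:

    4 parameters x (overall mean, overall SD)                        =  8
    4 parameters x 3 categories x (fraction, norm. mean, norm. SD)   = 36

These are joined with 12 histomorphometric parameters and the patient
covariates into one rectangular cohort table used by the duration and
fracture models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .spectral import PIXEL_SIZE_UM

__all__ = [
    "FTIR_PARAMS",
    "CATEGORIES",
    "IR_FEATURES",
    "HIST_FEATURES",
    "HIST_EXTRAS",
    "COVARIATES",
    "CategoryThresholds",
    "compute_category_thresholds",
    "categorize",
    "category_area_stats",
    "assemble_ir_features",
    "build_cohort_table",
]

FTIR_PARAMS = ("mmr", "cpr", "crystallinity", "xlr")
CATEGORIES = ("low", "medium", "high")

IR_FEATURES: tuple[str, ...] = tuple(
    [f"{p}_{stat}" for p in FTIR_PARAMS for stat in ("mean", "sd")]
    + [
        f"{p}_{c}_{stat}"
        for p in FTIR_PARAMS
        for c in CATEGORIES
        for stat in ("area_fraction", "norm_mean", "norm_sd")
    ]
)

# Canonical 12 histomorphometric modelling parameters (ASBMR nomenclature,
# lower-cased): structure (BV/TV, Tb.Sp, Tb.Th), formation (OV/BV, OS/BS,
# O.Th, N.Ob/B.Pm), resorption (ES/BS, N.Oc/B.Pm) and dynamics (MAR, MS/BS,
# Ac.f).  BFR/BS and Mlt are carried as derived extras outside the default
# modelling set.
HIST_FEATURES = (
    "bv_tv",
    "tb_sp",
    "tb_th",
    "ov_bv",
    "os_bs",
    "o_th",
    "n_ob_bpm",
    "es_bs",
    "n_oc_bpm",
    "mar",
    "ms_bs",
    "ac_f",
)
HIST_EXTRAS = ("bfr_bs", "mlt")

COVARIATES = ("age", "bmi", "bmd_spine", "bmd_hip", "duration_years", "fracture")

# Published cohort-level categorisation thresholds (low, high) per parameter.
PUBLISHED_THRESHOLDS = {
    "mmr": (3.580, 5.230),
    "cpr": (0.008, 0.010),
    "crystallinity": (1.072, 1.164),
    "xlr": (3.065, 3.769),
}


def _half_stats(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size >= 2 else 0.0
    return mean, sd


def compute_category_thresholds(values: Iterable[float]) -> tuple[float, float]:
    """Low/high cut values for one parameter from pooled pixel values.

    The pooled values are split at their median (median-equal values go to
    the lower half); low = mean(lower half) - SD(lower half), high =
    mean(upper half) + SD(upper half), with sample SD (n-1).  A constant
    vector yields low = high = the constant.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values to compute thresholds")
    med = np.median(v)
    lower = v[v <= med]
    upper = v[v > med]
    if upper.size == 0:  # all values tie at the median
        upper = lower
    lo_mean, lo_sd = _half_stats(lower)
    hi_mean, hi_sd = _half_stats(upper)
    return lo_mean - lo_sd, hi_mean + hi_sd


@dataclass(frozen=True)
class CategoryThresholds:
    """Per-parameter (low, high) cut values for FTIR categorisation."""

    mmr: tuple[float, float]
    cpr: tuple[float, float]
    crystallinity: tuple[float, float]
    xlr: tuple[float, float]

    def __post_init__(self) -> None:
        for p in FTIR_PARAMS:
            lo, hi = getattr(self, p)
            if not lo <= hi:
                raise ValueError(f"{p}: low threshold {lo} exceeds high {hi}")

    def for_param(self, param: str) -> tuple[float, float]:
        if param not in FTIR_PARAMS:
            raise KeyError(f"unknown FTIR parameter {param!r}")
        return getattr(self, param)

    @classmethod
    def published_defaults(cls) -> "CategoryThresholds":
        """The published cohort-level threshold values."""
        return cls(**PUBLISHED_THRESHOLDS)

    @classmethod
    def from_pixel_values(
        cls, pooled: Mapping[str, Iterable[float]]
    ) -> "CategoryThresholds":
        """Compute thresholds from pooled per-parameter pixel values."""
        return cls(
            **{p: compute_category_thresholds(pooled[p]) for p in FTIR_PARAMS}
        )

    @classmethod
    def from_pixel_table(cls, pixel_table: pd.DataFrame) -> "CategoryThresholds":
        valid = pixel_table[pixel_table["valid"].astype(bool)]
        return cls.from_pixel_values({p: valid[p].to_numpy() for p in FTIR_PARAMS})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({p: list(getattr(self, p)) for p in FTIR_PARAMS}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CategoryThresholds":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**{p: tuple(raw[p]) for p in FTIR_PARAMS})


def categorize(value: float, thresholds: tuple[float, float]) -> str:
    """Assign low/medium/high; boundary values are medium (strict inequalities)."""
    if not np.isfinite(value):
        raise ValueError("value must be finite")
    low, high = thresholds
    if value < low:
        return "low"
    if value > high:
        return "high"
    return "medium"


def category_area_stats(
    pixel_table: pd.DataFrame,
    thresholds: CategoryThresholds,
    pixel_area_um2: float = PIXEL_SIZE_UM**2,
) -> pd.DataFrame:
    """Area-weighted per-category statistics for each FTIR parameter.

    Returns a DataFrame indexed by (parameter, category) with columns
    ``n_pixels, area_um2, area_fraction, norm_mean, norm_sd``.  Only valid
    pixels contribute; category areas are exact multiples of the pixel area
    and the three fractions sum to 1 for every parameter.
    """
    valid = pixel_table[pixel_table["valid"].astype(bool)]
    if valid.empty:
        raise ValueError("pixel table contains no valid pixels")
    n_total = len(valid)
    rows = []
    for p in FTIR_PARAMS:
        cuts = thresholds.for_param(p)
        vals = valid[p].to_numpy(dtype=float)
        cats = np.where(vals < cuts[0], "low", np.where(vals > cuts[1], "high", "medium"))
        for c in CATEGORIES:
            in_cat = vals[cats == c]
            n = in_cat.size
            frac = n / n_total
            mean = float(np.mean(in_cat)) if n else 0.0
            sd = float(np.std(in_cat, ddof=1)) if n >= 2 else 0.0
            rows.append((p, c, n, n * pixel_area_um2, frac, mean * frac, sd * frac))
    out = pd.DataFrame(
        rows,
        columns=[
            "parameter",
            "category",
            "n_pixels",
            "area_um2",
            "area_fraction",
            "norm_mean",
            "norm_sd",
        ],
    ).set_index(["parameter", "category"])
    return out


def assemble_ir_features(
    pixel_table: pd.DataFrame,
    thresholds: CategoryThresholds,
    pixel_area_um2: float = PIXEL_SIZE_UM**2,
) -> dict[str, float]:
    """The canonical 44-entry infrared feature vector for one sample."""
    valid = pixel_table[pixel_table["valid"].astype(bool)]
    if valid.empty:
        raise ValueError("pixel table contains no valid pixels")
    stats = category_area_stats(pixel_table, thresholds, pixel_area_um2)
    features: dict[str, float] = {}
    for p in FTIR_PARAMS:
        vals = valid[p].to_numpy(dtype=float)
        features[f"{p}_mean"] = float(np.mean(vals))
        features[f"{p}_sd"] = float(np.std(vals, ddof=1)) if vals.size >= 2 else 0.0
    for p in FTIR_PARAMS:
        for c in CATEGORIES:
            row = stats.loc[(p, c)]
            features[f"{p}_{c}_area_fraction"] = float(row["area_fraction"])
            features[f"{p}_{c}_norm_mean"] = float(row["norm_mean"])
            features[f"{p}_{c}_norm_sd"] = float(row["norm_sd"])
    assert len(features) == 44 and list(features) == list(IR_FEATURES)
    return features


def build_cohort_table(
    sample_features: Mapping[str, Mapping[str, float]],
    patient_table: pd.DataFrame,
    id_column: str = "patient_id",
) -> pd.DataFrame:
    """Join per-sample IR features onto the patient table, one row per patient.

    ``sample_features`` maps patient id -> 44-entry feature mapping.  Raises
    on duplicate patients, on patients without features, and on feature
    vectors without a matching patient, naming the offending key.
    """
    ids = patient_table[id_column]
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate patient id {dup.iloc[0]!r}")
    missing = [pid for pid in ids if pid not in sample_features]
    if missing:
        raise ValueError(f"missing IR features for patient {missing[0]!r}")
    extra = [pid for pid in sample_features if pid not in set(ids)]
    if extra:
        raise ValueError(f"IR features for unknown patient {extra[0]!r}")
    feat_df = pd.DataFrame(
        [dict(sample_features[pid]) for pid in ids], index=patient_table.index
    )
    bad = [c for c in feat_df.columns if c not in IR_FEATURES]
    if bad:
        raise ValueError(f"unexpected IR feature column {bad[0]!r}")
    out = pd.concat([patient_table.reset_index(drop=True),
                     feat_df.reset_index(drop=True)], axis=1)
    if out[list(IR_FEATURES)].isna().any().any():
        raise ValueError("missing values in assembled IR features")
    return out
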