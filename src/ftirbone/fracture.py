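"""Fracture model: low-energy fracture as outcome, feature-set comparison.

The presence/absence of a low-energy fracture is modelled from bone-quality
features and treatment duration, the latter entering either as the
continuous number of years or as the two-period category from the duration
model's selected cutpoint.  Evaluation balances the fracture/no-fracture
classes by repeated random down-sampling before cross-validation, exactly as
in the duration model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import features as ft
from .duration import dichotomize_duration, resolve_feature_set, _grid_frame
from .model import BoosterParams, averaged_importances, cross_validated_eval

__all__ = [
    "FRACTURE_FEATURE_SETS",
    "FractureModel",
    "FractureResults",
    "compare_fracture_models",
    "fracture_importances",
]

FRACTURE_FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "histomorphometry": ft.HIST_FEATURES,
    "duration_categorical": ("duration_category",),
    "duration_continuous": ("duration_years",),
    "ir": ft.IR_FEATURES,
    "ir_histo": ft.IR_FEATURES + ft.HIST_FEATURES,
    "ir_duration_continuous": ft.IR_FEATURES + ("duration_years",),
    "ir_histo_duration_continuous": ft.IR_FEATURES + ft.HIST_FEATURES + ("duration_years",),
    # every candidate parameter, for the importance ranking: patient
    # covariates (age, BMI, hip BMD) enter so their irrelevance is testable
    "full": ft.IR_FEATURES
    + ft.HIST_FEATURES
    + ("duration_years", "age", "bmi", "bmd_hip"),
}


def _prepare(cohort: pd.DataFrame, cutpoint_years: float) -> pd.DataFrame:
    if cohort["fracture"].nunique() < 2:
        raise ValueError("fracture model requires both outcome classes present")
    work = cohort.sort_values("patient_id").reset_index(drop=True)
    work = work.assign(
        duration_category=dichotomize_duration(work["duration_years"], cutpoint_years)
    )
    return work


def compare_fracture_models(
    cohort: pd.DataFrame,
    specs: list[str],
    cutpoint_years: float = 8.0,
    params: BoosterParams | None = None,
    cv_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    mrmr_k: int | None = 15,
) -> pd.DataFrame:
    """One balanced repeated-CV evaluation per feature-set spec (grid layout).

    Grid columns follow the fracture-table layout: AUC, accuracy, then
    precision/sensitivity/F-1 for the no-fracture and fracture classes.
    """
    deduped = list(dict.fromkeys(specs))
    if len(deduped) < len(specs):
        warnings.warn("duplicate spec names were deduplicated")
    work = _prepare(cohort, cutpoint_years)
    rows = {}
    for name in deduped:
        cols = resolve_feature_set(name, FRACTURE_FEATURE_SETS)
        rows[name] = cross_validated_eval(
            work, cols, "fracture", params, cv_folds, n_repeats, seed, mrmr_k
        )
    return _grid_frame(rows, "feature_set", ("no_fracture", "fracture"))


def fracture_importances(
    cohort: pd.DataFrame,
    spec: str = "ir_histo_duration_continuous",
    cutpoint_years: float = 8.0,
    params: BoosterParams | None = None,
    n_repeats: int = 50,
    seed: int = 0,
    mrmr_k: int | None = 15,
    retention: float = 0.2,
) -> pd.DataFrame:
    """Repeat-averaged signed coefficients for the fracture outcome."""
    cols = resolve_feature_set(spec, FRACTURE_FEATURE_SETS)
    work = _prepare(cohort, cutpoint_years)
    return averaged_importances(
        work, cols, "fracture", params, n_repeats, seed, mrmr_k, retention
    )


class FractureModel:
    """Relates bone-quality features and treatment duration to fracture."""

    def __init__(
        self,
        cohort: pd.DataFrame,
        specs: list[str] | None = None,
        cutpoint_years: float = 8.0,
        booster_params: BoosterParams | None = None,
        cv_folds: int = 5,
        n_repeats: int = 50,
        mrmr_k: int | None = 15,
    ):
        self.specs = list(specs) if specs is not None else list(FRACTURE_FEATURE_SETS)
        for s in dict.fromkeys(self.specs):
            resolve_feature_set(s, FRACTURE_FEATURE_SETS)
        self.cohort = cohort
        self.cutpoint_years = cutpoint_years
        self.booster_params = booster_params or BoosterParams()
        self.cv_folds = cv_folds
        self.n_repeats = n_repeats
        self.mrmr_k = mrmr_k

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, **kwargs) -> "FractureModel":
        return cls(cohort, **kwargs)

    def fit(self, seed: int = 0) -> "FractureResults":
        grid = compare_fracture_models(
            self.cohort,
            self.specs,
            self.cutpoint_years,
            self.booster_params,
            self.cv_folds,
            self.n_repeats,
            seed,
            self.mrmr_k,
        )
        return FractureResults(self, grid, seed)


class FractureResults:
    """Fitted fracture model: evaluation grid and per-spec importances."""

    def __init__(self, model: FractureModel, grid_frame: pd.DataFrame, seed: int):
        self.model = model
        self._grid = grid_frame
        self.seed = seed

    def grid(self) -> pd.DataFrame:
        return self._grid.copy()

    @property
    def best_spec(self) -> str:
        idx = self._grid["auc"].idxmax()
        return str(self._grid.loc[idx, "feature_set"])

    @property
    def best_auc(self) -> float:
        return float(self._grid["auc"].max())

    def importances(
        self,
        spec: str = "ir_histo_duration_continuous",
        retention: float = 0.2,
        seed: int | None = None,
    ) -> pd.DataFrame:
        return fracture_importances(
            self.model.cohort,
            spec,
            self.model.cutpoint_years,
            self.model.booster_params,
            self.model.n_repeats,
            self.seed if seed is None else seed,
            self.model.mrmr_k,
            retention,
        )

    def summary(self) -> str:
        counts = self.model.cohort["fracture"].value_counts()
        return "\n".join(
            [
                "Fracture model (boosted linear classifier, repeated balanced CV)",
                f"  cohort: {int(counts.get(0, 0))} no-fracture / {int(counts.get(1, 0))} fracture",
                f"  duration cutpoint for the categorical spec: {self.model.cutpoint_years:g} years",
                f"  repeats: {self.model.n_repeats}, folds: {self.model.cv_folds}, seed: {self.seed}",
                f"  best feature set: {self.best_spec} (AUC = {self.best_auc:.2f})",
                "",
                self._grid.round(3).to_string(index=False),
            ]
        )
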