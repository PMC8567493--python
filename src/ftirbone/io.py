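"""Formats, configuration and the staged pipeline.

Spectral maps travel in an HDF5 container::

    /wavenumbers                  (n,)        float64, cm^-1
    /samples/<id>/absorbance      (H, W, n)   float64
    /samples/<id>/mask            (H, W)      bool
    attrs: pixel_size_um, schema_version

Tabular outputs are CSV (prefixed with a ``# config_hash=...`` comment line
so every artefact is traceable to its configuration), results and thresholds
are JSON.  ``run_pipeline`` chains simulate -> extract -> features ->
duration sweep -> fracture comparison and writes every grid.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

from . import features as ft
from . import synthetic as syn
from .duration import DurationModel
from .fracture import FractureModel
from .model import BoosterParams
from .spectral import BandConfig, SpectralMap, extract_pixel_table

__all__ = [
    "SchemaError",
    "DimensionError",
    "PipelineConfig",
    "write_spectral_container",
    "read_spectral_container",
    "run_pipeline",
]

SCHEMA_VERSION = "1"
log = logging.getLogger("ftirbone")


class SchemaError(ValueError):
    """Container layout or version not understood."""


class DimensionError(ValueError):
    """Dataset dimensions are inconsistent."""


def write_spectral_container(path, maps: Mapping[str, SpectralMap]) -> None:
    """Write spectral maps; all samples must share one wavenumber axis."""
    maps = dict(maps)
    if not maps:
        raise ValueError("no maps to write")
    first = next(iter(maps.values()))
    for m in maps.values():
        if not np.array_equal(m.wavenumbers, first.wavenumbers):
            raise ValueError("all maps must share one wavenumber axis")
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["pixel_size_um"] = first.pixel_size_um
        fh.create_dataset("wavenumbers", data=first.wavenumbers)
        grp = fh.create_group("samples")
        for sid, m in maps.items():
            g = grp.create_group(str(sid))
            g.create_dataset("absorbance", data=m.absorbance)
            g.create_dataset("mask", data=m.mask)


def read_spectral_container(path) -> dict[str, SpectralMap]:
    """Read every sample; raises distinct errors for schema/dimension problems."""
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(f"unknown schema version {version!r}")
        if "wavenumbers" not in fh:
            raise SchemaError("container missing /wavenumbers")
        if "samples" not in fh:
            raise SchemaError("container missing /samples")
        wn = fh["wavenumbers"][()]
        pixel_size = float(fh.attrs.get("pixel_size_um", 6.0))
        out: dict[str, SpectralMap] = {}
        for sid, g in fh["samples"].items():
            for name in ("absorbance", "mask"):
                if name not in g:
                    raise SchemaError(f"sample {sid!r} missing {name}")
            ab = g["absorbance"][()]
            mask = g["mask"][()]
            if ab.ndim != 3 or ab.shape[2] != wn.size:
                raise DimensionError(
                    f"sample {sid!r}: absorbance shape {ab.shape} does not match "
                    f"axis length {wn.size}"
                )
            if mask.shape != ab.shape[:2]:
                raise DimensionError(
                    f"sample {sid!r}: mask shape {mask.shape} != grid {ab.shape[:2]}"
                )
            out[sid] = SpectralMap(wn, ab, mask.astype(bool), pixel_size)
    return out


# --- configuration ----------------------------------------------------------


@dataclass
class PipelineConfig:
    """Validated configuration for the full pipeline."""

    seed: int = 0
    generator: syn.GeneratorConfig = field(default_factory=syn.GeneratorConfig)
    bands: BandConfig = field(default_factory=BandConfig)
    booster: BoosterParams = field(default_factory=BoosterParams)
    threshold_mode: str = "computed"  # "computed" | "published"
    candidates: tuple[int, ...] = (5, 6, 7, 8, 9)
    duration_feature_set: str = "ir_histo_bmi"
    fracture_specs: tuple[str, ...] | None = None  # None -> all
    retention: float = 0.2
    n_repeats: int = 10
    cv_folds: int = 5
    mrmr_k: int | None = 15
    via_spectra: bool = True

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("computed", "published"):
            raise ValueError("threshold_mode must be 'computed' or 'published'")
        if not self.candidates:
            raise ValueError("candidates must be non-empty")
        self.generator.validate()

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        cfg = cls()
        for section_name, target in (
            ("generator", cfg.generator),
            ("bands", cfg.bands),
            ("booster", cfg.booster),
        ):
            section = raw.pop(section_name, None)
            if section is not None:
                if section_name == "bands":
                    section = {
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in section.items()
                    }
                known = {f.name for f in dataclasses.fields(target)}
                unknown = set(section) - known
                if unknown:
                    raise ValueError(
                        f"unknown key {sorted(unknown)[0]!r} in config section "
                        f"{section_name!r}"
                    )
                setattr(cfg, section_name, dataclasses.replace(target, **section))
        top_known = {f.name for f in dataclasses.fields(cls)} - {"generator", "bands", "booster"}
        unknown = set(raw) - top_known
        if unknown:
            raise ValueError(f"unknown config key {sorted(unknown)[0]!r}")
        for k, v in raw.items():
            if k in ("candidates", "fracture_specs") and isinstance(v, list):
                v = tuple(v)
            setattr(cfg, k, v)
        cfg.__post_init__()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def _write_json(obj, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        json.dump({"config_hash": config_hash, **obj}, fh, indent=2, default=str)


# --- pipeline stages --------------------------------------------------------


def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    """Generate the patient table, planted truth, and (optionally) spectral maps."""
    chash = config.config_hash()
    patients, truth = syn.generate_cohort(config.generator, config.seed)
    _write_csv(patients, outdir / "patients.csv", chash)
    _write_json(
        {
            "change_point_years": truth.change_point_years,
            "latent": truth.latent.to_dict(orient="list"),
        },
        outdir / "truth.json",
        chash,
    )
    if config.via_spectra:
        ss = np.random.SeedSequence(config.seed)
        seeds = ss.spawn(len(patients))
        maps = {}
        for i, (_, row) in enumerate(patients.iterrows()):
            pseed = int(seeds[i].generate_state(1)[0] % (2**31))
            maps[row["patient_id"]] = syn.generate_spectral_map(
                row, config.generator, pseed, config.bands
            )
        write_spectral_container(outdir / "maps.h5", maps)
    log.info("simulate: wrote %d patients (hash %s)", len(patients), chash)


def stage_extract(config: PipelineConfig, outdir: Path) -> None:
    """Per-sample pixel tables, from the container or the fast sampling path."""
    chash = config.config_hash()
    pixdir = outdir / "pixels"
    pixdir.mkdir(exist_ok=True)
    if config.via_spectra:
        maps = read_spectral_container(outdir / "maps.h5")
        for sid, smap in maps.items():
            tbl = extract_pixel_table(smap, config.bands)
            _write_csv(tbl, pixdir / f"{sid}.csv", chash)
        n = len(maps)
    else:
        patients = pd.read_csv(outdir / "patients.csv", comment="#")
        ss = np.random.SeedSequence(config.seed)
        seeds = ss.spawn(len(patients) + 1)
        for i, (_, row) in enumerate(patients.iterrows()):
            pseed = int(seeds[i].generate_state(1)[0] % (2**31))
            tbl = syn.generate_pixel_table(row, config.generator, pseed)
            _write_csv(tbl, pixdir / f"{row['patient_id']}.csv", chash)
        n = len(patients)
    log.info("extract: wrote %d pixel tables", n)


def stage_features(config: PipelineConfig, outdir: Path) -> None:
    """Thresholds, 44 IR features per sample, cohort table with outcomes."""
    chash = config.config_hash()
    patients = pd.read_csv(outdir / "patients.csv", comment="#")
    tables = {
        pid: pd.read_csv(outdir / "pixels" / f"{pid}.csv", comment="#")
        for pid in patients["patient_id"]
    }
    if config.threshold_mode == "published":
        thresholds = ft.CategoryThresholds.published_defaults()
    else:
        pooled = {
            p: np.concatenate([t.loc[t["valid"], p].to_numpy() for t in tables.values()])
            for p in ft.FTIR_PARAMS
        }
        thresholds = ft.CategoryThresholds.from_pixel_values(pooled)
    thresholds.to_json(outdir / "thresholds.json")
    feats = {pid: ft.assemble_ir_features(t, thresholds) for pid, t in tables.items()}
    cohort = ft.build_cohort_table(feats, patients)
    flags, _ = syn.generate_fracture_outcomes(
        cohort,
        config.generator.fracture_coeffs,
        config.seed + 1,
        config.generator.fracture_centers,
    )
    cohort["fracture"] = flags
    _write_csv(cohort, outdir / "cohort.csv", chash)
    log.info(
        "features: cohort table %d x %d, %d fractures",
        *cohort.shape,
        int(cohort["fracture"].sum()),
    )


def stage_duration(config: PipelineConfig, outdir: Path) -> int:
    chash = config.config_hash()
    cohort = pd.read_csv(outdir / "cohort.csv", comment="#")
    model = DurationModel(
        cohort,
        feature_set=config.duration_feature_set,
        candidates=config.candidates,
        booster_params=config.booster,
        cv_folds=config.cv_folds,
        n_repeats=config.n_repeats,
        mrmr_k=config.mrmr_k,
    )
    res = model.fit(seed=config.seed)
    _write_csv(res.grid(), outdir / "duration_grid.csv", chash)
    imp = res.importances(retention=config.retention)
    _write_csv(imp, outdir / "duration_importances.csv", chash)
    _write_json(
        {
            "selected_cutpoint_years": res.selected_cutpoint,
            "auc": res.auc,
            "feature_set": res.sweep.feature_set,
            "skipped_candidates": list(res.sweep.skipped),
        },
        outdir / "sweep.json",
        chash,
    )
    log.info("duration: selected cutpoint %d (AUC %.3f)", res.selected_cutpoint, res.auc)
    return res.selected_cutpoint


def stage_fracture(config: PipelineConfig, outdir: Path, cutpoint: float) -> None:
    chash = config.config_hash()
    cohort = pd.read_csv(outdir / "cohort.csv", comment="#")
    model = FractureModel(
        cohort,
        specs=list(config.fracture_specs) if config.fracture_specs else None,
        cutpoint_years=cutpoint,
        booster_params=config.booster,
        cv_folds=config.cv_folds,
        n_repeats=config.n_repeats,
        mrmr_k=config.mrmr_k,
    )
    res = model.fit(seed=config.seed)
    _write_csv(res.grid(), outdir / "fracture_grid.csv", chash)
    imp = res.importances(retention=config.retention)
    _write_csv(imp, outdir / "fracture_importances.csv", chash)
    _write_json(
        {"best_spec": res.best_spec, "best_auc": res.best_auc},
        outdir / "fracture.json",
        chash,
    )
    log.info("fracture: best spec %s (AUC %.3f)", res.best_spec, res.best_auc)


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Path]:
    """simulate -> extract -> features -> duration sweep -> fracture comparison.

    Writes every grid/JSON into ``outdir``; each file carries the config
    hash.  Raises (with the failing stage in the log) on any stage error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("config hash %s; seed %d", config.config_hash(), config.seed)
        log.info("defaults in effect: %s", json.dumps(config.to_dict(), default=str))
        for stage_name, fn in (
            ("simulate", lambda: stage_simulate(config, outdir)),
            ("extract", lambda: stage_extract(config, outdir)),
            ("features", lambda: stage_features(config, outdir)),
        ):
            try:
                fn()
            except Exception:
                log.exception("stage %s failed", stage_name)
                raise
        try:
            cutpoint = stage_duration(config, outdir)
        except Exception:
            log.exception("stage duration failed")
            raise
        try:
            stage_fracture(config, outdir, cutpoint)
        except Exception:
            log.exception("stage fracture failed")
            raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return {p.name: p for p in sorted(outdir.iterdir())}
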