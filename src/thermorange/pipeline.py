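"""End-to-end orchestration of the invasion-risk analysis.

A single YAML config drives the stages: the species-level suitability map,
the intraspecific trait-ensemble map, niche-dynamics statistics and forecast
evaluation.  Every run writes a manifest recording the config hash, seeds and
output checksums, so identical configs reproduce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, io, niche_metrics, sensitivity, suitability, synthetic_data
from .landscape import Landscape

__all__ = ["RunConfig", "run"]

log = logging.getLogger("thermorange")

MODES = ("species", "intraspecific", "niche", "evaluate", "all")


@dataclass
class RunConfig:
    out_dir: str
    mode: str = "species"
    seed: int = 0
    climate_dir: str | None = None
    traits_csv: str | None = None
    occurrences_csv: str | None = None
    #: alternatively build a synthetic demo world
    synthetic: dict | None = None
    species: str | None = None
    omission_rate: float = 0.05
    tss_min: float = 0.3
    importance_min: float = 0.05
    intraspecific_n: int = sensitivity.INTRASPECIFIC_N

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.synthetic is None:
            for path in (self.climate_dir, self.traits_csv):
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"missing input: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps({k: v for k, v in vars(cfg).items()}, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        syn = dict(cfg.synthetic)
        archetype = syn.pop("archetype", "small_finch")
        n_occ = syn.pop("n_occurrences", 150)
        scfg = synthetic_data.SyntheticConfig(seed=cfg.seed, **syn)
        land = synthetic_data.generate_landscape(scfg)
        traits = synthetic_data.generate_species(archetype, seed=cfg.seed)
        truth = synthetic_data.truth_suitability(traits, land.climate)
        occ = synthetic_data.sample_occurrences(truth, n_occ, seed=cfg.seed, species=archetype)
        # a "native" subtropical subset: the warm end of the suitable climate
        import dataclasses as _dc

        warm_cut = np.quantile(truth.coldest_tmin_c[truth.at_risk], 0.6) if truth.at_risk.any() else 0.0
        native_truth = _dc.replace(truth, at_risk=truth.at_risk & (truth.coldest_tmin_c >= warm_cut))
        if native_truth.at_risk.any():
            nat = synthetic_data.sample_occurrences(
                native_truth, n_occ, seed=cfg.seed + 1, species=archetype, range_label="native"
            )
            occ = pd.concat([occ, nat], ignore_index=True)
        return land, traits, occ
    land = io.read_landscape(cfg.climate_dir)
    traits = io.read_traits(cfg.traits_csv)
    occ = io.read_occurrences(cfg.occurrences_csv) if cfg.occurrences_csv else None
    return land, traits, occ


def _climate_matrix(land: Landscape) -> np.ndarray:
    """Per-cell climate feature matrix for environmental-space analyses."""
    c = land.climate
    feats = [c.tmin_c.reshape(12, -1).T, c.tmax_c.reshape(12, -1).T,
             c.wind_ms.mean(axis=0).reshape(-1, 1), c.cloud_frac.mean(axis=0).reshape(-1, 1)]
    return np.hstack(feats)


def _write_map(out: Path, name: str, land: Landscape, smap: suitability.SuitabilityMap) -> list[Path]:
    clim = land.climate
    xll, yll, cs = io._grid_geometry(clim.lat, clim.lon)
    p1 = out / f"{name}_at_risk.asc"
    p2 = out / f"{name}_max_multiple.asc"
    io.write_ascii_grid(p1, smap.at_risk.astype(float), xll, yll, cs)
    io.write_ascii_grid(p2, smap.max_monthly_multiple, xll, yll, cs)
    return [p1, p2]


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "mode": config.mode,
        "stages": {},
        "outputs": {},
    }
    land, traits, occ = _load_inputs(config)
    species = config.species or traits.name
    artifacts: list[Path] = []
    do = lambda stage: config.mode in (stage, "all")  # noqa: E731

    env = suitability.precompute_environment(land, traits.animal_height_m)
    smap = None

    if do("species") or do("evaluate"):
        t0 = time.time()
        smap = suitability.map_species(traits, land, env=env)
        artifacts += _write_map(out, f"{species}_species", land, smap)
        frac = float(smap.at_risk.mean())
        summary = pd.DataFrame([{
            "species": species, "sex": traits.sex,
            "cells_at_risk": int(smap.at_risk.sum()), "fraction_at_risk": frac,
        }])
        p = out / f"{species}_summary.csv"
        summary.to_csv(p, index=False)
        artifacts.append(p)
        manifest["stages"]["species"] = {"seconds": round(time.time() - t0, 2), "fraction_at_risk": frac}
        log.info("species map: %.1f%% of cells at risk", 100 * frac)

    if do("intraspecific"):
        t0 = time.time()
        ranges = {k: v for k, v in sensitivity.default_ranges(traits).items()
                  if k in sensitivity.INTRASPECIFIC_PARAMETERS}
        design = sensitivity.lhs_sample(ranges, n=config.intraspecific_n, seed=config.seed)
        imap, minmult = sensitivity.intraspecific_map(design, land, traits, env=env)
        artifacts += _write_map(out, f"{species}_intraspecific", land, imap)
        manifest["stages"]["intraspecific"] = {
            "seconds": round(time.time() - t0, 2),
            "fraction_at_risk": float(imap.at_risk.mean()),
            "n_variants": design.n,
        }

    if do("niche") and occ is not None and {"native", "invasive"} <= set(occ["range"].unique()):
        t0 = time.time()
        feats = _climate_matrix(land)
        scores_bg, pca = niche_metrics.env_pca(feats)
        nat = occ[occ["range"] == "native"]
        inv = occ[occ["range"] == "invasive"]
        cells_nat = synthetic_data.occurrence_cells(nat, land.climate.lat, land.climate.lon)
        cells_inv = synthetic_data.occurrence_cells(inv, land.climate.lat, land.climate.lon)
        g_nat = niche_metrics.density_grid(scores_bg, scores_bg[cells_nat])
        g_inv = niche_metrics.density_grid(scores_bg, scores_bg[cells_inv])
        esu = niche_metrics.niche_esu(g_nat, g_inv)
        eq = niche_metrics.niche_randomization_test(
            scores_bg[cells_nat], scores_bg[cells_inv], scores_bg, scores_bg,
            mode="equivalency", seed=config.seed, resolution=50,
        )
        sim = niche_metrics.niche_randomization_test(
            scores_bg[cells_nat], scores_bg[cells_inv], scores_bg, scores_bg,
            mode="similarity", seed=config.seed, resolution=50,
        )
        tr_idx = niche_metrics.pnti(g_inv.z, g_inv.z_env)
        p = out / f"{species}_niche_metrics.csv"
        pd.DataFrame([{
            "species": species, "expansion": esu.expansion, "stability": esu.stability,
            "unfilling": esu.unfilling, "D": eq.d_observed,
            "p_equiv": eq.p_value, "p_simil": sim.p_value, "pnti": tr_idx,
        }]).to_csv(p, index=False)
        artifacts.append(p)
        manifest["stages"]["niche"] = {"seconds": round(time.time() - t0, 2),
                                       "expansion": esu.expansion, "unfilling": esu.unfilling}

    if do("evaluate") and occ is not None:
        t0 = time.time()
        inv = occ[occ["range"] == "invasive"] if "range" in occ else occ
        thin = evaluation.thin_occurrences(inv, min_km=50.0, seed=config.seed)
        if len(thin) < evaluation.__dict__.get("MIN_EVAL_POINTS", 5):
            thin = evaluation.thin_occurrences(inv, min_km=10.0, seed=config.seed)
        cells = synthetic_data.occurrence_cells(thin, land.climate.lat, land.climate.lon)
        pred = smap.at_risk.ravel()
        labels = np.zeros(land.n_cells, dtype=bool)
        labels[cells] = True
        res = evaluation.confusion_metrics(pred, labels) if labels.any() and not labels.all() else None
        score_surface = -smap.max_monthly_multiple.ravel()
        auc_ratio, p_val = evaluation.partial_roc(
            score_surface, score_surface[cells], e_rate=config.omission_rate,
            iterations=1000, seed=config.seed,
        )
        p = out / f"{species}_evaluation.csv"
        pd.DataFrame([{
            "species": species,
            "n_thinned": len(thin),
            "sensitivity": res.sensitivity if res else np.nan,
            "specificity": res.specificity if res else np.nan,
            "tss": res.tss if res else np.nan,
            "auc_ratio": auc_ratio, "p_value": p_val,
            "omission_rate": config.omission_rate,
        }]).to_csv(p, index=False)
        artifacts.append(p)
        manifest["stages"]["evaluate"] = {"seconds": round(time.time() - t0, 2),
                                          "tss": res.tss if res else None}

    for path in artifacts:
        manifest["outputs"][path.name] = _checksum(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
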