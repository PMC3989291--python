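"""End-to-end pipeline: configuration, orchestration, run manifest.

A single YAML file configures every stage — domain building, wind
synthesis (or ingestion), regime classification, circulation, dispersal
runs over the scenario factor grid, connectivity matrices and the
variance decomposition. ``run_pipeline`` executes the stages in order,
writes per-stage outputs under the configured directory, and records a
manifest (inputs, seeds, output checksums) so a rerun with the same
configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Invalid pipeline configuration; lists every violation."""


_DEFAULTS = {
    "seed": 0,
    "output_dir": "runs/out",
    "domain": {
        "area_km2": 142.0, "mean_depth_m": 41.0, "max_depth_m": 70.0,
        "n_sigma": 8, "dx_m": 500.0, "k_sectors": 12,
    },
    "wind": {
        "source": "synthetic", "path": None,
        "start": "1999-01-01", "end": "2008-12-31",
        "persistence_days": 10.0,
    },
    "regimes": {
        "k": 12, "window_days": 30, "overlap_days": 20, "variance_kept": 0.95,
        "method": "pam",
    },
    "circulation": {
        "gyre_peak_speed": 0.05, "south_cell_factor": 0.5,
        "shear_fraction": 0.5, "exchange_m3s": 270.0,
    },
    "transport": {
        "dt_hours": 3.0, "kh": 1.0, "kz": 1e-3, "alpha": 1e-3,
    },
    "scenarios": ["potential"],
    "release_levels": ["longline", "bottom"],
    "swim": [True, False],
    "pld_days": [15, 20, 25, 30],
    "reared_density_per_ha": 12000.0,
    "anova": True,
}


@dataclass
class PipelineConfig:
    """Normalized pipeline configuration (defaults filled, validated)."""

    raw: dict = dc_field(default_factory=dict)

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)


def _merge(defaults, override):
    out = dict(defaults)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(path_or_dict) -> PipelineConfig:
    """Load, default-fill and cross-validate a pipeline configuration.

    Every violation is collected and reported in a single
    :class:`ConfigError`.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = _merge(_DEFAULTS, user)
    errors = []
    d = cfg["domain"]
    if not 0 < d["mean_depth_m"] < d["max_depth_m"]:
        errors.append("domain: need 0 < mean_depth_m < max_depth_m")
    if d["n_sigma"] < 3:
        errors.append("domain: n_sigma must be >= 3")
    r = cfg["regimes"]
    if r["overlap_days"] >= r["window_days"]:
        errors.append("regimes: overlap_days must be < window_days")
    w = cfg["wind"]
    if w["source"] not in ("synthetic", "csv"):
        errors.append(f"wind: unknown source {w['source']!r}")
    if w["source"] == "csv":
        if not w.get("path"):
            errors.append("wind: csv source requires a path")
        elif not Path(w["path"]).exists():
            errors.append(f"wind: file not found: {w['path']}")
    if not cfg["pld_days"]:
        errors.append("pld_days must not be empty")
    elif max(cfg["pld_days"]) * 1.0 > r["window_days"]:
        errors.append("pld_days: longest PLD exceeds the flow horizon "
                      f"({r['window_days']} d wind sequences)")
    if not isinstance(cfg["seed"], int):
        errors.append("seed must be an explicit integer")
    for sc in cfg["scenarios"]:
        if sc not in ("potential", "natural", "reared"):
            errors.append(f"unknown scenario {sc!r}")
    if errors:
        raise ConfigError("; ".join(errors))
    return PipelineConfig(raw=cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | dict | str, progress=None) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stages: domain -> wind -> regimes -> circulation -> dispersal
    (one run per wind regime x release level x swim flag) ->
    connectivity matrices -> variance decomposition. Outputs and a
    ``manifest.json`` land under the configured output directory.
    """
    from lagoonconnect import domain as dm
    from lagoonconnect import wind as wi
    from lagoonconnect.regimes import WindRegimeClassifier
    from lagoonconnect.circulation import CirculationModel, CirculationParams, flow_for_sequence
    from lagoonconnect.transport import ReleaseSpec, SwimmingParams, run_dispersal
    from lagoonconnect.connectivity import potential_connectivity, realistic_connectivity
    from lagoonconnect.variance import ConnectivityAnova, assemble_scenario_grid
    from lagoonconnect.datasets import ahe_regime_specs

    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    cfg = config.raw
    log = progress or (lambda msg: None)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"config": cfg, "seeds": {}, "outputs": {}}

    # -- domain ----------------------------------------------------------
    log("building domain")
    d = cfg["domain"]
    grid = dm.build_idealized_lagoon(
        area_km2=d["area_km2"], mean_depth_m=d["mean_depth_m"],
        max_depth_m=d["max_depth_m"], n_sigma=d["n_sigma"], dx_m=d["dx_m"])
    sectors = dm.partition_sectors(grid, k=d["k_sectors"], seed=seed)
    manifest["seeds"]["sectors"] = seed
    dm.grid_to_netcdf(grid, out / "domain.nc", sectors)

    nat = dm.natural_stock(grid)
    conc_mask = dm.synthetic_concessions(grid, sectors, seed=seed + 1)
    manifest["seeds"]["concessions"] = seed + 1
    rea = dm.reared_stock(grid, conc_mask, cfg["reared_density_per_ha"])
    w_nat = dm.stock_by_sector(nat, sectors)
    w_rea = dm.stock_by_sector(rea, sectors)
    stock_df = w_rea.rename("reared").to_frame()
    stock_df["natural"] = w_nat
    stock_df.to_csv(out / "stock.csv")

    # -- wind ------------------------------------------------------------
    log("wind series")
    w = cfg["wind"]
    if w["source"] == "csv":
        series = wi.read_wind_csv(w["path"])
    else:
        series = wi.generate_wind_series(w["start"], w["end"], ahe_regime_specs(),
                                         persistence_days=w["persistence_days"],
                                         seed=seed + 2)
        manifest["seeds"]["wind"] = seed + 2
    wi.write_wind_csv(series, out / "wind.csv")

    # -- regimes ---------------------------------------------------------
    log("classifying wind regimes")
    r = cfg["regimes"]
    res = WindRegimeClassifier(series, window_days=r["window_days"],
                               overlap_days=r["overlap_days"], k=r["k"],
                               variance_kept=r["variance_kept"],
                               method=r["method"], seed=seed + 3).fit()
    manifest["seeds"]["regimes"] = seed + 3
    res.to_csv(out / "regimes.csv")

    # -- circulation + dispersal over the factor grid --------------------
    c = cfg["circulation"]
    circ = CirculationModel(grid, CirculationParams(
        gyre_peak_speed=c["gyre_peak_speed"], south_cell_factor=c["south_cell_factor"],
        shear_fraction=c["shear_fraction"], exchange_m3s=c["exchange_m3s"]))
    t = cfg["transport"]
    plds = sorted(cfg["pld_days"])
    bands = {"longline": (5.0, 10.0), "bottom": dm.BOTTOM}
    matrices = {}
    for regime in res.regimes:
        flow = flow_for_sequence(grid, regime.reference, model=circ)
        for rl in cfg["release_levels"]:
            for sw in cfg["swim"]:
                log(f"dispersal: regime {regime.regime_id}, release {rl}, swim {sw}")
                spec = ReleaseSpec(scenario="potential", band=bands[rl])
                swim = SwimmingParams(alpha=t["alpha"], enabled=bool(sw))
                snaps = run_dispersal(grid, sectors, flow, spec, swim,
                                      pld_days=plds, dt=t["dt_hours"] * 3600.0,
                                      kh=t["kh"], kz=t["kz"])
                for day, snap in snaps.items():
                    M = potential_connectivity(snap, sectors, meta={
                        "regime": regime.regime_id, "release": rl,
                        "swim": bool(sw), "pld": day})
                    matrices[(rl, sw, regime.regime_id, day)] = M
                    M.to_csv(out / f"P_r{regime.regime_id}_{rl}_swim{int(sw)}_d{day}.csv")

    # realistic connectivity from the spawner weights; each stock uses the
    # release level matching its emission depth when that level was run
    levels = cfg["release_levels"]
    rl_for = {"natural": "bottom" if "bottom" in levels else levels[0],
              "reared": "longline" if "longline" in levels else levels[0]}
    for (rl, sw, rid, day), M in list(matrices.items()):
        if "natural" in cfg["scenarios"] and rl == rl_for["natural"]:
            realistic_connectivity(M, w_nat).to_csv(
                out / f"L_natural_r{rid}_swim{int(sw)}_d{day}.csv")
        if "reared" in cfg["scenarios"] and rl == rl_for["reared"]:
            realistic_connectivity(M, w_rea).to_csv(
                out / f"L_reared_r{rid}_swim{int(sw)}_d{day}.csv")

    # -- variance decomposition ------------------------------------------
    if cfg["anova"] and len(matrices) > 1:
        log("variance decomposition")
        long = assemble_scenario_grid(matrices)
        terms = ["RL", "Swim", "WR", "PLD", "S", "D"]
        # drop single-level factors (e.g. one regime in a smoke run)
        terms = [f for f in terms if long[f].nunique() > 1] + (
            ["S:D"] if long["S"].nunique() > 1 and long["D"].nunique() > 1 else [])
        anova = ConnectivityAnova(long, response_kind="potential", terms=terms).fit()
        anova.to_csv(out / "anova_potential.csv")

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
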