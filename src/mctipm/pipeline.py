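"""End-to-end driver: generate -> fit -> kernels -> coexistence -> decomposition.

Every stage is reproducible from the :class:`~mctipm.config.PipelineConfig`
seeds alone; the written report bundle includes a provenance manifest with
the config hash, seeds and package versions.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .coexistence import analyze_temperature, propagate_uncertainty, simulate_competition
from .decomposition import decompose
from .design import generate_design
from .ipm import MeshConfig
from .simulate import (
    simulate_experiment,
    write_census_csv,
    write_records_csv,
    write_samples_csv,
)
from .standardize import DEFAULT_TEMPERATURE_SCALE
from .truth import TrueParameters, default_truth
from .vital_rates import (
    InferenceConfig,
    fit_all_rates,
    fit_genotype_frequencies,
    prepare_records,
    save_models,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _frequency_samples(samples: pd.DataFrame, design, scale) -> pd.DataFrame:
    """Restrict genotype samples to inter-latitudinal aquaria, add temperature."""
    info = {a.id: a for a in design.aquaria}
    mixed = {a.id for a in design.aquaria if a.is_interlatitudinal}
    out = samples[samples["aquarium"].isin(mixed)].copy()
    out["temperature_std"] = scale.to_std(
        out["aquarium"].map(lambda a: info[a].temperature_c))
    return out


def run_pipeline(config: PipelineConfig, out_dir,
                 truth: TrueParameters | None = None) -> dict:
    """Execute the full pipeline; returns the report dict written to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scale = DEFAULT_TEMPERATURE_SCALE
    mesh = MeshConfig(n_classes=config.mesh_classes,
                      z_min=config.z_range[0], z_max=config.z_range[1])
    truth = truth or default_truth()

    stage = "generate"
    try:
        design = generate_design(
            config.n_ponds_per_latitude, config.n_genotypes_per_pond,
            config.mono_temperatures_c, config.competition_temperatures_c,
            seed=config.seeds.design)
        records, census, samples = simulate_experiment(
            design, truth, n_days=config.n_days,
            census_days=config.census_days,
            n_isolated_per_aquarium=config.n_isolated_per_aquarium,
            seed=config.seeds.simulation)
        design.to_json(out / "design.json")
        truth.to_yaml(out / "truth.yaml")
        write_records_csv(records, out / "individuals.csv")
        write_census_csv(census, out / "census.csv")
        write_samples_csv(samples, out / "genotype_samples.csv")

        stage = "fit"
        infer = InferenceConfig(n_draws=config.n_draws,
                                seed=config.seeds.inference)
        freq_model = fit_genotype_frequencies(
            _frequency_samples(samples, design, scale), infer)
        prepared = prepare_records(records, census, design, freq_model, scale)
        models = fit_all_rates(prepared, structure=config.structure,
                               inference=infer)
        save_models(models, out / "models")

        stage = "coexist"
        coex: dict = {"temperatures": {}}
        for tc in config.analysis_temperatures_c:
            T = float(scale.to_std(tc))
            point = analyze_temperature(
                models, T, mesh=mesh, n_grid=config.isocline_grid_points,
                density_grid=config.density_range,
                interval_days=config.interval_days,
                growth_mode=config.growth_mode)
            block = {
                "extrapolated": bool(
                    tc > max(config.mono_temperatures_c)
                    or tc < min(config.mono_temperatures_c)),
                "point": {
                    "classification": point.classification,
                    "rho": _j(point.rho), "k_ratio": _j(point.k_ratio),
                    "p_south": _j(point.p_south),
                    "N_south": _j(point.N_south), "N_north": _j(point.N_north),
                },
            }
            traj = simulate_competition(
                models, T, n_days=config.simulation_days,
                init_per_latitude=config.init_per_latitude, mesh=mesh,
                interval_days=config.interval_days,
                growth_mode=config.growth_mode)
            block["simulation"] = {
                "final_p_south": _j(traj["p_south"].iloc[-1]),
                "final_N_south": _j(traj["N_south"].iloc[-1]),
                "final_N_north": _j(traj["N_north"].iloc[-1]),
            }
            if config.n_draws > 0:
                _, summary = propagate_uncertainty(
                    models, T, n_draws=config.n_draws, mesh=mesh,
                    n_grid=config.isocline_grid_points_draws,
                    density_grid=config.density_range,
                    interval_days=config.interval_days,
                    growth_mode=config.growth_mode)
                block["classification_fractions"] = summary[
                    "classification_fractions"]
                block["quantiles"] = {
                    k: {q: _j(v) for q, v in qs.items()}
                    for k, qs in summary["quantiles"].items()}
            coex["temperatures"][f"{tc:g}"] = block
        with open(out / "coexistence.json", "w") as fh:
            json.dump(coex, fh, indent=1)

        stage = "decompose"
        temps_std = [float(scale.to_std(t))
                     for t in config.analysis_temperatures_c]
        dec = decompose(models, temps_std, n_draws=0, mesh=mesh,
                        n_grid=config.isocline_grid_points_draws,
                        density_grid=config.density_range)
        dec.table.to_csv(out / "decomposition.csv", index=False)

        stage = "manifest"
        manifest = {
            "config_hash": config.content_hash(),
            "seeds": config.seeds.__dict__,
            "versions": {"mctipm": __version__,
                         "numpy": np.__version__,
                         "pandas": pd.__version__,
                         "python": platform.python_version()},
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        config.to_yaml(out / "config.yaml")
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(stage, str(err)) from err
    return {"manifest": manifest, "coexistence": coex}


def _j(x) -> float | None:
    """JSON-safe float (NaN/inf -> None)."""
    x = float(x)
    return x if np.isfinite(x) else None
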