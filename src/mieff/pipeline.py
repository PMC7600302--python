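"""End-to-end orchestration: simulate -> preprocess -> indicators ->
response -> regression -> clustering, with persisted intermediates.

Every stage reads its inputs from and writes its outputs to the run
directory, so stages can be re-run independently; a JSON manifest
records the configuration and seeds for full reproducibility.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import CONFIG_2CH, CONFIG_6CH, ChannelConfig, default_montage
from .preprocess import laplacian
from .indicators import compute_xi1, compute_xi2
from .response import DELTA_TAUS, accuracy_response
from .drn import (DeepRegressionNetwork, SubjectData, build_inputs, evaluate,
                  linear_baseline, loo_evaluate, psi_map)
from .clustering import cluster_subjects, flag_outliers
from .io import load_cohort, save_cohort
from .synth import make_cohort, simulate_resting, simulate_trial_set

__all__ = ["RunConfig", "run_pipeline", "stage_simulate", "stage_indicators",
           "stage_response", "stage_regress", "stage_cluster"]

_CONFIGS = {"2Ch": CONFIG_2CH, "6Ch": CONFIG_6CH}


@dataclass
class RunConfig:
    """Configuration of one pipeline run (mirrors the CLI flags)."""

    out_dir: str = "mieff_run"
    seed: int = 0
    # data source: synthetic cohort spec or a pre-built cohort file
    n_subjects: int = 12
    n_trials: int = 20           # per class
    fs: float = 160.0
    cohort_path: str | None = None
    # analysis
    channel_configs: tuple[str, ...] = ("2Ch", "6Ch")
    bands: tuple[str, ...] = ("mu", "beta")
    delta_taus: tuple[float, ...] = DELTA_TAUS
    cv_repeats: int = 10
    cv_folds: int = 10
    # regression
    sources: tuple[str, ...] = ("baseline", "resting", "erds")
    psi_modes: tuple[str, ...] = ("mean", "pca1")
    epochs: int = 1000
    run_loo: bool = False

    def validate(self) -> None:
        montage = default_montage()
        for name in self.channel_configs:
            if name not in _CONFIGS:
                raise ValueError(f"unknown channel config {name!r}")
            missing = set(_CONFIGS[name].channels) - set(montage.labels)
            if missing:
                raise ValueError(f"montage is missing channels {missing}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("channel_configs", "bands", "delta_taus", "sources", "psi_modes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _outdir(config: RunConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _write_manifest(config: RunConfig, out: Path) -> None:
    manifest = {
        "config": dataclasses.asdict(config),
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _load_or_simulate(config: RunConfig, out: Path):
    cohort_file = Path(config.cohort_path) if config.cohort_path else out / "cohort.h5"
    if not cohort_file.exists():
        stage_simulate(config)
    return load_cohort(cohort_file)


def _preprocessed(trial_sets):
    """Laplacian over the full montage; band-pass is applied per stage."""
    return [laplacian(ts) for ts in trial_sets]


def stage_simulate(config: RunConfig) -> Path:
    """Generate the synthetic cohort and persist it."""
    out = _outdir(config)
    profiles = make_cohort(config.n_subjects, config.seed)
    trial_sets = [simulate_trial_set(p, config.n_trials, config.fs) for p in profiles]
    restings = [simulate_resting(p, config.fs) for p in profiles]
    path = out / "cohort.h5"
    save_cohort(path, trial_sets, restings, profiles,
                config=dataclasses.asdict(config))
    return path


def stage_indicators(config: RunConfig) -> pd.DataFrame:
    """xi1 (both resting scenarios) and xi2 (band combinations) per subject."""
    out = _outdir(config)
    trial_sets, restings, _, _ = _load_or_simulate(config, out)
    trial_sets = _preprocessed(trial_sets)
    restings = [laplacian(r) for r in restings]
    rows = []
    band_combos = {"mu": ("mu",), "beta": ("beta",), "mu+beta": ("mu", "beta")}
    for m, (ts, rest) in enumerate(zip(trial_sets, restings)):
        for name in config.channel_configs:
            cc = _CONFIGS[name]
            for scenario, data in (("baseline", ts), ("resting", rest)):
                r1 = compute_xi1(data, cc, scenario=scenario, seed=config.seed)
                rows.append({"subject": m, "indicator": "xi1", "scenario": scenario,
                             "config": name, "band": "", "value": r1.value})
            for combo, bands in band_combos.items():
                r2 = compute_xi2(ts, cc, bands)
                rows.append({"subject": m, "indicator": "xi2", "scenario": "training",
                             "config": name, "band": combo, "value": r2.value})
    table = pd.DataFrame(rows)
    table.to_csv(out / "indicators.csv", index=False)
    return table


def stage_response(config: RunConfig) -> pd.DataFrame:
    """Sliding-window CSP/LDA accuracy per subject and window length."""
    out = _outdir(config)
    trial_sets, _, _, _ = _load_or_simulate(config, out)
    trial_sets = _preprocessed(trial_sets)
    rows = []
    curve_rows = []
    for m, ts in enumerate(trial_sets):
        for name in config.channel_configs:
            cc = _CONFIGS[name]
            resp = accuracy_response(ts, cc, config.delta_taus,
                                     cv=(config.cv_repeats, config.cv_folds),
                                     seed=config.seed)
            for dt in config.delta_taus:
                rows.append({"subject": m, "config": name, "delta_tau": dt,
                             "accuracy": resp.max_accuracy[dt],
                             "mean_accuracy": resp.mean_accuracy[dt],
                             "dispersion": resp.dispersion[dt]})
                for start, acc in zip(resp.window_starts[dt], resp.curves[dt]):
                    curve_rows.append({"subject": m, "config": name, "delta_tau": dt,
                                       "window_start": start, "accuracy": acc})
    table = pd.DataFrame(rows)
    table.to_csv(out / "response.csv", index=False)
    pd.DataFrame(curve_rows).to_csv(out / "response_curves.csv", index=False)
    return table


def _targets_table(resp: pd.DataFrame, name: str, delta_taus, psi_modes):
    sub = resp[resp["config"] == name].pivot(index="subject", columns="delta_tau",
                                             values="accuracy")
    V = sub[list(delta_taus)].to_numpy()
    targets = {f"{dt}": V[:, i] for i, dt in enumerate(delta_taus)}
    for mode in psi_modes:
        targets[mode] = psi_map(V, mode)
    return V, targets


def stage_regress(config: RunConfig) -> pd.DataFrame:
    """LC, scalar-network and full-network regression tables."""
    out = _outdir(config)
    trial_sets, restings, _, _ = _load_or_simulate(config, out)
    trial_sets = _preprocessed(trial_sets)
    restings = [laplacian(r) for r in restings]
    resp = pd.read_csv(out / "response.csv") if (out / "response.csv").exists() \
        else stage_response(config)
    ind = pd.read_csv(out / "indicators.csv") if (out / "indicators.csv").exists() \
        else stage_indicators(config)
    scenario_of = {"baseline": "baseline", "resting": "resting", "erds": "training"}
    rows = []
    for name in config.channel_configs:
        cc = _CONFIGS[name]
        V, targets = _targets_table(resp, name, config.delta_taus, config.psi_modes)
        for source in config.sources:
            # scalar indicator for this source: xi1 for resting data, xi2 for erds
            ind_name = "xi2" if source == "erds" else "xi1"
            mask = ((ind["indicator"] == ind_name) & (ind["config"] == name)
                    & (ind["scenario"] == scenario_of[source]))
            if ind_name == "xi2":
                mask &= ind["band"] == "mu+beta"
            scalar = ind[mask].sort_values("subject")["value"].to_numpy()
            stacks = np.stack([
                build_inputs(SubjectData(ts, rest), source, cc, config.bands)
                for ts, rest in zip(trial_sets, restings)
            ])
            for label, vec in targets.items():
                lc = linear_baseline(scalar, vec)
                rows.append({"source": source, "config": name, "estimator": "LC",
                             "target": label, "spearman_r": lc.r})
                sres = DeepRegressionNetwork(scalar, vec).fit(
                    epochs=config.epochs, seed=config.seed)
                rows.append({"source": source, "config": name,
                             "estimator": "DRN_scalar", "target": label,
                             "spearman_r": sres.spearman()})
                fres = DeepRegressionNetwork(stacks, vec).fit(
                    epochs=config.epochs, seed=config.seed)
                rows.append({"source": source, "config": name, "estimator": "DRN",
                             "target": label, "spearman_r": fres.spearman()})
                if config.run_loo:
                    loo = loo_evaluate(stacks, vec, epochs=config.epochs,
                                       seed=config.seed)
                    rows.append({"source": source, "config": name,
                                 "estimator": "DRN_LOO", "target": label,
                                 "spearman_r": loo.r})
    table = pd.DataFrame(rows)
    table.to_csv(out / "regression.csv", index=False)
    return table


def stage_cluster(config: RunConfig) -> pd.DataFrame:
    """Efficiency groups from the accuracy profiles (per channel config)."""
    out = _outdir(config)
    resp = pd.read_csv(out / "response.csv") if (out / "response.csv").exists() \
        else stage_response(config)
    frames = []
    for name in config.channel_configs:
        V, _ = _targets_table(resp, name, config.delta_taus, ())
        k_max = min(6, V.shape[0] - 1)
        result = cluster_subjects(V, range(2, k_max + 1), seed=config.seed,
                                  provenance=name)
        frames.append(result.to_frame(run=name))
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(out / "clusters.csv", index=False)
    return table


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute every stage in order and write the run manifest."""
    config.validate()
    out = _outdir(config)
    stage_simulate(config)
    tables = {
        "indicators": stage_indicators(config),
        "response": stage_response(config),
        "regression": stage_regress(config),
        "clusters": stage_cluster(config),
    }
    _write_manifest(config, out)
    return tables
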