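"""Scripted experiment presets and the report machinery behind the CLI.

Each preset regenerates one of the desk-scale studies: manifold recovery and
sensitivity for the 2-D models, error-versus-sample-size trends, the
exponential-pair and Hartmann multifidelity comparisons.  A config plus a
seed fully determines every number in the report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .models import Dataset, get_model, make_dataset
from .multifidelity import neuram_mf_study
from .sensitivity import global_indices, sensitivity_profile, sobol_first_order
from .train import (NetworkArchitecture, TrainingConfig, evaluation_errors,
                    train_neuram)

__all__ = ["ExperimentConfig", "PRESETS", "run_experiment"]


@dataclass
class ExperimentConfig:
    experiment: str
    models: list[str] = field(default_factory=list)
    n_train: int = 1000
    n_test: int = 1000
    hidden_layers: int = 2
    neurons_per_layer: int = 8
    epochs: int = 10000
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    restarts: int = 3
    budget: float = 1000.0
    cost_ratio: float = 0.01
    n_pilot: int = 1000
    repetitions: int = 100
    n_grid: int = 1024
    n_list: list[int] = field(default_factory=lambda: [10, 100, 1000])
    seed: int = 0
    out_dir: str | None = None

    def arch(self) -> NetworkArchitecture:
        return NetworkArchitecture(self.hidden_layers, self.neurons_per_layer)

    def training(self, seed: int) -> TrainingConfig:
        return TrainingConfig(epochs=self.epochs, learning_rate=self.learning_rate,
                              validation_fraction=self.validation_fraction,
                              seed=seed, restarts=self.restarts)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text)
        return cls(**data)


def _seed_for(config: ExperimentConfig, *tags) -> int:
    # crc32 keeps tag hashing stable across processes (str hash is salted)
    import zlib

    keys = [zlib.crc32(str(t).encode()) for t in tags]
    ss = np.random.SeedSequence([config.seed] + keys)
    return int(ss.generate_state(1)[0] % 2**31)


def _train_one(config, model_name, seed, out_dir=None, tag=""):
    spec, dist = get_model(model_name)
    data = make_dataset(spec, dist, config.n_train, seed=seed)
    nam = train_neuram(data, config.arch(), config.training(seed))
    if out_dir is not None:
        nio.save_neuram(nam, Path(out_dir) / f"neuram_{model_name}{tag}.json")
        np.savetxt(Path(out_dir) / f"loss_{model_name}{tag}.csv",
                   np.column_stack([nam.history["loss"],
                                    nam.history["loss_terms"]]),
                   delimiter=",", header="total,L1,L2,L3", comments="")
    return spec, dist, nam


def _exp_sensitivity(config: ExperimentConfig, model_name: str, out_dir):
    spec, dist, nam = _train_one(config, model_name,
                                 _seed_for(config, "sens", model_name), out_dir)
    prof = sensitivity_profile(nam, config.n_grid)
    sob = sobol_first_order(spec, dist, n=1024, seed=_seed_for(config, "sobol"))
    return {
        "model": model_name,
        "Theta": prof.global_idx.tolist(),
        "Theta_sum": float(prof.global_idx.sum()),
        "sobol_first_order": sob.tolist(),
        "latent_interval": list(nam.latent_interval),
    }


def _exp_mf(config: ExperimentConfig, hf_name: str, lf_name: str, out_dir):
    hf_spec, dist = get_model(hf_name)
    lf_spec, _ = get_model(lf_name)
    res = neuram_mf_study(hf_spec, lf_spec, dist, budget=config.budget,
                          w=config.cost_ratio, n_pilot=config.n_pilot,
                          repetitions=config.repetitions,
                          seed=_seed_for(config, "mf", hf_name, lf_name),
                          arch=config.arch(),
                          config=config.training(config.seed))
    if out_dir is not None:
        nio.save_neuram(res.neuram_HF, Path(out_dir) / f"neuram_{hf_name}_hf.json")
        nio.save_neuram(res.neuram_LF, Path(out_dir) / f"neuram_{lf_name}_lf.json")
    return {
        "hf": hf_name, "lf": lf_name,
        "rho_original": res.rho_original,
        "rho_neuram": res.rho_neuram,
        "rho_ideal": res.rho_ideal,
        "q_standard": res.q_standard.tolist(),
        "q_neuram": res.q_neuram.tolist(),
        "q_mc": res.q_mc.tolist(),
        "plan_standard": asdict(res.plan_standard),
        "plan_neuram": asdict(res.plan_neuram),
        "var_standard": float(np.var(res.q_standard, ddof=1)),
        "var_neuram": float(np.var(res.q_neuram, ddof=1)),
        "var_mc": float(np.var(res.q_mc, ddof=1)),
    }


def _run_parabolic_sensitivity(config, out_dir):
    from .models import analytic_parabolic_neuram

    triple = analytic_parabolic_neuram()
    Th = global_indices(triple, max(config.n_grid, 4096))
    out = {"analytic_Theta": Th.tolist(), "analytic_Theta_sum": float(Th.sum())}
    out["trained"] = _exp_sensitivity(config, "parabolic", out_dir)
    return out


def _run_two_d_models(config, out_dir):
    out = {}
    for name in (config.models or ["q1", "q2", "q3"]):
        spec, dist, nam = _train_one(config, name, _seed_for(config, "2d", name),
                                     out_dir)
        test = make_dataset(spec, dist, config.n_test,
                            seed=_seed_for(config, "test", name))
        out[name] = evaluation_errors(spec, nam, test)
    return out


def _run_error_vs_n(config, out_dir):
    spec, dist = get_model("sine_parabolic")
    reps = max(1, config.repetitions)
    table = {}
    for n in config.n_list:
        maes = {"e1": [], "e2": []}
        for r in range(reps):
            data = make_dataset(spec, dist, n, seed=_seed_for(config, "evn", n, r))
            nam = train_neuram(data, config.arch(),
                               config.training(_seed_for(config, "evn-t", n, r)))
            test = make_dataset(spec, dist, config.n_test,
                                seed=_seed_for(config, "evn-test", n, r))
            err = evaluation_errors(spec, nam, test)
            maes["e1"].append(err["e1"]["mae"])
            maes["e2"].append(err["e2"]["mae"])
        table[str(n)] = {k: {"median": float(np.median(v)), "all": v}
                         for k, v in maes.items()}
    return table


PRESETS = {
    "parabolic_sensitivity": lambda c, d: _run_parabolic_sensitivity(c, d),
    "two_d_models": lambda c, d: _run_two_d_models(c, d),
    "exp_pair_mf": lambda c, d: _exp_mf(c, "hf_exp", "lf_exp", d),
    "hartmann_mf": lambda c, d: _exp_mf(c, "hartmann_u", "hartmann_b", d),
    "hartmann_sensitivity": lambda c, d: _exp_sensitivity(c, "hartmann_u", d),
    "error_vs_N": lambda c, d: _run_error_vs_n(c, d),
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Run a preset end to end; writes report.json (and artifacts) if
    `config.out_dir` is set, and returns the report."""
    if config.experiment not in PRESETS:
        raise KeyError(f"unknown experiment '{config.experiment}'; "
                       f"known: {', '.join(PRESETS)}")
    out_dir = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    try:
        results = PRESETS[config.experiment](config, out_dir)
    except Exception as exc:
        raise RuntimeError(
            f"experiment '{config.experiment}' failed in stage "
            f"{type(exc).__name__}: {exc}") from exc
    report = {
        "experiment": config.experiment,
        "seed": config.seed,
        "model": ",".join(config.models) if config.models else config.experiment,
        "config": asdict(config),
        "results": results,
    }
    nio.validate_report(report)
    if out_dir is not None:
        (out_dir / "report.json").write_text(json.dumps(report, indent=1),
                                             encoding="utf-8")
    return report
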