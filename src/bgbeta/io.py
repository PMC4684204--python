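"""Run configuration, artifact persistence and the protocol runner.

Everything is written as diff-able plain text: trajectories and grids as
CSV (9 significant digits, with the resolved configuration embedded in a
``# config:`` header line), metrics as JSON, spike times as newline-
delimited ms values, and the fully resolved configuration as YAML next to
the artifacts so any run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import yaml

from .core_model import ConfigError, Trajectory, lesion_panel, simulate
from .metrics_and_fit import OscillationMetrics, extract_metrics, fit
from .params import ModelParameters, PRESET_NAMES, preset

log = logging.getLogger("bgbeta")

PROTOCOLS = ("simulate", "lesion-panel", "fit", "stability", "delay-scan",
             "spiketrain")

#: keys accepted in a configuration file
_KNOWN_KEYS = {
    "protocol", "preset", "params", "variant", "duration", "step",
    "transient", "record_dt", "seed", "out", "options",
}

_PARAM_KEYS = {
    "w_SG", "w_GS", "w_CS", "w_SC", "w_GG", "w_CC", "C", "Str",
    "T_SG", "T_GS", "T_GG", "T_CS", "T_SC", "T_CC",
    "tau_S", "tau_G", "tau_E", "tau_I",
    "M_S", "B_S", "M_G", "B_G", "M_E", "B_E", "M_I", "B_I",
}


@dataclass
class RunConfig:
    """Validated, fully explicit description of one run."""

    protocol: str = "simulate"
    preset: Optional[str] = "fig3A"
    params: Dict[str, float] = field(default_factory=dict)
    variant: Optional[str] = None
    duration: float = 5000.0
    step: float = 0.05
    transient: float = 1000.0
    record_dt: float = 0.5
    seed: int = 0
    out: Optional[str] = None
    options: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.protocol not in PROTOCOLS:
            raise ConfigError(
                f"unknown protocol {self.protocol!r}; one of {PROTOCOLS}"
            )
        if self.preset is not None and self.preset not in PRESET_NAMES:
            raise ConfigError(
                f"unknown preset {self.preset!r}; one of {PRESET_NAMES}"
            )
        bad = set(self.params) - _PARAM_KEYS
        if bad:
            raise ConfigError(f"unknown parameter keys {sorted(bad)}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def resolve_params(self) -> ModelParameters:
        from .params import ActivationParams

        p = preset(self.preset) if self.preset else preset("fig3A")
        if self.variant:
            p = p.replace(variant=self.variant)
        d = dict(self.params)
        act_over = {}
        for pop in ("E", "I", "S", "G"):
            M, B = d.pop(f"M_{pop}", None), d.pop(f"B_{pop}", None)
            if M is not None or B is not None:
                cur = getattr(p, f"act_{pop}")
                act_over[f"act_{pop}"] = ActivationParams(
                    M if M is not None else cur.M,
                    B if B is not None else cur.B,
                )
        return p.replace(**d, **act_over)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# -- writers ------------------------------------------------------------

def _config_line(config: RunConfig) -> str:
    return "# config: " + json.dumps(config.to_dict(), sort_keys=True)


def write_trajectory_csv(path: Path, traj: Trajectory,
                         config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_config_line(config) + "\n")
        fh.write("time_ms,S,G,E,I\n")
        for row in zip(traj.times, traj.S, traj.G, traj.E, traj.I):
            fh.write(",".join(f"{v:.9g}" for v in row) + "\n")


def read_trajectory_csv(path: Path):
    import pandas as pd

    return pd.read_csv(path, comment="#")


def _metrics_dict(m: OscillationMetrics) -> dict:
    return {
        "stn": dataclasses.asdict(m.stn),
        "gpe": dataclasses.asdict(m.gpe),
        "frequency_hz": m.frequency,
        "frequency_fft_hz": m.frequency_fft,
        "is_oscillating": m.is_oscillating,
    }


def write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"config": config.to_dict(), **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_config_echo(outdir: Path, config: RunConfig) -> None:
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


# -- protocol runner ----------------------------------------------------

def run(config: RunConfig) -> Path:
    """Execute one protocol and write its artifacts; returns the output
    directory."""
    outdir = Path(config.out or "bgbeta_out")
    outdir.mkdir(parents=True, exist_ok=True)
    write_config_echo(outdir, config)
    sim_kw = dict(duration=config.duration, step=config.step,
                  transient=config.transient, record_dt=config.record_dt)

    if config.protocol == "simulate":
        traj = simulate(config.resolve_params(), **sim_kw)
        write_trajectory_csv(outdir / "trajectory.csv", traj, config)
        m = extract_metrics(traj)
        log.info("intact: %s", _metrics_dict(m))
        write_json(outdir / "metrics.json", {"intact": _metrics_dict(m)},
                   config)

    elif config.protocol == "lesion-panel":
        panel = lesion_panel(config.resolve_params(), **sim_kw)
        metrics = {}
        for name, traj in panel.items():
            write_trajectory_csv(outdir / f"trajectory_{name}.csv", traj,
                                 config)
            metrics[name] = _metrics_dict(extract_metrics(traj))
            log.info("%s: %s", name, metrics[name])
        write_json(outdir / "metrics.json", metrics, config)

    elif config.protocol == "fit":
        opts = dict(config.options)
        res = fit(
            config.resolve_params(), seed=config.seed,
            n_iter=int(opts.get("n_iter", 2000)),
            n_restarts=int(opts.get("n_restarts", 1)),
            duration=config.duration, step=max(config.step, 0.1),
            transient=config.transient,
        )
        payload = {
            "best_cost": res.cost,
            "best_parameters": dict(zip(
                ("w_SG", "w_GS", "w_CS", "w_SC", "w_GG", "w_CC", "C", "Str",
                 "T_CC", "tau_E", "tau_I", "B_E", "B_I", "M_E", "M_I"),
                map(float, res.x))),
            "n_evaluations": int(res.trace.size),
            "metrics": {k: _metrics_dict(v)
                        for k, v in (res.metrics or {}).items()},
        }
        log.info("fit: best cost %.4g", res.cost)
        write_json(outdir / "fit_result.json", payload, config)

    elif config.protocol == "stability":
        from .linear_analysis import stability_surface

        opts = dict(config.options)
        n = int(opts.get("grid", 8))
        w_max = float(opts.get("w_max", 4.0))
        sb, freq = stability_surface(
            np.linspace(0, w_max, n), np.linspace(0, w_max, n),
            duration=float(opts.get("duration", 2000.0)),
        )
        with open(outdir / "stability_grid.csv", "w") as fh:
            fh.write(_config_line(config) + "\n")
            fh.write("w_loop_SG,w_CC,critical_long,onset_frequency_hz\n")
            for i in range(n):
                for j in range(n):
                    fh.write(",".join(
                        f"{v:.9g}" for v in (
                            sb.values[i, j, 0], sb.values[i, j, 1],
                            sb.critical[i, j], freq[i, j])) + "\n")

    elif config.protocol == "delay-scan":
        from .linear_analysis import delay_scan

        opts = dict(config.options)
        alphas = opts.get("alphas") or np.linspace(0.25, 3.0, 12)
        df = delay_scan(config.resolve_params(), alphas=alphas,
                        duration=config.duration, step=config.step,
                        transient=config.transient)
        with open(outdir / "delay_scan.csv", "w") as fh:
            fh.write(_config_line(config) + "\n")
            df.to_csv(fh, index=False, float_format="%.9g")

    elif config.protocol == "spiketrain":
        from .spiketrain import (GPE_RATE_PROCESS, STN_RATE_PROCESS,
                                 autocorrelogram, generate_train)

        opts = dict(config.options)
        pop = opts.get("population", "STN")
        proc = STN_RATE_PROCESS if pop.upper() == "STN" else GPE_RATE_PROCESS
        train = generate_train(proc, seed=config.seed)
        with open(outdir / "spikes.txt", "w") as fh:
            fh.write(_config_line(config) + "\n")
            for t in train.times:
                fh.write(f"{t:.9g}\n")
        ac = autocorrelogram(train)
        with open(outdir / "autocorrelogram.csv", "w") as fh:
            fh.write(_config_line(config) + "\n")
            fh.write("lag_ms,count\n")
            for lag, cnt in zip(ac.lags, ac.counts):
                fh.write(f"{lag:.9g},{cnt:.9g}\n")
        write_json(outdir / "spiketrain.json", {
            "population": pop,
            "process": dataclasses.asdict(proc),
            "n_spikes": train.n_spikes,
            "empirical_mean_rate_spk_s": train.mean_rate,
        }, config)
        log.info("spiketrain %s: %d spikes, %.2f spk/s", pop,
                 train.n_spikes, train.mean_rate)

    return outdir
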