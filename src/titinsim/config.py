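"""Run configuration: YAML/JSON parsing, validation, and the run driver.

Interface units follow the conventions of the muscle-mechanics literature:
lengths in the config and CSV outputs are micrometres, forces picoNewtons,
times seconds.  Config files, however, specify model parameters in SI
(metres, Newtons), mirroring the field names of the parameter dataclasses.
"""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, ValidationError
from .kinetics import (ClusterModel, Cluster, RefoldingParams,
                       default_cluster_model, noisy_linear_clusters,
                       single_cluster_model)
from .mechanics import (ForceCurveFamily, Isoform, MechanicalParams,
                        build_force_curves)
from .montecarlo import simulate_ensemble
from .exact import solve_master
from .protocols import (LengthProtocol, make_cycles, make_hysteresis_protocol,
                        make_ramp)

__all__ = ["RunConfig", "load_config", "run"]

_DEFAULT_SOLVER = {
    "dt_mc": 1e-4,
    "dt_exact": 1e-3,
    "max_step_prob": 0.1,
    "force_eval": "as_printed",
}
_DEFAULT_GRID = {"l_min": 0.99e-6, "l_max": 2.0e-6, "spacing": 1e-9}
_DEFAULT_RUN = {"R": 200, "seed": 1}


@dataclass
class RunConfig:
    """Fully validated simulation configuration."""

    params: MechanicalParams
    isoform: Isoform
    clusters: ClusterModel
    protocol: LengthProtocol
    dt_mc: float
    dt_exact: float
    max_step_prob: float
    force_eval: str
    grid: dict
    R: int
    seed: int
    raw: dict

    _family: ForceCurveFamily | None = None

    def family(self) -> ForceCurveFamily:
        """Force-curve family on the configured grid (built once, cached)."""
        if self._family is None:
            g = self.grid
            n = int(round((g["l_max"] - g["l_min"]) / g["spacing"]))
            length_grid = g["l_min"] + g["spacing"] * np.arange(n + 1)
            self._family = build_force_curves(length_grid, self.params,
                                              self.isoform)
        return self._family

    def resolved(self) -> dict:
        """Plain-dict view of the configuration (for manifests)."""
        d = {
            "mechanics": dataclasses.asdict(self.params),
            "isoform": dataclasses.asdict(self.isoform),
            "clusters": {
                "sizes": [int(n) for n in self.clusters.sizes],
                "omega0": [float(w) for w in self.clusters.omega0],
                "x_u": self.clusters.x_u,
                "temperature": self.clusters.temperature,
                "refolding": (None if self.clusters.refolding is None else
                              dataclasses.asdict(self.clusters.refolding)),
            },
            "protocol": {
                "times_s": [float(t) for t in self.protocol.times],
                "lengths_um": [float(l) * 1e6 for l in self.protocol.lengths],
            },
            "solver": {"dt_mc": self.dt_mc, "dt_exact": self.dt_exact,
                       "max_step_prob": self.max_step_prob,
                       "force_eval": self.force_eval},
            "grid": dict(self.grid),
            "run": {"R": self.R, "seed": self.seed},
        }
        return d


def _build_clusters(spec: dict, temperature: float,
                    n_prox_ig: int) -> ClusterModel:
    spec = dict(spec or {})
    kind = spec.pop("kind", "geometric")
    refolding = spec.pop("refolding", None)
    ref = RefoldingParams(**refolding) if refolding else None
    try:
        if kind == "geometric":
            model = default_cluster_model(
                n_domains=spec.pop("n_domains", n_prox_ig),
                m=spec.pop("m", 5),
                omega0_min=spec.pop("omega0_min", 1e-5),
                omega0_max=spec.pop("omega0_max", 1e-3),
                x_u=spec.pop("x_u", 0.25e-9),
                temperature=temperature, refolding=ref)
        elif kind == "single":
            model = single_cluster_model(
                n_domains=spec.pop("n_domains", n_prox_ig),
                omega0=spec.pop("omega0", 1e-4),
                x_u=spec.pop("x_u", 0.25e-9),
                temperature=temperature, refolding=ref)
        elif kind == "noisy_linear":
            model = noisy_linear_clusters(
                n_domains=spec.pop("n_domains", n_prox_ig),
                omega0_min=spec.pop("omega0_min", 1e-5),
                omega0_max=spec.pop("omega0_max", 1e-3),
                noise_sd=spec.pop("noise_sd", 0.2),
                noise_scale=spec.pop("noise_scale", "log10"),
                rng=spec.pop("seed", 0),
                x_u=spec.pop("x_u", 0.25e-9),
                temperature=temperature)
        elif kind == "explicit":
            sizes = spec.pop("sizes")
            omega0 = spec.pop("omega0")
            if len(sizes) != len(omega0):
                raise ConfigError("sizes and omega0 must have equal length")
            model = ClusterModel(
                tuple(Cluster(int(n), float(w))
                      for n, w in zip(sizes, omega0)),
                x_u=spec.pop("x_u", 0.25e-9),
                temperature=temperature, refolding=ref)
        else:
            raise ConfigError(f"unknown cluster kind {kind!r}")
    except (TypeError, KeyError, ValidationError) as exc:
        raise ConfigError(f"bad cluster spec: {exc}") from exc
    if spec:
        raise ConfigError(f"unknown cluster keys: {sorted(spec)}")
    if model.n_domains != n_prox_ig:
        raise ConfigError(
            f"cluster model covers {model.n_domains} domains but the "
            f"isoform has {n_prox_ig} proximal Ig domains")
    return model


def _build_protocol(spec: dict, base_dir: Path) -> LengthProtocol:
    spec = dict(spec or {})
    kind = spec.pop("kind", "ramp")
    try:
        if kind == "ramp":
            prot = make_ramp(spec.pop("l_start", 1e-6),
                             spec.pop("l_end", 2e-6),
                             spec.pop("speed", 1e-6))
        elif kind == "hysteresis":
            prot = make_hysteresis_protocol(
                l_low=spec.pop("l_low", 1e-6),
                l_high=spec.pop("l_high", 1.7e-6),
                speed=spec.pop("speed", 1e-6),
                n_pre=spec.pop("n_pre", 2),
                rest=spec.pop("rest", 30.0),
                n_post=spec.pop("n_post", 1))
        elif kind == "cycles":
            base = spec.pop("base", 1.85e-6)
            amp = spec.pop("amplitude", 0.125e-6)
            speed = spec.pop("speed", 1e-6)
            prot = make_cycles(base, amp, spec.pop("n_cycles", 10), speed)
            start = spec.pop("approach_from", None)
            if start is not None:
                ramp_t = (base - start) / speed
                times = np.concatenate([[0.0], prot.times + ramp_t])
                lengths = np.concatenate([[start], prot.lengths])
                prot = LengthProtocol(times, lengths)
        elif kind == "csv":
            prot = LengthProtocol.from_csv(base_dir / spec.pop("path"))
        else:
            raise ConfigError(f"unknown protocol kind {kind!r}")
    except (TypeError, KeyError, ValidationError) as exc:
        raise ConfigError(f"bad protocol spec: {exc}") from exc
    if spec:
        raise ConfigError(f"unknown protocol keys: {sorted(spec)}")
    return prot


def load_config(source: str | Path | dict) -> RunConfig:
    """Load and validate a YAML/JSON config file or an equivalent dict."""
    if isinstance(source, dict):
        raw = source
        base_dir = Path.cwd()
    else:
        path = Path(source)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        raw = yaml.safe_load(text)
        base_dir = path.parent
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = {"mechanics", "isoform", "clusters", "protocol", "solver",
             "grid", "run"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config sections: {sorted(unknown)}")
    try:
        params = MechanicalParams(**(raw.get("mechanics") or {}))
        isoform = Isoform(**(raw.get("isoform") or {}))
    except (TypeError, ValidationError) as exc:
        raise ConfigError(f"bad mechanics/isoform: {exc}") from exc
    clusters = _build_clusters(raw.get("clusters"), params.temperature,
                               isoform.n_prox_ig)
    protocol = _build_protocol(raw.get("protocol"), base_dir)
    solver = {**_DEFAULT_SOLVER, **(raw.get("solver") or {})}
    grid = {**_DEFAULT_GRID, **(raw.get("grid") or {})}
    run_sec = {**_DEFAULT_RUN, **(raw.get("run") or {})}
    if solver["force_eval"] not in ("as_printed", "start", "end"):
        raise ConfigError("solver.force_eval must be as_printed|start|end")
    for key in ("dt_mc", "dt_exact", "max_step_prob"):
        if not solver[key] > 0:
            raise ConfigError(f"solver.{key} must be positive")
    if grid["l_max"] < float(protocol.lengths.max()):
        raise ConfigError("grid.l_max is below the protocol's peak length")
    if int(run_sec["R"]) < 1:
        raise ConfigError("run.R must be >= 1")
    return RunConfig(params=params, isoform=isoform, clusters=clusters,
                     protocol=protocol, dt_mc=float(solver["dt_mc"]),
                     dt_exact=float(solver["dt_exact"]),
                     max_step_prob=float(solver["max_step_prob"]),
                     force_eval=str(solver["force_eval"]), grid=grid,
                     R=int(run_sec["R"]), seed=int(run_sec["seed"]), raw=raw)


def run(config: RunConfig, out_dir: str | Path,
        methods: tuple[str, ...] = ("mc", "exact"),
        dry_run: bool = False) -> dict:
    """Execute the configured solver(s) and write CSV results + manifest.

    Returns the manifest dict.  ``dry_run`` only validates and reports the
    resolved configuration.
    """
    manifest: dict = {
        "package": "titinsim",
        "version": __version__,
        "config": config.resolved(),
        "methods": list(methods),
        "outputs": {},
        "timings_s": {},
    }
    if dry_run:
        return manifest
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    family = config.family()
    results = {}
    if "mc" in methods:
        t0 = _time.perf_counter()
        ens = simulate_ensemble(config.protocol, config.R, config.clusters,
                                family, dt=config.dt_mc, seed=config.seed,
                                max_step_prob=config.max_step_prob,
                                force_eval=config.force_eval)
        manifest["timings_s"]["mc"] = _time.perf_counter() - t0
        df = pd.DataFrame({
            "time_s": ens.times,
            "length_um": ens.lengths * 1e6,
            "mean_force_pN": ens.mean_force * 1e12,
        })
        df.to_csv(out / "mc.csv", index=False)
        manifest["outputs"]["mc"] = "mc.csv"
        results["mc"] = ens
    if "exact" in methods:
        t0 = _time.perf_counter()
        sol = solve_master(config.protocol, config.clusters, family,
                           dt=config.dt_exact)
        manifest["timings_s"]["exact"] = _time.perf_counter() - t0
        df = pd.DataFrame({
            "time_s": sol.times,
            "length_um": sol.lengths * 1e6,
            "expected_force_pN": sol.expected_force * 1e12,
        })
        for l in range(sol.aggregated.shape[1]):
            df[f"P_{l}"] = sol.aggregated[:, l]
        df.to_csv(out / "exact.csv", index=False)
        manifest["outputs"]["exact"] = "exact.csv"
        results["exact"] = sol
    if "mc" in results and "exact" in results:
        ens, sol = results["mc"], results["exact"]
        mc_on_exact = np.interp(sol.times, ens.times, ens.mean_force)
        diff = mc_on_exact - sol.expected_force
        pd.DataFrame({
            "time_s": sol.times,
            "length_um": sol.lengths * 1e6,
            "mc_mean_force_pN": mc_on_exact * 1e12,
            "expected_force_pN": sol.expected_force * 1e12,
            "difference_pN": diff * 1e12,
        }).to_csv(out / "compare.csv", index=False)
        manifest["outputs"]["compare"] = "compare.csv"
        manifest["max_abs_difference_pN"] = float(np.abs(diff).max()) * 1e12
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(manifest["config"], fh, sort_keys=False)
    return manifest
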