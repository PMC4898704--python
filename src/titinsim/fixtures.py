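"""Canonical simulation setups as ready-made config dicts.

Each fixture bundles a cluster model, a length protocol and solver
settings for one of the standard numerical experiments:

* ``ramp`` — 1 -> 2 um half-sarcomere ramp at 1 um/s, five stability
  clusters of ten domains; the setting for the MC-vs-exact comparison and
  the first-unfolding-force distribution.
* ``hysteresis`` — two 1 -> 1.7 -> 1 um stretch-shortening cycles, a 30 s
  rest, then a third cycle, with a single cluster and refolding enabled;
  hysteresis collapses in cycle 2 and recovers in cycle 3.
* ``cycles`` — approach ramp to a 1.85 um base length followed by ten
  +-0.125 um triangular cycles (a 3.7 um sarcomere cycled by ~0.25 um,
  expressed per half sarcomere); peak forces decline as unfolding
  accumulates.
* ``cluster_comparison`` — 50 single-domain clusters with noisy linearly
  declining rate constants, to be compared against the 5-cluster model
  with the same rate envelope at R = 50.

``write_fixture`` materialises a fixture as a config YAML + protocol CSV
pair.  The Monte Carlo step of 0.1 ms keeps the per-step event
probability several-fold below the 0.1 validity bound on these protocols.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .config import RunConfig, load_config
from .errors import ConfigError

__all__ = ["FIXTURES", "fixture_config", "load_fixture", "write_fixture"]


def _ramp() -> dict:
    return {
        "clusters": {"kind": "geometric", "m": 5},
        "protocol": {"kind": "ramp", "l_start": 1.0e-6, "l_end": 2.0e-6,
                     "speed": 1.0e-6},
        "solver": {"dt_mc": 1.0e-4, "dt_exact": 1.0e-3},
        "run": {"R": 200, "seed": 1},
    }


def _hysteresis() -> dict:
    return {
        "clusters": {"kind": "single", "omega0": 1.0e-4,
                     "refolding": {"omega1": 1.0, "x_f": 2.2e-9}},
        "protocol": {"kind": "hysteresis", "l_low": 1.0e-6,
                     "l_high": 1.7e-6, "speed": 1.0e-6, "n_pre": 2,
                     "rest": 30.0, "n_post": 1},
        "solver": {"dt_mc": 1.0e-4, "dt_exact": 1.0e-3},
        "run": {"R": 200, "seed": 1},
    }


def _cycles() -> dict:
    return {
        "clusters": {"kind": "geometric", "m": 5},
        "protocol": {"kind": "cycles", "base": 1.85e-6,
                     "amplitude": 0.125e-6, "n_cycles": 10,
                     "speed": 1.0e-6, "approach_from": 1.0e-6},
        "solver": {"dt_mc": 1.0e-4, "dt_exact": 1.0e-3},
        "run": {"R": 200, "seed": 1},
    }


def _cluster_comparison() -> dict:
    return {
        "clusters": {"kind": "noisy_linear", "noise_sd": 0.2, "seed": 0},
        "protocol": {"kind": "ramp", "l_start": 1.0e-6, "l_end": 2.0e-6,
                     "speed": 1.0e-6},
        "solver": {"dt_mc": 1.0e-4, "dt_exact": 1.0e-3},
        "run": {"R": 50, "seed": 1},
    }


FIXTURES = {
    "ramp": _ramp,
    "hysteresis": _hysteresis,
    "cycles": _cycles,
    "cluster_comparison": _cluster_comparison,
}


def fixture_config(name: str) -> dict:
    """Config dict for a named fixture."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ConfigError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}")


def load_fixture(name: str) -> RunConfig:
    """Validated :class:`RunConfig` for a named fixture."""
    return load_config(fixture_config(name))


def write_fixture(name: str, out_dir: str | Path) -> tuple[Path, Path]:
    """Write ``<name>_config.yaml`` and ``<name>_protocol.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = fixture_config(name)
    config_path = out / f"{name}_config.yaml"
    protocol_path = out / f"{name}_protocol.csv"
    rc = load_config(cfg)
    rc.protocol.to_csv(protocol_path)
    # the written config references the materialised protocol CSV
    cfg["protocol"] = {"kind": "csv", "path": protocol_path.name}
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return config_path, protocol_path
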