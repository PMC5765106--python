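"""Configuration loading and result serialization.

Run configurations are nested key-value text (YAML).  Validation is
strict: unknown keys are rejected by name, required blocks for the
chosen mode must be present, and every invariant violation reports the
offending key.  All stochastic draws descend from the single root
``seed``, which is recorded in every output artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import metadata
from pathlib import Path

import numpy as np
import yaml

from .coupling import CouplingParams
from .dynamics import FullState, ModelParams, ReducedState, Trajectory
from .equilibria import Equilibrium
from .experiments import ExperimentConfig, OutcomeTally

__all__ = ["RunConfig", "load_config", "save_config", "export_results",
           "ConfigError"]

MODES = ("simulate", "equilibria", "classify", "experiment")


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _package_version() -> str:
    try:
        return metadata.version("starwta")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunConfig:
    """Validated top-level run description."""

    mode: str
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1
    model: ModelParams | None = None
    initial_state: dict | None = None
    simulate: dict = field(default_factory=dict)     # t_end, rtol, atol, sample_dt, system
    classify: dict = field(default_factory=dict)     # winner, window, delta, slope_tol
    experiment: ExperimentConfig | None = None

    def digest(self) -> str:
        """Stable hash of the full configuration for provenance headers."""
        return hashlib.sha256(
            json.dumps(_to_plain(self), sort_keys=True).encode()).hexdigest()[:16]


def _to_plain(obj):
    if isinstance(obj, (RunConfig, ModelParams, CouplingParams, ExperimentConfig)):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


_COUPLING_KEYS = {"nu", "mu", "sigma"}
_MODEL_KEYS = {"omega", "b", "alpha", "beta", "gamma", "c", "coupling"}
_STATE_KEYS = {"phi", "theta", "theta0", "omega0", "a"}
_SIM_KEYS = {"t_end", "rtol", "atol", "sample_dt", "system"}
_CLASSIFY_KEYS = {"winner", "window", "delta", "slope_tol"}
_EXPERIMENT_KEYS = {
    "preset", "variant", "n", "omega_dist", "phase_range", "theta0_init",
    "omega0_init", "a1_init", "a_other_init", "coupling", "b", "alpha",
    "beta", "c", "gamma", "T1", "T2", "H_high", "H_low", "n_runs", "seed",
    "rtol", "atol", "sample_dt",
}
_TOP_KEYS = {"mode", "seed", "output_dir", "verbosity", "model",
             "initial_state", "simulate", "classify", "experiment"}


def _reject_unknown(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def _parse_coupling(block: dict) -> CouplingParams:
    _reject_unknown(block, _COUPLING_KEYS, "coupling")
    try:
        return CouplingParams(**{k: float(v) for k, v in block.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"coupling: {exc}") from exc


def _parse_model(block: dict) -> ModelParams:
    _reject_unknown(block, _MODEL_KEYS, "model")
    if "omega" not in block:
        raise ConfigError("model: missing required key 'omega'")
    if "b" not in block:
        raise ConfigError("model: missing required key 'b'")
    kwargs = dict(block)
    kwargs["omega"] = np.asarray(kwargs["omega"], dtype=float)
    if "coupling" in kwargs:
        kwargs["coupling"] = _parse_coupling(kwargs["coupling"] or {})
    try:
        return ModelParams(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"model: {exc}") from exc


def _parse_experiment(block: dict) -> ExperimentConfig:
    _reject_unknown(block, _EXPERIMENT_KEYS, "experiment")
    kwargs = dict(block)
    preset = kwargs.pop("preset", None)
    variant = kwargs.pop("variant", None)
    if preset is not None:
        from .experiments import example_preset
        base = example_preset(preset, variant,
                              n_runs=int(kwargs.pop("n_runs", 1000)),
                              seed=int(kwargs.pop("seed", 0)))
        if kwargs:
            raise ConfigError(
                f"experiment: preset configs accept only n_runs and seed "
                f"overrides, got {sorted(kwargs)}")
        return base
    if "coupling" in kwargs:
        kwargs["coupling"] = _parse_coupling(kwargs["coupling"] or {})
    for tup_key in ("omega_dist", "phase_range"):
        if tup_key in kwargs:
            kwargs[tup_key] = tuple(float(v) for v in kwargs[tup_key])
    try:
        return ExperimentConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"experiment: {exc}") from exc


def load_config(source) -> RunConfig:
    """Parse and validate a run configuration.

    ``source`` is a path to a YAML file or an in-memory mapping.
    Defaults mirror the documented operating point of the experiment
    protocol; unknown keys are rejected with the offending key named.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError("configuration must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "top level")
    mode = raw.get("mode")
    if mode not in MODES:
        raise ConfigError(f"mode must be one of {MODES}, got {mode!r}")

    cfg = RunConfig(
        mode=mode,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", ".")),
        verbosity=int(raw.get("verbosity", 1)),
    )
    if "model" in raw:
        cfg.model = _parse_model(raw["model"] or {})
    if "initial_state" in raw:
        block = dict(raw["initial_state"] or {})
        _reject_unknown(block, _STATE_KEYS, "initial_state")
        cfg.initial_state = block
    if "simulate" in raw:
        block = dict(raw["simulate"] or {})
        _reject_unknown(block, _SIM_KEYS, "simulate")
        cfg.simulate = block
    if "classify" in raw:
        block = dict(raw["classify"] or {})
        _reject_unknown(block, _CLASSIFY_KEYS, "classify")
        cfg.classify = block
    if "experiment" in raw:
        cfg.experiment = _parse_experiment(raw["experiment"] or {})

    if mode in ("simulate", "equilibria", "classify") and cfg.model is None:
        raise ConfigError(f"mode {mode!r} requires a 'model' block")
    if mode == "experiment" and cfg.experiment is None:
        raise ConfigError("mode 'experiment' requires an 'experiment' block")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Serialize a RunConfig back to YAML (round-trips through load)."""
    plain = _to_plain(cfg)
    plain = {k: v for k, v in plain.items()
             if v not in (None, {}, [])}
    with open(path, "w") as fh:
        yaml.safe_dump(plain, fh, sort_keys=True)


def initial_state_from_config(cfg: RunConfig):
    """Build a FullState or ReducedState from the initial_state block."""
    if cfg.model is None or cfg.initial_state is None:
        raise ConfigError("model and initial_state blocks are required")
    n = cfg.model.n
    blk = cfg.initial_state
    omega0 = float(blk.get("omega0", float(np.mean(cfg.model.omega))))
    a = np.asarray(blk.get("a", np.full(n, cfg.model.c)), dtype=float)
    if "theta" in blk or "theta0" in blk:
        theta = np.asarray(blk.get("theta", np.zeros(n)), dtype=float)
        return FullState(theta0=float(blk.get("theta0", 0.0)), theta=theta,
                         omega0=omega0, a=a)
    phi = np.asarray(blk.get("phi", np.zeros(n)), dtype=float)
    return ReducedState(phi=phi, omega0=omega0, a=a)


# ---------------------------------------------------------------------------
# Result export
# ---------------------------------------------------------------------------

def _provenance(cfg: RunConfig | None, seed: int | None) -> str:
    lines = [f"starwta version {_package_version()}"]
    if seed is not None:
        lines.append(f"seed {seed}")
    if cfg is not None:
        lines.append(f"config digest {cfg.digest()}")
    return "\n".join("# " + ln for ln in lines) + "\n"


def _equilibrium_record(eq: Equilibrium) -> str:
    lines = [f"label\t{eq.label}",
             f"residual\t{eq.residual:.12g}"]
    if eq.winner is not None:
        lines.append(f"winner\t{eq.winner + 1}")
    if eq.phi_star is not None:
        lines.append(f"phi_star\t{eq.phi_star:.12g}")
    s = eq.state
    lines.append("phi\t" + "\t".join(f"{v:.12g}" for v in s.phi))
    lines.append(f"omega0\t{s.omega0:.12g}")
    lines.append("a\t" + "\t".join(f"{v:.12g}" for v in s.a))
    if eq.stability is not None:
        lines.append(f"classification\t{eq.stability.classification}")
        lines.append("eigenvalues\t" + "\t".join(
            f"{lam.real:.12g}{lam.imag:+.12g}j"
            for lam in np.sort_complex(eq.stability.eigenvalues)))
    return "\n".join(lines) + "\n"


def export_results(bundle: dict, dest, *, cfg: RunConfig | None = None,
                   seed: int | None = None) -> list[Path]:
    """Write result artifacts as delimited/structured text.

    ``bundle`` maps names to result objects: `Trajectory` (optionally a
    ``(Trajectory, ModelParams)`` pair), `OutcomeTally`, or lists of
    `Equilibrium`.  Every file starts with a provenance header (package
    version, seed, config digest); identical inputs produce identical
    bytes.
    """
    if not bundle:
        raise ValueError("empty result bundle")
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    header = _provenance(cfg, seed)
    written = []
    for name, obj in bundle.items():
        params = None
        if isinstance(obj, tuple) and len(obj) == 2 and isinstance(obj[0], Trajectory):
            obj, params = obj
        if isinstance(obj, Trajectory):
            path = dest / f"{name}.tsv"
            tmp = path.with_suffix(".tsv.tmp")
            obj.to_text(tmp, params=params)
            path.write_text(header + tmp.read_text())
            tmp.unlink()
        elif isinstance(obj, OutcomeTally):
            path = dest / f"{name}.txt"
            path.write_text(header + obj.summary() + "\n")
            table = dest / f"{name}_runs.tsv"
            rows = ["\t".join(["run", "outcome", "winner"]
                              + [f"omega_{i + 1}" for i in range(obj.config.n)])]
            for r in obj.records:
                rows.append("\t".join(
                    [str(r.run_index), r.outcome,
                     "-" if r.winner is None else str(r.winner + 1)]
                    + [f"{w:.12g}" for w in r.omega]))
            table.write_text(header + "\n".join(rows) + "\n")
            written.append(table)
        elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], Equilibrium):
            path = dest / f"{name}.txt"
            path.write_text(header + "\n".join(
                _equilibrium_record(eq) for eq in obj))
        else:
            raise TypeError(f"cannot export object of type {type(obj)!r} "
                            f"under name {name!r}")
        written.append(path)
    return written
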