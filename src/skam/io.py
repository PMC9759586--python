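"""Fixture generation, configuration files, persistence and run manifests.

Configs are flat ``key = value`` text files; results are tab-separated
tables with a header row; weight matrices and patterns go to ``.npz``
containers with a small JSON header; every experiment run writes one
manifest that is sufficient to reproduce its outputs bit-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .encoding import Dictionary, RelationalStructure
from .experiments import ConfigError, ExperimentConfig
from .memory import WeightMatrix

__all__ = [
    "RunManifest",
    "generate_dictionary",
    "load_config",
    "load_results",
    "load_structures",
    "load_weights",
    "make_experiment_config",
    "parse_config_text",
    "save_results",
    "save_structures",
    "save_weights",
    "write_manifest",
]


def generate_dictionary(
    n_units: int, n_items: int, seed: int | np.random.Generator = 0, role: str = "object"
) -> Dictionary:
    """Random item dictionary: n_items x n_units i.i.d. Normal(0, 1/N)."""
    if n_units < 1 or n_items < 1:
        raise ValueError("n_units and n_items must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    items = rng.normal(0.0, 1.0 / np.sqrt(n_units), (n_items, n_units))
    return Dictionary(items=items, role=role)


_TRUE = {"true", "yes", "on"}
_FALSE = {"false", "no", "off"}


def _coerce(raw: str):
    s = raw.strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        pass
    low = s.lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    return s


def parse_config_text(text: str) -> dict:
    """Parse ``key = value`` lines ('#' comments allowed) with type inference."""
    out = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        out[key.strip()] = _coerce(value)
    return out


_ALIASES = {
    "N": "n_units",
    "L": "n_pairs",
    "L0": "cue_size",
    "P": "n_patterns",
    "D": "dict_size",
}


def make_experiment_config(values: dict) -> ExperimentConfig:
    """Build a validated :class:`ExperimentConfig` from a flat mapping.

    Short parameter names (N, L, L0, P, D) are accepted as aliases.
    Unknown keys and all constraint violations are reported together.
    """
    known = {f.name for f in fields(ExperimentConfig)}
    mapped = {}
    errors = []
    for key, value in values.items():
        name = _ALIASES.get(key, key)
        if name not in known:
            errors.append(f"unknown key {key!r}")
        else:
            mapped[name] = value
    missing = [k for k in ("n_units", "n_pairs", "cue_size") if k not in mapped]
    if missing:
        errors.append(f"missing required keys: {', '.join(missing)}")
    if not missing:
        try:
            cfg = ExperimentConfig(**mapped)
        except ConfigError as exc:
            errors.append(str(exc))
        else:
            if not errors:
                return cfg
    raise ConfigError("; ".join(errors))


def load_config(path) -> ExperimentConfig:
    """Read and validate a key-value experiment config file."""
    return make_experiment_config(parse_config_text(Path(path).read_text()))


def save_results(records: pd.DataFrame, path) -> None:
    """Write a result table as TSV with a header row (lossless round trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, sep="\t", index=False)


def load_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_structures(structures, path) -> None:
    """Serialize structures as one pair per row: structure_id, object_index,
    attribute_index."""
    rows = [
        dict(structure_id=i, object_index=o, attribute_index=a)
        for i, s in enumerate(structures)
        for o, a in s.pairs
    ]
    save_results(pd.DataFrame(rows), path)


def load_structures(path) -> list[RelationalStructure]:
    df = load_results(path)
    return [
        RelationalStructure(list(zip(g.object_index, g.attribute_index)))
        for _, g in df.groupby("structure_id", sort=True)
    ]


def save_weights(weights: WeightMatrix, path, seed: int | None = None) -> None:
    """Persist couplings to an .npz container with a JSON text header."""
    header = json.dumps(
        dict(n_units=weights.n_units, n_patterns=weights.n_patterns, rule=weights.rule, seed=seed)
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, J=weights.J, header=np.array(header))


def load_weights(path) -> tuple[WeightMatrix, dict]:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        w = WeightMatrix(J=data["J"], rule=header["rule"], n_patterns=header["n_patterns"])
    return w, header


@dataclass
class RunManifest:
    experiment: str
    seed: int
    config: dict
    outputs: list[str]
    timestamp: str
    version: str


def write_manifest(out_dir, experiment: str, seed: int, config: dict, outputs: list[str]) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        experiment=experiment,
        seed=seed,
        config=config,
        outputs=list(outputs),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        version=__version__,
    )
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(asdict(manifest), indent=2, default=str) + "\n")
    return path
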