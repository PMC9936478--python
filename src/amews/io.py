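"""Table schemas, validated CSV readers/writers, configuration and run manifests.

CSV is the interchange format (inspectable, diffable); months are ISO
``YYYY-MM`` strings; prevalence columns carry a ``_pct`` suffix to keep
the percent/proportion distinction explicit.  Every numeric output file
starts with a comment header recording the run's seed and config hash,
and every CLI run writes a ``manifest.json`` sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .core import SimulationParams

_MONTH_RE = re.compile(r"^\d{4}-(0[1-9]|1[0-2])$")


class ValidationError(Exception):
    """Raised when an input table or configuration violates its schema."""


@dataclass(frozen=True)
class Column:
    dtype: str  # "str" | "float" | "int" | "month"
    min: float | None = None
    max: float | None = None
    required: bool = True


@dataclass(frozen=True)
class Schema:
    name: str
    columns: Mapping[str, Column]
    key: tuple = ()


HOUSEHOLDS_SCHEMA = Schema(
    name="households",
    columns={
        "id": Column("str"),
        "ward_id": Column("str"),
        "x": Column("float"),
        "y": Column("float"),
        "cap_own": Column("float", 0, 1),
        "cap_network": Column("float", 0, 1),
        "cap_market": Column("float", 0, 1),
        "h_p": Column("float", 0, 1),
        "h_a": Column("float", 0, 1),
        "n_children": Column("int", 1, None),
    },
    key=("id",),
)

STRESSORS_SCHEMA = Schema(
    name="stressors",
    columns={
        "ward_id": Column("str"),
        "month": Column("month"),
        "ndvi": Column("float"),
        "ndvi_lt_mean": Column("float"),
        "ndvi_lt_sd": Column("float", 1e-12, None),
        "price": Column("float", 0, None),
        "price_baseline": Column("float", 1e-12, None),
    },
    key=("ward_id", "month"),
)

PREVALENCE_SCHEMA = Schema(
    name="prevalence",
    columns={
        "ward_id": Column("str"),
        "month": Column("month"),
        "prevalence_pct": Column("float", 0, 100),
        "ipc_phase": Column("int", 1, 5, required=False),
    },
    key=("ward_id", "month"),
)

SCHEMAS = {s.name: s for s in (HOUSEHOLDS_SCHEMA, STRESSORS_SCHEMA, PREVALENCE_SCHEMA)}


def _rows(mask) -> list[int]:
    # 1-based data row numbers as a human would count them in the CSV body
    return [int(i) + 1 for i in mask[mask].index.tolist()][:10]


def validate_table(df: pd.DataFrame, schema: Schema) -> pd.DataFrame:
    """Validate header names, column types and ranges; report offending rows."""
    df = df.reset_index(drop=True)
    missing = [
        c for c, spec in schema.columns.items() if spec.required and c not in df.columns
    ]
    if missing:
        raise ValidationError(f"{schema.name}: missing columns {missing}")
    out = df.copy()
    for name, spec in schema.columns.items():
        if name not in out.columns:
            continue
        col = out[name]
        if spec.dtype in ("float", "int"):
            converted = pd.to_numeric(col, errors="coerce")
            bad = converted.isna() & col.notna()
            if bad.any():
                raise ValidationError(
                    f"{schema.name}: non-numeric values in column {name!r} at rows {_rows(bad)}"
                )
            if converted.isna().any():
                raise ValidationError(
                    f"{schema.name}: missing values in column {name!r} at rows {_rows(converted.isna())}"
                )
            if spec.dtype == "int":
                if not (converted == converted.round()).all():
                    frac = converted != converted.round()
                    raise ValidationError(
                        f"{schema.name}: non-integer values in column {name!r} at rows {_rows(frac)}"
                    )
                converted = converted.astype(int)
            if spec.min is not None:
                low = converted < spec.min
                if low.any():
                    raise ValidationError(
                        f"{schema.name}: column {name!r} below {spec.min} at rows {_rows(low)}"
                    )
            if spec.max is not None:
                high = converted > spec.max
                if high.any():
                    raise ValidationError(
                        f"{schema.name}: column {name!r} above {spec.max} at rows {_rows(high)}"
                    )
            out[name] = converted
        elif spec.dtype == "month":
            as_str = col.astype(str)
            bad = ~as_str.str.match(_MONTH_RE)
            if bad.any():
                raise ValidationError(
                    f"{schema.name}: column {name!r} must be ISO YYYY-MM at rows {_rows(bad)}"
                )
            out[name] = as_str
        else:
            out[name] = col.astype(str)
    if schema.key:
        dup = out.duplicated(subset=list(schema.key))
        if dup.any():
            raise ValidationError(
                f"{schema.name}: duplicate {schema.key} keys at rows {_rows(dup)}"
            )
    return out


def read_table(path, schema: Schema) -> pd.DataFrame:
    """Read and validate a CSV table (comment lines starting with '#' are ignored)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"{schema.name}: cannot parse {path}: {exc}") from exc
    return validate_table(df, schema)


def write_table(df: pd.DataFrame, path, manifest: "RunManifest | None" = None) -> None:
    """Write a CSV, prefixing the manifest's seed and config hash as a comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        if manifest is not None:
            fh.write(manifest.header_comment() + "\n")
        df.to_csv(fh, index=False)


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record: everything needed to re-run a command exactly."""

    command: str
    seed: int
    config_hash: str
    package_version: str
    input_checksums: dict = field(default_factory=dict)
    created: str = ""

    @classmethod
    def create(cls, command: str, seed: int, config: Mapping, inputs: Sequence = ()) -> "RunManifest":
        from . import __version__

        return cls(
            command=command,
            seed=int(seed),
            config_hash=config_hash(config),
            package_version=__version__,
            input_checksums={str(p): file_sha256(p) for p in inputs},
            created=datetime.now(timezone.utc).isoformat(timespec="seconds"),
        )

    def header_comment(self) -> str:
        return f"# amews={self.package_version} seed={self.seed} config_hash={self.config_hash}"

    def write(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "model": {
        "lambda": 0.05,
        "spawn_rate": 0.05,
        "n_0": 0.5,
        "K": 2,
        "neighborhood_k": 8,
        "selection_floor": 0.05,
        "ema_alpha": 0.3,
        "init_set_size": 3,
        "max_set_size": 8,
        "spawn_scale": 0.1,
    },
    "stressors": {
        "beta_c": 0.25,
        "beta_m": 0.5,
        "climate_floor": 0.1,
        "market_floor": 0.1,
    },
    "catalog": {
        "grid_step": 0.25,
        "zone_masks": {},
        "ward_zones": {},
    },
    "calibration": {
        "lambdas": [round(0.01 * i, 2) for i in range(1, 11)],
        "spawns": [0.05],
        "replicates": 20,
        "burn_in": 6,
    },
    "run": {
        "months": 24,
        "seed": 0,
        "replicates": 20,
    },
    "synth": {},
}


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, merged over the package defaults."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config {path} must be a YAML mapping")
        unknown = [k for k in raw if k not in DEFAULT_CONFIG]
        if unknown:
            raise ValidationError(f"unknown config sections: {unknown}")
        cfg = _deep_merge(cfg, raw)
    return cfg


def params_from_config(cfg: Mapping, seed: int | None = None) -> SimulationParams:
    m = cfg["model"]
    try:
        return SimulationParams(
            learning_rate=m["lambda"],
            spawn_rate=m["spawn_rate"],
            sufficiency_threshold=m["n_0"],
            persistence_window=m["K"],
            neighborhood_k=m["neighborhood_k"],
            selection_floor=m["selection_floor"],
            ema_alpha=m["ema_alpha"],
            init_set_size=m["init_set_size"],
            max_set_size=m["max_set_size"],
            spawn_scale=m["spawn_scale"],
            seed=cfg["run"]["seed"] if seed is None else seed,
        )
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"invalid model configuration: {exc}") from exc
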