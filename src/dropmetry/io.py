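"""File formats and run configuration.

Dataset CSV schema (strict: comma separator, '.' decimals, exact header,
no silently missing values)::

    viscosity_mPa_s,nozzle_id_mm,printing_time_s,pressure_psi,cell_conc_per_mL,volume_uL

Measurement CSV, model-card JSON, render-manifest CSV and the YAML run
configuration also live here.  Every CLI run additionally writes a
sidecar ``*.run.json`` log embedding the seed, a config hash and package
versions so any output artifact can be traced to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .imaging import DetectorConfig, PipelineConfig, PreprocessingConfig
from .models import FEATURES, TARGET, MetricsReport, ModelSpec
from .synthetic import GeneratorConfig, PrintRecord, RawImage

__all__ = [
    "DATASET_COLUMNS",
    "SchemaError",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "read_image",
    "write_image",
    "write_measurements",
    "write_model_card",
    "read_model_card",
    "write_run_log",
    "config_hash",
]

DATASET_COLUMNS = FEATURES + [TARGET]


class SchemaError(ValueError):
    """Dataset file does not match the expected schema."""


# ---------------------------------------------------------------------------
# dataset CSV
# ---------------------------------------------------------------------------

def read_dataset(path) -> list[PrintRecord]:
    """Read a parameter/volume dataset, strictly validating the schema.

    Raises :class:`SchemaError` naming a missing column, or a
    row-indexed ``ValueError`` for any non-numeric or missing cell.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: malformed CSV: {exc}") from exc
    for col in DATASET_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in DATASET_COLUMNS]
    if extra:
        raise SchemaError(f"{path}: unexpected columns {extra}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        values = {}
        for col, cell in zip(df.columns, row):
            try:
                values[col] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: row {i + 1}, column {col!r}: "
                    f"cannot parse {cell!r} as a number"
                ) from exc
        records.append(PrintRecord(**values))
    return records


def write_dataset(records, path) -> Path:
    """Write records in the canonical dialect (shortest round-trip floats)."""
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        records = [
            PrintRecord(**{c: float(records.iloc[i][c]) for c in DATASET_COLUMNS})
            for i in range(len(records))
        ]
    lines = [",".join(DATASET_COLUMNS)]
    for r in records:
        lines.append(",".join(repr(getattr(r, c)) for c in DATASET_COLUMNS))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# images and measurement tables
# ---------------------------------------------------------------------------

def read_image(path) -> RawImage:
    """Read an 8-bit grayscale or RGB PNG/TIFF."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    return RawImage(pixels=np.asarray(arr))


def write_image(image, path) -> Path:
    import imageio.v3 as iio

    path = Path(path)
    arr = image.pixels if isinstance(image, RawImage) else np.asarray(image)
    iio.imwrite(path, arr)
    return path


def _sig4(x: float) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.4g}"


def write_measurements(df: pd.DataFrame, path) -> Path:
    """Write a batch measurement table: contact angle to 2 dp, diameter and
    volume to 4 significant figures."""
    path = Path(path)
    out = df.copy()
    out["diameter_mm"] = out["diameter_mm"].map(_sig4)
    out["volume_uL"] = out["volume_uL"].map(_sig4)
    out["contact_angle_deg"] = out["contact_angle_deg"].map(
        lambda x: "nan" if not np.isfinite(x) else f"{x:.2f}"
    )
    out.to_csv(path, index=False, lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# model cards
# ---------------------------------------------------------------------------

def write_model_card(
    path,
    spec: ModelSpec,
    metrics: MetricsReport | None = None,
    model_path: str | None = None,
) -> Path:
    """JSON model card: algorithm, hyperparameters, seed, metrics, and the
    path of the persisted estimator."""
    card = {
        "algorithm": spec.algorithm,
        "hyperparameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in spec.hyperparameters.items()
        },
        "seed": spec.seed,
        "metrics": dataclasses.asdict(metrics) if metrics else None,
        "model_path": model_path,
        "dropmetry_version": __version__,
    }
    path = Path(path)
    path.write_text(json.dumps(card, indent=2) + "\n", encoding="utf-8")
    return path


def read_model_card(path) -> dict:
    card = json.loads(Path(path).read_text(encoding="utf-8"))
    hp = card.get("hyperparameters", {})
    if "hidden_layer_sizes" in hp and isinstance(hp["hidden_layer_sizes"], list):
        hp["hidden_layer_sizes"] = tuple(hp["hidden_layer_sizes"])
    return card


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Aggregated configuration for a pipeline run (all defaults documented
    on the individual config dataclasses)."""

    calibration_known_length_mm: float = 10.0
    calibration_span_px: float = 1028.0
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0
    output_dir: str = "."

    def pipeline_config(self) -> PipelineConfig:
        return PipelineConfig(preprocessing=self.preprocessing, detector=self.detector)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a YAML run configuration, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        blocks = {
            "preprocessing": PreprocessingConfig,
            "detector": DetectorConfig,
            "generator": GeneratorConfig,
        }
        simple = {
            f.name for f in dataclasses.fields(cls) if f.name not in blocks
        }
        kwargs = {}
        for key, value in raw.items():
            if key in blocks:
                known = {f.name for f in dataclasses.fields(blocks[key])}
                bad = set(value) - known
                if bad:
                    raise SchemaError(
                        f"unknown keys in {key!r} block: {sorted(bad)}"
                    )
                kwargs[key] = blocks[key](**value)
            elif key in simple:
                kwargs[key] = value
            else:
                raise SchemaError(f"unknown configuration key {key!r}")
        return cls(**kwargs)


def config_hash(obj) -> str:
    """Stable short hash of any (nested) dataclass/dict configuration."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    payload = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_run_log(path, command: str, seed: int, config) -> Path:
    """Sidecar reproducibility log for one CLI invocation."""
    import datetime

    log = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash(config),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "dropmetry_version": __version__,
        "python_version": platform.python_version(),
    }
    path = Path(path)
    path.write_text(json.dumps(log, indent=2) + "\n", encoding="utf-8")
    return path
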