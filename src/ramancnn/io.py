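"""Tabular spectra I/O and run configuration.

Spectra tables are plain UTF-8 CSV: metadata columns (patient_id, condition,
layer, region, gender) followed by one column per wavenumber, headers being
the literal grid values.  Reading and writing round-trip exactly at float64
precision.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import (
    ConfigError,
    FormatError,
    SchemaError,
    SpectralDataset,
    Spectrum,
    TASKS,
)

METADATA_COLUMNS = ("patient_id", "condition", "layer", "region", "gender")


def read_spectra_table(path, schema: dict[str, str] | None = None) -> SpectralDataset:
    """Read a spectra table from CSV.

    ``schema`` optionally maps canonical metadata names to the file's column
    names, e.g. ``{"patient_id": "donor"}``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    colmap = {name: (schema or {}).get(name, name) for name in METADATA_COLUMNS}
    for canonical, col in colmap.items():
        if col not in df.columns:
            raise SchemaError(f"missing metadata column {col!r} (for {canonical})")
    meta_cols = set(colmap.values())
    wn_cols = [c for c in df.columns if c not in meta_cols]
    try:
        grid = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber column header: {exc}") from None
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise FormatError("wavenumber headers are not strictly increasing")
    values = df[wn_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError("ragged or non-numeric intensity rows")
    spectra = []
    for i in range(len(df)):
        spectra.append(
            Spectrum(
                wavenumbers=grid,
                intensities=values[i],
                patient_id=str(df[colmap["patient_id"]].iloc[i]),
                condition=str(df[colmap["condition"]].iloc[i]),
                layer=str(df[colmap["layer"]].iloc[i]),
                region=str(df[colmap["region"]].iloc[i]),
                gender=str(df[colmap["gender"]].iloc[i]),
            )
        )
    return SpectralDataset(spectra)


def write_spectra_table(dataset: SpectralDataset, path) -> Path:
    """Write a dataset as CSV; bitwise stable for identical inputs."""
    path = Path(path)
    grid = dataset.grid
    header = list(METADATA_COLUMNS) + [repr(v) for v in grid.tolist()]
    lines = [",".join(header)]
    for s in dataset:
        meta = [s.patient_id, s.condition, s.layer, s.region, s.gender]
        lines.append(",".join(meta + [repr(v) for v in s.intensities.tolist()]))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One experiment's settings; defaults equal the study protocol."""

    task: str = "disease_superficial"
    region: str = "A"
    method: str = "multichannel"
    channel_method_names: tuple[str, ...] = (
        "pspline_aspls", "jbcd", "ria", "fabc", "adaptive_minmax", "goldindec", "beads",
    )
    seed: int = 0
    epochs: int = 100
    learning_rate: float = 1e-4
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 4
    val_batch_size: int = 1
    test_batch_size: int = 1
    k_folds: int = 6
    subset_sizes: tuple[int, ...] = (1, 2, 3, 5, 10, 20, 50, 100, 300, 1015)
    n_blocks: int = 6
    hidden_filters: int = 100
    kernel_size: int = 5

    def validate(self) -> None:
        checks = [
            (self.task in TASKS, f"task: unknown value {self.task!r}"),
            (self.region in ("A", "B"), f"region: must be A or B, got {self.region!r}"),
            (self.method in ("raw", "preprocessed", "multichannel"),
             f"method: unknown value {self.method!r}"),
            (self.epochs >= 1, "epochs: must be >= 1"),
            (self.learning_rate > 0, "learning_rate: must be > 0"),
            (self.k_folds >= 2, "k_folds: must be >= 2"),
            (all(s >= 1 for s in self.subset_sizes), "subset_sizes: all must be >= 1"),
            (min(self.batch_size, self.val_batch_size, self.test_batch_size) >= 1,
             "batch sizes: must be >= 1"),
        ]
        errors = [msg for ok, msg in checks if not ok]
        if errors:
            raise ConfigError("; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("channel_method_names", "betas", "subset_sizes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> Path:
        path = Path(path)
        d = asdict(self)
        for key in ("channel_method_names", "betas", "subset_sizes"):
            d[key] = list(d[key])
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path
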