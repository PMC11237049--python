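"""Core containers for Raman spectra and labelled spectral cohorts.

A :class:`Spectrum` is one acquisition: a fixed wavenumber grid (cm^-1),
intensities (arbitrary units) and the clinical metadata used by the four
classification tasks (donor condition, cartilage layer, spectral region,
gender).  A :class:`SpectralDataset` is an ordered cohort of spectra sharing
one grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterator

import numpy as np

CONDITIONS = ("OA", "Healthy")
LAYERS = ("superficial", "deep")
REGIONS = ("A", "B")
GENDERS = ("male", "female", "unknown")

#: Wavenumber bounds (cm^-1) of the two acquisition windows.
REGION_BOUNDS = {"A": (614.0, 1722.0), "B": (2495.0, 3264.0)}
#: Number of points on the acquisition grid.
DEFAULT_GRID_POINTS = 1015

#: task name -> (metadata field used as label, positive value, fixed-subset field, fixed value)
TASKS = {
    "disease_superficial": ("condition", "OA", "layer", "superficial"),
    "disease_deep": ("condition", "OA", "layer", "deep"),
    "layer_healthy": ("layer", "deep", "condition", "Healthy"),
    "layer_oa": ("layer", "deep", "condition", "OA"),
}


class SchemaError(ValueError):
    """A required metadata column or field is missing or mis-typed."""


class FormatError(ValueError):
    """On-disk data violates a structural invariant (ragged rows, bad grid)."""


class ConfigError(ValueError):
    """A run or cohort configuration fails validation."""


class DegenerateInputError(ValueError):
    """An operation received an input it is undefined on (e.g. zero vector)."""


@dataclass(frozen=True)
class Spectrum:
    """One Raman acquisition with its clinical metadata."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    patient_id: str
    condition: str
    layer: str
    region: str
    gender: str = "unknown"

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", it)
        if wn.ndim != 1 or it.ndim != 1 or wn.size != it.size:
            raise FormatError(
                f"wavenumbers and intensities must be 1-D of equal length, got {wn.shape} vs {it.shape}"
            )
        if wn.size >= 2 and not np.all(np.diff(wn) > 0):
            raise FormatError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(it)):
            raise FormatError("intensities contain non-finite values")
        for name, value, allowed in (
            ("condition", self.condition, CONDITIONS),
            ("layer", self.layer, LAYERS),
            ("region", self.region, REGIONS),
            ("gender", self.gender, GENDERS),
        ):
            if value not in allowed:
                raise SchemaError(f"{name}={value!r} not one of {allowed}")

    @property
    def metadata(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "condition": self.condition,
            "layer": self.layer,
            "region": self.region,
            "gender": self.gender,
        }

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass
class SpectralDataset:
    """An ordered cohort of spectra on one shared wavenumber grid."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            for i, s in enumerate(self.spectra):
                if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
                    raise FormatError(f"spectrum {i} is not on the shared grid")

    @property
    def grid(self) -> np.ndarray:
        if not self.spectra:
            return np.empty(0, dtype=float)
        return self.spectra[0].wavenumbers

    @property
    def n_points(self) -> int:
        return int(self.grid.size)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i) -> Spectrum:
        return self.spectra[i]

    def patients(self) -> list[str]:
        """Unique patient ids in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.spectra:
            seen.setdefault(s.patient_id, None)
        return list(seen)

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, W) array of raw intensities."""
        return np.stack([s.intensities for s in self.spectra]) if self.spectra else np.empty((0, 0))

    def subset(self, predicate: Callable[[Spectrum], bool]) -> "SpectralDataset":
        return SpectralDataset([s for s in self.spectra if predicate(s)])

    def for_task(self, task: str) -> tuple["SpectralDataset", np.ndarray]:
        """Restrict to the spectra a task uses and return binary labels.

        Label 1 marks the positive class (OA for disease tasks, deep layer
        for layer tasks).
        """
        if task not in TASKS:
            raise ConfigError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
        label_field, positive, fix_field, fix_value = TASKS[task]
        sub = self.subset(lambda s: getattr(s, fix_field) == fix_value)
        y = np.array([1 if getattr(s, label_field) == positive else 0 for s in sub], dtype=int)
        return sub, y


def task_positive_class(task: str) -> str:
    if task not in TASKS:
        raise ConfigError(f"unknown task {task!r}")
    return TASKS[task][1]


def patient_labels(dataset: SpectralDataset, task: str) -> dict[str, int]:
    """Binary class per patient for a task (patients are single-condition)."""
    sub, y = dataset.for_task(task)
    out: dict[str, int] = {}
    for s, lab in zip(sub, y):
        prev = out.setdefault(s.patient_id, int(lab))
        if prev != lab:
            raise FormatError(f"patient {s.patient_id} has inconsistent labels for task {task}")
    return out
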