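"""Specimen-level landmark data and metadata.

A :class:`LandmarkConfiguration` is one specimen's named 3D points under a
governing :class:`~thoraxgm.template.Template`, with a per-point presence
mask so that partially preserved (fossil-like) specimens can be represented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .template import Template

TAXA = ("recent_sapiens", "fossil_sapiens", "erectus", "neanderthal")
CLIMATE_GROUPS = ("cold", "temperate", "warm")

#: climate classification thresholds (deg C); boundary -> colder class
COLD_MAX_TEMP_C = 7.0
TEMPERATE_MAX_TEMP_C = 23.0


def classify_climate(temp_c: float) -> str:
    """Classify a mean annual temperature into cold/temperate/warm.

    cold if <= 7 degC, temperate if <= 23 degC, warm above; boundary values
    belong to the colder class.
    """
    if not np.isfinite(temp_c):
        raise ValueError("temperature must be finite")
    if temp_c <= COLD_MAX_TEMP_C:
        return "cold"
    if temp_c <= TEMPERATE_MAX_TEMP_C:
        return "temperate"
    return "warm"


@dataclass
class LandmarkConfiguration:
    """One specimen's 3D points in template order.

    ``coords`` has shape (k, 3) in mm, rows ordered as ``labels``; rows where
    ``present`` is False hold NaN and represent missing (unpreserved) points.
    """

    specimen_id: str
    labels: tuple[str, ...]
    coords: np.ndarray
    present: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        k = len(self.labels)
        if self.coords.shape != (k, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({k}, 3)")
        if self.present.shape != (k,):
            raise ValueError("present mask length mismatch")
        if not np.all(np.isfinite(self.coords[self.present])):
            raise ValueError("non-finite coordinates at present points")
        self.coords = self.coords.copy()
        self.coords[~self.present] = np.nan

    @classmethod
    def from_mapping(cls, specimen_id: str,
                     coords: Mapping[str, Iterable[float]],
                     template: Template) -> "LandmarkConfiguration":
        """Build from a label -> (x, y, z) mapping; absent labels are masked."""
        unknown = set(coords) - set(template.labels)
        if unknown:
            raise KeyError(f"labels not in template: {sorted(unknown)[:5]}")
        k = len(template)
        arr = np.full((k, 3), np.nan)
        present = np.zeros(k, dtype=bool)
        for lab, xyz in coords.items():
            i = template.index_of(lab)
            arr[i] = np.asarray(tuple(xyz), dtype=float)
            present[i] = True
        return cls(specimen_id, template.labels, arr, present)

    @property
    def is_complete(self) -> bool:
        return bool(self.present.all())

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    def present_labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, p in zip(self.labels, self.present) if p)

    def __getitem__(self, label: str) -> np.ndarray:
        i = self.labels.index(label)
        return self.coords[i]

    def restrict(self, labels: Iterable[str]) -> "LandmarkConfiguration":
        """Configuration restricted to ``labels`` (input order ignored;
        template order preserved)."""
        keep = set(labels)
        unknown = keep - set(self.labels)
        if unknown:
            raise KeyError(f"unknown labels: {sorted(unknown)[:5]}")
        idx = [i for i, lab in enumerate(self.labels) if lab in keep]
        return LandmarkConfiguration(
            self.specimen_id, tuple(self.labels[i] for i in idx),
            self.coords[idx], self.present[idx],
            {lab: self.provenance[lab] for lab in self.provenance
             if lab in keep})

    def with_coords(self, coords: np.ndarray,
                    present: np.ndarray | None = None,
                    specimen_id: str | None = None) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            specimen_id or self.specimen_id, self.labels, coords,
            self.present if present is None else present,
            dict(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of the present points."""
        rows = self.present
        return pd.DataFrame({
            "specimen_id": self.specimen_id,
            "label": np.asarray(self.labels)[rows],
            "x": self.coords[rows, 0],
            "y": self.coords[rows, 1],
            "z": self.coords[rows, 2],
        })


@dataclass(frozen=True)
class SpecimenMeta:
    """Group membership and provenance of one specimen."""

    specimen_id: str
    taxon: str
    climate_group: str | None = None
    mean_annual_temp: float | None = None
    population: str = ""

    def __post_init__(self) -> None:
        if self.taxon not in TAXA:
            raise ValueError(f"unknown taxon {self.taxon!r}")
        if self.climate_group is not None \
                and self.climate_group not in CLIMATE_GROUPS:
            raise ValueError(f"unknown climate group {self.climate_group!r}")
        if self.mean_annual_temp is not None \
                and self.climate_group is not None:
            expected = classify_climate(self.mean_annual_temp)
            if expected != self.climate_group:
                raise ValueError(
                    f"climate group {self.climate_group!r} inconsistent with "
                    f"{self.mean_annual_temp} degC (expected {expected!r})")


def meta_to_frame(metas: Iterable[SpecimenMeta]) -> pd.DataFrame:
    return pd.DataFrame([{
        "specimen_id": m.specimen_id, "taxon": m.taxon,
        "climate_group": m.climate_group or "",
        "mean_annual_temp": "" if m.mean_annual_temp is None
        else m.mean_annual_temp,
        "population": m.population,
    } for m in metas])
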