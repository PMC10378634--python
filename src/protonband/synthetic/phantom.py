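"""Phantom construction: voxel grids plus named binary structures.

A phantom stands in for a planning CT with contoured targets and organs at
risk.  Structure solids are evaluated at voxel centers, so a voxel belongs
to a structure iff its center lies inside the solid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from ..errors import ConfigurationError, EmptyStructureError, ValidationError
from ..geometry import GridSpec

__all__ = [
    "ROLES",
    "METRIC_KINDS",
    "Structure",
    "Phantom",
    "build_phantom",
    "solid_contains",
]

ROLES = ("primary_target", "secondary_target", "oar")
METRIC_KINDS = ("target_D95_V100", "oar_max", "oar_mean")

_TARGET_ROLES = ("primary_target", "secondary_target")


@dataclass(frozen=True)
class Structure:
    """A named binary mask with an analysis role.

    ``prescription_Gy`` is required (and > 0) for targets and must be absent
    for OARs.  ``metric_kind`` selects which plan-quality metrics apply.
    """

    name: str
    role: str
    mask: np.ndarray
    prescription_Gy: float | None = None
    metric_kind: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for structure {self.name!r}")
        kind = self.metric_kind or (
            "target_D95_V100" if self.role in _TARGET_ROLES else "oar_max"
        )
        if kind not in METRIC_KINDS:
            raise ValidationError(f"unknown metric kind {kind!r} for {self.name!r}")
        if self.role in _TARGET_ROLES:
            if kind != "target_D95_V100":
                raise ValidationError(f"target {self.name!r} must use target_D95_V100")
            if self.prescription_Gy is None or self.prescription_Gy <= 0:
                raise ValidationError(
                    f"target {self.name!r} needs a positive prescription, "
                    f"got {self.prescription_Gy}"
                )
        else:
            if kind == "target_D95_V100":
                raise ValidationError(f"OAR {self.name!r} cannot use target metrics")
            if self.prescription_Gy is not None:
                raise ValidationError(f"OAR {self.name!r} must not carry a prescription")
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise EmptyStructureError(self.name)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "metric_kind", kind)

    @property
    def is_target(self) -> bool:
        return self.role in _TARGET_ROLES

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class Phantom:
    """A grid plus its structures (masks may overlap)."""

    grid: GridSpec
    structures: list[Structure]
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate structure names: {names}")
        for s in self.structures:
            if s.mask.shape != tuple(self.grid.shape):
                raise ConfigurationError(
                    f"mask for {s.name!r} has shape {s.mask.shape}, "
                    f"grid is {self.grid.shape}"
                )

    def structure(self, name: str) -> Structure:
        for s in self.structures:
            if s.name == name:
                return s
        raise KeyError(f"no structure named {name!r}")

    @property
    def targets(self) -> list[Structure]:
        return [s for s in self.structures if s.is_target]

    @property
    def primary_target(self) -> Structure:
        for s in self.structures:
            if s.role == "primary_target":
                return s
        raise ConfigurationError("phantom has no primary target")

    @property
    def oars(self) -> list[Structure]:
        return [s for s in self.structures if s.role == "oar"]

    def structure_points(self, name: str) -> np.ndarray:
        """(N, 3) voxel-center positions of a structure's mask."""
        s = self.structure(name)
        idx = np.argwhere(s.mask).astype(float)
        return idx * np.asarray(self.grid.spacing) + np.asarray(self.grid.origin)


# --- solid membership -------------------------------------------------------

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}


def solid_contains(points: np.ndarray, spec: Mapping) -> np.ndarray:
    """Vectorized point-in-solid test for one structure spec.

    Supported shapes: ``ellipsoid`` (center, radii), ``box`` (center,
    half_sizes), ``cylinder`` and ``capsule`` (center, radius, half_length,
    axis).  A capsule is a cylinder with hemispherical end caps.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    shape = spec["shape"]
    center = np.asarray(spec["center_mm"], dtype=float)
    rel = pts - center
    if shape == "ellipsoid":
        radii = np.asarray(spec["radii_mm"], dtype=float)
        if np.any(radii <= 0):
            return np.zeros(len(pts), dtype=bool)
        return np.sum((rel / radii) ** 2, axis=1) <= 1.0
    if shape == "box":
        half = np.asarray(spec["half_size_mm"], dtype=float)
        if np.any(half <= 0):
            return np.zeros(len(pts), dtype=bool)
        return np.all(np.abs(rel) <= half, axis=1)
    if shape in ("cylinder", "capsule"):
        radius = float(spec["radius_mm"])
        half_len = float(spec["half_length_mm"])
        if radius <= 0 or half_len < 0:
            return np.zeros(len(pts), dtype=bool)
        ax = _AXIS_INDEX[spec.get("axis", "z")]
        along = rel[:, ax]
        perp = np.delete(rel, ax, axis=1)
        r2 = np.sum(perp**2, axis=1)
        in_cyl = (np.abs(along) <= half_len) & (r2 <= radius**2)
        if shape == "cylinder":
            return in_cyl
        cap = (np.abs(along) > half_len) & (
            r2 + (np.abs(along) - half_len) ** 2 <= radius**2
        )
        return in_cyl | cap
    raise ConfigurationError(f"unknown solid shape {shape!r}")


def _structure_from_spec(grid: GridSpec, spec: Mapping, centers: np.ndarray) -> Structure:
    name = spec["name"]
    inside = solid_contains(centers, spec)
    mask = inside.reshape(grid.shape)
    if not mask.any():
        raise EmptyStructureError(
            name, f"solid {spec['shape']!r} contains no voxel centers on this grid"
        )
    return Structure(
        name=name,
        role=spec["role"],
        mask=mask,
        prescription_Gy=spec.get("prescription_Gy"),
        metric_kind=spec.get("metric_kind", ""),
    )


def build_phantom(config: Mapping) -> Phantom:
    """Build a phantom from a geometry config mapping.

    ``config`` needs ``grid`` (shape / spacing_mm / origin_mm, origin
    optional meaning centered) and a ``structures`` list of solid specs; at
    least one structure must have role ``primary_target``.
    """
    gcfg = config["grid"]
    if "origin_mm" in gcfg and gcfg["origin_mm"] is not None:
        grid = GridSpec(tuple(gcfg["shape"]), tuple(gcfg["spacing_mm"]), tuple(gcfg["origin_mm"]))
    else:
        grid = GridSpec.centered(tuple(gcfg["shape"]), gcfg["spacing_mm"])
    specs = list(config.get("structures", []))
    if not any(s.get("role") == "primary_target" for s in specs):
        raise ConfigurationError("config must define at least one primary_target structure")
    centers = grid.voxel_centers()
    structures = [_structure_from_spec(grid, s, centers) for s in specs]
    iso = tuple(float(v) for v in config.get("isocenter_mm", (0.0, 0.0, 0.0)))
    return Phantom(grid=grid, structures=structures, isocenter=iso)
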