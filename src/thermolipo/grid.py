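"""Spherically symmetric finite-volume grid over the nested geometry.

Nodes are cell centers of a node-centered scheme: node i owns the control
volume between the face radii midway to its neighbours, so conservation
statements telescope exactly.  Region interfaces (injection site | tumor |
normal tissue) always coincide with grid nodes; the interface node's control
volume straddles the interface, so region-restricted integrals weight each
control volume by its exact geometric overlap with the region shell, which
makes region volumes independent of resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = ("injection", "tumor", "normal")


@dataclass(frozen=True)
class RadialGrid:
    r: np.ndarray  # node radii, r[0] = 0, r[-1] = outer radius (m)
    faces: np.ndarray  # control-volume face radii, length N+1
    region: np.ndarray  # region label per node (str array)
    boundaries: dict  # region -> (inner radius, outer radius)

    @property
    def n(self) -> int:
        return len(self.r)

    @property
    def volumes(self) -> np.ndarray:
        """Control-volume measures 4/3 pi (r_out^3 - r_in^3)."""
        return 4.0 / 3.0 * np.pi * np.diff(self.faces**3)

    @property
    def face_areas(self) -> np.ndarray:
        """4 pi r^2 at interior faces (length N+1; zero at the center)."""
        return 4.0 * np.pi * self.faces**2

    def region_weights(self, region: str) -> np.ndarray:
        """Exact overlap volume of each control volume with a region shell."""
        if region == "all":
            lo, hi = 0.0, self.faces[-1]
        elif region in self.boundaries:
            lo, hi = self.boundaries[region]
        else:
            raise ValueError(f"unknown region {region!r}")
        inner = np.clip(self.faces[:-1], lo, hi)
        outer = np.clip(self.faces[1:], lo, hi)
        return 4.0 / 3.0 * np.pi * np.maximum(outer**3 - inner**3, 0.0)

    def region_volume(self, region: str) -> float:
        return float(self.region_weights(region).sum())


@dataclass
class ScalarField:
    grid: RadialGrid
    values: np.ndarray
    name: str = ""
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n,):
            raise ValueError(
                f"field {self.name!r}: length {self.values.shape} does not "
                f"match grid ({self.grid.n} nodes)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"field {self.name!r} contains non-finite values")


def _graded_segment(r_lo: float, r_hi: float, n: int, grading: float,
                    refine: str) -> np.ndarray:
    """n+1 radii spanning [r_lo, r_hi] with optional refinement.

    ``refine`` is 'both', 'inner', 'outer' or 'none'; ``grading`` > 1
    concentrates nodes toward the refined end(s) via a tanh stretch.
    """
    s = np.linspace(0.0, 1.0, n + 1)
    if grading > 1.0 and refine != "none":
        g = np.tanh(grading)
        if refine == "both":
            s = 0.5 * (1.0 + np.tanh(grading * (2 * s - 1)) / g)
        elif refine == "inner":
            s = np.tanh(grading * s) / g
        else:  # outer
            s = 1.0 - np.tanh(grading * (1 - s)) / g
        s[0], s[-1] = 0.0, 1.0
    return r_lo + (r_hi - r_lo) * s


def build_grid(injection_radius: float, tumor_radius: float,
               outer_radius: float, n_injection: int = 20, n_tumor: int = 80,
               n_normal: int = 60, grading: float = 3.0) -> RadialGrid:
    """Build the nested spherical grid with interfaces exactly on nodes."""
    if not (0 < injection_radius < tumor_radius < outer_radius):
        raise ValueError("radii must satisfy 0 < injection < tumor < outer")
    if n_injection + n_tumor < 50:
        raise ValueError("at least 50 nodes are required across the tumor")
    seg_inj = _graded_segment(0.0, injection_radius, n_injection, grading, "outer")
    seg_tum = _graded_segment(injection_radius, tumor_radius, n_tumor, grading, "both")
    seg_nor = _graded_segment(tumor_radius, outer_radius, n_normal, grading, "inner")
    r = np.concatenate([seg_inj, seg_tum[1:], seg_nor[1:]])

    faces = np.empty(len(r) + 1)
    faces[0] = 0.0
    faces[-1] = outer_radius
    faces[1:-1] = 0.5 * (r[:-1] + r[1:])

    region = np.empty(len(r), dtype=object)
    region[r <= injection_radius] = "injection"
    region[(r > injection_radius) & (r <= tumor_radius)] = "tumor"
    region[r > tumor_radius] = "normal"

    boundaries = {
        "injection": (0.0, injection_radius),
        "tumor": (injection_radius, tumor_radius),
        "normal": (tumor_radius, outer_radius),
        # the whole malignant sphere: injection site plus tumor annulus;
        # "mean intratumoral" quantities average over this shell
        "malignant": (0.0, tumor_radius),
    }
    return RadialGrid(r=r, faces=faces, region=np.asarray(region),
                      boundaries=boundaries)


def volume_average(field: ScalarField | np.ndarray, grid_or_region=None,
                   region: str = "all") -> float:
    """Control-volume-weighted mean of a field over a region.

    Accepts either ``volume_average(ScalarField, region=...)`` or
    ``volume_average(values, grid, region)``.
    """
    if isinstance(field, ScalarField):
        grid = field.grid
        values = field.values
        if isinstance(grid_or_region, str):
            region = grid_or_region
    else:
        grid = grid_or_region
        values = np.asarray(field, dtype=float)
    weights = grid.region_weights(region)
    total = weights.sum()
    if total <= 0:
        raise ValueError(f"region {region!r} is empty")
    return float(np.dot(weights, values) / total)


def region_mask(grid: RadialGrid, inner: float, outer: float) -> np.ndarray:
    """Per-node overlap fraction of each control volume with [inner, outer].

    Used to localize sources (e.g. the MNP deposition zone) so that the
    deposited dose is independent of grid resolution.
    """
    lo = np.clip(grid.faces[:-1], inner, outer)
    hi = np.clip(grid.faces[1:], inner, outer)
    overlap = 4.0 / 3.0 * np.pi * np.maximum(hi**3 - lo**3, 0.0)
    return overlap / grid.volumes
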