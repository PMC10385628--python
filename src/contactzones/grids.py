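"""Regular 3-D scalar and vector fields with world-coordinate metadata.

Grids are axis-aligned, with an ``origin`` (world coordinates of voxel
``[0, 0, 0]``, in Angstrom) and per-axis ``spacing``.  Values are stored in
``(nx, ny, nz)`` C order; vector fields carry a trailing length-3 axis.
Volumetric export is provided in Gaussian cube (values converted to the
cube convention of Bohr-based coordinates) and CCP4/MRC formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular grid: origin (A), per-axis spacing (A), dims."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if any(d < 2 for d in self.dims):
            raise ValueError(f"grid needs >= 2 points per axis, got {self.dims}")

    @classmethod
    def around(
        cls,
        coords: np.ndarray,
        spacing: float = 0.2,
        margin: float = 4.0,
    ) -> "GridSpec":
        """Grid covering the bounding box of ``coords`` plus ``margin`` (A)."""
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        lo = coords.min(axis=0) - margin
        hi = coords.max(axis=0) + margin
        dims = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
        return cls(tuple(lo), (spacing,) * 3, dims)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing[k] * np.arange(self.dims[k])
            for k in range(3)
        )

    def points(self) -> np.ndarray:
        """All voxel centers as an ``(N, 3)`` array in C (x-major) order."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_points(self) -> int:
        return int(np.prod(self.dims))


@dataclass
class ScalarGrid:
    spec: GridSpec
    values: np.ndarray
    units: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.dims:
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.spec.dims}"
            )


@dataclass
class VectorGrid:
    spec: GridSpec
    values: np.ndarray  # (nx, ny, nz, 3)
    units: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.dims + (3,):
            raise ValueError(
                f"values shape {self.values.shape} != grid dims {self.spec.dims}+(3,)"
            )


def write_cube(grid: ScalarGrid, path, atoms=None, comment: str = "") -> None:
    """Write a Gaussian cube file (coordinates in Bohr, x fastest in voxels
    is z per the cube convention: outer loop x, inner loop z)."""
    spec = grid.spec
    b = BOHR_PER_ANGSTROM
    atoms = atoms or []
    with open(path, "w") as fh:
        fh.write((comment or "contactzones volumetric map") + "\n")
        fh.write(f"units: {grid.units or 'arbitrary'}\n")
        fh.write(
            f"{len(atoms):5d} {spec.origin[0]*b:12.6f} {spec.origin[1]*b:12.6f} "
            f"{spec.origin[2]*b:12.6f}\n"
        )
        for k in range(3):
            step = [0.0, 0.0, 0.0]
            step[k] = spec.spacing[k] * b
            fh.write(
                f"{spec.dims[k]:5d} {step[0]:12.6f} {step[1]:12.6f} {step[2]:12.6f}\n"
            )
        for a in atoms:
            z = getattr(a, "atomic_number", 0)
            p = np.asarray(a.position) * b
            fh.write(f"{z:5d} {0.0:12.6f} {p[0]:12.6f} {p[1]:12.6f} {p[2]:12.6f}\n")
        vals = grid.values
        for i in range(spec.dims[0]):
            for j in range(spec.dims[1]):
                row = vals[i, j, :]
                for start in range(0, len(row), 6):
                    fh.write(
                        " ".join(f"{v:13.5e}" for v in row[start : start + 6]) + "\n"
                    )


def write_ccp4(grid: ScalarGrid, path) -> None:
    """Write a CCP4/MRC map via gemmi (orthogonal cell, axis order X, Y, Z)."""
    import gemmi

    spec = grid.spec
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    # cell spans the full grid extent; origin recorded in the header start words
    m.grid.unit_cell = gemmi.UnitCell(
        spec.spacing[0] * spec.dims[0],
        spec.spacing[1] * spec.dims[1],
        spec.spacing[2] * spec.dims[2],
        90, 90, 90,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for k in range(3):
        m.set_header_i32(5 + k, int(round(spec.origin[k] / spec.spacing[k])))
    m.write_ccp4_map(str(path))
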