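"""Point-charge electrostatics and Nucleophilic Influence Zone mapping.

The potential of a set of partial charges is the bare Coulomb sum
``phi(r) = sum_i q_i / |r - r_i|`` in reduced units of e/A (multiply by
``COULOMB_KCAL`` for kcal/mol per unit test charge); the field is the
analytic gradient.  No dielectric screening is applied: this is a vacuum
point-charge model standing in for an aspherical multipolar description,
and every output records that substitution in its metadata.

A *Nucleophilic Influence Zone* (NIZ) of a nucleophilic atom is the region
of space whose electric-field lines — traced along the direction of the
force on a positive test charge — converge to that atom.  An electrophilic
(positively charged) group placed anywhere inside the zone is pulled toward
the nucleophile.  Basins are delineated by tracing a field line from every
voxel center of an analysis grid and labeling the voxel by the line's
terminal atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, ScalarGrid, VectorGrid
from .structure_io import AtomRecord, TypedModel

#: conversion of the reduced potential (e/A) to kcal/mol per elementary charge
COULOMB_KCAL = 332.0637

#: field magnitudes below this (reduced units) count as stagnation
FIELD_FLOOR = 1e-8

#: distance (A) below which a grid point counts as singular at a source
SINGULAR_RADIUS = 0.05

ESCAPED = -1
STAGNATED = -2
UNSEEDED = -3


@dataclass
class ChargedModel:
    """Atoms with point partial charges (elementary charges)."""

    atoms: list[AtomRecord]
    charges: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        if len(self.charges) != len(self.atoms):
            raise ValueError("one charge per atom required")
        if not np.all(np.isfinite(self.charges)):
            raise ValueError("charges must be finite")

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def __len__(self) -> int:
        return len(self.atoms)

    def without(self, exclude) -> "ChargedModel":
        """Copy with the selected atom indices removed (ligand exclusion)."""
        exclude = set(np.atleast_1d(exclude).tolist()) if exclude is not None else set()
        keep = [i for i in range(len(self.atoms)) if i not in exclude]
        if not keep:
            raise ValueError("exclusion removed every charged atom")
        return ChargedModel(
            [self.atoms[i] for i in keep],
            self.charges[keep],
            metadata=dict(self.metadata, excluded=sorted(exclude)),
        )


class ChargeAssignmentError(ValueError):
    pass


def assign_charges(
    model: TypedModel,
    charge_table: dict,
    overrides: dict[int, float] | None = None,
    strict: bool = False,
) -> ChargedModel:
    """Attach partial charges to a typed model by table lookup.

    Lookup precedence per atom: explicit ``overrides`` by atom id, then
    ``(residue_name, atom_name)`` tuple keys, then interaction-type string
    keys, then element symbols.  Unmatched atoms default to zero charge and
    are listed in the result metadata (``strict=True`` raises instead).
    """
    overrides = overrides or {}
    charges = np.zeros(len(model))
    unmatched: list[str] = []
    for i, (atom, itype) in enumerate(zip(model.atoms, model.types)):
        if atom.id in overrides:
            charges[i] = overrides[atom.id]
        elif (atom.residue_name, atom.name) in charge_table:
            charges[i] = charge_table[(atom.residue_name, atom.name)]
        elif itype in charge_table:
            charges[i] = charge_table[itype]
        elif atom.element.upper() in charge_table:
            charges[i] = charge_table[atom.element.upper()]
        elif atom.element.capitalize() in charge_table:
            charges[i] = charge_table[atom.element.capitalize()]
        else:
            unmatched.append(
                f"{atom.chain}/{atom.residue_number}/{atom.residue_name}/{atom.name}"
            )
    if unmatched and strict:
        raise ChargeAssignmentError(
            f"{len(unmatched)} atoms without a charge: {unmatched[:5]}..."
        )
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} atoms defaulted to zero charge", stacklevel=2
        )
    return ChargedModel(
        list(model.atoms),
        charges,
        metadata={"unmatched": unmatched, "model": "point charges, vacuum"},
    )


def _sources(model: ChargedModel, exclude=None):
    m = model.without(exclude) if exclude is not None else model
    if len(m) == 0:
        raise ValueError("no source atoms")
    return m.positions, m.charges


def potential(model: ChargedModel, points, exclude=None) -> np.ndarray:
    """Reduced Coulomb potential (e/A) at ``points`` (N, 3)."""
    pos, q = _sources(model, exclude)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=2)
    with np.errstate(divide="ignore"):
        return (q / d).sum(axis=1)


def electric_field(model: ChargedModel, points, exclude=None) -> np.ndarray:
    """Analytic field E = -grad(phi) = sum q (r - r_i)/|r - r_i|^3."""
    pos, q = _sources(model, exclude)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dvec = points[:, None, :] - pos[None, :, :]
    d = np.linalg.norm(dvec, axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.einsum("j,ijk->ik", q, dvec / d[:, :, None] ** 3)


def potential_and_field(
    model: ChargedModel, spec: GridSpec, exclude=None
) -> tuple[ScalarGrid, VectorGrid]:
    """Potential and field sampled on a grid; voxels within
    ``SINGULAR_RADIUS`` of a source are masked with NaN."""
    pos, q = _sources(model, exclude)
    pts = spec.points()
    d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)
    singular = (d < SINGULAR_RADIUS).any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (q / d).sum(axis=1)
        dvec = pts[:, None, :] - pos[None, :, :]
        e = np.einsum("j,ijk->ik", q, dvec / d[:, :, None] ** 3)
    phi[singular] = np.nan
    e[singular] = np.nan
    meta = {"units": "reduced e/A", "model": "point charges, vacuum"}
    return (
        ScalarGrid(spec, phi.reshape(spec.dims), units="e/A", metadata=meta),
        VectorGrid(spec, e.reshape(spec.dims + (3,)), units="e/A^2", metadata=meta),
    )


@dataclass
class FieldLine:
    """One traced electric-field line."""

    vertices: np.ndarray          # (n, 3)
    terminal: int | str           # atom index, "escaped" or "stagnated"
    arc_length: float


@dataclass
class TracerParams:
    step: float = 0.05            # RK4 step, A
    capture_radius: float = 0.4   # A, around every (non-excluded) atom
    max_length: float = 50.0      # A
    box: tuple | None = None      # ((lo3,), (hi3,)) domain; None = auto


def _trace_batch(
    starts: np.ndarray,
    pos: np.ndarray,
    q: np.ndarray,
    params: TracerParams,
    record_path: bool = False,
):
    """Trace many field lines at once with fixed-step RK4 on dr/ds = E/|E|.

    Returns (terminals, arc_lengths, paths).  Terminal codes: atom index
    into ``pos`` if captured, ESCAPED if the line left the domain box,
    STAGNATED on vanishing field or exhausted length budget.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))
    n = len(starts)
    if params.box is None:
        lo = pos.min(axis=0) - 2 * params.max_length
        hi = pos.max(axis=0) + 2 * params.max_length
    else:
        lo = np.asarray(params.box[0], dtype=float)
        hi = np.asarray(params.box[1], dtype=float)

    def unit_field(x):
        dvec = x[:, None, :] - pos[None, :, :]
        d = np.linalg.norm(dvec, axis=2)
        d = np.maximum(d, 1e-12)
        e = np.einsum("j,ijk->ik", q, dvec / d[:, :, None] ** 3)
        mag = np.linalg.norm(e, axis=1)
        return e / np.maximum(mag, 1e-300)[:, None], mag

    terminals = np.full(n, STAGNATED, dtype=int)
    r = starts.copy()
    active = np.ones(n, dtype=bool)
    paths = [[starts[i].copy()] for i in range(n)] if record_path else None
    arc = np.zeros(n)
    n_steps = int(np.ceil(params.max_length / params.step))
    h = params.step
    for _ in range(n_steps):
        if not active.any():
            break
        x = r[active]
        # capture / escape checks on current positions
        d = np.linalg.norm(x[:, None, :] - pos[None, :, :], axis=2)
        dmin = d.min(axis=1)
        captured = dmin < params.capture_radius
        escaped = ((x < lo) | (x > hi)).any(axis=1) & ~captured
        idx = np.nonzero(active)[0]
        if captured.any():
            terminals[idx[captured]] = d[captured].argmin(axis=1)
            active[idx[captured]] = False
        if escaped.any():
            terminals[idx[escaped]] = ESCAPED
            active[idx[escaped]] = False
        moving = ~captured & ~escaped
        if not moving.any():
            continue
        x = x[moving]
        k1, m1 = unit_field(x)
        stag = m1 < FIELD_FLOOR
        k2, _ = unit_field(x + 0.5 * h * k1)
        k3, _ = unit_field(x + 0.5 * h * k2)
        k4, _ = unit_field(x + h * k3)
        xn = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        mid = idx[moving]
        if stag.any():
            terminals[mid[stag]] = STAGNATED
            active[mid[stag]] = False
            xn[stag] = x[stag]
        r[mid] = xn
        arc[mid[~stag]] += h
        if record_path:
            for i, p in zip(mid[~stag], xn[~stag]):
                paths[i].append(p.copy())
    return terminals, arc, paths


def trace_field_line(
    start,
    model: ChargedModel,
    params: TracerParams | None = None,
    exclude=None,
) -> FieldLine:
    """Trace a single field line from ``start`` (A).

    Integrates dr/ds = E/|E| (direction of force on a positive test
    charge) with fixed-step 4th-order Runge-Kutta; terminates on capture by
    any atom, on leaving the domain box, or on stagnation (vanishing field
    or length budget).
    """
    params = params or TracerParams()
    pos, q = _sources(model, exclude)
    start = np.asarray(start, dtype=float)
    if np.linalg.norm(start - pos, axis=1).min() < params.capture_radius:
        raise ValueError("start point lies inside an atom's capture radius")
    terms, arcs, paths = _trace_batch(
        start[None, :], pos, q, params, record_path=True
    )
    term = int(terms[0])
    terminal = (
        term if term >= 0 else ("escaped" if term == ESCAPED else "stagnated")
    )
    return FieldLine(np.array(paths[0]), terminal, float(arcs[0]))


@dataclass
class NIZMap:
    """Per-voxel field-line basin labels over an analysis grid.

    Labels: index of the terminal atom (>= 0), or ESCAPED / STAGNATED /
    UNSEEDED codes.  ``volumes`` reports voxel-count volumes (A^3) per
    target atom plus the escaped/stagnated/other-sink pools.
    """

    spec: GridSpec
    labels: np.ndarray
    targets: list[int]
    volumes: dict
    params: TracerParams
    metadata: dict = field(default_factory=dict)

    @property
    def seeded(self) -> np.ndarray:
        return self.labels != UNSEEDED

    def basin_fraction(self, target: int) -> float:
        n_seeded = int(self.seeded.sum())
        return float((self.labels == target).sum()) / max(n_seeded, 1)

    def to_scalar_grid(self) -> ScalarGrid:
        return ScalarGrid(
            self.spec, self.labels.astype(float), units="basin label",
            metadata=dict(self.metadata),
        )

    def summary(self) -> dict:
        return {
            "targets": {str(t): self.volumes[t] for t in self.targets},
            "other_sink": self.volumes["other_sink"],
            "escaped": self.volumes["escaped"],
            "stagnated": self.volumes["stagnated"],
            "voxel_volume_A3": self.spec.voxel_volume,
            "n_seeded": int(self.seeded.sum()),
            "metadata": self.metadata,
        }


def niz_map(
    model: ChargedModel,
    targets,
    spec: GridSpec | None = None,
    spacing: float = 0.5,
    margin: float = 4.0,
    params: TracerParams | None = None,
    exclude=None,
) -> NIZMap:
    """Delineate nucleophilic influence zones on a grid.

    A field line is traced from every voxel center outside the atoms'
    capture radii; the voxel is labeled by the terminal atom (or escaped /
    stagnated).  ``targets`` are indices into the model's atom list (after
    exclusion the indices refer to the reduced atom list of the traced
    model); per-target basin volumes are voxel counts times voxel volume.
    """
    params = params or TracerParams()
    m = model.without(exclude) if exclude is not None else model
    targets = [int(t) for t in np.atleast_1d(targets)]
    if not targets:
        raise ValueError("no target atoms given")
    if any(t < 0 or t >= len(m) for t in targets):
        raise ValueError("target index out of range")
    pos, q = m.positions, m.charges
    if spec is None:
        spec = GridSpec.around(pos, spacing=spacing, margin=margin)
    if params.box is None:
        pad = np.asarray(spec.spacing)
        params = TracerParams(
            params.step,
            params.capture_radius,
            params.max_length,
            (
                tuple(np.asarray(spec.origin) - pad),
                tuple(
                    np.asarray(spec.origin)
                    + np.asarray(spec.spacing) * (np.asarray(spec.dims) - 1)
                    + pad
                ),
            ),
        )
    pts = spec.points()
    d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=2)
    seed_mask = d.min(axis=1) >= params.capture_radius
    labels = np.full(spec.n_points, UNSEEDED, dtype=int)
    terms, _, _ = _trace_batch(pts[seed_mask], pos, q, params)
    labels[seed_mask] = terms
    vol = spec.voxel_volume
    volumes = {t: float((labels == t).sum()) * vol for t in targets}
    other = (labels >= 0) & ~np.isin(labels, targets)
    volumes["other_sink"] = float(other.sum()) * vol
    volumes["escaped"] = float((labels == ESCAPED).sum()) * vol
    volumes["stagnated"] = float((labels == STAGNATED).sum()) * vol
    return NIZMap(
        spec,
        labels.reshape(spec.dims),
        targets,
        volumes,
        params,
        metadata={"model": "point charges, vacuum"},
    )


def fieldlines_to_pdb(lines: list[FieldLine], path) -> None:
    """Export traced polylines as pseudo-atom PDB traces for visualization."""
    with open(path, "w") as fh:
        serial = 0
        for li, line in enumerate(lines):
            chain = chr(ord("A") + (li % 26))
            for vi, v in enumerate(line.vertices):
                serial += 1
                fh.write(
                    f"HETATM{serial:5d}  Q   FLN {chain}{vi + 1:4d}    "
                    f"{v[0]:8.3f}{v[1]:8.3f}{v[2]:8.3f}  1.00  0.00"
                    f"          He\n"
                )
        fh.write("END\n")
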