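"""Spherical-atom (promolecule) electron densities and Hirshfeld weights.

The promolecule density of a molecule is the superposition of spherically
averaged, non-interacting atomic densities placed at the nuclear positions.
Per-element radial densities are stored as sums of exponentials,
``rho_elem(r) = sum_k c_k exp(-z_k r)`` (e/A^3, r in A), loaded from a
plain-text table shipped with the package; the table's header records its
provenance.  Atomic contributions are occupancy-weighted.

The Hirshfeld weight of side A against side B at a point is
``w = rho_A / (rho_A + rho_B)``; the w = 0.5 locus is the Hirshfeld
interface between the two moieties (see :mod:`contactzones.hirshfeld`).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.integrate import quad

from .grids import GridSpec, ScalarGrid

#: densities smaller than this are treated as numerically absent
DENSITY_FLOOR = 1e-30


class UnknownElementError(KeyError):
    pass


@lru_cache(maxsize=1)
def load_density_table() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Parse the shipped exponential-density table.

    Returns a map ``element -> (coefficients, exponents)``.
    """
    table: dict[str, tuple[list, list]] = {}
    text = (
        resources.files("contactzones.data")
        .joinpath("atomic_densities.txt")
        .read_text()
    )
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        el, c, z = line.split()
        table.setdefault(el, ([], []))
        table[el][0].append(float(c))
        table[el][1].append(float(z))
    return {el: (np.array(c), np.array(z)) for el, (c, z) in table.items()}


def available_elements() -> tuple[str, ...]:
    return tuple(load_density_table())


def _coeffs(element: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        return load_density_table()[element.capitalize()]
    except KeyError:
        raise UnknownElementError(
            f"no atomic density for element {element!r}; available: "
            f"{sorted(load_density_table())}"
        ) from None


def atomic_density(element: str, r) -> np.ndarray | float:
    """Spherically averaged atomic density (e/A^3) at distance ``r`` (A).

    Strictly positive and strictly decreasing in r.
    """
    c, z = _coeffs(element)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    out = np.exp(-np.multiply.outer(r, z)) @ c
    return float(out) if out.ndim == 0 else out


def electron_count(element: str, r_max: float = 40.0) -> float:
    """Quadrature of 4*pi*rho*r^2; equals the element's electron count."""
    val, _ = quad(lambda r: 4 * np.pi * atomic_density(element, r) * r * r,
                  0.0, r_max, limit=200)
    return val


def _positions_occ_elements(model):
    """Coordinates (n,3), occupancies (n,) and element list of a model-like
    object (TypedModel, ChargedModel or plain AtomRecord sequence)."""
    atoms = getattr(model, "atoms", model)
    if len(atoms) == 0:
        raise ValueError("empty model")
    pos = np.array([np.asarray(a.position, dtype=float) for a in atoms])
    occ = np.array([a.occupancy for a in atoms])
    els = [a.element for a in atoms]
    return pos, occ, els


def promolecule_density(model, points: np.ndarray) -> np.ndarray:
    """Occupancy-weighted promolecule density (e/A^3) at ``points`` (N, 3).

    Zero-occupancy atoms are skipped.
    """
    pos, occ, els = _positions_occ_elements(model)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros(len(points))
    for p, q, el in zip(pos, occ, els):
        if q == 0.0:
            continue
        r = np.linalg.norm(points - p, axis=1)
        out += q * atomic_density(el, r)
    return out


def per_atom_density(model, points: np.ndarray) -> np.ndarray:
    """Individual occupancy-weighted atomic contributions.

    Returns an ``(n_atoms, n_points)`` array; rows of zero-occupancy atoms
    are zero.
    """
    pos, occ, els = _positions_occ_elements(model)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros((len(pos), len(points)))
    for i, (p, q, el) in enumerate(zip(pos, occ, els)):
        if q == 0.0:
            continue
        r = np.linalg.norm(points - p, axis=1)
        out[i] = q * atomic_density(el, r)
    return out


def promolecule_on_grid(
    model,
    spec: GridSpec | None = None,
    spacing: float = 0.2,
    margin: float = 4.0,
) -> ScalarGrid:
    """Promolecule density sampled on a regular grid.

    If ``spec`` is omitted, a grid with the given spacing covering the model
    bounding box plus ``margin`` (A) is built.
    """
    pos, _, _ = _positions_occ_elements(model)
    if spec is None:
        spec = GridSpec.around(pos, spacing=spacing, margin=margin)
    ax, ay, az = spec.axes()
    values = np.zeros(spec.dims)
    atoms = getattr(model, "atoms", model)
    for a in atoms:
        if a.occupancy == 0.0:
            continue
        p = np.asarray(a.position, dtype=float)
        c, z = _coeffs(a.element)
        # atoms contribute only inside the radius where their density
        # exceeds ~1e-18 e/A^3 — far below any density of interest, so the
        # truncation never shows up even at tight relative tolerances
        r_max = float(np.max(np.log(np.maximum(c, 1.0) / (1e-18 / len(c))) / z))
        sl = []
        for axis, x0 in zip((ax, ay, az), p):
            idx = np.nonzero(np.abs(axis - x0) <= r_max)[0]
            if idx.size == 0:
                sl = None
                break
            sl.append(slice(idx[0], idx[-1] + 1))
        if sl is None:
            continue
        d2 = (
            ((ax[sl[0]] - p[0]) ** 2)[:, None, None]
            + ((ay[sl[1]] - p[1]) ** 2)[None, :, None]
            + ((az[sl[2]] - p[2]) ** 2)[None, None, :]
        )
        r = np.sqrt(d2)
        acc = np.zeros(r.shape)
        for ck, zk in zip(c, z):
            acc += ck * np.exp(-zk * r)
        values[tuple(sl)] += a.occupancy * acc
    return ScalarGrid(spec, values, units="e/A^3",
                      metadata={"model": "spherical promolecule"})


def hirshfeld_weight(model_a, model_b, points: np.ndarray) -> np.ndarray:
    """Hirshfeld weight of side A, ``w = rho_a / (rho_a + rho_b)``.

    Raises if the total density is numerically zero at any requested point.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rho_a = promolecule_density(model_a, points)
    rho_b = promolecule_density(model_b, points)
    total = rho_a + rho_b
    if np.any(total < DENSITY_FLOOR):
        bad = np.argmax(total < DENSITY_FLOOR)
        raise ValueError(
            f"Hirshfeld weight undefined at point {points[bad]}: "
            f"total promolecule density < {DENSITY_FLOOR:g}"
        )
    return rho_a / total
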