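"""Seeded generators for every fixture class the analyses need.

All generators draw from one :class:`numpy.random.Generator` created from
the integer seed passed in — no global state — so any fixture is exactly
reproducible.  Fixture kinds:

* two-atom complexes with an analytically known (bisector-plane) interface;
* composition-controlled random complexes in two abutting half-boxes, used
  for the random-mixing null of the enrichment statistics (independent type
  draws make every enrichment ratio converge to 1);
* jittered-lattice complexes that stay packable at high atom counts;
* synthetic interface patch sets with independently drawn facet types (the
  facet-level enrichment null);
* point-charge systems with known field-line basins;
* per-atom isotropic Gaussian positional ensembles with specified sigma.
"""

from __future__ import annotations

import numpy as np

from .electrostatics import ChargedModel
from .flucts import Ensemble
from .hirshfeld import InterfacePatchSet
from .structure_io import AtomRecord, TypedModel, INTERACTION_TYPES

#: element carrying each interaction type in generated fixtures
TYPE_ELEMENTS = {"C": "C", "Hc": "H", "N": "N", "Ho/n": "H", "O": "O", "W": "O"}


def _atom(i, element, pos, chain="A", resnum=None, name=None, resname="UNK",
          occ=1.0, b=0.0):
    return AtomRecord(
        id=i,
        element=element,
        name=name or element,
        residue_name=resname,
        residue_number=resnum if resnum is not None else i,
        chain=chain,
        position=tuple(pos),
        occupancy=occ,
        b_factor=b,
    )


def make_two_atom_complex(
    element: str = "C", distance: float = 3.0
) -> tuple[TypedModel, TypedModel]:
    """Two single-atom models on the x-axis at +/- distance/2.

    For equal elements the Hirshfeld interface is exactly the x = 0 plane.
    """
    if distance <= 0:
        raise ValueError(f"distance must be positive, got {distance}")
    itype = {"H": "Hc", "C": "C", "N": "N", "O": "O"}.get(element, "C")
    a = _atom(1, element, (-distance / 2, 0.0, 0.0), chain="A")
    b = _atom(2, element, (+distance / 2, 0.0, 0.0), chain="B")
    return (
        TypedModel([a], [itype], side="a"),
        TypedModel([b], [itype], side="b"),
    )


def _draw_types(rng, composition: dict[str, float], n: int) -> list[str]:
    types = list(composition)
    bad = set(types) - set(INTERACTION_TYPES)
    if bad:
        raise ValueError(f"unknown interaction types in composition: {bad}")
    p = np.array([composition[t] for t in types], dtype=float)
    if np.any(p < 0):
        raise ValueError("composition percentages must be non-negative")
    # tolerance admits published one-decimal-rounded compositions
    if abs(p.sum() - 100.0) > 0.5:
        raise ValueError(f"composition must sum to 100, got {p.sum()}")
    return [types[i] for i in rng.choice(len(types), size=n, p=p / p.sum())]


def _pack_half_box(rng, n, box, min_sep, x_offset, max_attempts=200):
    """Uniform positions in [x_offset, x_offset+box/2] x [0,box]^2 with a
    minimum pairwise separation, by bounded rejection sampling."""
    placed = np.empty((0, 3))
    for _ in range(max_attempts):
        need = n - len(placed)
        cand = rng.uniform(0, 1, size=(max(4 * need, 16), 3))
        cand[:, 0] = x_offset + cand[:, 0] * (box / 2)
        cand[:, 1:] *= box
        for p in cand:
            if len(placed) and np.linalg.norm(placed - p, axis=1).min() < min_sep:
                continue
            placed = np.vstack([placed, p])
            if len(placed) == n:
                return placed
    raise RuntimeError(
        f"could not place {n} atoms with min_sep={min_sep} in half-box "
        f"{box / 2}x{box}x{box}; try a larger box"
    )


def make_random_complex(
    n_per_side: int,
    composition: dict[str, float],
    box: float = 20.0,
    min_sep: float = 1.5,
    seed: int = 0,
    composition_b: dict[str, float] | None = None,
) -> tuple[TypedModel, TypedModel]:
    """Two random models in abutting half-boxes sharing the x = box/2 wall.

    Atom types are independent draws from the composition (side b may have
    its own); positions are uniform with ``min_sep`` enforced within each
    side.  Fully reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = []
    for side, comp, x0 in (
        ("a", composition, 0.0),
        ("b", composition_b or composition, box / 2),
    ):
        types = _draw_types(rng, comp, n_per_side)
        pos = _pack_half_box(rng, n_per_side, box, min_sep, x0)
        atoms = [
            _atom(i + 1, TYPE_ELEMENTS[t], p, chain="A" if side == "a" else "B",
                  resname="HOH" if t == "W" else "UNK")
            for i, (t, p) in enumerate(zip(types, pos))
        ]
        out.append(TypedModel(atoms, types, side=side))
    return out[0], out[1]


def make_lattice_complex(
    n_per_side: int,
    composition: dict[str, float],
    lattice_spacing: float = 2.0,
    jitter: float = 0.3,
    seed: int = 0,
) -> tuple[TypedModel, TypedModel]:
    """Jittered-lattice variant of the random complex; packing is feasible
    at any n because sites start on a cubic lattice."""
    rng = np.random.default_rng(seed)
    side_len = int(np.ceil(n_per_side ** (1 / 3)))
    grid = np.array(
        [
            (i, j, k)
            for i in range(side_len)
            for j in range(side_len)
            for k in range(side_len)
        ],
        dtype=float,
    )[:n_per_side]
    out = []
    for side, x0 in (("a", 0.0), ("b", (side_len + 1) * lattice_spacing)):
        types = _draw_types(rng, composition, n_per_side)
        pos = grid * lattice_spacing + rng.uniform(
            -jitter, jitter, size=(n_per_side, 3)
        )
        pos[:, 0] += x0
        atoms = [
            _atom(i + 1, TYPE_ELEMENTS[t], p, chain="A" if side == "a" else "B",
                  resname="HOH" if t == "W" else "UNK")
            for i, (t, p) in enumerate(zip(types, pos))
        ]
        out.append(TypedModel(atoms, types, side=side))
    return out[0], out[1]


def make_random_patchset(
    n_facets: int,
    composition_a: dict[str, float],
    composition_b: dict[str, float],
    seed: int = 0,
    equal_areas: bool = True,
) -> InterfacePatchSet:
    """Synthetic interface whose facet types are independent draws from the
    stated side compositions — the exact null of the enrichment statistic,
    where every E converges to 1 as n_facets grows."""
    rng = np.random.default_rng(seed)
    t_in = np.array(_draw_types(rng, composition_a, n_facets), dtype=object)
    t_out = np.array(_draw_types(rng, composition_b, n_facets), dtype=object)
    areas = (
        np.ones(n_facets)
        if equal_areas
        else rng.uniform(0.5, 1.5, size=n_facets)
    )
    return InterfacePatchSet(
        areas=areas,
        type_in=t_in,
        type_out=t_out,
        atom_in=np.arange(n_facets),
        atom_out=np.arange(n_facets),
        metadata={"synthetic": True, "seed": seed},
    )


def make_charge_system(spec: list[tuple]) -> ChargedModel:
    """Literal point-charge construction from ``[(position, q), ...]``.

    Atoms are placed as oxygen (negative or zero q) / nitrogen (positive q)
    pseudo-atoms; only positions and charges matter to the tracer.
    """
    atoms, charges = [], []
    for i, (pos, q) in enumerate(spec, start=1):
        if not np.isfinite(q):
            raise ValueError(f"charge {i} is not finite")
        el = "N" if q > 0 else "O"
        atoms.append(_atom(i, el, pos, chain="Q", resname="CHG"))
        charges.append(float(q))
    return ChargedModel(atoms, np.array(charges),
                        metadata={"synthetic": True})


def make_gaussian_ensemble(
    model,
    sigma: float | np.ndarray,
    n_frames: int,
    seed: int = 0,
    frame_interval: float | None = None,
) -> Ensemble:
    """Frames = model coordinates + i.i.d. isotropic Gaussian displacements.

    ``sigma`` is the per-coordinate standard deviation in A, scalar or
    per-atom; the expected isotropic RMSF is sigma * sqrt(3).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    atoms = getattr(model, "atoms", model)
    base = np.array([a.position for a in atoms], dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (len(atoms),))
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(n_frames, len(atoms), 3)) * sigma[None, :, None]
    return Ensemble(
        base[None, :, :] + noise,
        atoms=list(atoms),
        frame_interval=frame_interval,
        metadata={"synthetic": True, "seed": seed},
    )
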