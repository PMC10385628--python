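"""Molecular model I/O, chemical interaction typing, residue contacts and
sequence isoelectric points.

Structures are read with gemmi (PDB and mmCIF, author numbering preserved)
into plain :class:`AtomRecord` lists grouped by chain.  Interaction typing
follows a six-class scheme used for interface statistics:

====== =====================================================================
type   meaning
====== =====================================================================
C      carbon
Hc     hydrogen covalently bonded to carbon (apolar)
N      nitrogen (sp2 peptide/guanidinium N without a lone pair is counted
       hydrophobic; an override list can mark chosen N atoms hydrophilic)
Ho/n   hydrogen bonded to nitrogen or oxygen (polar, electropositive)
O      oxygen (non-water)
W      oxygen of a water molecule (waters carry no hydrogens in this scheme)
====== =====================================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

INTERACTION_TYPES = ("C", "Hc", "N", "Ho/n", "O", "W")

WATER_RESIDUES = {"HOH", "WAT", "H2O", "DOD", "TIP3"}

#: single-bond covalent radii (A), sufficient for protein/peptide chemistry
COVALENT_RADII = {
    "H": 0.31, "D": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "P": 1.07,
    "S": 1.05, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39, "SE": 1.20,
    "NA": 1.66, "MG": 1.41, "K": 2.03, "CA": 1.76, "ZN": 1.22, "FE": 1.32,
    "MN": 1.39, "CU": 1.32,
}

ATOMIC_NUMBERS = {
    "H": 1, "D": 1, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "CU": 29, "ZN": 30, "SE": 34, "BR": 35, "I": 53,
}

#: neutron-normalized X-H bond lengths (A) used when placing riding hydrogens
XH_BOND_LENGTHS = {"C": 1.083, "N": 1.009, "O": 0.967, "S": 1.338}

#: default elements mapped onto the six-type scheme beyond the literal ones;
#: sulfur is apolar and grouped with carbon
DEFAULT_ELEMENT_TYPES = {"S": "C", "SE": "C", "P": "C"}


class StructureParseError(ValueError):
    pass


class UnknownElementError(ValueError):
    pass


class TypingError(ValueError):
    pass


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a crystallographic or synthetic model."""

    id: int
    element: str
    name: str
    residue_name: str
    residue_number: int
    chain: str
    position: tuple[float, float, float]
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"atom {self.id} ({self.name}): occupancy {self.occupancy} "
                "outside [0, 1]"
            )
        if self.b_factor < 0:
            raise ValueError(
                f"atom {self.id} ({self.name}): negative B-factor {self.b_factor}"
            )
        el = self.element.upper()
        if el not in ATOMIC_NUMBERS:
            raise UnknownElementError(
                f"atom {self.id} ({self.name} in {self.residue_name} "
                f"{self.chain}/{self.residue_number}): unknown element "
                f"{self.element!r}"
            )
        object.__setattr__(self, "position", tuple(float(x) for x in self.position))

    @property
    def atomic_number(self) -> int:
        return ATOMIC_NUMBERS[self.element.upper()]

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_RESIDUES

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.residue_name)


@dataclass
class TypedModel:
    """Atoms plus one interaction type each and a molecule-side label."""

    atoms: list[AtomRecord]
    types: list[str]
    side: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) != len(self.types):
            raise ValueError("one interaction type per atom required")
        bad = sorted(set(self.types) - set(INTERACTION_TYPES))
        if bad:
            raise ValueError(f"unknown interaction types {bad}")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    def type_counts(self) -> dict[str, int]:
        out = {t: 0 for t in INTERACTION_TYPES}
        for t in self.types:
            out[t] += 1
        return out

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "atom_id": [a.id for a in self.atoms],
                "name": [a.name for a in self.atoms],
                "residue": [
                    f"{a.chain}/{a.residue_number}/{a.residue_name}"
                    for a in self.atoms
                ],
                "type": self.types,
                "side": self.side,
            }
        )


@dataclass(frozen=True)
class ResidueContact:
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    min_distance: float
    is_hbond: bool


@dataclass
class StructureModel:
    """Atom records grouped by chain (one coordinate model)."""

    chains: dict[str, list[AtomRecord]]
    name: str = ""

    @property
    def atoms(self) -> list[AtomRecord]:
        return [a for ch in self.chains.values() for a in ch]

    def chain(self, chain_id: str) -> list[AtomRecord]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"no chain {chain_id!r}; available: {sorted(self.chains)}"
            ) from None


# ---------------------------------------------------------------------------
# reading and writing


def _gemmi_to_models(st) -> list[StructureModel]:
    models = []
    for mi, model in enumerate(st):
        chains: dict[str, list[AtomRecord]] = {}
        serial = 0
        for chain in model:
            records = chains.setdefault(chain.name, [])
            for res in chain:
                for atom in res:
                    serial += 1
                    el = atom.element.name
                    if not el or el == "X":
                        raise UnknownElementError(
                            f"atom {atom.name} in {res.name} "
                            f"{chain.name}/{res.seqid.num}: element not "
                            "recognized"
                        )
                    records.append(
                        AtomRecord(
                            id=atom.serial if atom.serial else serial,
                            element=el,
                            name=atom.name,
                            residue_name=res.name,
                            residue_number=res.seqid.num,
                            chain=chain.name,
                            position=(atom.pos.x, atom.pos.y, atom.pos.z),
                            occupancy=atom.occ,
                            b_factor=atom.b_iso,
                            altloc=atom.altloc if atom.altloc != "\x00" else "",
                        )
                    )
        models.append(StructureModel(chains, name=f"{st.name}:{mi + 1}"))
    return models


def _read_gemmi(path, format: str = "auto"):
    import gemmi

    fmt = {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }[format]
    try:
        return gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc


def read_structure(path, format: str = "auto") -> StructureModel:
    """Read the first coordinate model of a PDB/mmCIF file.

    Author chain identifiers and residue numbering are preserved, all
    ATOM/HETATM records (including alternate locations) are returned.
    """
    models = _gemmi_to_models(_read_gemmi(path, format))
    if not models:
        raise StructureParseError(f"{path}: no coordinate model found")
    return models[0]


def read_ensemble(path, format: str = "auto") -> list[StructureModel]:
    """Read all models of a (multi-model) PDB/mmCIF file, in file order."""
    models = _gemmi_to_models(_read_gemmi(path, format))
    if not models:
        raise StructureParseError(f"{path}: no coordinate model found")
    return models


def _pdb_atom_line(a: AtomRecord, serial: int) -> str:
    record = "HETATM" if a.is_water else "ATOM  "
    name = a.name
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    x, y, z = a.position
    return (
        f"{record}{serial:5d} {name:<4s}{a.altloc or ' ':1s}"
        f"{a.residue_name:>3s} {a.chain[:1]:1s}{a.residue_number:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{a.b_factor:6.2f}"
        f"          {a.element.upper():>2s}"
    )


def write_pdb(models, path) -> None:
    """Write atoms (or a list of models, as a multi-model file) to PDB.

    Accepts an AtomRecord sequence, a StructureModel, a TypedModel, or a
    list of any of these (written as MODEL/ENDMDL blocks).
    """

    def atoms_of(m):
        if isinstance(m, StructureModel):
            return m.atoms
        if isinstance(m, TypedModel):
            return m.atoms
        return list(m)

    multi = isinstance(models, list) and models and not isinstance(
        models[0], AtomRecord
    )
    blocks = [atoms_of(m) for m in models] if multi else [atoms_of(models)]
    with open(path, "w") as fh:
        for bi, atoms in enumerate(blocks):
            if multi:
                fh.write(f"MODEL     {bi + 1:4d}\n")
            for i, a in enumerate(atoms, start=1):
                fh.write(_pdb_atom_line(a, i) + "\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def dedupe_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom site: highest occupancy, ties broken by
    alphabetic altloc (so 'A' wins)."""
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in atoms:
        key = (a.chain, a.residue_number, a.residue_name, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, b.altloc or "~") > (b.occupancy, a.altloc or "~"):
                best[key] = a
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# bonds and typing


def covalent_bonds(
    atoms: list[AtomRecord], tolerance: float = 0.4
) -> list[tuple[int, int]]:
    """Bonds inferred from element-pair distances: bonded if
    d <= r_cov(a) + r_cov(b) + tolerance.  Returns index pairs (i < j)."""
    if not atoms:
        return []
    pos = np.array([a.position for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element.upper(), 1.5) for a in atoms])
    tree = cKDTree(pos)
    rmax = 2 * radii.max() + tolerance
    bonds = []
    for i, j in tree.query_pairs(rmax):
        d = np.linalg.norm(pos[i] - pos[j])
        if d <= radii[i] + radii[j] + tolerance and d > 1e-6:
            bonds.append((min(i, j), max(i, j)))
    return sorted(bonds)


def assign_interaction_types(
    atoms,
    side: str = "",
    bonds: list[tuple[int, int]] | None = None,
    hydrophilic_nitrogens: set[tuple[str, int, str]] | None = None,
    element_types: dict[str, str] | None = None,
    drop_water_hydrogens: bool = True,
) -> TypedModel:
    """Assign one of {C, Hc, N, Ho/n, O, W} to every atom.

    Hydrogens are typed by the element of their bonded heavy atom (bonds are
    inferred by distance unless supplied).  Water oxygens become W; waters
    carry no hydrogens in this scheme, so their hydrogens are dropped by
    default.  All nitrogens are typed N (hydrophobic in the grouped
    statistics) unless listed in ``hydrophilic_nitrogens`` by
    ``(chain, residue_number, atom_name)`` — those are still typed N but the
    flag is honored by the grouped summary via per-call grouping overrides.
    Elements outside the literal scheme are mapped via ``element_types``
    (default: S/Se/P treated as carbon-like apolar atoms).
    """
    if isinstance(atoms, StructureModel):
        atoms = atoms.atoms
    atoms = list(atoms)
    if drop_water_hydrogens:
        atoms = [a for a in atoms if not (a.is_water and a.element.upper() in ("H", "D"))]
    emap = dict(DEFAULT_ELEMENT_TYPES)
    if element_types:
        emap.update({k.upper(): v for k, v in element_types.items()})
    if bonds is None:
        bonds = covalent_bonds(atoms)
    neighbors: dict[int, list[int]] = {}
    for i, j in bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)

    types: list[str] = []
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if a.is_water:
            if el != "O":
                raise TypingError(
                    f"water residue atom {a.name} ({a.chain}/{a.residue_number})"
                    f" has element {a.element}; only bare oxygen is supported"
                )
            types.append("W")
        elif el in ("H", "D"):
            heavies = [
                atoms[j] for j in neighbors.get(i, [])
                if atoms[j].element.upper() not in ("H", "D")
            ]
            if not heavies:
                raise TypingError(
                    f"hydrogen {a.name} ({a.chain}/{a.residue_number}/"
                    f"{a.residue_name}) has no bonded heavy atom within the "
                    "covalent-distance tolerance"
                )
            # nearest bonded heavy atom decides polarity
            p = np.asarray(a.position)
            heavy = min(
                heavies, key=lambda h: np.linalg.norm(np.asarray(h.position) - p)
            )
            types.append("Ho/n" if heavy.element.upper() in ("N", "O") else "Hc")
        elif el == "C":
            types.append("C")
        elif el == "N":
            types.append("N")
        elif el == "O":
            types.append("O")
        elif el in emap:
            types.append(emap[el])
        else:
            raise TypingError(
                f"no interaction type for element {a.element} "
                f"(atom {a.name}, {a.chain}/{a.residue_number})"
            )
    return TypedModel(atoms, types, side=side)


def place_riding_hydrogens(
    atoms: list[AtomRecord], bonds: list[tuple[int, int]] | None = None
) -> list[AtomRecord]:
    """Complete missing hydrogens at idealized riding positions.

    Heuristic valence completion for protein-like chemistry: implicit
    hydrogen counts come from element valences (C 4, N 3, O 2) minus the
    number of covalent neighbors, with sp2 corrections (carbonyl and
    carboxylate carbons get none; amide/ring nitrogens with two heavy
    neighbors get one in-plane hydrogen).  X-H bond lengths use
    neutron-normalized values (C-H 1.083, N-H 1.009, O-H 0.967 A).  Waters
    are left bare.  Intended for completing mostly-protonated models, not as
    a protonation-state predictor.
    """
    atoms = list(atoms)
    if bonds is None:
        bonds = covalent_bonds(atoms)
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(atoms))}
    for i, j in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)
    pos = np.array([a.position for a in atoms])

    out = list(atoms)
    next_id = max((a.id for a in atoms), default=0)
    valence = {"C": 4, "N": 3, "O": 2}
    for i, a in enumerate(atoms):
        el = a.element.upper()
        if el not in valence or a.is_water:
            continue
        heavy = [j for j in neighbors[i] if atoms[j].element.upper() not in ("H", "D")]
        hyd = [j for j in neighbors[i] if atoms[j].element.upper() in ("H", "D")]
        n_h = valence[el] - len(heavy) - len(hyd)
        if el == "C" and any(
            atoms[j].element.upper() == "O"
            and np.linalg.norm(pos[i] - pos[j]) < 1.30
            for j in heavy
        ):
            n_h = max(0, 3 - len(heavy) - len(hyd))  # sp2 carbonyl/carboxylate C
        if el == "O" and any(
            atoms[j].element.upper() == "C"
            and np.linalg.norm(pos[i] - pos[j]) < 1.30
            for j in heavy
        ):
            n_h = 0  # carbonyl oxygen (C=O), no proton
        if el == "N" and len(heavy) >= 2:
            n_h = max(0, 3 - len(heavy) - len(hyd))  # amide / ring N, one planar H
        if n_h <= 0:
            continue
        length = XH_BOND_LENGTHS.get(el, 1.0)
        existing = [pos[j] for j in heavy + hyd]
        if existing:
            away = pos[i] - np.mean(existing, axis=0)
            nrm = np.linalg.norm(away)
            axis = away / nrm if nrm > 1e-8 else np.array([0.0, 0.0, 1.0])
        else:
            axis = np.array([0.0, 0.0, 1.0])
        if n_h == 1:
            directions = [axis]
        else:
            # cone around the mean-repulsion axis: 109.5 deg H-X-H for two
            # hydrogens, methyl-like spread for three
            tilt = math.radians(54.75 if n_h == 2 else 70.5)
            perp1 = np.cross(axis, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp1) < 1e-6:
                perp1 = np.cross(axis, [0.0, 1.0, 0.0])
            perp1 /= np.linalg.norm(perp1)
            perp2 = np.cross(axis, perp1)
            directions = [
                math.cos(tilt) * axis
                + math.sin(tilt) * (
                    math.cos(2 * math.pi * k / n_h) * perp1
                    + math.sin(2 * math.pi * k / n_h) * perp2
                )
                for k in range(n_h)
            ]
        for k, direction in enumerate(directions):
            next_id += 1
            hpos = pos[i] + length * direction
            out.append(
                AtomRecord(
                    id=next_id,
                    element="H",
                    name=f"H{a.name}"[:4] if n_h == 1 else f"H{a.name[:2]}{k + 1}"[:4],
                    residue_name=a.residue_name,
                    residue_number=a.residue_number,
                    chain=a.chain,
                    position=tuple(hpos),
                    occupancy=a.occupancy,
                    b_factor=a.b_factor,
                )
            )
            existing.append(hpos)
    return out


# ---------------------------------------------------------------------------
# residue contacts


def residue_contacts(
    model_a,
    model_b,
    cutoff: float = 4.0,
    hbond_distance: float = 3.5,
) -> list[ResidueContact]:
    """All residue pairs with any interatomic distance below ``cutoff`` (A).

    Each pair appears once with its minimum distance; the hydrogen-bond flag
    marks pairs with an N/O...N/O distance below ``hbond_distance``
    (a distance-only donor-acceptor criterion).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    atoms_a = model_a.atoms if hasattr(model_a, "atoms") else list(model_a)
    atoms_b = model_b.atoms if hasattr(model_b, "atoms") else list(model_b)
    if not atoms_a or not atoms_b:
        raise ValueError("both models must be non-empty")
    pos_a = np.array([a.position for a in atoms_a])
    pos_b = np.array([a.position for a in atoms_b])
    tree_a, tree_b = cKDTree(pos_a), cKDTree(pos_b)
    pairs = tree_a.query_ball_tree(tree_b, cutoff)
    found: dict[tuple, dict] = {}
    for i, js in enumerate(pairs):
        for j in js:
            d = float(np.linalg.norm(pos_a[i] - pos_b[j]))
            if d >= cutoff:
                continue
            key = (atoms_a[i].residue_key, atoms_b[j].residue_key)
            rec = found.setdefault(key, {"min": d, "hbond": False})
            rec["min"] = min(rec["min"], d)
            if (
                d < hbond_distance
                and atoms_a[i].element.upper() in ("N", "O")
                and atoms_b[j].element.upper() in ("N", "O")
            ):
                rec["hbond"] = True
    return sorted(
        (
            ResidueContact(ka, kb, rec["min"], rec["hbond"])
            for (ka, kb), rec in found.items()
        ),
        key=lambda c: (c.residue_a, c.residue_b),
    )


# ---------------------------------------------------------------------------
# isoelectric point

#: EMBOSS pKa values (side chains and termini)
PKA_SETS = {
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
}

_POSITIVE_GROUPS = {"Nterm", "K", "R", "H"}

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def net_charge(sequence: str, ph: float, pka_set="emboss") -> float:
    """Henderson-Hasselbalch net charge of a 1-letter sequence at ``ph``."""
    pka = PKA_SETS[pka_set] if isinstance(pka_set, str) else dict(pka_set)
    counts: dict[str, int] = {}
    for letter in sequence:
        if letter not in STANDARD_AA:
            raise ValueError(f"unknown residue letter {letter!r}")
        counts[letter] = counts.get(letter, 0) + 1
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    q = 0.0
    for group, n in counts.items():
        if group not in pka:
            continue
        if group in _POSITIVE_GROUPS:
            q += n / (1.0 + 10.0 ** (ph - pka[group]))
        else:
            q -= n / (1.0 + 10.0 ** (pka[group] - ph))
    return q


def isoelectric_point(
    sequence: str, pka_set="emboss", tol: float = 1e-4
) -> float:
    """pH at which the Henderson-Hasselbalch net charge vanishes.

    Found by bisection on [0, 14]; the charge is monotone decreasing in
    pH, so the root is unique.  The interval is narrowed until the root is
    localized to 1e-6 pH units (which also guarantees ``|charge| < tol``
    at the returned pH — the charge can plateau near zero over a wide pH
    range, so charge magnitude alone would under-determine the root).
    Values depend on the pKa set; the shipped default is the EMBOSS table.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid, pka_set)
        if q == 0.0:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    assert abs(net_charge(sequence, mid, pka_set)) < tol
    return mid
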