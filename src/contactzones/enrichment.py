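"""Contact-enrichment statistics on a Hirshfeld interface.

The interface area is decomposed by the chemical types of the atoms facing
each facet.  With ``S_X`` the percentage of each side's surface contributed
by type X, the random-mixing expectation for the unordered contact X...Y is
the probability product

    R_XY = (S_a[X] * S_b[Y] + S_a[Y] * S_b[X]) / 100     (X != Y)
    R_XX = S_a[X] * S_b[X] / 100

and the enrichment ratio is E_XY = C_XY / R_XY, where C_XY is the observed
percentage of interface area with types X and Y facing each other (pooled
over the two orientations).  E > 1 marks over-represented (favored)
contacts, E < 1 under-represented ones.  A grouped summary pools types into
hydrophobic {C, Hc, N} and hydrophilic {Ho/n, O, W} classes and applies the
same arithmetic to the two-class system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import INTERACTION_TYPES

#: default hydrophobic/hydrophilic grouping; sp2 peptide and guanidinium
#: nitrogens carry no lone pair and count as hydrophobic
DEFAULT_GROUPING = {
    "Hphob": frozenset({"C", "Hc", "N"}),
    "Hphil": frozenset({"Ho/n", "O", "W"}),
}

#: random-contact proportions at or below this value (%) make E undefined
R_EPSILON = 0.05

_ORDER = {t: i for i, t in enumerate(INTERACTION_TYPES)}


def pair_key(x: str, y: str) -> tuple[str, str]:
    """Canonical unordered type pair, sorted by the conventional order."""
    return (x, y) if _ORDER[x] <= _ORDER[y] else (y, x)


def all_pairs(types=INTERACTION_TYPES) -> list[tuple[str, str]]:
    ts = sorted(types, key=_ORDER.get)
    return [(ts[i], ts[j]) for i in range(len(ts)) for j in range(i, len(ts))]


def surface_composition(patches, side: str = "a") -> dict[str, float]:
    """Percentage of interface area per interaction type on one side.

    ``S_X = 100 * area(facets whose side atom has type X) / total_area``.
    """
    if patches.is_empty:
        raise ValueError("empty patch set")
    types = patches.type_in if side == "a" else patches.type_out
    out: dict[str, float] = {}
    total = patches.total_area
    for t in INTERACTION_TYPES:
        a = patches.areas[types == t].sum()
        if a > 0:
            out[t] = 100.0 * a / total
    missing = [t for t, x in zip(types, patches.areas) if t is None]
    if missing:
        raise ValueError("patch set contains untyped facets")
    return out


def contact_proportions(patches) -> dict[tuple[str, str], float]:
    """Percentage of interface area per unordered contact type pair."""
    if patches.is_empty:
        raise ValueError("empty patch set")
    out: dict[tuple[str, str], float] = {}
    total = patches.total_area
    for ti, to, a in zip(patches.type_in, patches.type_out, patches.areas):
        key = pair_key(ti, to)
        out[key] = out.get(key, 0.0) + a
    return {k: 100.0 * v / total for k, v in out.items()}


def random_contacts(
    s_a: dict[str, float], s_b: dict[str, float]
) -> dict[tuple[str, str], float]:
    """Equiprobable (random-mixing) contact percentages from the two
    surface compositions, via probability products."""
    for name, s in (("side a", s_a), ("side b", s_b)):
        if any(v < 0 for v in s.values()):
            raise ValueError(f"negative surface composition on {name}")
    types = sorted(set(s_a) | set(s_b), key=lambda t: _ORDER.get(t, 99))
    out: dict[tuple[str, str], float] = {}
    for i, x in enumerate(types):
        for y in types[i:]:
            if x == y:
                r = s_a.get(x, 0.0) * s_b.get(x, 0.0) / 100.0
            else:
                r = (
                    s_a.get(x, 0.0) * s_b.get(y, 0.0)
                    + s_a.get(y, 0.0) * s_b.get(x, 0.0)
                ) / 100.0
            out[pair_key(x, y) if x in _ORDER and y in _ORDER else (x, y)] = r
    return out


def enrichment(
    c: dict[tuple[str, str], float],
    r: dict[tuple[str, str], float],
    eps: float = R_EPSILON,
) -> dict[tuple[str, str], float | None]:
    """E = C / R per pair; pairs with R <= eps (%) are undefined (None),
    never reported as 0 or infinity."""
    unknown = set(c) - set(r)
    if unknown:
        raise ValueError(f"contact pairs without a random expectation: {unknown}")
    out: dict[tuple[str, str], float | None] = {}
    for key, rv in r.items():
        if rv > eps:
            out[key] = c.get(key, 0.0) / rv
        else:
            out[key] = None
    return out


def group_hydrophobic(
    s_a: dict[str, float],
    s_b: dict[str, float],
    c: dict[tuple[str, str], float],
    grouping: dict[str, frozenset] = DEFAULT_GROUPING,
) -> dict:
    """Two-class (hydrophobic/hydrophilic) summary.

    Member surface shares and contact shares are summed per class, then the
    same probability-product and ratio formulas are applied to the grouped
    system.  ``grouping`` must partition the type set.
    """
    members = [t for g in grouping.values() for t in g]
    if sorted(members) != sorted(set(members)) or set(members) != set(
        INTERACTION_TYPES
    ):
        raise ValueError(
            f"grouping must partition the type set {INTERACTION_TYPES}"
        )
    names = list(grouping)
    of = {t: g for g, ts in grouping.items() for t in ts}
    gs_a = {g: sum(s_a.get(t, 0.0) for t in ts) for g, ts in grouping.items()}
    gs_b = {g: sum(s_b.get(t, 0.0) for t in ts) for g, ts in grouping.items()}
    gc: dict[tuple[str, str], float] = {}
    for (x, y), v in c.items():
        gx, gy = of[x], of[y]
        key = tuple(sorted((gx, gy), key=names.index))
        gc[key] = gc.get(key, 0.0) + v
    gr: dict[tuple[str, str], float] = {}
    for i, gx in enumerate(names):
        for gy in names[i:]:
            if gx == gy:
                gr[(gx, gx)] = gs_a[gx] * gs_b[gx] / 100.0
            else:
                gr[(gx, gy)] = (
                    gs_a[gx] * gs_b[gy] + gs_a[gy] * gs_b[gx]
                ) / 100.0
    ge = {
        k: (gc.get(k, 0.0) / v if v > R_EPSILON else None) for k, v in gr.items()
    }
    return {"S_a": gs_a, "S_b": gs_b, "C": gc, "R": gr, "E": ge}


@dataclass
class ContactTable:
    """Surface compositions, contact/random proportions, enrichments and
    the grouped hydrophobic/hydrophilic summary for one interface."""

    S_a: dict[str, float]
    S_b: dict[str, float]
    C: dict[tuple[str, str], float]
    R: dict[tuple[str, str], float]
    E: dict[tuple[str, str], float | None]
    grouped: dict
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self, undefined_as_zero: bool = True) -> dict:
        def e_val(v):
            if v is None:
                return 0.0 if undefined_as_zero else None
            return round(v, 2)

        return {
            "surface_a": {t: round(v, 1) for t, v in self.S_a.items()},
            "surface_b": {t: round(v, 1) for t, v in self.S_b.items()},
            "contacts": {f"{x}|{y}": round(v, 1) for (x, y), v in self.C.items()},
            "random": {f"{x}|{y}": round(v, 1) for (x, y), v in self.R.items()},
            "enrichment": {f"{x}|{y}": e_val(v) for (x, y), v in self.E.items()},
            "grouped": {
                "surface_a": {g: round(v, 1) for g, v in self.grouped["S_a"].items()},
                "surface_b": {g: round(v, 1) for g, v in self.grouped["S_b"].items()},
                "contacts": {
                    f"{x}|{y}": round(v, 1) for (x, y), v in self.grouped["C"].items()
                },
                "enrichment": {
                    f"{x}|{y}": e_val(v) for (x, y), v in self.grouped["E"].items()
                },
            },
            "metadata": self.metadata,
        }

    def to_tsv(self, path, undefined_as_zero: bool = True) -> None:
        """Triangular layout: surface rows, C block, E block, grouped block."""
        types = [t for t in INTERACTION_TYPES
                 if t in self.S_a or t in self.S_b]

        def fmt_e(v):
            if v is None:
                return "0" if undefined_as_zero else "undef"
            return f"{v:.2f}"

        lines = ["atom_type\t" + "\t".join(types)]
        for label, s in (("surface_a", self.S_a), ("surface_b", self.S_b)):
            lines.append(
                label + "\t" + "\t".join(f"{s.get(t, 0.0):.1f}" for t in types)
            )
        for block, fmt in (("C", lambda v: f"{v:.1f}"), ("E", fmt_e)):
            data = self.C if block == "C" else self.E
            lines.append(f"# {block}_XY")
            for i, x in enumerate(types):
                row = [x]
                row.extend("" for _ in types[:i])
                for y in types[i:]:
                    v = data.get(pair_key(x, y), 0.0 if block == "C" else None)
                    row.append(fmt(v) if (v is not None or block == "E") else "0.0")
                lines.append("\t".join(row))
        g = self.grouped
        names = list(g["S_a"])
        lines.append("# grouped\t" + "\t".join(names) + "\tcross")
        lines.append(
            "surface_a\t" + "\t".join(f"{g['S_a'][n]:.1f}" for n in names)
        )
        lines.append(
            "surface_b\t" + "\t".join(f"{g['S_b'][n]:.1f}" for n in names)
        )
        cross = tuple(sorted(names, key=names.index))
        lines.append(
            "contacts\t"
            + "\t".join(f"{g['C'].get((n, n), 0.0):.1f}" for n in names)
            + f"\t{g['C'].get(cross, 0.0):.1f}"
        )
        lines.append(
            "enrichment\t"
            + "\t".join(fmt_e(g["E"].get((n, n))) for n in names)
            + f"\t{fmt_e(g['E'].get(cross))}"
        )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def compute_contact_table(
    patches, grouping: dict[str, frozenset] = DEFAULT_GROUPING
) -> ContactTable:
    """Full enrichment table from an assigned interface patch set."""
    s_a = surface_composition(patches, "a")
    s_b = surface_composition(patches, "b")
    c = contact_proportions(patches)
    r = random_contacts(s_a, s_b)
    e = enrichment(c, r)
    grouped = group_hydrophobic(s_a, s_b, c, grouping)
    return ContactTable(
        s_a, s_b, c, r, e, grouped, metadata=dict(patches.metadata)
    )
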