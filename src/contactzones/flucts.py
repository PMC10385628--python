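"""Ensemble and crystallographic fluctuation analytics.

Implements least-squares rigid-body superposition (Kabsch algorithm),
per-frame RMSD series over conformational ensembles, per-atom RMSF
(root mean square fluctuation about the ensemble mean, after optional
superposition), conversion between crystallographic isotropic B-factors
and root mean square thermal displacements

    RMSTD = sqrt(B / (8 pi^2)),

and Pearson correlation between fluctuation profiles.  Ensembles are plain
coordinate stacks over a fixed atom roster, typically read from multi-model
PDB files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Ensemble:
    """Ordered coordinate frames over a fixed atom roster."""

    coords: np.ndarray                    # (n_frames, n_atoms, 3), A
    atoms: list | None = None             # optional AtomRecord roster
    frame_interval: float | None = None   # e.g. ps between frames
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.atoms is not None and len(self.atoms) != self.coords.shape[1]:
            raise ValueError(
                "atom roster length does not match the coordinate frames"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_models(cls, models, frame_interval: float | None = None):
        """Build from a list of StructureModel (e.g. multi-model PDB).

        All models must share the same atom roster (chain, residue, name),
        in the same order; the first mismatch is reported.
        """
        rosters = [
            [(a.chain, a.residue_number, a.name) for a in m.atoms] for m in models
        ]
        for k, roster in enumerate(rosters[1:], start=2):
            if roster != rosters[0]:
                for i, (x, y) in enumerate(zip(rosters[0], roster)):
                    if x != y:
                        raise ValueError(
                            f"model {k} differs from model 1 at atom {i}: "
                            f"{y} != {x}"
                        )
                raise ValueError(
                    f"model {k} has {len(roster)} atoms, model 1 has "
                    f"{len(rosters[0])}"
                )
        coords = np.array([[a.position for a in m.atoms] for m in models])
        return cls(coords, atoms=list(models[0].atoms),
                   frame_interval=frame_interval)

    def select(self, predicate) -> np.ndarray:
        """Indices of roster atoms matching ``predicate(AtomRecord)``."""
        if self.atoms is None:
            raise ValueError("ensemble carries no atom roster")
        return np.array(
            [i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int
        )

    def backbone_indices(self) -> np.ndarray:
        return self.select(
            lambda a: a.name in BACKBONE_ATOMS and not a.is_water
        )

    def calpha_indices(self) -> np.ndarray:
        return self.select(lambda a: a.name == "CA" and not a.is_water)


@dataclass
class FluctuationProfile:
    """Per-atom (or per-residue) fluctuation values in A."""

    values: np.ndarray
    kind: str                      # "RMSF" or "RMSTD"
    labels: list | None = None     # e.g. residue numbers
    selection: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("fluctuation values must be non-negative")


# ---------------------------------------------------------------------------
# superposition


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation/translation of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best matches ``reference`` in the
    weighted least-squares sense; reflection solutions are resolved to a
    proper rotation.  ``rmsd = sqrt(sum w |x' - y|^2 / sum w)``.
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(
            f"point sets must share shape (n, 3); got {x.shape} vs {y.shape}"
        )
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(x):
        raise ValueError("one weight per point required")
    wsum = w.sum()
    xc = (w[:, None] * x).sum(axis=0) / wsum
    yc = (w[:, None] * y).sum(axis=0) / wsum
    xm, ym = x - xc, y - yc
    h = (w[:, None] * xm).T @ ym
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    moved = xm @ rot.T
    rmsd = float(np.sqrt((w * ((moved - ym) ** 2).sum(axis=1)).sum() / wsum))
    return rot, trans, rmsd


def superpose_frames(
    coords: np.ndarray, reference: np.ndarray, fit_idx: np.ndarray
) -> np.ndarray:
    """Superpose every frame onto ``reference`` using the ``fit_idx``
    selection, applying the transform to all atoms of the frame."""
    out = np.empty_like(coords)
    for k, frame in enumerate(coords):
        rot, trans, _ = kabsch_superpose(frame[fit_idx], reference[fit_idx])
        out[k] = frame @ rot.T + trans
    return out


def rmsd_series(
    ensemble: Ensemble, reference: np.ndarray, selection: np.ndarray
) -> np.ndarray:
    """Per-frame RMSD (A) of the selection after per-frame superposition of
    the same selection onto the reference."""
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    reference = np.asarray(reference, dtype=float)
    out = np.empty(ensemble.n_frames)
    for k, frame in enumerate(ensemble.coords):
        _, _, out[k] = kabsch_superpose(frame[selection], reference[selection])
    return out


def rmsf(
    ensemble: Ensemble,
    selection: np.ndarray | None = None,
    align: bool = True,
    fit_selection: np.ndarray | None = None,
    about: str = "mean",
) -> FluctuationProfile:
    """Per-atom RMSF (A) over the ensemble.

    Frames are first superposed (by default on ``fit_selection``, falling
    back to ``selection``, onto the first frame); fluctuations are then
    measured about the ensemble mean position (``about="mean"``) or about
    the first-frame position (``about="reference"``).
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames for fluctuations")
    if about not in ("mean", "reference"):
        raise ValueError(f"unknown fluctuation center {about!r}")
    coords = ensemble.coords
    sel = (
        np.arange(ensemble.n_atoms)
        if selection is None
        else np.asarray(selection, dtype=int)
    )
    if sel.size == 0:
        raise ValueError("empty selection")
    if align:
        fit = sel if fit_selection is None else np.asarray(fit_selection, int)
        coords = superpose_frames(coords, coords[0], fit)
    sub = coords[:, sel, :]
    center = sub.mean(axis=0) if about == "mean" else sub[0]
    vals = np.sqrt(((sub - center) ** 2).sum(axis=2).mean(axis=0))
    labels = (
        [ensemble.atoms[i].residue_number for i in sel]
        if ensemble.atoms is not None
        else None
    )
    return FluctuationProfile(vals, kind="RMSF", labels=labels)


# ---------------------------------------------------------------------------
# B-factor conversions


def rmstd_from_b(b) -> np.ndarray | float:
    """Root mean square thermal displacement sqrt(B / 8 pi^2), A."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("B-factors must be non-negative")
    out = np.sqrt(b / (8.0 * np.pi**2))
    return float(out) if out.ndim == 0 else out


def b_from_rmstd(rmstd) -> np.ndarray | float:
    """Inverse conversion: B = 8 pi^2 rmstd^2, A^2."""
    rmstd = np.asarray(rmstd, dtype=float)
    if np.any(rmstd < 0):
        raise ValueError("displacements must be non-negative")
    out = 8.0 * np.pi**2 * rmstd**2
    return float(out) if out.ndim == 0 else out


def rmstd_profile(atoms, name: str = "CA") -> FluctuationProfile:
    """Per-residue RMSTD profile from the B-factors of the named atom
    (default C-alpha); residues missing the atom are skipped."""
    import warnings

    sel = [a for a in atoms if a.name == name and not a.is_water]
    seen = {}
    for a in sel:
        seen.setdefault((a.chain, a.residue_number), a)
    residues = {}
    for a in atoms:
        if not a.is_water:
            residues.setdefault((a.chain, a.residue_number), a)
    missing = set(residues) - set(seen)
    if missing:
        warnings.warn(
            f"{len(missing)} residues lack a {name} atom and were skipped",
            stacklevel=2,
        )
    keys = sorted(seen)
    vals = rmstd_from_b(np.array([seen[k].b_factor for k in keys]))
    return FluctuationProfile(
        np.atleast_1d(vals), kind="RMSTD", labels=[k[1] for k in keys]
    )


def correlate_profiles(p1, p2) -> float:
    """Pearson correlation between two fluctuation profiles."""
    v1 = p1.values if isinstance(p1, FluctuationProfile) else np.asarray(p1, float)
    v2 = p2.values if isinstance(p2, FluctuationProfile) else np.asarray(p2, float)
    if len(v1) != len(v2):
        raise ValueError(f"profile lengths differ: {len(v1)} vs {len(v2)}")
    if len(v1) < 3:
        raise ValueError("need at least 3 values")
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("correlation undefined for a zero-variance profile")
    return float(pearsonr(v1, v2).statistic)
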