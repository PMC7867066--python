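"""Ensemble superposition, mean structures, RMSD matrices, displacement maps.

Conventions: "backbone" means Calpha, C', N; "heavy" means all C, N, O
atoms.  Within-ensemble (diagonal) RMSDs are mean +/- sd over all member
pairs; between-ensemble entries are mean +/- sd of the RMSD from one
ensemble's mean structure to each member of the other bundle, so the
matrix is deliberately asymmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, NumericalError

__all__ = [
    "Conformer",
    "SuperpositionResult",
    "kabsch_superpose",
    "ensemble_mean",
    "rmsd_matrix",
    "displacement_profile",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C")
_HEAVY_ELEMENTS = ("C", "N", "O")


def _element_of(atom_name: str) -> str:
    name = atom_name.strip()
    return name[0] if name else ""


@dataclass
class Conformer:
    """One structural model: parallel arrays keyed by (residue, atom)."""

    residue_numbers: np.ndarray
    residue_types: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray  # (n, 3) in Angstrom
    model_id: int = 0
    chain_id: str = "A"

    def __post_init__(self):
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.residue_types = np.asarray(self.residue_types, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_numbers)
        if not (len(self.residue_types) == len(self.atom_names) == n
                and self.coords.shape == (n, 3)):
            raise InputError("conformer arrays have inconsistent shapes")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("non-finite coordinates")
        keys = list(zip(self.residue_numbers.tolist(), self.atom_names.tolist()))
        if len(set(keys)) != n:
            raise InputError("duplicate (residue, atom) in conformer")
        self._index = {k: i for i, k in enumerate(keys)}

    def atom_index(self, residue: int, atom: str) -> int | None:
        return self._index.get((residue, atom))

    def selection_mask(self, residue_range=None, atom_set: str = "backbone"):
        """Boolean mask over atoms for a residue range and atom-set name."""
        if atom_set == "backbone":
            keep = np.array([a in BACKBONE_ATOMS for a in self.atom_names])
        elif atom_set == "heavy":
            keep = np.array(
                [_element_of(a) in _HEAVY_ELEMENTS for a in self.atom_names]
            )
        else:
            raise InputError(f"unknown atom set {atom_set!r} (backbone|heavy)")
        if residue_range is not None:
            lo, hi = residue_range
            keep &= (self.residue_numbers >= lo) & (self.residue_numbers <= hi)
        return keep

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformer":
        return Conformer(
            self.residue_numbers.copy(), self.residue_types.copy(),
            self.atom_names.copy(), self.coords @ rotation.T + translation,
            self.model_id, self.chain_id,
        )


@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    selection: dict = field(default_factory=dict)


def _paired_coords(mobile: Conformer, target: Conformer,
                   residue_range, atom_set: str):
    """Coordinates of atoms present in both structures under the selection."""
    mask = mobile.selection_mask(residue_range, atom_set)
    xs, ys = [], []
    for i in np.flatnonzero(mask):
        j = target.atom_index(int(mobile.residue_numbers[i]),
                              str(mobile.atom_names[i]))
        if j is not None:
            xs.append(mobile.coords[i])
            ys.append(target.coords[j])
    return np.array(xs), np.array(ys)


def _kabsch(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rotation R and translation t with R@P+t ~= Q."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def kabsch_superpose(
    mobile: Conformer,
    target: Conformer,
    residue_range=None,
    atom_set: str = "backbone",
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Minimizes the RMSD over the selected, shared atoms; a reflection is
    never applied.  Requires at least 3 non-collinear atom pairs.
    """
    P, Q = _paired_coords(mobile, target, residue_range, atom_set)
    if len(P) < 3:
        raise InputError(
            f"superposition needs >=3 shared atom pairs, got {len(P)}"
        )
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-8) < 2:
        raise NumericalError("selected atoms are collinear")
    R, t = _kabsch(P, Q)
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd,
        selection={"residue_range": residue_range, "atom_set": atom_set},
    )


def superposed_rmsd(a: Conformer, b: Conformer, residue_range=None,
                    atom_set: str = "backbone") -> float:
    return kabsch_superpose(a, b, residue_range, atom_set).rmsd


def ensemble_mean(
    ensemble: list[Conformer],
    residue_range=None,
    atom_set: str = "backbone",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> Conformer:
    """Iterative mean structure of an ensemble.

    All models are superposed (on the selection) onto the current mean,
    coordinates re-averaged, until the mean moves by less than ``tol``
    Angstrom per coordinate.  The returned conformer averages ALL atoms
    shared by every model, not just the superposition selection.
    """
    if len(ensemble) < 2:
        raise InputError("ensemble mean needs >=2 conformers")
    ref = ensemble[0]
    shared = [
        (int(r), str(a))
        for r, a in zip(ref.residue_numbers, ref.atom_names)
        if all(c.atom_index(int(r), str(a)) is not None for c in ensemble[1:])
    ]
    if not shared:
        raise InputError("no atoms shared by all conformers")
    idx = [[c.atom_index(r, a) for r, a in shared] for c in ensemble]
    mean = Conformer(
        np.array([r for r, _ in shared]),
        np.array([ref.residue_types[ref.atom_index(r, a)] for r, a in shared],
                 dtype=object),
        np.array([a for _, a in shared], dtype=object),
        ref.coords[idx[0]].copy(),
    )
    for _ in range(max_iter):
        stack = []
        for c, rows in zip(ensemble, idx):
            sup = kabsch_superpose(c, mean, residue_range, atom_set)
            stack.append(c.coords[rows] @ sup.rotation.T + sup.translation)
        new_coords = np.mean(stack, axis=0)
        shift = float(np.max(np.abs(new_coords - mean.coords)))
        mean = Conformer(mean.residue_numbers, mean.residue_types,
                         mean.atom_names, new_coords)
        if shift < tol:
            return mean
    raise NumericalError(f"ensemble mean did not converge in {max_iter} iterations")


def rmsd_matrix(
    ensembles: dict[str, list[Conformer]],
    residue_range=None,
    atom_set: str = "backbone",
) -> pd.DataFrame:
    """Bundle/mean RMSD matrix over named ensembles.

    Diagonal: mean +/- sd of all pairwise member RMSDs within the ensemble.
    Off-diagonal (row -> column): mean +/- sd of RMSDs from the ROW
    ensemble's mean structure to each member of the COLUMN bundle.  Cells
    are (mean, sd) tuples; single-conformer "bundles" act as their own mean.
    """
    names = list(ensembles)
    means = {
        n: (ensemble_mean(models, residue_range, atom_set)
            if len(models) > 1 else models[0])
        for n, models in ensembles.items()
    }

    def cell(vals):
        v = np.asarray(vals, dtype=float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        return (float(v.mean()), sd)

    data = {}
    for row in names:
        data[row] = {}
        for col in names:
            if row == col:
                models = ensembles[row]
                if len(models) == 1:
                    data[row][col] = (0.0, 0.0)
                    continue
                vals = [
                    superposed_rmsd(models[i], models[j], residue_range, atom_set)
                    for i in range(len(models))
                    for j in range(i + 1, len(models))
                ]
            else:
                vals = [
                    superposed_rmsd(means[row], m, residue_range, atom_set)
                    for m in ensembles[col]
                ]
            data[row][col] = cell(vals)
    return pd.DataFrame(data).T.loc[names, names]


def displacement_profile(
    mean_a: Conformer,
    mean_b: Conformer,
    residue_range=None,
) -> pd.DataFrame:
    """Per-residue global displacement between two structures.

    After ONE global backbone superposition of ``mean_b`` onto ``mean_a``,
    each residue's displacement is the RMS distance over its selected atoms
    (columns ``d_backbone`` and ``d_heavy``); residues missing from either
    structure are absent from the output, not reported as zero.
    """
    sup = kabsch_superpose(mean_b, mean_a, residue_range, "backbone")
    b_moved = mean_b.transformed(sup.rotation, sup.translation)

    rows = {}
    for atom_set, col in (("backbone", "d_backbone"), ("heavy", "d_heavy")):
        mask = mean_a.selection_mask(residue_range, atom_set)
        per_res: dict[int, list[float]] = {}
        for i in np.flatnonzero(mask):
            res = int(mean_a.residue_numbers[i])
            j = b_moved.atom_index(res, str(mean_a.atom_names[i]))
            if j is None:
                continue
            d2 = float(((mean_a.coords[i] - b_moved.coords[j]) ** 2).sum())
            per_res.setdefault(res, []).append(d2)
        for res, d2s in per_res.items():
            rows.setdefault(res, {})[col] = math.sqrt(sum(d2s) / len(d2s))
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "residue"
    return df
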