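"""Rigid-body superposition, Cα RMSD, and residue-selection windows.

The windowed analyses follow one convention throughout: a selection
(sequence window, Cα-distance window, or ligand pocket) is resolved once
on a designated reference structure and propagated to other structures
through a :class:`~ensdock.structio.ResidueMap`, so every structure in a
comparison uses the *same* residue set.  Distance thresholds are closed
(``d <= r``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBIO, PDBParser, Select
from scipy.spatial.transform import Rotation

from .structio import ResidueMap, Structure, map_shared_residues

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Superposition:
    """Least-squares rigid transform ``x -> rotation @ x + translation``.

    ``rotation`` is proper (det = +1): reflections are never returned,
    preserving chirality.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ResidueSelection:
    """A deterministic set of residue numbers with the rule that produced it."""

    resnums: frozenset[int]
    rule: str
    anchor: str | int | None = None

    def __len__(self) -> int:
        return len(self.resnums)

    def to_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "rule": self.rule,
            "resnums": sorted(self.resnums),
        }


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Optimal rigid superposition of ``mobile`` onto ``target`` (Kabsch).

    Both inputs are (n, 3) point sets, n >= 3, paired by index.  Returns
    the proper-rotation least-squares transform and the resulting RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(
            f"point sets differ in shape: {mobile.shape} vs {target.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")
    if not (np.all(np.isfinite(mobile)) and np.all(np.isfinite(target))):
        raise ValueError("point sets contain non-finite values")

    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    with warnings.catch_warnings():
        # colinear/planar point sets leave a rotation axis undetermined;
        # any optimal rotation gives the same rmsd, so the warning is moot
        warnings.simplefilter("ignore", UserWarning)
        rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    rotation = rot.as_matrix()
    translation = ct - rotation @ cm
    # evaluate the residual directly: the rssd shortcut loses precision
    # to cancellation near rmsd = 0
    dev = mobile @ rotation.T + translation - target
    rmsd = float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))
    return Superposition(rotation=rotation, translation=translation,
                         rmsd=rmsd, n_atoms=n)


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD of two paired (n, 3) point sets after optimal superposition."""
    return kabsch_superpose(a, b).rmsd


def pairwise_superposed_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pairs minimum RMSD for a stack of conformations.

    ``coords`` is (n_items, n_atoms, 3).  Uses the closed form
    rmsd^2 = (|A|^2 + |B|^2 - 2(s1 + s2 +/- s3)) / n on the singular
    values of the cross-covariance, with the sign fixed so the optimal
    rotation is proper.  Returns a symmetric matrix with zero diagonal.
    """
    coords = np.asarray(coords, dtype=float)
    n_items, n_atoms, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    sq = np.einsum("kmi,kmi->k", centered, centered)
    ii, jj = np.triu_indices(n_items, k=1)
    if ii.size == 0:
        return np.zeros((n_items, n_items))
    h = np.einsum("kmi,kmj->kij", centered[ii], centered[jj])
    s = np.linalg.svd(h, compute_uv=False)
    sign = np.where(np.linalg.det(h) < 0.0, -1.0, 1.0)
    trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
    msd = (sq[ii] + sq[jj] - 2.0 * trace) / n_atoms
    rmsd = np.sqrt(np.clip(msd, 0.0, None))
    out = np.zeros((n_items, n_items))
    out[ii, jj] = rmsd
    out[jj, ii] = rmsd
    return out


def ca_rmsd(
    a: Structure,
    b: Structure,
    selection: ResidueSelection | None = None,
    rmap: ResidueMap | None = None,
    superpose_scope: str = "selection",
) -> float:
    """Cα RMSD between two structures over a residue selection.

    The structures are first superposed on ``superpose_scope`` atoms
    ("selection" for a local fit, "whole" for all mapped residues), then
    the RMSD is reported over the selection atoms.  With no selection,
    all mapped residues are used.
    """
    if superpose_scope not in ("selection", "whole"):
        raise ValueError("superpose_scope must be 'selection' or 'whole'")
    if rmap is None:
        rmap = map_shared_residues(a, b)
    ia, ib = rmap.indices(a, b)
    mapped_nums = np.array([p for p, _ in rmap.pairs])

    if selection is None:
        sel_mask = np.ones(len(mapped_nums), dtype=bool)
    else:
        sel_mask = np.isin(mapped_nums, sorted(selection.resnums))
    if not sel_mask.any():
        raise ValueError("selection is empty after residue mapping")

    fit_mask = sel_mask if superpose_scope == "selection" else np.ones_like(sel_mask)
    if fit_mask.sum() < 3:
        raise ValueError(
            f"only {int(fit_mask.sum())} mapped atoms in superposition scope; need >= 3"
        )

    ca_a = a.coords[ia]
    ca_b = b.coords[ib]
    sup = kabsch_superpose(ca_b[fit_mask], ca_a[fit_mask])
    moved = sup.apply(ca_b)
    dev = moved[sel_mask] - ca_a[sel_mask]
    return float(np.sqrt(np.mean(np.sum(dev * dev, axis=1))))


def distance_window(s: Structure, anchor_resnum: int, r: float) -> ResidueSelection:
    """Residues whose Cα lies within ``r`` Å of the anchor residue's Cα.

    The anchor is always included (distance 0); the threshold is closed.
    """
    idx = s.index_of(anchor_resnum)
    d = np.linalg.norm(s.coords - s.coords[idx], axis=1)
    nums = {res.resnum for res, di in zip(s.residues, d) if di <= r}
    return ResidueSelection(
        resnums=frozenset(nums), rule=f"distance-window {r} A", anchor=anchor_resnum
    )


def sequence_window(s: Structure, anchor_resnum: int, k: int) -> ResidueSelection:
    """Residues with ``|resnum - anchor| <= k`` that exist in the structure."""
    s.index_of(anchor_resnum)  # raises if anchor absent
    nums = {r.resnum for r in s.residues if abs(r.resnum - anchor_resnum) <= k}
    return ResidueSelection(
        resnums=frozenset(nums), rule=f"sequence-window {k}", anchor=anchor_resnum
    )


class _PocketSelect(Select):
    def __init__(self, keep_residues, ligand_res):
        self._keep = keep_residues
        self._ligand = ligand_res

    def accept_residue(self, residue):
        return residue in self._keep or residue is self._ligand


def pocket_residues(
    complex_pdb: str | Path,
    ligand_id: str,
    r: float,
    out_pdb: str | Path | None = None,
) -> ResidueSelection:
    """Protein residues with any atom within ``r`` Å of any ligand atom.

    ``ligand_id`` selects a HETATM residue by name, optionally qualified
    as ``NAME/CHAIN`` or ``NAME/CHAIN/RESNUM``; an ambiguous id raises
    with the list of candidates.  If ``out_pdb`` is given, the selected
    pocket residues plus the ligand are written as a PDB fragment
    suitable as input preparation for a quantum-chemistry engine.
    """
    path = Path(complex_pdb)
    parser = PDBParser(QUIET=True)
    pdb = parser.get_structure(path.stem, str(path))
    model = next(pdb.get_models())

    parts = ligand_id.split("/")
    want_name = parts[0]
    want_chain = parts[1] if len(parts) > 1 else None
    want_num = int(parts[2]) if len(parts) > 2 else None

    candidates = []
    for chain_obj in model:
        for res in chain_obj:
            if res.id[0] == " ":
                continue
            if res.resname.strip() != want_name:
                continue
            if want_chain is not None and chain_obj.id != want_chain:
                continue
            if want_num is not None and res.id[1] != want_num:
                continue
            candidates.append((chain_obj.id, res))
    if not candidates:
        raise ValueError(f"{path}: ligand {ligand_id!r} not found")
    if len(candidates) > 1:
        names = ", ".join(f"{want_name}/{c}/{res.id[1]}" for c, res in candidates)
        raise ValueError(
            f"{path}: ligand id {ligand_id!r} is ambiguous; candidates: {names}"
        )
    ligand = candidates[0][1]
    lig_xyz = np.stack([atom.get_coord() for atom in ligand.get_atoms()])

    keep = []
    nums = set()
    for chain_obj in model:
        for res in chain_obj:
            if res.id[0] != " ":
                continue
            xyz = np.stack([atom.get_coord() for atom in res.get_atoms()])
            d = np.linalg.norm(xyz[:, None, :] - lig_xyz[None, :, :], axis=2)
            if r > 0 and d.min() <= r:
                keep.append(res)
                nums.add(res.id[1])

    selection = ResidueSelection(
        resnums=frozenset(nums), rule=f"pocket {r} A", anchor=ligand_id
    )
    if out_pdb is not None:
        io = PDBIO()
        io.set_structure(pdb)
        io.save(str(out_pdb), select=_PocketSelect(set(keep), ligand))
    return selection
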