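"""Synthetic fixtures with known ground truth.

Every generator is a pure function of its :class:`SynthConfig` (the
seed included), and each one plants the structure its downstream
analysis is supposed to find: trajectories carry a known
frame-to-conformer assignment, mutants a known localized perturbation,
score tables a known active/decoy energy shift, and toy complexes
residues at scripted ligand distances.  Tests never re-derive ground
truth — the generators hand it back alongside the data.

The defaults mirror the study conditions the package targets: 100
recorded trajectory frames, a handful of metastable conformers, and
virtual-screening tables of 120 actives among 2500 decoys in the style
of a DEKOIS-2.0 benchmark set.  There is no physical realism here — no
force field, no docking physics — only controllable signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .enrichment import ScoreTable
from .structio import (
    MutationSpec,
    Residue,
    Structure,
    Trajectory,
    aa3,
)

_AA_CODES = (
    "ALA CYS ASP GLU PHE GLY HIS ILE LYS LEU MET ASN PRO GLN ARG "
    "SER THR VAL TRP TYR"
).split()

CA_SPACING = 3.8  # Å, consecutive Cα distance of an idealized trace


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for all fixture generators (Å and kcal/mol throughout)."""

    seed: int = 0
    # chains / trajectories
    n_residues: int = 60
    n_frames: int = 100
    n_conformers: int = 3
    conformer_weights: tuple[float, ...] = (0.6, 0.3, 0.1)
    jitter_sigma: float = 0.05
    conformer_separation: float = 2.0
    # mutants
    mutation_radius: float = 5.0
    mutation_magnitude: float = 1.0
    # score tables
    n_actives: int = 120
    n_decoys: int = 2500
    decoy_energy_mu: float = -6.0
    decoy_energy_sigma: float = 1.0
    active_shift: float = 2.0
    n_conformations: int = 5
    n_sites: int = 1
    signal_conformations: tuple[int, ...] | None = None  # None = all carry signal
    # toy complexes
    complex_distances: tuple[float, ...] = (3.0, 4.9, 5.1, 8.0)
    include_ligand: bool = True

    def __post_init__(self) -> None:
        for name in ("n_frames", "n_conformers", "n_actives", "n_decoys",
                     "n_conformations", "n_sites"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if len(self.conformer_weights) != self.n_conformers:
            raise ValueError("one occupancy weight per conformer required")
        if abs(sum(self.conformer_weights) - 1.0) > 1e-9:
            raise ValueError("conformer weights must sum to 1")
        if self.jitter_sigma < 0 or self.decoy_energy_sigma < 0:
            raise ValueError("sigmas must be nonnegative")


def make_chain(cfg: SynthConfig) -> Structure:
    """Idealized Cα trace: exact 3.8 Å steps along a smooth random curve."""
    if cfg.n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(cfg.seed)
    direction = np.array([1.0, 0.0, 0.0])
    omega = rng.normal(scale=0.1, size=3)
    coords = [np.zeros(3)]
    for _ in range(cfg.n_residues - 1):
        # smooth angular-velocity walk keeps the curve gently bending
        omega = 0.8 * omega + 0.2 * rng.normal(scale=0.35, size=3)
        direction = Rotation.from_rotvec(omega).apply(direction)
        direction /= np.linalg.norm(direction)
        coords.append(coords[-1] + CA_SPACING * direction)
    names = rng.choice(_AA_CODES, size=cfg.n_residues)
    residues = [
        Residue(resnum=i + 1, chain="A", resname=str(names[i]), ca=tuple(coords[i]))
        for i in range(cfg.n_residues)
    ]
    return Structure(id=f"chain-seed{cfg.seed}", residues=residues)


def make_trajectory(cfg: SynthConfig) -> tuple[Trajectory, np.ndarray]:
    """Trajectory of jittered draws from planted base conformers.

    Each conformer is the chain plus its own isotropic Gaussian
    displacement field scaled so pairwise conformer RMSD is close to
    ``conformer_separation``; frames add i.i.d. jitter of sd
    ``jitter_sigma`` per coordinate.  Returns the trajectory and the
    ground-truth frame-to-conformer assignment.
    """
    chain = make_chain(cfg)
    rng = np.random.default_rng(cfg.seed)
    rng.normal(size=3)  # decouple from make_chain's draws, keep determinism
    base = chain.coords
    n = len(chain)
    # two independent N(0, s^2 I) fields differ by 6 s^2 per atom in
    # expectation, so s = separation / sqrt(6) sets the pairwise RMSD scale
    s = cfg.conformer_separation / np.sqrt(6.0)
    conformers = base[None] + rng.normal(scale=s, size=(cfg.n_conformers, n, 3))
    assignments = rng.choice(
        cfg.n_conformers, size=cfg.n_frames, p=np.asarray(cfg.conformer_weights)
    )
    frames = conformers[assignments]
    if cfg.jitter_sigma > 0:
        frames = frames + rng.normal(scale=cfg.jitter_sigma, size=frames.shape)
    traj = Trajectory(topology=chain, frames=frames)
    return traj, assignments


def make_mutant(s: Structure, spec: MutationSpec, cfg: SynthConfig) -> Structure:
    """Variant of ``s`` with a planted local perturbation or a deletion.

    Substitutions rename the residue and displace every residue whose
    Cα lies within ``mutation_radius`` of the site by a random direction
    of norm ``mutation_magnitude``; deletions drop the residue range and
    keep the numbering (leaving a gap).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if spec.kind == "deletion":
        kept = [r for r in s.residues if not (spec.start <= r.resnum <= spec.end)]
        if len(kept) == len(s.residues):
            raise ValueError(f"deletion range {spec.start}-{spec.end} not present in {s.id!r}")
        return Structure(id=f"{s.id}_{spec.label}", residues=kept, variant=spec.label)

    site_idx = s.index_of(spec.position)
    coords = s.coords
    d = np.linalg.norm(coords - coords[site_idx], axis=1)
    moved = coords.copy()
    for i in np.nonzero(d <= cfg.mutation_radius)[0]:
        u = rng.normal(size=3)
        moved[i] += cfg.mutation_magnitude * u / np.linalg.norm(u)
    out = s.with_coords(moved, id=f"{s.id}_{spec.label}")
    out.variant = spec.label
    out.residues[site_idx] = Residue(
        resnum=spec.position,
        chain=out.residues[site_idx].chain,
        resname=aa3(spec.alt_residue),
        ca=out.residues[site_idx].ca,
    )
    return out


def make_score_table(cfg: SynthConfig) -> ScoreTable:
    """Docking-score table with planted actives.

    Decoy energies are N(mu, sigma); actives are shifted down by
    ``active_shift`` in the signal conformations (all of them by
    default), independently per (conformation, site).  Active ids carry
    the ground truth.
    """
    rng = np.random.default_rng(cfg.seed)
    actives = [f"ACT{i:04d}" for i in range(1, cfg.n_actives + 1)]
    decoys = [f"DEC{i:04d}" for i in range(1, cfg.n_decoys + 1)]
    signal = (
        set(range(cfg.n_conformations))
        if cfg.signal_conformations is None
        else set(cfg.signal_conformations)
    )
    records = []
    for conf in range(cfg.n_conformations):
        shift = cfg.active_shift if conf in signal else 0.0
        for site in range(1, cfg.n_sites + 1):
            e_act = rng.normal(
                cfg.decoy_energy_mu - shift, cfg.decoy_energy_sigma, cfg.n_actives
            )
            e_dec = rng.normal(
                cfg.decoy_energy_mu, cfg.decoy_energy_sigma, cfg.n_decoys
            )
            for cid, e in zip(actives, e_act):
                records.append((cid, conf, site, e))
            for cid, e in zip(decoys, e_dec):
                records.append((cid, conf, site, e))
    df = pd.DataFrame(
        records, columns=["compound_id", "conformation", "site", "energy"]
    )
    return ScoreTable(df=df, actives=frozenset(actives))


# ---------------------------------------------------------------------------
# Toy protein-ligand complex


def _atom_line(record, serial, name, resname, chain, resnum, xyz, element):
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{'':1s}{resname:>3s} "
        f"{chain:1s}{resnum:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n"
    )


def make_complex(cfg: SynthConfig, path: str | Path) -> dict[int, float]:
    """Write a toy protein-ligand complex PDB with scripted pocket distances.

    One ligand atom (HETATM, resname LIG) sits at the origin; protein
    residue i's nearest atom is placed exactly ``complex_distances[i]``
    Å away along its own direction, with two more atoms farther out on
    the same ray.  Returns resnum -> nearest-atom distance, the ground
    truth for pocket selection.  With ``include_ligand`` false, no
    HETATM is written.
    """
    rng = np.random.default_rng(cfg.seed)
    dists = cfg.complex_distances
    # well-separated directions so residues never shadow each other
    dirs = rng.normal(size=(len(dists), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    for _ in range(200):  # push directions apart until pairwise angle is wide
        dots = dirs @ dirs.T
        np.fill_diagonal(dots, -1)
        i, j = np.unravel_index(np.argmax(dots), dots.shape)
        if dots[i, j] < 0.6:
            break
        dirs[j] = dirs[j] - 0.5 * dirs[i]
        dirs[j] /= np.linalg.norm(dirs[j])

    lines = []
    serial = 1
    truth = {}
    for i, (d, e) in enumerate(zip(dists, dirs)):
        resnum = i + 1
        truth[resnum] = float(d)
        for name, extra, element in (("N", 0.0, "N"), ("CA", 1.3, "C"), ("C", 2.5, "C")):
            lines.append(
                _atom_line("ATOM", serial, name, "GLY", "A", resnum, (d + extra) * e, element)
            )
            serial += 1
    if cfg.include_ligand:
        lines.append(
            _atom_line("HETATM", serial, "C1", "LIG", "L", 900, (0.0, 0.0, 0.0), "C")
        )
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)
    return truth
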