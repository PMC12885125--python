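"""Structure and trajectory I/O, mutation specs, residue correspondence.

Structures are reduced to their Cα trace on read: every downstream
comparison in this package (windowed RMSD, clustering, RMSF) is a
Cα-level analysis.  Full-atom coordinates are only touched by the
ligand-pocket extraction in :mod:`ensdock.geometry`, which re-reads the
file itself.

Residue numbering is taken verbatim from the PDB file and is assumed to
be pre-harmonized across variants (e.g. UniProt numbering), so
correspondences between a wild-type and a deletion variant are built by
shared residue *number*, never by sequence alignment.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser

logger = logging.getLogger(__name__)

_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

_AA1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


@dataclass(frozen=True)
class Residue:
    """One residue of a Cα trace."""

    resnum: int
    chain: str
    resname: str
    ca: tuple[float, float, float]

    @property
    def ca_array(self) -> np.ndarray:
        return np.asarray(self.ca, dtype=float)


@dataclass
class Structure:
    """An ordered Cα trace with a variant label (``WT`` or a mutant name)."""

    id: str
    residues: list[Residue]
    variant: str = "WT"

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for r in self.residues:
            if not np.all(np.isfinite(r.ca_array)):
                raise ValueError(f"non-finite Cα coordinate at residue {r.resnum}")
            if r.chain in seen and r.resnum <= seen[r.chain]:
                raise ValueError(
                    f"residue numbers not strictly increasing in chain {r.chain!r} "
                    f"at residue {r.resnum}"
                )
            seen[r.chain] = r.resnum

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of Cα coordinates in Å, residue order."""
        if not self.residues:
            return np.empty((0, 3))
        return np.stack([r.ca_array for r in self.residues])

    @property
    def resnums(self) -> list[int]:
        return [r.resnum for r in self.residues]

    def index_of(self, resnum: int) -> int:
        for i, r in enumerate(self.residues):
            if r.resnum == resnum:
                return i
        raise KeyError(f"residue {resnum} not present in structure {self.id!r}")

    def with_coords(self, coords: np.ndarray, id: str | None = None) -> "Structure":
        """Copy of this structure with replaced Cα coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.residues), 3):
            raise ValueError("coordinate array shape does not match residue count")
        residues = [replace(r, ca=tuple(c)) for r, c in zip(self.residues, coords)]
        return Structure(id=id or self.id, residues=residues, variant=self.variant)


@dataclass
class Trajectory:
    """Frames sharing a single residue topology.

    ``frame_index`` runs contiguously from 0; frame 0 is conventionally
    the starting structure used for the simulation.
    """

    topology: Structure
    frames: np.ndarray  # (n_frames, n_residues, 3), Å

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.topology), 3):
            raise ValueError(
                f"frames must have shape (n_frames, {len(self.topology)}, 3), "
                f"got {self.frames.shape}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_index(self) -> list[int]:
        return list(range(self.n_frames))

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(
            self.frames[i], id=f"{self.topology.id}:frame{i}"
        )


@dataclass(frozen=True)
class MutationSpec:
    """A parsed point substitution or residue-range deletion."""

    kind: str  # "substitution" | "deletion"
    wt_residue: str | None = None
    position: int | None = None
    alt_residue: str | None = None
    start: int | None = None
    end: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if self.position is None or self.position <= 0:
                raise ValueError("substitution position must be a positive integer")
        elif self.kind == "deletion":
            if self.start is None or self.end is None or self.end < self.start:
                raise ValueError("deletion range must be nonempty")
            if self.start <= 0:
                raise ValueError("deletion start must be positive")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")


@dataclass(frozen=True)
class ResidueMap:
    """One-to-one residue-number correspondences between two structures.

    Deletions appear as gaps (unmapped residues), never as shifted pairs.
    """

    pairs: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    def indices(self, a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays into a.residues / b.residues for the mapped pairs."""
        ia = np.array([a.index_of(p) for p, _ in self.pairs], dtype=int)
        ib = np.array([b.index_of(q) for _, q in self.pairs], dtype=int)
        return ia, ib

    def mapped_resnums_a(self) -> set[int]:
        return {p for p, _ in self.pairs}


# ---------------------------------------------------------------------------
# PDB reading


def _pick_ca(residue) -> np.ndarray | None:
    """Cα coordinate preferring altloc blank or 'A'."""
    if "CA" not in residue:
        return None
    atom = residue["CA"]
    if atom.is_disordered():
        children = atom.disordered_get_list()
        preferred = [a for a in children if a.get_altloc() in (" ", "", "A")]
        atom = preferred[0] if preferred else children[0]
    return np.asarray(atom.get_coord(), dtype=float)


def _residues_from_model(model, chain_id: str | None, path: str):
    chains = list(model.get_chains())
    if not chains:
        raise ValueError(f"{path}: no chains in model")
    if chain_id is None:
        chain = chains[0]
    else:
        match = [c for c in chains if c.id == chain_id]
        if not match:
            raise ValueError(f"{path}: chain {chain_id!r} not found")
        chain = match[0]
    residues: list[Residue] = []
    for res in chain:
        hetflag, resnum, icode = res.id
        if hetflag != " ":
            continue
        if icode != " ":
            raise ValueError(
                f"{path}: insertion-coded residue {resnum}{icode.strip()} not supported; "
                "renumber the structure first"
            )
        ca = _pick_ca(res)
        if ca is None:
            logger.warning("%s: residue %s %d has no Cα, skipped", path, res.resname, resnum)
            continue
        residues.append(
            Residue(resnum=resnum, chain=chain.id, resname=res.resname, ca=tuple(ca))
        )
    return residues


def read_structure(
    path: str | Path,
    model_index: int = 0,
    chain: str | None = None,
    variant: str = "WT",
    id: str | None = None,
) -> Structure:
    """Read one model of a PDB file as a Cα-only :class:`Structure`.

    A file without MODEL records counts as one model, index 0.  Residues
    missing a Cα atom are skipped with a warning; non-CA atoms are
    ignored; altloc blank/'A' is preferred.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        pdb = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # biopython raises assorted types on bad input
        raise ValueError(f"{path}: unparseable PDB file: {exc}") from exc
    models = list(pdb.get_models())
    if model_index < 0 or model_index >= len(models):
        raise IndexError(
            f"{path}: model {model_index} out of range (file has {len(models)} model(s))"
        )
    residues = _residues_from_model(models[model_index], chain, str(path))
    if not residues:
        raise ValueError(f"{path}: no Cα atoms found")
    return Structure(id=id or path.stem, residues=residues, variant=variant)


def read_trajectory(
    path: str | Path, chain: str | None = None, variant: str = "WT"
) -> Trajectory:
    """Read a multi-model PDB as a trajectory (frame i = model i, 0-based).

    All models must share one residue topology; the first discordant
    residue is named in the error otherwise.
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        pdb = parser.get_structure(path.stem, str(path))
    except Exception as exc:
        raise ValueError(f"{path}: unparseable PDB file: {exc}") from exc
    models = list(pdb.get_models())
    if not models:
        raise ValueError(f"{path}: no models found")

    ref = _residues_from_model(models[0], chain, str(path))
    ref_key = [(r.resnum, r.resname, r.chain) for r in ref]
    frames = np.empty((len(models), len(ref), 3))
    frames[0] = np.stack([r.ca_array for r in ref])
    for i, model in enumerate(models[1:], start=1):
        cur = _residues_from_model(models[i], chain, str(path))
        cur_key = [(r.resnum, r.resname, r.chain) for r in cur]
        if cur_key != ref_key:
            bad = _first_discordant(ref_key, cur_key)
            raise ValueError(
                f"{path}: model {i} topology mismatch at residue {bad}"
            )
        frames[i] = np.stack([r.ca_array for r in cur])
    topology = Structure(id=path.stem, residues=ref, variant=variant)
    return Trajectory(topology=topology, frames=frames)


def _first_discordant(ref_key, cur_key):
    for a, b in zip(ref_key, cur_key):
        if a != b:
            return b[0] if b else a[0]
    longer = ref_key if len(ref_key) > len(cur_key) else cur_key
    return longer[min(len(ref_key), len(cur_key))][0]


# ---------------------------------------------------------------------------
# PDB writing (Cα traces / multi-model trajectories)


def _atom_line(serial: int, resname: str, chain: str, resnum: int, xyz) -> str:
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d}  CA  {resname:>3s} {chain:1s}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{'C':>2s}\n"
    )


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Cα trace as a single-model PDB file."""
    with open(path, "w") as fh:
        for i, r in enumerate(s.residues, start=1):
            fh.write(_atom_line(i, r.resname, r.chain, r.resnum, r.ca))
        fh.write("END\n")


def write_trajectory(t: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    with open(path, "w") as fh:
        for f in range(t.n_frames):
            fh.write(f"MODEL     {f + 1:4d}\n")
            for i, r in enumerate(t.topology.residues, start=1):
                fh.write(_atom_line(i, r.resname, r.chain, r.resnum, t.frames[f, i - 1]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Mutation specs

_SUB_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_DELRANGE_RE = re.compile(r"^del(\d+)-(\d+)$", re.IGNORECASE)
_DELALIAS_RE = re.compile(r"^del([A-Za-z0-9]+)$", re.IGNORECASE)


def parse_mutation_spec(
    text: str, aliases: dict[str, tuple[int, int]] | None = None
) -> MutationSpec:
    """Parse ``T790M``-style substitutions and ``del746-750`` deletions.

    Named deletion aliases like ``del19`` are accepted only when
    ``aliases`` supplies the concrete residue range, e.g.
    ``{"del19": (746, 750)}``.
    """
    text = text.strip()
    m = _SUB_RE.match(text)
    if m:
        wt, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        if wt not in _AA1 or alt not in _AA1:
            raise ValueError(f"{text!r}: not a standard amino-acid code")
        return MutationSpec(
            kind="substitution", wt_residue=wt, position=pos, alt_residue=alt, label=text
        )
    m = _DELRANGE_RE.match(text)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        return MutationSpec(kind="deletion", start=start, end=end, label=text)
    m = _DELALIAS_RE.match(text)
    if m:
        key = text
        table = aliases or {}
        rng = table.get(key) or table.get(key.lower())
        if rng is None:
            raise ValueError(
                f"{text!r}: deletion alias has no configured residue range"
            )
        start, end = int(rng[0]), int(rng[1])
        return MutationSpec(kind="deletion", start=start, end=end, label=text)
    raise ValueError(f"{text!r}: cannot parse mutation specification")


def format_mutation_spec(spec: MutationSpec) -> str:
    """Canonical string form; inverse of :func:`parse_mutation_spec`."""
    if spec.kind == "substitution":
        return f"{spec.wt_residue}{spec.position}{spec.alt_residue}"
    return f"del{spec.start}-{spec.end}"


def aa3(one_letter: str) -> str:
    """Three-letter residue code for a one-letter amino-acid code."""
    try:
        return _AA1TO3[one_letter.upper()]
    except KeyError:
        raise ValueError(f"{one_letter!r}: not a standard amino-acid code") from None


# ---------------------------------------------------------------------------
# Residue correspondence


def map_shared_residues(a: Structure, b: Structure) -> ResidueMap:
    """Pair residues with equal residue numbers present in both structures.

    Residues absent from either side stay unmapped (gaps for deletion
    variants).  Raises if the structures share no residue number.
    """
    nums_a = set(a.resnums)
    nums_b = set(b.resnums)
    shared = sorted(nums_a & nums_b)
    if not shared:
        raise ValueError(
            f"structures {a.id!r} and {b.id!r} share no residue numbers"
        )
    return ResidueMap(pairs=tuple((n, n) for n in shared))
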