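"""Ligand-binding energies from component single-point energies.

The binding energy of a ligand to a protein pocket is assembled from
three component energies computed by an external quantum-chemistry
engine:

    E_binding = E_complex - (E_protein + E_ligand)

with all quantities in kcal/mol and more negative values more
favorable.  (The interaction-energy definition groups the protein and
ligand terms; this is the only reading under which favorable complexes
come out negative.)  The engine itself is out of scope: this module
consumes a component-energy table — the adapter contract is simply one
row per labeled structure with the three energies — and produces a
ranked variant-preference report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class EnergyComponents:
    """Single-point energies (kcal/mol) for one labeled complex."""

    label: str
    e_complex: float
    e_protein: float
    e_ligand: float
    variant: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        for name in ("e_complex", "e_protein", "e_ligand"):
            v = getattr(self, name)
            if v is None or not math.isfinite(float(v)):
                raise ValueError(f"{self.label}: component {name} missing or non-finite")


def binding_energy(c: EnergyComponents) -> float:
    """E_complex - (E_protein + E_ligand), kcal/mol."""
    return c.e_complex - (c.e_protein + c.e_ligand)


@dataclass
class BindingReport:
    """Rows sorted most-favorable-first, with a variant preference order."""

    df: pd.DataFrame  # label, e_binding, variant, note, unfavorable
    preference_order: str

    def to_tsv(self, path=None) -> str:
        text = (
            f"# variant preference: {self.preference_order}\n"
            + self.df.to_csv(sep="\t", index=False, float_format="%.2f")
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def compare_variants(rows: Sequence[EnergyComponents]) -> BindingReport:
    """Ranked binding report across structures and variants.

    Rows sort ascending by binding energy (most favorable first); rows
    with positive binding energy are flagged ``unfavorable``.  The
    preference-order string (e.g. ``"T790M > L858R > WT"``) orders each
    variant by its most favorable row.
    """
    if not rows:
        raise ValueError("need at least one component row")
    records = [
        {
            "label": c.label,
            "e_binding": binding_energy(c),
            "variant": c.variant,
            "note": c.note,
        }
        for c in rows
    ]
    df = pd.DataFrame(records).sort_values(
        ["e_binding", "label"], kind="mergesort"
    ).reset_index(drop=True)
    df["unfavorable"] = df["e_binding"] > 0.0

    order: list[str] = []
    for v in df["variant"]:
        if v and v not in order:
            order.append(v)
    return BindingReport(df=df, preference_order=" > ".join(order))


def load_components(path: str | Path) -> list[EnergyComponents]:
    """Read a component CSV: label,variant,e_complex,e_protein,e_ligand[,note]."""
    df = pd.read_csv(path)
    required = {"label", "e_complex", "e_protein", "e_ligand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        rows.append(
            EnergyComponents(
                label=str(rec["label"]),
                e_complex=float(rec["e_complex"]),
                e_protein=float(rec["e_protein"]),
                e_ligand=float(rec["e_ligand"]),
                variant=str(rec.get("variant", "") or ""),
                note=str(rec.get("note", "") or ""),
            )
        )
    return rows
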