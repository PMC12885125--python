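"""Ensemble docking-score enrichment analysis and hit selection.

Scores are long-format records (compound, receptor conformation,
binding site, docked energy in kcal/mol) with lower (more negative)
energies better, as for free-energy docking scores.  A ranked screen is
judged by the percent of known active compounds recovered within the
top fraction of the ranking, against the random diagonal: a
conformation/site is performing better than random at fraction f when
its recovery strictly exceeds 100·f.

Missing scores are left missing: averages run over the conformations a
compound was actually scored in, and a compound absent from a
conformation's table simply cannot rank there.  Imputing a worst-case
energy for docking failures would bias enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("compound_id", "conformation", "site", "energy")


@dataclass
class ScoreTable:
    """Validated long-format docking scores plus the active-compound set."""

    df: pd.DataFrame
    actives: frozenset[str]

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"score table missing column(s): {missing}")
        df = self.df.copy()
        df["compound_id"] = df["compound_id"].astype(str)
        df["conformation"] = df["conformation"].astype(int)
        df["site"] = df["site"].astype(int)
        df["energy"] = pd.to_numeric(df["energy"], errors="raise").astype(float)
        if not np.all(np.isfinite(df["energy"])):
            raise ValueError("non-finite energies in score table")
        dup = df.duplicated(subset=["compound_id", "conformation", "site"], keep=False)
        if dup.any():
            n = int(dup.sum())
            logger.warning(
                "%d duplicate (compound, conformation, site) rows; keeping best energy", n
            )
            df = (
                df.sort_values("energy", kind="mergesort")
                .drop_duplicates(subset=["compound_id", "conformation", "site"], keep="first")
            )
        self.df = df.reset_index(drop=True)
        self.actives = frozenset(str(a) for a in self.actives)
        absent = self.actives - set(self.df["compound_id"])
        if absent:
            logger.warning(
                "%d active compound(s) absent from the score table; they count as "
                "never found: %s",
                len(absent), sorted(absent)[:5],
            )

    @property
    def compounds(self) -> list[str]:
        return sorted(self.df["compound_id"].unique())

    def conformation_sites(self) -> list[tuple[int, int]]:
        pairs = self.df[["conformation", "site"]].drop_duplicates()
        return sorted(map(tuple, pairs.to_numpy()))


def load_scores(path: str | Path, actives_path: str | Path) -> ScoreTable:
    """Load a scores CSV/TSV and a newline-delimited active-compound list."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    actives = frozenset(
        line.strip()
        for line in Path(actives_path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    )
    if not actives:
        raise ValueError(f"{actives_path}: no active compounds listed")
    return ScoreTable(df=df, actives=actives)


# ---------------------------------------------------------------------------
# Rankings


def aggregate(t: ScoreTable, mode: str = "best") -> pd.DataFrame:
    """Per-compound ranking across all (conformation, site) scores.

    ``best`` takes the minimum (most negative) energy per compound;
    ``average`` the arithmetic mean over the rows that exist.  Output is
    sorted ascending by energy, ties broken by compound id, with a
    1-based ``rank`` column.
    """
    if mode not in ("best", "average"):
        raise ValueError("mode must be 'best' or 'average'")
    if t.df.empty:
        raise ValueError("empty score table")
    agg = t.df.groupby("compound_id")["energy"].agg(
        "min" if mode == "best" else "mean"
    )
    out = agg.rename("energy").reset_index()
    out = out.sort_values(["energy", "compound_id"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def conformation_site_ranking(t: ScoreTable, conformation: int, site: int) -> pd.DataFrame:
    """Ranking restricted to one conformation/site table."""
    sub = t.df[(t.df["conformation"] == conformation) & (t.df["site"] == site)]
    if sub.empty:
        raise ValueError(f"no scores for conformation {conformation}, site {site}")
    out = sub[["compound_id", "energy"]].sort_values(
        ["energy", "compound_id"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Enrichment curves


@dataclass
class EnrichmentCurve:
    """Percent of actives recovered vs fraction of the ranking screened.

    A step curve with one point per rank; the random baseline at
    fraction f is 100·f.  The curve ends at (1.0, 100.0) only when every
    active was actually scored.
    """

    fractions: np.ndarray
    pct_actives_found: np.ndarray
    source: str
    n_actives: int
    variant: str | None = None

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.pct_actives_found = np.asarray(self.pct_actives_found, dtype=float)
        if np.any(np.diff(self.fractions) < 0) or np.any(np.diff(self.pct_actives_found) < -1e-12):
            raise ValueError("enrichment curve must be nondecreasing")

    def baseline(self) -> np.ndarray:
        return 100.0 * self.fractions

    def recovery_at(self, fraction: float) -> float:
        """Percent of actives within the top floor(fraction·N) ranks."""
        n = len(self.fractions)
        n_top = math.floor(fraction * n)
        if n_top == 0:
            return 0.0
        return float(self.pct_actives_found[n_top - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction_screened": self.fractions,
                "pct_actives_found": self.pct_actives_found,
                "baseline": self.baseline(),
                "source": self.source,
            }
        )


def enrichment_curve(
    ranking: pd.DataFrame,
    actives: Iterable[str],
    source: str = "ranking",
    variant: str | None = None,
) -> EnrichmentCurve:
    """Enrichment curve of a ranking against a set of known actives.

    The denominator is the full active set: actives missing from the
    ranking are counted as never found, so the curve tops out below 100%.
    """
    actives = frozenset(str(a) for a in actives)
    if not actives:
        raise ValueError("empty active set")
    ids = ranking["compound_id"].to_numpy()
    n = len(ids)
    is_active = np.isin(ids, sorted(actives))
    found = np.cumsum(is_active)
    fractions = np.arange(1, n + 1) / n
    pct = 100.0 * found / len(actives)
    return EnrichmentCurve(
        fractions=fractions,
        pct_actives_found=pct,
        source=source,
        n_actives=len(actives),
        variant=variant,
    )


@dataclass(frozen=True)
class TopFractionRecovery:
    recovery_pct: float
    enrichment_factor: float
    n_top: int
    n_actives_found: int


def top_fraction_recovery(
    ranking: pd.DataFrame, actives: Iterable[str], q: float
) -> TopFractionRecovery:
    """Percent of actives in the top floor(q·N) ranked compounds.

    Also reports the enrichment factor recovery / (100·q); 1.0 is the
    random expectation.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"q must be in (0, 1], got {q}")
    actives = frozenset(str(a) for a in actives)
    if not actives:
        raise ValueError("empty active set")
    ids = ranking["compound_id"].to_numpy()
    n_top = math.floor(q * len(ids))
    n_found = int(np.isin(ids[:n_top], sorted(actives)).sum())
    recovery = 100.0 * n_found / len(actives)
    return TopFractionRecovery(
        recovery_pct=recovery,
        enrichment_factor=recovery / (100.0 * q),
        n_top=n_top,
        n_actives_found=n_found,
    )


# ---------------------------------------------------------------------------
# Better-than-random report


@dataclass
class BetterThanRandomReport:
    """Per-curve flags at one screening fraction, with per-variant counts."""

    at: float
    rows: list[dict]

    @property
    def flagged_sources(self) -> list[str]:
        return [r["source"] for r in self.rows if r["flagged"]]

    def counts_per_variant(self) -> dict:
        out: dict = {}
        for r in self.rows:
            key = r["variant"]
            total, flagged = out.get(key, (0, 0))
            out[key] = (total + 1, flagged + int(r["flagged"]))
        return out

    def to_tsv(self, path=None) -> str:
        lines = [f"# better-than-random at fraction {self.at}",
                 "source\tvariant\trecovery_pct\tbaseline_pct\tflagged"]
        for r in self.rows:
            lines.append(
                f"{r['source']}\t{r['variant'] or ''}\t{r['recovery_pct']:.2f}"
                f"\t{r['baseline_pct']:.2f}\t{int(r['flagged'])}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def better_than_random(
    curves: Sequence[EnrichmentCurve], at: float
) -> BetterThanRandomReport:
    """Flag curves whose recovery at the given fraction strictly beats random.

    A curve equal to the baseline is not flagged.  Counts are summarized
    per variant when curves carry one.
    """
    if not (0.0 < at <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {at}")
    rows = []
    for c in curves:
        rec = c.recovery_at(at)
        base = 100.0 * at
        rows.append(
            {
                "source": c.source,
                "variant": c.variant,
                "recovery_pct": rec,
                "baseline_pct": base,
                "flagged": rec > base,
            }
        )
    return BetterThanRandomReport(at=at, rows=rows)


# ---------------------------------------------------------------------------
# Multi-conformation hit selection


@dataclass
class HitList:
    """Compounds ranked by how many conformation/site screens they top."""

    df: pd.DataFrame  # compound_id, n_conformations_in_top_q, best_energy, mean_energy
    q: float
    min_conformations: int
    n_rankings: int

    def to_tsv(self, path=None) -> str:
        header = (
            f"# hits: top-{self.q:g} fraction in >= {self.min_conformations} of "
            f"{self.n_rankings} conformation/site rankings"
        )
        text = header + "\n" + self.df.to_csv(sep="\t", index=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def select_hits(t: ScoreTable, q: float, min_conformations: int = 2) -> HitList:
    """Tier-1 lead selection: a high score in multiple conformations.

    A compound qualifies when it lies in the top floor(q·N) of at least
    ``min_conformations`` per-(conformation, site) rankings.  Hits are
    ordered by that count (descending), then best energy, then id.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError(f"q must be in (0, 1], got {q}")
    if min_conformations < 1:
        raise ValueError("min_conformations must be >= 1")
    pairs = t.conformation_sites()
    counts: dict[str, int] = {}
    for conf, site in pairs:
        ranking = conformation_site_ranking(t, conf, site)
        n_top = math.floor(q * len(ranking))
        for cid in ranking["compound_id"].iloc[:n_top]:
            counts[cid] = counts.get(cid, 0) + 1

    stats = t.df.groupby("compound_id")["energy"].agg(["min", "mean"])
    rows = [
        {
            "compound_id": cid,
            "n_conformations_in_top_q": n,
            "best_energy": float(stats.loc[cid, "min"]),
            "mean_energy": float(stats.loc[cid, "mean"]),
        }
        for cid, n in counts.items()
        if n >= min_conformations
    ]
    df = pd.DataFrame(
        rows, columns=["compound_id", "n_conformations_in_top_q", "best_energy", "mean_energy"]
    )
    if not df.empty:
        df = df.sort_values(
            ["n_conformations_in_top_q", "best_energy", "compound_id"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return HitList(df=df, q=q, min_conformations=min_conformations, n_rankings=len(pairs))


def plot_curves(curves: Sequence[EnrichmentCurve], path: str | Path) -> None:
    """Basic enrichment plot: one line per curve plus the random diagonal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c in curves:
        ax.plot(c.fractions, c.pct_actives_found, lw=1, label=c.source)
    ax.plot([0, 1], [0, 100], "k--", lw=1, label="random")
    ax.set_xlabel("fraction of ranked compounds screened")
    ax.set_ylabel("% of actives recovered")
    if len(curves) <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
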