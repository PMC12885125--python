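"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the code paths they check: rotation search by
grid + polish instead of the closed-form fit, explicit double loops
instead of vectorized matrices, naive re-reading of PDB text instead of
the package parser.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def grid_min_rmsd(mobile, target, n_coarse=24):
    """Minimum RMSD over rigid motions via an SO(3) Euler grid plus polish."""
    a = np.asarray(mobile, float)
    b = np.asarray(target, float)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    alphas = np.linspace(0.0, 2 * np.pi, n_coarse, endpoint=False)
    betas = np.linspace(0.0, np.pi, max(2, n_coarse // 2))
    grid = [(x, y, z) for x in alphas for y in betas for z in alphas]
    rots = Rotation.from_euler("zyz", grid)
    moved = np.einsum("kij,mj->kmi", rots.as_matrix(), a)
    rmsds = np.sqrt(((moved - b[None]) ** 2).sum(axis=-1).mean(axis=-1))

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((a @ r.T - b) ** 2).sum(axis=-1).mean())

    # polish from several grid minima: a single basin hop can stall short
    # of the global optimum
    best = float(rmsds.min())
    for k in np.argsort(rmsds)[:8]:
        res = minimize(
            objective,
            rots[int(k)].as_rotvec(),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 5000},
        )
        best = min(best, float(res.fun))
    return best


def gromos_brute(matrix, cutoff):
    """Exhaustive restatement of the neighbor-count clustering rule.

    Returns [(sorted members, center), ...] in discovery order.
    """
    matrix = [list(map(float, row)) for row in np.asarray(matrix)]
    n = len(matrix)
    remaining = list(range(n))
    clusters = []
    while remaining:
        best, best_neighbors = None, None
        for i in remaining:  # ascending, so ties keep the lowest index
            neighbors = [j for j in remaining if j != i and matrix[i][j] <= cutoff]
            if best is None or len(neighbors) > len(best_neighbors):
                best, best_neighbors = i, neighbors
        members = sorted([best] + best_neighbors)
        clusters.append((members, best))
        remaining = [x for x in remaining if x not in members]
    return clusters


def tightness_brute(matrix, members):
    """Min over members of the mean distance to the other members."""
    if len(members) == 1:
        return 0.0
    best = None
    for i in members:
        mean = sum(matrix[i][j] for j in members if j != i) / (len(members) - 1)
        best = mean if best is None else min(best, mean)
    return float(best)


def read_pdb_atoms_naive(path):
    """(record, atom, resname, chain, resnum, xyz) from fixed PDB columns."""
    rows = []
    for line in open(path):
        if line.startswith(("ATOM  ", "HETATM")):
            rows.append(
                (
                    line[:6].strip(),
                    line[12:16].strip(),
                    line[17:20].strip(),
                    line[21],
                    int(line[22:26]),
                    np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])]),
                )
            )
    return rows


def pocket_brute(path, ligand_resname, r):
    """All-pairs distance scan for the pocket rule (closed threshold)."""
    rows = read_pdb_atoms_naive(path)
    lig = [xyz for rec, _, resname, _, _, xyz in rows
           if rec == "HETATM" and resname == ligand_resname]
    selected = set()
    for rec, _, resname, chain, resnum, xyz in rows:
        if rec != "ATOM":
            continue
        for lx in lig:
            if r > 0 and np.linalg.norm(xyz - lx) <= r:
                selected.add(resnum)
                break
    return selected


def top_fraction_brute(ordered_ids, active_set, q):
    """Prefix recount of the top-fraction recovery rule."""
    import math

    n_top = math.floor(q * len(ordered_ids))
    hits = sum(1 for cid in ordered_ids[:n_top] if cid in active_set)
    return 100.0 * hits / len(active_set)


def select_hits_brute(df, q, min_conformations):
    """Per-(conformation, site) top-q membership recount."""
    import math

    counts = {}
    for (conf, site), sub in df.groupby(["conformation", "site"]):
        ordered = sub.sort_values(["energy", "compound_id"], kind="mergesort")
        n_top = math.floor(q * len(ordered))
        for cid in ordered["compound_id"].iloc[:n_top]:
            counts[cid] = counts.get(cid, 0) + 1
    return {cid: n for cid, n in counts.items() if n >= min_conformations}
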