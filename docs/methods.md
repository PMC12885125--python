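# Methods

`ensdock` implements the analysis layer of an ensemble-based workflow for
assessing drug resistance in mutant kinases (the EGFR kinase domain and its
clinical variants — T790M, L858R, exon-19 deletions — are the motivating
system). Upstream heavy lifting (structure prediction, molecular dynamics,
docking engines, quantum chemistry) is explicitly out of scope: the package
consumes their standard outputs (PDB structures and multi-model PDB
trajectories, docking score tables, component single-point energies) and
performs the statistics and geometry that turn them into conclusions.

## Structures and correspondence

All comparative analyses run on Cα traces. Structures are read from PDB
files via Biopython, keeping one chain (the first by default), preferring
altloc blank/'A', skipping residues without a Cα (with a warning), and
rejecting insertion codes outright — the package assumes residue numbering
already harmonized to a common scheme (e.g. UniProt), so correspondences
between variants are built by shared residue *number*, never by alignment.
A deletion variant therefore maps with a gap, not a shift. Mutation
identifiers follow the clinical notation (`T790M`, `del746-750`); named
deletion aliases like `del19` require an explicit residue range in
configuration, since the shorthand does not determine the coordinates.

Trajectories are multi-model PDBs whose models must share one residue
topology; frame 0 is, by convention, the starting structure of the
simulation (for predicted models, the modeling output itself). The writer
emits standard fixed-width records, and round-trips are exact to the
format's 10⁻³ Å coordinate precision.

## Superposition and windowed RMSD

Rigid superposition is the least-squares (Kabsch) fit, computed through
`scipy.spatial.transform.Rotation.align_vectors`, which always returns a
proper rotation (det = +1) so protein chirality is never inverted. The
reported RMSD is evaluated from the applied transform rather than from the
solver's residual, which loses precision to cancellation near zero. For
all-pairs RMSD matrices a batched closed form is used: with both
conformations centered, `rmsd² = (|A|² + |B|² − 2(σ₁+σ₂±σ₃))/n` on the
singular values of the 3×3 cross-covariance, the sign chosen to keep the
optimal rotation proper.

Mutation-site comparisons use residue windows: a *sequence window* (± k
residues) or a *distance window* (all residues whose Cα lies within r Å of
the site's Cα, r = 5 Å being the usual choice). A window is resolved once
on a designated reference structure and propagated to every other structure
through the residue map, so all pairwise RMSDs in one analysis cover the
same residue set — per-structure windows would make the matrix entries
incomparable. Two open choices are fixed as follows and exposed as options:
distance thresholds are closed (d ≤ r), and windowed RMSD superposes on the
window itself by default (`superpose_scope="selection"`); a whole-domain
fit is available via `superpose_scope="whole"`. The local fit matches the
analyses' focus on local mutation effects; which scope upstream work used
is generally unstated, so both are provided.

The ligand-pocket selection is the one full-atom operation: protein
residues with *any* atom within r Å (closed) of *any* ligand atom, the
ligand identified by HETATM residue name (optionally qualified by chain and
number; ambiguity is an error listing candidates). The selected residues
plus the ligand can be written out as a PDB fragment — the input a
quantum-chemistry engine would take for pocket single-point energies.

## Clustering

Two clusterers share one tightness statistic: the minimum over cluster
members of that member's mean RMSD to the rest, with singletons reporting
exactly 0; the minimizing member doubles as a natural medoid.

*Hierarchical*: agglomerative clustering of the pairwise RMSD matrix
(scipy linkage; complete linkage by default, average/single available), cut
at a user-chosen k. No objective k-selection is imposed, because in
practice the group count is read off the clustered heatmap; clusters are
emitted in dendrogram leaf order to match that left-to-right reading. A
composition summary reports each cluster's percent WT vs mutant membership
(formatted to one decimal, raw fractions retained).

*GROMOS-style*: for trajectories. All pairwise frame RMSDs are computed
(superposed per pair, whole topology by default), then iteratively the
frame with the most neighbors within the cutoff seeds a cluster, the seed
("middle" frame) plus neighbors are removed, and counts are recomputed on
the remainder. The seed is the cluster representative — the natural
receptor candidate for ensemble docking. Determinism is pinned by breaking
neighbor-count ties toward the lowest frame index; neighbor counting
excludes self, so isolated frames become singletons with tightness 0. The
cutoff is deliberately a required parameter with no default: it sets the
granularity of the conformer definition and must be chosen per system
(for the synthetic fixtures, anything between the jitter scale and the
conformer separation recovers the planted partition).

## RMSF

Each frame is rigid-fitted on all Cα atoms to a reference — frame 0, or by
default the mean structure, refined by two fixed-point passes (align to
frame 0, re-align to the aligned mean; further iteration changes nothing
at these noise levels). RMSF_i is the root-mean-square deviation of residue
i's Cα about its mean aligned position. Profiles carry optional site
annotations (binding/active-site residues, mutation positions). A
single-frame trajectory is rejected rather than returning a silently
meaningless all-zero profile.

## Enrichment analysis

Docking scores are long-format records (compound, conformation, site,
energy); lower energy is better, following free-energy score conventions.
Within each conformation/site screen, compounds are ranked ascending by
energy with ties broken by compound id (full determinism). Ensemble
combinations rank by the best (minimum) or the arithmetic-mean energy
across available rows — "average" averages energies, not ranks, and a
compound's mean runs over the conformations it was actually scored in;
docking failures are left missing rather than imputed, which would bias
the curves. Duplicate (compound, conformation, site) rows keep the best
energy with a warning.

The enrichment curve reports, at every rank, the percent of the known
active set recovered, against the random diagonal (100·f at screened
fraction f). Actives missing from the table count as never found, so the
curve honestly tops out below 100%. Top-fraction recovery uses
n_top = ⌊q·N⌋ (a convention that had to be fixed; flooring is the
conservative choice) and also reports the enrichment factor
recovery/(100·q). A screen is "better than random" at fraction f when its
recovery *strictly* exceeds 100·f — a calibrated, not conservative, flag:
on a no-signal screen it fires about half the time, as the null
distribution of recovery is centered on the baseline. Conclusions should
therefore rest on counts of flagged conformations (as in comparing
variants), not on any single flag.

Tier-1 hit selection rewards consistency across the ensemble: a compound
qualifies when it lies in the top q of at least `min_conformations`
(default 2) per-conformation/site rankings, ordered by that count, then
best energy. Tier-2 (expert review) is inherently manual and out of scope.

## Binding-energy assembly

Binding energies are assembled from external single-point component
energies as E_binding = E_complex − (E_protein + E_ligand), in kcal/mol —
the standard interaction-energy grouping, and the only reading under which
favorable complexes come out negative. Unit conversion (e.g. hartree →
kcal/mol) belongs upstream. The report sorts most-favorable-first, flags
positive energies as unfavorable, and derives a variant preference string
(e.g. `T790M > L858R > WT`) from each variant's best row. The adapter
contract for any engine is a CSV row per labeled structure with the three
energies; whether the pocket geometry was relaxed before the single points
is the adapter author's concern, not this module's.

## Synthetic data

The generators are pure functions of a frozen config (seed included) and
always return ground truth alongside the data. Chains are idealized Cα
traces with exact 3.8 Å steps along a smooth random curve. Trajectories
draw frames from n conformers — the chain plus per-conformer isotropic
Gaussian displacement fields scaled so pairwise conformer RMSD ≈ the
configured separation (s = sep/√6 per coordinate) — with i.i.d. Gaussian
jitter on top. Mutants plant a localized perturbation (random unit
directions of fixed magnitude within a radius of the site) or a numbering-
preserving deletion. Score tables draw decoys from N(μ, σ) and actives
from N(μ−Δ, σ) per conformation/site; toy complexes place each residue's
nearest atom at a scripted distance from a single ligand atom.

Defaults are the study conditions the package targets: 100 trajectory
frames, 3 conformers at occupancies (0.6, 0.3, 0.1) with 2 Å separation
and 0.05 Å jitter; screens of 120 actives among 2500 decoys (the
DEKOIS-2.0-style benchmark shape) over 5 conformations with a 2 kcal/mol
active shift at unit σ; chain length 60, kept modest so test suites and
the acceptance script run in seconds. What the fixtures deliberately lack
is physics: no force field, no docking energetics, no correlated motions.
Passing tests therefore demonstrate that the *statistics and geometry* are
correct and calibrated — not that any particular real system's conformers,
scores, or energies will look like the fixtures.

## Numerical choices and limitations

- Batched RMSD clips tiny negative mean-square deviations to 0 before the
  square root; identical conformations report 0 to ~1e-7 Å.
- Degenerate (colinear/planar) point sets leave a rotation axis
  undetermined; any optimal rotation yields the same RMSD, so the solver's
  warning is suppressed.
- All orderings that could tie (score ties, neighbor-count ties, equal
  binding energies) are broken lexicographically or by lowest index, so
  every output table is byte-reproducible for a given seed.
- Insertion codes, multi-chain mapping, mmCIF, and alignment-based residue
  correspondence are unsupported; inputs must be renumbered first.
- The trajectory reader holds all frames in memory as a dense array —
  appropriate for the hundreds-of-frames scale of recorded snapshots, not
  for raw MD output.
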