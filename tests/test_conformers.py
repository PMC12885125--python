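import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ensdock import (
    Cluster,
    ClusterResult,
    RmsdMatrix,
    SynthConfig,
    Trajectory,
    composition,
    gromos_cluster,
    gromos_cluster_from_matrix,
    hierarchical_cluster,
    make_chain,
    make_trajectory,
    pairwise_rmsd,
    rmsf,
)

from conftest import random_rigid_motion, straight_chain
from _oracles import gromos_brute, tightness_brute


def random_distance_matrix(rng, n, scale=2.0):
    m = rng.uniform(0.05, scale, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


def planted_matrix(groups, within, between):
    """Block distance matrix with exact within/between values."""
    n = sum(groups)
    label = np.repeat(np.arange(len(groups)), groups)
    m = np.where(label[:, None] == label[None, :], within, between).astype(float)
    np.fill_diagonal(m, 0.0)
    return m, label


class TestPairwiseRmsd:
    def test_copies_give_zero_matrix(self, chain10):
        m = pairwise_rmsd([chain10, chain10, chain10])
        np.testing.assert_allclose(m.values, 0.0, atol=1e-7)

    def test_rigid_displacement_gives_zero(self, rng, chain10):
        rot, trans = random_rigid_motion(rng)
        moved = chain10.with_coords(chain10.coords @ rot.T + trans, id="moved")
        m = pairwise_rmsd([chain10, moved])
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_planted_conformers_separate(self):
        # 2 planted conformers x 2 jittered replicas: within-conformer
        # entries must sit far below between-conformer entries
        cfg = SynthConfig(seed=21, n_residues=40, n_frames=4,
                          n_conformers=2, conformer_weights=(0.5, 0.5),
                          jitter_sigma=0.05, conformer_separation=2.0)
        traj, assign = make_trajectory(cfg)
        items = [traj.frame_structure(i) for i in range(4)]
        m = pairwise_rmsd(items)
        within = [m.values[i, j] for i in range(4) for j in range(i + 1, 4)
                  if assign[i] == assign[j]]
        between = [m.values[i, j] for i in range(4) for j in range(i + 1, 4)
                   if assign[i] != assign[j]]
        assert within and between
        assert max(within) < min(between) / 5

    def test_requires_two_items(self, chain10):
        with pytest.raises(ValueError):
            pairwise_rmsd([chain10])

    def test_csv_round_trip(self, tmp_path, chain10):
        m = pairwise_rmsd([chain10, chain10.with_coords(chain10.coords + 1.0, id="b")])
        path = tmp_path / "m.csv"
        m.to_csv(path)
        back = RmsdMatrix.from_csv(path)
        assert back.labels == m.labels
        np.testing.assert_allclose(back.values, m.values, atol=1e-12)


class TestHierarchical:
    def test_k_equals_n_gives_singletons(self, rng):
        n = 6
        m = RmsdMatrix(labels=[f"s{i}" for i in range(n)],
                       values=random_distance_matrix(rng, n))
        res = hierarchical_cluster(m, k=n)
        assert res.sizes() == [1] * n
        assert all(c.tightness_rmsd == 0.0 for c in res.clusters)

    def test_k_one_gives_single_cluster(self, rng):
        n = 5
        m = RmsdMatrix(labels=[f"s{i}" for i in range(n)],
                       values=random_distance_matrix(rng, n))
        res = hierarchical_cluster(m, k=1)
        assert res.sizes() == [n]

    @pytest.mark.parametrize("linkage", ["complete", "average", "single"])
    def test_recovers_planted_partition(self, linkage):
        values, label = planted_matrix([4, 4], within=0.25, between=2.5)
        m = RmsdMatrix(labels=[f"s{i}" for i in range(8)], values=values)
        res = hierarchical_cluster(m, k=2, linkage=linkage)
        expected = {frozenset(f"s{i}" for i in np.nonzero(label == g)[0]) for g in (0, 1)}
        assert res.partition() == expected

    def test_matches_sklearn_reference(self, rng):
        from sklearn.cluster import AgglomerativeClustering

        for trial in range(10):
            n = int(rng.integers(5, 12))
            k = int(rng.integers(2, n))
            values = random_distance_matrix(rng, n)
            m = RmsdMatrix(labels=[str(i) for i in range(n)], values=values)
            for linkage in ("complete", "average", "single"):
                ours = hierarchical_cluster(m, k=k, linkage=linkage)
                ref = AgglomerativeClustering(
                    n_clusters=k, metric="precomputed", linkage=linkage
                ).fit_predict(values)
                ref_partition = {
                    frozenset(str(i) for i in np.nonzero(ref == g)[0])
                    for g in np.unique(ref)
                }
                assert ours.partition() == ref_partition

    def test_recovers_well_separated_partitions_always(self, rng):
        # separation ratio >= 5 between planted groups: recovery must be
        # certain, not merely likely
        for seed in range(100):
            local = np.random.default_rng(seed)
            sizes = [int(local.integers(2, 5)) for _ in range(3)]
            values, label = planted_matrix(sizes, within=0.3, between=1.6)
            jitter = local.uniform(0, 0.05, size=values.shape)
            values = values + (jitter + jitter.T) * (values > 0)
            m = RmsdMatrix(labels=[str(i) for i in range(sum(sizes))], values=values)
            res = hierarchical_cluster(m, k=3)
            expected = {
                frozenset(str(i) for i in np.nonzero(label == g)[0]) for g in range(3)
            }
            assert res.partition() == expected

    def test_tightness_and_representative_definition(self, rng):
        n = 7
        values = random_distance_matrix(rng, n)
        m = RmsdMatrix(labels=[str(i) for i in range(n)], values=values)
        res = hierarchical_cluster(m, k=2)
        for c in res.clusters:
            members = [int(x) for x in c.members]
            assert c.tightness_rmsd == pytest.approx(tightness_brute(values, members))
            assert c.representative in c.members

    def test_k_out_of_range(self, rng):
        m = RmsdMatrix(labels=["a", "b", "c"], values=random_distance_matrix(rng, 3))
        with pytest.raises(ValueError):
            hierarchical_cluster(m, k=0)
        with pytest.raises(ValueError):
            hierarchical_cluster(m, k=4)


class TestComposition:
    @staticmethod
    def _result(sizes_and_labels):
        clusters, labels = [], {}
        idx = 0
        for size, n_mutant in sizes_and_labels:
            members = tuple(f"m{idx + i}" for i in range(size))
            for i, m in enumerate(members):
                labels[m] = "mutant" if i < n_mutant else "WT"
            clusters.append(Cluster(members=members, representative=members[0],
                                    size=size, tightness_rmsd=0.1))
            idx += size
        return ClusterResult(clusters=clusters, method="hierarchical", params={}), labels

    def test_mostly_mutant_cluster_percentage(self):
        res, labels = self._result([(8, 7)])
        row = composition(res, labels).rows[0]
        assert row["pct_mutant"] == pytest.approx(87.5)
        assert row["pct_wt"] == pytest.approx(12.5)

    def test_minority_wt_percentage(self):
        res, labels = self._result([(13, 10)])
        row = composition(res, labels).rows[0]
        assert row["pct_wt"] == pytest.approx(100 * 3 / 13)
        assert f"{row['pct_wt']:.1f}" == "23.1"

    def test_all_wt_cluster(self):
        res, labels = self._result([(5, 0)])
        row = composition(res, labels).rows[0]
        assert row["pct_mutant"] == 0.0

    def test_percentages_sum_to_100(self):
        res, labels = self._result([(8, 3), (6, 6), (4, 1)])
        for row in composition(res, labels).rows:
            assert row["pct_wt"] + row["pct_mutant"] == pytest.approx(100.0)

    def test_relabel_swap_symmetry(self):
        res, labels = self._result([(9, 4)])
        swapped = {k: ("WT" if v == "mutant" else "mutant") for k, v in labels.items()}
        a = composition(res, labels).rows[0]
        b = composition(res, swapped).rows[0]
        assert a["pct_wt"] == pytest.approx(b["pct_mutant"])

    def test_unlabeled_member_raises(self):
        res, labels = self._result([(4, 2)])
        labels.pop(next(iter(labels)))
        with pytest.raises(ValueError, match="unlabeled"):
            composition(res, labels)


class TestGromos:
    def test_identical_frames_single_cluster(self):
        chain = straight_chain(10)
        frames = np.repeat(chain.coords[None], 7, axis=0)
        res = gromos_cluster(Trajectory(topology=chain, frames=frames), cutoff=0.1)
        assert res.sizes() == [7]
        assert res.clusters[0].tightness_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_cutoff_below_all_distances_gives_singletons(self, small_cfg):
        traj, _ = make_trajectory(small_cfg)
        res = gromos_cluster(traj, cutoff=1e-6)
        assert res.sizes() == [1] * traj.n_frames
        assert all(c.tightness_rmsd == 0.0 for c in res.clusters)
        assert [c.representative for c in res.clusters] == list(range(traj.n_frames))

    def test_recovers_planted_three_conformers(self):
        cfg = SynthConfig(seed=33, n_residues=30, n_frames=12, n_conformers=3,
                          conformer_weights=(5 / 12, 4 / 12, 3 / 12),
                          jitter_sigma=0.05, conformer_separation=2.0)
        traj, assign = make_trajectory(cfg)
        res = gromos_cluster(traj, cutoff=0.5)
        expected = {frozenset(np.nonzero(assign == g)[0].tolist())
                    for g in np.unique(assign)}
        assert res.partition() == expected

    def test_matches_brute_force_on_random_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 13))
            values = random_distance_matrix(rng, n)
            cutoff = float(rng.uniform(0.1, 2.0))
            res = gromos_cluster_from_matrix(values, cutoff)
            expected = gromos_brute(values, cutoff)
            got = [(list(c.members), c.representative) for c in res.clusters]
            assert got == expected
            for c in res.clusters:
                assert c.tightness_rmsd == pytest.approx(
                    tightness_brute(values, list(c.members))
                )

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_partition_invariants(self, seed):
        local = np.random.default_rng(seed)
        n = int(local.integers(1, 13))
        values = random_distance_matrix(local, n)
        cutoff = float(local.uniform(0.1, 2.5))
        res = gromos_cluster_from_matrix(values, cutoff)
        members = [m for c in res.clusters for m in c.members]
        assert sorted(members) == list(range(n))  # exact partition
        for c in res.clusters:
            rep = c.representative
            assert rep in c.members
            assert all(values[rep, m] <= cutoff for m in c.members)
            if c.size == 1:
                assert c.tightness_rmsd == 0.0

    def test_nonpositive_cutoff_rejected(self, small_cfg):
        traj, _ = make_trajectory(small_cfg)
        with pytest.raises(ValueError):
            gromos_cluster(traj, cutoff=0.0)

    def test_table_export_shapes(self, small_cfg, tmp_path):
        traj, _ = make_trajectory(small_cfg)
        res = gromos_cluster(traj, cutoff=0.5)
        tsv = res.to_tsv(tmp_path / "c.tsv", header_comment="params")
        lines = [l for l in tsv.splitlines() if not l.startswith("#")]
        assert len(lines) == len(res.clusters) + 1  # header + one row each


class TestRmsf:
    def test_constant_trajectory_is_zero(self):
        chain = straight_chain(12)
        frames = np.repeat(chain.coords[None], 10, axis=0)
        prof = rmsf(Trajectory(topology=chain, frames=frames))
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    @pytest.mark.parametrize("superpose_to", ["mean", "frame0"])
    def test_two_frame_single_displacement(self, superpose_to):
        # a 1 Å displacement of one residue between two frames fluctuates
        # +/- 0.5 Å about the mean; a large rigid anchor pins the fit
        chain = make_chain(SynthConfig(seed=6, n_residues=200))
        f0 = chain.coords
        f1 = f0.copy()
        j = 100
        f1[j] += np.array([1.0, 0.0, 0.0])
        prof = rmsf(Trajectory(topology=chain, frames=np.stack([f0, f1])),
                    superpose_to=superpose_to)
        assert prof.rmsf[j] == pytest.approx(0.5, abs=0.01)
        others = np.delete(prof.rmsf, j)
        assert others.max() < 0.02

    def test_planted_flexible_window(self):
        rng = np.random.default_rng(77)
        chain = make_chain(SynthConfig(seed=7, n_residues=60))
        base = chain.coords
        window = np.arange(25, 35)
        sigma = np.full(60, 0.05)
        sigma[window] = 1.0
        frames = base[None] + rng.normal(size=(40, 60, 3)) * sigma[None, :, None]
        prof = rmsf(Trajectory(topology=chain, frames=frames))
        inside = prof.rmsf[window].mean()
        outside = np.delete(prof.rmsf, window).mean()
        assert inside > 5 * outside

    def test_rigid_motion_invariance(self, rng, small_cfg):
        traj, _ = make_trajectory(small_cfg)
        base = rmsf(traj).rmsf
        rot, trans = random_rigid_motion(rng)
        moved = Trajectory(topology=traj.topology,
                           frames=traj.frames @ rot.T + trans)
        np.testing.assert_allclose(rmsf(moved).rmsf, base, atol=1e-6)

    def test_single_frame_rejected(self):
        chain = straight_chain(5)
        with pytest.raises(ValueError, match="at least 2"):
            rmsf(Trajectory(topology=chain, frames=chain.coords[None]))

    def test_annotations_attach_to_known_residues(self, small_cfg):
        traj, _ = make_trajectory(small_cfg)
        prof = rmsf(traj)
        prof.annotate({3: "binding site", 999: "absent"})
        assert prof.annotations == {3: "binding site"}
        assert "binding site" in prof.to_tsv()
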