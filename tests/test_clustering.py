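"""Pooling, RMSD matrices, GROMOS clustering and transition statistics."""

import numpy as np
import pandas as pd
import pytest

from pepmd import (
    AtomSelection,
    BACKBONE,
    PeptidePositionMap,
    Trajectory,
    build_rmsd_matrix,
    default_four_state_spec,
    generate_multistate_trajectory,
    gromos_cluster,
    pool_and_subsample,
    transition_stats,
)
from pepmd.clustering import ConformationSet
from pepmd.errors import ConfigError, ContractError, StructureError

from conftest import make_point_topology
from oracles import gromos_brute_force, two_selection_rmsd_pair


def _multistate_traj(n_frames, seed=0, **kw):
    spec = default_four_state_spec(n_frames=n_frames, seed=seed, **kw)
    return generate_multistate_trajectory(spec)


CHAIN_P = AtomSelection(chain_ids=frozenset({"P"}))


class TestPooling:
    def test_stride_four_counts(self):
        traj, _ = _multistate_traj(100)
        pooled = pool_and_subsample([traj], [[CHAIN_P]], stride=4)
        assert pooled.n == 25
        assert list(pooled.provenance["frame"][:3]) == [0, 4, 8]

    def test_two_trajectories_two_sites(self):
        # two chains in one topology -> two binding sites per trajectory
        spec = default_four_state_spec(n_frames=40, seed=1)
        traj_p, _ = generate_multistate_trajectory(spec)
        from pepmd.synthetic import reference_peptide_frames

        other = reference_peptide_frames(chain_id="Q")
        topo = traj_p.topology + other["hairpin"].topology
        coords = np.concatenate(
            [traj_p.coords, np.tile(other["hairpin"].coords, (40, 1, 1))], axis=1
        )
        two_site = Trajectory(topo, coords, dt=traj_p.dt)
        sels = [CHAIN_P, AtomSelection(chain_ids=frozenset({"Q"}))]
        pooled = pool_and_subsample([two_site, two_site], [sels, sels], stride=1)
        assert pooled.n == 2 * 2 * 40
        assert set(map(tuple, pooled.provenance[["traj", "site"]].drop_duplicates().values)) == {
            (0, 0), (0, 1), (1, 0), (1, 1)
        }

    def test_incompatible_site_templates_rejected(self):
        traj, _ = _multistate_traj(10)
        topo = make_point_topology(8, "Q")
        other = Trajectory(topo, np.zeros((10, 8, 3)))
        with pytest.raises(StructureError):
            pool_and_subsample(
                [traj, other],
                [[CHAIN_P], [AtomSelection(chain_ids=frozenset({"Q"}))]],
                stride=1,
            )

    def test_invalid_stride_rejected(self):
        traj, _ = _multistate_traj(10)
        with pytest.raises(ConfigError):
            pool_and_subsample([traj], [[CHAIN_P]], stride=0)


def _conf_set(coords, template):
    prov = pd.DataFrame(
        {"traj": 0, "site": 0, "frame": np.arange(len(coords)), "time": np.arange(len(coords), dtype=float)}
    )
    return ConformationSet(coords=np.asarray(coords, float), template=template, provenance=prov)


class TestRmsdMatrix:
    def test_identical_conformations_give_zero_matrix(self, ref_frames):
        f = ref_frames["hairpin"]
        cs = _conf_set(np.tile(f.coords, (4, 1, 1)), f.topology)
        sel = AtomSelection(atom_names=BACKBONE)
        mat = build_rmsd_matrix(cs, sel, sel)
        assert np.allclose(mat.values, 0.0, atol=1e-9)

    def test_rigid_motion_removed_by_fit(self, ref_frames):
        from scipy.spatial.transform import Rotation

        f = ref_frames["lshape"]
        rot = Rotation.from_euler("xyz", [30, -40, 75], degrees=True).as_matrix()
        moved = f.coords @ rot.T + np.array([3.0, -2.0, 8.0])
        cs = _conf_set(np.stack([f.coords, moved]), f.topology)
        sel = AtomSelection(atom_names=BACKBONE)
        mat = build_rmsd_matrix(cs, sel, sel)
        assert mat.values[0, 1] < 1e-9

    def test_matches_per_pair_oracle(self, ref_frames):
        rng = np.random.default_rng(17)
        f = ref_frames["hairpin"]
        coords = np.stack(
            [ref_frames[n].coords for n in ref_frames]
            + [f.coords + rng.normal(0, 0.4, f.coords.shape)]
        )
        cs = _conf_set(coords, f.topology)
        pmap = PeptidePositionMap.from_topology(f.topology, "P")
        fit_sel = pmap.selection([0, -1, -2])
        bb = AtomSelection(atom_names=BACKBONE)
        mat = build_rmsd_matrix(cs, fit_sel, bb)
        fit_idx = fit_sel.resolve(f.topology)
        bb_idx = bb.resolve(f.topology)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                oracle = two_selection_rmsd_pair(
                    coords[j][fit_idx], coords[i][fit_idx],
                    coords[j][bb_idx], coords[i][bb_idx],
                )
                assert abs(mat.values[i, j] - oracle) < 1e-9

    def test_matrix_is_symmetric_with_zero_diagonal(self, ref_frames):
        rng = np.random.default_rng(3)
        f = ref_frames["vshape"]
        coords = f.coords[None] + rng.normal(0, 0.5, (6, f.n_atoms, 3))
        cs = _conf_set(coords, f.topology)
        sel = AtomSelection(atom_names=BACKBONE)
        mat = build_rmsd_matrix(cs, sel, sel)
        mat.validate()  # symmetry within 1e-9, zero diagonal, non-negative


class TestGromosCluster:
    def test_identical_conformations_form_one_full_cluster(self):
        mat = np.zeros((3, 3))
        res = gromos_cluster(mat, 1.5)
        assert res.n_clusters == 1
        assert res.sizes.tolist() == [3]
        assert np.isclose(res.percentages.sum(), 100.0)

    def test_two_separated_groups_recovered_with_percentages(self):
        # groups of 6 and 4, intra < 0.5 Å apart, inter = 10 Å
        rng = np.random.default_rng(0)
        pts = np.concatenate([rng.uniform(0, 0.2, (6, 3)),
                              rng.uniform(0, 0.2, (4, 3)) + 10.0])
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = gromos_cluster(dist, 1.5)
        assert res.sizes.tolist() == [6, 4]
        assert np.allclose(res.percentages, [60.0, 40.0])

    def test_tie_break_prefers_lowest_index(self):
        # two disjoint pairs: all neighbor counts equal (1); index 0 first
        dist = np.full((4, 4), 10.0)
        np.fill_diagonal(dist, 0.0)
        dist[0, 1] = dist[1, 0] = 1.0
        dist[2, 3] = dist[3, 2] = 1.0
        res = gromos_cluster(dist, 1.5)
        assert res.centers.tolist() == [0, 2]  # formation order on size ties

    def test_singletons_allowed(self):
        dist = np.full((3, 3), 10.0)
        np.fill_diagonal(dist, 0.0)
        dist[0, 1] = dist[1, 0] = 1.0
        res = gromos_cluster(dist, 1.5)
        assert res.n_clusters == 2
        assert res.sizes.tolist() == [2, 1]

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_on_random_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(2, 13))
        pts = rng.uniform(0, 4, (n, 3))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        cutoff = float(rng.uniform(0.5, 3.0))
        res = gromos_cluster(dist, cutoff)
        labels, centers = gromos_brute_force(dist, cutoff)
        assert res.labels.tolist() == labels
        assert res.centers.tolist() == centers

    def test_membership_radius_never_exceeds_cutoff(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 2, (60, 3))
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = gromos_cluster(dist, 1.2)
        for k, center in enumerate(res.centers, start=1):
            members = np.nonzero(res.labels == k)[0]
            assert dist[center, members].max() <= 1.2 + 1e-12

    def test_state_recovery_on_multistate_ensemble(self):
        # scaled-down version of the headline parameter-recovery readout
        spec = default_four_state_spec(n_frames=2000, seed=12)
        traj, _ = generate_multistate_trajectory(spec)
        pooled = pool_and_subsample([traj], [[CHAIN_P]], stride=1)
        bb = AtomSelection(atom_names=BACKBONE)
        mat = build_rmsd_matrix(pooled, bb, bb)
        res = gromos_cluster(mat, 1.5)
        assert res.n_clusters == 4
        fractions = np.sort(res.percentages)[::-1] / 100
        pops = np.sort(spec.stationary_populations)[::-1]
        for f, p in zip(fractions, pops):
            assert abs(f - p) <= 3 * np.sqrt(p * (1 - p) / pooled.n)


class TestTransitionStats:
    def _prov(self, n, traj=0, site=0):
        return pd.DataFrame({"traj": traj, "site": site, "frame": np.arange(n),
                             "time": np.arange(n, dtype=float)})

    def test_constant_labels_no_transitions(self):
        stats = transition_stats(np.ones(10, dtype=int), self._prov(10), 5.0)
        assert stats.n_transitions == 0
        assert stats.rate_per_ps == 0.0

    def test_alternating_labels_counted_exactly(self):
        stats = transition_stats(np.array([1, 2, 1, 2]), self._prov(4), 10.0)
        assert stats.n_transitions == 3
        assert np.isclose(stats.rate_per_ps, 0.1)
        assert stats.pair_counts["count"].sum() == 3

    def test_no_transitions_across_pooling_boundaries(self):
        prov = pd.concat([self._prov(3, site=0), self._prov(3, site=1)],
                         ignore_index=True)
        labels = np.array([1, 1, 1, 2, 2, 2])  # change only at the boundary
        stats = transition_stats(labels, prov, 1.0)
        assert stats.n_transitions == 0

    def test_missing_provenance_is_contract_error(self):
        with pytest.raises(ContractError):
            transition_stats(np.ones(4, dtype=int), pd.DataFrame({"frame": range(4)}), 1.0)

    def test_markov_chain_switch_rate_matches_theory(self):
        spec = default_four_state_spec(n_frames=20000, seed=2)
        _, labels = generate_multistate_trajectory(spec)
        stats = transition_stats(labels, self._prov(len(labels)), spec.dt)
        p_switch = 1.0 - float(np.sum(spec.stationary_populations**2))
        se = np.sqrt(p_switch * (1 - p_switch) / (len(labels) - 1))
        assert abs(stats.per_step_probability - p_switch) <= 3 * se
        assert np.isclose(stats.rate_per_ps, stats.per_step_probability / spec.dt)
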