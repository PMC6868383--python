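"""Clustering, state assignment, occupancy statistics and coordinate PCA."""

import numpy as np
import pytest

from triacyl import (
    Ensemble,
    SynthSpec,
    assign_states,
    conformational_preference,
    generate_ensemble,
    gromos_cluster,
    pca,
    rmsd,
    rmsd_matrix,
    state_fractions,
)


def brute_force_gromos(matrix, cutoff):
    """Independent re-implementation of the greedy rule with explicit loops."""
    n = matrix.shape[0]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        best_frame, best_count = None, -1
        for i in sorted(unassigned):
            count = sum(1 for j in unassigned if matrix[i, j] <= cutoff)
            if count > best_count:
                best_frame, best_count = i, count
        members = sorted(j for j in unassigned if matrix[best_frame, j] <= cutoff)
        clusters.append((best_frame, tuple(members)))
        unassigned -= set(members)
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return clusters


def backbone_ensemble(templates, frames):
    coords = np.asarray(frames, dtype=float)
    return Ensemble(topology=templates.topology, coords=coords)


class TestGromosCluster:
    def test_two_well_separated_groups(self, cca_templates):
        frames = [cca_templates.collapsed] * 3 + [cca_templates.extended] * 2
        ens = backbone_ensemble(cca_templates, frames)
        result = gromos_cluster(ens, cca_templates.backbone_atoms, 0.5)
        assert result.sizes == [3, 2]
        assert sum(result.sizes) == 5

    def test_all_identical_frames_form_one_cluster(self, cca_templates):
        ens = backbone_ensemble(cca_templates, [cca_templates.collapsed] * 6)
        result = gromos_cluster(ens, cca_templates.backbone_atoms, 0.5)
        assert len(result.clusters) == 1
        assert result.clusters[0].size == 6

    def test_matches_brute_force_oracle_on_random_ensemble(self, cca_templates):
        spec = SynthSpec(weights=(0.4, 0.3, 0.3), jitter_sigma=0.4, n_frames=20, seed=3)
        ens, _ = generate_ensemble(cca_templates, spec)
        atoms = cca_templates.backbone_atoms
        for cutoff in (0.5, 1.0, 2.5):
            result = gromos_cluster(ens, atoms, cutoff)
            oracle = brute_force_gromos(rmsd_matrix(ens, atoms), cutoff)
            ours = [(c.center_frame, c.member_frames) for c in result.clusters]
            assert ours == oracle

    def test_sizes_non_increasing_and_partition_complete(self, small_mixture):
        ensemble, _ = small_mixture
        result = gromos_cluster(ensemble, ensemble.topology.groups["cluster_backbone"], 0.8)
        sizes = result.sizes
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        all_members = [f for c in result.clusters for f in c.member_frames]
        assert sorted(all_members) == list(range(ensemble.n_frames))

    def test_middle_frame_is_member_with_least_mean_rmsd(self, small_mixture):
        ensemble, _ = small_mixture
        atoms = ensemble.topology.groups["cluster_backbone"]
        matrix = rmsd_matrix(ensemble, atoms)
        result = gromos_cluster(ensemble, atoms, 0.8)
        top = result.clusters[0]
        members = np.array(top.member_frames)
        means = matrix[np.ix_(members, members)].mean(axis=1)
        assert top.middle_frame == members[np.argmin(means)]
        assert top.middle_frame in top.member_frames

    def test_invalid_cutoff_errors(self, small_mixture):
        ensemble, _ = small_mixture
        with pytest.raises(ValueError):
            gromos_cluster(ensemble, ensemble.topology.groups["cluster_backbone"], 0.0)


class TestAssignStates:
    def test_pure_and_intermediate_frames_labelled_correctly(self, cca_templates):
        atoms = np.asarray(cca_templates.backbone_atoms)
        col = cca_templates.collapsed[atoms]
        ext = cca_templates.extended[atoms]
        mid = 0.5 * (cca_templates.collapsed + cca_templates.extended)
        frames = [cca_templates.collapsed, cca_templates.extended, mid]
        ens = backbone_ensemble(cca_templates, frames)
        result = assign_states(ens, col, ext, atoms, cutoff=1.5)
        assert list(result.labels) == ["collapsed", "extended", "other"]
        assert result.rmsd_to_collapsed[0] == pytest.approx(0, abs=1e-9)

    def test_double_hit_goes_to_nearer_center(self, cca_templates):
        atoms = np.asarray(cca_templates.backbone_atoms)
        col = cca_templates.collapsed[atoms]
        ext = cca_templates.extended[atoms]
        near_ext = 0.25 * cca_templates.collapsed + 0.75 * cca_templates.extended
        ens = backbone_ensemble(cca_templates, [near_ext])
        # a generous cutoff puts the frame inside both shells
        result = assign_states(ens, col, ext, atoms, cutoff=10.0)
        assert result.rmsd_to_extended[0] < result.rmsd_to_collapsed[0]
        assert result.labels[0] == "extended"

    def test_exact_tie_resolves_to_collapsed(self, cca_templates):
        atoms = np.asarray(cca_templates.backbone_atoms)
        col = cca_templates.collapsed[atoms]
        ens = backbone_ensemble(cca_templates, [cca_templates.collapsed])
        result = assign_states(ens, col, col, atoms, cutoff=1.5)
        assert result.labels[0] == "collapsed"

    def test_infinite_cutoff_labels_nothing_other(self, small_mixture, cca_templates):
        ensemble, _ = small_mixture
        atoms = np.asarray(cca_templates.backbone_atoms)
        result = assign_states(
            ensemble,
            cca_templates.collapsed[atoms],
            cca_templates.extended[atoms],
            atoms,
            cutoff=1e9,
        )
        assert not np.any(result.labels == "other")
        assert result.f_collapsed + result.f_extended == pytest.approx(1.0)


class TestOccupancyStatistics:
    def test_fraction_example(self):
        labels = ["collapsed", "collapsed", "extended", "other", "other"]
        assert state_fractions(labels) == pytest.approx((0.4, 0.2, 0.4))

    def test_all_collapsed(self):
        assert state_fractions(["collapsed"] * 4) == pytest.approx((1.0, 0.0, 0.0))

    def test_fractions_sum_to_one(self, rng):
        labels = rng.choice(["collapsed", "extended", "other"], size=101)
        assert sum(state_fractions(labels)) == pytest.approx(1.0, abs=1e-12)

    def test_preference_zero_at_equal_occupancy(self):
        assert conformational_preference(0.3, 0.3) == pytest.approx(0.0)

    def test_preference_of_reference_average_occupancies(self):
        """Collapsed 20% vs extended 6.6% average occupancy gives -1.109."""
        assert conformational_preference(0.20, 0.066) == pytest.approx(-1.109, abs=5e-4)

    def test_preference_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.01, 1.0, size=2)
            assert conformational_preference(a, b) == pytest.approx(
                -conformational_preference(b, a), abs=1e-12
            )

    def test_zero_occupancy_is_flagged_undefined(self):
        assert np.isnan(conformational_preference(0.0, 0.5))
        assert np.isnan(conformational_preference(0.5, 0.0))


class TestPCA:
    def test_identical_frames_give_zero_spectrum(self, cca_templates):
        ens = backbone_ensemble(cca_templates, [cca_templates.collapsed] * 5)
        result = pca(ens, cca_templates.backbone_atoms)
        assert np.abs(result.eigenvalues).max() < 1e-10

    def test_planted_single_mode_dominates(self, cca_templates, rng):
        base = cca_templates.collapsed.copy()
        frames = []
        for k in range(40):
            f = base.copy()
            f[0, 0] += 3.0 * np.sin(2 * np.pi * k / 40)  # one atom oscillates along x
            frames.append(f)
        ens = backbone_ensemble(cca_templates, frames)
        result = pca(ens, np.arange(ens.n_atoms))
        assert result.eigenvalues[0] / result.eigenvalues.sum() > 0.99
        assert result.projections.shape == (40, 2)

    def test_eigenvalue_sum_equals_covariance_trace(self, small_mixture):
        ensemble, _ = small_mixture
        atoms = ensemble.topology.groups["cluster_backbone"]
        result = pca(ensemble, atoms)
        assert np.all(result.eigenvalues > -1e-8)
        # recompute the covariance trace per the documented fitting procedure
        from triacyl.geometry import kabsch_superpose

        sel = ensemble.coords[:, np.asarray(atoms), :]
        mean0 = sel.mean(axis=0)
        fitted = np.array([kabsch_superpose(mean0, f).apply(f) for f in sel])
        flat = (fitted - fitted.mean(axis=0)).reshape(ensemble.n_frames, -1)
        trace = (flat**2).sum() / ensemble.n_frames
        assert result.eigenvalues.sum() == pytest.approx(trace, rel=1e-6)

    def test_too_few_frames_errors(self, cca_templates):
        ens = backbone_ensemble(cca_templates, [cca_templates.collapsed] * 2)
        with pytest.raises(ValueError):
            pca(ens, cca_templates.backbone_atoms)
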