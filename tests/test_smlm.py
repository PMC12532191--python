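"""qSMLM analysis chain: drift, photophysics, counting, g(r), clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
import scipy.stats as sps

from memdomain import smlm
from memdomain.smlm import (
    LocalizationError,
    PhotophysicsModel,
    Roi,
    _square_set_covariance_integral,
    assign_clusters,
    correct_drift,
    count_molecules,
    estimate_photophysics,
    merge_localizations,
    pair_correlation,
)
from memdomain.synthetic_data import SmlmGroundTruth, simulate_smlm

from conftest import make_table


def csr_table(n, side, seed):
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0, side, (n, 2))
    return make_table(np.zeros(n), xy[:, 0], xy[:, 1])


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------


class TestDriftCorrection:
    def test_zero_drift_is_identity(self):
        f = np.arange(1000)
        tab = make_table(f, 5000.0 * np.ones(1000), 7000.0 * np.ones(1000),
                         fiducial=True)
        out = correct_drift(tab)
        np.testing.assert_allclose(out["x_nm"], 5000.0, atol=1e-9)
        np.testing.assert_allclose(out["y_nm"], 7000.0, atol=1e-9)

    def test_constructed_linear_drift_removed(self):
        """Noiseless fiducial under 0.001 nm/frame drift: residual RMS < 1 nm."""
        f = np.arange(60_000)
        tab = make_table(f, 5000 + 0.001 * f, 7000 + 0.0005 * f, fiducial=True)
        out = correct_drift(tab)
        dx = out["x_nm"] - out["x_nm"].mean()
        dy = out["y_nm"] - out["y_nm"].mean()
        assert np.sqrt((dx ** 2 + dy ** 2).mean()) < 1.0

    def test_no_fiducial_raises(self):
        tab = csr_table(200, 3000, 0)
        with pytest.raises(LocalizationError, match="no fiducial"):
            correct_drift(tab)

    def test_fiducial_found_by_persistence_without_flag(self):
        f = np.arange(2000)
        fid = make_table(f, 1000 + 0.01 * f, 1000.0 * np.ones(2000))
        tab = pd.concat([fid, csr_table(100, 5000, 1)], ignore_index=True)
        out = correct_drift(tab)
        assert out["is_fiducial"].sum() == 2000

    def test_recovers_simulated_drift_trajectory(self):
        truth = SmlmGroundTruth(drift_velocity=(0.003, -0.002))
        table, truth = simulate_smlm(truth, seed=2)
        out = correct_drift(table)
        est = out.attrs["drift_trajectory"]
        true = truth.drift_trajectory
        err = (est - est[0]) - (true - true[0])
        assert np.sqrt((err ** 2).sum(axis=1).mean()) < 5.0


# ---------------------------------------------------------------------------
# photophysics
# ---------------------------------------------------------------------------


class TestPhotophysics:
    def test_single_appearance_probes_give_alpha_one(self):
        tab = csr_table(50, 100_000, 3)
        phys = estimate_photophysics(tab, frame_exposure=0.01)
        assert phys.alpha == 1.0

    def test_hand_enumerated_groups(self):
        """Probes with frame sets {1,2,10} and {5}: alpha 2.0, max gap 8 frames."""
        frames, xs, ys = [], [], []
        for k in range(5):  # five copies, well separated, to clear the group minimum
            x0 = 10_000.0 * k
            frames += [1, 2, 10]
            xs += [x0, x0, x0]
            ys += [0.0, 0.0, 0.0]
            frames += [5]
            xs += [x0 + 5000.0]
            ys += [5000.0]
        tab = make_table(frames, xs, ys)
        phys = estimate_photophysics(tab, frame_exposure=1.0)
        assert phys.alpha == pytest.approx(2.0)
        assert phys.max_dark_time == pytest.approx(8.0)
        assert phys.max_dark_frames == 8

    def test_recovers_simulated_alpha(self):
        """Sparse field with alpha 3.3: estimate within 5% (1e4 probes)."""
        truth = SmlmGroundTruth(cluster_density=0.0, background_density=0.5,
                                field_size=141.0, alpha_true=3.3,
                                localization_precision=10.0,
                                drift_velocity=(0.0, 0.0))
        table, truth = simulate_smlm(truth, seed=7)
        phys = estimate_photophysics(table)
        assert abs(phys.alpha - 3.3) / 3.3 < 0.05

    def test_too_few_groups_raises(self):
        tab = make_table([0, 1], [0.0, 10.0], [0.0, 0.0])
        with pytest.raises(LocalizationError, match="need >= 10"):
            estimate_photophysics(tab)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------


class TestCounting:
    def test_alpha_division(self):
        """330 localizations in 1 um^2 at alpha 3.3: 100 molecules/um^2."""
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 1000, (330, 2))
        tab = make_table(np.zeros(330), xy[:, 0], xy[:, 1])
        phys = PhotophysicsModel(alpha=3.3, max_dark_time=1.0, max_dark_frames=100)
        assert count_molecules(tab, Roi((0, 0), 1000), phys) == pytest.approx(100.0)

    def test_empty_roi_returns_zero_with_warning(self):
        tab = make_table([0], [5000.0], [5000.0])
        phys = PhotophysicsModel(alpha=3.3, max_dark_time=1.0, max_dark_frames=100)
        with pytest.warns(UserWarning, match="empty ROI"):
            assert count_molecules(tab, Roi((0, 0), 1000), phys) == 0.0

    def test_exact_for_no_blinking(self):
        """alpha=1, zero precision: detected density equals the true density."""
        truth = SmlmGroundTruth(cluster_density=0.0, background_density=30.0,
                                field_size=4.0, alpha_true=1.0,
                                localization_precision=0.0,
                                drift_velocity=(0.0, 0.0), n_fiducials=0)
        table, truth = simulate_smlm(truth, seed=4)
        phys = PhotophysicsModel(alpha=1.0, max_dark_time=1.0, max_dark_frames=1)
        roi = Roi((0, 0), 4000)
        mols = truth.molecule_positions
        assert count_molecules(table, roi, phys) == pytest.approx(len(mols) / 16.0)

    def test_recovers_known_density(self):
        """60 molecules/um^2 field: blinking-corrected density within 10%."""
        densities = []
        for s in range(5):
            truth = SmlmGroundTruth(cluster_density=0.0, background_density=60.0,
                                    field_size=4.0)
            table, _ = simulate_smlm(truth, seed=s)
            phys = PhotophysicsModel(alpha=3.3, max_dark_time=20.0,
                                     max_dark_frames=2000)
            densities.append(count_molecules(table, Roi((500, 500), 3000), phys))
        assert abs(np.mean(densities) - 60.0) / 60.0 < 0.10


# ---------------------------------------------------------------------------
# pair correlation
# ---------------------------------------------------------------------------


class TestPairCorrelation:
    def test_matches_brute_force_pair_counts(self):
        """Binned g(r) equals the O(n^2) pair-count oracle exactly."""
        side = 3000.0
        tab = csr_table(200, side, 1)
        pc = pair_correlation(tab, Roi((0, 0), side), fit=False)
        d = pdist(tab[["x_nm", "y_nm"]].to_numpy())
        edges = np.arange(0.0, 505.0, 10.0)
        obs, _ = np.histogram(d, edges)
        expected = 200 * 199 / 2 * _square_set_covariance_integral(edges, side)
        np.testing.assert_allclose(pc.g, obs / expected, rtol=0, atol=1e-12)

    def test_csr_is_flat_at_unity(self):
        """CSR points: mean g within 3 SE of 1 in every bin (100 seeds)."""
        side = 3000.0
        roi = Roi((0, 0), side)
        gs = np.array([pair_correlation(csr_table(500, side, s), roi, fit=False).g
                       for s in range(100)])
        mean = gs.mean(axis=0)
        se = gs.std(axis=0, ddof=1) / np.sqrt(100)
        assert np.all(np.abs(mean - 1.0) <= 3 * se)

    def test_recovers_cluster_correlation_length(self):
        """Clustered blinking field: xi within 25% of the analytic target."""
        xi_true = smlm.thomas_correlation_length(
            30.0, 15.0, cluster_density=5.0, molecules_per_cluster=10.0,
            alpha=3.3, background_density=20.0)
        xis = []
        for s in range(3):
            table, _ = simulate_smlm(SmlmGroundTruth(), seed=s)
            table = correct_drift(table)
            pc = pair_correlation(table, Roi((1000, 1000), 3000))
            assert pc.converged
            xis.append(pc.cluster_radius)
        assert abs(np.mean(xis) - xi_true) / xi_true < 0.25

    def test_rmax_beyond_roi_rejected(self):
        tab = csr_table(50, 400.0, 0)
        with pytest.raises(ValueError, match="edge correction"):
            pair_correlation(tab, Roi((0, 0), 400.0), r_max=500.0)


# ---------------------------------------------------------------------------
# merging and clustering
# ---------------------------------------------------------------------------


class TestMergeLocalizations:
    def test_blinking_track_collapses_to_one_molecule(self):
        tab = make_table([0, 3, 9], [100.0, 110.0, 90.0], [50.0, 50.0, 50.0])
        out = merge_localizations(tab, max_dark_frames=10)
        assert len(out) == 1
        assert out["n_locs"].iloc[0] == 3
        assert out["x_nm"].iloc[0] == pytest.approx(100.0)

    def test_long_dark_gap_splits_molecules(self):
        tab = make_table([0, 500], [100.0, 100.0], [50.0, 50.0])
        out = merge_localizations(tab, max_dark_frames=100)
        assert len(out) == 2

    def test_distant_molecules_not_merged(self):
        tab = make_table([0, 1], [0.0, 500.0], [0.0, 0.0])
        out = merge_localizations(tab, max_dark_frames=100)
        assert len(out) == 2


class TestAssignClusters:
    def test_empty_input_all_zero(self):
        rep = assign_clusters(np.empty((0, 2)), 50.0, 9.0)
        assert rep.molecules_per_cluster == 0.0
        assert rep.clusters_per_area == 0.0
        assert rep.clustered_fraction == 0.0

    def test_hand_enumerated_cluster(self):
        """6 molecules in a 50 nm disc + 3 isolated: one cluster, fraction 6/9."""
        rng = np.random.default_rng(0)
        disc = 1500 + 20 * rng.standard_normal((6, 2))
        lone = np.array([[200.0, 200.0], [2800.0, 300.0], [300.0, 2800.0]])
        rep = assign_clusters(np.vstack([disc, lone]), 50.0, 9.0)
        assert rep.n_clusters == 1
        assert rep.molecules_per_cluster == pytest.approx(6.0)
        assert rep.clustered_fraction == pytest.approx(6.0 / 9.0)

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError, match="cluster_radius"):
            assign_clusters(np.zeros((3, 2)), 0.0, 9.0)

    def test_translation_invariance(self):
        """Shifting all molecules by a constant changes no report field."""
        rng = np.random.default_rng(5)
        xy = rng.uniform(0, 3000, (300, 2))
        a = assign_clusters(xy, 50.0, 9.0)
        b = assign_clusters(xy + np.array([12_345.6, -9876.5]), 50.0, 9.0)
        assert a.as_dict() == pytest.approx(b.as_dict())

    def test_recovers_cluster_surface_density(self):
        """5 clusters/um^2 with 10 molecules each: clusters/area within 25%."""
        phys = PhotophysicsModel(alpha=3.3, max_dark_time=20.0, max_dark_frames=2000)
        cpas = []
        for s in range(3):
            table, _ = simulate_smlm(SmlmGroundTruth(), seed=s)
            table = correct_drift(table)
            rep, _ = smlm.analyze_roi(table, Roi((1000, 1000), 3000), phys)
            cpas.append(rep.clusters_per_area)
        target = 5.0 * sps.poisson.sf(4, 10.0)
        assert abs(np.mean(cpas) - target) / target < 0.25

    def test_molecules_per_cluster_monotone_in_truth(self):
        """Richer clusters in truth never report fewer molecules per cluster."""
        phys = PhotophysicsModel(alpha=3.3, max_dark_time=20.0, max_dark_frames=2000)
        means = []
        for mpc in (6.0, 10.0, 16.0):
            vals = []
            for s in range(3):
                truth = SmlmGroundTruth(molecules_per_cluster_mean=mpc,
                                        field_size=4.0, n_frames=20_000)
                table, _ = simulate_smlm(truth, seed=s)
                table = correct_drift(table)
                rep, _ = smlm.analyze_roi(table, Roi((500, 500), 3000), phys)
                vals.append(rep.molecules_per_cluster)
            means.append(np.mean(vals))
        assert means[0] <= means[1] <= means[2]


class TestRoiHelpers:
    def test_auto_rois_respect_count_and_area(self):
        table, _ = simulate_smlm(SmlmGroundTruth(field_size=8.0, n_frames=2000), 0)
        rois = smlm.auto_rois(table, side=3500.0, n_rois=4)
        assert 3 <= len(rois) <= 4
        for roi in rois:
            assert 9.0 <= roi.area_um2 <= 16.0

    def test_roi_membership_is_half_open(self):
        roi = Roi((0, 0), 100.0)
        assert roi.contains(0.0, 0.0)
        assert not roi.contains(100.0, 50.0)

    def test_io_round_trip(self, tmp_path):
        tab = csr_table(20, 1000, 0)
        p = tmp_path / "loc.csv"
        smlm.write_localizations(tab, p)
        back = smlm.read_localizations(p)
        assert len(back) == 20
        np.testing.assert_allclose(back["x_nm"], tab["x_nm"], atol=1e-4)
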