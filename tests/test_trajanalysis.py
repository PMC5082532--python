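"""Trajectory statistics: binding classification, RDF, free-energy profiles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ferrobind.constants import RT_300K
from ferrobind.mcsim import IonTrajectory, single_site_model, simulate_ion
from ferrobind.trajanalysis import (
    BindingRecords,
    binding_series,
    co_binding,
    free_energy,
    per_site_profiles,
    rdf,
    site_occupancy,
    well_and_barrier,
)


def _traj(frames, sites, box=40.0, ids=None):
    frames = np.asarray(frames, dtype=float)
    sites = np.asarray(sites, dtype=float)
    ids = tuple(ids or (f"o{k:02d}" for k in range(len(sites))))
    return IonTrajectory(frames=frames, site_ids=ids, site_positions=sites,
                         box_edge=box, seed=0)


def _records(site_bound, cutoff=3.0):
    """Hand-built records from a boolean (frames, sites) matrix."""
    site_bound = np.asarray(site_bound, dtype=bool)
    dist = np.where(site_bound, 1.0, 10.0)
    ids = tuple(f"s{j}" for j in range(site_bound.shape[1]))
    return BindingRecords(site_ids=ids, min_dist=dist, cutoff=cutoff)


class TestBindingSeries:
    def test_hand_counted_bound_fraction(self):
        # one site at origin; ion at distances 2.9, 3.2, 2.4, 5.0
        frames = [[2.9, 0, 0], [3.2, 0, 0], [2.4, 0, 0], [5.0, 0, 0]]
        traj = _traj(frames, [[0.0, 0.0, 0.0]])
        records = binding_series(traj, cutoff=3.0)
        assert records.bound_fraction == pytest.approx(0.5)

    def test_boundary_distance_counts_as_bound(self):
        traj = _traj([[3.0, 0, 0]], [[0.0, 0.0, 0.0]])
        assert binding_series(traj, cutoff=3.0).bound_fraction == 1.0

    def test_all_far_gives_zero(self):
        traj = _traj([[10.0, 0, 0], [12.0, 0, 0]], [[0.0, 0.0, 0.0]])
        assert binding_series(traj, cutoff=3.0).bound_fraction == 0.0

    def test_minimum_image_convention(self):
        # ion at 39, site at 1: separation is 2 through the boundary
        traj = _traj([[39.0, 1.0, 1.0]], [[1.0, 1.0, 1.0]], box=40.0)
        assert binding_series(traj, cutoff=3.0).bound_fraction == 1.0
        assert binding_series(traj, cutoff=3.0,
                              periodic=False).bound_fraction == 0.0

    def test_empty_trajectory_rejected(self):
        traj = _traj(np.empty((0, 3)), [[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="empty"):
            binding_series(traj)

    @given(st.lists(st.floats(0.1, 15.0), min_size=1, max_size=30))
    def test_bound_fraction_nonincreasing_in_cutoff(self, distances):
        frames = [[d, 0.0, 0.0] for d in distances]
        traj = _traj(frames, [[0.0, 0.0, 0.0]])
        fractions = [binding_series(traj, cutoff=c).bound_fraction
                     for c in (2.0, 3.0, 4.0, 6.0)]
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))


class TestOccupancy:
    def test_single_site_always_bound(self):
        occ = site_occupancy(_records(np.ones((10, 1))))
        assert occ["s0"] == (1.0, "high")

    def test_hand_built_occupancy_count(self):
        flags = np.zeros((100, 2), dtype=bool)
        flags[:56, 0] = True       # site A in 56 of 100 bound frames
        flags[56:, 1] = True       # remaining frames bound via site B
        occ = site_occupancy(_records(flags))
        assert occ["s0"][0] == pytest.approx(0.56)

    def test_threshold_categories(self):
        flags = np.zeros((100, 3), dtype=bool)
        flags[:, 0] = np.arange(100) < 56
        flags[:, 1] = np.arange(100) < 20
        flags[:, 2] = np.arange(100) < 5
        occ = site_occupancy(_records(flags), thresholds=(0.4, 0.15))
        assert occ["s0"][1] == "high"
        assert occ["s1"][1] == "medium"
        assert occ["s2"][1] == "low"

    def test_no_bound_frames_gives_all_zero(self):
        occ = site_occupancy(_records(np.zeros((10, 2))))
        assert all(v == (0.0, "none") for v in occ.values())


class TestCoBinding:
    def test_always_cobound(self):
        flags = np.ones((20, 2), dtype=bool)
        assert co_binding(_records(flags), "s0", "s1") == 1.0

    def test_hand_count_45_of_50(self):
        flags = np.zeros((100, 2), dtype=bool)
        flags[:50, 0] = True
        flags[:45, 1] = True
        assert co_binding(_records(flags), "s0", "s1") == pytest.approx(0.90)

    def test_never_bound_marginal_is_undefined_not_zero(self):
        flags = np.zeros((10, 2), dtype=bool)
        flags[:, 1] = True
        assert co_binding(_records(flags), "s0", "s1") is None

    def test_unknown_site_rejected(self):
        with pytest.raises(ValueError, match="unknown site"):
            co_binding(_records(np.ones((5, 2))), "s0", "nope")


class TestRDF:
    def test_fixed_ion_concentrates_mass_in_one_bin(self):
        frames = np.tile([22.85, 20.0, 20.0], (200, 1))
        # add tail frames so normalization is defined
        rng = np.random.default_rng(0)
        shell = rng.uniform(0, 40, size=(2000, 3))
        traj = _traj(np.vstack([frames, shell]), [[20.0, 20.0, 20.0]])
        dist = rdf(traj, bin_width=0.05)
        peak_bin = np.argmax(dist.counts[: int(5 / 0.05)])
        assert abs(dist.r[peak_bin] - 2.85) <= 0.05

    def test_uniform_positions_give_unit_g_in_bulk(self):
        rng = np.random.default_rng(7)
        frames = rng.uniform(0, 40, size=(100_000, 3))
        traj = _traj(frames, [[20.0, 20.0, 20.0]])
        # 0.5 A bins: every bulk shell then holds >~250 counts, so Poisson
        # noise sits well below the 0.1 band being asserted
        dist = rdf(traj, bin_width=0.5)
        window = (dist.r >= 5) & (dist.r <= 15)
        assert np.all(np.abs(dist.g[window] - 1.0) < 0.1)

    def test_tail_mean_is_one_on_uniform_run(self):
        rng = np.random.default_rng(8)
        frames = rng.uniform(0, 40, size=(100_000, 3))
        traj = _traj(frames, [[20.0, 20.0, 20.0]])
        dist = rdf(traj)
        tail = dist.r >= dist.r_max - dist.tail_window
        assert 0.98 <= dist.g[tail].mean() <= 1.02

    def test_first_peak_position_matches_boltzmann_mode(self):
        # expected g(r) is exp(-U(r)/RT), whose mode sits at the potential
        # minimum (the bond distance) for the generating single-well model
        model = single_site_model(-6.7)
        traj = simulate_ion(model, n_sweeps=1_000_000, sample_every=10,
                            start_site="o01", seed=2)
        dist = rdf(traj, bin_width=0.05)
        site = model.sites[0]
        r_grid = np.arange(0.0, 20.0, 0.001)
        u = site.well_depth * np.exp(
            -((r_grid - site.bond_distance) ** 2) / (2 * site.well_width ** 2))
        mode = r_grid[np.argmax(np.exp(-u / RT_300K))]
        assert mode == pytest.approx(site.bond_distance, abs=1e-6)
        # exclude near-empty shells whose g estimate is pure Poisson noise
        usable = (dist.counts >= 5) & (dist.r < 5.0)
        peak = dist.r[usable][np.argmax(dist.g[usable])]
        assert abs(peak - mode) <= 0.1

    def test_r_max_beyond_half_box_rejected(self):
        traj = _traj([[1.0, 1.0, 1.0]], [[20.0, 20.0, 20.0]])
        with pytest.raises(ValueError, match="half box"):
            rdf(traj, r_max=25.0)


class TestFreeEnergy:
    def test_unit_g_gives_zero_free_energy(self):
        profile = free_energy((np.array([5.0]), np.array([1.0])))
        assert profile.a[0] == 0.0

    def test_kj_per_mol_to_rt_scale_conversion(self):
        g = np.exp(6.7 / RT_300K)
        profile = free_energy((np.array([2.85]), np.array([g])))
        assert profile.a[0] == pytest.approx(-6.7, abs=1e-9)
        assert profile.a[0] / RT_300K == pytest.approx(-2.7, abs=0.02)

    def test_unit_log_case(self):
        profile = free_energy((np.array([5.0]), np.array([np.e])))
        assert profile.a[0] == pytest.approx(-2.494, abs=5e-4)

    def test_zero_g_marked_absent_not_infinite(self):
        profile = free_energy((np.array([1.0, 2.0]), np.array([0.0, 1.0])))
        assert np.isnan(profile.a[0])
        assert np.isfinite(profile.a[1])

    def test_negative_g_rejected(self):
        with pytest.raises(ValueError):
            free_energy((np.array([1.0]), np.array([-0.1])))

    @given(st.lists(st.floats(1e-3, 1e3), min_size=1, max_size=20))
    def test_round_trip_through_boltzmann_factor(self, gs):
        g = np.array(gs)
        r = np.arange(len(g), dtype=float)
        profile = free_energy((r, g), temperature=300.0)
        back = np.exp(-profile.a / RT_300K)
        assert np.allclose(back, g, rtol=1e-9)


class TestWellAndBarrier:
    def _profile(self, r, a):
        g = np.exp(-np.asarray(a) / RT_300K)
        return free_energy((np.asarray(r, dtype=float), g))

    def test_well_with_interposed_maximum(self):
        r = np.array([2.0, 2.85, 3.5, 5.0, 10.0])
        a = np.array([1.0, -6.7, 3.5, 0.1, 0.0])
        annotated = well_and_barrier(self._profile(r, a))
        assert annotated.well == (2.85, pytest.approx(-6.7, abs=1e-9))
        assert annotated.barrier[0] == 3.5
        assert annotated.desorption_barrier == pytest.approx(10.2, abs=1e-9)

    def test_monotone_rise_has_zero_barrier_height(self):
        r = np.linspace(2.0, 10.0, 30)
        a = np.linspace(-5.0, 0.0, 30)
        annotated = well_and_barrier(self._profile(r, a))
        assert annotated.barrier is None
        assert annotated.desorption_barrier == pytest.approx(5.0, abs=1e-9)

    def test_all_positive_profile_has_no_binding_well(self):
        r = np.linspace(2.0, 10.0, 10)
        a = np.abs(np.linspace(4.0, 0.5, 10))
        annotated = well_and_barrier(self._profile(r, a))
        assert annotated.has_binding_well is False
        assert annotated.well is None


class TestPerSite:
    def test_per_site_well_depths_ordered_by_generating_depth(self):
        from ferrobind.mcsim import BindingSite, SiteModel

        sites = (
            BindingSite("strong", (10.0, 20.0, 20.0), -11.0),
            BindingSite("weak", (30.0, 20.0, 20.0), -4.0),
        )
        model = SiteModel(sites=sites, box_edge=40.0)
        traj = simulate_ion(model, n_sweeps=1_500_000, sample_every=10,
                            step_size=6.0, seed=4)
        profiles = per_site_profiles(traj)
        depth_strong = profiles["strong"].well[1]
        depth_weak = profiles["weak"].well[1]
        assert depth_strong < depth_weak < 0

    def test_aggregate_counts_equal_sum_of_per_site_counts(self):
        rng = np.random.default_rng(3)
        frames = rng.uniform(0, 40, size=(20_000, 3))
        sites = [[15.0, 20.0, 20.0], [25.0, 20.0, 20.0]]
        traj = _traj(frames, sites, ids=("a", "b"))
        combined = rdf(traj, bin_width=0.1)
        from ferrobind.trajanalysis import _histogram_rdf, _site_distances

        d = _site_distances(traj)
        per_site = [_histogram_rdf(d[:, j], 0.1, 20.0, 3.0).counts
                    for j in range(2)]
        assert np.array_equal(combined.counts, per_site[0] + per_site[1])

    def test_unapproached_site_flagged_empty(self):
        # ion pinned near site a; site b's min-image distances all beyond r_max
        frames = np.tile([10.0, 10.0, 10.0], (50, 1))
        traj = _traj(frames, [[10.0, 10.0, 12.0], [30.0, 30.0, 30.0]],
                     ids=("a", "b"))
        profiles = per_site_profiles(traj, r_max=5.0)
        assert profiles["a"] is not None
        assert profiles["b"] is None
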