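"""Toy Metropolis ion simulator: sampling correctness and file round trips."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import chisquare

from ferrobind.constants import RT_300K
from ferrobind.mcsim import (
    BindingSite,
    SiteModel,
    XYZParseError,
    batch_ensemble,
    default_deev_model,
    model_from_yaml,
    model_to_yaml,
    read_xyz,
    simulate_ion,
    single_site_model,
    write_xyz,
)
from ferrobind.trajanalysis import binding_series


def _min_image_dist(points, sites, box):
    delta = points[:, None, :] - sites[None, :, :]
    delta -= box * np.round(delta / box)
    return np.sqrt((delta ** 2).sum(axis=2))


def _flat_model(n_sites=4, box=40.0):
    rng = np.random.default_rng(99)
    sites = tuple(
        BindingSite(id=f"o{k:02d}", position=tuple(rng.uniform(5, 35, 3)),
                    well_depth=0.0)
        for k in range(n_sites)
    )
    return SiteModel(sites=sites, box_edge=box)


class TestSampling:
    def test_flat_potential_nearest_site_distance_matches_uniform_oracle(self):
        model = _flat_model()
        sites = model.positions()
        # Monte-Carlo integral oracle: 1e6 uniform draws in the box
        rng = np.random.default_rng(2024)
        draws = rng.uniform(0, model.box_edge, size=(1_000_000, 3))
        oracle = _min_image_dist(draws, sites, model.box_edge).min(axis=1).mean()

        means = []
        for seed in range(10):
            traj = simulate_ion(model, n_sweeps=50_000, sample_every=50,
                                step_size=10.0, seed=seed)
            d = _min_image_dist(traj.frames, sites, model.box_edge)
            means.append(d.min(axis=1).mean())
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - oracle) < 3 * se + 1e-9

    def test_flat_potential_histogram_uniform_by_chi_square(self):
        model = _flat_model(n_sites=1)
        edges = np.linspace(0, model.box_edge, 5)
        rejections = 0
        for seed in range(10):
            traj = simulate_ion(model, n_sweeps=200_000, sample_every=100,
                                step_size=12.0, seed=seed)
            counts, _ = np.histogramdd(traj.frames, bins=[edges] * 3)
            _, p = chisquare(counts.ravel())
            if p < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_bound_fraction_monotone_in_well_depth(self):
        fractions = {}
        for depth in (-15.0, -4.0):
            model = single_site_model(depth)
            traj = simulate_ion(model, n_sweeps=300_000, sample_every=10,
                                start_site="o01", seed=5)
            fractions[depth] = binding_series(traj).bound_fraction
        assert fractions[-15.0] > fractions[-4.0]

    def test_two_site_occupancy_ratio_matches_boltzmann_oracle(self):
        d1, d2, w, r0 = -8.0, -4.0, 0.35, 2.85
        sites = (
            BindingSite("deep", (10.0, 20.0, 20.0), d1, w, r0),
            BindingSite("shallow", (30.0, 20.0, 20.0), d2, w, r0),
        )
        model = SiteModel(sites=sites, box_edge=40.0)
        traj = simulate_ion(model, n_sweeps=2_000_000, sample_every=5,
                            step_size=6.0, seed=0)
        records = binding_series(traj, cutoff=3.0)
        occ = records.site_bound.mean(axis=0)
        sim_ratio = occ[0] / occ[1]

        def boltz_weight(depth):
            u = lambda r: depth * np.exp(-((r - r0) ** 2) / (2 * w * w))
            val, _ = quad(lambda r: r * r * np.exp(-u(r) / RT_300K), 0.0, 3.0)
            return val

        oracle = boltz_weight(d1) / boltz_weight(d2)
        assert sim_ratio == pytest.approx(oracle, rel=0.10)

    def test_same_seed_reproduces_trajectory(self):
        model = default_deev_model()
        a = simulate_ion(model, n_sweeps=20_000, seed=11)
        b = simulate_ion(model, n_sweeps=20_000, seed=11)
        assert np.array_equal(a.frames, b.frames)

    def test_frame_count_and_wrapping(self):
        model = default_deev_model()
        traj = simulate_ion(model, n_sweeps=10_000, sample_every=10, seed=0)
        assert len(traj) == 1000
        assert traj.frames.min() >= 0
        assert traj.frames.max() < model.box_edge

    def test_unknown_start_site_rejected(self):
        with pytest.raises(ValueError, match="start site"):
            simulate_ion(default_deev_model(), n_sweeps=100,
                         start_site="nope", seed=0)


class TestEnsemble:
    def test_twelve_distinct_starts(self):
        model = default_deev_model()
        trajs = batch_ensemble(model, n_starts=12,
                               seeds=list(range(12)), n_sweeps=2_000,
                               sample_every=10)
        assert len(trajs) == 12
        starts = {t.meta["start_site"] for t in trajs}
        assert starts == set(model.site_ids)

    def test_seed_list_shorter_than_starts_rejected(self):
        with pytest.raises(ValueError, match="seeds"):
            batch_ensemble(default_deev_model(), n_starts=12, seeds=[1, 2])

    def test_unit_depth_scale_leaves_fe3_identical_to_fe2(self):
        fe2 = default_deev_model("Fe2")
        fe3 = default_deev_model("Fe3")
        t2 = batch_ensemble(fe2, n_starts=2, seeds=[0, 1], n_sweeps=5_000)
        t3 = batch_ensemble(fe3, n_starts=2, depth_scale=1.0, seeds=[0, 1],
                            n_sweeps=5_000)
        for a, b in zip(t2, t3):
            assert np.array_equal(a.frames, b.frames)

    def test_extra_charge_depth_scale_raises_bound_fraction(self):
        fe2 = default_deev_model("Fe2")
        fe3 = default_deev_model("Fe3")
        seeds = list(range(4))
        kwargs = dict(n_starts=4, seeds=seeds, n_sweeps=100_000,
                      sample_every=10)
        bf2 = np.mean([binding_series(t).bound_fraction
                       for t in batch_ensemble(fe2, **kwargs)])
        bf3 = np.mean([binding_series(t).bound_fraction
                       for t in batch_ensemble(fe3, depth_scale=1.5, **kwargs)])
        assert bf3 > bf2


class TestModelValidation:
    def test_positive_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            BindingSite("x", (1, 1, 1), well_depth=2.0)

    def test_site_outside_box_rejected(self):
        site = BindingSite("x", (45.0, 1.0, 1.0), well_depth=-1.0)
        with pytest.raises(ValueError, match="outside box"):
            SiteModel(sites=(site,), box_edge=40.0)

    def test_model_yaml_round_trip(self, tmp_path):
        model = default_deev_model()
        path = tmp_path / "model.yaml"
        model_to_yaml(model, path)
        loaded = model_from_yaml(path)
        assert loaded.site_ids == model.site_ids
        assert np.allclose(loaded.positions(), model.positions())
        assert [s.well_depth for s in loaded.sites] == \
            [s.well_depth for s in model.sites]


class TestXYZ:
    def test_round_trip(self, tmp_path):
        traj = simulate_ion(default_deev_model(), n_sweeps=500,
                            sample_every=10, seed=1)
        path = tmp_path / "traj.xyz"
        write_xyz(traj, path)
        loaded = read_xyz(path)
        assert np.allclose(loaded.frames, traj.frames, atol=1e-6)
        assert np.allclose(loaded.site_positions, traj.site_positions,
                           atol=1e-6)
        assert loaded.site_ids == traj.site_ids
        assert loaded.box_edge == pytest.approx(traj.box_edge, abs=1e-6)

    def test_inconsistent_atom_count_reports_frame(self, tmp_path):
        traj = simulate_ion(default_deev_model(), n_sweeps=30,
                            sample_every=10, seed=1)
        path = tmp_path / "traj.xyz"
        write_xyz(traj, path)
        lines = path.read_text().splitlines()
        lines[len(lines) // 2] = "7"  # corrupt a count line mid-file
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(XYZParseError, match="frame"):
            read_xyz(path)

    def test_externally_produced_xyz_with_same_convention_parses(self, tmp_path):
        text = (
            "3\n"
            "box=20.000000 frame=0 sites=a,b\n"
            "O 5.0 5.0 5.0\n"
            "O 15.0 15.0 15.0\n"
            "FE 10.0 10.0 10.0\n"
            "3\n"
            "box=20.000000 frame=1\n"
            "O 5.0 5.0 5.0\n"
            "O 15.0 15.0 15.0\n"
            "FE 11.0 10.0 10.0\n"
        )
        path = tmp_path / "ext.xyz"
        path.write_text(text)
        traj = read_xyz(path)
        assert len(traj) == 2
        assert traj.site_ids == ("a", "b")
        assert traj.box_edge == 20.0
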