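"""Capture engines: Monte Carlo vs analytic mixture, step conditioning."""

import numpy as np
import pytest

from lipodimer.capture import (
    CaptureConfig,
    OccupancyDistribution,
    ideal_pair_at_chi,
    occupancy_analytic,
    simulate_capture,
    to_photobleach,
    total_variation,
)
from lipodimer.labeling import LabelingYields
from lipodimer.liposomes import RadiusDistribution, counts_for_chi


def single_bin(radius=30.0):
    return RadiusDistribution(radii=np.array([radius]), probs=np.array([1.0]))


class TestOccupancyAnalytic:
    def test_one_particle_two_liposomes_exact(self, perfect_yields):
        occ = occupancy_analytic(CaptureConfig(
            species="monomer", n_subunits=1, n_liposomes=2,
            radius_dist=single_bin(), yields=perfect_yields,
        ))
        np.testing.assert_allclose(occ.p_star[:2], [0.5, 0.5], atol=1e-12)
        assert occ.p_star[2:].sum() == pytest.approx(0.0, abs=1e-12)

    def test_invisible_protein(self):
        occ = occupancy_analytic(CaptureConfig(
            species="monomer", n_subunits=100, n_liposomes=100,
            radius_dist=single_bin(), yields=LabelingYields(0.0, 0.0),
        ))
        assert occ.f0 == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_multinomial_simulation(
        self, three_bin_dist, yields, rng
    ):
        """Large-replicate Monte Carlo agrees with the mixture law on a
        three-bin population."""
        cfg = CaptureConfig(
            species="monomer", n_subunits=4000, n_liposomes=2000,
            radius_dist=three_bin_dist, yields=yields, max_ncy5=12,
        )
        exact = occupancy_analytic(cfg)
        reps = 2500  # 5e6 liposome draws in total
        acc = np.zeros_like(exact.p_star)
        for seed in range(reps):
            acc += simulate_capture(
                CaptureConfig(**{**cfg.__dict__, "seed": seed})
            ).p_star
        tv = 0.5 * np.abs(acc / reps - exact.p_star).sum()
        assert tv < 1e-3

    def test_mean_fluorophore_conservation(self, radius_dist, yields):
        """Mean visible fluorophores per liposome equals
        n_particles * E[N_Cy5] / n_liposomes (dilute, negligible tail)."""
        cfg = CaptureConfig(
            species="dimer", n_subunits=2000, n_liposomes=1e7,
            radius_dist=radius_dist, r_min=25.0, yields=yields,
        )
        occ = occupancy_analytic(cfg)
        expected = cfg.n_particles * cfg.label_dist.mean / cfg.n_liposomes
        assert occ.mean_ncy5 == pytest.approx(expected, rel=1e-9)

    def test_p3plus_nondecreasing_in_chi(self, radius_dist, yields):
        grid = np.logspace(-9, -4, 8)
        for species in ("monomer", "dimer"):
            last = -1.0
            for chi in grid:
                pm, pdist = ideal_pair_at_chi(
                    chi, yields=yields, radius_dist=radius_dist, m=3
                )
                pb = pm if species == "monomer" else pdist
                assert pb.probs[-1] >= last - 1e-12
                last = pb.probs[-1]


class TestSimulateCapture:
    def test_two_outcome_case_unbiased(self, perfect_yields):
        """One particle into two liposomes: occupied fraction is 1/2 in
        expectation; the seeded average stays within 3 sigma binomial."""
        cfg = dict(
            species="monomer", n_subunits=1, n_liposomes=2,
            radius_dist=single_bin(), yields=perfect_yields,
        )
        n = 1000
        hits = sum(
            simulate_capture(CaptureConfig(**cfg, seed=s)).p_star[1] * 2
            for s in range(n)
        ) / 2.0
        sd = np.sqrt(0.25 * n)
        assert abs(hits - 0.5 * n) < 3 * sd

    def test_dilute_monomer_is_single_step(self, radius_dist, perfect_yields):
        n_sub, n_lip = counts_for_chi(
            7.5e-10, 20_000, radius_dist, perfect_yields
        )
        occ = simulate_capture(CaptureConfig(
            species="monomer", n_subunits=n_sub, n_liposomes=n_lip,
            radius_dist=radius_dist, yields=perfect_yields, seed=7,
        ))
        pb = to_photobleach(occ, m=3)
        assert pb.probs[0] > 0.99
        assert pb.probs[1] < 0.01

    def test_total_variation_against_oracle(self, radius_dist, yields):
        """MC at ~1e5 occupied liposomes sits within TV < 0.01 of the
        analytic mixture (mid-range density, both species)."""
        for species, r_min in (("monomer", 0.0), ("dimer", 25.0)):
            n_sub, n_lip = counts_for_chi(
                1e-7, 1.2e5, radius_dist, yields, species=species, r_min=r_min
            )
            cfg = CaptureConfig(
                species=species, n_subunits=n_sub, n_liposomes=n_lip,
                radius_dist=radius_dist, r_min=r_min, yields=yields, seed=3,
            )
            tv = total_variation(occupancy_analytic(cfg), simulate_capture(cfg))
            assert tv < 0.01

    def test_seed_determinism(self, radius_dist, yields):
        cfg = dict(
            species="dimer", n_subunits=10_000, n_liposomes=1e6,
            radius_dist=radius_dist, r_min=25.0, yields=yields,
        )
        a = simulate_capture(CaptureConfig(**cfg, seed=11))
        b = simulate_capture(CaptureConfig(**cfg, seed=11))
        c = simulate_capture(CaptureConfig(**cfg, seed=12))
        np.testing.assert_array_equal(a.p_star, b.p_star)
        assert not np.array_equal(a.p_star, c.p_star)

    def test_odd_dimer_subunit_count_warns(self, radius_dist, yields):
        cfg = CaptureConfig(
            species="dimer", n_subunits=101, n_liposomes=1000,
            radius_dist=radius_dist, yields=yields,
        )
        with pytest.warns(UserWarning, match="odd subunit count"):
            assert cfg.n_particles == 50


class TestToPhotobleach:
    def test_direct_arithmetic(self):
        occ = OccupancyDistribution(p_star=np.array([0.5, 0.3, 0.15, 0.05]))
        pb = to_photobleach(occ, m=3)
        np.testing.assert_allclose(pb.probs, [0.6, 0.3, 0.1], atol=1e-12)
        assert occ.f0 == 0.5

    def test_all_single(self):
        pb = to_photobleach(OccupancyDistribution(p_star=np.array([0.0, 1.0])),
                            m=3)
        assert pb.probs[0] == 1.0

    def test_matches_conditional_histogram(self, rng):
        raw = rng.dirichlet(np.ones(8))
        occ = OccupancyDistribution(p_star=raw)
        pb = to_photobleach(occ, m=5)
        cond = raw[1:] / raw[1:].sum()
        np.testing.assert_allclose(pb.probs[:4], cond[:4], atol=1e-12)
        assert pb.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert pb.probs[4] == pytest.approx(cond[4:].sum(), abs=1e-12)

    def test_empty_population_rejected(self):
        occ = OccupancyDistribution(p_star=np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            to_photobleach(occ)


class TestIdealDistributions:
    def test_dilute_limit_is_visibility_conditioned_label_law(
        self, radius_dist, yields
    ):
        """As chi -> 0 the step distributions converge to the label-count
        distributions conditioned on carrying at least one fluorophore."""
        pm, pdist = ideal_pair_at_chi(
            7.5e-10, yields=yields, radius_dist=radius_dist, m=3
        )
        mono = np.array([0.3612, 0.5576, 0.0812])
        cond = mono[1:] / mono[1:].sum()
        assert pm.probs[0] == pytest.approx(cond[0], abs=2e-3)
        assert pm.probs[1] == pytest.approx(cond[1], abs=2e-3)
        from lipodimer.labeling import dimer_label_distribution

        dim = dimer_label_distribution(yields).probs
        condd = dim[1:] / dim[1:].sum()
        assert pdist.probs[0] == pytest.approx(condd[0], abs=2e-3)
        assert pdist.probs[1] == pytest.approx(condd[1], abs=2e-3)

    def test_dilute_perfect_dimer_bleaches_twice(self, radius_dist,
                                                 perfect_yields):
        _, pdist = ideal_pair_at_chi(
            1e-9, yields=perfect_yields, radius_dist=radius_dist, m=3
        )
        assert pdist.probs[1] > 0.999

    def test_high_density_warns(self, radius_dist, yields):
        with pytest.warns(UserWarning, match="dynamic-range"):
            ideal_pair_at_chi(5e-4, yields=yields, radius_dist=radius_dist)

    def test_table_output_shape(self, radius_dist, yields):
        from lipodimer.capture import ideal_distribution_pair

        table = ideal_distribution_pair(
            [1e-8, 1e-6], yields=yields, radius_dist=radius_dist, m=5
        )
        assert list(table.columns) == [
            "chi", "species", "P1", "P2", "P3", "P4", "P5plus", "F0"
        ]
        assert len(table) == 4
        probs = table[["P1", "P2", "P3", "P4", "P5plus"]].to_numpy()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)
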