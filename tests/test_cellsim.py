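"""Stochastic kernel: SSA exactness at fixed volume, cell-cycle machinery
(growth, replication, division, partitioning), ploidy scaling."""

import numpy as np
import pytest
from scipy import stats

from galnoise.cellsim import (
    CellCycleModel,
    CellState,
    GeneLocus,
    Reaction,
    ReactionNetwork,
    apply_ploidy,
    simulate_population,
    step_cell,
)


def discrete_ks_pvalue(x, dist, seed):
    """KS test for integer data via the randomized probability-integral
    transform (exactly uniform under the null, valid with ties)."""
    rng = np.random.default_rng(seed)
    u = dist.cdf(x - 1) + rng.random(len(x)) * dist.pmf(x)
    return stats.kstest(u, stats.uniform.cdf).pvalue


def textbook_gillespie_telegraph(n_cells, t_end, seed):
    """Independent reference: direct-method SSA for the two-state promoter
    network (2 gene copies, k_on=0.2, k_off=0.3, k_tx=1.0, dm=0.1)."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_cells, np.int64)
    for c in range(n_cells):
        n_on, m, t = 0, 0, 0.0
        while True:
            a = [0.2 * (2 - n_on), 0.3 * n_on, 1.0 * n_on, 0.1 * m]
            a0 = sum(a)
            t += rng.exponential(1.0 / a0)
            if t >= t_end:
                break
            r = rng.random() * a0
            if r < a[0]:
                n_on += 1
            elif r < a[0] + a[1]:
                n_on -= 1
            elif r < a[0] + a[1] + a[2]:
                m += 1
            else:
                m -= 1
        out[c] = m
    return out


class TestFixedVolumeExactness:
    def test_birth_death_stationary_poisson(self, birth_death_network,
                                            fixed_volume_ccm):
        """Constitutive gene at fixed volume: endpoint counts follow
        Poisson(kV/gamma)."""
        s = simulate_population(birth_death_network, fixed_volume_ccm,
                                4000, 40.0, seed=123)
        lam = 3.0 * 2.0 / 0.4
        p = discrete_ks_pvalue(s.species_counts("P"), stats.poisson(lam),
                               seed=1)
        assert p > 0.01
        assert s.species_counts("P").mean() == pytest.approx(lam, rel=0.03)

    def test_telegraph_mean(self, telegraph_network, fixed_volume_ccm):
        """Two-state promoter: stationary mRNA mean matches the closed
        form copies * p_on * k_tx / delta_m."""
        s = simulate_population(telegraph_network, fixed_volume_ccm,
                                6000, 120.0, seed=7)
        expected = 2 * (0.2 / 0.5) * 1.0 / 0.1
        assert s.species_counts("M").mean() == pytest.approx(expected,
                                                             rel=0.02)

    def test_matches_textbook_gillespie(self, telegraph_network,
                                        fixed_volume_ccm):
        """With growth disabled the kernel's endpoint distribution is
        indistinguishable from an independently written direct-method SSA
        (two-sample KS)."""
        mine = simulate_population(telegraph_network, fixed_volume_ccm,
                                   1200, 120.0, seed=21).species_counts("M")
        ref = textbook_gillespie_telegraph(1200, 120.0, seed=99)
        assert stats.ks_2samp(mine, ref).pvalue > 0.01


class TestCellCycleMachinery:
    def test_inert_cell_growth_and_division(self, inert_network,
                                            deterministic_cycle_ccm):
        """No reactions: volume doubles over one cycle; division halves
        volume and partitions molecules binomially."""
        cell = CellState(volume=30.0, phase=0.0, counts={"Z": 1000},
                         promoter_on={"g": 0}, seed=3)
        grown = step_cell(cell, inert_network, deterministic_cycle_ccm, 99.9)
        assert grown.counts["Z"] == 1000
        assert grown.volume == pytest.approx(30.0 * 2 ** 0.999, rel=1e-3)
        divided = step_cell(cell, inert_network, deterministic_cycle_ccm,
                            100.5)
        assert divided.volume == pytest.approx(30.0 * 2 ** 0.005, rel=1e-3)
        # binomial(1000, 1/2) stays within 5 sigma of half
        assert abs(divided.counts["Z"] - 500) < 5 * np.sqrt(250)

    def test_partition_conserves_mass_in_expectation(
            self, inert_network, deterministic_cycle_ccm):
        """Retained + discarded daughter counts sum to the mother's, so
        the retained mean is half the pre-division count."""
        kept = []
        for seed in range(300):
            cell = CellState(volume=30.0, phase=0.0, counts={"Z": 1000},
                             promoter_on={"g": 0}, seed=seed)
            kept.append(step_cell(cell, inert_network,
                                  deterministic_cycle_ccm, 101.0).counts["Z"])
        se = np.sqrt(250 / 300)
        assert np.mean(kept) == pytest.approx(500.0, abs=5 * se)

    def test_replication_time_averaged_copy_number(
            self, inert_network, deterministic_cycle_ccm):
        """Copies double at the S-phase point, so the cycle-averaged copy
        number is copies * (1 + (1 - s_phase_fraction))."""
        s = simulate_population(inert_network, deterministic_cycle_ccm,
                                3000, 237.0, seed=5)
        expected = 1 + (1 - deterministic_cycle_ccm.s_phase_fraction)
        assert s.locus_copies.mean() == pytest.approx(expected, rel=0.02)

    def test_concentration_homeostasis_over_ten_generations(self):
        """Volume-proportional synthesis: mean concentration drifts < 5%
        across 10 consecutive generations."""
        net = ReactionNetwork(
            species=["P"], loci=[],
            reactions=[
                Reaction("synth", "const", 1.0, vexp=1.0, stoich={"P": 1}),
                Reaction("decay", "uni", 0.01, s1="P", stoich={"P": -1}),
            ],
            init_counts={"P": 2400},  # ~ stationary mean at birth volume
        )
        ccm = CellCycleModel(doubling_time=100.0, birth_volume=30.0,
                             cycle_length_cv=0.0, s_phase_jitter=0.0)
        early = simulate_population(net, ccm, 800, 100.0, seed=11)
        late = simulate_population(net, ccm, 800, 1100.0, seed=12)
        conc_early = (early.species_counts("P") / early.volumes).mean()
        conc_late = (late.species_counts("P") / late.volumes).mean()
        assert abs(conc_late / conc_early - 1) < 0.05

    def test_concentration_cv_below_count_cv(self):
        """Volume variation inflates counts, not concentrations, for a
        volume-proportional constitutive reporter."""
        net = ReactionNetwork(
            species=["P"], loci=[],
            reactions=[
                Reaction("synth", "const", 1.0, vexp=1.0, stoich={"P": 1}),
                Reaction("decay", "uni", 0.02, s1="P", stoich={"P": -1}),
            ],
            init_counts={"P": 2000},
        )
        ccm = CellCycleModel(doubling_time=100.0, birth_volume=30.0)
        s = simulate_population(net, ccm, 2000, 600.0, seed=4)
        counts = s.species_counts("P").astype(float)
        conc = counts / s.volumes
        assert conc.std() / conc.mean() < counts.std() / counts.mean()


class TestDeterminismAndEdges:
    def test_duration_zero_returns_initial_condition(self, telegraph_network):
        ccm = CellCycleModel(doubling_time=100.0, birth_volume=30.0)
        s = simulate_population(telegraph_network, ccm, 100, 0.0, seed=1)
        assert (s.counts == 0).all()

    def test_same_seed_reproduces(self, telegraph_network, fixed_volume_ccm):
        a = simulate_population(telegraph_network, fixed_volume_ccm, 80,
                                60.0, seed=11)
        b = simulate_population(telegraph_network, fixed_volume_ccm, 80,
                                60.0, seed=11)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.volumes, b.volumes)

    def test_different_seeds_differ(self, telegraph_network,
                                    fixed_volume_ccm):
        a = simulate_population(telegraph_network, fixed_volume_ccm, 80,
                                60.0, seed=11)
        b = simulate_population(telegraph_network, fixed_volume_ccm, 80,
                                60.0, seed=12)
        assert not np.array_equal(a.counts, b.counts)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            ReactionNetwork(["A"], [], [Reaction("x", "uni", 1.0, s1="B")])
        with pytest.raises(ValueError):
            Reaction("x", "frobnicate", 1.0)
        with pytest.raises(ValueError):
            CellCycleModel(growth_law="cubic")
        with pytest.raises(ValueError):
            GeneLocus("g", copies=0)

    def test_extrinsic_capacity_is_lognormal_and_scales_output(
            self, fixed_volume_ccm):
        net = ReactionNetwork(
            species=["P"], loci=[],
            reactions=[Reaction("s", "const", 5.0, stoich={"P": 1},
                                extrinsic=True),
                       Reaction("d", "uni", 0.2, s1="P", stoich={"P": -1})],
        )
        s = simulate_population(net, fixed_volume_ccm, 3000, 80.0, seed=9,
                                extrinsic_sd=0.4, extrinsic_tau=1e9)
        xi = s.capacities
        assert np.log(xi).std() == pytest.approx(0.4, rel=0.1)
        # counts track the per-cell capacity factor
        r = np.corrcoef(np.log(xi), np.log(s.species_counts("P") + 1))[0, 1]
        assert r > 0.8


class TestApplyPloidy:
    def test_identity(self, telegraph_network, deterministic_cycle_ccm):
        net, ccm = apply_ploidy(telegraph_network, deterministic_cycle_ccm, 1)
        assert net is telegraph_network and ccm is deterministic_cycle_ccm

    def test_doubles_copies_and_volume(self, telegraph_network,
                                       deterministic_cycle_ccm):
        net, ccm = apply_ploidy(telegraph_network, deterministic_cycle_ccm, 2)
        assert [l.copies for l in net.loci] == [4]  # 2 copies doubled
        assert ccm.birth_volume == 2 * deterministic_cycle_ccm.birth_volume
        for r_old, r_new in zip(telegraph_network.reactions, net.reactions):
            assert r_old.k == r_new.k

    def test_mean_concentration_invariant(self):
        """Doubling gene copies and volume together leaves the mean
        endpoint concentration of a constitutive reporter unchanged."""
        net = ReactionNetwork(
            species=["P"],
            loci=[GeneLocus("g", copies=1, init_on=1)],
            reactions=[
                Reaction("syn", "per_tot", 2.0, locus="g", stoich={"P": 1}),
                Reaction("dec", "uni", 0.01, s1="P", stoich={"P": -1}),
            ],
            init_counts={"P": 190},
        )
        ccm = CellCycleModel(doubling_time=100.0, birth_volume=30.0)
        hap = simulate_population(net, ccm, 1500, 800.0, seed=31)
        net2, ccm2 = apply_ploidy(net, ccm, 2)
        net2.init_counts["P"] = 380
        dip = simulate_population(net2, ccm2, 1500, 800.0, seed=32)
        c_hap = (hap.species_counts("P") / hap.volumes).mean()
        c_dip = (dip.species_counts("P") / dip.volumes).mean()
        assert c_dip / c_hap == pytest.approx(1.0, abs=0.03)

    def test_invalid_factor(self, telegraph_network, deterministic_cycle_ccm):
        with pytest.raises(ValueError):
            apply_ploidy(telegraph_network, deterministic_cycle_ccm, 3)
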