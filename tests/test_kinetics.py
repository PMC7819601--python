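"""Gillespie kinetics: rates, event enumeration, samplers vs exact oracles."""

import math

import numpy as np
import pytest

import nucleosim as ns
from nucleosim.exact import ring_gap_distribution, two_state_occupancy
from nucleosim.kinetics import (
    crystalline_configuration,
    enumerate_events,
    gillespie_step,
)
from nucleosim.lattice import NucleosomeConfiguration


@pytest.fixture()
def lattice():
    return ns.LatticeSpec(length_bp=1470, tss_index=700)


@pytest.fixture()
def uniform_model(lattice):
    return ns.KineticModel(field=ns.EnergyField.uniform(lattice), D=1.0)


class TestRateExpressions:
    def test_diffusion_rate_examples(self):
        assert ns.diffusion_rate(0.0) == pytest.approx(1.0)
        assert ns.diffusion_rate(math.inf) == 0.0
        assert ns.diffusion_rate(2 * math.log(2)) == pytest.approx(0.5)

    def test_exchange_rate_examples(self):
        assert ns.exchange_rates(0.0, 0.0, 0.1) == pytest.approx((0.1, 0.1))
        r_on, r_off = ns.exchange_rates(2 * math.log(10), 0.0, 12.0)
        assert (r_on, r_off) == pytest.approx((1.2, 120.0))

    def test_product_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            dU, mu = rng.normal(0, 5, 2)
            r_on, r_off = ns.exchange_rates(dU, mu, 0.3)
            assert r_on * r_off == pytest.approx(0.3**2)


class TestEnumerateEvents:
    def test_single_nucleosome_has_two_unit_hops(self, lattice, uniform_model):
        cfg = NucleosomeConfiguration(np.array([500]), lattice)
        events = enumerate_events(cfg, uniform_model)
        assert len(events) == 2
        assert all(e.kind == "hop" and e.rate == pytest.approx(1.0) for e in events)

    def test_contact_pair_blocks_inward_hops_and_enzyme(self, lattice):
        model = ns.KineticModel(
            field=ns.EnergyField.uniform(lattice), D=1.0, enzyme_rate=0.16
        )
        cfg = NucleosomeConfiguration(np.array([500, 647]), lattice)
        events = enumerate_events(cfg, model)
        hops = [e for e in events if e.kind == "hop"]
        # only the two outward hops survive; the gap-147 pair is ineligible
        assert len(hops) == 2
        assert {(e.index, e.step) for e in hops} == {(0, -1), (1, +1)}
        # the wrap-around pair at gap 1470-147 is beyond the enzyme range
        assert not [e for e in events if e.kind == "enzyme"]

    def test_pair_in_range_yields_one_enzyme_event(self, lattice):
        model = ns.KineticModel(
            field=ns.EnergyField.uniform(lattice), D=0.0, enzyme_rate=0.16
        )
        cfg = NucleosomeConfiguration(np.array([500, 700]), lattice)
        events = enumerate_events(cfg, model)
        enzyme = [e for e in events if e.kind == "enzyme"]
        assert len(enzyme) == 1
        assert enzyme[0].rate == pytest.approx(0.16)

    def test_kernel_total_rate_matches_python_enumeration(self, lattice):
        """The compiled kernel and the reference enumeration agree exactly."""
        from nucleosim._engine import _step_rates_and_fire
        from nucleosim.kinetics import _dense_attraction

        rng = np.random.default_rng(8)
        field = ns.EnergyField(
            site_energy=rng.normal(-0.3, 0.05, lattice.length_bp),
            barrier=ns.make_barrier(lattice, height=6.0),
            lattice=lattice,
        )
        pair = ns.PairPotential(effective_attraction=-np.linspace(1.5, 0, 186))
        model = ns.KineticModel(
            field=field, pair=pair, D=1.0, enzyme_rate=0.16, r_const=2.0, mu=30.0
        )
        E1 = field.dyad_energies()
        u_att = _dense_attraction(model)
        for n in (0, 1, 2, 5, 8):
            cfg = ns.random_initial_configuration(n, lattice, rng)
            py_total = sum(e.rate for e in enumerate_events(cfg, model))
            pos = np.zeros(lattice.capacity + 2, dtype=np.int64)
            pos[: cfg.n] = cfg.dyads
            kernel_total, _ = _step_rates_and_fire(
                pos, cfg.n, lattice.length_bp, lattice.footprint_bp, E1, u_att,
                1.0, 0.16, 332, 2.0, 30.0, -1.0, False,
            )
            assert kernel_total == pytest.approx(py_total, rel=1e-12)


class TestGillespieStep:
    def test_waiting_time_is_exponential_in_total_rate(self, lattice):
        field = ns.EnergyField.uniform(lattice)
        model = ns.KineticModel(field=field, D=1.0)
        cfg = NucleosomeConfiguration(np.array([500]), lattice)  # total rate 2
        rng = np.random.default_rng(1)
        dts = []
        for _ in range(4000):
            _, dt = gillespie_step(cfg, model, rng)
            dts.append(dt)
        mean = np.mean(dts)
        se = np.std(dts) / np.sqrt(len(dts))
        assert abs(mean - 0.5) < 3 * se

    def test_selection_frequencies_follow_rates(self, lattice):
        """A 3:1 rate split is chosen 75/25 within the binomial CI."""
        # a one-site well at x+1 makes the right hop 3x faster than the left
        lat = lattice
        x = 500
        dU = -2 * math.log(3)
        pos_pot = np.zeros(lat.length_bp)
        pos_pot[x + 1] = dU
        field = ns.EnergyField(np.zeros(lat.length_bp), None, pos_pot, lat)
        model = ns.KineticModel(field=field, D=1.0)
        cfg = NucleosomeConfiguration(np.array([x]), lat)
        events = enumerate_events(cfg, model)
        rates = sorted(e.rate for e in events)
        assert rates[1] / rates[0] == pytest.approx(3.0)
        rng = np.random.default_rng(2)
        n_right = 0
        trials = 4000
        for _ in range(trials):
            new, _ = gillespie_step(cfg, model, rng)
            n_right += int(new.dyads[0] == x + 1)
        p_hat = n_right / trials
        assert abs(p_hat - 0.75) < 3 * math.sqrt(0.75 * 0.25 / trials)

    def test_single_site_occupancy_matches_two_state_solution(self):
        """Insertion/removal only: time-weighted occupancy matches exp(-dV)."""
        lat = ns.LatticeSpec(length_bp=147, tss_index=0)
        field = ns.EnergyField.uniform(lat, binding_energy=-3.0)
        mu = 2.0
        model = ns.KineticModel(field=field, D=0.0, r_const=1.0, mu=mu)
        # every dyad position is an insertion channel; occupied-state odds
        # are the sum over channels of exp(-dV)
        S = 147 * math.exp(-(-3.0 + mu))
        expected = S / (1.0 + S)
        rng = np.random.default_rng(3)
        cfg = NucleosomeConfiguration(np.empty(0, dtype=int), lat)
        t_occ = t_tot = 0.0
        for _ in range(6000):
            new, dt = gillespie_step(cfg, model, rng)
            t_tot += dt
            t_occ += dt * (cfg.n == 1)
            cfg = new
        assert t_occ / t_tot == pytest.approx(expected, abs=0.02)


class TestRunSimulation:
    def test_bit_for_bit_determinism(self, lattice):
        model = ns.KineticModel(
            field=ns.EnergyField.uniform(lattice), D=1.0, enzyme_rate=0.16
        )
        proto = ns.SimulationProtocol(
            n_replicas=2, t_end=50.0, burn_in=10.0, sample_interval=1.0,
            initial_n_nucleosomes=5, seed=77,
        )
        rec1 = ns.run_simulation(model, proto)
        rec2 = ns.run_simulation(model, proto)
        assert all(np.array_equal(a, b) for a, b in zip(rec1.dyads, rec2.dyads))
        assert np.array_equal(rec1.times, rec2.times)

    def test_frozen_model_keeps_configuration(self, lattice):
        """No enzymes, no exchange, blocked hops: an absorbing state persists."""
        model = ns.KineticModel(field=ns.EnergyField.uniform(lattice), D=0.0)
        proto = ns.SimulationProtocol(
            n_replicas=1, t_end=100.0, burn_in=0.0, sample_interval=10.0,
            initial_n_nucleosomes=4, seed=5,
        )
        rec = ns.run_simulation(model, proto)
        first = rec.dyads[0]
        assert all(np.array_equal(d, first) for d in rec.dyads)

    def test_two_rod_gap_distribution_uniform_over_allowed_gaps(self):
        """Fixed-N diffusion on a uniform ring: every gap equally likely."""
        lat = ns.LatticeSpec(length_bp=588, tss_index=0)
        model = ns.KineticModel(field=ns.EnergyField.uniform(lat), D=1.0)
        proto = ns.SimulationProtocol(
            n_replicas=8, t_end=40000.0, burn_in=2000.0, sample_interval=50.0,
            initial_n_nucleosomes=2, seed=11,
        )
        rec = ns.run_simulation(model, proto)
        L = 588
        hist = np.zeros(L + 1)
        for d in rec.configurations():
            g = np.diff(d, append=d[0] + L)
            np.add.at(hist, g, 1)
        hist /= hist.sum()
        exact = ring_gap_distribution(L, 2)
        # bin by 6 bp to suppress shot noise before comparing
        nb = 294 // 6
        emp_b = np.add.reduceat(hist[147:295], np.arange(0, 148, 6))
        ex_b = np.add.reduceat(exact[147:295], np.arange(0, 148, 6))
        tv = 0.5 * np.abs(emp_b - ex_b).sum()
        assert tv < 0.05

    def test_exclusion_never_violated_in_samples(self, lattice):
        model = ns.KineticModel(
            field=ns.EnergyField.uniform(lattice), D=1.0, enzyme_rate=0.16,
            r_const=1.0, mu=40.0,
        )
        proto = ns.SimulationProtocol(
            n_replicas=2, t_end=200.0, burn_in=0.0, sample_interval=1.0,
            initial_n_nucleosomes=6, seed=13,
        )
        rec = ns.run_simulation(model, proto)  # EnsembleRecord asserts on build
        for d in rec.configurations():
            if d.size >= 2:
                gaps = np.diff(d, append=d[0] + lattice.length_bp)
                assert gaps.min() >= 147


class TestInitialConfigurations:
    def test_zero_and_capacity(self, lattice):
        rng = np.random.default_rng(0)
        assert ns.random_initial_configuration(0, lattice, rng).n == 0
        full = ns.random_initial_configuration(10, lattice, rng)  # capacity
        assert np.all(full.gaps() == 147)
        with pytest.raises(ValueError):
            ns.random_initial_configuration(11, lattice, rng)

    def test_feasible_random_placement(self):
        lat = ns.LatticeSpec()
        rng = np.random.default_rng(1)
        cfg = ns.random_initial_configuration(86, lat, rng)
        assert cfg.n == 86 and cfg.gaps().min() >= 147

    def test_crystalline_cluster_shape(self, lattice):
        cfg = crystalline_configuration(5, lattice)
        gaps = np.sort(cfg.gaps())
        assert np.all(gaps[:4] == 147)


class TestCalibrateMu:
    def test_tiny_lattice_calibration_matches_exact_grand_canonical(self):
        """Calibrated mu reproduces the enumerated grand-canonical density."""
        from nucleosim.exact import grand_canonical_density

        lat = ns.LatticeSpec(length_bp=441, tss_index=200)
        field = ns.EnergyField.uniform(lat, binding_energy=-8.0)
        model = ns.KineticModel(field=field, D=0.0, r_const=5.0)
        cal = ns.calibrate_mu(
            model, target_density=0.5, tolerance=0.02,
            protocol=ns.SimulationProtocol(
                n_replicas=2, t_end=400.0, burn_in=100.0, sample_interval=0.5,
                seed=9,
            ),
        )
        exact = grand_canonical_density(441, field.dyad_energies(), cal.mu, max_n=3)
        assert exact == pytest.approx(0.5, abs=0.03)
        assert len(cal.trace) >= 2  # iteration log is populated

    def test_invalid_target_rejected(self, lattice):
        model = ns.KineticModel(
            field=ns.EnergyField.uniform(lattice), D=0.0, r_const=5.0
        )
        with pytest.raises(ValueError):
            ns.calibrate_mu(model, 0.0)
        with pytest.raises(ValueError):
            ns.calibrate_mu(model, 1.0)
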