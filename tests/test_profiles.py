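"""Profile analysis: densities, smoothing, RDF, spacing, heatmap, phases."""

import numpy as np
import pytest

import nucleosim as ns
from nucleosim.kinetics import EnsembleRecord
from nucleosim.profiles import (
    DensityProfile,
    InsufficientPeaksError,
    classify_profile,
    density_profile,
    mean_neighbor_gap,
    mean_spacing,
    ordered_heatmap,
    radial_distribution,
    smooth_profile,
)


def _record(dyads_list, lattice):
    n = len(dyads_list)
    return EnsembleRecord(
        replica_ids=np.zeros(n, dtype=np.int64),
        times=np.arange(n, dtype=float),
        dyads=[np.asarray(d, dtype=np.int64) for d in dyads_list],
        lattice=lattice,
    )


@pytest.fixture()
def lattice():
    return ns.LatticeSpec(length_bp=1470, tss_index=700)


class TestDensityProfile:
    def test_single_dyad_lands_in_its_bin(self, lattice):
        rec = _record([[lattice.tss_index + 100]], lattice)
        prof = density_profile(rec, window=(-200, 200))
        nz = prof.offsets[prof.density > 0]
        assert nz.size == 1 and nz[0] == 100

    def test_empty_ensemble_rejected(self, lattice):
        with pytest.raises(ValueError):
            density_profile(_record([], lattice))

    def test_uniform_ensemble_is_flat_at_one(self, lattice):
        rng = np.random.default_rng(0)
        recs = [
            ns.random_initial_configuration(5, lattice, rng).dyads
            for _ in range(3000)
        ]
        prof = density_profile(_record(recs, lattice), window=(-500, 500), bin_bp=50)
        assert np.all(np.abs(prof.density - 1.0) < 0.12)

    def test_normalisation_lattice_mean_is_one(self, barrier_only_ensemble):
        lat = barrier_only_ensemble.lattice
        prof = density_profile(
            barrier_only_ensemble, window=(-lat.length_bp // 2, lat.length_bp // 2)
        )
        assert prof.density.mean() == pytest.approx(1.0, abs=0.01)


class TestSmoothing:
    def test_constant_profile_unchanged(self):
        prof = DensityProfile(np.arange(-100, 100), np.ones(200), 1)
        sm = smooth_profile(prof, 10.0)
        assert np.allclose(sm.density, 1.0)

    def test_tiny_bandwidth_is_near_identity(self):
        rng = np.random.default_rng(1)
        y = rng.uniform(0.5, 1.5, 200)
        prof = DensityProfile(np.arange(-100, 100), y, 1)
        sm = smooth_profile(prof, 0.05)
        assert np.allclose(sm.density, y, atol=1e-6)

    def test_cosine_attenuation_matches_kernel_transfer(self):
        """A period-165 cosine is damped by exp(-(2 pi bw / T)^2 / 2)."""
        x = np.arange(-2000, 2000)
        T, bw = 165.0, 10.0
        y = 1.0 + 0.5 * np.cos(2 * np.pi * x / T)
        prof = DensityProfile(x, y, 1)
        sm = smooth_profile(prof, bw)
        expected = 0.5 * np.exp(-0.5 * (2 * np.pi * bw / T) ** 2)
        mid = slice(500, 3500)
        amp = (sm.density[mid].max() - sm.density[mid].min()) / 2
        assert amp == pytest.approx(expected, rel=0.02)

    def test_mass_preserved(self):
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 2, 400)
        prof = DensityProfile(np.arange(-200, 200), y, 1)
        sm = smooth_profile(prof, 15.0, kernel="boxcar")
        assert sm.density.mean() == pytest.approx(y.mean(), rel=1e-3)

    def test_oversized_bandwidth_rejected(self):
        prof = DensityProfile(np.arange(-50, 50), np.ones(100), 1)
        with pytest.raises(ValueError):
            smooth_profile(prof, 200.0)


class TestRadialDistribution:
    def test_zero_inside_hard_core(self, spacer_ensemble):
        rdf = radial_distribution(spacer_ensemble, max_distance_bp=400)
        assert np.all(rdf.g[rdf.distances < 147] == 0.0)

    def test_crystalline_packing_spikes_at_contact(self):
        lat = ns.LatticeSpec(length_bp=588, tss_index=0)
        cfg = np.array([0, 147, 294, 441])
        rdf = radial_distribution(_record([cfg] * 10, lat), max_distance_bp=294)
        nz = rdf.distances[rdf.g > 0]
        assert set(nz.tolist()) == {147, 294}
        assert rdf.g[147 - 1] > rdf.g[294 - 1]  # contact dominates

    def test_bulk_value_near_one_for_dilute_homogeneous_system(self):
        # dilute ring: hard-core excluded mass is small, so g -> 1 at large r
        lat = ns.LatticeSpec()
        rng = np.random.default_rng(3)
        recs = [
            ns.random_initial_configuration(4, lat, rng).dyads
            for _ in range(1500)
        ]
        rdf = radial_distribution(_record(recs, lat), max_distance_bp=2000)
        far = rdf.g[(rdf.distances > 800)]
        assert np.mean(far) == pytest.approx(1.0, abs=0.1)


class TestMeanSpacing:
    def test_arithmetic_on_planted_peaks(self):
        x = np.arange(0, 1000)
        y = np.zeros(x.size)
        for p in (150, 315, 480, 645, 810):
            y += np.exp(-0.5 * ((x - p) / 12.0) ** 2)
        prof = DensityProfile(x, y + 0.1, 1)
        assert mean_spacing(prof, n_peaks=5) == pytest.approx(165.0, abs=1.0)

    def test_pure_cosine_recovers_period(self):
        x = np.arange(0, 1200)
        prof = DensityProfile(x, 1.0 + 0.3 * np.cos(2 * np.pi * (x - 80) / 160.0), 1)
        assert mean_spacing(prof, n_peaks=5) == pytest.approx(160.0, abs=1.0)

    def test_flat_profile_raises(self):
        prof = DensityProfile(np.arange(1000), np.ones(1000), 1)
        with pytest.raises(InsufficientPeaksError):
            mean_spacing(prof)


class TestMeanNeighborGap:
    def test_crystal_gap_excluding_tss_void(self):
        lat = ns.LatticeSpec(length_bp=1470, tss_index=0)
        cfg = np.array([100, 247, 394, 541])  # void spans the TSS (wrap gap)
        m, se = mean_neighbor_gap(_record([cfg] * 5, lat))
        assert m == pytest.approx(147.0)
        m_all, _ = mean_neighbor_gap(
            _record([cfg] * 5, lat), exclude_tss_flanking=False
        )
        assert m_all == pytest.approx(1470 / 4)


class TestOrderedHeatmap:
    def test_identical_configurations_give_identical_rows(self, lattice):
        cfg = np.array([lattice.tss_index + 60, lattice.tss_index + 260])
        rec = _record([cfg] * 40, lattice)
        m, keys, offs = ordered_heatmap(rec, n_per_row=10, window=(-100, 400))
        assert m.shape[0] == 4
        assert np.allclose(m, m[0])

    def test_row_keys_non_decreasing(self, spacer_ensemble):
        m, keys, _ = ordered_heatmap(spacer_ensemble, n_per_row=500)
        finite = keys[np.isfinite(keys)]
        assert np.all(np.diff(finite) >= 0)

    def test_fallback_single_row_warns(self, lattice):
        rec = _record([[lattice.tss_index + 50]] * 5, lattice)
        with pytest.warns(UserWarning):
            m, keys, _ = ordered_heatmap(rec, n_per_row=100, window=(-100, 200))
        assert m.shape[0] == 1


class TestClassification:
    def _profile_with_peaks(self, h1, h2):
        x = np.arange(-200, 800)
        y = 0.5 + h1 * np.exp(-0.5 * ((x - 150) / 30.0) ** 2)
        y += h2 * np.exp(-0.5 * ((x - 330) / 30.0) ** 2)
        return DensityProfile(x, y, 1)

    def test_decreasing_peaks_is_yeast_like(self):
        assert classify_profile(self._profile_with_peaks(1.0, 0.7)) == "yeast_like"

    def test_increasing_peaks_is_mouse_like(self):
        assert classify_profile(self._profile_with_peaks(0.7, 1.0)) == "mouse_like"

    def test_tie_is_boundary(self):
        assert classify_profile(self._profile_with_peaks(0.8, 0.8)) == "boundary"

    def test_single_peak_unclassifiable(self):
        x = np.arange(-200, 800)
        y = 0.5 + np.exp(-0.5 * ((x - 150) / 30.0) ** 2)
        with pytest.raises(InsufficientPeaksError):
            classify_profile(DensityProfile(x, y, 1))


class TestPhaseDiagram:
    def _fake_ensemble(self, lattice, h1, h2):
        """Synthetic ensemble whose profile has two controlled peaks."""
        rng = np.random.default_rng(9)
        tss = lattice.tss_index
        dyads = []
        for _ in range(400):
            d = []
            if rng.random() < h1:
                d.append(tss + 150 + int(rng.normal(0, 12)))
            if rng.random() < h2:
                d2 = tss + 360 + int(rng.normal(0, 12))
                if d:
                    d2 = max(d2, d[0] + 147)  # respect hard-core exclusion
                d.append(d2)
            d.append(tss - 600)  # bulk anchor keeping normalisation sane
            dyads.append(np.sort(np.array(d)))
        return _record(dyads, lattice)

    def test_grid_labels_and_error_isolation(self):
        lat = ns.LatticeSpec(length_bp=4410, tss_index=2200)
        from nucleosim.profiles import phase_diagram

        def simulate(depth, rate):
            if rate < 0:  # provoke a per-point failure
                raise RuntimeError("bad point")
            # deeper well favours the first peak; faster enzymes the second
            return self._fake_ensemble(lat, 0.5 - depth / 4.0, 0.3 + rate)

        df = phase_diagram([0.0, -2.0], [-1.0, 0.0, 0.5], simulate)
        assert len(df) == 6
        assert set(df.loc[df["enzyme_rate"] < 0, "label"]) == {"error"}
        strong_first = df[(df["depth_kBT"] == -2.0) & (df["enzyme_rate"] == 0.0)]
        strong_second = df[(df["depth_kBT"] == 0.0) & (df["enzyme_rate"] == 0.5)]
        assert strong_first["label"].item() == "yeast_like"
        assert strong_second["label"].item() == "mouse_like"


def test_positioning_well_breaks_tss_symmetry(well_fast_ensemble, spacer_ensemble):
    """The well pulls density to the downstream side of the TSS."""

    def asym(rec):
        prof = smooth = ns.smooth_profile(
            ns.density_profile(rec, window=(-800, 800)), 10.0
        )
        left = prof.density[prof.offsets < -50].mean()
        right = prof.density[prof.offsets > 50].mean()
        return right - left

    assert asym(well_fast_ensemble) > asym(spacer_ensemble) + 0.05
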