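"""Synthetic-data generators: kinetics, spectra, site tables, force traces."""

import numpy as np
import pytest
from scipy.stats import binom

from lipidstab.contacts import contact_stats
from lipidstab.sites import basic_span, screen_database
from lipidstab.synthetic import (
    BindingKineticsParams,
    CompetitionSpec,
    CompetitionSpecies,
    ForceSimParams,
    SiteTableSpec,
    SpectrumSpec,
    SpectrumSpecies,
    TwoSiteKineticsParams,
    sim_competition_experiment,
    sim_contact_trace,
    sim_force_traces,
    sim_site_table,
    sim_spectrum,
    sim_two_site_trace,
)


def occupancy_se(pi: float, p_on: float, p_off: float, n: int) -> float:
    """Standard error of the time-average occupancy of the two-state chain.

    The chain's autocorrelation is rho = 1 - p_on - p_off per frame, so the
    variance of the mean is inflated by (1 + rho) / (1 - rho).
    """
    rho = 1.0 - p_on - p_off
    return float(np.sqrt(pi * (1 - pi) * (1 + rho) / (1 - rho) / n))


class TestTwoStateChain:
    def test_absorbing_unbound_limit(self):
        # k_off dt >> 1: any binding ends within a frame
        trace = sim_contact_trace(BindingKineticsParams(
            k_on=0.01, k_off=100.0, dt=1.0, n_frames=50_000, seed=0))
        assert trace.bound.mean() < 0.05

    def test_symmetric_rates_give_half_occupancy(self):
        p = BindingKineticsParams(k_on=0.1, k_off=0.1, dt=1.0, n_frames=100_000, seed=0)
        trace = sim_contact_trace(p)
        p_step = 1 - np.exp(-0.1)
        se = occupancy_se(0.5, p_step, p_step, p.n_frames)
        assert trace.bound.mean() == pytest.approx(0.5, abs=3 * se)

    def test_occupancy_matches_transition_matrix_oracle(self):
        p = BindingKineticsParams(k_on=0.1, k_off=0.05, dt=1.0,
                                  n_frames=200_000, seed=0)
        trace = sim_contact_trace(p)
        # independent oracle: stationary vector of the explicit 2x2 matrix
        p_on = 1 - np.exp(-p.k_on * p.dt)
        p_off = 1 - np.exp(-p.k_off * p.dt)
        P = np.array([[1 - p_on, p_on], [p_off, 1 - p_off]])
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi = pi / pi.sum()
        se = occupancy_se(pi[1], p_on, p_off, p.n_frames)
        # the frame-discretized chain equilibrates at p_on/(p_on+p_off),
        # within sampling error of the continuous-time k_on/(k_on+k_off)
        assert trace.bound.mean() == pytest.approx(pi[1], abs=3 * se)
        assert trace.bound.mean() == pytest.approx(2 / 3, abs=3 * se)

    def test_mean_dwell_matches_discrete_correction(self):
        p = BindingKineticsParams(k_on=0.1, k_off=0.05, dt=1.0,
                                  n_frames=200_000, seed=0)
        stats = contact_stats(sim_contact_trace(p))
        durations = np.array([e.duration for e in stats.events if not e.censored])
        se = durations.std(ddof=1) / np.sqrt(durations.size)
        assert stats.mean_residence == pytest.approx(p.mean_dwell_frames * p.dt,
                                                     abs=3 * se)

    def test_reproducible_and_seed_sensitive(self):
        p = BindingKineticsParams(k_on=0.1, k_off=0.1, n_frames=1000, seed=7)
        a = sim_contact_trace(p).bound
        b = sim_contact_trace(p).bound
        c = sim_contact_trace(BindingKineticsParams(
            k_on=0.1, k_off=0.1, n_frames=1000, seed=8)).bound
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    @pytest.mark.parametrize("bad", [
        dict(k_on=0.0, k_off=0.1), dict(k_on=0.1, k_off=-1.0),
        dict(k_on=0.1, k_off=0.1, dt=0.0), dict(k_on=0.1, k_off=0.1, n_frames=0),
    ])
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ValueError):
            BindingKineticsParams(**{"dt": 1.0, "n_frames": 10, **bad})


class TestTwoSiteChain:
    def test_at_most_one_site_bound_per_frame(self):
        s1, s2 = sim_two_site_trace(TwoSiteKineticsParams(
            0.1, 0.1, 0.05, 0.05, 0.05, 0.05, n_frames=20_000, seed=0))
        assert np.max(s1.bound + s2.bound) <= 1

    def test_symmetric_rates_give_equal_occupancies(self):
        s1, s2 = sim_two_site_trace(TwoSiteKineticsParams(
            0.08, 0.08, 0.04, 0.04, 0.02, 0.02, n_frames=200_000, seed=1))
        assert s1.bound.mean() == pytest.approx(s2.bound.mean(), abs=0.02)

    def test_occupancies_match_eigenvector_oracle(self):
        params = TwoSiteKineticsParams(0.05, 0.03, 0.05, 0.04, 0.02, 0.01,
                                       n_frames=200_000, seed=3)
        s1, s2 = sim_two_site_trace(params)
        # independent linear-algebra oracle on the documented discretization
        def p_row(rates):
            k_tot = sum(r for _, r in rates)
            p_exit = 1 - np.exp(-k_tot * params.dt)
            return {j: p_exit * r / k_tot for j, r in rates}
        rows = [p_row([(1, params.k_on_site1), (2, params.k_on_site2)]),
                p_row([(0, params.k_off_site1), (2, params.k_hop_12)]),
                p_row([(0, params.k_off_site2), (1, params.k_hop_21)])]
        P = np.zeros((3, 3))
        for i, row in enumerate(rows):
            for j, v in row.items():
                P[i, j] = v
            P[i, i] = 1 - sum(row.values())
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmin(np.abs(w - 1))])
        pi = pi / pi.sum()
        # conservative SE bound from the chain's slowest relaxation mode
        rho = sorted(np.abs(w))[-2]
        for trace, target in ((s1, pi[1]), (s2, pi[2])):
            se = np.sqrt(target * (1 - target) * (1 + rho) / (1 - rho)
                         / params.n_frames)
            assert trace.bound.mean() == pytest.approx(target, abs=3 * se)

    def test_zero_hop_rates_reduce_to_independent_entries(self):
        s1, s2 = sim_two_site_trace(TwoSiteKineticsParams(
            0.05, 0.05, 0.1, 0.1, 0.0, 0.0, n_frames=5_000, seed=0))
        # no direct exchange: transitions between the two bound states never occur
        states = s1.bound.astype(int) - s2.bound.astype(int)  # +1, -1, or 0
        direct = np.abs(np.diff(states)) == 2
        assert not direct.any()

    def test_all_entry_rates_zero_rejected(self):
        with pytest.raises(ValueError):
            TwoSiteKineticsParams(0.0, 0.0, 0.1, 0.1)


class TestSimSpectrum:
    def single_species(self, **kw):
        defaults = dict(
            species=(SpectrumSpecies("tet", 100_000.0, (17,)),),
            n_max_adducts=3, p_bind=0.3, noise_sd=0.0,
            mz_min=5500.0, mz_max=6500.0, mz_step=0.25, seed=0)
        defaults.update(kw)
        return SpectrumSpec(**defaults)

    def test_p_bind_zero_gives_apo_only(self):
        _, truth = sim_spectrum(self.single_species(p_bind=0.0))
        assert set(truth["n_adducts"]) == {0}

    def test_noiseless_centroid_at_theoretical_mz(self):
        from lipidstab.nms import detect_peaks
        spec = self.single_species(p_bind=0.0)
        spectrum, truth = sim_spectrum(spec)
        peaks = detect_peaks(spectrum, min_separation=5.0)
        assert len(peaks) == 1
        assert peaks[0].centroid == pytest.approx(truth["mz"].iloc[0],
                                                  abs=spec.mz_step)

    def test_binomial_adduct_weights(self):
        _, truth = sim_spectrum(self.single_species())
        weights = truth.sort_values("n_adducts")["intensity"].to_numpy()
        np.testing.assert_allclose(weights, [0.343, 0.441, 0.189, 0.027],
                                   atol=1e-12)
        np.testing.assert_allclose(
            weights, binom.pmf(np.arange(4), 3, 0.3), atol=1e-12)

    def test_truth_sums_to_abundance_per_species(self):
        spec = SpectrumSpec(
            species=(SpectrumSpecies("a", 100_000.0, (16, 17), abundance=2.0),
                     SpectrumSpecies("b", 99_000.0, (16, 17), abundance=0.5)),
            noise_sd=0.0, mz_min=5000.0, mz_max=7000.0, seed=0)
        _, truth = sim_spectrum(spec)
        sums = truth.groupby("species")["intensity"].sum()
        assert sums["a"] == pytest.approx(2.0)
        assert sums["b"] == pytest.approx(0.5)

    def test_fixed_seed_bit_identical(self):
        spec = self.single_species(noise_sd=0.05)
        s1, _ = sim_spectrum(spec)
        s2, _ = sim_spectrum(spec)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            self.single_species(p_bind=1.5)
        with pytest.raises(ValueError):
            self.single_species(mz_min=7000.0, mz_max=5000.0)


class TestSimSiteTable:
    def test_all_single_when_fraction_multi_zero(self):
        _, truth = sim_site_table(SiteTableSpec(n_sites=40, fraction_multi=0.0, seed=0))
        assert set(truth["true_class"]) == {"single_helix"}

    def test_screen_recovers_pure_multi_population(self):
        records, truth = sim_site_table(SiteTableSpec(
            n_sites=120, fraction_multi=1.0, multi_log_mu=float(np.log(60.0)),
            multi_log_sigma=0.2, seed=0))
        result = screen_database(records)
        assert result.n_above >= 0.99 * len(records)

    def test_expected_class_counts_hit_exactly(self):
        _, truth = sim_site_table(SiteTableSpec(n_sites=255,
                                                fraction_multi=180 / 255, seed=0))
        counts = truth["true_class"].value_counts()
        assert counts["multi_helix"] == 180
        assert counts["single_helix"] == 75

    def test_every_record_has_two_basic_residues_at_true_span(self):
        records, truth = sim_site_table(SiteTableSpec(n_sites=30, seed=2))
        for record, (_, row) in zip(records, truth.iterrows()):
            res = basic_span(record)
            assert res.n_basic >= 2
            assert res.span == row["true_span"]

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            SiteTableSpec(single_log_sigma=0.0)


class TestSimForceTraces:
    def test_noiseless_work_is_half_k_d_squared(self):
        from lipidstab.pull import work_integral
        traces = sim_force_traces(ForceSimParams(noise_sd=0.0, n_replicates=1))
        res = work_integral(traces[0], displacement_stop=1.1)
        assert res.work == pytest.approx(0.5 * 1000.0 * 1.1**2, rel=1e-9)

    def test_lipid_bonus_adds_exactly_that_work(self):
        from lipidstab.pull import work_integral
        params = ForceSimParams(noise_sd=0.0, lipid_work_bonus=50.0, n_replicates=1)
        apo = work_integral(sim_force_traces(params, with_lipid=False)[0]).work
        lipid = work_integral(sim_force_traces(params, with_lipid=True)[0]).work
        assert lipid - apo == pytest.approx(50.0, rel=1e-9)

    def test_replicates_distinct_and_reproducible(self):
        params = ForceSimParams(n_replicates=20, seed=4)
        traces = sim_force_traces(params)
        assert len(traces) == 20
        assert not np.array_equal(traces[0].force, traces[1].force)
        again = sim_force_traces(params)
        np.testing.assert_array_equal(traces[5].force, again[5].force)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ForceSimParams(k=-1.0)
        with pytest.raises(ValueError):
            ForceSimParams(rupture_displacement=0.0)


class TestSimCompetition:
    def test_equal_fractions_give_zero_true_delta(self):
        spec = CompetitionSpec(test_frac_no_lipid=0.3, test_frac_with_lipid=0.3,
                               ref_frac_no_lipid=0.3, ref_frac_with_lipid=0.3)
        assert spec.true_delta == 0.0

    def test_reference_stabilization_raises_test_ratio(self):
        # lipid halves the reference's dissociation only
        spec = CompetitionSpec()
        assert spec.true_ratio("with_lipid") > spec.true_ratio("no_lipid")
        assert spec.true_delta > 0

    def test_spectra_layout_and_reproducibility(self):
        spec = CompetitionSpec(n_replicates=2, seed=9)
        spectra, truth = sim_competition_experiment(spec)
        assert set(spectra) == {(c, r) for c in ("no_lipid", "with_lipid")
                                for r in range(2)}
        again, _ = sim_competition_experiment(spec)
        for key in spectra:
            np.testing.assert_array_equal(spectra[key].intensity,
                                          again[key].intensity)
        assert not truth["collision_warning"]

    def test_mass_collision_warning(self):
        spec = CompetitionSpec(
            test_species=CompetitionSpecies("a", 100_000.0, 25_000.0),
            ref_species=CompetitionSpecies("b", 100_010.0, 25_002.0))
        _, truth = sim_competition_experiment(
            CompetitionSpec(test_species=spec.test_species,
                            ref_species=spec.ref_species, n_replicates=1))
        assert truth["collision_warning"]

    def test_monomer_intensity_proportional_to_fraction(self):
        spec = CompetitionSpec(replicate_noise_sd=0.0, noise_sd=0.0, n_replicates=1)
        _, truth = sim_competition_experiment(spec)
        table = truth["table"]
        for _, row in table.iterrows():
            assert row["monomer_intensity"] == pytest.approx(
                row["dissociated_fraction"])
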