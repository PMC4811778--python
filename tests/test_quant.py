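"""Isotope-pair ratio estimation: regression, confidence, aggregation, EICs."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from xlquant.chem import Channel, LinkType, LinkedSpecies, builtin_linker, species_mass
from xlquant.quant import (
    AllOrNone,
    EicPair,
    PeakStrategy,
    RatioEstimate,
    aggregate_link,
    choose_peak_ratio,
    confidence_score,
    detect_all_or_none,
    extract_eic_pair,
    fit_ratio,
    normalize_to_spikein,
    predict_envelope,
    quantify_eic_pair,
    reciprocal_combine,
    SiteQuant,
)
from xlquant.synthgen import (
    InterferenceSim,
    SimulationConfig,
    SpeciesSim,
    simulate_ms1_run,
)

LINKER = builtin_linker("bAL2")


def mono_species(peptide="AKDLFGR", charge=2):
    return LinkedSpecies(link_type=LinkType.MONO, peptide_a=peptide,
                         site_a=2, charge=charge)


def sim_run(ratio=2.0, noise=0.0, seed=0, interferences=(), species=None):
    species = species or mono_species()
    cfg = SimulationConfig(
        species=(SpeciesSim(species=species, true_ratio=ratio, apex_time=100.0),),
        interferences=tuple(interferences),
        rt_end=200.0,
        noise_cv=noise,
        seed=seed,
    )
    return simulate_ms1_run(cfg, LINKER)[0], species


class TestEnvelope:
    def test_small_mass_monoisotopic_dominates(self):
        assert predict_envelope(1000.0).most_abundant_index == 0

    def test_large_mass_most_abundant_beyond_monoisotopic(self):
        assert predict_envelope(4432.0).most_abundant_index >= 2

    def test_full_truncation_single_peak(self):
        env = predict_envelope(1000.0, truncation=1.0)
        assert env.offsets == (0.0,)
        assert env.abundances == (1.0,)

    def test_base_peak_normalized_and_bounded(self):
        env = predict_envelope(3000.0, truncation=0.01)
        assert max(env.abundances) == pytest.approx(1.0)
        assert len(env.offsets) <= 8

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            predict_envelope(0.0)


class TestFitRatio:
    def test_exact_fit(self):
        a, s = fit_ratio([1, 2, 3], [2, 4, 6])
        assert a == pytest.approx(2.0) and s == pytest.approx(0.0)

    def test_residual_example(self):
        a, s = fit_ratio([1, 2, 3], [2, 4, 7])
        assert a == pytest.approx(31 / 14, rel=1e-9)
        assert s == pytest.approx(0.1130, abs=1e-4)

    def test_degenerate_light_channel(self):
        with pytest.raises(ZeroDivisionError):
            fit_ratio([0, 0, 0], [1, 1, 1])

    def test_matches_least_squares_oracle_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(2, 12))
            x = rng.uniform(0.1, 100.0, size=k)
            y = rng.uniform(0.0, 100.0, size=k)
            a, s = fit_ratio(x, y)
            a_oracle = float(np.linalg.lstsq(x[:, None], y, rcond=None)[0][0])
            assert a == pytest.approx(a_oracle, rel=1e-9)
            resid = y - a_oracle * x
            s_oracle = math.sqrt(resid @ resid / ((k - 1) * (x @ x)))
            assert s == pytest.approx(s_oracle, rel=1e-9, abs=1e-12)

    @given(st.floats(0.01, 100.0))
    def test_scale_equivariance_in_y(self, c):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        y = np.array([2.0, 3.5, 11.0, 6.5])
        a, _ = fit_ratio(x, y)
        a_scaled, _ = fit_ratio(x, c * y)
        assert a_scaled == pytest.approx(c * a, rel=1e-9)

    @given(st.floats(0.01, 100.0))
    def test_confidence_invariant_under_joint_scaling(self, c):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        y = np.array([2.0, 3.5, 11.0, 6.5])
        sigma = confidence_score(*fit_ratio(x, y))
        sigma_scaled = confidence_score(*fit_ratio(c * x, c * y))
        assert sigma_scaled == pytest.approx(sigma, rel=1e-9)


class TestConfidenceScore:
    @pytest.mark.parametrize("a,s,expected", [
        (2.0, 0.0, 0.0),        # perfect fit, highest confidence
        (2.0, 2.0, 1.0),        # clamp boundary
        (31 / 14, 0.11294, 0.0510),
        (0.0, 1.0, 1.0),        # no light signal
    ])
    def test_examples(self, a, s, expected):
        assert confidence_score(a, s) == pytest.approx(expected, abs=5e-4)

    @given(st.floats(1e-6, 1e6), st.floats(0, 1e6))
    def test_bounded(self, a, s):
        assert 0.0 <= confidence_score(a, s) <= 1.0


def estimate(a=1.0, sigma=0.1, peak=0, degenerate=None):
    return RatioEstimate(
        a_hat=a, sigma_hat=sigma * a, sigma=sigma,
        strategy=PeakStrategy.MONOISOTOPIC, peak_index=peak, k=5,
        degenerate=degenerate,
    )


class TestChoosePeakRatio:
    def test_least_interfered_is_argmin_sigma(self):
        ests = [estimate(a=1.0, sigma=0.4, peak=0),
                estimate(a=2.0, sigma=0.1, peak=1),
                estimate(a=3.0, sigma=0.3, peak=2)]
        chosen = choose_peak_ratio(ests, PeakStrategy.LEAST_INTERFERED)
        assert chosen.peak_index == 1

    def test_monoisotopic_ignores_sigma(self):
        ests = [estimate(sigma=0.9, peak=0), estimate(sigma=0.0, peak=1)]
        assert choose_peak_ratio(ests, PeakStrategy.MONOISOTOPIC).peak_index == 0

    def test_most_intense_uses_areas(self):
        ests = [estimate(peak=0), estimate(peak=1)]
        chosen = choose_peak_ratio(ests, PeakStrategy.MOST_INTENSE, areas=[1.0, 9.0])
        assert chosen.peak_index == 1

    def test_single_peak_under_every_strategy(self):
        ests = [estimate(peak=0)]
        for strategy in PeakStrategy:
            assert choose_peak_ratio(ests, strategy, areas=[1.0]).peak_index == 0


class TestAggregate:
    def test_median_of_kept_ratios(self):
        ests = [estimate(a=1.9, sigma=0.1), estimate(a=2.0, sigma=0.2),
                estimate(a=2.2, sigma=0.3)]
        q = aggregate_link("L", ests)
        assert q.median_ratio == pytest.approx(2.0)
        assert q.n_spectra_used == 3

    def test_high_sigma_spectra_discarded(self):
        ests = [estimate(a=2.0, sigma=0.1), estimate(a=9.0, sigma=0.6)]
        q = aggregate_link("L", ests)
        assert q.median_ratio == pytest.approx(2.0)
        assert q.n_spectra_used == 1

    def test_sigma_cutoff_is_inclusive_discard(self):
        # sigma exactly at the cutoff is discarded
        ests = [estimate(a=3.0, sigma=0.5)]
        q = aggregate_link("L", ests)
        assert q.median_ratio is None

    def test_all_discarded_goes_all_or_none(self):
        ests = [estimate(a=2.0, sigma=0.7)]
        grid = np.arange(5.0)
        pair = EicPair(
            rt_grid=grid,
            light=np.ones((1, 5)),
            heavy=np.zeros((1, 5)),
            window=(0, 5),
        )
        q = aggregate_link("L", ests, eic_pairs=[pair])
        assert q.median_ratio is None
        assert q.all_or_none is AllOrNone.ONLY_LIGHT


class TestNormalize:
    def quants(self, *vals, prefix="BSA"):
        return [SiteQuant(link_id=f"{prefix}-{i}", median_ratio=v, n_spectra_used=1)
                for i, v in enumerate(vals)]

    def test_divides_by_spikein_median(self):
        qs = (self.quants(2.5, prefix="LNK")
              + self.quants(1.2, 1.25, 1.3, prefix="BSA"))
        out = normalize_to_spikein(qs, "BSA")
        assert out[0].normalized_ratio == pytest.approx(2.0)

    def test_unit_spikein_is_identity(self):
        qs = self.quants(3.3, prefix="LNK") + self.quants(1.0, 1.0, prefix="BSA")
        out = normalize_to_spikein(qs, "BSA")
        assert out[0].normalized_ratio == pytest.approx(3.3)

    def test_missing_spikein_instructs_explicit_skip(self):
        with pytest.raises(ValueError, match="skip normalization"):
            normalize_to_spikein(self.quants(1.0, prefix="LNK"), "BSA")


class TestAllOrNone:
    def make_pair(self, light, heavy):
        light = np.asarray(light, float)[None, :]
        heavy = np.asarray(heavy, float)[None, :]
        return EicPair(rt_grid=np.arange(light.shape[1], dtype=float),
                       light=light, heavy=heavy, window=(0, light.shape[1]))

    def test_only_light(self):
        pair = self.make_pair([10, 100, 10], [0, 0, 0])
        assert detect_all_or_none(pair) is AllOrNone.ONLY_LIGHT

    def test_only_heavy(self):
        pair = self.make_pair([0, 0, 0], [10, 100, 10])
        assert detect_all_or_none(pair) is AllOrNone.ONLY_HEAVY

    def test_both_strong_none(self):
        pair = self.make_pair([10, 100, 10], [20, 200, 20])
        assert detect_all_or_none(pair) is AllOrNone.NONE

    def test_both_zero_is_unquantifiable_not_all_or_none(self):
        pair = self.make_pair([0, 0, 0], [0, 0, 0])
        assert detect_all_or_none(pair) is AllOrNone.NONE


class TestReciprocal:
    def test_consistent_increase(self):
        calls = reciprocal_combine(
            {"L": 1 / 6.0}, {"L": 5.5}, fold_threshold=5.0,
        )
        assert calls[0].consistent_change and calls[0].direction == "up"
        assert calls[0].forward_ratio == pytest.approx(6.0)

    def test_one_direction_only_not_consistent(self):
        calls = reciprocal_combine({"L": 1 / 6.0}, {"L": 1.1}, fold_threshold=5.0)
        assert not calls[0].consistent_change

    def test_consistent_decrease_side(self):
        calls = reciprocal_combine({"L": 10.0}, {"L": 0.15}, fold_threshold=5.0)
        assert calls[0].consistent_change and calls[0].direction == "down"

    def test_unpaired_link_reported(self):
        calls = reciprocal_combine({"L": 1 / 6.0}, {}, fold_threshold=5.0)
        assert calls[0].direction == "unpaired"
        assert not calls[0].consistent_change


class TestEicExtraction:
    def test_apex_matches_injected_intensity(self):
        run, species = sim_run(ratio=1.0)
        env = predict_envelope(species_mass(species, LINKER))
        pair = extract_eic_pair(run, species, LINKER, env, rt_center=100.0)
        # light monoisotopic apex equals the injected apex (abundance 1 peak)
        apex = pair.light[env.most_abundant_index].max()
        assert apex == pytest.approx(1e6, rel=1e-6)

    def test_absent_species_gives_zero_traces(self):
        run, _ = sim_run(ratio=1.0)
        other = LinkedSpecies(link_type=LinkType.MONO, peptide_a="GGGGKGGGGR",
                              site_a=5, charge=3)
        env = predict_envelope(species_mass(other, LINKER))
        pair = extract_eic_pair(run, other, LINKER, env, rt_center=100.0)
        assert pair.light.sum() == 0.0 and pair.heavy.sum() == 0.0

    def test_coeluting_species_within_tolerance_contaminates_trace(self):
        species = mono_species()
        mass_d0 = species_mass(species, LINKER)
        mz_mono = (mass_d0 + 2 * 1.007276) / 2
        clean_run, _ = sim_run(ratio=1.0)
        dirty_run, _ = sim_run(
            ratio=1.0,
            interferences=[InterferenceSim(mz=mz_mono * (1 + 5e-6),
                                           apex_time=100.0, apex_intensity=5e5)],
        )
        env = predict_envelope(mass_d0)
        clean = extract_eic_pair(clean_run, species, LINKER, env, rt_center=100.0)
        dirty = extract_eic_pair(dirty_run, species, LINKER, env, rt_center=100.0)
        assert dirty.light[0].sum() > clean.light[0].sum()

    def test_window_outside_run_rejected(self):
        run, species = sim_run()
        env = predict_envelope(species_mass(species, LINKER))
        with pytest.raises(ValueError):
            extract_eic_pair(run, species, LINKER, env, rt_center=10_000.0)

    def test_interference_strictly_increases_sigma(self):
        species = mono_species()
        mass_d0 = species_mass(species, LINKER)
        mz_mono = (mass_d0 + 2 * 1.007276) / 2
        env = predict_envelope(mass_d0)
        clean_run, _ = sim_run(ratio=2.0)
        # co-eluting but time-shifted interferent in the light channel
        dirty_run, _ = sim_run(
            ratio=2.0,
            interferences=[InterferenceSim(mz=mz_mono, apex_time=107.0,
                                           apex_intensity=4e5)],
        )
        clean = quantify_eic_pair(
            extract_eic_pair(clean_run, species, LINKER, env, rt_center=100.0),
            PeakStrategy.MONOISOTOPIC,
        )
        dirty = quantify_eic_pair(
            extract_eic_pair(dirty_run, species, LINKER, env, rt_center=100.0),
            PeakStrategy.MONOISOTOPIC,
        )
        assert dirty.sigma > clean.sigma

    def test_label_swap_inverts_ratio_on_clean_signal(self):
        run, species = sim_run(ratio=2.0)
        env = predict_envelope(species_mass(species, LINKER))
        pair = extract_eic_pair(run, species, LINKER, env, rt_center=100.0)
        swapped = dataclasses.replace(pair, light=pair.heavy, heavy=pair.light)
        est = quantify_eic_pair(pair, PeakStrategy.MONOISOTOPIC)
        est_swapped = quantify_eic_pair(swapped, PeakStrategy.MONOISOTOPIC)
        assert est_swapped.a_hat == pytest.approx(1.0 / est.a_hat, rel=1e-9)
        assert est_swapped.sigma == pytest.approx(est.sigma, abs=1e-9)
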