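"""Synthetic thermograms, diffraction patterns and screening campaigns:
round-trip recovery of planted ground truth."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import find_peaks

import asdscreen as asd
from asdscreen.classify import classify_campaign, merge_unresolvable_tgs, TgEvent
from asdscreen.errors import ValidationError
from asdscreen.synthetic import (
    CampaignSpec,
    ThermalEventSpec,
    detect_crystallinity,
    extract_peaks,
    extract_tg_steps,
    fox_tg,
    make_campaign,
    make_thermogram,
    make_xrpd,
    planted_class,
    planted_max_a_loading,
)


def _tg(center, width=12.0, height=0.3):
    return ThermalEventSpec("glass_transition", center, width, height)


class TestThermograms:
    def test_single_step_round_trip(self):
        """Zero noise: the extractor recovers the step center within one
        grid step and the onset-to-end width within 10%."""
        trace = make_thermogram([_tg(85.0, width=14.0)], noise_sd=0.0)
        steps = extract_tg_steps(trace)
        assert len(steps) == 1
        grid_step = trace.temperature_c[1] - trace.temperature_c[0]
        assert abs(steps[0].center_c - 85.0) <= grid_step
        assert steps[0].width_c == pytest.approx(14.0, rel=0.10)

    def test_inflection_point_sits_at_specified_center(self):
        trace = make_thermogram([_tg(120.0)], noise_sd=0.0)
        dy = np.gradient(trace.reverse_heat_flow, trace.temperature_c)
        t_inflect = trace.temperature_c[np.argmax(dy)]
        grid_step = trace.temperature_c[1] - trace.temperature_c[0]
        assert abs(t_inflect - 120.0) <= grid_step

    def test_two_close_steps_report_one_after_resolution_merge(self):
        """Two transitions 5 degC apart: below the 10 degC instrument
        resolution, extractor + merge yields a single event."""
        trace = make_thermogram([_tg(60.0, 8.0), _tg(65.0, 8.0)], noise_sd=0.0)
        steps = extract_tg_steps(trace)
        events = tuple(TgEvent(s.center_c, max(s.width_c, 0.1)) for s in steps)
        assert len(merge_unresolvable_tgs(events)) == 1

    def test_two_distant_steps_stay_separate(self):
        trace = make_thermogram([_tg(60.0, 8.0), _tg(130.0, 8.0)], noise_sd=0.0)
        steps = extract_tg_steps(trace)
        assert len(steps) == 2

    def test_melting_endotherm_sign_and_area(self):
        """Planted melting peak: detected as endothermic (negative area),
        and the integrated area matches the planted magnitude within 5%."""
        melt = ThermalEventSpec("melting", 160.0, 6.0, -40.0)
        trace = make_thermogram([_tg(60.0), melt], noise_sd=0.0)
        peaks = extract_peaks(trace, min_area=1.0)
        assert len(peaks) == 1
        assert peaks[0].area < 0
        # independent numerical integration of the generated curve
        resid = trace.total_heat_flow - trace.reverse_heat_flow
        oracle = np.trapezoid(resid, trace.temperature_c)
        assert peaks[0].area == pytest.approx(oracle, rel=0.05)
        assert peaks[0].area == pytest.approx(-40.0, rel=0.05)

    def test_event_outside_grid_rejected(self):
        with pytest.raises(ValidationError):
            make_thermogram([_tg(500.0)])

    def test_seeded_reproducibility(self):
        a = make_thermogram([_tg(85.0)], noise_sd=0.02, seed=9)
        b = make_thermogram([_tg(85.0)], noise_sd=0.02, seed=9)
        assert np.array_equal(a.reverse_heat_flow, b.reverse_heat_flow)
        assert np.array_equal(a.total_heat_flow, b.total_heat_flow)


class TestXrpd:
    def test_halo_only_is_amorphous(self):
        pattern = make_xrpd(halo_weight=1.0, bragg_peaks=(), noise_sd=0.005, seed=1)
        assert not detect_crystallinity(pattern)

    def test_sharp_peaks_well_above_noise_are_crystalline(self):
        pattern = make_xrpd(
            halo_weight=1.0,
            bragg_peaks=[(10.0, 0.5), (16.3, 0.4), (22.1, 0.3)],
            noise_sd=0.005, seed=1,
        )
        assert detect_crystallinity(pattern)

    def test_decision_at_detection_limit_matches_bruteforce_scan(self):
        """Near the limit of detection the flag agrees with an exhaustive
        prominence scan over every local maximum."""
        lod = 0.05
        for intensity in (0.02, 0.04, 0.06, 0.10, 0.30):
            pattern = make_xrpd(
                halo_weight=1.0, bragg_peaks=[(14.0, intensity)],
                noise_sd=0.0, seed=0,
            )
            flagged = detect_crystallinity(pattern, limit_of_detection=lod)

            # oracle: scan all strict local maxima, compute prominence and
            # width by find_peaks on the full signal, then apply the rule
            idx, props = find_peaks(pattern.intensity, prominence=0.0, width=(None, None), rel_height=0.5)
            step = pattern.two_theta[1] - pattern.two_theta[0]
            oracle = any(
                prom >= lod and w * step <= 0.5
                for prom, w in zip(props["prominences"], props["widths"])
            )
            assert flagged == oracle, f"intensity {intensity}"

    def test_peak_outside_scan_range_rejected(self):
        with pytest.raises(ValidationError):
            make_xrpd(bragg_peaks=[(45.0, 1.0)])


@pytest.fixture(scope="module")
def campaign_spec(compounds):
    drugs = ("IBU", "ITR")
    polymers = ("PK30", "PVA", "SOL")
    boundary = {
        ("IBU", "PK30"): 0.6, ("IBU", "PVA"): 0.4, ("IBU", "SOL"): 0.2,
        ("ITR", "PK30"): 0.4, ("ITR", "PVA"): 0.6, ("ITR", "SOL"): 0.2,
    }
    return CampaignSpec(
        drugs=drugs, polymers=polymers, true_boundary=boundary,
        method_bias={"QC": 0.2, "FC_RT": -0.2, "FC_RP": 0.0, "AD": 0.0, "SD": 0.0},
        seed=11,
    )


@pytest.fixture(scope="module")
def compounds():
    return asd.load_all_compounds()


class TestFoxRule:
    @given(w=st.floats(0.01, 0.99))
    def test_mixed_tg_between_pure_values(self, w):
        tg = fox_tg(-44.0, 162.0, w)
        assert -44.0 < tg < 162.0

    def test_monotone_in_drug_loading(self):
        tgs = [fox_tg(-44.0, 162.0, w) for w in np.linspace(0.05, 0.95, 19)]
        assert all(a > b for a, b in zip(tgs, tgs[1:]))  # more drug, lower Tg


class TestCampaigns:
    def test_noiseless_recovery_is_perfect(self, campaign_spec, compounds):
        """Zero noise, planted boundaries: classification recovers every
        planted class and the planted polymer ranking scores 1/1."""
        spec = replace(campaign_spec, tg_noise_sd=0.0)
        result = make_campaign(spec, compounds)
        recovered = classify_campaign(result.records, compounds)
        assert recovered == dict(result.truth)

    def test_noisy_recovery_above_95_percent(self, campaign_spec, compounds):
        result = make_campaign(campaign_spec, compounds)
        recovered = classify_campaign(result.records, compounds)
        agree = sum(recovered[k] == result.truth[k] for k in result.truth)
        assert agree / len(result.truth) >= 0.95

    def test_planted_ranking_recovered_with_full_concordance(
        self, campaign_spec, compounds
    ):
        """The SD ranking recovered from the records equals the ranking
        implied by the planted boundaries: concordance (1, 1)."""
        from asdscreen.ranking import concordance, rank_experimental, PolymerOutcome

        spec = replace(campaign_spec, tg_noise_sd=0.0)
        result = make_campaign(spec, compounds)
        recovered = classify_campaign(result.records, compounds)

        outcomes = []
        for poly in spec.polymers:
            a_loadings = [
                dl for dl in spec.loadings
                if recovered[("IBU", poly, dl, "SD")] == "A"
            ]
            outcomes.append(
                PolymerOutcome(
                    polymer=poly, best_class="A",
                    max_loading_class_a=max(a_loadings) if a_loadings else None,
                )
            )
        recovered_rank = rank_experimental("IBU", "SD", outcomes).top(3)
        planted = sorted(
            spec.polymers,
            key=lambda p: (-(planted_max_a_loading(spec, "IBU", p, "SD") or 0), p),
        )[:3]
        scores = concordance(list(recovered_rank), planted)
        assert (scores.f_position, scores.f_identity) == (1.0, 1.0)

    def test_quench_cooling_bias_shifts_boundary_one_level(self, campaign_spec):
        """A +0.2 bias moves the maximum glass-solution loading up exactly
        one step of the 0.2-spaced loading grid (direct boundary
        arithmetic, no simulation)."""
        for pair, boundary in campaign_spec.true_boundary.items():
            ref = planted_max_a_loading(campaign_spec, *pair, "SD")
            qc = planted_max_a_loading(campaign_spec, *pair, "QC")
            if ref is not None and ref + 0.2 <= max(campaign_spec.loadings):
                assert qc == pytest.approx(ref + 0.2)

    def test_identical_biases_give_identical_truth(self, campaign_spec):
        """AD and SD share a zero bias, so their planted grids agree
        everywhere -> concordance of their rankings is trivially (1, 1)."""
        for (drug, poly), boundary in campaign_spec.true_boundary.items():
            for dl in campaign_spec.loadings:
                a = planted_class(dl, boundary, campaign_spec.method_bias["AD"],
                                  campaign_spec.aa_band)
                s = planted_class(dl, boundary, campaign_spec.method_bias["SD"],
                                  campaign_spec.aa_band)
                assert a == s

    def test_bit_identical_records_across_runs(self, campaign_spec, compounds):
        r1 = make_campaign(campaign_spec, compounds)
        r2 = make_campaign(campaign_spec, compounds)
        assert r1.records == r2.records
        assert dict(r1.truth) == dict(r2.truth)

    def test_different_seeds_differ(self, campaign_spec, compounds):
        r1 = make_campaign(campaign_spec, compounds)
        r2 = make_campaign(replace(campaign_spec, seed=99), compounds)
        assert r1.records != r2.records

    def test_subresolution_domains_plant_hidden_phase_separation(
        self, campaign_spec, compounds
    ):
        """With all AA domains forced below the 30 nm limit, phase-separated
        samples show a single averaged transition and are misread as one
        phase -- ground truth the classifier cannot access."""
        spec = replace(
            campaign_spec, subresolution_fraction=1.0, tg_noise_sd=0.0
        )
        result = make_campaign(spec, compounds)
        recovered = classify_campaign(result.records, compounds)
        aa_cells = [k for k, lab in result.truth.items() if lab == "AA"]
        assert aa_cells
        assert all(recovered[k] != "AA" for k in aa_cells)

    def test_missing_boundary_rejected(self, compounds):
        spec = CampaignSpec(
            drugs=("IBU",), polymers=("PK30",), true_boundary={}, seed=0
        )
        with pytest.raises(ValidationError):
            make_campaign(spec, compounds)

    def test_shifted_boundary_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            CampaignSpec(
                drugs=("IBU",), polymers=("PK30",),
                true_boundary={("IBU", "PK30"): 0.9},
                method_bias={"QC": 0.2},
            )
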