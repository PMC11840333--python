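"""Synthetic-cohort generator: planted structure, determinism, raw-signal truth."""

import numpy as np
import pandas as pd
import pytest

from synlink.cohort import (
    BehaviourSpec,
    CohortSpec,
    LatentComponentSpec,
    default_aif,
    default_kinetic_ranges,
    generate_behaviour_outcomes,
    generate_paired_matrices,
    generate_subject_tacs,
    generate_trial_records,
    load_cohort_bundle,
    write_cohort_bundle,
)
from synlink.fmri import behavioural_stats, switching_design, nback_design
from synlink.kinetics import fit_1tc
from synlink.pls import pls_canonical_fit


class TestSpecValidation:
    def test_component_count_exceeding_rank_budget_rejected(self):
        comps = tuple(LatentComponentSpec(0.1) for _ in range(6))
        with pytest.raises(ValueError, match="rank budget"):
            CohortSpec(components=comps)

    def test_components_sorted_by_norm_product(self):
        spec = CohortSpec(
            components=(
                LatentComponentSpec(0.63, pet_norm=1, fmri_norm=1),
                LatentComponentSpec(0.28, pet_norm=2, fmri_norm=2),
            )
        )
        assert spec.components[0].norm_product == 4.0
        assert spec.components[0].latent_correlation == 0.28

    @pytest.mark.parametrize("bad", [dict(latent_correlation=1.5),
                                     dict(latent_correlation=0.3, pet_norm=0.0)])
    def test_invalid_component_specs(self, bad):
        with pytest.raises(ValueError):
            LatentComponentSpec(**bad)

    def test_invalid_behaviour_r2(self):
        with pytest.raises(ValueError):
            BehaviourSpec(target_r_squared=1.0)

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_subjects=3)


class TestPairedMatrices:
    def test_identical_seed_bit_identical_output(self):
        spec = CohortSpec(seed=123)
        Xa, Ya, _ = generate_paired_matrices(spec)
        Xb, Yb, _ = generate_paired_matrices(CohortSpec(seed=123))
        assert Xa.to_csv() == Xb.to_csv()
        assert Ya.to_csv() == Yb.to_csv()

    def test_null_components_give_near_zero_latent_correlation(self):
        spec = CohortSpec(n_subjects=5000, seed=9,
                          components=(LatentComponentSpec(0.0),))
        _, _, truth = generate_paired_matrices(spec)
        r = np.corrcoef(truth.pet_scores[:, 0], truth.fmri_scores[:, 0])[0, 1]
        assert abs(r) < 0.05

    def test_noiseless_unit_correlation_component(self):
        spec = CohortSpec(n_subjects=200, seed=4, feature_noise_sd=0.0,
                          components=(LatentComponentSpec(1.0),))
        X, Y, _ = generate_paired_matrices(spec)
        ca = pls_canonical_fit(X, Y, 1)
        assert ca.correlations[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_component_recovery_tracks_stored_scores(self):
        spec = CohortSpec(
            n_subjects=5000,
            components=(LatentComponentSpec(0.28, pet_norm=2, fmri_norm=2),
                        LatentComponentSpec(0.63, pet_norm=1, fmri_norm=1)),
            feature_noise_sd=0.01,
            seed=2024,
        )
        X, Y, truth = generate_paired_matrices(spec)
        ca = pls_canonical_fit(X, Y, 2)
        oracle = np.corrcoef(truth.pet_scores[:, 1], truth.fmri_scores[:, 1])[0, 1]
        assert abs(oracle - 0.63) < 0.02  # generator-level consistency
        assert abs(ca.correlations[1] - 0.63) < 0.02  # fit-level recovery

    def test_explicit_loading_vectors_respected(self):
        p = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        spec = CohortSpec(
            n_subjects=100, feature_noise_sd=0.0,
            components=(LatentComponentSpec(0.5, pet_loadings=p),), seed=1,
        )
        X, _, truth = generate_paired_matrices(spec)
        assert np.allclose(X.iloc[:, 1:], 0.0)
        assert np.allclose(X.iloc[:, 0], truth.pet_scores[:, 0])


class TestTACGeneration:
    def test_noiseless_fit_recovers_stored_kinetics(self):
        spec = CohortSpec(n_subjects=4, seed=6)
        aif = default_aif()
        tacs, truth = generate_subject_tacs(spec, aif=aif, frame_noise_scale=0.0)
        subj = spec.subject_ids[0]
        for roi in ("centrum_semiovale", "dlpfc"):
            row = truth[(truth.subject == subj) & (truth.roi == roi)].iloc[0]
            fit = fit_1tc(tacs[subj][roi], aif)
            assert abs(fit.k1 - row.k1) / row.k1 < 1e-4
            assert abs(fit.k2 - row.k2) / row.k2 < 1e-4

    def test_planted_dvr_ratio_recovered(self):
        spec = CohortSpec(n_subjects=4, seed=8)
        aif = default_aif()
        targets = pd.DataFrame(
            3.0, index=spec.subject_ids, columns=list(spec.roi_labels)
        )
        tacs, truth = generate_subject_tacs(
            spec, aif=aif, frame_noise_scale=0.0, dvr_targets=targets
        )
        subj = spec.subject_ids[0]
        vt_cs = fit_1tc(tacs[subj]["centrum_semiovale"], aif).vt
        vt_roi = fit_1tc(tacs[subj]["dlpfc"], aif).vt
        assert vt_roi / vt_cs == pytest.approx(3.0, rel=1e-3)

    def test_mean_fitted_vt_within_5pct_under_frame_noise(self):
        spec = CohortSpec(n_subjects=100, seed=10)
        aif = default_aif()
        ranges = {
            "centrum_semiovale": {"k1": (0.15, 0.15), "k2": (0.03, 0.03)},
            "dlpfc": {"k1": (0.3, 0.3), "k2": (0.02, 0.02)},
        }
        tacs, truth = generate_subject_tacs(
            spec, kinetic_ranges=ranges, aif=aif, frame_noise_scale=0.05
        )
        fits = [fit_1tc(tacs[s]["dlpfc"], aif).vt for s in spec.subject_ids]
        assert abs(np.mean(fits) - 15.0) / 15.0 < 0.05

    def test_nonpositive_k2_range_rejected(self):
        spec = CohortSpec(n_subjects=4)
        with pytest.raises(ValueError, match="k2"):
            generate_subject_tacs(
                spec,
                kinetic_ranges={"centrum_semiovale": {"k1": (0.1, 0.2), "k2": (0.0, 0.1)}},
            )

    def test_centrum_semiovale_sits_at_low_vt_end(self):
        ranges = default_kinetic_ranges()
        cs = ranges["centrum_semiovale"]
        grey = ranges["dlpfc"]
        assert cs["k1"][1] / cs["k2"][0] < grey["k1"][0] / grey["k2"][1]


class TestTrialRecords:
    def test_decoupled_outcome_uncorrelated_with_latent(self):
        design = switching_design(seed=0)
        beh = BehaviourSpec(scale=0.0, target_r_squared=0.0, residual_sd=0.05)
        rng = np.random.default_rng(3)
        latents = rng.standard_normal(300)
        costs = []
        for i, lat in enumerate(latents):
            rec = generate_trial_records(design, lat, beh, seed=1000 + i)
            costs.append(behavioural_stats(rec, "switching")["switch_cost_s"])
        r = np.corrcoef(latents, costs)[0, 1]
        assert abs(r) < 0.15

    def test_identical_rts_give_zero_cost_for_every_subject(self):
        design = switching_design(seed=0)
        rec = design.events.copy()
        rec["response_time_s"] = 0.7
        rec["correct"] = True
        assert behavioural_stats(rec, "switching")["switch_cost_s"] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_realised_cohort_r2_tracks_target(self):
        design = switching_design(seed=0)
        beh = BehaviourSpec(target_r_squared=0.45)
        rng = np.random.default_rng(12)
        latents = rng.standard_normal(2000)
        costs = np.empty(2000)
        for i, lat in enumerate(latents):
            rec = generate_trial_records(design, lat, beh, seed=50_000 + i)
            costs[i] = behavioural_stats(rec, "switching")["switch_cost_s"]
        r2 = np.corrcoef(latents, costs)[0, 1] ** 2
        assert abs(r2 - 0.45) < 0.05

    def test_nback_accuracy_coupling_direction(self):
        design = nback_design(seed=0)
        beh = BehaviourSpec.nback_default()
        lo = generate_trial_records(design, -3.0, beh, seed=1)
        hi = generate_trial_records(design, 3.0, beh, seed=1)
        acc_lo = behavioural_stats(lo, "nback")["mean_12back_accuracy"]
        acc_hi = behavioural_stats(hi, "nback")["mean_12back_accuracy"]
        assert acc_hi > acc_lo

    def test_invalid_target_r2_rejected(self):
        with pytest.raises(ValueError):
            BehaviourSpec(target_r_squared=1.0)
        with pytest.raises(ValueError):
            BehaviourSpec(target_r_squared=-0.1)


class TestBehaviourOutcomes:
    def test_seeded_outcomes_reproducible(self):
        spec = CohortSpec(seed=5)
        _, _, truth = generate_paired_matrices(spec)
        a = generate_behaviour_outcomes(truth, spec.behaviour, seed=77)
        b = generate_behaviour_outcomes(truth, spec.behaviour, seed=77)
        assert a.equals(b)

    def test_population_r2_matches_target_at_large_n(self):
        spec = CohortSpec(n_subjects=20000, seed=31,
                          behaviour=BehaviourSpec(target_r_squared=0.45))
        _, _, truth = generate_paired_matrices(spec)
        y = generate_behaviour_outcomes(truth, spec.behaviour, seed=3)
        r2 = np.corrcoef(truth.pet_scores[:, 0], y)[0, 1] ** 2
        assert abs(r2 - 0.45) < 0.02


def test_bundle_roundtrip(tmp_path):
    spec = CohortSpec(n_subjects=5, seed=2)
    X, Y, truth = generate_paired_matrices(spec)
    y = generate_behaviour_outcomes(truth, spec.behaviour, subject_ids=list(X.index))
    aif = default_aif()
    tacs, _ = generate_subject_tacs(spec, aif=aif, frame_noise_scale=0.0)
    design = switching_design(seed=0)
    events = {
        s: generate_trial_records(design, 0.0, spec.behaviour, seed=i)
        for i, s in enumerate(X.index)
    }
    out = write_cohort_bundle(tmp_path / "cohort", X, Y, y, truth,
                              tacs=tacs, events=events, aif=aif)
    loaded = load_cohort_bundle(out)
    assert np.allclose(loaded["pet"].to_numpy(), X.to_numpy())
    assert np.allclose(loaded["truth"].pet_scores, truth.pet_scores)
    ev = pd.read_csv(out / "events" / "sub-001_events.tsv", sep="\t")
    assert {"onset", "duration", "trial_type", "response_time", "correct"} <= set(ev.columns)
    assert (out / "tacs" / "sub-001_tacs.tsv").exists()
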