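"""Generator contracts: cohort structure, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest

from twinplacebo import synth


class TestGenerateCohort:
    def test_study_scale_composition(self):
        cohort = synth.generate_cohort(synth.CohortSpec(142, 160, 93, seed=0))
        assert len(cohort) == 395
        by_z = cohort.drop_duplicates("family_id").groupby("zygosity").size()
        assert by_z["MZ"] == 71
        assert by_z["DZ"] == 80
        assert by_z["singleton"] == 93
        sizes = cohort.groupby(["zygosity", "family_id"]).size()
        assert (sizes.loc[["MZ", "DZ"]] == 2).all()
        assert (sizes.loc["singleton"] == 1).all()

    def test_empty_cohort(self):
        assert synth.generate_cohort(synth.CohortSpec(0, 0, 0)).empty

    def test_small_enumerated_cohort(self):
        cohort = synth.generate_cohort(synth.CohortSpec(4, 2, 1))
        assert len(cohort) == 7
        assert cohort["family_id"].nunique() == 4
        assert sorted(cohort.groupby("family_id").size()) == [1, 2, 2, 2]

    @pytest.mark.parametrize("counts", [(3, 2, 1), (2, 5, 0)])
    def test_odd_twin_counts_rejected(self, counts):
        with pytest.raises(ValueError, match="pairs"):
            synth.CohortSpec(*counts)

    def test_ids_deterministic(self):
        a = synth.generate_cohort(synth.CohortSpec(6, 4, 2, seed=3))
        b = synth.generate_cohort(synth.CohortSpec(6, 4, 2, seed=3))
        pd.testing.assert_frame_equal(a, b)


class TestTrialTable:
    def test_run_and_cell_structure(self, trial_table):
        per_participant = trial_table.groupby("participant_id")
        assert (per_participant.size() == 32).all()
        # runs 1 and 4 are control, 2 and 3 placebo
        cond_by_run = trial_table.groupby("run")["condition"].unique()
        assert list(cond_by_run[1]) == ["control"]
        assert list(cond_by_run[4]) == ["control"]
        assert list(cond_by_run[2]) == ["placebo"]
        assert list(cond_by_run[3]) == ["placebo"]
        # 4 thermal + 4 mechanical per run
        mix = trial_table.groupby(["participant_id", "run"])["modality"].value_counts()
        assert (mix == 4).all()
        assert trial_table["intensity_rating"].between(0, 1).all()
        assert trial_table["unpleasantness_rating"].between(0, 1).all()

    def test_noise_free_equals_linear_predictor(self, small_cohort):
        vc = synth.VarianceComponents(
            family_cov=np.zeros((3, 3)),
            sd_individual_mz=(0, 0, 0),
            sd_individual_dz=(0, 0, 0),
            sd_residual=0.0,
        )
        effects = synth.EffectSpec()
        table, _ = synth.simulate_trial_table(
            small_cohort, effects, vc, seed=1, rt_violation_fraction=0.0
        )
        lc = table["stimulus_level"].map(synth.LEVEL_CODES)
        cc = table["condition"].map(synth.CONDITION_CODES)
        for modality in ("thermal", "mechanical"):
            b = effects.betas(modality)
            sel = table["modality"] == modality
            eta = b[0] + b[1] * lc[sel] + b[2] * cc[sel] + b[3] * lc[sel] * cc[sel]
            assert np.allclose(table.loc[sel, "intensity_latent"], eta, atol=1e-12)

    def test_same_seed_bit_identical(self, small_cohort):
        a, _ = synth.simulate_trial_table(small_cohort, seed=11)
        b, _ = synth.simulate_trial_table(small_cohort, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_mz_pairs_correlate_more_than_dz(self):
        cohort = synth.generate_cohort(synth.CohortSpec(1200, 1200, 0, seed=5))
        table, _ = synth.simulate_trial_table(cohort, seed=5, rt_violation_fraction=0.0)
        means = table.groupby(["family_id", "zygosity", "participant_id"])[
            "intensity_latent"
        ].mean().reset_index()

        def pair_corr(z):
            sub = means[means["zygosity"] == z]
            wide = sub.groupby("family_id")["intensity_latent"].agg(list)
            arr = np.array([v for v in wide if len(v) == 2])
            return np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]

        assert pair_corr("MZ") > pair_corr("DZ")

    def test_planted_placebo_effect_recovered_in_cell_means(self):
        cohort = synth.generate_cohort(synth.CohortSpec(400, 400, 0, seed=9))
        table, _ = synth.simulate_trial_table(cohort, seed=9, rt_violation_fraction=0.0)
        th = table[table["modality"] == "thermal"]
        diff = (
            th[th["condition"] == "placebo"]["intensity_latent"].mean()
            - th[th["condition"] == "control"]["intensity_latent"].mean()
        )
        # planted thermal placebo effect on the z scale
        assert diff == pytest.approx(-0.359, abs=0.03)

    def test_unpleasantness_tracks_intensity_within_participant(self, clean_trials):
        rs = clean_trials.groupby("participant_id").apply(
            lambda g: np.corrcoef(g["intensity_latent"], g["unpleasantness_latent"])[0, 1],
            include_groups=False,
        )
        assert 0.80 < rs.median() < 0.97

    def test_clipping_fraction_logged(self, small_cohort):
        _, log = synth.simulate_trial_table(small_cohort, seed=7)
        assert 0.0 <= log.clipped_fraction_intensity < 0.1

    def test_non_psd_family_cov_rejected(self, small_cohort):
        bad = np.array([[1.0, 2.0, 0.0], [2.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="semidefinite"):
            synth.VarianceComponents(family_cov=bad)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            synth.simulate_trial_table(pd.DataFrame(columns=["participant_id"]))

    def test_family_correlation_decreases_with_individual_sd(self):
        cohort = synth.generate_cohort(synth.CohortSpec(0, 800, 0, seed=2))
        corrs = []
        for sd_ind in (0.1, 0.6, 1.5):
            vc = synth.VarianceComponents(sd_individual_dz=(sd_ind, 0.1, 0.1))
            table, _ = synth.simulate_trial_table(
                cohort, vc=vc, seed=2, rt_violation_fraction=0.0
            )
            means = table.groupby(["family_id", "participant_id"])["intensity_latent"].mean()
            wide = means.groupby("family_id").agg(list)
            arr = np.array([v for v in wide if len(v) == 2])
            corrs.append(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
        assert corrs[0] > corrs[1] > corrs[2]


class TestSignatureAndMaps:
    def test_subregion_construction(self, signature):
        labels = signature.labels()
        assert len(labels) == 8
        signs = [signature.subregion_signs[l] for l in labels]
        assert signs.count(1) == 2 and signs.count(-1) == 6
        for label in labels:
            w = signature.weights[signature.subregions == label]
            assert np.abs(w).sum() > 0
            assert np.all(np.sign(w) == signature.subregion_signs[label])

    def test_signature_deterministic(self):
        a = synth.make_synthetic_signature((16, 16, 16), 2, 6, seed=4)
        b = synth.make_synthetic_signature((16, 16, 16), 2, 6, seed=4)
        assert np.array_equal(a.weights, b.weights)
        assert np.array_equal(a.subregions, b.subregions)

    def test_too_many_subregions_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            synth.make_synthetic_signature((8, 8, 8), 5, 5, seed=0)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            synth.make_synthetic_signature((4, 16, 16), 1, 1, seed=0)

    def test_noise_free_planting_is_exact(self, signature):
        from twinplacebo.scoring import signature_score

        cells = pd.DataFrame(
            {
                "participant_id": ["P1", "P2"],
                "modality": ["thermal", "thermal"],
                "condition": ["control", "placebo"],
                "stimulus_level": ["high", "high"],
                "score": [2.5, 0.0],
            }
        )
        maps = synth.simulate_contrast_maps(cells, signature, noise_sd=0.0, seed=0)
        s1 = signature_score(maps[("P1", "thermal", "control", "high")], signature)
        s0 = signature_score(maps[("P2", "thermal", "placebo", "high")], signature)
        assert s1 == pytest.approx(2.5, abs=1e-6)
        assert s0 == pytest.approx(0.0, abs=1e-9)

    def test_noisy_planting_unbiased(self, signature):
        from twinplacebo.scoring import signature_score

        cells = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(300)],
                "modality": "thermal",
                "condition": "control",
                "stimulus_level": "high",
                "score": 1.7,
            }
        )
        maps = synth.simulate_contrast_maps(cells, signature, noise_sd=0.05, seed=3)
        scores = [signature_score(v, signature) for v in maps.values()]
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(np.mean(scores) - 1.7) < 3 * se
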