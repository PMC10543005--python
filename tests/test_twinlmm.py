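"""Twin mixed model: encoding, REML oracles, Satterthwaite df, protocols."""

import numpy as np
import pandas as pd
import pytest

from twinplacebo import synth, twinlmm

from oracles import oneway_anova_components, welch_df


def _twin_frame(rng, n_fam=40, zygosity="MZ", sd_fam=0.5, sd_ind=0.4, sd_res=0.8,
                beta=(0.2, 0.4, -0.3)):
    rows = []
    for f in range(n_fam):
        bf = rng.normal(0, sd_fam)
        for p in range(2):
            bp = rng.normal(0, sd_ind)
            for lev, lc in (("low", -0.5), ("medium", 0.0), ("high", 0.5)):
                for cond, cc in (("control", -0.5), ("placebo", 0.5)):
                    for _ in range(2):
                        rows.append(
                            dict(
                                participant_id=f"F{f}P{p}", family_id=f"F{f}",
                                zygosity=zygosity, stimulus_level=lev, condition=cond,
                                y=beta[0] + beta[1] * lc + beta[2] * cc + bf + bp
                                + rng.normal(0, sd_res),
                            )
                        )
    return pd.DataFrame(rows)


class TestEncodeDesign:
    def test_mz_rows_zero_dz_suffixed_columns(self, clean_trials):
        enc = twinlmm.encode_design(
            clean_trials[clean_trials.modality == "thermal"],
            twinlmm.ModelSpec(outcome="intensity_latent"),
        )
        Z, names = enc.dense_random_matrix()
        mz_rows = enc.zygosity == "MZ"
        dz_cols = [i for i, n in enumerate(names) if "dizygotic" in n]
        mz_cols = [i for i, n in enumerate(names) if "monozygotic" in n]
        assert np.all(Z[np.ix_(mz_rows, dz_cols)] == 0)
        assert np.all(Z[np.ix_(enc.zygosity == "DZ", mz_cols)] == 0)
        # singletons carry no individual columns at all
        single_rows = enc.zygosity == "singleton"
        assert np.all(Z[np.ix_(single_rows, mz_cols + dz_cols)] == 0)

    def test_centred_codes_balance(self, clean_trials):
        enc = twinlmm.encode_design(
            clean_trials, twinlmm.ModelSpec(outcome="intensity_latent")
        )
        level = enc.X[:, enc.fixed_names.index("stimulus_level")]
        cond = enc.X[:, enc.fixed_names.index("placebo_condition")]
        assert abs(cond.mean()) < 1e-12          # 16 control vs 16 placebo
        assert abs(level.mean()) < 0.02          # 3+3+2 rotation is near-balanced

    def test_interaction_code_is_product(self, clean_trials):
        enc = twinlmm.encode_design(
            clean_trials,
            twinlmm.ModelSpec(outcome="intensity_latent", include_interaction=True),
        )
        i = enc.fixed_names.index("stimulus_level:placebo_condition")
        row = (clean_trials.stimulus_level == "high") & (clean_trials.condition == "placebo")
        assert np.allclose(enc.X[row.to_numpy(), i], 0.25)

    def test_unknown_zygosity_rejected(self, clean_trials):
        bad = clean_trials.copy()
        bad.loc[bad.index[:5], "zygosity"] = "unknown"
        with pytest.raises(ValueError, match="zygosity"):
            twinlmm.encode_design(bad, twinlmm.ModelSpec(outcome="intensity_latent"))


class TestRemlOracles:
    def test_zero_variance_limit_matches_ols(self, rng):
        df = _twin_frame(rng, n_fam=60, sd_fam=0.0, sd_ind=0.0, sd_res=0.9)
        fit = twinlmm.fit_reml(
            twinlmm.encode_design(df, twinlmm.ModelSpec(outcome="y")), seed=0
        )
        enc = twinlmm.encode_design(df, twinlmm.ModelSpec(outcome="y"))
        ols = np.linalg.lstsq(enc.X, enc.y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=0.02)
        assert fit.sigma2 == pytest.approx(0.81, rel=0.1)
        assert fit.boundary  # random SDs at (numerically) zero are flagged

    def test_balanced_oneway_equals_anova_closed_form(self, rng):
        m, n_per = 30, 8
        rows = []
        for g in range(m):
            b = rng.normal(0, 0.7)
            rows += [
                dict(participant_id=f"P{g}", family_id=f"F{g}", zygosity="singleton",
                     y=1.5 + b + rng.normal(0, 1.1))
                for _ in range(n_per)
            ]
        df = pd.DataFrame(rows)
        fit = twinlmm.fit_reml(
            twinlmm.encode_design(
                df, twinlmm.ModelSpec(outcome="y", fixed=(), random=("intercept",))
            ),
            seed=0,
        )
        sb2, sw2 = oneway_anova_components(df["y"].to_numpy(), df["family_id"].to_numpy())
        assert fit.variance_components["family_cov"][0, 0] == pytest.approx(sb2, abs=1e-6)
        assert fit.sigma2 == pytest.approx(sw2, abs=1e-6)

    def test_single_zygosity_matches_statsmodels(self, rng):
        import statsmodels.formula.api as smf

        df = _twin_frame(rng, n_fam=40)
        fit = twinlmm.fit_reml(
            twinlmm.encode_design(
                df, twinlmm.ModelSpec(outcome="y", random=("intercept",))
            ),
            seed=0,
        )
        df = df.assign(
            lc=df.stimulus_level.map(synth.LEVEL_CODES),
            cc=df.condition.map(synth.CONDITION_CODES),
        )
        sm_fit = smf.mixedlm(
            "y ~ lc + cc", df, groups="family_id", re_formula="1",
            vc_formula={"pid": "0 + C(participant_id)"},
        ).fit(reml=True)
        ours = dict(zip(fit.fixed_names, fit.beta))
        se = np.sqrt(np.diag(fit.cov_beta))
        assert ours["intercept"] == pytest.approx(sm_fit.params["Intercept"], abs=1e-4)
        assert ours["stimulus_level"] == pytest.approx(sm_fit.params["lc"], abs=1e-4)
        assert ours["placebo_condition"] == pytest.approx(sm_fit.params["cc"], abs=1e-4)
        assert np.allclose(se, sm_fit.bse[:3], atol=1e-4)

    def test_loglik_invariant_to_family_relabeling_and_shift(self, rng):
        df = _twin_frame(rng, n_fam=25)
        spec = twinlmm.ModelSpec(outcome="y")
        base = twinlmm.fit_reml(twinlmm.encode_design(df, spec), seed=0)

        relabeled = df.copy()
        mapping = {f"F{i}": f"G{99 - i}" for i in range(25)}
        relabeled["family_id"] = relabeled["family_id"].map(mapping)
        relabeled["participant_id"] = relabeled["participant_id"].map(
            lambda s: mapping[s[:-2]] + s[-2:]
        )
        fit_r = twinlmm.fit_reml(twinlmm.encode_design(relabeled, spec), seed=0)
        assert fit_r.reml_loglik == pytest.approx(base.reml_loglik, abs=1e-5)

        shifted = df.assign(y=df.y + 7.5)
        fit_s = twinlmm.fit_reml(twinlmm.encode_design(shifted, spec), seed=0)
        assert fit_s.reml_loglik == pytest.approx(base.reml_loglik, abs=1e-5)
        assert fit_s.coef("intercept") == pytest.approx(base.coef("intercept") + 7.5, abs=1e-5)
        assert fit_s.coef("placebo_condition") == pytest.approx(
            base.coef("placebo_condition"), abs=1e-5
        )

    def test_too_few_families_rejected(self, rng):
        df = _twin_frame(rng, n_fam=1)
        with pytest.raises(ValueError, match="families"):
            twinlmm.fit_reml(twinlmm.encode_design(df, twinlmm.ModelSpec(outcome="y")))


class TestSatterthwaite:
    def test_iid_intercept_only_df_is_n_minus_1(self, rng):
        n = 25
        df = pd.DataFrame(
            dict(
                participant_id=[f"p{i}" for i in range(n)],
                family_id=[f"f{i}" for i in range(n)],
                zygosity="singleton",
                y=rng.normal(2, 1, n),
            )
        )
        spec = twinlmm.ModelSpec(
            outcome="y", fixed=(), random=("intercept",),
            include_family_block=False, include_individual_blocks=False,
        )
        est = twinlmm.test_fixed_effect(
            twinlmm.fit_reml(twinlmm.encode_design(df, spec), seed=0), "intercept"
        )
        assert est.df == pytest.approx(n - 1, abs=1e-6)

    def test_two_group_heteroskedastic_df_matches_welch(self, rng):
        y_a = rng.normal(0.0, 1.0, 12)
        y_b = rng.normal(0.5, 2.5, 20)
        df = pd.DataFrame(
            dict(
                participant_id=[f"a{i}" for i in range(12)] + [f"b{i}" for i in range(20)],
                family_id=[f"fa{i}" for i in range(12)] + [f"fb{i}" for i in range(20)],
                zygosity="singleton",
                grp=["A"] * 12 + ["B"] * 20,
                gb=[0.0] * 12 + [1.0] * 20,
                y=np.concatenate([y_a, y_b]),
            )
        )
        spec = twinlmm.ModelSpec(
            outcome="y", fixed=("gb",), random=("intercept",),
            include_family_block=False, residual_group_col="grp",
        )
        est = twinlmm.test_fixed_effect(
            twinlmm.fit_reml(twinlmm.encode_design(df, spec), seed=0), "gb"
        )
        assert est.df == pytest.approx(welch_df(y_a, y_b), abs=1e-4)

    def test_df_invariant_to_contrast_scaling(self, rng):
        df = _twin_frame(rng, n_fam=20)
        fit = twinlmm.fit_reml(
            twinlmm.encode_design(df, twinlmm.ModelSpec(outcome="y")), seed=0
        )
        c = np.array([0.0, 0.0, 1.0])
        d1 = twinlmm.satterthwaite_df(fit, c)
        d2 = twinlmm.satterthwaite_df(fit, 17.0 * c)
        assert d1 == pytest.approx(d2, rel=1e-8)

    def test_estimate_invariants(self, rng):
        from scipy import stats

        df = _twin_frame(rng, n_fam=25)
        fit = twinlmm.fit_reml(
            twinlmm.encode_design(df, twinlmm.ModelSpec(outcome="y")), seed=0
        )
        est = twinlmm.test_fixed_effect(fit, "placebo_condition")
        assert est.t == pytest.approx(est.beta / est.se)
        tcrit = stats.t.ppf(0.975, est.df)
        assert est.ci95[0] == pytest.approx(est.beta - tcrit * est.se)
        assert est.ci95[1] == pytest.approx(est.beta + tcrit * est.se)
        assert 0 < est.p <= 1
        with pytest.raises(KeyError):
            twinlmm.test_fixed_effect(fit, "nonexistent")


class TestInteractionProtocol:
    def test_null_interaction_reports_reduced_model(self, rng):
        df = _twin_frame(rng, n_fam=40)
        rep = twinlmm.interaction_protocol(df, "y", seed=0)
        assert rep.reduced is not None
        assert rep.source["placebo_condition"] == "reduced"
        assert rep.source["stimulus_level:placebo_condition"] == "full"
        assert rep.reported is rep.reduced

    def test_strong_interaction_keeps_full_model(self, rng):
        df = _twin_frame(rng, n_fam=40)
        lc = df.stimulus_level.map(synth.LEVEL_CODES)
        cc = df.condition.map(synth.CONDITION_CODES)
        df = df.assign(y=df.y + 3.0 * lc * cc)
        rep = twinlmm.interaction_protocol(df, "y", seed=0)
        assert rep.reduced is None
        assert rep.interaction.p < 0.05
        assert all(src == "full" for src in rep.source.values())


class TestEffectSizeAndPower:
    def test_two_point_example(self):
        out = twinlmm.cohens_d(np.array([0.0, 2.0]))
        assert out.d == pytest.approx(1 / np.sqrt(2), abs=1e-3)
        assert out.n == 2

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            twinlmm.cohens_d(np.ones(10))

    def test_planted_effect_size_recovered_at_study_scale(self, rng):
        scores = 1.11 + rng.standard_normal(392)
        out = twinlmm.cohens_d(scores)
        assert out.d == pytest.approx(1.11, abs=3 / np.sqrt(392))

    def test_power_monotone_in_effect_size(self):
        powers = [twinlmm.one_sample_t_power(d, 392) for d in (0.05, 0.15, 0.3)]
        assert powers[0] < powers[1] < powers[2]
        assert twinlmm.one_sample_t_power(0.0, 392) == pytest.approx(0.05, abs=1e-10)
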