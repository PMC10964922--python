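import math

import numpy as np
import pandas as pd
import pytest

import phonohpp as p
from lmm_oracle import brute_force_ml_loglik
from phonohpp.analysis import CONFIRMATORY_TERMS, _nested_design
from phonohpp.errors import AnalysisError


class TestPreprocess:
    def test_drops_warmups_and_logs(self, simulated, analysis_table):
        t = analysis_table
        n_test = (simulated.trial_type == "test").sum()
        assert t.n_obs == n_test
        merged = simulated[simulated.trial_type == "test"].reset_index(drop=True)
        assert np.allclose(t.data["log_lt"], np.log(merged["looking_time"]))
        assert set(t.data["phon_code"].unique()) == {-1.0, 1.0}

    def test_natural_log_convention(self):
        df = pd.DataFrame(
            {
                "participant": ["a"] * 14,
                "language": ["French"] * 14,
                "block": [1] * 14,
                "trial_index": range(1, 15),
                "trial_type": ["warmup"] * 2 + ["test"] * 12,
                "pronunciation": [None] * 2 + ["French"] * 12,
                "phonotactics": [None] * 2 + ["s-initial", "ʃ-initial"] * 6,
                "looking_time": [5.0] * 2 + [math.e**2] * 12,
            }
        )
        t = p.preprocess(df)
        assert np.allclose(t.data["log_lt"], 2.0)

    def test_partial_second_block_retained(self, versions):
        df = p.simulate_dataset(
            p.SimParams(n_per_group=6, dropout=p.DropoutModel(hazard=0.0), seed=0),
            versions=versions,
        )
        # participant F001: keep 20 of 28 trials → 16 test rows survive
        cut = df[~((df.participant == "F001") & (df.trial_index > 20))]
        t = p.preprocess(cut)
        assert (t.data.participant == "F001").sum() == 16
        assert t.n_excluded_participants == 0

    def test_incomplete_first_block_excluded(self, versions):
        df = p.simulate_dataset(
            p.SimParams(n_per_group=6, dropout=p.DropoutModel(hazard=0.0), seed=0),
            versions=versions,
        )
        cut = df[~((df.participant == "F001") & (df.trial_index > 13))]
        t = p.preprocess(cut)
        assert "F001" not in set(t.data.participant)
        assert t.n_excluded_participants == 1

    def test_nonpositive_lt_named(self, simulated):
        df = simulated.copy()
        df.loc[df.index[5], "looking_time"] = 0.0
        with pytest.raises(AnalysisError, match=str(df.loc[df.index[5], "participant"])):
            p.preprocess(df)

    def test_all_excluded_raises(self, simulated):
        df = simulated[simulated.trial_index <= 5]
        with pytest.raises(AnalysisError):
            p.preprocess(df)


class TestConfirmatoryFit:
    def test_twelve_reported_terms(self, analysis_table):
        fit = p.fit_confirmatory(analysis_table)
        assert tuple(fit.coefficients) == CONFIRMATORY_TERMS
        assert len(fit.coefficients) == 12
        for c in fit.coefficients.values():
            assert c.ci_low <= c.estimate <= c.ci_high
        assert fit.method == "REML"
        assert fit.n_participants == 48
        assert {"intercept_var", "pronunciation_slope_var", "residual_var"} <= set(fit.random)

    def test_bic_convention(self, analysis_table):
        fit = p.fit_confirmatory(analysis_table, method="ML")
        k = 12 + 3 + 1
        assert fit.bic == pytest.approx(-2 * fit.loglik + k * math.log(fit.n_obs))

    def test_near_zero_noise_recovers_zero_effects(self, versions):
        zero = {"French": 0.0, "German": 0.0}
        fx = p.FixedEffects(
            language=0.0,
            phonotactics=dict(zero),
            pronunciation=dict(zero),
            block=dict(zero),
            phonotactics_x_pronunciation=dict(zero),
            phonotactics_x_block=dict(zero),
        )
        re = p.RandomEffects(intercept_sd=0.0, pronunciation_slope_sd=0.0, residual_sd=1e-6)
        df = p.simulate_dataset(
            p.SimParams(n_per_group=8, fixed=fx, random=re, dropout=p.DropoutModel(hazard=0.0), seed=5),
            versions=versions,
        )
        fit = p.fit_confirmatory(p.preprocess(df))
        for name, c in fit.coefficients.items():
            target = 1.75 if name == "(Intercept)" else 0.0
            assert c.estimate == pytest.approx(target, abs=1e-6)

    def test_row_order_invariance(self, analysis_table):
        fit_a = p.fit_confirmatory(analysis_table)
        shuffled = p.AnalysisTable(
            data=analysis_table.data.sample(frac=1.0, random_state=7),
            codebook=analysis_table.codebook,
        )
        fit_b = p.fit_confirmatory(shuffled)
        for name in fit_a.coefficients:
            assert fit_a.coefficients[name].estimate == pytest.approx(
                fit_b.coefficients[name].estimate, abs=1e-8
            )
        assert fit_a.loglik == pytest.approx(fit_b.loglik, abs=1e-6)

    def test_contrast_sign_flip_flips_estimates_only(self, simulated):
        base = p.fit_confirmatory(p.preprocess(simulated))
        flipped_cb = p.flipped(p.DEFAULT_CODEBOOK, "phonotactics")
        flip = p.fit_confirmatory(p.preprocess(simulated, codebook=flipped_cb))
        for name in base.coefficients:
            b, f = base.coefficients[name], flip.coefficients[name]
            sign = -1.0 if "Phonotactics" in name and name.count(":") == 1 else 1.0
            # pure phonotactics terms flip; phonotactics×X products flip too
            if "Phonotactics" in name and "Block" not in name and "Pronunciation" not in name:
                sign = -1.0
            elif "Phonotactics" in name:
                sign = -1.0
            assert f.estimate == pytest.approx(sign * b.estimate, abs=1e-6)
            assert f.p == pytest.approx(b.p, abs=1e-6)
        assert flip.loglik == pytest.approx(base.loglik, abs=1e-6)
        assert flip.bic == pytest.approx(base.bic, abs=1e-6)

    def test_single_language_rejected(self, analysis_table):
        only_fr = p.AnalysisTable(
            data=analysis_table.data[analysis_table.data.language == "French"],
            codebook=analysis_table.codebook,
        )
        with pytest.raises(AnalysisError):
            p.fit_confirmatory(only_fr)

    def test_loglik_matches_brute_force_marginal_likelihood(self, versions):
        """ML log-likelihood equals a direct maximization of the marginal
        Gaussian likelihood (GLS-profiled Nelder–Mead) on a small fixture."""
        df = p.simulate_dataset(
            p.SimParams(n_per_group=3, dropout=p.DropoutModel(hazard=0.0), seed=11),
            versions=versions,
        )
        df = df[df.participant != "G003"]  # 5-participant fixture
        table = p.preprocess(df)
        fit = p.fit_confirmatory(table, method="ML")
        d = table.data
        X = _nested_design(d).to_numpy()
        Z = np.column_stack([np.ones(len(d)), d["pron_code"].to_numpy()])
        oracle = brute_force_ml_loglik(d["log_lt"].to_numpy(), X, Z, d["participant"].to_numpy())
        assert fit.loglik == pytest.approx(oracle, abs=1e-4)


class TestBayesComparison:
    def test_reported_bf_maps_to_posterior(self):
        assert p.posterior_from_bf(22.851) == pytest.approx(0.96, abs=0.005)

    def test_even_odds(self):
        assert p.posterior_from_bf(1.0) == 0.5

    def test_closed_form_delta_two(self):
        bc = p.BayesComparison(bic_h0=100.0, bic_h1=102.0)
        assert bc.bf01 == pytest.approx(math.e)
        assert bc.posterior_h0 == pytest.approx(math.e / (1 + math.e))
        assert bc.posterior_h0 == pytest.approx(0.7311, abs=1e-4)

    def test_posterior_strictly_increasing_in_delta_bic(self):
        deltas = np.linspace(-10, 10, 41)
        posts = [p.BayesComparison(0.0, d).posterior_h0 for d in deltas]
        assert all(b > a for a, b in zip(posts, posts[1:]))
        assert p.BayesComparison(0.0, 0.0).posterior_h0 == 0.5
        assert all(0 < q < 1 for q in posts)

    def test_interaction_comparison_runs_ml(self, analysis_table):
        bc = p.fit_interaction_comparison(analysis_table)
        assert bc.bf01 > 0
        assert 0 < bc.posterior_h0 < 1
        assert bc.bf01 == pytest.approx(math.exp(bc.delta_bic / 2))


class TestPerBlock:
    def test_two_block_fits(self, analysis_table):
        fits = p.fit_per_block(analysis_table)
        assert set(fits) == {1, 2}
        for fit in fits.values():
            assert "Language[French]:Block" not in fit.coefficients
            assert "Language[French]:Phonotactics:Block" not in fit.coefficients
            assert len(fit.coefficients) == 8

    def test_single_block_table(self, analysis_table):
        t = p.AnalysisTable(
            data=analysis_table.data[analysis_table.data.block == 1],
            codebook=analysis_table.codebook,
        )
        fits = p.fit_per_block(t)
        assert set(fits) == {1}

    def test_identical_blocks_give_identical_fits(self, analysis_table):
        b1 = analysis_table.data[analysis_table.data.block == 1]
        b2 = b1.copy()
        b2["block"] = 2
        t = p.AnalysisTable(data=pd.concat([b1, b2]), codebook=analysis_table.codebook)
        fits = p.fit_per_block(t)
        for name in fits[1].coefficients:
            assert fits[1].coefficients[name].estimate == pytest.approx(
                fits[2].coefficients[name].estimate, abs=1e-10
            )

    def test_block_fit_recovers_effect_sign(self, versions):
        df = p.simulate_dataset(
            p.SimParams(n_per_group=40, dropout=p.DropoutModel(hazard=0.0), seed=21),
            versions=versions,
        )
        fits = p.fit_per_block(p.preprocess(df))
        assert fits[1].coefficients["Language[French]:Phonotactics"].estimate < 0


class TestDescriptives:
    def test_manual_toy_counts(self):
        rows = []
        # 3 French participants, 2 trials per condition each
        lts = {
            "a": {"s-initial": [8.0, 6.0], "ʃ-initial": [5.0, 5.0]},  # longer s
            "b": {"s-initial": [4.0, 4.0], "ʃ-initial": [6.0, 4.0]},  # longer ʃ
            "c": {"s-initial": [5.0, 5.0], "ʃ-initial": [5.0, 5.0]},  # tie
        }
        for pid, d in lts.items():
            for cond, vals in d.items():
                for i, lt in enumerate(vals):
                    rows.append(
                        {
                            "participant": pid,
                            "language": "French",
                            "trial_type": "test",
                            "phonotactics": cond,
                            "looking_time": lt,
                        }
                    )
        out = p.descriptives(pd.DataFrame(rows))
        s_row = out[(out.language == "French") & (out.condition == "s-initial")].iloc[0]
        # participant condition means: a=7, b=4, c=5 → mean 16/3
        assert s_row.mean_s == pytest.approx(16 / 3)
        assert s_row.n_longer_s == 1
        assert s_row.n_longer_sh == 1
        assert s_row.n_tie == 1

    def test_all_equal_lts_are_all_ties(self, versions):
        df = p.simulate_dataset(
            p.SimParams(
                n_per_group=4,
                fixed=p.FixedEffects(
                    language=0.0,
                    phonotactics={"French": 0.0, "German": 0.0},
                    pronunciation={"French": 0.0, "German": 0.0},
                    block={"French": 0.0, "German": 0.0},
                    phonotactics_x_pronunciation={"French": 0.0, "German": 0.0},
                    phonotactics_x_block={"French": 0.0, "German": 0.0},
                ),
                random=p.RandomEffects(intercept_sd=0.0, pronunciation_slope_sd=0.0, residual_sd=0.0),
                dropout=p.DropoutModel(hazard=0.0),
                seed=0,
            ),
            versions=versions,
        )
        out = p.descriptives(df)
        assert (out.n_longer_s == 0).all()
        assert (out.n_longer_sh == 0).all()
        assert (out.n_tie == 4).all()

    def test_output_schema(self, simulated):
        out = p.descriptives(simulated)
        assert list(out.columns) == [
            "language",
            "condition",
            "mean_s",
            "sd_s",
            "n_longer_s",
            "n_longer_sh",
            "n_tie",
        ]
        assert len(out) == 4

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            p.descriptives(pd.DataFrame())
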