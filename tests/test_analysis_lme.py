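"""Mixed-model contrasts: exact recovery, OLS agreement, df behaviour."""

import numpy as np
import pandas as pd
import pytest

from iaread.analysis_lme import (
    AnalysisError,
    analyze_trials,
    cell_means_2x2,
    contrasts_to_frame,
    factorial_effects,
    fit_lme_2way,
    fit_lme_3way,
    planned_contrasts_2way,
)

SQ_LEVELS = (20, 40, 60, 80, 100)


def make_balanced_data(
    n_words_per_band=20,
    sq_effect=None,
    band_effect=None,
    interaction=None,
    sigma_b=0.0,
    sigma_e=0.0,
    ia_levels=None,
    ia_interaction_boost=0.0,
    seed=0,
):
    """Balanced cell-structured latencies with known built-in effects."""
    rng = np.random.default_rng(seed)
    sq_effect = sq_effect or {s: (100 - s) * 0.05 for s in SQ_LEVELS}
    band_effect = band_effect or {"low": 4.0, "high": 0.0}
    interaction = interaction or {s: 0.0 for s in SQ_LEVELS}
    ia_levels = ia_levels or [None]
    words = [f"w{i:03d}" for i in range(2 * n_words_per_band)]
    bands = ["low"] * n_words_per_band + ["high"] * n_words_per_band
    intercepts = dict(zip(words, rng.normal(0, sigma_b, len(words))))
    rows = []
    for word, band in zip(words, bands):
        for sq in SQ_LEVELS:
            for ia in ia_levels:
                y = 50.0 + sq_effect[sq] + band_effect[band]
                if band == "low":
                    y += interaction[sq]
                    if ia == "on":
                        y += ia_interaction_boost * (100 - sq) / 80.0
                y += intercepts[word] + rng.normal(0, sigma_e)
                row = {"word": word, "band": band, "sq_percent": sq, "cycles": y}
                if ia is not None:
                    row["ia"] = ia
                rows.append(row)
    return pd.DataFrame(rows)


class TestFactorialEffects:
    def test_published_words_only_decomposition(self):
        # human naming data, words-only context
        table = factorial_effects(
            lf_high_sq=481, lf_low_sq=602, hf_high_sq=470, hf_low_sq=576
        )
        assert table.sq_effect_lf == 121
        assert table.sq_effect_hf == 106
        assert table.wf_effect_high_sq == 11
        assert table.wf_effect_low_sq == 26
        assert table.interaction == 15

    def test_published_mixed_context_decomposition(self):
        # same words intermixed with non-words: additivity
        table = factorial_effects(
            lf_high_sq=513, lf_low_sq=624, hf_high_sq=506, hf_low_sq=614
        )
        assert table.sq_effect_lf == 111
        assert table.sq_effect_hf == 108
        assert table.wf_effect_high_sq == 7
        assert table.wf_effect_low_sq == 10
        assert table.interaction == 3

    def test_flat_table_has_zero_effects(self):
        table = factorial_effects(7.0, 7.0, 7.0, 7.0)
        assert table.sq_effect_lf == table.sq_effect_hf == 0
        assert table.interaction == 0

    def test_nonfinite_cells_rejected(self):
        with pytest.raises(AnalysisError):
            factorial_effects(1.0, float("nan"), 2.0, 3.0)

    def test_interaction_identity_holds_for_trial_tables(self):
        data = make_balanced_data(interaction={s: (100 - s) * 0.01 for s in SQ_LEVELS})
        table = cell_means_2x2(data, low_sq=20)
        assert table.interaction == pytest.approx(
            (table.lf_low_sq - table.lf_high_sq) - (table.hf_low_sq - table.hf_high_sq)
        )


class TestFitTwoWay:
    def test_noiseless_cells_recovered_exactly(self):
        inter = {20: 3.0, 40: 2.0, 60: 1.0, 80: 0.5, 100: 0.0}
        data = make_balanced_data(interaction=inter)
        fit = fit_lme_2way(data)
        raw_means = data.groupby(["band", "sq_percent"])["cycles"].mean()
        for key, est in zip(fit.cells, fit.beta):
            assert est == pytest.approx(raw_means[key], abs=1e-8)
        wf, sq, ia = planned_contrasts_2way(fit, 20)
        assert wf.estimate == pytest.approx(4.0 + 1.5, abs=1e-8)
        assert sq.estimate == pytest.approx(4.0, abs=1e-8)
        assert ia.estimate == pytest.approx(3.0, abs=1e-8)

    def test_zero_variance_fit_matches_ols(self):
        import statsmodels.api as sm

        # words identical within band: random-intercept variance collapses
        data = make_balanced_data(sigma_b=0.0, sigma_e=1.0, seed=4)
        fit = fit_lme_2way(data)
        cells = fit.cells
        X = pd.get_dummies(
            data[["band", "sq_percent"]].apply(tuple, axis=1)
        ).to_numpy(dtype=float)
        keys = sorted(data[["band", "sq_percent"]].apply(tuple, axis=1).unique())
        ols = sm.OLS(data["cycles"].to_numpy(), X).fit()
        beta_by_key = dict(zip(keys, ols.params))
        for key, est in zip(cells, fit.beta):
            assert est == pytest.approx(beta_by_key[key], abs=1e-6)
        inter = planned_contrasts_2way(fit, 20)[2]
        c = np.zeros(len(keys))
        for key, w in [
            (("low", 20), 1), (("low", 100), -1), (("high", 20), -1), (("high", 100), 1),
        ]:
            c[keys.index(key)] = w
        ols_t = ols.t_test(c)
        assert inter.estimate == pytest.approx(float(ols_t.effect[0]), abs=1e-6)
        assert inter.se == pytest.approx(float(ols_t.sd[0, 0]), rel=1e-2)

    def test_constant_shift_moves_only_cell_means(self):
        data = make_balanced_data(sigma_b=2.0, sigma_e=0.5, seed=9)
        shifted = data.assign(cycles=data["cycles"] + 100.0)
        a = planned_contrasts_2way(fit_lme_2way(data), 40)
        b = planned_contrasts_2way(fit_lme_2way(shifted), 40)
        for ca, cb in zip(a, b):
            assert ca.estimate == pytest.approx(cb.estimate, abs=1e-6)
            assert ca.se == pytest.approx(cb.se, rel=1e-6)

    def test_band_relabel_flips_wf_and_interaction_signs(self):
        data = make_balanced_data(
            interaction={s: (100 - s) * 0.02 for s in SQ_LEVELS},
            sigma_b=1.0, sigma_e=0.3, seed=2,
        )
        swapped = data.assign(band=data["band"].map({"low": "high", "high": "low"}))
        orig = planned_contrasts_2way(fit_lme_2way(data), 20)
        flip = planned_contrasts_2way(fit_lme_2way(swapped), 20)
        assert flip[0].estimate == pytest.approx(-orig[0].estimate, abs=1e-6)
        assert flip[2].estimate == pytest.approx(-orig[2].estimate, abs=1e-6)

    def test_t_equals_estimate_over_se(self):
        data = make_balanced_data(sigma_b=1.5, sigma_e=0.5, seed=6)
        fit = fit_lme_2way(data)
        for lo in (20, 40, 60, 80):
            for cr in planned_contrasts_2way(fit, lo):
                assert cr.t == pytest.approx(cr.estimate / cr.se, rel=1e-10)
                assert 0.0 <= cr.p <= 1.0

    def test_satterthwaite_df_regimes(self, study_trials):
        # within-word contrasts should land on the residual df; the
        # between-word frequency contrast on a df between the word count
        # and the observation count
        d = study_trials["clean"]
        sub = d[(d.locus == "feature-letter-weights") & (d.ia == "on")]
        fit = fit_lme_2way(sub)
        wf, sq_hf, inter = planned_contrasts_2way(fit, 20)
        n_words = sub["word"].nunique()
        residual_df = len(sub) - 10 - (n_words - 2)
        assert inter.df == pytest.approx(residual_df, rel=1e-6)
        assert n_words - 2 < wf.df < len(sub)

    def test_contrasts_match_r_lmertest(self, tmp_path):
        # independent oracle: lmerTest's Satterthwaite machinery on the
        # same data, same cell-means model, same contrast vectors
        import shutil
        import subprocess

        rscript = shutil.which("Rscript")
        assert rscript, "Rscript required for the lmerTest cross-check"
        data = make_balanced_data(
            n_words_per_band=15,
            interaction={s: (100 - s) * 0.03 for s in SQ_LEVELS},
            sigma_b=3.0,
            sigma_e=1.0,
            seed=31,
        )
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            """
            suppressMessages(library(lmerTest))
            d <- read.csv(commandArgs(TRUE)[1])
            d$band <- factor(d$band); d$sq <- factor(d$sq_percent)
            m <- lmer(cycles ~ 0 + band:sq + (1|word), data=d, REML=TRUE)
            cells <- names(fixef(m))
            pick <- function(b, s) as.numeric(cells == paste0('band', b, ':sq', s))
            K_wf <- 0.5*pick('low',20) + 0.5*pick('low',100) -
                    0.5*pick('high',20) - 0.5*pick('high',100)
            K_in <- pick('low',20) - pick('low',100) - pick('high',20) + pick('high',100)
            for (K in list(K_wf, K_in)) {
              ct <- contest1D(m, K, ddf='Satterthwaite')
              cat(sprintf('%.10f %.10f %.6f %.6f\\n',
                  ct$Estimate, ct$`Std. Error`, ct$df, ct$`t value`))
            }
            """
        )
        out = subprocess.run(
            [rscript, str(script), str(csv)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        lines = [line.split() for line in out.stdout.strip().splitlines()]
        fit = fit_lme_2way(data)
        wf, _, inter = planned_contrasts_2way(fit, 20)
        for ours, ref in zip((wf, inter), lines):
            est, se, df, t = map(float, ref)
            assert ours.estimate == pytest.approx(est, rel=1e-6)
            assert ours.se == pytest.approx(se, rel=1e-4)
            assert ours.df == pytest.approx(df, rel=1e-3)
            assert ours.t == pytest.approx(t, rel=1e-4)

    def test_single_sq_level_rejected(self):
        data = make_balanced_data()
        with pytest.raises(AnalysisError):
            fit_lme_2way(data[data.sq_percent == 100])
        fit = fit_lme_2way(data)
        with pytest.raises(AnalysisError):
            planned_contrasts_2way(fit, 50)

    def test_mixed_condition_cells_rejected(self):
        data = make_balanced_data()
        data["ia"] = np.where(np.arange(len(data)) % 2 == 0, "on", "off")
        with pytest.raises(AnalysisError):
            fit_lme_2way(data)


class TestFitThreeWay:
    def test_null_by_construction_gives_tiny_threeway(self):
        data = make_balanced_data(
            ia_levels=["on", "off"], sigma_b=1.0, sigma_e=0.2, seed=3,
            interaction={s: (100 - s) * 0.02 for s in SQ_LEVELS},
        )
        _, contrasts = fit_lme_3way(data)
        for cr in contrasts:
            assert abs(cr.estimate) < 0.15
            assert abs(cr.t) < 2.5

    def test_injected_ia_dependent_interaction_recovered(self):
        delta = 2.0
        data = make_balanced_data(
            n_words_per_band=69,
            ia_levels=["on", "off"],
            ia_interaction_boost=delta,
            sigma_b=1.0,
            sigma_e=0.4,
            seed=8,
        )
        _, contrasts = fit_lme_3way(data)
        by_label = {cr.label: cr for cr in contrasts}
        cr = by_label["SQ x WF x IA (low SQ 20%)"]
        assert abs(cr.estimate - delta) < 2 * cr.se

    def test_missing_ia_level_is_an_error_not_a_silent_twoway(self):
        data = make_balanced_data(ia_levels=["on"])
        with pytest.raises(AnalysisError):
            fit_lme_3way(data)


class TestAnalyzeTrials:
    def test_outputs_cover_all_cells(self):
        frames = []
        for locus in ("feature-input", "feature-letter-weights"):
            d = make_balanced_data(
                ia_levels=["on", "off"], sigma_b=0.8, sigma_e=0.3, seed=5
            )
            frames.append(d.assign(locus=locus))
        trials = pd.concat(frames, ignore_index=True)
        out = analyze_trials(trials)
        assert len(out["contrasts_2way"]) == 2 * 2 * 4 * 3
        assert len(out["contrasts_3way"]) == 2 * 4
        assert set(out["wf_effects"]["sq_percent"]) == set(SQ_LEVELS)

    def test_wf_effect_equals_groupby_difference(self):
        d = make_balanced_data(ia_levels=["on", "off"], sigma_e=0.1, seed=12)
        trials = d.assign(locus="feature-input")
        out = analyze_trials(trials)
        means = trials.groupby(["ia", "sq_percent", "band"])["cycles"].mean().unstack()
        for _, row in out["wf_effects"].iterrows():
            expected = (
                means.loc[(row["ia"], row["sq_percent"]), "low"]
                - means.loc[(row["ia"], row["sq_percent"]), "high"]
            )
            assert row["wf_effect"] == pytest.approx(expected, abs=1e-9)

    def test_single_level_table_is_a_clear_error(self):
        d = make_balanced_data(ia_levels=["on", "off"]).assign(locus="feature-input")
        with pytest.raises(AnalysisError, match="pairing"):
            analyze_trials(d[d.sq_percent == 100])

    def test_contrast_frame_has_report_columns(self):
        data = make_balanced_data(sigma_b=0.5, sigma_e=0.2, seed=1)
        frame = contrasts_to_frame(planned_contrasts_2way(fit_lme_2way(data), 20))
        assert list(frame.columns) == ["contrast", "estimate", "se", "df", "t", "p"]
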