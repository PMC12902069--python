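"""Mixed-effects inference: REML components, Satterthwaite df, EMMs,
Tukey contrasts, variance decomposition."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from dyadsync.stats_models import (
    LMMSpec,
    descriptive_marginals,
    fit_sync_lmm,
    phase_contrasts,
    r2_mixed,
)

PHASES = ["baseline", "audio", "silence"]
CONTEXTS = ["neutral", "negative", "positive"]


def simulate_table(
    rng,
    n_dyads=24,
    phase_means=(40.0, 25.0, 31.0),
    sd_dyad=15.0,
    sd_res=10.0,
):
    """Balanced dyad x trial x phase response with known components."""
    eff = dict(zip(PHASES, phase_means))
    rows = []
    for d in range(n_dyads):
        u = rng.normal(0, sd_dyad)
        for trial, ctx in enumerate(CONTEXTS, start=1):
            for ph in PHASES:
                rows.append(
                    {
                        "dyad": f"d{d:02d}",
                        "trial": trial,
                        "context": ctx,
                        "phase": ph,
                        "sync_pct": eff[ph] + u + rng.normal(0, sd_res),
                    }
                )
    return pd.DataFrame(rows)


class TestFit:
    def test_all_equal_response_gives_zero_contrasts(self):
        rng = np.random.default_rng(0)
        table = simulate_table(rng, n_dyads=6, phase_means=(5, 5, 5), sd_dyad=0, sd_res=0)
        res = fit_sync_lmm(table)
        assert res.singular
        assert (res.anova["F"] == 0).all()
        assert (phase_contrasts(res)["estimate"] == 0).all()
        np.testing.assert_allclose(res.emm_phase["emm"], 5.0)

    def test_no_dyad_variance_flags_singular_and_matches_ols(self):
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(20):
            table = simulate_table(rng, n_dyads=10, sd_dyad=0.0, sd_res=8.0)
            res = fit_sync_lmm(table)
            if res.singular:
                hits += 1
                # with sigma2_dyad = 0 the GLS estimate equals OLS
                import patsy

                y, X = patsy.dmatrices(LMMSpec().formula, table, return_type="dataframe")
                ols = np.linalg.lstsq(np.asarray(X), np.asarray(y).ravel(), rcond=None)[0]
                np.testing.assert_allclose(res.params.to_numpy(), ols, atol=1e-6)
        assert hits >= 0.95 * 20 - 1  # singularity detected in (nearly) all replicates

    def test_balanced_satterthwaite_df_matches_classical(self):
        rng = np.random.default_rng(2)
        table = simulate_table(rng, n_dyads=24, sd_dyad=15.0, sd_res=10.0)
        res = fit_sync_lmm(table)
        phase_row = res.anova[res.anova["term"] == "phase"].iloc[0]
        # classical within-dyad error df: (24-1) x (9-1) = 184
        assert phase_row["den_df"] == pytest.approx(184.0, abs=0.5)
        assert phase_row["num_df"] == 2

    def test_fixed_effect_recovery_within_2se(self):
        rng = np.random.default_rng(3)
        ok = 0
        n_rep = 30
        for _ in range(n_rep):
            table = simulate_table(rng)
            res = fit_sync_lmm(table)
            con = phase_contrasts(res).set_index("pair")
            row = con.loc["audio - baseline"]
            if abs(row["estimate"] - (25.0 - 40.0)) <= 2 * row["se"]:
                ok += 1
        assert ok >= 0.9 * n_rep

    def test_missing_cells_dropped_listwise(self):
        rng = np.random.default_rng(4)
        table = simulate_table(rng, n_dyads=8)
        table.loc[[3, 40], "sync_pct"] = np.nan
        res = fit_sync_lmm(table)
        assert res.n_obs == len(table) - 2


class TestR2:
    def test_known_variance_components_recovered(self):
        # phase means (40,25,31) give sigma2_f = 38 exactly under balance;
        # components chosen for true R2 = (0.04, 0.48)
        total = 38.0 / 0.04
        sd_dyad = np.sqrt(0.44 * total)
        sd_res = np.sqrt(0.52 * total)
        rng = np.random.default_rng(5)
        r2m, r2c = [], []
        for _ in range(25):
            res = fit_sync_lmm(simulate_table(rng, sd_dyad=sd_dyad, sd_res=sd_res))
            r2m.append(res.r2_marginal)
            r2c.append(res.r2_conditional)
        assert np.mean(r2m) == pytest.approx(0.04, abs=0.05)
        assert np.mean(r2c) == pytest.approx(0.48, abs=0.05)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            res = fit_sync_lmm(simulate_table(rng, n_dyads=8))
            assert 0.0 <= res.r2_marginal <= res.r2_conditional <= 1.0

    def test_zero_dyad_variance_makes_r2_equal(self):
        rng = np.random.default_rng(7)
        table = simulate_table(rng, n_dyads=10, sd_dyad=0.0, sd_res=5.0)
        res = fit_sync_lmm(table)
        if res.singular:
            m, c = r2_mixed(res)
            assert m == pytest.approx(c)


class TestContrasts:
    def test_two_level_tukey_equals_unadjusted_t(self):
        from scipy import stats as st

        rng = np.random.default_rng(8)
        table = simulate_table(rng, n_dyads=10)
        table = table[table["phase"] != "silence"]
        res = fit_sync_lmm(table)
        row = phase_contrasts(res).iloc[0]
        t = row["estimate"] / row["se"]
        p_t = 2 * st.t.sf(abs(t), row["df"])
        assert row["p_tukey"] == pytest.approx(p_t, rel=1e-4)

    def test_contrast_count_and_symmetry(self):
        rng = np.random.default_rng(9)
        res = fit_sync_lmm(simulate_table(rng, n_dyads=8))
        con = phase_contrasts(res)
        assert len(con) == 3
        emm = res.emm_phase.set_index("phase")["emm"]
        for _, row in con.iterrows():
            a, b = row["pair"].split(" - ")
            assert row["estimate"] == pytest.approx(emm[a] - emm[b], rel=1e-9)


class TestDescriptives:
    def test_cell_mean_and_sd(self):
        table = pd.DataFrame(
            {
                "measure": ["n_peaks"] * 3,
                "role": ["listener"] * 3,
                "phase": ["baseline"] * 3,
                "value": [9.0, 10.0, 11.0],
            }
        )
        out = descriptive_marginals(table, "n_peaks", ["role", "phase"])
        assert out.loc[0, "mean"] == pytest.approx(10.0)
        assert out.loc[0, "sd"] == pytest.approx(1.0)
        assert out.loc[0, "n"] == 3

    def test_single_value_cell_has_missing_sd(self):
        table = pd.DataFrame(
            {"measure": ["m"], "role": ["listener"], "phase": ["audio"], "value": [4.2]}
        )
        out = descriptive_marginals(table, "m", ["role", "phase"])
        assert out.loc[0, "mean"] == 4.2
        assert np.isnan(out.loc[0, "sd"])

    def test_groupby_matches_bruteforce(self, dyad_and_truth):
        from dyadsync.cli_pipeline import process_dyads
        from dyadsync.ocular_event_metrics import build_metrics_table

        dyad, _ = dyad_and_truth
        cleaned, peaks, _ = process_dyads([dyad])
        tab = build_metrics_table([dyad], cleaned, peaks)
        out = descriptive_marginals(tab, "n_blinks", ["role", "phase"]).set_index(["role", "phase"])
        sub = tab[tab["measure"] == "n_blinks"]
        for (role, phase), grp in sub.groupby(["role", "phase"]):
            assert out.loc[(role, phase), "mean"] == pytest.approx(grp["value"].mean())


class TestAgainstLmerTest:
    """Cross-check the whole inference layer against R's lmerTest/emmeans."""

    def test_f_df_emm_tukey_and_r2_match_r(self, tmp_path):
        rng = np.random.default_rng(42)
        table = simulate_table(rng, n_dyads=12, sd_dyad=15.0, sd_res=10.0)
        table = table.drop(index=[5, 77]).reset_index(drop=True)  # mild imbalance
        csv = tmp_path / "fixture.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages({{library(lmerTest); library(emmeans)}})
                d <- read.csv("{csv}")
                m <- lmer(sync_pct ~ phase*context + (1|dyad), data=d, REML=TRUE)
                vc <- as.data.frame(VarCorr(m))
                a <- anova(m, type=3)
                s <- summary(pairs(emmeans(m, ~phase), adjust="tukey"))
                Xb <- predict(m, re.form=NA)
                s2f <- mean((Xb-mean(Xb))^2)
                tot <- s2f+vc$vcov[1]+vc$vcov[2]
                cat(a["phase","F value"], a["phase","DenDF"],
                    s$estimate[1], s$p.value[1],
                    s2f/tot, (s2f+vc$vcov[1])/tot, sep="\\n")
                """
            )
        )
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
        )
        assert proc.returncode == 0, proc.stderr
        f_r, ddf_r, est_r, p_r, r2m_r, r2c_r = map(float, proc.stdout.strip().splitlines())

        res = fit_sync_lmm(table)
        phase_row = res.anova.set_index("term").loc["phase"]
        assert phase_row["F"] == pytest.approx(f_r, rel=1e-3)
        assert phase_row["den_df"] == pytest.approx(ddf_r, abs=0.2)
        con = phase_contrasts(res).set_index("pair")
        # R's emmeans orders levels alphabetically: first pair audio - baseline
        assert con.loc["audio - baseline", "estimate"] == pytest.approx(est_r, rel=1e-6)
        assert con.loc["audio - baseline", "p_tukey"] == pytest.approx(p_r, rel=0.05, abs=1e-8)
        assert res.r2_marginal == pytest.approx(r2m_r, abs=1e-3)
        assert res.r2_conditional == pytest.approx(r2c_r, abs=1e-3)
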