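"""AOD association, concordance statistics, and pipeline orchestration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dmrscan import (
    PipelineConfig,
    aod_effect_scan,
    cross_cohort_concordance,
    run_full_pipeline,
)
from dmrscan.dataio import BetaMatrix


def _control_cohort(n=34, seed=0):
    rng = np.random.default_rng(seed)
    sheet = pd.DataFrame(
        {
            "sample_id": [f"c{i}" for i in range(n)],
            "group": "control",
            "aod": rng.integers(66, 96, n),
            "gender": rng.choice(["M", "F"], n),
            "race": rng.choice(["W", "B"], n, p=[0.8, 0.2]),
            "array": rng.choice(["chip1", "chip2", "chip3"], n),
            "np": rng.normal(0.3, 0.03, n),
        }
    )
    return sheet, rng


class TestAodScan:
    def test_planted_age_slope_detected(self):
        sheet, rng = _control_cohort()
        aod = sheet["aod"].to_numpy(float)
        hits = 0
        n_rep = 40
        for rep in range(n_rep):
            y = 0.3 + 0.002 * (aod - 80) + rng.normal(0, 0.001, len(aod))
            beta = BetaMatrix(
                pd.DataFrame(
                    y[None, :], index=["cgA"], columns=sheet["sample_id"]
                )
            )
            top = pd.DataFrame({"probe_id": ["cgA"], "direction": ["hyper"]})
            summary, table = aod_effect_scan(beta, sheet, top)
            hits += (table["p"].iloc[0] < 0.05) and (table["slope"].iloc[0] > 0)
        assert hits / n_rep >= 0.95

    def test_null_type_one_error_calibrated(self):
        sheet, rng = _control_cohort(seed=1)
        n_cpg = 400
        values = rng.uniform(0.3, 0.7, size=(n_cpg, len(sheet)))
        beta = BetaMatrix(
            pd.DataFrame(
                values,
                index=[f"cg{i}" for i in range(n_cpg)],
                columns=sheet["sample_id"],
            )
        )
        top = pd.DataFrame(
            {"probe_id": [f"cg{i}" for i in range(n_cpg)], "direction": "hyper"}
        )
        summary, table = aod_effect_scan(beta, sheet, top)
        frac = float((table["p"] < 0.05).mean())
        sd = np.sqrt(0.05 * 0.95 / n_cpg)
        assert abs(frac - 0.05) < 3 * sd

    def test_empty_direction_reported_as_nan_not_zero(self):
        sheet, rng = _control_cohort(seed=2)
        beta = BetaMatrix(
            pd.DataFrame(
                rng.uniform(0.2, 0.8, (1, len(sheet))),
                index=["cgA"],
                columns=sheet["sample_id"],
            )
        )
        top = pd.DataFrame({"probe_id": ["cgA"], "direction": ["hyper"]})
        summary, _ = aod_effect_scan(beta, sheet, top)
        assert summary["hypo_n"] == 0
        assert np.isnan(summary["hypo_significant_fraction"])

    def test_case_samples_rejected(self):
        sheet, rng = _control_cohort(seed=3)
        sheet.loc[0, "group"] = "case"
        beta = BetaMatrix(
            pd.DataFrame(
                rng.uniform(0.2, 0.8, (1, len(sheet))),
                index=["cgA"],
                columns=sheet["sample_id"],
            )
        )
        with pytest.raises(ValueError, match="control"):
            aod_effect_scan(beta, sheet, pd.DataFrame({"probe_id": ["cgA"], "direction": ["hyper"]}))


def _effects(coefs, p_hyper=None, ids=None):
    coefs = np.asarray(coefs, float)
    n = len(coefs)
    if p_hyper is None:
        p_hyper = np.where(coefs >= 0, 0.01, 0.99)
    return pd.DataFrame(
        {
            "probe_id": ids if ids is not None else [f"cg{i}" for i in range(n)],
            "coef": coefs,
            "p_hyper": p_hyper,
            "p_hypo": 1 - np.asarray(p_hyper, float),
        }
    )


class TestConcordance:
    def test_identical_effects_fully_replicate(self):
        rng = np.random.default_rng(0)
        coefs = rng.normal(0, 0.03, 50)
        a = _effects(coefs)
        b = a[["probe_id", "coef"]]
        rep = cross_cohort_concordance(a, b)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.n_shared == 50
        assert rep.n_replicated == 50  # one-tailed p 0.01 toward matching sign

    def test_anticorrelated_effects_never_replicate(self):
        rng = np.random.default_rng(1)
        coefs = rng.normal(0, 0.03, 30)
        a = _effects(coefs)
        b = a[["probe_id", "coef"]].assign(coef=-coefs)
        rep = cross_cohort_concordance(a, b)
        assert rep.pearson_r == pytest.approx(-1.0)
        assert rep.n_replicated == 0

    def test_pearson_p_from_t_transform(self):
        # r = 0.34 over 96 pairs -> two-sided p ~= 7.0e-4
        rng = np.random.default_rng(2)
        x = rng.normal(size=96)
        z = rng.normal(size=96)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x  # orthogonalize
        z /= z.std()
        r = 0.34
        y = r * x + np.sqrt(1 - r**2) * z
        a = _effects(x)
        b = _effects(y)[["probe_id", "coef"]]
        rep = cross_cohort_concordance(a, b)
        assert rep.pearson_r == pytest.approx(0.34, abs=1e-10)
        assert rep.pearson_p == pytest.approx(7.0089e-4, rel=1e-3)

    def test_pearson_p_matches_permutation_null(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        a = _effects(x)
        b = _effects(y)[["probe_id", "coef"]]
        rep = cross_cohort_concordance(a, b)
        perm_hits = 0
        n_perm = 2000
        r_obs = abs(rep.pearson_r)
        for _ in range(n_perm):
            r_p = abs(stats.pearsonr(x, rng.permutation(y))[0])
            perm_hits += r_p >= r_obs
        p_perm = (1 + perm_hits) / (1 + n_perm)
        mc_sd = np.sqrt(max(rep.pearson_p * (1 - rep.pearson_p), 1e-6) / n_perm)
        assert abs(p_perm - rep.pearson_p) < max(4 * mc_sd, 0.01)

    def test_direction_flip_of_both_cohorts_is_symmetric(self):
        rng = np.random.default_rng(4)
        coefs = rng.normal(0, 0.02, 40)
        p_hyper = rng.uniform(size=40)
        a = _effects(coefs, p_hyper)
        b = _effects(rng.normal(0, 0.02, 40))[["probe_id", "coef"]]
        rep1 = cross_cohort_concordance(a, b)
        a_flip = _effects(-coefs, 1 - p_hyper)
        b_flip = b.assign(coef=-b["coef"])
        rep2 = cross_cohort_concordance(a_flip, b_flip)
        assert rep1.n_replicated == rep2.n_replicated
        assert rep1.pearson_r == pytest.approx(rep2.pearson_r)

    def test_zero_variance_flagged(self):
        a = _effects([0.1, 0.1, 0.1])
        b = _effects([0.1, 0.2, 0.3])[["probe_id", "coef"]]
        rep = cross_cohort_concordance(a, b)
        assert rep.degenerate and np.isnan(rep.pearson_r)

    def test_too_few_shared_cpgs_rejected(self):
        a = _effects([0.1, 0.2])
        b = _effects([0.1, 0.2])[["probe_id", "coef"]]
        with pytest.raises(ValueError, match="shared"):
            cross_cohort_concordance(a, b)


class TestPipeline:
    CFG = dict(
        n_probes=3000,
        chromosome_length=3_000_000,
        n_planted_dmrs=10,
        dmr_cpg_count_range=(4, 6),
        dmr_effect_range=(0.05, 0.05),
    )

    def test_missing_inputs_fail_before_computation(self, tmp_path):
        cfg = PipelineConfig(out_dir=str(tmp_path))
        with pytest.raises(ValueError, match="missing"):
            run_full_pipeline(cfg)

    def test_identical_seed_byte_identical_tables(self, tmp_path):
        outs = []
        for name in ("run1", "run2"):
            cfg = PipelineConfig(
                out_dir=str(tmp_path / name), seed=5, simulate=self.CFG, n_perm=200
            )
            run_full_pipeline(cfg)
            outs.append(tmp_path / name)
        for fname in ("dmrs.tsv", "cpg_results.tsv", "beta.tsv", "dmrs.bed"):
            assert (outs[0] / fname).read_bytes() == (outs[1] / fname).read_bytes()

    def test_pipeline_artifacts_and_recovery(self, tmp_path):
        cfg = PipelineConfig(
            out_dir=str(tmp_path / "run"), seed=6, simulate=self.CFG, n_perm=200
        )
        results = run_full_pipeline(cfg)
        for fname in (
            "manifest.tsv", "sample_sheet.tsv", "beta.tsv", "filter_report.tsv",
            "dmrs.tsv", "cpg_results.tsv", "run_manifest.json", "np_comparison.json",
        ):
            assert (tmp_path / "run" / fname).exists(), fname
        dmrs = results["dmrs"]
        truth = results["truth"].planted_dmrs
        recovered = 0
        for t in truth.itertuples(index=False):
            hit = dmrs[
                (dmrs["chromosome"] == t.chromosome)
                & (dmrs["start"] <= t.end)
                & (dmrs["end"] >= t.start)
                & (dmrs["direction"] == t.direction)
            ]
            recovered += len(hit) > 0
        assert recovered >= 0.8 * len(truth)
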