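import numpy as np
import pandas as pd
import pytest

import lowbiome as lb
from lowbiome.survival import AliasedCovariateError
from oracles import cox_grid_mle


def meta_row(sample, subject, time, status, stage="I", age=60.0, site="siteA",
             histology="adenocarcinoma", tissue="tumor"):
    return {
        "sample_id": sample,
        "subject_id": subject,
        "tissue": tissue,
        "platform": "16S",
        "study_site": site,
        "batch": "b1",
        "sex": "F",
        "age_years": age,
        "ancestry": "EUR",
        "stage": stage,
        "histology": histology,
        "survival_time_years": time,
        "vital_status": status,
    }


class TestPrepareSurvival:
    def test_ten_year_truncation_censors_event(self):
        meta = pd.DataFrame([meta_row("s1", "P1", 12.3, "dead")]).set_index(
            "sample_id", drop=False
        )
        rec = lb.prepare_survival(meta)
        assert rec.loc["s1", "time_years"] == 10.0
        assert rec.loc["s1", "event"] == 0

    @pytest.mark.parametrize("stage,expected", [("I", "I"), ("II", "II-IV"),
                                                ("III", "II-IV"), ("IV", "II-IV")])
    def test_stage_grouping(self, stage, expected):
        meta = pd.DataFrame([meta_row("s1", "P1", 2.0, "dead", stage=stage)]).set_index(
            "sample_id", drop=False
        )
        assert lb.prepare_survival(meta).loc["s1", "stage_group"] == expected

    def test_age_binning(self):
        meta = pd.DataFrame([meta_row("s1", "P1", 2.0, "alive", age=64.9)]).set_index(
            "sample_id", drop=False
        )
        rec = lb.prepare_survival(meta)
        assert rec.loc["s1", "age_group"] == "<=65"
        assert rec.loc["s1", "age_decade"] == "60"

    def test_unknown_stage_dropped_with_warning(self, caplog):
        meta = pd.DataFrame(
            [meta_row("s1", "P1", 2.0, "dead", stage="unknown"),
             meta_row("s2", "P2", 3.0, "dead")]
        ).set_index("sample_id", drop=False)
        with caplog.at_level("WARNING"):
            rec = lb.prepare_survival(meta)
        assert list(rec.index) == ["s2"]
        assert "dropped 1" in caplog.text


class TestCoxFit:
    @pytest.fixture
    def worked_example(self):
        return pd.DataFrame(
            {"time_years": [1, 2, 3, 4], "event": [1, 1, 0, 1], "z": [1, 0, 1, 0]}
        )

    def test_worked_example_closed_form(self, worked_example):
        fit = lb.cox_fit(worked_example, covariates=["z"])
        assert fit.params["z"] == pytest.approx(np.log(np.sqrt(2)), abs=1e-6)
        assert fit.converged
        assert fit.gradient_norm < 1e-6

    def test_constant_covariate_aliased(self, worked_example):
        df = worked_example.assign(c=1.0)
        with pytest.raises(AliasedCovariateError):
            lb.cox_fit(df, covariates=["c"])

    def test_duplicating_subjects_keeps_beta_shrinks_se(self, worked_example):
        fit1 = lb.cox_fit(worked_example, covariates=["z"])
        fit2 = lb.cox_fit(
            pd.concat([worked_example, worked_example], ignore_index=True),
            covariates=["z"],
        )
        assert fit2.params["z"] == pytest.approx(fit1.params["z"], abs=1e-6)
        assert fit2.se["z"] == pytest.approx(fit1.se["z"] / np.sqrt(2), rel=1e-4)

    def test_single_stratum_equals_unstratified(self, worked_example):
        df = worked_example.assign(site="only")
        strat = lb.cox_fit(df, covariates=["z"], strata=["site"])
        plain = lb.cox_fit(df, covariates=["z"])
        assert strat.params["z"] == pytest.approx(plain.params["z"], abs=1e-10)
        assert strat.log_likelihood == pytest.approx(plain.log_likelihood, abs=1e-10)

    def test_grid_search_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 50:
            n = int(rng.integers(4, 7))
            time = rng.exponential(1.0, n).round(2) + 0.05
            event = rng.integers(0, 2, n)
            z = rng.normal(size=n).round(2)
            if event.sum() < 2 or z.std() == 0:
                continue
            df = pd.DataFrame({"time_years": time, "event": event, "z": z})
            try:
                fit = lb.cox_fit(df, covariates=["z"])
            except AliasedCovariateError:
                continue
            if not fit.converged or "monotone_likelihood" in fit.flags:
                continue  # separation: MLE at infinity, grid oracle meaningless
            oracle = cox_grid_mle(time, event, z)
            if abs(oracle) > 4.5:
                continue  # near the grid edge: effectively separated
            assert fit.params["z"] == pytest.approx(oracle, abs=1e-4)
            checked += 1

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(23)
        n = 80
        df = pd.DataFrame(
            {
                "time_years": rng.exponential(2.0, n),  # continuous: no ties
                "event": rng.integers(0, 2, n),
                "z": rng.normal(size=n),
                "w": rng.normal(size=n),
                "site": rng.choice(["a", "b"], n),
            }
        )
        ours = lb.cox_fit(df, covariates=["z", "w"], strata=["site"], ties="efron")
        cph = lifelines.CoxPHFitter()
        cph.fit(df, duration_col="time_years", event_col="event", strata=["site"],
                formula="z + w")
        for col in ("z", "w"):
            assert ours.params[col] == pytest.approx(cph.params_[col], abs=1e-5)
            assert ours.se[col] == pytest.approx(cph.standard_errors_[col], rel=1e-3)
        # tie-free data: Breslow and Efron coincide
        breslow = lb.cox_fit(df, covariates=["z", "w"], strata=["site"],
                             ties="breslow")
        assert breslow.params["z"] == pytest.approx(ours.params["z"], abs=1e-8)


class TestTaxonScan:
    def _scan_inputs(self, rng, n=120, effect_taxon=None, log_hr=0.0):
        taxa = [f"t{i}" for i in range(6)]
        clr_vals = rng.normal(size=(len(taxa), n))
        samples = [f"s{i}" for i in range(n)]
        eta = np.zeros(n)
        if effect_taxon is not None:
            eta = log_hr * clr_vals[taxa.index(effect_taxon)]
        u = rng.uniform(size=n)
        time = -np.log(u) * np.exp(-eta) * 5.0
        event = (rng.uniform(size=n) < 0.7).astype(int)
        records = pd.DataFrame(
            {
                "time_years": np.minimum(time, 10.0),
                "event": event,
                "study_site": rng.choice(["a", "b"], n),
                "stage_group": rng.choice(["I", "II-IV"], n),
                "age_group": rng.choice(["<=65", ">65"], n),
                "histology": rng.choice(["adeno", "other"], n),
                "age_decade": rng.choice(["50", "60", "70"], n),
            },
            index=samples,
        )
        clr = lb.ClrMatrix(pd.DataFrame(clr_vals, index=taxa, columns=samples))
        return clr, records

    def test_planted_hazard_taxon_ranks_first(self):
        rng = np.random.default_rng(5)
        clr, records = self._scan_inputs(rng, n=300, effect_taxon="t2", log_hr=0.8)
        scan = lb.taxon_survival_scan(clr, records)
        assert scan["p"].idxmin() == "t2"
        assert scan.loc["t2", "p_adj"] < 0.05

    def test_constant_taxon_flagged_aliased(self):
        rng = np.random.default_rng(6)
        clr, records = self._scan_inputs(rng)
        clr.data.iloc[0] = 0.0
        scan = lb.taxon_survival_scan(clr, records)
        assert scan.iloc[0]["flag"] == "aliased"
        assert np.isnan(scan.iloc[0]["p"])
        assert scan["p"].iloc[1:].notna().all()

    def test_scan_invariant_to_taxon_order(self):
        rng = np.random.default_rng(7)
        clr, records = self._scan_inputs(rng)
        scan = lb.taxon_survival_scan(clr, records)
        shuffled = lb.ClrMatrix(clr.data.iloc[::-1])
        scan2 = lb.taxon_survival_scan(shuffled, records)
        pd.testing.assert_frame_equal(scan.sort_index(), scan2.sort_index())
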