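"""Normalization, Hill fitting, POD derivation, and assay QC."""

import numpy as np
import pandas as pd
import pytest

from namscreen import conc_response as cr
from namscreen.synthetic import (
    CellTypePotency,
    ClassPotencyProfile,
    ScreenDesign,
    TrueCurve,
    analytic_pod,
    hill_response,
    simulate_screen,
)

CONCS = np.array([100.0, 10.0, 1.0, 0.1, 0.01])


def well_rows(responses, chemical="chem", plate="p1", phenotype="ph", conc=None, **kw):
    conc = CONCS if conc is None else conc
    return pd.DataFrame(
        {
            "chemical": chemical,
            "chem_class": kw.get("chem_class", ""),
            "cell_type": kw.get("cell_type", "hepatocyte"),
            "phenotype": phenotype,
            "category": kw.get("category", "functional"),
            "conc_uM": conc,
            "replicate": np.arange(1, len(responses) + 1),
            "plate": plate,
            "response_pct": responses,
        }
    )


class TestNormalization:
    def test_treated_scaled_to_vehicle_mean(self):
        veh = well_rows([1000.0, 1000.0, 990.0, 1010.0], chemical="vehicle", conc=np.zeros(4))
        trt = well_rows([800.0] * 5)
        norm, vstats = cr.normalize_to_vehicle(pd.concat([veh, trt], ignore_index=True))
        treated = norm[norm["chemical"] == "chem"]
        assert np.allclose(treated["response_pct"], 80.0)
        assert vstats.loc[0, "mean"] == 100.0

    def test_vehicle_sd_rescaled_consistently(self):
        veh = well_rows([990.0, 1010.0], chemical="vehicle", conc=np.zeros(2))
        trt = well_rows([500.0] * 5)
        _, vstats = cr.normalize_to_vehicle(pd.concat([veh, trt], ignore_index=True))
        raw_sd = np.std([990.0, 1010.0], ddof=1)
        assert vstats.loc[0, "sd"] == pytest.approx(100.0 * raw_sd / 1000.0)

    def test_missing_vehicle_wells_raise_with_location(self):
        trt = well_rows([100.0] * 5, plate="plateX", phenotype="phY")
        with pytest.raises(cr.QCError, match="plateX.*phY"):
            cr.normalize_to_vehicle(trt)

    def test_zero_vehicle_mean_rejected(self):
        veh = well_rows([0.0, 0.0], chemical="vehicle", conc=np.zeros(2))
        trt = well_rows([10.0] * 5)
        with pytest.raises(cr.DegenerateInputError):
            cr.normalize_to_vehicle(pd.concat([veh, trt], ignore_index=True))

    def test_identical_vehicle_wells_give_zero_sd_then_pod_rejects(self):
        veh = well_rows([1000.0] * 4, chemical="vehicle", conc=np.zeros(4))
        trt = well_rows([800.0] * 5)
        _, vstats = cr.normalize_to_vehicle(pd.concat([veh, trt], ignore_index=True))
        assert vstats.loc[0, "sd"] == 0.0
        fit = cr.HillFit(100, 40, 1, 1, "decreasing", 0.0, True, 5)
        with pytest.raises(cr.DegenerateInputError):
            cr.derive_pod(fit, sigma_v=0.0, max_conc=100.0)


class TestHillFitting:
    def test_recovers_noiseless_parameters(self):
        conc = np.repeat(CONCS, 3)
        resp = hill_response(conc, 100.0, 40.0, 1.0, 1.0)
        fit = cr.fit_hill(conc, resp)
        assert fit.converged
        assert fit.bottom == pytest.approx(100.0, rel=1e-3)
        assert fit.top == pytest.approx(40.0, rel=1e-3)
        assert fit.ec50 == pytest.approx(1.0, rel=1e-3)
        assert fit.hill == pytest.approx(1.0, rel=1e-3)
        assert fit.direction == "decreasing"

    def test_flat_data_has_undefined_direction_or_tiny_span(self):
        fit = cr.fit_hill(CONCS, np.full(5, 100.0))
        assert abs(fit.top - fit.bottom) < 1e-6 or fit.direction is None

    def test_increasing_data_direction(self):
        resp = hill_response(CONCS, 100.0, 180.0, 5.0, 1.5)
        fit = cr.fit_hill(CONCS, resp)
        assert fit.direction == "increasing"
        assert fit.top > fit.bottom

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(cr.InsufficientDataError):
            cr.fit_hill([1.0, 10.0, 100.0], [100.0, 80.0, 60.0])

    def test_vehicle_wells_anchor_baseline(self):
        rng = np.random.default_rng(5)
        conc = np.concatenate([np.repeat(CONCS, 3), np.zeros(16)])
        resp = hill_response(conc, 100.0, 40.0, 1.0, 1.0) + rng.normal(0, 10, conc.size)
        resp[conc == 0] = rng.normal(100, 10, 16)
        fit = cr.fit_hill(conc, resp)
        assert abs(fit.bottom - 100.0) < 8.0


class TestDerivePod:
    FIT = cr.HillFit(100.0, 40.0, 1.0, 1.0, "decreasing", 0.0, True, 15)

    def test_matches_closed_form(self):
        res = cr.derive_pod(self.FIT, sigma_v=5.0, max_conc=100.0)
        assert not res.censored
        assert res.pod == pytest.approx(1 / 11, rel=1e-6)
        assert res.side == "below"

    def test_flat_fit_censored_at_max(self):
        flat = cr.HillFit(100.0, 100.0, 1.0, 1.0, None, 0.0, True, 15)
        res = cr.derive_pod(flat, sigma_v=5.0, max_conc=100.0)
        assert res.censored and res.pod == 100.0

    def test_plateau_short_of_benchmark_censored(self):
        shy = cr.HillFit(100.0, 96.0, 1.0, 1.0, "decreasing", 0.0, True, 15)
        assert cr.derive_pod(shy, sigma_v=5.0, max_conc=100.0).censored

    def test_crossing_below_floor_flagged(self):
        potent = cr.HillFit(100.0, 0.0, 1e-4, 1.0, "decreasing", 0.0, True, 15)
        res = cr.derive_pod(potent, sigma_v=5.0, max_conc=100.0)
        assert res.below_range and res.pod == cr.MIN_CONC

    def test_matches_brute_force_search_on_random_fits(self):
        """Root-finding equals grid-plus-bisection to 1e-4 relative tolerance."""
        rng = np.random.default_rng(17)
        checked = 0
        for _ in range(300):
            top = rng.uniform(0, 90) if rng.random() < 0.7 else rng.uniform(110, 200)
            fit = cr.HillFit(
                100.0, top, 10 ** rng.uniform(-3, 3), rng.uniform(0.4, 6), None, 0.0, True, 15
            )
            sigma = rng.uniform(3, 15)
            res = cr.derive_pod(fit, sigma_v=sigma, max_conc=100.0)
            grid = np.logspace(-3, 2, 20001)
            exceed = np.abs(fit.predict(grid) - 100.0) >= sigma
            if res.censored:
                assert not exceed.any() or exceed.mean() < 1e-3
                continue
            if res.below_range:
                assert exceed[0]
                continue
            brute = grid[np.argmax(exceed)]
            assert res.pod == pytest.approx(brute, rel=1e-3)
            checked += 1
        assert checked > 100


class TestPodTable:
    def test_noiseless_pods_match_analytic(self, small_design, small_profiles):
        screen = simulate_screen(small_profiles, small_design, noise_sd=0.0, seed=9)
        # noiseless vehicle wells have zero variance; impose the benchmark SD
        norm, vstats = cr.normalize_to_vehicle(screen.measurements)
        vstats["sd"] = 5.0
        pods = cr.pod_table(norm, vstats)
        truth = screen.truth.set_index(["chemical", "cell_type", "phenotype"])
        for row in pods.itertuples():
            tr = truth.loc[(row.chemical, row.cell_type, row.phenotype)]
            expected = analytic_pod(
                TrueCurve(row.chemical, row.cell_type, row.phenotype,
                          tr.bottom, tr.top, tr.ec50_uM, tr.hill, tr.direction, tr.active),
                5.0,
            )
            if row.censored:
                assert not np.isfinite(expected) or expected > 100.0
            elif not row.below_range and 1e-3 < expected <= 100.0:
                assert row.pod_uM == pytest.approx(expected, rel=1e-3)

    def test_noisy_pods_recover_truth_within_quarter_decade(self, screen, pods):
        truth = screen.truth
        merged = pods.merge(truth, on=["chemical", "cell_type", "phenotype"])
        active = merged[merged["active"] & ~merged["censored"] & ~merged["below_range"]]
        true_pod = [
            analytic_pod(
                TrueCurve(r.chemical, r.cell_type, r.phenotype, r.bottom, r.top,
                          r.ec50_uM, r.hill, r.direction, r.active),
                10.0,
            )
            for r in active.itertuples()
        ]
        active = active.assign(true_pod=true_pod)
        inside = active[(active["true_pod"] > 0.01) & (active["true_pod"] < 100.0)]
        err = np.abs(np.log10(inside["pod_uM"]) - np.log10(inside["true_pod"]))
        assert err.median() < 0.25


class TestQC:
    def _plate(self, plate, responses, chemical="chem"):
        return well_rows(responses, chemical=chemical, plate=plate, cell_type="hepatocyte")

    def test_duplicate_plates_give_perfect_interplate_correlation(self):
        resp = hill_response(CONCS, 100.0, 40.0, 1.0, 1.0)
        df = pd.concat([self._plate("p1", resp), self._plate("p2", resp)], ignore_index=True)
        report = cr.qc_assay(df)
        inter = report[report["parameter"] == "inter_plate_correlation"]
        assert np.allclose(inter["value"], 1.0)
        assert (inter["status"] == "pass").all()

    def test_vehicle_vs_medium_null_passes_most_runs(self):
        """Same-distribution negative controls pass the difference check ~95%
        of the time at alpha = 0.05 (Monte-Carlo under the null)."""
        rng = np.random.default_rng(23)
        passes = 0
        n_runs = 300
        for _ in range(n_runs):
            veh = well_rows(rng.normal(100, 10, 16), chemical="vehicle", conc=np.zeros(16))
            med = well_rows(rng.normal(100, 10, 16), chemical="medium", conc=np.zeros(16))
            report = cr.qc_assay(pd.concat([veh, med], ignore_index=True))
            row = report[report["parameter"] == "vehicle_vs_medium"].iloc[0]
            passes += row["status"] == "pass"
        assert passes / n_runs > 0.90

    def test_positive_control_outside_window_fails(self):
        resp = np.asarray(hill_response(np.repeat(CONCS, 3), 100.0, 40.0, 10.0, 1.0))
        df = well_rows(resp, chemical="posctrl", conc=np.repeat(CONCS, 3))
        thresholds = cr.QCThresholds(positive_controls={"hepatocyte": ("posctrl", (0.01, 0.1))})
        report = cr.qc_assay(df, thresholds)
        pc = report[report["parameter"] == "positive_control_ec50"]
        assert (pc["status"] == "fail").all()

    def test_absent_controls_not_evaluable(self):
        df = self._plate("p1", hill_response(CONCS, 100, 40, 1, 1))
        report = cr.qc_assay(df)
        medium = report[report["parameter"] == "medium_cv"]
        assert (medium["status"] == "not-evaluable").all()


class TestCategoryContrast:
    def test_lower_functional_pods_detected(self, ):
        records = []
        for i in range(6):
            records.append(("c", "hepatocyte", f"f{i}", "functional", 0.1, False))
            records.append(("c", "hepatocyte", f"t{i}", "cytotoxicity", 10.0, False))
        pods = pd.DataFrame(
            records, columns=["chemical", "cell_type", "phenotype", "category", "pod_uM", "censored"]
        )
        out = cr.phenotype_category_contrast(pods)
        pooled = out[out["cell_type"] == "all"].iloc[0]
        assert pooled["p_one_sided"] < 0.05

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(200):
            pods = pd.DataFrame(
                {
                    "chemical": "c",
                    "cell_type": "hepatocyte",
                    "phenotype": [f"p{i}" for i in range(16)],
                    "category": ["functional"] * 8 + ["cytotoxicity"] * 8,
                    "pod_uM": rng.lognormal(0, 1, 16),
                    "censored": False,
                }
            )
            out = cr.phenotype_category_contrast(pods)
            ps.append(out[out["cell_type"] == "all"].iloc[0]["p_one_sided"])
        assert 0.35 < np.mean(ps) < 0.65

    def test_single_pod_per_category_flagged_low_n(self):
        pods = pd.DataFrame(
            [
                ("c", "hepatocyte", "f", "functional", 0.1, False),
                ("c", "hepatocyte", "t", "cytotoxicity", 10.0, False),
            ],
            columns=["chemical", "cell_type", "phenotype", "category", "pod_uM", "censored"],
        )
        out = cr.phenotype_category_contrast(pods)
        assert (out["status"] == "low-n").all()

    def test_absent_category_not_evaluable(self):
        pods = pd.DataFrame(
            [("c", "hepatocyte", "f", "functional", 0.1, False)],
            columns=["chemical", "cell_type", "phenotype", "category", "pod_uM", "censored"],
        )
        out = cr.phenotype_category_contrast(pods)
        assert (out["status"] == "not-evaluable").all()

    def test_functional_pods_lower_in_planted_screen(self, pods):
        # the default generator plants no category effect; just exercise shape
        out = cr.phenotype_category_contrast(pods)
        assert set(out.columns) >= {"cell_type", "p_one_sided", "status"}
        assert len(out) == 6  # pooled + five cell types
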