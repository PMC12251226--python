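"""Inhibition maps, error measure E, and the cubic response surface."""

import numpy as np
import pytest

from apdbench.benchmark import (
    ConditionMismatchError,
    DeltaAPDMap,
    ExperimentalRecord,
    ModelExcludedError,
    SurfaceFit,
    compute_map,
    error_measure,
    evaluate_surface,
    fit_cubic_surface,
    predict_study,
    zero_contour,
    zero_line_slope,
)
from apdbench.pharmacology import DrugCondition, DrugEntry, HillParameters


def make_records(values, sems=None):
    out = []
    for i, v in enumerate(values):
        out.append(ExperimentalRecord(
            drug=f"drug{i % 3}", concentration=float(i + 1),
            mean_delta_apd90=float(v),
            sem=float(sems[i]) if sems is not None else 5.0,
            n_trabeculae=5, mean_baseline_apd90=300.0, baseline_sd=40.0))
    return out


class TestErrorMeasure:
    def test_zero_when_predictions_equal_means(self, rng):
        recs = make_records(rng.normal(0, 50, 12))
        preds = {r.condition: r.mean_delta_apd90 for r in recs}
        assert error_measure(preds, recs).total_e == 0.0

    def test_single_condition_two_sem(self):
        recs = make_records([10.0])
        preds = {recs[0].condition: 10.0 + 2 * recs[0].sem}
        rep = error_measure(preds, recs)
        assert rep.total_e == pytest.approx(2.0)

    def test_per_drug_sums_conserve_total(self, rng):
        recs = make_records(rng.normal(0, 50, 15), sems=rng.uniform(2, 20, 15))
        preds = {r.condition: float(rng.normal(0, 30)) for r in recs}
        rep = error_measure(preds, recs)
        assert sum(rep.per_drug.values()) == pytest.approx(rep.total_e)
        assert sum(z for *_, z in rep.per_condition) == pytest.approx(rep.total_e)

    def test_order_invariance(self, rng):
        recs = make_records(rng.normal(0, 50, 10))
        preds = {r.condition: 3.0 for r in recs}
        a = error_measure(preds, recs).total_e
        b = error_measure(preds, list(reversed(recs))).total_e
        assert a == b

    def test_sem_scaling_inverse(self, rng):
        values = rng.normal(0, 50, 10)
        sems = rng.uniform(2, 20, 10)
        preds = {r.condition: 0.0 for r in make_records(values, sems)}
        e1 = error_measure(preds, make_records(values, sems)).total_e
        e3 = error_measure(preds, make_records(values, sems * 3.0)).total_e
        assert e3 == pytest.approx(e1 / 3.0)

    def test_zero_predictor_matches_brute_force(self, tables):
        preds = {c: 0.0 for c in tables.conditions}
        rep = error_measure(preds, tables.table1)
        # independent brute-force summation over the packaged table
        total = 0.0
        for r in tables.table1:
            total += abs(r.mean_delta_apd90) / r.sem
        assert rep.total_e == pytest.approx(total, abs=1e-12)

    def test_mismatched_conditions_listed(self, tables):
        preds = {c: 0.0 for c in tables.conditions[:-1]}
        with pytest.raises(ConditionMismatchError, match="Verapamil"):
            error_measure(preds, tables.table1)


class TestCubicSurface:
    def test_plane_recovered_exactly(self, rng):
        pts = [(x, y, 3.0 + 2.0 * x - 1.0 * y)
               for x, y in rng.random((25, 2))]
        fit = fit_cubic_surface(pts)
        assert fit.coefficients[0] == pytest.approx(3.0, abs=1e-9)
        assert fit.coefficients[1] == pytest.approx(2.0, abs=1e-9)
        assert fit.coefficients[2] == pytest.approx(-1.0, abs=1e-9)
        assert np.all(np.abs(fit.coefficients[3:]) < 1e-9)

    def test_known_cubic_recovered(self, rng):
        truth = np.array([4.0, -3.0, 2.5, 1.0, -0.5, 2.0, 0.7, -1.2, 0.3, 0.9])
        fit_pts = []
        for x, y in rng.random((20, 2)):
            z = evaluate_surface(SurfaceFit(coefficients=truth), x, y)
            fit_pts.append((x, y, z))
        fit = fit_cubic_surface(fit_pts)
        assert np.allclose(fit.coefficients, truth, rtol=1e-8, atol=1e-10)

    def test_nine_points_rejected(self, rng):
        pts = [(x, y, 0.0) for x, y in rng.random((9, 2))]
        with pytest.raises(ValueError, match="10"):
            fit_cubic_surface(pts)

    def test_rank_deficiency_named(self):
        # 12 points on a single line cannot span the bivariate basis
        pts = [(t, t, 1.0 + t) for t in np.linspace(0, 1, 12)]
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_cubic_surface(pts)

    def test_weighting_changes_fit(self, rng):
        pts = [(x, y, x + y + rng.normal(0, 0.5)) for x, y in rng.random((30, 2))]
        w = rng.uniform(0.1, 10.0, 30)
        f1 = fit_cubic_surface(pts)
        f2 = fit_cubic_surface(pts, weights=w)
        assert not np.allclose(f1.coefficients, f2.coefficients)

    def test_exactly_ten_coefficients(self):
        with pytest.raises(ValueError):
            SurfaceFit(coefficients=np.zeros(9))


class TestMapStructure:
    def _synthetic_map(self, fn, n=21):
        axis = np.linspace(0, 1, n)
        values = np.array([[fn(i, c) for c in axis] for i in axis])
        return DeltaAPDMap(ikr_axis=axis, ical_axis=axis, values=values, model="synth")

    def test_origin_must_be_zero(self):
        axis = np.linspace(0, 1, 3)
        with pytest.raises(ValueError, match=r"\(0, 0\)"):
            DeltaAPDMap(ikr_axis=axis, ical_axis=axis,
                        values=np.ones((3, 3)), model="bad")

    def test_zero_contour_contains_origin(self):
        m = self._synthetic_map(lambda i, c: 100.0 * i - 90.0 * c)
        assert (0, 0) in zero_contour(m)

    def test_zero_contour_excludes_flagged_cells(self):
        m = self._synthetic_map(lambda i, c: 100.0 * i - 90.0 * c)
        vals = m.values.copy()
        vals[5, 5] = np.nan
        m2 = DeltaAPDMap(m.ikr_axis, m.ical_axis, vals, "synth")
        assert (5, 5) not in zero_contour(m2, tol=1e9)

    def test_singleton_contour(self):
        m = self._synthetic_map(lambda i, c: 0.0 if (i == 0 and c == 0) else 50.0)
        assert zero_contour(m) == {(0, 0)}

    def test_slope_of_linear_zero_line(self):
        # zero line of 100 i - 90 c is c = (100/90) i: slope 1.111
        m = self._synthetic_map(lambda i, c: 100.0 * i - 90.0 * c)
        assert zero_line_slope(m) == pytest.approx(100.0 / 90.0, abs=0.02)


class TestComputeMap:
    def test_reduced_resolution_consistency(self, tp):
        # maps are cellwise-independent simulations of the same protocol,
        # so shared grid fractions agree exactly across resolutions
        m3 = compute_map(tp, resolution=3, n_paces=30)
        m5 = compute_map(tp, resolution=5, n_paces=30)
        assert m3.values[0, 0] == 0.0
        for i3, i5 in ((0, 0), (1, 2), (2, 4)):
            for j3, j5 in ((0, 0), (1, 2), (2, 4)):
                assert m3.values[i3, j3] == m5.values[i5, j5]

    def test_resolution_validation(self, tp):
        with pytest.raises(ValueError):
            compute_map(tp, resolution=1)


class TestPredictStudy:
    def test_tnnp_excluded(self, tables):
        with pytest.raises(ModelExcludedError, match="TNNP"):
            predict_study("TNNP", "Pharm", tables.drug_conditions())

    def test_fully_censored_drug_predicts_zero_without_simulation(self, tp):
        table = {("Inertium", "Pharm"): DrugEntry(
            drug="Inertium", dataset="Pharm",
            ikr=HillParameters(None, None, censored_above=10.0),
            ical=HillParameters(None, None, censored_above=10.0))}
        conds = [DrugCondition("Inertium", c) for c in (0.1, 1.0, 10.0)]
        preds = predict_study(tp, "Pharm", conds, n_paces=10 ** 9, table=table)
        assert all(v == 0.0 for v in preds.values())

    def test_balanced_blocker_ordering_ord_above_tp(self, tables):
        # Chlorpromazine 3 uM blocks IKr and ICaL comparably; the
        # IKr-dominated ORd family must predict more prolongation than TP
        conds = [DrugCondition("Chlorpromazine", 3.0)]
        tp_pred = predict_study("TP", "Pharm", conds, n_paces=150,
                                table=tables.table3)
        ord_pred = predict_study("ORd", "Pharm", conds, n_paces=150,
                                 table=tables.table3)
        key = ("Chlorpromazine", 3.0)
        assert ord_pred[key] > tp_pred[key]
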