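"""Gompertz-Makeham sampling correctness against closed forms."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

from lifespans import (
    GompertzParams,
    ParameterError,
    StudyDesign,
    build_study_cohort,
    gompertz_a_for_median,
    load_design,
    save_design,
    simulate_gompertz_makeham,
    theoretical_median,
    week1_design,
    week2_design,
)


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            GompertzParams(a=0.0)
        with pytest.raises(ParameterError):
            GompertzParams(a=1e-5, b=-0.001)
        with pytest.raises(ParameterError):
            GompertzParams(a=1e-5, c=-1.0)

    def test_hazard_ratio_scales_a(self):
        p = GompertzParams(a=1e-5, b=0.01).with_hazard_ratio(2.0)
        assert p.a == 2e-5 and p.b == 0.01


class TestSampling:
    def test_exponential_limit_mean(self):
        """b = c = 0 reduces to an exponential law with mean 1/a."""
        a = 1e-3
        x = simulate_gompertz_makeham(GompertzParams(a=a), n=100_000, seed=11)
        se = (1 / a) / np.sqrt(x.size)
        assert abs(x.mean() - 1 / a) < 3 * se

    def test_empirical_median_matches_closed_form(self):
        params = GompertzParams(a=2e-5, b=0.008)
        x = simulate_gompertz_makeham(params, n=10_000, seed=5)
        target = theoretical_median(params)
        rng = np.random.default_rng(0)
        boots = np.median(
            x[rng.integers(0, x.size, size=(200, x.size))], axis=1
        )
        assert abs(np.median(x) - target) < 3 * boots.std()

    def test_same_seed_bit_identical(self):
        p = GompertzParams(a=2e-5, b=0.008, c=1e-5)
        x1 = simulate_gompertz_makeham(p, 1000, seed=42)
        x2 = simulate_gompertz_makeham(p, 1000, seed=42)
        np.testing.assert_array_equal(x1, x2)

    def test_larger_b_shortens_lifespans(self):
        a = 2e-5
        meds = [
            np.median(simulate_gompertz_makeham(GompertzParams(a=a, b=b), 10_000, seed=3))
            for b in (0.004, 0.008, 0.016)
        ]
        assert meds[0] > meds[1] > meds[2]

    def test_ks_against_closed_form_survival(self):
        params = GompertzParams(a=2e-5, b=0.008)
        x = simulate_gompertz_makeham(params, 10_000, seed=9)
        stat = stats.kstest(x, lambda t: 1.0 - params.survival(t))
        assert stat.pvalue > 0.01

    def test_makeham_sampling_inverts_cumulative_hazard(self):
        params = GompertzParams(a=2e-5, b=0.008, c=5e-4)
        x = simulate_gompertz_makeham(params, 10_000, seed=13)
        stat = stats.kstest(x, lambda t: 1.0 - params.survival(t))
        assert stat.pvalue > 0.01

    def test_invalid_n(self):
        with pytest.raises(ParameterError):
            simulate_gompertz_makeham(GompertzParams(a=1e-4), 0, seed=1)


class TestTheoreticalMedian:
    def test_exponential_limit(self):
        p = GompertzParams(a=np.log(2.0), b=1e-12)
        assert theoretical_median(p) == pytest.approx(1.0, rel=1e-6)

    def test_matches_bisection_oracle(self):
        p = GompertzParams(a=2e-5, b=0.008)
        root = brentq(lambda t: p.survival(t) - 0.5, 1.0, 5000.0, xtol=1e-9)
        assert theoretical_median(p) == pytest.approx(root, rel=1e-6)

    def test_makeham_numeric_branch(self):
        p = GompertzParams(a=2e-5, b=0.008, c=3e-4)
        m = theoretical_median(p)
        assert p.survival(m) == pytest.approx(0.5, abs=1e-8)

    def test_doubling_a_decreases_median(self):
        m1 = theoretical_median(GompertzParams(a=2e-5, b=0.008))
        m2 = theoretical_median(GompertzParams(a=4e-5, b=0.008))
        assert m2 < m1

    def test_a_for_median_inverts(self):
        a = gompertz_a_for_median(1004.0, b=0.0077)
        assert theoretical_median(GompertzParams(a=a, b=0.0077)) == pytest.approx(1004.0)


class TestStudyDesign:
    def test_week1_cohort_size(self):
        assert len(build_study_cohort(week1_design(seed=1))) == 149

    def test_week2_cohort_size(self):
        assert len(build_study_cohort(week2_design(seed=1))) == 123

    def test_one_cell_design(self):
        d = StudyDesign(
            cells={("dwarf", "GH", "male"): (5, GompertzParams(a=1e-4, b=0.005))},
            seed=3,
        )
        cohort = build_study_cohort(d)
        assert len(cohort) == 5
        assert {r.cell for r in cohort} == {("dwarf", "GH", "male")}

    def test_empty_design_rejected(self):
        with pytest.raises(ParameterError):
            StudyDesign(cells={}, seed=0)

    def test_cell_substreams_independent_of_other_cells(self):
        """Adding a cell must not perturb the draws of existing cells."""
        base = {("dwarf", "GH", "male"): (8, GompertzParams(a=1e-4, b=0.005))}
        extra = dict(base)
        extra[("control", "saline", "female")] = (4, GompertzParams(a=2e-4, b=0.004))
        c1 = build_study_cohort(StudyDesign(cells=base, seed=99))
        c2 = build_study_cohort(StudyDesign(cells=extra, seed=99))
        ages1 = [r.age_days for r in c1 if r.cell == ("dwarf", "GH", "male")]
        ages2 = [r.age_days for r in c2 if r.cell == ("dwarf", "GH", "male")]
        assert ages1 == ages2

    def test_round_to_days_gives_integer_ages(self):
        cohort = build_study_cohort(week1_design(seed=2), round_to_days=True)
        assert all(float(r.age_days).is_integer() for r in cohort)

    def test_design_yaml_round_trip(self, tmp_path):
        d = week2_design(seed=17)
        p = tmp_path / "design.yaml"
        save_design(d, p)
        d2 = load_design(p)
        assert d2.seed == 17 and d2.cells == d.cells
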