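"""Stage-structured projection core: matrix entries, growth rate, projection."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from lynxcast.demography import (
    InvalidParameterError,
    VitalRates,
    build_projection_matrix,
    derived_survival,
    potential_growth_rate,
    project,
    stable_age_distribution,
)

# prior-mean vital rates used in several worked examples
PRIOR_MEANS_AREA1 = dict(phi1=0.90, phi2=0.96, r1=0.19, r2=0.39, rho=0.0)


class TestProjectionMatrix:
    def test_survival_only_identity_structure(self):
        A = build_projection_matrix(VitalRates(1.0, 1.0, 0.0, 0.0, 0.0))
        assert np.allclose(A, [[0, 0, 0], [1, 0, 0], [0, 1, 1]])

    def test_structural_zeros_and_equal_adult_entries(self):
        A = build_projection_matrix(VitalRates(0.9, 0.95, 0.3, 0.4, 0.1))
        assert A[0, 0] == A[1, 1] == A[1, 2] == A[2, 0] == 0.0
        assert A[2, 1] == A[2, 2] and np.all(A >= 0)

    def test_northern_sweden_posterior_means(self):
        # derived subadult and adult survival at the published posterior
        A = build_projection_matrix(VitalRates(0.91, 0.98, 0.23, 0.39, 0.18))
        assert A[1, 0] == pytest.approx(0.738, abs=5e-4)
        assert A[2, 1] == pytest.approx(0.802, abs=5e-4)

    def test_prior_mean_entries_no_extra_mortality(self):
        A = build_projection_matrix(VitalRates(**PRIOR_MEANS_AREA1))
        assert A[0, 1] == pytest.approx(0.19 * 0.96**0.25, abs=1e-10)
        assert A[0, 2] == pytest.approx(0.39 * 0.96**0.25, abs=1e-10)
        assert A[1, 0] == pytest.approx(0.90)
        assert A[2, 2] == pytest.approx(0.96)

    def test_excessive_extra_mortality_rejected(self):
        with pytest.raises(InvalidParameterError, match="negative|derived"):
            build_projection_matrix(VitalRates(0.3, 0.9, 0.2, 0.4, 0.6))

    def test_out_of_range_rates_rejected(self):
        with pytest.raises(InvalidParameterError):
            VitalRates(1.2, 0.9, 0.2, 0.4, 0.0)


class TestDerivedSurvival:
    def test_published_adult_value(self):
        assert derived_survival(0.98, 0.18) == pytest.approx(0.8018, abs=1e-4)

    def test_subadult_value(self):
        assert derived_survival(0.91, 0.18) == pytest.approx(0.7383, abs=1e-4)

    @given(st.floats(0.0, 1.0))
    @hsettings(max_examples=50, deadline=None)
    def test_zero_extra_mortality_is_identity(self, phi):
        assert derived_survival(phi, 0.0) == pytest.approx(phi)

    def test_negative_result_rejected(self):
        with pytest.raises(InvalidParameterError):
            derived_survival(0.09, 0.9)


def _char_poly_root(A):
    """Largest real root of the characteristic cubic, by bisection."""
    a12, a13 = A[0, 1], A[0, 2]
    a21 = A[1, 0]
    a32, a33 = A[2, 1], A[2, 2]

    def p(lam):
        return (
            lam**3
            - a33 * lam**2
            - a12 * a21 * lam
            + a12 * a21 * a33
            - a13 * a21 * a32
        )

    lo, hi = a33, 5.0  # dominant root exceeds the diagonal entry
    if p(lo) == 0:
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if p(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestGrowthRate:
    def test_single_diagonal_entry(self):
        A = np.zeros((3, 3))
        A[2, 2] = 0.9
        assert potential_growth_rate(A) == pytest.approx(0.9)

    @pytest.mark.parametrize(
        "rates, printed",
        [
            ((0.91, 0.98, 0.23, 0.39, 0.18), 1.01),  # northern Sweden
            ((0.91, 0.98, 0.46, 0.49, 0.088), 1.19),  # southern Norway
        ],
    )
    def test_posterior_median_growth_rates(self, rates, printed):
        lam = potential_growth_rate(build_projection_matrix(VitalRates(*rates)))
        assert lam == pytest.approx(printed, abs=0.01)

    @pytest.mark.parametrize(
        "rates",
        [
            (0.91, 0.98, 0.23, 0.39, 0.18),
            (0.90, 0.96, 0.19, 0.39, 0.0),
            (0.85, 0.93, 0.5, 0.5, 0.05),
        ],
    )
    def test_matches_characteristic_cubic(self, rates):
        A = build_projection_matrix(VitalRates(*rates))
        assert potential_growth_rate(A) == pytest.approx(
            _char_poly_root(A), abs=1e-9
        )

    def test_monotone_in_vital_rates(self):
        base = dict(phi1=0.85, phi2=0.9, r1=0.3, r2=0.4, rho=0.1)
        lam0 = potential_growth_rate(build_projection_matrix(VitalRates(**base)))
        for name, up in [
            ("phi1", True), ("phi2", True), ("r1", True), ("r2", True),
            ("rho", False),
        ]:
            bumped = dict(base)
            bumped[name] += 0.05
            lam = potential_growth_rate(
                build_projection_matrix(VitalRates(**bumped))
            )
            assert (lam >= lam0) == up


class TestStableAgeDistribution:
    def test_survival_only_concentrates_on_adults(self):
        sad = stable_age_distribution(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 1]], dtype=float)
        )
        assert sad == pytest.approx([0.0, 0.0, 1.0], abs=1e-8)

    def test_prior_mean_area1_against_power_iteration(self):
        A = build_projection_matrix(VitalRates(**PRIOR_MEANS_AREA1))
        # independent oracle: plain power iteration
        v = np.ones(3) / 3
        for _ in range(2000):
            v = A @ v
            v /= v.sum()
        sad = stable_age_distribution(A)
        assert sad == pytest.approx(v, abs=1e-8)
        assert sad == pytest.approx([0.221, 0.164, 0.616], abs=5e-3)

    @given(
        st.floats(0.5, 0.99), st.floats(0.5, 0.99),
        st.floats(0.05, 0.9), st.floats(0.05, 0.9), st.floats(0.0, 0.3),
    )
    @hsettings(max_examples=50, deadline=None)
    def test_proportions_normalized(self, phi1, phi2, r1, r2, rho):
        try:
            A = build_projection_matrix(VitalRates(phi1, phi2, r1, r2, rho))
        except InvalidParameterError:
            return
        sad = stable_age_distribution(A)
        assert np.all(sad >= 0) and sad.sum() == pytest.approx(1.0)


class TestProject:
    def test_no_harvest_identity_structure(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 1]], dtype=float)
        mu = project(np.array([4.0, 5.0, 6.0]), np.zeros(3), A)
        assert mu == pytest.approx([0.0, 4.0, 11.0])

    def test_prior_mean_projection_by_hand(self):
        A = build_projection_matrix(VitalRates(**PRIOR_MEANS_AREA1))
        mu = project(np.array([10.0, 5.0, 20.0]), np.zeros(3), A)
        assert mu == pytest.approx([8.661, 9.0, 24.0], abs=2e-3)

    def test_full_removal_floors_with_warning(self, caplog):
        A = build_projection_matrix(VitalRates(**PRIOR_MEANS_AREA1))
        with caplog.at_level("WARNING"):
            mu = project(np.ones(3), np.ones(3), A)
        assert np.all(mu < 1e-4) and np.all(mu >= 0)
        assert any("floor" in rec.message for rec in caplog.records)

    def test_harvest_subtracted_before_projection(self):
        A = build_projection_matrix(VitalRates(**PRIOR_MEANS_AREA1))
        n = np.array([10.0, 5.0, 20.0])
        h = np.array([2.0, 1.0, 3.0])
        assert project(n, h, A) == pytest.approx(A @ (n - h))

    def test_stable_distribution_scales_by_lambda(self):
        A = build_projection_matrix(VitalRates(0.91, 0.98, 0.23, 0.39, 0.18))
        lam = potential_growth_rate(A)
        sad = stable_age_distribution(A) * 100.0
        assert project(sad, np.zeros(3), A) == pytest.approx(lam * sad, abs=1e-8)
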