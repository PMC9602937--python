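"""Tests for the analytic fixed point, branch elimination and stability."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psychseir import (
    SteadyState,
    analytic_steady_state,
    effective_infection_rate,
    infeasible_branch_infectious_density,
    is_locally_stable,
    steady_state_residual,
)
from psychseir.model_core import rhs_array
from psychseir.steady_state import DegenerateParameterError

from conftest import random_params


# ---------------------------------------------------------------------------
# analytic fixed point
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "updates,expected",
    [
        ({}, (0.0, 0.078424, 0.054210, 0.867366)),          # baseline
        ({"r": 0.0}, (0.0, 0.062992, 0.055118, 0.881890)),  # all intimate
        ({"r": 1.0}, (0.0, 0.183066, 0.048055, 0.768879)),  # none intimate
    ],
)
def test_analytic_fixed_point_values(baseline, updates, expected):
    point = analytic_steady_state(baseline.with_updates(**updates))
    np.testing.assert_allclose(point.as_array(), expected, atol=5e-7)
    assert point.feasible
    assert point.residual_norm < 1e-12


def test_no_forgetting_absorbs_into_recovered(baseline):
    point = analytic_steady_state(baseline.with_updates(f=0.0))
    np.testing.assert_allclose(point.as_array(), [0, 0, 0, 1], atol=0)


def test_degenerate_denominator_raises(baseline):
    with pytest.raises(DegenerateParameterError):
        analytic_steady_state(baseline.with_updates(b=0.0, f=0.0))


@given(seed=st.integers(0, 10_000))
def test_fixed_point_on_simplex_with_zero_residual(seed):
    params = random_params(np.random.default_rng(seed))
    point = analytic_steady_state(params)
    arr = point.as_array()
    assert abs(arr.sum() - 1.0) < 1e-12
    assert np.all(arr >= 0) and np.all(arr <= 1)
    assert steady_state_residual(point, params) < 1e-10


@given(seed=st.integers(0, 10_000))
def test_fixed_point_ignores_contact_and_transfer_rates(seed):
    """The equilibrium depends only on b, c, f, r, delta: changing a, d,
    e or K moves the transient but not where the system settles."""
    rng = np.random.default_rng(seed)
    params = random_params(rng)
    other = params.with_updates(
        a=rng.uniform(0.05, 1), d=rng.uniform(0, 1), e=rng.uniform(0, 1),
        K=rng.uniform(1, 20),
    )
    np.testing.assert_array_equal(
        analytic_steady_state(params).as_array(),
        analytic_steady_state(other).as_array(),
    )


def test_monotone_in_effective_rate(baseline):
    """I* and R* rise, E* falls, as the effective E->I rate grows."""
    betas, e_stars, i_stars, r_stars = [], [], [], []
    for b in np.linspace(0.05, 1.0, 12):
        params = baseline.with_updates(b=float(b))
        betas.append(effective_infection_rate(params))
        point = analytic_steady_state(params)
        e_stars.append(point.E_star)
        i_stars.append(point.I_star)
        r_stars.append(point.R_star)
    assert np.all(np.diff(betas) > 0)
    assert np.all(np.diff(e_stars) < 0)
    assert np.all(np.diff(i_stars) > 0)
    assert np.all(np.diff(r_stars) > 0)


# ---------------------------------------------------------------------------
# rejected branch
# ---------------------------------------------------------------------------

def test_infeasible_branch_baseline(baseline):
    value = infeasible_branch_infectious_density(baseline)
    assert value == pytest.approx(-0.3 / 2.8, abs=1e-15)


def test_infeasible_branch_sign(baseline):
    assert infeasible_branch_infectious_density(
        baseline.with_updates(d=0.0, e=0.0)
    ) == 0.0
    rng = np.random.default_rng(7)
    for _ in range(50):
        params = random_params(rng)
        if params.d + params.e > 0:
            assert infeasible_branch_infectious_density(params) < 0


def test_infeasible_branch_zero_contact_errors(baseline):
    with pytest.raises(ZeroDivisionError):
        infeasible_branch_infectious_density(baseline.with_updates(a=0.0))


# ---------------------------------------------------------------------------
# residual and stability
# ---------------------------------------------------------------------------

def test_residual_of_non_fixed_points(baseline):
    corner = SteadyState(1, 0, 0, 0, feasible=False, residual_norm=np.nan)
    assert steady_state_residual(corner, baseline) == pytest.approx(0.3)
    absorbing = SteadyState(0, 0, 0, 1, feasible=True, residual_norm=np.nan)
    assert steady_state_residual(absorbing, baseline.with_updates(f=0.0)) == 0.0


def test_baseline_fixed_point_is_stable(baseline):
    point = analytic_steady_state(baseline)
    report = is_locally_stable(point, baseline)
    assert report.stable
    assert np.all(report.eigenvalues.real < 0)
    # conservation forces a zero eigenvalue of the full 4x4 Jacobian
    assert np.min(np.abs(report.full_eigenvalues)) < 1e-12


def test_stability_against_finite_difference_jacobian(baseline):
    """Cross-check the reduced spectrum against a finite-difference
    linearization of the flow restricted to the simplex."""
    point = analytic_steady_state(baseline)
    y0 = point.as_array()
    h = 1e-7
    # perturb within the simplex: directions with zero component sum
    basis = np.array([[1, -1, 0, 0], [0, 1, -1, 0], [0, 0, 1, -1]], float)
    fd = np.empty((3, 3))
    for j, direction in enumerate(basis):
        df = (rhs_array(y0 + h * direction, baseline)
              - rhs_array(y0 - h * direction, baseline)) / (2 * h)
        # express df in the same tangent basis via least squares
        fd[:, j] = np.linalg.lstsq(basis.T, df, rcond=None)[0]
    fd_eigs = np.sort_complex(np.linalg.eigvals(fd))
    report = is_locally_stable(point, baseline)
    np.testing.assert_allclose(
        fd_eigs, np.sort_complex(report.eigenvalues), atol=1e-5
    )


def test_no_forgetting_spectrum_nonpositive(baseline):
    params = baseline.with_updates(f=0.0)
    point = SteadyState(0, 0, 0, 1, feasible=True, residual_norm=0.0)
    report = is_locally_stable(point, params)
    assert np.all(report.eigenvalues.real <= 1e-12)
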