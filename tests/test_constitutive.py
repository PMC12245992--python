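"""Hyperelastic models: invariants, energies, and stress/oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vadsim.constitutive import (
    LinearElasticParams,
    MartinsParams,
    NeoHookeanParams,
    compute_invariants,
    linear_elastic_stress,
    martins_cauchy_stress,
    martins_energy,
    martins_energy_parts,
    martins_uniaxial_stress,
    neo_hookean_energy,
    neo_hookean_stress,
    neo_hookean_uniaxial_stress,
    numerical_stress_oracle,
    uniaxial_isochoric_F,
)
from vadsim.errors import (
    InvalidDeformationError,
    ModeError,
    NormalizationError,
)

from conftest import random_isochoric_states

TABLE = MartinsParams()


@pytest.mark.parametrize(
    "F, N, J, I1, lf",
    [
        (np.eye(3), (1, 0, 0), 1.0, 3.0, 1.0),
        (np.diag([1.1, 1.1 ** -0.5, 1.1 ** -0.5]), (1, 0, 0),
         1.0, 1.1 ** 2 + 2 / 1.1, 1.1),
        (2.0 * np.eye(3), (0, 0, 1), 8.0, 3.0, 1.0),
    ],
)
def test_invariant_examples(F, N, J, I1, lf):
    st_ = compute_invariants(F, N)
    assert st_.J == pytest.approx(J, abs=1e-12)
    assert st_.Ibar1 == pytest.approx(I1, abs=1e-12)
    assert st_.lambdabar_f == pytest.approx(lf, abs=1e-12)


def test_invariant_errors():
    with pytest.raises(InvalidDeformationError):
        compute_invariants(-np.eye(3), (1, 0, 0))
    with pytest.raises(NormalizationError):
        compute_invariants(np.eye(3), (1, 1, 0))


@settings(derandomize=True, max_examples=30)
@given(st.floats(min_value=0.2, max_value=3.0))
def test_pure_dilation_leaves_isochoric_invariants(c):
    """Any pure dilation has Ibar1 = 3 and unit isochoric fiber stretch."""
    s = compute_invariants(c * np.eye(3), (0, 1, 0))
    assert s.Ibar1 == pytest.approx(3.0, abs=1e-12)
    assert s.lambdabar_f == pytest.approx(1.0, abs=1e-12)


def test_energy_and_stress_vanish_at_reference():
    s = compute_invariants(np.eye(3), (1, 0, 0))
    assert martins_energy(s, TABLE) == 0.0
    assert neo_hookean_energy(s, NeoHookeanParams()) == 0.0
    assert np.allclose(martins_cauchy_stress(s, TABLE), 0.0, atol=1e-15)
    assert np.allclose(neo_hookean_stress(s, NeoHookeanParams()), 0.0, atol=1e-15)


def test_martins_energy_uniaxial_parts():
    """Energy contributions at incompressible stretch 1.1 along the fiber,
    frozen from direct evaluation of the closed forms with the published
    constants."""
    s = compute_invariants(uniaxial_isochoric_F(1.1), (1, 0, 0))
    parts = martins_energy_parts(s, TABLE)
    assert parts["U_m"] == pytest.approx(6.21780e-4, rel=1e-4)
    assert parts["U_fPE"] == pytest.approx(1.74562e-4, rel=1e-4)
    assert parts["U_fSE"] == 0.0
    assert parts["U_J"] == pytest.approx(0.0, abs=1e-28)
    assert martins_energy(s, TABLE) == pytest.approx(7.96342e-4, rel=1e-4)


def test_active_term_inert_when_passive():
    """theta = 0 makes energy and stress independent of the max tension."""
    s = compute_invariants(uniaxial_isochoric_F(1.3), (1, 0, 0))
    lo = MartinsParams(T0M=1e-6)
    hi = MartinsParams(T0M=50.0)
    assert martins_energy(s, lo) == martins_energy(s, hi)
    assert np.array_equal(
        martins_cauchy_stress(s, lo), martins_cauchy_stress(s, hi)
    )
    active = MartinsParams(theta=0.5)
    assert martins_energy(s, active) > martins_energy(s, lo)


@pytest.mark.parametrize("model", ["martins", "neo_hookean"])
def test_analytic_stress_matches_oracle(model):
    """Analytic Cauchy stress equals central-difference differentiation of
    the strain energy on 20 seeded random isochoric states (rel 1e-5)."""
    if model == "martins":
        p = TABLE
        energy = lambda s: martins_energy(s, p)
        stress = lambda s: martins_cauchy_stress(s, p)
    else:
        p = NeoHookeanParams(c10=0.1)
        energy = lambda s: neo_hookean_energy(s, p)
        stress = lambda s: neo_hookean_stress(s, p)
    states = random_isochoric_states(20, seed=42)
    assert len(states) == 20
    for F, N in states:
        s = compute_invariants(F, N)
        ana = stress(s)
        num = numerical_stress_oracle(energy, s)
        scale = np.abs(ana).max()
        assert np.abs(ana - num).max() <= 1e-5 * max(scale, 1e-6)


def test_oracle_on_quadratic_energy():
    """U = k/2 ||F - I||^2 has zero stress at the reference."""
    s = compute_invariants(np.eye(3), (1, 0, 0))
    num = numerical_stress_oracle(
        lambda st_: 0.5 * 3.0 * np.sum((st_.F - np.eye(3)) ** 2), s
    )
    assert np.allclose(num, 0.0, atol=1e-8)


def test_oracle_step_domain():
    s = compute_invariants(np.eye(3), (1, 0, 0))
    with pytest.raises(ValueError):
        numerical_stress_oracle(lambda st_: 0.0, s, step=1e-2)


def test_neo_hookean_uniaxial_closed_form():
    s = compute_invariants(uniaxial_isochoric_F(1.5), (1, 0, 0))
    sig = neo_hookean_stress(s, NeoHookeanParams(c10=0.1),
                             pressure="from-traction-free-lateral")
    assert sig[0, 0] == pytest.approx(0.31667, rel=1e-4)
    assert sig[1, 1] == 0.0 and sig[2, 2] == 0.0
    assert neo_hookean_uniaxial_stress(1.5, NeoHookeanParams(c10=0.1)) == \
        pytest.approx(2 * 0.1 * (1.5 ** 2 - 1 / 1.5), rel=1e-12)


def test_pure_dilation_mean_stress():
    """With the deviatoric terms off, mean stress is (2/D)(J - 1)."""
    J = 1.01
    s = compute_invariants(J ** (1 / 3) * np.eye(3), (0, 0, 1))
    p = MartinsParams(c=0.0, A=0.0, D=0.1)
    sig = martins_cauchy_stress(s, p)
    assert np.trace(sig) / 3.0 == pytest.approx(0.2, rel=1e-12)


def test_traction_free_mode_rejects_non_uniaxial():
    s = compute_invariants(np.diag([1.2, 1.0, 1.0 / 1.2]), (1, 0, 0))
    with pytest.raises(ModeError):
        martins_cauchy_stress(s, TABLE, pressure="from-traction-free-lateral")


def test_uniaxial_convenience_matches_tensor_mode():
    lam = 1.4
    s = compute_invariants(uniaxial_isochoric_F(lam), (1, 0, 0))
    sig = martins_cauchy_stress(s, TABLE, pressure="from-traction-free-lateral")
    assert sig[0, 0] == pytest.approx(martins_uniaxial_stress(lam, TABLE), rel=1e-12)
    num = numerical_stress_oracle(lambda st_: martins_energy(st_, TABLE), s)
    axial_num = num[0, 0] - num[1, 1]  # impose traction-free laterals
    assert sig[0, 0] == pytest.approx(axial_num, rel=1e-5)


def test_small_strain_shear_modulus():
    """Matrix shear response at gamma = 1e-4 recovers mu = 2 c b within 1%."""
    gamma = 1e-4
    F = np.eye(3)
    F[0, 1] = gamma
    s = compute_invariants(F, (0, 0, 1))  # fiber unsheared
    sig = martins_cauchy_stress(s, TABLE)
    mu = 2 * TABLE.c * TABLE.b
    assert mu == pytest.approx(0.0434, rel=2e-3)
    assert sig[0, 1] / gamma == pytest.approx(mu, rel=0.01)


def test_objectivity_under_rotations():
    """Energy is invariant under 50 seeded random rotations R F."""
    from scipy.spatial.transform import Rotation

    F, N = random_isochoric_states(1, seed=7)[0]
    s0 = compute_invariants(F, N)
    u0 = martins_energy(s0, TABLE)
    rots = Rotation.random(50, random_state=11).as_matrix()
    for R in rots:
        u = martins_energy(compute_invariants(R @ F, N), TABLE)
        assert abs(u - u0) < 1e-12


@pytest.mark.parametrize(
    "eps, E, unit, expected",
    [(0.0, 23.8, "kPa", 0.0), (0.1, 23.8, "kPa", 2.38), (2.01, 23.8, "kPa", 47.838)],
)
def test_linear_elastic_values(eps, E, unit, expected):
    p = LinearElasticParams(E=E, nu=0.49, unit=unit)
    assert linear_elastic_stress(eps, p) == pytest.approx(expected, rel=1e-12)


def test_parameter_validation():
    with pytest.raises(ValueError):
        MartinsParams(b=-1.0)
    with pytest.raises(ValueError):
        MartinsParams(theta=1.5)
    with pytest.raises(ValueError):
        LinearElasticParams(E=1.0, nu=0.6)
    # c = A = 0 is allowed: matrix-only / fiber-only materials are valid
    MartinsParams(c=0.0)
    MartinsParams(A=0.0)
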