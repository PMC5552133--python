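"""Flow algebra: boundary conventions, special-case reductions, the
η-representation identity, and parameter validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from efrbm import (
    DegenerateInteractionWarning,
    EFRBMParams,
    ThermoSpec,
    effective_rates,
    flows,
    output_rate,
    padded_density,
    site_flow,
    thermo_to_qr,
    vector_field,
    vector_field_jacobian,
)


def rfm_rhs(lam, x):
    """Independent reference right-hand side of the plain ribosome flow
    model: dx_i/dt = λ_{i-1} x_{i-1} (1-x_i) - λ_i x_i (1-x_{i+1}) with
    x_0=1, x_{n+1}=0, written directly from that formula."""
    n = len(x)
    xx = np.concatenate([[1.0], x, [0.0]])
    out = np.empty(n)
    for i in range(1, n + 1):
        out[i - 1] = lam[i - 1] * xx[i - 1] * (1 - xx[i]) - lam[i] * xx[i] * (1 - xx[i + 1])
    return out


class TestPaddedDensity:
    @pytest.mark.parametrize(
        "i, expected",
        [(2, 0.7), (1, 0.3), (0, 0.0), (3, 0.0), (-1, 0.0), (4, 0.0)],
    )
    def test_padding_is_zero_outside_lattice(self, i, expected):
        assert padded_density([0.3, 0.7], i) == expected


class TestSiteFlow:
    def test_empty_lattice_entry_flow_is_initiation_rate(self):
        # x_0 ≡ 1 and all interaction paddings vanish on an empty lattice
        p = EFRBMParams(np.array([0.5, 0.8, 0.7, 0.6]), r=0.3, q=4.0)
        assert site_flow(p, np.zeros(3), 0) == pytest.approx(0.5, abs=1e-15)

    def test_hand_computed_interior_flow(self):
        # λ_2 x_2 (1-x_3) (1+(q-1)x_4) (1+(r-1)x_1)
        #   = 1 · 0.5 · 0.5 · (1 + 1·0.5) · (1 + 2·0.5) = 0.75
        lam = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        p = EFRBMParams(lam, r=3.0, q=2.0)
        assert site_flow(p, np.full(4, 0.5), 2) == pytest.approx(0.75, abs=1e-15)

    @pytest.mark.parametrize("i", [-1, 5])
    def test_flow_index_out_of_range_rejected(self, i):
        p = EFRBMParams(np.ones(5), r=1.0, q=1.0)
        with pytest.raises(IndexError):
            site_flow(p, np.full(4, 0.5), i)

    def test_flows_nonnegative_on_cube(self, rng):
        with pytest.warns(DegenerateInteractionWarning):
            p = EFRBMParams(np.array([0.5, 2.0, 1.0]), r=0.0, q=3.0)
        for _ in range(50):
            assert np.all(flows(p, rng.uniform(0, 1, 2)) >= 0)


class TestVectorField:
    def test_rfm_reduction_matches_reference_rhs(self, rng):
        lam = np.array([1.0, 1.2, 0.9, 4.0, 0.2, 1.0, 1.1])
        p = EFRBMParams(lam, r=1.0, q=1.0)
        for _ in range(100):
            x = rng.uniform(0, 1, 6)
            np.testing.assert_allclose(
                vector_field(p, x), rfm_rhs(lam, x), rtol=0, atol=1e-15
            )

    def test_extended_object_limit(self, rng):
        # q = r = 0: g_i = λ_i x_i (1-x_{i+1}) (1-z_{i+2}) (1-z_{i-1})
        lam = np.array([0.5, 0.8, 0.7, 0.6])
        with pytest.warns(DegenerateInteractionWarning):
            p = EFRBMParams(lam, r=0.0, q=0.0)
        for _ in range(20):
            x = rng.uniform(0, 1, 3)
            z = np.concatenate([[0.0, 0.0], x, [0.0, 0.0]])  # z[j+1] == z_j
            X = np.concatenate([[1.0], x, [0.0]])
            expected = np.array(
                [lam[i] * X[i] * (1 - X[i + 1]) * (1 - z[i + 3]) * (1 - z[i])
                 for i in range(4)]
            )
            np.testing.assert_allclose(flows(p, x), expected, atol=1e-15)

    @given(
        x=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        r=st.floats(0.01, 10),
        q=st.floats(0.01, 10),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_mass_balance_telescopes_exactly(self, x, r, q):
        # Σ_i dx_i/dt == g_0 - g_n identically (not just to rounding):
        # the interior flows cancel pairwise in the sum.
        p = EFRBMParams(np.array([0.5, 0.8, 0.7, 0.6]), r=r, q=q)
        x = np.asarray(x)
        g = flows(p, x)
        assert np.sum(vector_field(p, x)) == pytest.approx(g[0] - g[-1], abs=1e-12)

    def test_degenerate_boundary_continuum_is_stationary(self):
        # q=1, r=0, n=3: every [1, 1, s] is an equilibrium
        with pytest.warns(DegenerateInteractionWarning):
            p = EFRBMParams(np.array([0.5, 0.8, 0.7, 0.6]), r=0.0, q=1.0)
        for s in (0.0, 0.25, 0.5, 0.75, 1.0):
            assert np.all(vector_field(p, np.array([1.0, 1.0, s])) == 0.0)

    def test_output_rate_conventions(self):
        p = EFRBMParams(np.array([1.0, 2.0, 3.0]), r=4.0, q=0.25)
        assert output_rate(p, np.array([0.5, 0.0])) == 0.0
        # r=1 → plain λ_n x_n
        p_rfm = EFRBMParams(np.array([1.0, 2.0, 3.0]), r=1.0, q=1.0)
        assert output_rate(p_rfm, np.array([0.4, 0.6])) == pytest.approx(1.8)
        # n=1: the neighbor factor uses z_0 = 0 and drops out
        p1 = EFRBMParams(np.array([1.0, 2.0]), r=7.0, q=0.1)
        assert output_rate(p1, np.array([0.5])) == pytest.approx(1.0)

    def test_jacobian_matches_finite_differences(self, rng):
        p = EFRBMParams(np.array([0.5, 0.8, 0.7, 0.6, 1.3]), r=0.4, q=2.5)
        x = rng.uniform(0.1, 0.9, 4)
        J = vector_field_jacobian(p, x)
        h = 1e-7
        for j in range(4):
            dx = np.zeros(4)
            dx[j] = h
            fd = (vector_field(p, x + dx) - vector_field(p, x - dx)) / (2 * h)
            np.testing.assert_allclose(J[:, j], fd, rtol=1e-6, atol=1e-8)


class TestEffectiveRates:
    def test_no_interaction_gives_bare_rates(self):
        p = EFRBMParams(np.array([1.0, 2.0, 3.0, 4.0]), r=1.0, q=1.0)
        np.testing.assert_array_equal(
            effective_rates(p, np.array([0.2, 0.5, 0.9])), p.lambdas
        )

    def test_bounds_and_rfm_form_identity(self, rng):
        # a_i = min(1,q)min(1,r)λ_i ≤ η_i ≤ max(1,q)max(1,r)λ_i, and the
        # η-based RFM right-hand side reproduces the flow-based one exactly
        for _ in range(1000):
            n = int(rng.integers(1, 7))
            lam = np.exp(rng.uniform(-1.5, 1.5, n + 1))
            r, q = np.exp(rng.uniform(-2, 2, 2))
            p = EFRBMParams(lam, r=float(r), q=float(q))
            x = rng.uniform(0, 1, n)
            eta = effective_rates(p, x)
            lo = min(1, q) * min(1, r) * lam
            hi = max(1, q) * max(1, r) * lam
            assert np.all(eta >= lo - 1e-12) and np.all(eta <= hi + 1e-12)
            xx = np.concatenate([[1.0], x, [0.0]])
            rhs_eta = np.array(
                [eta[i - 1] * xx[i - 1] * (1 - xx[i]) - eta[i] * xx[i] * (1 - xx[i + 1])
                 for i in range(1, n + 1)]
            )
            np.testing.assert_allclose(rhs_eta, vector_field(p, x), rtol=1e-12, atol=1e-14)


class TestThermodynamicMap:
    def test_zero_energy_is_rfm(self):
        assert thermo_to_qr(0.0) == (1.0, 1.0)

    def test_closed_form_energy(self):
        q, r = thermo_to_qr(2 * np.log(5))
        assert q == pytest.approx(5.0, rel=1e-14)
        assert r == pytest.approx(0.2, rel=1e-14)

    @given(E=st.floats(-10, 10))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_detailed_balance_product(self, E):
        q, r = ThermoSpec(E).to_qr()
        assert q * r == pytest.approx(1.0, rel=1e-12)
        if E > 1e-8:
            assert q > 1 > r  # attractive
        elif E < -1e-8:
            assert q < 1 < r  # repulsive

    def test_thermodynamic_constructor_couples_qr(self):
        p = EFRBMParams.thermodynamic([1.0, 2.0, 3.0], E=1.7)
        assert p.q * p.r == pytest.approx(1.0, rel=1e-14)


class TestValidation:
    def test_nonpositive_rate_named_in_error(self):
        with pytest.raises(ValueError, match="λ_1"):
            EFRBMParams(np.array([1.0, -1.0, 2.0]), r=1.0, q=1.0)

    def test_negative_interaction_rejected(self):
        with pytest.raises(ValueError, match="r must be"):
            EFRBMParams(np.ones(3), r=-0.5, q=1.0)

    def test_single_rate_rejected(self):
        with pytest.raises(ValueError, match="n\\+1"):
            EFRBMParams(np.array([1.0]), r=1.0, q=1.0)

    def test_degenerate_interaction_warns(self):
        with pytest.warns(DegenerateInteractionWarning):
            EFRBMParams(np.ones(4), r=0.0, q=2.0)
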