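"""Superstructure model: regulation factors, algebraic subsystem, simulation."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.optimize import brentq

from kdpselect.kdp_model import (
    AlgebraicSolveError,
    ExperimentDesign,
    IntegratorSettings,
    KineticParameters,
    StructureVector,
    algebraic_residuals,
    initial_state,
    regulation_proteolysis,
    regulation_translation,
    rhs,
    simulate,
    solve_algebraic,
    stimulus_counteraction,
    N_ODE,
)
from kdpselect.synthetic_data import NOMINAL_STRUCTURE, nominal_parameters


# ---------------------------------------------------------------------------
# StructureVector


class TestStructureVector:
    @pytest.mark.parametrize("kwargs", [
        dict(bin1=2, bin2=0, bin3=0),
        dict(bin1=0, bin2=0, bin3=0, n1=4),
        dict(bin1=0, bin2=0, bin3=0, n4=-1),
        dict(bin1=0, bin2=0, bin3=0, n2=1.5),
    ])
    def test_rejects_out_of_range(self, kwargs):
        with pytest.raises(ValueError):
            StructureVector(**kwargs)

    def test_activity_rule(self):
        s = StructureVector(bin1=0, bin2=1, bin3=0, n2=1, n3=2, n4=3)
        assert s.active_exponents() == ("n2", "n3", "n4")
        assert "ktrans" not in s.active_reals()
        assert "kdeg" in s.active_reals()
        assert "Khy" not in s.active_reals()
        assert "khy" in s.active_reals()  # always active (wild strain)

    def test_canonical_zeroes_inactive(self):
        s = StructureVector(bin1=0, bin2=0, bin3=0, n1=3, n2=2, n3=1, n4=2, n5=3)
        assert s.canonical() == StructureVector(bin1=0, bin2=0, bin3=0, n4=2)

    def test_roundtrip_array(self):
        s = NOMINAL_STRUCTURE
        assert StructureVector.from_array(s.as_array()) == s


# ---------------------------------------------------------------------------
# Regulation factors


class TestRegulationFactors:
    def test_translation_off_is_unity(self, nominal):
        s = StructureVector(bin1=0, bin2=0, bin3=0)
        assert regulation_translation(123.0, s, nominal[1]) == 1.0

    def test_translation_at_zero_complex(self, nominal):
        # 1/(0^3 + 0.974) with the Table-value ktrans
        s = StructureVector(bin1=1, bin2=0, bin3=0, n1=3)
        p = nominal[1].replace(ktrans=0.974)
        assert regulation_translation(0.0, s, p) == pytest.approx(1 / 0.974, rel=1e-12)

    def test_translation_vanishes_at_large_F(self, nominal):
        s = StructureVector(bin1=1, bin2=0, bin3=0, n1=2)
        vals = [regulation_translation(F, s, nominal[1]) for F in (1.0, 10.0, 1e6)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-10

    def test_translation_rejects_nonfinite(self, nominal):
        s = StructureVector(bin1=1, bin2=0, bin3=0, n1=1)
        with pytest.raises(ValueError):
            regulation_translation(float("nan"), s, nominal[1])

    def test_proteolysis_off_is_unity(self, nominal):
        s = StructureVector(bin1=0, bin2=0, bin3=0)
        assert regulation_proteolysis(5.0, s, nominal[1]) == 1.0

    def test_proteolysis_hand_value(self, nominal):
        # F^1/(F^2 + 0.136) at F=1 -> 1/1.136
        s = StructureVector(bin1=0, bin2=1, bin3=0, n2=1, n3=2)
        p = nominal[1].replace(kdeg=0.136)
        assert regulation_proteolysis(1.0, s, p) == pytest.approx(1 / 1.136, rel=1e-12)

    def test_proteolysis_equal_orders_limit(self, nominal):
        s = StructureVector(bin1=0, bin2=1, bin3=0, n2=2, n3=2)
        p = nominal[1].replace(kdeg=1e-14)
        assert regulation_proteolysis(0.7, s, p) == pytest.approx(1.0, rel=1e-9)

    def test_counteraction_mutant_ignores_feedback(self, nominal):
        _, p = nominal
        vals = {
            stimulus_counteraction(2.0, "mutant", StructureVector(1, 1, b3, 1, 1, 1, n4, n5),
                                   p.replace(khy=k, Khy=K), 10.0)
            for b3 in (0, 1) for n4 in (0, 3) for n5 in (0, 2)
            for k in (1.0, 1e6) for K in (0.5, 2.0)
        }
        assert len(vals) == 1

    def test_counteraction_wild_reduces_to_mutant(self, nominal):
        _, p = nominal
        s = StructureVector(1, 1, 0, n4=3)
        tiny = p.replace(khy=1e-300)
        assert stimulus_counteraction(2.0, "wild", s, tiny, 10.0) == pytest.approx(
            stimulus_counteraction(2.0, "mutant", s, tiny, 10.0), rel=1e-12
        )

    @pytest.mark.parametrize("F", [0.0, 0.3, 1.7, 42.0])
    def test_counteraction_saturating_form_degeneracy(self, nominal, F):
        # with n5=0 the saturating form is the linear form scaled by 1/(1+Khy)
        _, p = nominal
        base = stimulus_counteraction(F, "mutant", NOMINAL_STRUCTURE, p, 10.0)
        lin = stimulus_counteraction(
            F, "wild", StructureVector(1, 1, 0, 3, 1, 2, 3, 0), p, 10.0) - base
        sat = stimulus_counteraction(
            F, "wild", StructureVector(1, 1, 1, 3, 1, 2, 3, 0), p, 10.0) - base
        assert sat == pytest.approx(lin / (1.0 + p.Khy), rel=1e-12)

    def test_counteraction_rejects_unknown_strain(self, nominal):
        with pytest.raises(ValueError):
            stimulus_counteraction(1.0, "hybrid", NOMINAL_STRUCTURE, nominal[1], 10.0)


# ---------------------------------------------------------------------------
# Algebraic subsystem


def _oracle_algebraic(EP, p):
    """Independent bracketing solution: eliminate DNAf, bisect the KdpEfP residual."""
    cc = (1.0 + 1.0 / (p.alpha * p.K)) / p.Ka

    def f(E):
        DNAf = p.DNA0 / (1.0 + 1.0 / p.K + cc * E * E)
        return EP - E - 2.0 * cc * E * E * DNAf

    if EP == 0.0:
        return 0.0
    return brentq(f, 0.0, EP, xtol=1e-300, rtol=8.9e-16, maxiter=500)


class TestAlgebraicSubsystem:
    def test_zero_regulator(self, nominal):
        _, p = nominal
        E, DNAf = solve_algebraic(0.0, p)
        assert E == 0.0
        assert DNAf == pytest.approx(p.DNA0 / (1.0 + 1.0 / p.K), rel=1e-14)

    @given(logEP=st.floats(-9.0, 1.0))
    @hyp_settings(max_examples=50, deadline=None)
    def test_residuals_below_tolerance(self, logEP):
        _, p = nominal_parameters()
        EP = 10.0**logEP
        E, DNAf = solve_algebraic(EP, p)
        assert 0.0 <= E <= EP
        assert 0.0 < DNAf <= p.DNA0
        r1, r2 = algebraic_residuals(EP, E, DNAf, p)
        assert max(abs(r1), abs(r2)) < 1e-10

    @given(
        logEP=st.floats(-8.0, 0.0),
        logKa=st.floats(-9.0, -4.0),
        logDNA0=st.floats(-6.0, -2.0),
        logK=st.floats(0.0, 4.0),
        alpha=st.floats(1e-3, 1.0),
    )
    @hyp_settings(max_examples=60, deadline=None)
    def test_matches_bisection_oracle(self, logEP, logKa, logDNA0, logK, alpha):
        _, p0 = nominal_parameters()
        p = p0.replace(Ka=10.0**logKa, DNA0=10.0**logDNA0, K=10.0**logK, alpha=alpha)
        EP = 10.0**logEP
        E, _ = solve_algebraic(EP, p)
        E_oracle = _oracle_algebraic(EP, p)
        assert E == pytest.approx(E_oracle, rel=1e-8, abs=1e-300)

    def test_invalid_input_raises(self, nominal):
        with pytest.raises(AlgebraicSolveError):
            solve_algebraic(float("nan"), nominal[1])


# ---------------------------------------------------------------------------
# Right-hand side and simulation


def _reference_rhs(y, s, p, strain, Kplus):
    """Slow, independent transcription-circuit right-hand side for cross-checking."""
    m, D0, E0, EP, F = [max(v, 0.0) for v in y]
    cc = (1.0 + 1.0 / (p.alpha * p.K)) / p.Ka

    def res(E):
        DNAf = p.DNA0 / (1.0 + 1.0 / p.K + cc * E * E)
        return EP - E - 2.0 * cc * E * E * DNAf

    E = brentq(res, 0.0, EP, rtol=8.9e-16) if EP > 0 else 0.0
    DNAf = p.DNA0 / (1.0 + 1.0 / p.K + cc * E * E)
    trans = p.ktr * (DNAf / p.K) * (1.0 + E * E / (p.alpha * p.Ka)) / p.DNA0
    R1 = regulation_translation(F, s, p)
    R2 = regulation_proteolysis(F, s, p)
    k3f = stimulus_counteraction(F, strain, s, p, Kplus)
    return np.array([
        trans - (p.kz + p.mu) * m,
        p.ktl * m - (p.kd + p.mu) * D0,
        p.ktl2 * m - (p.kd + p.mu) * E0,
        p.k2 * p.KdpDP_const * (E0 - EP)
        - (p.kd + k3f + p.kminus2 * max(D0 - p.KdpDP_const, 0.0)) * EP,
        p.ktl3 * m * R1 - (p.kd2 * R2 + p.mu) * F,
    ])


class TestRhs:
    @given(
        scale=st.floats(0.1, 10.0),
        bin1=st.integers(0, 1), bin2=st.integers(0, 1), bin3=st.integers(0, 1),
        n=st.tuples(*[st.integers(0, 3)] * 5),
        wild=st.booleans(),
    )
    @hyp_settings(max_examples=40, deadline=None)
    def test_matches_reference_implementation(self, scale, bin1, bin2, bin3, n, wild):
        _, p = nominal_parameters()
        s = StructureVector(bin1, bin2, bin3, *n)
        strain = "wild" if wild else "mutant"
        design = ExperimentDesign(strain, 10.0, (0.0, 1.0))
        y = scale * np.array([2e-2, 60.0, 12.0, 1e-4, 1.5])
        got = rhs(0.0, y, s, p, design)
        want = _reference_rhs(y, s, p, strain, 10.0)
        # the two independent algebraic root solvers agree to ~1e-9
        np.testing.assert_allclose(got, want, rtol=1e-7)

    def test_vanishes_at_steady_state(self, nominal):
        s, p = nominal
        y0 = initial_state(s, p, "wild")
        design = ExperimentDesign("wild", IntegratorSettings().prestimulus_Kplus, (0.0, 1.0))
        dy = rhs(0.0, y0, s, p, design)
        assert np.max(np.abs(dy) / (np.abs(y0) + 1e-12)) < 1e-6

    def test_rejects_bad_state(self, nominal, wild_design):
        s, p = nominal
        with pytest.raises(ValueError):
            rhs(0.0, [1.0, 2.0, np.nan, 0.0, 0.0], s, p, wild_design)


class TestSimulate:
    def test_mutant_invariant_to_feedback_switches(self, nominal, mutant_design):
        _, p = nominal
        base = simulate(StructureVector(1, 1, 0, 3, 1, 2, 3, 0), p, mutant_design)
        for s2, p2 in [
            (StructureVector(1, 1, 1, 3, 1, 2, 0, 2), p),
            (StructureVector(1, 1, 0, 3, 1, 2, 1, 0), p.replace(khy=3.3e4)),
            (StructureVector(1, 1, 1, 3, 1, 2, 3, 1), p.replace(Khy=17.0)),
        ]:
            other = simulate(s2, p2, mutant_design)
            np.testing.assert_array_equal(base.states, other.states)

    def test_nested_structures_ignore_inactive_entries(self, nominal, wild_design):
        _, p = nominal
        s_off = StructureVector(0, 0, 0, n4=3)
        base = simulate(s_off, p, wild_design)
        varied = simulate(
            StructureVector(0, 0, 0, n1=2, n2=1, n3=3, n4=3, n5=0).canonical(),
            p.replace(ktrans=0.123, kdeg=4.56, Khy=7.8), wild_design,
        )
        np.testing.assert_array_equal(base.states, varied.states)

    def test_states_nonnegative_and_algebraic_consistent(self, nominal, wild_design):
        s, p = nominal
        tr = simulate(s, p, wild_design)
        assert tr.ok
        assert np.all(tr.states >= 0.0)
        assert np.all(tr.get("DNAf") <= p.DNA0)
        assert np.all(tr.get("KdpEfP") <= tr.get("KdpEP") + 1e-15)
        for EP, E, DNAf in zip(tr.get("KdpEP"), tr.get("KdpEfP"), tr.get("DNAf")):
            r1, r2 = algebraic_residuals(EP, E, DNAf, p)
            assert max(abs(r1), abs(r2)) < 1e-8

    def test_self_convergence_under_tighter_tolerances(self, nominal, wild_design):
        s, p = nominal
        loose = simulate(s, p, wild_design, IntegratorSettings(rtol=1e-8, atol=1e-12))
        tight = simulate(s, p, wild_design, IntegratorSettings(rtol=1e-9, atol=1e-13))
        scale = np.abs(tight.states) + 1e-30
        rel = np.abs(loose.states - tight.states) / scale
        # states far above integration noise must agree tightly
        mask = np.abs(tight.states) > 1e3 * 1e-12
        assert np.max(rel[mask]) < 1e-4

    def test_finite_difference_consistency_with_rhs(self, nominal):
        s, p = nominal
        grid = tuple(np.linspace(0.0, 0.5, 201))
        design = ExperimentDesign("mutant", 10.0, grid)
        tr = simulate(s, p, design)
        y = tr.states[:N_ODE]
        h = grid[1] - grid[0]
        mid = (y[:, 2:] - y[:, :-2]) / (2.0 * h)
        # skip the initial boundary layer: the fast KdpEP balance relaxes on
        # ~1e-4 h, far below the finite-difference step, and compare each
        # state against its own derivative scale over the checked window
        ks = list(range(9, len(grid) - 1, 10))
        row_scale = np.max(np.abs(mid[:, [k - 1 for k in ks]]), axis=1)
        for k in ks:
            dy = rhs(grid[k], y[:, k], s, p, design)
            assert np.all(np.abs(mid[:, k - 1] - dy) <= 5e-3 * row_scale + 1e-12)

    def test_failure_is_flagged_not_raised(self, nominal, wild_design):
        _, p = nominal
        # an absurdly stiff parameter corner exhausts the work budget
        bad = p.replace(k2=1e15, k3=1e12)
        tr = simulate(NOMINAL_STRUCTURE, bad, wild_design,
                      IntegratorSettings(max_rhs_calls=500))
        assert not tr.ok
        assert tr.message


class TestTrajectoryExport:
    def test_long_format_frame(self, nominal, wild_design):
        s, p = nominal
        tr = simulate(s, p, wild_design)
        df = tr.to_frame("wild_K10")
        assert len(df) == 7 * len(wild_design.t_grid)
        assert set(df["state"]) == {"mRNA", "KdpD0", "KdpE0", "KdpEP",
                                    "KdpFABC", "KdpEfP", "DNAf"}
        sub = df[df["state"] == "mRNA"]["value"].to_numpy()
        np.testing.assert_array_equal(sub, tr.get("mRNA"))


class TestInitialState:
    def test_user_vector_passthrough(self, nominal):
        s, p = nominal
        y0 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = initial_state(s, p, "wild", y0=y0)
        np.testing.assert_array_equal(out, y0)
        assert out is not y0

    def test_steady_state_is_fixed_point(self, nominal):
        s, p = nominal
        y0 = initial_state(s, p, "mutant")
        settings = IntegratorSettings()
        design = ExperimentDesign("mutant", settings.prestimulus_Kplus,
                                  (0.0, 10.0, 25.0, 50.0))
        tr = simulate(s, p, design, settings, y0=y0)
        rel = np.abs(tr.states[:N_ODE, -1] - y0) / (np.abs(y0) + 1e-12)
        assert np.max(rel) < 1e-6
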