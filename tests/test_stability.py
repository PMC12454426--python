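"""Jacobian structure, vertex classification and the feasibility search."""

import numpy as np
import pytest

from carbongame.errors import ConfigurationError
from carbongame.payoffs import PROFILES, build_payoff_tensor
from carbongame.replicator import replicator_rhs
from carbongame.stability import (
    classify_equilibria,
    condition_table,
    ess_feasibility,
    feasible_strict_profiles,
    jacobian,
    report_frame,
    symbolic_vertex_eigenvalues,
    vertex_eigenvalues,
)

from conftest import random_params


class TestJacobian:
    def test_diagonal_at_vertices(self, baseline_tensor):
        for vertex in PROFILES:
            J = jacobian(baseline_tensor, vertex)
            off = J - np.diag(np.diag(J))
            np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_baseline_diagonal_at_ess_vertex(self, baseline_tensor):
        # (C_g - a D_h - k_g, D_h - C_h - S_h + R_h + 2 k_h,
        #  -(D_c + 2 k_c - S_c - C_c), (a - 1) D_h + C_p)
        np.testing.assert_allclose(
            vertex_eigenvalues(baseline_tensor, (1, 0, 1, 1)), [-2, -2, -10, -2], atol=1e-12
        )

    def test_matches_central_finite_differences(self, rng):
        eps = 1e-6
        for _ in range(4):
            tensor = build_payoff_tensor(random_params(rng))
            for _ in range(25):
                s = rng.uniform(0.05, 0.95, size=4)
                J = jacobian(tensor, s)
                num = np.empty((4, 4))
                for j in range(4):
                    hi, lo = s.copy(), s.copy()
                    hi[j] += eps
                    lo[j] -= eps
                    num[:, j] = (replicator_rhs(tensor, hi) - replicator_rhs(tensor, lo)) / (2 * eps)
                np.testing.assert_allclose(J, num, rtol=1e-4, atol=1e-6)

    def test_symbolic_vertex_eigenvalues_match_numeric(self, rng):
        import sympy as sp

        for vertex in [(1, 0, 1, 1), (0, 0, 0, 0), (1, 1, 0, 1)]:
            exprs = symbolic_vertex_eigenvalues(vertex)
            for _ in range(5):
                params = random_params(rng)
                tensor = build_payoff_tensor(params)
                numeric = vertex_eigenvalues(tensor, vertex)
                subs = {sp.Symbol(k, positive=True): v for k, v in params.to_dict().items()}
                symbolic = [float(e.subs(subs)) for e in exprs]
                np.testing.assert_allclose(numeric, symbolic, rtol=1e-10, atol=1e-10)


class TestClassification:
    def test_baseline_has_unique_ess(self, baseline_tensor):
        reports = classify_equilibria(baseline_tensor)
        ess = [r.vertex for r in reports if r.label == "ESS"]
        assert ess == [(1, 0, 1, 1)]

    def test_strict_strong_sd_nonparticipating_always_unstable(self, rng):
        # eigenvalue C_g + R_c + R_h > 0 for every admissible parameter set
        for _ in range(20):
            tensor = build_payoff_tensor(random_params(rng))
            eigs = vertex_eigenvalues(tensor, (1, 1, 1, 0))
            assert eigs[0] > 0

    def test_all_passive_vertex_becomes_ess_at_high_regulation_cost(self, baseline):
        tensor = build_payoff_tensor(baseline.with_updates(C_g=20.0))
        reports = {r.vertex: r for r in classify_equilibria(tensor)}
        rep = reports[(0, 0, 0, 0)]
        assert rep.label == "ESS"
        np.testing.assert_allclose(rep.eigenvalues, [-8, -14, -8, -1], atol=1e-12)

    def test_loose_regulation_vertices_unstable_except_origin(self, rng):
        for _ in range(20):
            tensor = build_payoff_tensor(random_params(rng))
            for r in classify_equilibria(tensor):
                if r.vertex[0] == 0 and r.vertex != (0, 0, 0, 0):
                    assert r.label == "unstable"

    def test_labels_invariant_to_nonentering_parameters(self, baseline, rng):
        base_labels = [r.label for r in classify_equilibria(build_payoff_tensor(baseline))]
        for name in ("R_g", "L_g", "L_p", "S_p"):
            bumped = baseline.with_updates(**{name: getattr(baseline, name) + 5.0})
            labels = [r.label for r in classify_equilibria(build_payoff_tensor(bumped))]
            assert labels == base_labels

    def test_report_frame_layout(self, baseline_tensor):
        frame = report_frame(classify_equilibria(baseline_tensor))
        assert list(frame.columns) == ["vertex", "eig1", "eig2", "eig3", "eig4", "label"]
        assert len(frame) == 16


class TestConditionTable:
    def test_baseline_convergence_conditions_hold(self, baseline):
        table = condition_table(baseline)
        row = table[(table.vertex == "1011") & (table.eigenvalue == "lambda1")].iloc[0]
        assert row.printed_value == pytest.approx(-2.0)  # C_g - a D_h - k_g
        assert row.condition_holds
        row2 = table[(table.vertex == "1011") & (table.eigenvalue == "lambda2")].iloc[0]
        assert row2.printed_value == pytest.approx(-2.0)  # D_h - C_h - S_h + R_h + 2 k_h
        assert row2.condition_holds

    def test_known_typos_are_flagged_not_fixed(self, baseline):
        """The published strict-regulation table has four formula-level
        mismatches against the tensor-derived eigenvalues: a D_h that should
        be D_c in rows (1,1,0,0)/(1,1,0,1), a sign slip in row (1,0,1,1)'s
        fourth eigenvalue, and a k_c that should be k_h in row (1,1,1,1)."""
        table = condition_table(baseline)
        flagged = set(
            map(tuple, table[~table.consistent][["vertex", "eigenvalue"]].itertuples(index=False))
        )
        assert flagged == {
            ("1011", "lambda4"),
            ("1100", "lambda4"),
            ("1101", "lambda4"),
            ("1111", "lambda2"),
        }

    def test_loose_regulation_rows_all_consistent(self, baseline):
        table = condition_table(baseline)
        loose = table[table.vertex.str.startswith("0")]
        assert loose.consistent.all()


class TestFeasibility:
    def test_full_participation_vertex_infeasible_by_shortcut(self):
        res = ess_feasibility((1, 1, 1, 1), n_draws=1000, seed=1)
        assert not res.feasible
        assert res.shortcut is not None and "C_p" in res.shortcut

    def test_strict_strong_sd_nonparticipating_infeasible_by_shortcut(self):
        res = ess_feasibility((1, 1, 1, 0), n_draws=1000, seed=1)
        assert not res.feasible
        assert res.shortcut is not None

    def test_strict_all_passive_feasible_with_valid_witness(self):
        res = ess_feasibility((1, 0, 0, 0), n_draws=20000, seed=3)
        assert res.feasible
        eigs = vertex_eigenvalues(build_payoff_tensor(res.witness), (1, 0, 0, 0))
        assert np.all(eigs < 0)

    def test_six_strict_profiles_feasible_three_with_participation(self):
        results = feasible_strict_profiles(n_draws=20000, seed=11)
        feasible = [r.profile for r in results if r.feasible]
        assert len(feasible) == 6
        assert sum(1 for v in feasible if v[3] == 1) == 3
        assert (1, 1, 1, 0) not in feasible and (1, 1, 1, 1) not in feasible

    def test_zero_draws_rejected(self):
        with pytest.raises(ConfigurationError):
            ess_feasibility((1, 0, 0, 0), n_draws=0)
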