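"""Structural identifiability: Lie derivatives, rank test, solution counts."""

import numpy as np
import pytest
import sympy as sp

import odeident as oi
from odeident.structural import (BudgetExceededError, LOCALLY_IDENTIFIABLE,
                                 NON_IDENTIFIABLE, input_derivative_symbol)


def _sym(n):
    return sp.Symbol(n, real=True)


class TestLieDerivatives:
    def test_order_zero_returns_measured_outputs(self, monod_haldane):
        setup = oi.ObservationSetup(("y1", "y2"))
        rows = oi.lie_derivatives(monod_haldane, setup, 0)
        assert rows == [monod_haldane.outputs["y1"], monod_haldane.outputs["y2"]]

    def test_twocomp_first_order(self, twocomp):
        rows = oi.lie_derivatives(twocomp, oi.ObservationSetup(("y",)), 1)
        x1, x2, p1, p2 = (_sym(n) for n in ("x1", "x2", "p1", "p2"))
        assert rows[0] == x2
        assert sp.simplify(rows[1] - (p1 * x1 - p2 * x2)) == 0

    def test_constant_input_class_has_no_input_derivatives(self, monod_haldane):
        setup = oi.ObservationSetup(("y1",), input_class="constant")
        rows = oi.lie_derivatives(monod_haldane, setup, 2)
        free = set().union(*(r.free_symbols for r in rows))
        assert input_derivative_symbol("u", 1) not in free
        assert input_derivative_symbol("u", 2) not in free

    def test_generic_smooth_introduces_input_derivatives(self, monod_haldane):
        # u enters dx2/dt, so u' appears in the second derivative of y2
        setup = oi.ObservationSetup(("y2",))
        rows = oi.lie_derivatives(monod_haldane, setup, 2)
        free = set().union(*(r.free_symbols for r in rows))
        assert input_derivative_symbol("u", 1) in free

    def test_node_budget_guard(self, methanogenesis):
        setup = oi.ObservationSetup(("xH2", "ng_H2"))
        with pytest.raises(BudgetExceededError):
            oi.lie_derivatives(methanogenesis, setup, 6, node_budget=50)


class TestRankVerdicts:
    def test_twocomp_locally_identifiable_with_unknown_ic(self, twocomp):
        res = oi.test_local_identifiability(twocomp)
        assert res.generic_rank == res.n_unknowns == 3
        assert res.per_quantity_verdict == {
            "p1": LOCALLY_IDENTIFIABLE,
            "p2": LOCALLY_IDENTIFIABLE,
            "x1(0)": LOCALLY_IDENTIFIABLE,
        }
        assert oi.nullspace_directions(res) == []

    def test_betacasein_rank_deficiency_one(self, betacasein_structural):
        res = betacasein_structural
        assert res.n_unknowns == 3
        assert res.generic_rank == 2
        assert set(res.non_identifiable()) == {"k", "Km", "kI"}
        assert len(res.nullspace_basis) == 1

    def test_betacasein_reduced_identifiable(self, betacasein_reduced):
        res = oi.test_local_identifiability(betacasein_reduced)
        assert res.all_identifiable
        assert set(res.identifiable()) == {"b1", "b2"}

    def test_rank_invariant_across_seeds(self, betacasein):
        ranks = {
            oi.test_local_identifiability(betacasein, seed=s).generic_rank
            for s in (1, 2, 3)
        }
        assert ranks == {2}

    def test_methanogenesis_two_output_split(self, methano_two_output):
        res = methano_two_output
        assert set(res.identifiable()) == {"mu_max", "Ks", "kd", "Y"}
        assert set(res.non_identifiable()) == {"YCO2", "YCH4"}

    def test_methanogenesis_all_outputs_all_identifiable(self, methano_four_output):
        assert methano_four_output.all_identifiable
        assert methano_four_output.n_unknowns == 6

    def test_adding_outputs_never_hurts(self, methano_two_output,
                                         methano_four_output):
        """Monotonicity: a larger measurement set cannot decrease the rank
        or flip a verdict from identifiable to non-identifiable."""
        assert methano_four_output.generic_rank >= methano_two_output.generic_rank
        for q in methano_two_output.identifiable():
            assert methano_four_output.per_quantity_verdict[q] == LOCALLY_IDENTIFIABLE

    def test_absent_symbol_is_non_identifiable(self, methanogenesis,
                                               methano_two_output):
        """YCH4 appears in no Lie derivative of {xH2, ng_H2}; the verdict
        must be non-identifiable and its null direction a coordinate axis."""
        setup = oi.ObservationSetup(("xH2", "ng_H2"))
        rows = oi.lie_derivatives(methanogenesis, setup, 3)
        free = set().union(*(r.free_symbols for r in rows))
        assert _sym("YCH4") not in free
        assert methano_two_output.per_quantity_verdict["YCH4"] == NON_IDENTIFIABLE


class TestNullspace:
    def test_betacasein_null_vector_matches_reparameterization(
            self, betacasein_structural):
        """The null direction must be orthogonal to the gradients of the
        identifiable combinations b1(k,Km,kI), b2(k,Km,kI) at the
        evaluation point (independent oracle: symbolic Jacobian of the
        reduction map)."""
        res = betacasein_structural
        (vec,) = res.nullspace_basis
        k, Km, kI, x0 = (_sym(n) for n in ("k", "Km", "kI", "x0"))
        b1 = k * kI / (Km - kI)
        b2 = Km * (kI + x0) / (Km - kI)
        J = sp.Matrix([b1, b2]).jacobian([k, Km, kI]).xreplace(res._point)
        residual = J * sp.Matrix(vec)
        assert all(sp.simplify(e) == 0 for e in residual)

    def test_methanogenesis_null_vectors_are_yield_axes(self, methano_two_output):
        basis = oi.nullspace_directions(methano_two_output)
        names = methano_two_output.unknown_names
        supports = {
            tuple(names[i] for i, e in enumerate(v) if e != 0) for v in basis
        }
        assert supports == {("YCO2",), ("YCH4",)}

    def test_full_rank_result_has_empty_nullspace(self, betacasein_reduced):
        res = oi.test_local_identifiability(betacasein_reduced)
        assert oi.nullspace_directions(res) == []


class TestSolutionCounting:
    def test_twocomp_two_swapped_solutions(self, twocomp):
        sc = oi.count_output_equivalent_params(twocomp, seed=23)
        assert sc.count == 2
        sols = sorted(sc.witnesses, key=lambda w: float(w["p1"]))
        # p1 and p2 exchanged between the two solutions, x1(0) adjusted
        assert sols[0]["p1"] == sols[1]["p2"]
        assert sols[0]["p2"] == sols[1]["p1"]
        assert sols[0]["x1"] != sols[1]["x1"]

    def test_twocomp_unique_with_known_ic(self, twocomp):
        setup = oi.ObservationSetup(("y",), {"x1": 5.0})
        sc = oi.count_output_equivalent_params(twocomp, setup, seed=23)
        assert sc.count == 1

    def test_betacasein_reduced_globally_unique(self, betacasein_reduced):
        sc = oi.count_output_equivalent_params(betacasein_reduced, seed=5)
        assert sc.count == 1

    def test_guard_rejects_large_models(self, methanogenesis):
        with pytest.raises(Exception, match="guard"):
            oi.count_output_equivalent_params(methanogenesis)

    def test_count_is_seed_independent(self, twocomp):
        counts = {
            oi.count_output_equivalent_params(twocomp, seed=s).count
            for s in (7, 101)
        }
        assert counts == {2}
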