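"""Unified cut-off analysis: interpolation, crossings, AOX, reciprocals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from indexroc import (
    AnnotatedCurve,
    CohortSpec,
    CurveKind,
    CurvePoint,
    IndexCutoffDiagram,
    ThresholdGrid,
    aox,
    generate_cohort,
    group_se_sp,
    index_cutoff_diagram,
    interpolate_index,
    max_index_point,
    reciprocal_diagram,
    unified_cutoff,
    unified_min_curve,
)
from indexroc.metrics import bayes_predictive_values, psi_index, youden_index


def line_curve(nodes, kind=CurveKind.INDEX_CUTOFF) -> AnnotatedCurve:
    pts = [CurvePoint(cutoff=float(c), x=float(c), y=float(y)) for c, y in nodes]
    return AnnotatedCurve(kind=kind, points=pts, axis_labels=("cut-off (µg/L)", "index"))


def diagram_from(j_nodes, psi_nodes) -> IndexCutoffDiagram:
    return IndexCutoffDiagram(j_curve=line_curve(j_nodes), psi_curve=line_curve(psi_nodes))


class TestInterpolation:
    def test_exact_at_node(self):
        c = line_curve([(5, 0.2), (10, 0.425), (30, 0.3)])
        assert interpolate_index(c, 10) == 0.425

    def test_linearity_preserved(self):
        c = line_curve([(0, 0.0), (100, 1.0)])
        assert interpolate_index(c, 43) == pytest.approx(0.43, abs=1e-15)

    def test_midpoint(self):
        c = line_curve([(10, 0.4), (30, 0.2)])
        assert interpolate_index(c, 20) == pytest.approx(0.3, abs=1e-15)

    def test_no_extrapolation(self):
        c = line_curve([(10, 0.4), (30, 0.2)])
        with pytest.raises(ValueError, match="outside curve span"):
            interpolate_index(c, 5)

    @given(st.floats(min_value=10, max_value=30))
    @settings(derandomize=True)
    def test_sandwich_between_bracketing_nodes(self, q):
        c = line_curve([(10, 0.4), (20, -0.1), (30, 0.2)])
        v = interpolate_index(c, q)
        i = 0 if q <= 20 else 1
        lo = min(c.points[i].y, c.points[i + 1].y)
        hi = max(c.points[i].y, c.points[i + 1].y)
        assert lo - 1e-12 <= v <= hi + 1e-12


class TestUnifiedCutoff:
    def test_analytic_crossing(self):
        d = diagram_from(
            [(0, 1.0), (100, 0.0)],  # J = 1 − c/100
            [(0, 0.0), (100, 1.0)],  # PSI = c/100
        )
        res = unified_cutoff(d)
        assert res.method == "crossing"
        assert res.cutoff_star == pytest.approx(50.0, abs=1e-6)
        assert res.index_star == pytest.approx(0.5, abs=1e-6)

    def test_segment_intersection_closed_form(self):
        """Bisection agrees with solving the two straddling segments
        analytically."""
        j_nodes = [(10, 0.60), (30, 0.50), (50, 0.20), (90, 0.10)]
        psi_nodes = [(10, 0.10), (30, 0.30), (50, 0.45), (90, 0.70)]
        d = diagram_from(j_nodes, psi_nodes)
        res = unified_cutoff(d)
        # crossing lies in [30, 50]: J: 0.50→0.20, PSI: 0.30→0.45 over 20 µg/L
        # 0.50 − 0.015 t = 0.30 + 0.0075 t  →  t = 0.20/0.0225
        t = 0.20 / 0.0225
        assert res.cutoff_star == pytest.approx(30 + t, abs=1e-6)
        assert res.index_star == pytest.approx(0.50 - 0.015 * t, abs=1e-6)
        assert res.bracket == (30.0, 50.0)

    def test_multiple_crossings_primary_maximises_index(self):
        d = diagram_from(
            [(0, 0.8), (50, 0.0), (100, 0.8)],
            [(0, 0.4), (50, 0.4), (100, 0.4)],
        )
        res = unified_cutoff(d)
        assert len(res.all_crossings) == 2
        assert res.index_star == pytest.approx(0.4, abs=1e-6)
        assert res.cutoff_star == pytest.approx(25.0, abs=1e-4)

    def test_coincident_curves_flagged(self):
        nodes = [(0, 0.1), (50, 0.4), (100, 0.2)]
        res = unified_cutoff(diagram_from(nodes, nodes))
        assert res.method == "coincident"
        assert res.cutoff_star is None

    def test_no_crossing_returns_argmin_gap(self):
        d = diagram_from(
            [(0, 0.9), (50, 0.7), (100, 0.8)],
            [(0, 0.1), (50, 0.5), (100, 0.2)],
        )
        res = unified_cutoff(d)
        assert res.method == "no-crossing"
        assert res.cutoff_star == 50.0

    def test_disjoint_spans_rejected(self):
        d = diagram_from([(0, 0.5), (10, 0.4)], [(20, 0.1), (30, 0.2)])
        with pytest.raises(ValueError, match="disjoint"):
            unified_cutoff(d)

    def test_recovers_bayes_analytic_crossing_under_grid_refinement(self):
        """On smooth population curves from known lognormal mixtures the
        located crossing converges to the analytic J(c) = PSI(c) root as the
        grid refines."""
        from scipy.optimize import brentq

        spec = CohortSpec()
        p = 91 / 1243

        def j_of(c):
            se, sp = group_se_sp(spec, c)
            return youden_index(se, sp)

        def psi_of(c):
            se, sp = group_se_sp(spec, c)
            return psi_index(*bayes_predictive_values(se, sp, p))

        truth = brentq(lambda c: j_of(c) - psi_of(c), 5, 200, xtol=1e-10)

        errors = []
        for n in (10, 40, 160):
            grid = np.linspace(5, 200, n)
            d = diagram_from(
                [(c, j_of(c)) for c in grid], [(c, psi_of(c)) for c in grid]
            )
            errors.append(abs(unified_cutoff(d).cutoff_star - truth))
        assert errors[2] < errors[0]
        assert errors[2] < (200 - 5) / 160  # within one refined grid step


class TestMaxIndexPoint:
    def test_fixture_nodes(self):
        c = line_curve([(5, 0.2), (10, 0.425), (30, 0.3)])
        assert max_index_point(c) == (10.0, 0.425)

    def test_tie_breaks_to_lower_cutoff(self):
        c = line_curve([(5, 0.3), (10, 0.3), (30, 0.3)])
        assert max_index_point(c) == (5.0, 0.3)

    def test_single_node(self):
        c = line_curve([(7.5, 0.1)])
        assert max_index_point(c) == (7.5, 0.1)


class TestAox:
    def test_constant_rectangle(self):
        c = line_curve([(0, 0.5), (100, 0.5)])
        assert aox(c).area == pytest.approx(50.0, abs=1e-12)
        assert aox(c).normalized == pytest.approx(0.5)

    def test_triangle(self):
        c = line_curve([(0, 0.0), (50, 1.0), (100, 0.0)])
        assert aox(c).area == pytest.approx(50.0, abs=1e-12)

    def test_matches_riemann_oracle(self):
        rng = np.random.default_rng(5)
        cutoffs = np.sort(rng.uniform(0, 300, 12))
        ys = rng.uniform(-0.5, 1.0, 12)
        c = line_curve(list(zip(cutoffs, ys)))
        # independent oracle: midpoint Riemann sum at step 1e-3 of max(f, 0)
        step = 1e-3
        xs = np.arange(cutoffs[0], cutoffs[-1], step) + step / 2
        xs = xs[xs < cutoffs[-1]]
        riemann = np.sum(np.maximum(np.interp(xs, cutoffs, ys), 0.0)) * step
        # trailing partial cell
        if xs.size:
            last = xs[-1] + step / 2
            if last < cutoffs[-1]:
                mid = (last + cutoffs[-1]) / 2
                riemann += max(np.interp(mid, cutoffs, ys), 0.0) * (cutoffs[-1] - last)
        assert aox(c).area == pytest.approx(riemann, abs=1e-4)

    def test_exact_against_segmentwise_closed_form(self):
        """Clipped trapezoid equals the per-segment closed-form integral of
        max(linear, 0) to near machine precision."""
        rng = np.random.default_rng(9)
        cutoffs = np.sort(rng.uniform(0, 100, 8))
        ys = rng.uniform(-1, 1, 8)
        total = 0.0
        for (x0, x1), (y0, y1) in zip(zip(cutoffs, cutoffs[1:]), zip(ys, ys[1:])):
            if y0 >= 0 and y1 >= 0:
                total += (y0 + y1) / 2 * (x1 - x0)
            elif y0 < 0 and y1 < 0:
                pass
            else:
                r = x0 + (x1 - x0) * (0 - y0) / (y1 - y0)
                if y0 > 0:
                    total += y0 / 2 * (r - x0)
                else:
                    total += y1 / 2 * (x1 - r)
        c = line_curve(list(zip(cutoffs, ys)))
        assert aox(c).area == pytest.approx(total, abs=1e-9)

    @given(st.floats(min_value=1, max_value=99))
    @settings(derandomize=True, max_examples=30)
    def test_additivity_over_subranges(self, m):
        c = line_curve([(0, -0.3), (40, 0.9), (70, -0.2), (100, 0.6)])
        full = aox(c).area
        left = aox(c, bounds=(0, m)).area
        right = aox(c, bounds=(m, 100)).area
        assert left + right == pytest.approx(full, abs=1e-12)

    def test_negative_regions_can_be_retained(self):
        c = line_curve([(0, -1.0), (100, 1.0)])
        assert aox(c).area == pytest.approx(25.0, abs=1e-12)  # clipped
        assert aox(c, clip_negative=False).area == pytest.approx(0.0, abs=1e-12)

    def test_invalid_range_rejected(self):
        c = line_curve([(0, 0.5), (100, 0.5)])
        with pytest.raises(ValueError):
            aox(c, bounds=(50, 150))
        with pytest.raises(ValueError):
            aox(c, bounds=(60, 40))


class TestReciprocalDiagram:
    def test_pointwise_reciprocal(self):
        d = diagram_from([(0, 0.5), (100, 0.5)], [(0, 0.25), (100, 0.25)])
        r = reciprocal_diagram(d)
        assert np.allclose(r.j_curve.ys, 2.0)
        assert np.allclose(r.psi_curve.ys, 4.0)

    def test_crossing_preserved_at_shared_node(self):
        """When the index crossing sits on a grid node the reciprocal
        diagram crosses at exactly the same cut-off (1/x is strictly
        decreasing, and node values map exactly)."""
        d = diagram_from(
            [(0, 1.0), (50, 0.5), (100, 0.1)],
            [(0, 0.1), (50, 0.5), (100, 1.0)],
        )
        res_idx = unified_cutoff(d)
        res_rec = unified_cutoff(reciprocal_diagram(d))
        assert res_idx.cutoff_star == pytest.approx(50.0, abs=1e-6)
        assert res_rec.cutoff_star == pytest.approx(res_idx.cutoff_star, abs=1e-6)

    def test_crossing_index_half_gives_two_persons(self):
        d = diagram_from(
            [(0, 1.0), (50, 0.5), (100, 0.1)], [(0, 0.1), (50, 0.5), (100, 1.0)]
        )
        r = reciprocal_diagram(d)
        res = unified_cutoff(r)
        assert res.cutoff_star == pytest.approx(50.0, abs=1e-6)
        assert res.index_star == pytest.approx(2.0, abs=1e-9)  # persons = 1/0.5

    def test_nonpositive_nodes_dropped(self):
        d = diagram_from([(0, -0.1), (50, 0.4), (100, 0.0)], [(0, 0.2), (100, 0.3)])
        r = reciprocal_diagram(d)
        assert [p.cutoff for p in r.j_curve.points] == [50.0]
        assert (0.0, "non-positive index") in r.j_curve.dropped

    def test_all_nonpositive_is_error(self):
        d = diagram_from([(0, -0.1), (100, 0.0)], [(0, 0.2), (100, 0.3)])
        with pytest.raises(ValueError, match="non-positive"):
            reciprocal_diagram(d)


class TestFromCohort:
    def test_diagram_from_cohort_matches_metric_table(self, synthetic_cohort, default_grid):
        d = index_cutoff_diagram(synthetic_cohort, default_grid)
        assert np.array_equal(d.j_curve.cutoffs, np.asarray(default_grid.values))
        for p in d.j_curve.points:
            assert p.y == pytest.approx(p.metric.se + p.metric.sp - 1, abs=1e-15)

    def test_unified_min_curve_bounded_by_both(self, synthetic_cohort, default_grid):
        d = index_cutoff_diagram(synthetic_cohort, default_grid)
        m = unified_min_curve(d)
        for p in m.points:
            assert p.y <= interpolate_index(d.j_curve, p.cutoff) + 1e-12
            assert p.y <= interpolate_index(d.psi_curve, p.cutoff) + 1e-12
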