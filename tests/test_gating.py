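"""Density cut-points, quadrant/tail/Boolean gates and templates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cytostand.gating import (
    GRID_PAD,
    ROOT,
    GatingTemplate,
    TemplateRow,
    apply_template,
    boolean_gate,
    builtin_template,
    density_cutpoint,
    density_grid,
    parse_template,
    quadrant_gate,
    tail_gate,
)
from cytostand.panels import PANEL_NAMES, builtin_panel


def brute_force_valley(values, grid_size=512):
    """Independent oracle: exhaustive argmin of the same KDE between the two
    clearly separated modes (left/right half argmax)."""
    grid, dens = density_grid(values, grid_size=grid_size)
    mid = len(grid) // 2
    left = int(np.argmax(dens[:mid]))
    right = mid + int(np.argmax(dens[mid:]))
    best = min(range(left, right + 1), key=lambda i: (dens[i], i))
    return float(grid[best])


class TestDensityCutpoint:
    def test_matches_brute_force_grid_minimizer_exactly(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(-2, 1, 3000), rng.normal(2, 1, 3000)])
            assert density_cutpoint(x) == brute_force_valley(x)

    def test_near_true_valley_of_analytic_mixture(self):
        # exact valley of 0.5 N(-2,1) + 0.5 N(2,1), found on a fine grid
        fine = np.linspace(-1, 1, 200_001)
        dens = 0.5 * np.exp(-0.5 * (fine + 2) ** 2) + 0.5 * np.exp(-0.5 * (fine - 2) ** 2)
        true_valley = float(fine[np.argmin(dens)])  # 0 by symmetry
        rng = np.random.default_rng(2024)
        x = np.concatenate([rng.normal(-2, 1, 10_000), rng.normal(2, 1, 10_000)])
        assert abs(density_cutpoint(x) - true_valley) <= 0.15

    def test_mirror_symmetric_sample_cuts_at_zero(self, rng):
        # mirror augmentation makes the sample exactly symmetric; with an
        # odd grid the center point is the unique (leftmost) minimizer
        half = rng.normal(2, 0.8, 4000)
        x = np.concatenate([half, -half])
        assert density_cutpoint(x, grid_size=513) == 0.0

    def test_unimodal_fallback_tracks_robust_sd(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 50_000)
        thr = density_cutpoint(x, fallback_k=2.0, fallback_side="+")
        assert abs(thr - 2.0) / 2.0 < 0.05

    def test_constant_input_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            density_cutpoint(np.ones(1000))

    def test_small_samples_fall_back_to_median(self, rng):
        x = rng.normal(0, 1, 150)
        with pytest.warns(UserWarning, match="falling back"):
            thr = density_cutpoint(x)
        assert thr == float(np.quantile(x, 0.5))

    def test_deterministic(self, rng):
        x = np.concatenate([rng.normal(-2, 0.5, 2000), rng.normal(2, 0.5, 2000)])
        assert density_cutpoint(x) == density_cutpoint(x)


class TestQuadrantGate:
    def test_constructed_partition(self):
        x = np.array([0.0, 2.0, 0.0, 2.0])
        y = np.array([0.0, 0.0, 2.0, 2.0])
        q = quadrant_gate(x, y, 1.0, 1.0)
        assert q["--"].tolist() == [True, False, False, False]
        assert q["+-"].tolist() == [False, True, False, False]
        assert q["-+"].tolist() == [False, False, True, False]
        assert q["++"].tolist() == [False, False, False, True]

    def test_all_below_both_cuts(self):
        q = quadrant_gate(np.zeros(5), np.zeros(5), 1.0, 1.0)
        assert q["--"].all() and not (q["++"] | q["+-"] | q["-+"]).any()

    def test_boundary_value_counts_as_positive(self):
        q = quadrant_gate(np.array([1.0]), np.array([1.0]), 1.0, 1.0)
        assert q["++"][0]

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_quadrants_partition_parent_exactly(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        q = quadrant_gate(x, y, float(rng.normal()), float(rng.normal()))
        total = sum(m.sum() for m in q.values())
        assert total == 10_000
        assert not (q["++"] & q["--"]).any()

    def test_non_finite_cut_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            quadrant_gate(np.zeros(3), np.zeros(3), np.nan, 0.0)


class TestTailGate:
    def test_gaussian_reference(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 50_000)
        assert abs(tail_gate(x, k=3.0) - 3.0) / 3.0 < 0.05

    def test_constant_parent_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            tail_gate(np.full(500, 2.0))

    def test_small_parent_widens_to_fixed_quantile(self, rng):
        x = rng.normal(0, 1, 30)
        with pytest.warns(UserWarning, match="fixed quantile"):
            thr = tail_gate(x)
        assert thr == float(np.quantile(x, 0.99))

    def test_recovers_high_spike(self, rng):
        bulk = rng.normal(-2, 0.5, 3000)
        spike = rng.normal(3.5, 0.5, 150)
        thr = tail_gate(np.concatenate([bulk, spike]), k=3.0)
        assert (spike >= thr).mean() >= 0.9


class TestBooleanGate:
    masks = {
        "A": np.array([1, 1, 0, 0, 1, 0], bool),
        "B": np.array([1, 0, 1, 0, 1, 1], bool),
    }

    def test_contradiction_is_empty(self):
        assert not boolean_gate(self.masks, "A & !A").any()

    def test_tautology_is_full(self):
        assert boolean_gate(self.masks, "A | !A").all()

    def test_hand_enumerated_combination(self):
        out = boolean_gate(self.masks, "!A & !B")  # neither marker
        assert out.tolist() == [False, False, False, True, False, False]

    def test_precedence_and_parens(self):
        lhs = boolean_gate(self.masks, "A | B & !A")
        rhs = self.masks["A"] | (self.masks["B"] & ~self.masks["A"])
        np.testing.assert_array_equal(lhs, rhs)

    def test_unknown_alias_rejected(self):
        with pytest.raises(ValueError, match="unknown alias"):
            boolean_gate(self.masks, "A & C")

    def test_unbalanced_parens_rejected(self):
        with pytest.raises(ValueError, match="parenthes|truncated"):
            boolean_gate(self.masks, "(A & B")


class TestTemplates:
    def test_builtin_templates_cover_published_populations(self):
        tcell = builtin_template("T-cell")
        reported = [r.alias for r in tcell.rows if r.report]
        assert len(reported) == 10
        assert "CD8 Activated" in reported
        row = next(r for r in tcell.rows if r.alias == "CD8 Activated")
        # CD3+/CD8+/CD4-/CD38+/HLADR+: quadrant on CD38/HLA-DR under the CD8 branch
        assert row.parent == "CD8" and row.dims == ["CD38", "HLA-DR"] and row.signs == ["+", "+"]
        for name in PANEL_NAMES:
            tpl = builtin_template(name)
            panel = builtin_panel(name)
            pops = {p.name for p in panel.populations}
            assert pops <= set(tpl.aliases)

    def test_template_dims_resolve_to_panel_markers(self):
        for name in PANEL_NAMES:
            markers = set(builtin_panel(name).fluoro_markers)
            for row in builtin_template(name).rows:
                if row.method != "boolean":
                    assert set(row.dims) <= markers, (name, row.alias)

    def test_empty_template_gates_root_only(self, tcell_experiment):
        tpl = GatingTemplate("T-cell", [])
        f = tcell_experiment.files[0]
        tree = apply_template(f.frame, tpl, np.ones(f.frame.n_events, bool))
        assert list(tree.results) == [ROOT]
        assert tree.count(ROOT) == f.frame.n_events

    def test_forward_reference_names_the_row(self):
        df = pd.DataFrame(
            [
                {"alias": "child", "parent": "late", "dims": "CD3", "method": "density_cut",
                 "args": "", "signs": "+", "denominator": "", "report": 1},
                {"alias": "late", "parent": "root", "dims": "CD3", "method": "density_cut",
                 "args": "", "signs": "+", "denominator": "", "report": 1},
            ]
        )
        with pytest.raises(ValueError, match="row 1"):
            parse_template(df)

    def test_duplicate_alias_and_bad_method_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            GatingTemplate("x", [
                TemplateRow("a", ROOT, ["m"], "density_cut", {}, ["+"], ""),
                TemplateRow("a", ROOT, ["m"], "density_cut", {}, ["+"], ""),
            ])
        with pytest.raises(ValueError, match="unknown method"):
            GatingTemplate("x", [TemplateRow("a", ROOT, ["m"], "kmeans", {}, ["+"], "")])

    def test_denominator_must_be_ancestor(self):
        rows = [
            TemplateRow("a", ROOT, ["m"], "density_cut", {}, ["+"], ""),
            TemplateRow("b", ROOT, ["m"], "density_cut", {}, ["-"], ""),
            TemplateRow("c", "a", ["m"], "density_cut", {}, ["+"], "b"),
        ]
        with pytest.raises(ValueError, match="ancestor"):
            GatingTemplate("x", rows)


class TestApplyTemplate:
    def test_counts_conserved_along_every_path(self, tcell_experiment):
        from cytostand.pipeline import gate_experiment

        for _, tree in gate_experiment(tcell_experiment):
            for res in tree.results.values():
                if res.alias == ROOT:
                    continue
                parent = tree.results[res.parent]
                assert res.count <= parent.count
                assert not (res.mask & ~parent.mask).any()

    def test_zero_event_parent_flags_children_unresolvable(self, tcell_experiment):
        f = tcell_experiment.files[0]
        tpl = parse_template(
            pd.DataFrame(
                [
                    {"alias": "none", "parent": "root", "dims": "CD3",
                     "method": "density_cut", "args": "", "signs": "+",
                     "denominator": "", "report": 1},
                    {"alias": "child", "parent": "none", "dims": "CD4",
                     "method": "density_cut", "args": "", "signs": "+",
                     "denominator": "", "report": 1},
                ]
            ),
            "T-cell",
        )
        tree = apply_template(f.frame, tpl, np.zeros(f.frame.n_events, bool))
        assert tree.results["none"].unresolvable and tree.results["child"].unresolvable
        assert tree.count("child") == 0

    def test_identical_inputs_identical_thresholds(self, tcell_experiment):
        from cytostand.pipeline import gate_experiment

        a = gate_experiment(tcell_experiment)
        b = gate_experiment(tcell_experiment)
        for (_, ta), (_, tb) in zip(a, b):
            for alias in ta.results:
                assert ta.results[alias].thresholds == tb.results[alias].thresholds
                assert ta.count(alias) == tb.count(alias)
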