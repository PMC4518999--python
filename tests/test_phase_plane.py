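"""Phase planes, production envelopes and the coupling statistic."""

import numpy as np
import pytest

from thermoflux.fba import optimize_with_fixed_fluxes
from thermoflux.phase_plane import (
    coupling_strength,
    phase_plane,
    product_range_at_optimum,
    production_envelope,
)
from thermoflux.synthetic import generate_coupled_toy
from thermoflux.model import knock_out_reactions
from thermoflux.tsac import strain


@pytest.fixture(scope="module")
def wt_grid(core_model):
    return phase_plane(core_model, "EX_glc", "EX_etoh",
                       (-10.0, 0.0), (0.0, 20.0), n_points=21)


class TestPhasePlane:
    def test_axes_must_differ(self, core_model):
        with pytest.raises(ValueError):
            phase_plane(core_model, "EX_glc", "EX_glc",
                        (-10, 0), (-10, 0), 5)

    def test_cells_match_direct_fixed_flux_fba(self, core_model, wt_grid):
        for i, k in [(0, 0), (0, 5), (10, 3), (20, 10)]:
            direct = optimize_with_fixed_fluxes(
                core_model, {"EX_glc": wt_grid.x_values[i],
                             "EX_etoh": wt_grid.y_values[k]})
            cell = wt_grid.growth[i, k]
            if direct.ok:
                assert cell == pytest.approx(direct.objective_value,
                                             abs=1e-6)
            else:
                assert np.isnan(cell)

    def test_wild_type_optimum_spans_many_ethanol_values(self, wt_grid):
        best = np.nanmax(wt_grid.growth)
        # at full uptake, count ethanol grid values attaining the optimum
        at_uptake = wt_grid.growth[0]
        n_at_best = int(np.sum(at_uptake >= best - 1e-6))
        assert n_at_best >= 5

    def test_coupled_strain_optimum_is_a_narrow_band(self, core_model):
        grid = phase_plane(strain(core_model, "ldh_hfs"),
                           "EX_glc", "EX_etoh", (-10.0, 0.0), (0.0, 20.0),
                           n_points=21)
        best = np.nanmax(grid.growth)
        n_at_best = int(np.sum(grid.growth[0] >= best - 1e-6))
        assert n_at_best <= 2

    def test_infeasible_cells_serialized_as_na(self, core_model, tmp_path,
                                               wt_grid):
        out = tmp_path / "grid.tsv"
        wt_grid.to_tsv(out)
        text = out.read_text()
        assert "NA" in text and "nan" not in text


class TestProductionEnvelope:
    def test_resting_cells_can_secrete_nothing(self, core_model):
        env = production_envelope(core_model, "EX_etoh", n_points=11)
        assert env.min_flux[0] == pytest.approx(0.0, abs=1e-6)

    def test_wild_type_envelope_is_wide_at_optimum(self, core_model):
        env = production_envelope(core_model, "EX_etoh", n_points=11)
        assert env.max_flux[-1] - env.min_flux[-1] > 5.0

    def test_coupled_strain_envelope_pinches_at_optimum(self, core_model):
        env = production_envelope(strain(core_model, "ldh_hfs"),
                                  "EX_etoh", n_points=11)
        assert env.min_flux[-1] > 1.0
        assert env.max_flux[-1] - env.min_flux[-1] < 0.5

    def test_envelope_closes(self, core_model):
        """Beyond the growth of the unconstrained-product optimum the upper
        edge cannot rise."""
        env = production_envelope(core_model, "EX_etoh", n_points=21)
        peak = int(np.argmax(env.max_flux))
        diffs = np.diff(env.max_flux[peak:])
        assert np.all(diffs <= 1e-6)

    def test_resolution_invariance_at_shared_points(self, core_model):
        coarse = production_envelope(core_model, "EX_etoh", n_points=6)
        fine = production_envelope(core_model, "EX_etoh", n_points=11)
        # growth grids share every other point
        for i, j in [(0, 0), (1, 2), (2, 4), (5, 10)]:
            assert coarse.growth_values[i] == pytest.approx(
                fine.growth_values[j], abs=1e-9)
            assert coarse.min_flux[i] == pytest.approx(fine.min_flux[j],
                                                       abs=1e-6)
            assert coarse.max_flux[i] == pytest.approx(fine.max_flux[j],
                                                       abs=1e-6)


class TestCouplingStrength:
    def test_strategy_ordering_at_99_percent(self, core_model):
        wt = coupling_strength(core_model, "EX_etoh", 0.99)
        pta = coupling_strength(strain(core_model, "ldh_pta"),
                                "EX_etoh", 0.99)
        hfs = coupling_strength(strain(core_model, "ldh_hfs"),
                                "EX_etoh", 0.99)
        assert hfs > pta + 1.0          # electron strategy couples harder
        assert pta >= wt - 1e-9
        assert wt == min(wt, pta, hfs)

    def test_monotone_in_fraction(self, core_model):
        sm = strain(core_model, "ldh_pta")
        values = [coupling_strength(sm, "EX_etoh", f)
                  for f in (0.2, 0.5, 0.9, 1.0)]
        assert all(b >= a - 1e-6 for a, b in zip(values, values[1:]))

    def test_fraction_zero_with_free_secretion_is_zero(self):
        toy = generate_coupled_toy(seed=1).model
        assert coupling_strength(toy, "EX_prod", 0.0) == \
            pytest.approx(0.0, abs=1e-9)

    def test_toy_ground_truth(self):
        bundle = generate_coupled_toy(seed=4)
        gt = bundle.ground_truth
        coupled = knock_out_reactions(bundle.model, {gt["sink_reaction"]})
        assert coupling_strength(coupled, gt["product_reaction"], 1.0) == \
            pytest.approx(gt["coupled_min_product"], abs=1e-5)

    def test_bad_fraction(self, core_model):
        with pytest.raises(ValueError):
            coupling_strength(core_model, "EX_etoh", 1.5)


class TestProductRangeAtOptimum:
    def test_wild_type_range_is_wide(self, core_model):
        lo, hi = product_range_at_optimum(core_model, "EX_etoh")
        assert (hi - lo) / hi >= 0.5

    def test_coupled_strain_range_is_narrow_and_positive(self, core_model):
        lo, hi = product_range_at_optimum(strain(core_model, "ldh_hfs"),
                                          "EX_etoh")
        assert lo > 0
        assert (hi - lo) / hi <= 0.2
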