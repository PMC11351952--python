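"""Profiling tests: VIP selection, region integration, control normalization."""

import numpy as np
import pandas as pd
import pytest

from nmropls.cohortsim import CohortConfig, MetaboliteSpec, Multiplet, simulate_cohort
from nmropls.profiling import (
    MetaboliteRegion,
    heatmap_table,
    integrate_regions,
    normalize_to_control,
    regions_from_specs,
    select_bins,
)
from tests.conftest import preprocess


class TestSelectBins:
    def test_unit_vips_select_nothing(self):
        vips = {c: np.ones(10) for c in ("a", "b", "c", "d")}
        assert select_bins(vips).size == 0

    def test_single_comparison_hit_is_enough(self):
        vips = {c: np.ones(10) for c in ("a", "b", "c")}
        vips["d"] = np.ones(10)
        vips["d"][3] = 1.6
        assert select_bins(vips).tolist() == [3]

    def test_raising_the_threshold_never_adds_bins(self, rng):
        vips = {c: rng.random(50) * 3 for c in ("a", "b")}
        lo = set(select_bins(vips, threshold=1.2).tolist())
        hi = set(select_bins(vips, threshold=1.8).tolist())
        assert hi <= lo

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            select_bins({"a": np.ones(5), "b": np.ones(6)})


class TestIntegrateRegions:
    def test_region_covering_all_bins_returns_one_for_normalized_rows(self, noiseless_cohort):
        norm, design = noiseless_cohort["norm"], noiseless_cohort["design"]
        lo, hi = norm.bin_edges[0, 0], norm.bin_edges[-1, 1]
        panel = integrate_regions(norm, [MetaboliteRegion("all", ((lo, hi),))], design)
        assert np.allclose(panel.levels["all"], 1.0, atol=1e-9)

    def test_disjoint_intervals_add(self, noiseless_cohort):
        norm, design = noiseless_cohort["norm"], noiseless_cohort["design"]
        r1 = MetaboliteRegion("a", ((0.8, 1.0),))
        r2 = MetaboliteRegion("b", ((3.0, 3.4),))
        r12 = MetaboliteRegion("ab", ((0.8, 1.0), (3.0, 3.4)))
        panel = integrate_regions(norm, [r1, r2, r12], design)
        assert np.allclose(panel.levels["ab"], panel.levels["a"] + panel.levels["b"])

    def test_alanine_group_means_follow_configured_multipliers(self, noiseless_cohort):
        # alanine at 1.48 ppm sits clear of the lipid envelope, so its region
        # integral tracks the injected amplitudes (lactate at 1.33 rides on
        # the lipid CH2 tail and is deliberately contaminated, as in real
        # plasma spectra)
        norm, design, truth = (
            noiseless_cohort["norm"],
            noiseless_cohort["design"],
            noiseless_cohort["truth"],
        )
        regions = regions_from_specs(truth.specs)
        panel = integrate_regions(norm, [r for r in regions if r.name == "alanine"], design)
        means = panel.levels["alanine"].groupby(panel.groups).mean()
        mults = {g: truth.amplitudes[("alanine", g)] for g in means.index}
        # same ordering as the injected amplitudes
        assert means.sort_values().index.tolist() == sorted(mults, key=mults.get)

    def test_empty_region_error_names_it(self, noiseless_cohort):
        with pytest.raises(ValueError, match="nothing_here"):
            integrate_regions(
                noiseless_cohort["norm"],
                [MetaboliteRegion("nothing_here", ((8.9001, 8.9002),))],
                noiseless_cohort["design"],
            )

    def test_requires_normalized_state(self, noiseless_cohort, rng):
        from nmropls.preproc import pareto_scale

        scaled = pareto_scale(noiseless_cohort["norm"])
        with pytest.raises(ValueError, match="normalized"):
            integrate_regions(
                scaled, [MetaboliteRegion("x", ((1.0, 2.0),))], noiseless_cohort["design"]
            )


def _panel_from_levels(levels, groups):
    from nmropls.profiling import MetabolitePanel

    idx = pd.Index([f"s{i}" for i in range(len(groups))], name="sample_id")
    return MetabolitePanel(
        levels=pd.DataFrame({"met": levels}, index=idx),
        groups=pd.Series(groups, index=idx),
        state="level",
    )


class TestNormalizeToControl:
    def test_equal_control_samples_map_to_exactly_100(self):
        panel = _panel_from_levels([2.0, 2.0, 4.0, 6.0], ["WT/CD", "WT/CD", "KO/WD", "KO/WD"])
        out = normalize_to_control(panel)
        assert np.allclose(out.levels["met"].iloc[:2], 100.0)

    def test_double_the_control_mean_maps_to_200(self):
        panel = _panel_from_levels([1.0, 3.0, 4.0], ["WT/CD", "WT/CD", "KO/WD"])
        out = normalize_to_control(panel)
        assert out.levels["met"].iloc[2] == pytest.approx(200.0)

    def test_control_group_mean_percent_is_100(self, rng):
        levels = rng.random(12) + 0.5
        groups = ["WT/CD"] * 3 + ["WT/WD"] * 3 + ["KO/CD"] * 3 + ["KO/WD"] * 3
        out = normalize_to_control(_panel_from_levels(levels, groups))
        ctrl = out.levels["met"][out.groups == "WT/CD"]
        assert ctrl.mean() == pytest.approx(100.0, abs=1e-9)

    def test_percent_is_invariant_to_global_intensity_rescaling(self, rng):
        levels = rng.random(8) + 0.5
        groups = ["WT/CD"] * 4 + ["KO/WD"] * 4
        a = normalize_to_control(_panel_from_levels(levels, groups))
        b = normalize_to_control(_panel_from_levels(levels * 37.0, groups))
        assert np.allclose(a.levels, b.levels)

    def test_missing_control_group_rejected(self):
        panel = _panel_from_levels([1.0, 2.0], ["KO/WD", "KO/WD"])
        with pytest.raises(ValueError, match="WT/CD"):
            normalize_to_control(panel)


class TestHeatmapTable:
    def test_additive_multiplicative_effects_compound_in_the_heatmap(self):
        # -25% genotype and -25% diet effects on a trace metabolite riding on
        # a dominant constant background: KO/WD should sit near 56.25% of
        # control (0.75 x 0.75), barely distorted by total-sum normalization.
        bulk = MetaboliteSpec(
            "bulk", (Multiplet(7.0, (1.0,), 0.0, 0.05),), 1000.0,
            {g: 1.0 for g in ("WT/CD", "WT/WD", "KO/CD", "KO/WD")},
        )
        met = MetaboliteSpec(
            "met", (Multiplet(2.5, (1.0,), 0.0, 0.01),), 10.0,
            {"WT/CD": 1.0, "WT/WD": 0.75, "KO/CD": 0.75, "KO/WD": 0.5625},
        )
        # gaussian lines: no long Lorentzian tails leaking the bulk signal
        # into the probe region
        cfg = CohortConfig(
            noise_sd=0.0, shift_jitter_sd=0.0, amplitude_cv=0.0,
            lineshape="gaussian", seed=0,
        )
        spectra, design, _ = simulate_cohort(cfg, (bulk, met))
        # no lactate resonance in this two-metabolite cohort: bin directly
        from nmropls.preproc import bin_cohort, total_sum_normalize

        norm = total_sum_normalize(bin_cohort(spectra))
        panel = integrate_regions(norm, regions_from_specs((met,)), design)
        heat = heatmap_table(normalize_to_control(panel))
        assert heat.loc["KO/WD", "met"] == pytest.approx(56.25, rel=5e-3)

    def test_null_cohort_heatmap_is_flat_at_100(self, rng):
        levels = np.full(12, 3.0)
        groups = ["WT/CD"] * 3 + ["WT/WD"] * 3 + ["KO/CD"] * 3 + ["KO/WD"] * 3
        heat = heatmap_table(normalize_to_control(_panel_from_levels(levels, groups)))
        assert np.allclose(heat["met"], 100.0)

    def test_strong_lipid_effect_peaks_in_ko_wd(self, noiseless_cohort):
        norm, design, truth = (
            noiseless_cohort["norm"],
            noiseless_cohort["design"],
            noiseless_cohort["truth"],
        )
        regions = regions_from_specs(truth.specs)
        panel = integrate_regions(norm, regions, design)
        heat = heatmap_table(normalize_to_control(panel))
        assert heat["lipid_ch2"].idxmax() == "KO/WD"
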