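"""Univariate statistics on control-normalized metabolite levels.

For one metabolite panel column: Shapiro-Wilk normality screen, genotype x
diet two-way ANOVA (Type II), Tukey post-hoc over the four groups, and the
one-sample t-test against 100% used for diet-normalized readouts.
"""

from nmropls.cohortsim import CohortConfig, default_metabolites, simulate_cohort
from nmropls.preproc import bin_cohort, reference_to_lactate, total_sum_normalize
from nmropls.profiling import integrate_regions, normalize_to_control, regions_from_specs
from nmropls.stats import one_sample_t, percent_of_group_mean, shapiro_wilk, tukey_hsd, two_way_anova

specs = default_metabolites()
spectra, design, _ = simulate_cohort(CohortConfig(seed=1), specs)
norm = total_sum_normalize(bin_cohort([reference_to_lactate(s) for s in spectra]))
panel = normalize_to_control(integrate_regions(norm, regions_from_specs(specs), design))

met = "alanine"
vals = panel.levels[met].to_numpy()
geno = design.set_index("sample_id")["genotype"].reindex(panel.levels.index).to_numpy()
diet = design.set_index("sample_id")["diet"].reindex(panel.levels.index).to_numpy()

w, p_sw = shapiro_wilk(vals)
print(f"{met}: Shapiro-Wilk W={w:.3f}, p={p_sw:.3f} (normality not rejected if p>0.05)")

res = two_way_anova(vals, geno, diet)
print(f"two-way ANOVA: genotype F={res.genotype.F:.2f} p={res.genotype.p:.4f} | "
      f"diet F={res.diet.F:.2f} p={res.diet.p:.4f} | "
      f"interaction F={res.interaction.F:.2f} p={res.interaction.p:.4f}")

tk = tukey_hsd(vals, panel.groups.to_numpy())
print("Tukey (adjusted p):")
for _, row in tk.table.iterrows():
    print(f"  {row.group_a:6s} vs {row.group_b:6s}: diff={row['diff']:7.1f}%  p={row.p_adj:.4f}")

# diet-normalized readout: KO/WD alanine as percent of the KO/CD mean vs 100%
ko_wd = vals[(geno == "KO") & (diet == "WD")]
ko_cd = vals[(geno == "KO") & (diet == "CD")]
pct = percent_of_group_mean(ko_wd, ko_cd)
t, p_t = one_sample_t(pct, mu=100.0)
print(f"KO/WD vs its genotype CD mean: {pct.mean():.1f}% of control, "
      f"one-sample t={t:.2f}, p={p_t:.4f}")
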