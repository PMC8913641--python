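"""Shannon diversity, Pielou evenness and between-class tests.

Diversity is computed from biomass shares per sample; class differences
are tested with one-way ANOVA (plus Tukey HSD letter groups) and the
Kruskal-Wallis test.
"""

from planknet import compare_classes, diversity_table, make_study_fixture

fixture = make_study_fixture(seed=0)
tables = {cls: diversity_table(m) for cls, m in fixture.items()}

for cls, t in tables.items():
    print(f"{cls}: mean H' = {t['shannon_h'].mean():.3f}, mean J' = {t['pielou_j'].mean():.3f}")

groups = {cls: t["shannon_h"].to_numpy() for cls, t in tables.items()}
anova = compare_classes(groups, "anova", variable="shannon_h")
kw = compare_classes(groups, "kruskal_wallis", variable="shannon_h")

print(f"\nANOVA on H': F = {anova.statistic:.2f}, df = {anova.df}, p = {anova.p_value:.3g}")
print(f"Tukey letter groups: {anova.tukey_groups}  (classes sharing no letter differ at alpha=0.05)")
print(f"Kruskal-Wallis on H': H = {kw.statistic:.2f}, p = {kw.p_value:.3g}")
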