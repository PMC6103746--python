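"""Does the like-C9 molecular signature predict clinical FTD?

Non-control patients are tallied into a 2x2 table of classification vs
FTD symptoms; the association is summarized as an odds ratio with Fisher's
exact test.  The published cohort counts are included for comparison.
"""

from splicestrat import clinical, simulate, splicing
from splicestrat.clinical import ContingencyTable2x2

cohort = simulate.simulate_cohort(seed=1)
matrix = splicing.build_psi_matrix(cohort.psi, cohort.annotation)
css = splicing.compute_css(matrix)["css"]
labels = splicing.classify_patients(css, cohort.metadata)

table = clinical.build_contingency(labels, cohort.metadata)
print(f"synthetic cohort table (rows like-C9/like-control, cols FTD/no-FTD):")
print(f"  [[{table.a:2d} {table.b:2d}]\n   [{table.c:2d} {table.d:2d}]]")
print(f"odds ratio: {clinical.odds_ratio(table):.2f}")
print(f"Fisher exact p: two-sided {clinical.fisher_exact(table, 'two'):.4f}, "
      f"one-sided {clinical.fisher_exact(table, 'greater'):.4f}")

published = ContingencyTable2x2(13, 13, 5, 19)
print(f"\npublished cohort counts (13,13,5,19): OR = {clinical.odds_ratio(published):.1f}")
print(f"3-SD rule nominal coverage: {clinical.normal_within_k_sd(3):.1f}% of a normal population")
print(
    "\nAn odds ratio well above 1 means like-C9 patients are several times"
    "\nmore likely to carry FTD symptoms - the molecular stratification has"
    "\nclinical teeth."
)
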