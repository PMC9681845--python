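"""Two-step Spearman reduction of the 55-variable feature table.

Builds the default 18-subject cohort, screens each parameter's five
distance columns for rank-equivalence (collapsing to q3), then excludes
parameters very strongly correlated with a retained one.
"""

from voitex import CohortSpec, build_feature_table, make_cohort, reduce_redundancy

cohort, _ = make_cohort(CohortSpec(master_seed=1))
ft = build_feature_table(cohort)
print(f"feature table: {ft.shape[0]} subjects x {ft.shape[1] - 1} variables")

report = reduce_redundancy(ft)
print(f"reference distance: {report.reference_distance}")
if report.distance_failures:
    print(f"distance-screen flags: {', '.join(report.distance_failures)}")
print(f"retained ({len(report.retained)}): {', '.join(report.retained)}")
for exc in report.excluded:
    print(f"excluded {exc.parameter:24s} vs {exc.partner:14s} rho={exc.rho:+.2f}")
# The sum/difference statistics are near-deterministic functions of the
# joint-distribution parameters (sum variance of variance, difference
# variance of contrast, the marginal entropies of entropy), so they are
# the ones the |rho| >= 0.9 screen removes.
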