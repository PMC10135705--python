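"""Median-split survival comparison on a synthetic 44-case cohort.

Simulates CDR3 repertoires and a synthetic antigen, aggregates one
complementarity score (CS) per case, simulates disease-free survival with
a hazard ratio of 2.5 against the upper-CS group, and runs the
Kaplan-Meier / logrank comparison.
"""

from cdr3comp import (CohortSpec, RunConfig, SurvivalRecord, score_cohort,
                      simulate_antigen, simulate_repertoires, simulate_survival,
                      survival_comparison)

spec = CohortSpec(seed=20)
cdr3s = simulate_repertoires(spec)
antigen = simulate_antigen(spec)

_, per_target = score_cohort(cdr3s, [antigen], RunConfig())
records = next(iter(per_target.values()))

survival_df = simulate_survival(records, spec)
survival = [SurvivalRecord(r.case_id, r.time_months, int(r.event))
            for r in survival_df.itertuples(index=False)]

res = survival_comparison(records, survival)
print(f"cohort: {len(records)} cases, split at CS threshold "
      f"{res.strata.threshold:.2f}")
print(f"upper group n={len(res.strata.upper)}, "
      f"lower group n={len(res.strata.lower)}")
print(f"KM median DFS: upper {res.curves['upper'].median_time():.1f} months, "
      f"lower {res.curves['lower'].median_time():.1f} months")
print(f"logrank chi-square = {res.logrank.chi_square:.3f}, "
      f"p = {res.logrank.p_value:.4f}")
print()
print("A small p-value says the high-complementarity half of the cohort")
print("progresses faster than the low-complementarity half, as simulated.")
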