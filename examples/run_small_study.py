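"""Run a scaled-down factorial study and print reporting-table rows.

Uses the full correlation grid but 100 replications x 200 bootstraps per
cell (the canonical study uses 1000 x 1000) so it finishes in about a
minute.  Prints the Case 1 rows: perfect manipulation with a near-errorless
check, where multicollinearity makes the indirect effect huge or tiny
depending on (r_my, r_ty).
"""

from tmcsim import StudyConfig, make_tables, run_study

cfg = StudyConfig(n_reps=100, n_boot=200, seed=7)
result = run_study(cfg)
print(f"ran {len(result.summaries)} conditions, "
      f"{len(result.exclusions)} excluded\n")

print("Case 1 (r_tx = 1, r_tm = 0.95):")
print(make_tables(result.summaries, case_filter=1).to_string(index=False))
print("\ndetection_rate is the t-test + bootstrap-CI conjunction; ab_mean "
      "is the mean indirect effect across replications.")
print("Rows with r_my != r_ty carry |ab| > 1.7 despite standardized "
      "variables - the suppression signature of a collinear mediator.")
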