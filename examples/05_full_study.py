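"""Run the complete synthetic study end to end (small cohort for speed).

Simulates a cohort, runs the behavioural rank-test battery, the windowed
ERP battery, the early/late spectral comparison and the pooled effect-size
verdict.  With the default 17 participants this is the package's full
acceptance-grade pipeline; 6 participants keep this demo under a minute.
"""

from psicat.study import run_synthetic_study

result = run_synthetic_study(n_participants=6, seed=3, make_stimuli=False,
                             n_perm=300)

print("behavioural tests:")
print(result.behavioural_tests[["hypothesis", "median_diff", "u_stat",
                                "p_adj", "es"]].round(3).to_string(index=False))
print("\nERP tests:")
print(result.erp_tests[["hypothesis", "diff_uv", "t", "df", "p_adj", "es"]]
      .round(3).to_string(index=False))
print("\neffect-size comparison:")
print(result.verdict.per_family.to_string(index=False))
print("\nheadline verdict (congruency ES > gestalt ES):",
      result.verdict.supported)
# the adjusted p-values and signs mirror the published battery; the pooled
# comparison asks whether the task-irrelevant primer outweighs the
# task-relevant gestalt — the package's central question.  At 6 participants
# the RTV rank test can drop below the significance cut (empty gestalt cell
# in the behavioural family); the default 17-participant cohort has the
# power the protocol was designed around
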