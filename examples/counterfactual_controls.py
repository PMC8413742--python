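"""Simulated-control (counterfactual) hyposmia prevalence.

Generates a Tracking-like PD cohort, then asks: if these same people (same
ages, same genders) did not have PD, what fraction would each definition
still label hyposmic?  Scores are redrawn from the normative healthy-control
model per replicate; the spread across 2000 replicates gives empirical CIs.
"""

from hyposmia import (
    NormativeModel,
    classify_cohort,
    derive_centile_cutoffs,
    generate_pd_cohort,
    sample_reference,
    simulate_counterfactual,
)
from hyposmia.normative import prevalence_to_frame

model = NormativeModel()
reference = sample_reference(n=100_000, model=model, seed=1)
cutoffs = derive_centile_cutoffs(reference)

cohort = generate_pd_cohort()  # Tracking-like defaults, n=1674
matrix = classify_cohort(cohort, cutoffs)
estimates = prevalence_to_frame(
    simulate_counterfactual(cohort, model, cutoffs, replicates=2000, seed=2,
                            include_grades=False)
)

print("PD cohort prevalence (%):")
for method, col in [("method1", "method1"), ("method2_any", "method2_binary"),
                    ("method3", "method3"), ("method4", "method4")]:
    pd_prev = 100.0 * matrix[col].mean()
    row = estimates[(estimates["method"] == method) & (estimates["stratum"] == "all")].iloc[0]
    print(f"  {method:12s} PD {pd_prev:5.1f}   controls {row['point']:5.1f} "
          f"({row['ci_low']:.1f}, {row['ci_high']:.1f})")

print(
    "\nEvery definition labels far more PD cases than matched healthy "
    "controls, but the\ncontrol rate itself ranges widely by method; the "
    "age/gender-corrected centile\nmethod pins it near its nominal 15%."
)
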