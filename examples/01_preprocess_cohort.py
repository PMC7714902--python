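"""Preprocess a narrow clinical cohort into shuffle-ready strata.

Builds the synthetic heart-failure surrogate cohort (711 patients, 13
binary flags of which 2 are endpoints, 6 measurements, realistic
missingness), then applies the three sequential exclusion criteria:
patients missing an endpoint, patients missing any other value, and
classes holding a single patient (which cannot be shuffled).
"""

from cohortshuffle import preprocess_pipeline, synthetic_hf_cohort

cohort = synthetic_hf_cohort(seed=1)
strat, report = preprocess_pipeline(cohort)

print(f"patients in:                {report.n_in}")
for name, count in report.removed.items():
    print(f"removed by {name:<18} {count}")
print(f"patients out:               {report.n_out}")
print(f"classes (strata):           {strat.n_classes}")
print(f"smallest / largest class:   {strat.class_sizes.min()} / {strat.class_sizes.max()}")

# The removal counts always reconcile: in = out + removed.  Each class
# is the set of patients sharing an identical 13-bit clinical pattern;
# shuffling is only meaningful (and only permitted) inside a class.
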