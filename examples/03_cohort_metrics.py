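"""Cohort evaluation: pipeline progression calls against a reader panel.

Simulates a small cohort, runs the pipeline on every patient, then evaluates
the automated two-or-more-new-lesions call against a simulated three-reader
majority panel (readers flip the true call with 5% probability, mirroring
inter-reader disagreement).  Prints the confusion matrix, sensitivity,
specificity, PPV, NPV and the unanimous-agreement rate.

Run:  python examples/03_cohort_metrics.py   (~1 minute: 8 patients)
"""

from bsitrack import (
    agreement_rate,
    confusion,
    consensus,
    default_atlas,
    metrics,
    run_cohort,
    simulate_cohort,
)
from bsitrack.cohort import simulate_reader_panel

atlas = default_atlas()

table, series_list, _ = simulate_cohort(8, progression_prevalence=0.5,
                                        seed=21, atlas=atlas)
results = run_cohort(series_list, atlas)
merged = table.merge(results, on="patient_id")
print(merged[["patient_id", "true_new_lesions", "n_new_lesions",
              "pcwg2_progression", "bsi_percent_change"]].to_string(index=False))

# three simulated readers vote on each patient; majority rule decides
truth_calls = {row.patient_id: row.true_new_lesions >= 2
               for row in merged.itertuples()}
reads = simulate_reader_panel(truth_calls, flip_probability=0.05, seed=3)
panel = consensus(reads)

auto_calls = dict(zip(merged["patient_id"], merged["pcwg2_progression"]))
c = confusion(auto_calls, panel)
print(f"\nconfusion vs reader panel: tp={c.tp} fp={c.fp} tn={c.tn} fn={c.fn}")
print(f"metrics (percent): {metrics(c)}")
print(f"unanimous reader agreement: {agreement_rate(reads)}%")
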