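"""Descriptive aggregates of the included-study roster.

Loads the 25-dataset schizophrenia FNC roster shipped with the package and
prints the pooled sample sizes and sample-size-weighted mean ages. Controls
shared between the split datasets of one study are counted once.
"""

import fncmeta as fm

roster = fm.load_reference_roster()
agg = fm.roster_aggregates(roster)

print(f"datasets: {agg['n_datasets']} (from {agg['n_studies']} studies)")
print(f"pooled patients: {agg['pooled_patients']}")
print(f"unique controls: {agg['unique_controls']}")
print(f"weighted mean patient age: {agg['weighted_mean_patient_age']:.1f} y")
print(f"weighted mean control age: {agg['weighted_mean_control_age']:.1f} y")
print(f"binary-FNC datasets: {sum(d.fnc_type == 'binary' for d in roster)}")

# The patient total and unique-control total are the cohort this
# meta-analysis pools; the weighted ages describe its demographic centre.
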