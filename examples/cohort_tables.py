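"""Marginal distributions of the gastric-polyp cohort tables.

Loads the bundled 111-patient contingency tables (histology x age band,
x polyp diameter, x location), and prints each marginal with its
percentage of patients.  Counts are patients; percentages use the cohort
size (111) as denominator, rounded half-up to one decimal.
"""

from endostitch.cohort_summary import (
    load_bundled_table,
    marginal,
    singleness_summary,
    summary_to_text,
)

for name, axis in [("age", "rows"), ("size", "rows"), ("location", "rows"),
                   ("age", "columns")]:
    table = load_bundled_table(name)
    title = f"{name} table, {axis} marginal"
    print(f"\n{title}\n{'-' * len(title)}")
    print(summary_to_text(marginal(table, axis)))

print("\nsingle vs multiple polyps\n-------------------------")
print(summary_to_text(singleness_summary(80, 31)))
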