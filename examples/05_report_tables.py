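"""Study-level report tables from the published murine estimates.

Assembles the three-mouse parameter table with derived front speeds and
cm/yr conversions, the hypothesis-comparison percentages, and the
speed-versus-volume pairs used for the size-velocity analysis.
"""

import pandas as pd

from gliomafit.reporting import (
    comparison_summary,
    hypothesis_comparison,
    reference_report,
    velocity_ranges_cmyr,
)

pd.set_option("display.width", 120)

report = reference_report()
print("parameter table (first rows):")
print(report.table.head(8).to_string(index=False))

print("\nper-subject velocity ranges (cm/yr):")
print(velocity_ranges_cmyr(report).to_string(index=False))

comp = hypothesis_comparison(report)
print("\nhypothesis comparison (percent decrease vs constant-parameter fit):")
print(comp.round(2).to_string(index=False))
print("\ncross-subject summary:")
print(comparison_summary(comp).round(2).to_string(index=False))

print("\nspeed-vs-volume pairs (sequential-fit interval speeds paired with")
print("the visible volume at each interval's start day):")
print(report.speed_volume_pairs.head(8).to_string(index=False))
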