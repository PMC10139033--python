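"""Curate raw bioassay IC50 records into one pIC50 value per compound.

Shows the duplicate-median rule and the qualified-record ("<"/">") class
rule: inequalities survive only when they pin the compound's 1000 nM
activity class.
"""

from funnelscreen.dataprep import ActivityRecord, curate_activities, to_pic50

records = [
    ActivityRecord("CHEM-A", 10.0),            # three exact replicates -> median
    ActivityRecord("CHEM-A", 100.0),
    ActivityRecord("CHEM-A", 1000.0),
    ActivityRecord("CHEM-B", 2000.0, "gt"),    # "> 2000 nM": inactive class pinned, kept
    ActivityRecord("CHEM-C", 500.0, "gt"),     # "> 500 nM": straddles 1000 nM, dropped
    ActivityRecord("CHEM-D", 800.0, "lt"),     # "< 800 nM": active class pinned, kept
    ActivityRecord("CHEM-E", -4.0),            # invalid, rejected with a log message
]

table = curate_activities(records)
print(table.to_string(index=False))
print(f"\n40 uM -> pIC50 {to_pic50(40000.0):.3f}; 1 nM -> pIC50 {to_pic50(1.0):.1f}")
# CHEM-A keeps the median (100 nM -> pIC50 7.0); CHEM-C and CHEM-E are gone;
# is_active marks the < 1000 nM class used downstream for classification.
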