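"""Filter screening hits with the negative-design rule engine.

Evaluates PAINS substructure alerts (from structures), drug-likeness
property windows, and annotation-driven promiscuity/aggregation exclusions
on a small mixed panel.
"""

from funnelscreen.negdesign import CompoundEntry, apply_filters, survivors

panel = [
    # rhodanine core: a classic assay-interference (PAINS) scaffold
    CompoundEntry("hit-01", smiles="O=C1CSC(=S)N1", annotations={"pScore": 50, "aggregator": 0}),
    # clean, drug-like, no flags
    CompoundEntry("hit-02", smiles="CC(=O)Oc1ccccc1C(=O)O", annotations={"pScore": 12, "aggregator": 0}),
    # structurally clean but promiscuous (pScore at the exclusion boundary)
    CompoundEntry("hit-03", smiles="c1ccccc1CCN", annotations={"pScore": 300, "aggregator": 0}),
    # flagged as an aggregator by an external predictor
    CompoundEntry("hit-04", smiles="CCCCCCCCCCCCCCCC(=O)O", annotations={"pScore": 8, "aggregator": 1}),
]

verdicts, counts = apply_filters(panel)
for v in verdicts:
    status = "PASS" if v.overall else "FAIL"
    why = f"  ({'; '.join(v.reasons)})" if v.reasons else ""
    print(f"{v.compound_id}: {status}{why}")
print(f"per-rule failure counts: { {k: v for k, v in counts.items() if v} }")
print(f"survivors: {sorted(survivors(verdicts))}")
# Only hit-02 survives: a PAINS match, a pScore >= 300 exclusion (the
# threshold is inclusive) and an aggregator flag (which also breaks the
# rotatable-bond window) remove the rest.
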