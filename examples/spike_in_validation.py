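"""Estimate the event caller's FDR and FOR by spike-in simulation.

Simulates ancestor/descendant pairs with boosted transition rates so that
all four event categories are spiked in hundreds of times, pushes the read
evidence through the caller at the default operating point (depth 50,
evidence error 1%, thresholds c_min=10, t0=0.25, t2=0.75) and matches the
calls to the known truth.
"""

from temara.validation_sim import default_operating_point_fdr

confusion, rates = default_operating_point_fdr(seed=7)

print("type      FDR      FOR      TP    FP    FN      TN")
for etype, (fdr, for_) in rates.items():
    c = confusion.counts[etype]
    print(
        f"{etype:<8} {fdr:8.4f} {for_:8.5f} {c['tp']:5d} {c['fp']:5d} "
        f"{c['fn']:5d} {c['tn']:7d}"
    )
print(
    "\nFDR = FP/(FP+TP): the fraction of called events of a type that are "
    "not real.\nFOR = FN/(FN+TN): missed events among evaluable cells. A "
    "max FDR below 3%\nmeans called rates overstate true rates by at most a "
    "few percent, which\nadjust_for_fdr then corrects multiplicatively."
)
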