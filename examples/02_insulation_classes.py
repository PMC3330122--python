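"""Predict mobility/segregation classes across informative genetic backgrounds.

The rule engine encodes: a MatP/ZapB-dependent constraining process spreads in
cis from the Ter macrodomain while Ter sits at mid-cell, and stops at the
first functional insulator (consensus GYTGACGTCAGC + YfbV).  Deleting tidR,
yfbV, matP or zapB reshapes the prediction for every marker.
"""

from termd import CellCycleStage, predict_strain_profile, spread_intervals
from termd.fixtures import build_strain

MARKERS = ["Ori-3", "NSR-2", "NSR-5", "Right-2", "Ter-3", "Left-1", "NSL-4"]

for name in ("wt", "dtidR", "dyfbV", "dmatP"):
    strain = build_strain(name)
    ivs = spread_intervals(strain)
    spans = ", ".join(f"{iv.span_bp/1000:.0f} kb (stop: {iv.stopped_by})"
                      for iv in ivs) or "none"
    print(f"\n{name}: constraining-process reach = {spans}")
    df = predict_strain_profile(strain, MARKERS, CellCycleStage.ANCHORED)
    print(df.to_string(index=False))

# CONSTRAINED marks loci reached by the spread: they move like macrodomain
# loci and segregate late, although they sit in normally-free NS regions.
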