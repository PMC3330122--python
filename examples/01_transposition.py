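"""Cut-and-paste transposition of a chromosome segment, with exact lift-over.

Moves the Right macrodomain of the wild-type map between the Ori macrodomain
and the NS-Right region (the att coordinates of strain LC13-R127), then prints
the configuration string before and after, the size of the excised arc, and
where a few landmark features end up on the new map.
"""

from termd import configuration_string, segment_length, transpose
from termd.fixtures import wt_genome

wt = wt_genome()
attL, attR, attB2 = 1_099_533, 651_775, 153_248

print("before :", configuration_string(wt))
new, liftover = transpose(wt, attL, attR, attB2)
print("after  :", configuration_string(new))
print(f"excised arc: {segment_length(wt, attR, attL):,} bp "
      "(ascending attR -> attL)")

for name in ("tidR", "Right-2", "NSR-2", "oriC"):
    old = wt.feature(name).position_bp
    print(f"  {name:8s} {old:>9,} -> {liftover(old):>9,}")

# The transposed NSR region is now flanked by Ter with no insulator between:
# that is the configuration in which NSR markers lose their high mobility.
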