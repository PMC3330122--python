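"""Degenerate 12-mer scanning: find tidRL-like sites in a sequence.

Builds a 5-kb random sequence with three planted sites (tidR exact, tidL
exact, and a one-mismatch variant), scans with budgets 0 and 1, and shows the
palindrome bookkeeping that keeps a palindromic site from being counted twice.
"""

from termd import is_palindrome, mismatch_count, scan
from termd.fixtures import planted_motif_fasta
from termd.motifs import TID_CONSENSUS, TIDL_SEQ, TIDR_SEQ

seq, plants = planted_motif_fasta(
    seed=7, length=5000,
    plants={101: TIDR_SEQ, 2500: TIDL_SEQ, 4800: "GATGACGTCAGC"})
print(f"planted sites: {plants}")
print(f"tidR palindrome: {is_palindrome(TIDR_SEQ)}, "
      f"tidL palindrome: {is_palindrome(TIDL_SEQ)}")
print(f"tidR vs tidL Hamming distance: {mismatch_count(TIDL_SEQ, TIDR_SEQ)}")

for budget in (0, 1):
    hits = scan(seq, TID_CONSENSUS, max_mismatch=budget)
    print(f"\nbudget {budget}: {len(hits)} site(s)")
    for h in hits:
        print(f"  pos {h.position:>5}  {h.site}  strand {h.strand}  "
              f"{h.mismatches} mismatch(es)")

# With the budget at 1 the scanner reports every site within one change of
# the consensus exactly once per locus (forward/reverse duplicates of
# palindromic windows are collapsed), the convention for per-genome censuses.
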