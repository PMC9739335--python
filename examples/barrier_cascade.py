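"""Compose per-barrier RI values into total reproductive isolation.

Barriers act sequentially: each one only blocks the gene flow earlier
barriers let through.  The absolute contribution AC_n = RI_n (1 - sum of
earlier ACs) attributes the total to individual barriers.
"""

from ricascade import absolute_contributions, total_ri, ri_from_overlap, ri_asymmetric
from ricascade.barriers import BARRIER_ORDER, MISSING

# a pair with moderate range overlap (D = 0.45) but fully disjoint flowering
ri_eco = ri_from_overlap(0.45)   # 0.55
ri_phen = ri_from_overlap(0.0)   # 1.0: no shared flowering weeks
acs = absolute_contributions([ri_eco, ri_phen])
print(f"RI values: eco={ri_eco:.2f}, phenology={ri_phen:.2f}")
print(f"absolute contributions: {[round(a, 2) for a in acs]}, "
      f"total RI = {total_ri(acs):.2f}")
# a single complete barrier drives the total to 1.00 no matter what follows

# partially observed pair: pollen-stigma data missing, later barriers present
ris = [0.8, MISSING, 0.5]
acs = absolute_contributions(ris)
print(f"\nwith an untested barrier: RI={ris} -> AC={[round(a, 2) for a in acs]}, "
      f"T={total_ri(acs):.2f}  (missing barrier contributes 0)")

# heterospecific advantage: between-species crosses outperform conspecific
ri = ri_asymmetric(within=0.2, between=0.6)
print(f"\npollen germination 0.2 within vs 0.6 between -> RI = {ri:.2f} "
      "(negative: crossing is easier than selfing the species)")
print(f"barrier order: {BARRIER_ORDER}")
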