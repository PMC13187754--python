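"""The ee <-> DDG transform.

Enantiomeric excess saturates near 100%, so selectivity is regressed on the
activation free-energy difference DDG = RT ln((1+x)/(1-x)), which spreads
the top of the scale out and is strictly monotone (rank orders agree).
"""

import transelect as ts

print("   ee %    DDG kcal/mol (308.15 K)")
for ee in (0.0, 50.0, 90.0, 95.0, 99.0, 99.9, 100.0):
    print(f"  {ee:6.1f}    {ts.ee_to_ddg(ee).value:8.3f}")

round_trip = ts.ddg_to_ee(ts.ee_to_ddg(99.0).value)
print(f"\nround trip at 99% ee: {round_trip:.12f}")
# 99% ee -> 3.241 kcal/mol: the last four ee points span just 5 ee units but
# a full 2 kcal/mol, which is what makes the regression problem well-posed.
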