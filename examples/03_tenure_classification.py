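"""Classify parcels as owner- or renter-occupied by matching the situs
(geographic) address to the owner's mailing address.

A match score >= 0.85 (default) yields an owner-occupied call; the score
weights house number, street name, directional, and street type after
canonicalization.
"""

import pandas as pd

from blockscape import classify_tenure, match_score, normalize_address

pairs = [
    ("p1", "123 North Main Street", "123 N MAIN ST"),     # same address, spelled differently
    ("p2", "123 N Main St", "125 N Main St"),             # neighbor: number mismatch caps score
    ("p3", "47 Oak Ave", "PO BOX 442"),                   # absentee owner
    ("p4", "9 W Elm Blvd Apt 2", ""),                     # missing owner address
]
parcels = pd.DataFrame(pairs, columns=["parcel_id", "situs_address", "owner_address"])

for pid, situs, owner in pairs:
    a, b = normalize_address(situs), normalize_address(owner)
    print(f"{pid}: score={match_score(a, b):.2f}  ({situs!r} vs {owner!r})")

calls, errors = classify_tenure(parcels)
print("\ncalls (owner_occupied iff score >= threshold; missing owner -> renter):")
print(calls.to_string(index=False))
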