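"""Reproduce the published per-rank summary's weighted bottom row.

Feeds the printed per-rank specimen counts and mean percentages through the
specimen-weighted averaging rule (undefined entries carry no weight in
their column) and prints the recomputed bottom row.
"""

from taxback import weighted_mean_summary
from taxback.metrics import RankSummary, round_half_up

rows = [
    RankSummary("species", 10_348, 82.4, 70.0, 64.9),
    RankSummary("subgenus", 1_799, 73.1, 75.3, 46.5),
    RankSummary("genus", 3_212, 65.0, 72.3, 30.6),
    RankSummary("tribe", 1_231, 64.1, 72.0, 30.1),
    RankSummary("subfamily", 2_573, 70.0, 66.6, 66.6),
    RankSummary("family", 1, None, 100.0, 100.0),  # one specimen: NA balanced accuracy
]

balanced, precision, recall = weighted_mean_summary(rows)
print(f"weighted mean balanced accuracy: {round_half_up(balanced)}")
print(f"weighted mean precision:         {round_half_up(precision)}")
print(f"weighted mean recall:            {round_half_up(recall)}")

# Expected output: 75.8 / 70.6 / 55.4 — the family row's undefined balanced
# accuracy is excluded from that column's weights, so its single specimen
# only contributes to precision and recall.
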