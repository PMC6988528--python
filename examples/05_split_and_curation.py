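"""Deterministic filename-hash splitting and curation bookkeeping.

Shows that the subset assignment is a pure function of the filename, that
the empirical proportions approach the 20/30/50 band design, and how the
curation filters report what they removed.
"""

import numpy as np

from taxback import assign_split, filter_specimens
from taxback.curation import SpecimenRecord

a = assign_split("BMNH_drawer042_specimen7.tif")
print(f"{a.image_id} -> fraction {a.fraction:.2f} -> {a.subset} (stable on every call)")

rng = np.random.default_rng(0)
ids = [f"specimen_{rng.integers(1e12):012d}.tif" for _ in range(10_000)]
subsets = [assign_split(i).subset for i in ids]
for name in ("validation", "test", "training"):
    print(f"{name:>10}: {100 * subsets.count(name) / len(subsets):.1f}% of 10,000 filenames")

records = (
    [SpecimenRecord(f"clean_{i}.jpg", "Amara aenea", frozenset(), 500, 1000) for i in range(60)]
    + [SpecimenRecord("larva.jpg", "Amara aenea", frozenset({"larva"}), 500, 1000)]
    + [SpecimenRecord(f"rare_{i}.jpg", "Blemus discus", frozenset(), 500, 1000) for i in range(3)]
)
kept, log = filter_specimens(records, min_per_species=50)
print(f"\nkept {len(kept)} of {len(records)} records; removals by reason: {log}")

# The 20/30/50 shares mirror the validation/test/training band design; the
# larva-tagged image and the 3 specimens of the under-sampled species are
# removed before any training or evaluation.
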