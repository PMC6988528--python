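"""Specimen curation filters and the deterministic filename-hash split.

Specimens flagged during manual quality checks (ventral mounting, missing
body parts, larvae, unidentified material) are excluded, together with
unlabeled records and species represented by too few specimens. The
training/validation/test split is a pure function of the image filename:
a cryptographic digest of the name is scaled to a percentage in [0, 100)
and fixed bands assign the subset, so the split is reproducible from the
filenames alone and stable under any reordering of the dataset.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import pandas as pd

#: Quality-check tags that exclude a specimen from analysis.
EXCLUSION_TAGS: frozenset[str] = frozenset({"ventral", "missing_part", "larva", "unidentified"})

#: Split bands as (upper bound, subset); fractions are in [0, 100).
SPLIT_BANDS: tuple[tuple[float, str], ...] = (
    (20.0, "validation"),
    (50.0, "test"),
    (100.0, "training"),
)


@dataclass(frozen=True)
class SpecimenRecord:
    """One curated museum specimen image."""

    image_id: str
    species_label: str | None
    tags: frozenset[str] = field(default_factory=frozenset)
    width_px: int = 1
    height_px: int = 1

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError(f"{self.image_id}: non-positive pixel dimensions")

    @property
    def megapixels(self) -> float:
        return self.width_px * self.height_px / 1e6


@dataclass(frozen=True)
class SplitAssignment:
    image_id: str
    fraction: float
    subset: str


def filter_specimens(
    records: list[SpecimenRecord], min_per_species: int
) -> tuple[list[SpecimenRecord], dict[str, int]]:
    """Apply the curation filters in order, returning survivors and a log.

    Order matters: unlabeled records and quality-tag exclusions are removed
    first, and only then are species counted against ``min_per_species``, so
    the rare-species threshold sees post-exclusion counts. Input order is
    preserved. The log maps removal reason (``unlabeled``, ``tagged``,
    ``rare_species``) to the number of records removed for that reason.
    """
    if min_per_species < 1:
        raise ValueError("min_per_species must be >= 1")
    log = {"unlabeled": 0, "tagged": 0, "rare_species": 0}

    labeled = []
    for rec in records:
        if rec.species_label is None or str(rec.species_label).strip() == "":
            log["unlabeled"] += 1
        else:
            labeled.append(rec)

    clean = []
    for rec in labeled:
        if rec.tags & EXCLUSION_TAGS:
            log["tagged"] += 1
        else:
            clean.append(rec)

    counts: dict[str, int] = {}
    for rec in clean:
        counts[rec.species_label] = counts.get(rec.species_label, 0) + 1
    kept = [rec for rec in clean if counts[rec.species_label] >= min_per_species]
    log["rare_species"] = len(clean) - len(kept)
    return kept, log


def split_fraction(image_id: str) -> float:
    """Deterministic percentage in [0, 100) derived from the filename.

    SHA-256 of the UTF-8 bytes of the name; the first 8 bytes of the digest,
    read as a big-endian unsigned integer, are scaled by 100/2^64. The map is
    approximately uniform over random filenames.
    """
    if not image_id:
        raise ValueError("image_id must be non-empty")
    digest = hashlib.sha256(image_id.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") / 2**64 * 100.0


def subset_for_fraction(fraction: float) -> str:
    """Band rule: [0,20) validation, [20,50) test, [50,100) training."""
    for upper, subset in SPLIT_BANDS:
        if fraction < upper:
            return subset
    raise ValueError(f"fraction {fraction} outside [0, 100)")


def assign_split(image_id: str) -> SplitAssignment:
    """Assign a filename to validation/test/training via its hash fraction."""
    fraction = split_fraction(image_id)
    return SplitAssignment(image_id, fraction, subset_for_fraction(fraction))


# -- CSV interface ---------------------------------------------------------


def load_specimens(path) -> list[SpecimenRecord]:
    """Read a specimen metadata CSV.

    Header ``image_id,species,tags,width_px,height_px``; tags are
    semicolon-joined tokens; an empty species cell means unlabeled.
    """
    frame = pd.read_csv(path, dtype={"image_id": str, "species": str, "tags": str})
    records = []
    for row in frame.itertuples(index=False):
        species = None if pd.isna(row.species) or row.species.strip() == "" else row.species.strip()
        tags = frozenset() if pd.isna(row.tags) or not row.tags else frozenset(
            t.strip() for t in row.tags.split(";") if t.strip()
        )
        records.append(
            SpecimenRecord(row.image_id, species, tags, int(row.width_px), int(row.height_px))
        )
    return records


def specimens_to_frame(records: list[SpecimenRecord], with_split: bool = False) -> pd.DataFrame:
    """Tabulate records; optionally append hash ``fraction`` and ``subset``."""
    frame = pd.DataFrame(
        {
            "image_id": [r.image_id for r in records],
            "species": [r.species_label for r in records],
            "tags": [";".join(sorted(r.tags)) for r in records],
            "width_px": [r.width_px for r in records],
            "height_px": [r.height_px for r in records],
        }
    )
    if with_split:
        assignments = [assign_split(r.image_id) for r in records]
        frame["fraction"] = [a.fraction for a in assignments]
        frame["subset"] = [a.subset for a in assignments]
    return frame
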