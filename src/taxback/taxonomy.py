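"""Taxonomic hierarchy used for confidence roll-up and multi-rank evaluation.

The rank ladder is fixed, finest first: species, subgenus, genus, tribe,
subfamily, family. Many carabid species have no subgenus (and some checklists
omit tribe or subfamily); at an absent rank a species inherits its class from
the nearest finer rank that is present, so every species has a well-defined
class at every rank and roll-up mass is conserved along the ladder.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

#: Rank ladder, finest first. "family" is the coarsest (root) rank.
RANKS: tuple[str, ...] = ("species", "subgenus", "genus", "tribe", "subfamily", "family")

#: Ranks that must be present for every species.
REQUIRED_RANKS: frozenset[str] = frozenset({"species", "genus", "family"})


class TaxonomyError(ValueError):
    """Raised when a taxonomy violates a structural invariant."""


class TaxonomyTable:
    """Species-to-lineage mapping over the fixed rank ladder.

    Parameters
    ----------
    frame
        One row per species with columns ``species, subgenus, genus, tribe,
        subfamily, family``. Missing values (NaN or empty string) in the
        optional ranks mark the rank as absent for that species.

    Notes
    -----
    The taxonomy is validated on construction: species names must be unique,
    genus and family must never be absent, and the hierarchy must be a strict
    tree (e.g. one genus cannot sit in two tribes or two subfamilies). Taxon
    names are compared case-sensitively after whitespace trimming.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for rank in RANKS:
            if rank not in frame.columns:
                frame[rank] = pd.NA
            col = frame[rank].astype("string").str.strip()
            frame[rank] = col.mask(col.fillna("") == "")
        frame = frame[list(RANKS)]
        self._validate(frame)
        self._frame = frame.reset_index(drop=True)
        # Resolved lineage: absent ranks inherit from the nearest finer rank.
        resolved = self._frame.copy()
        for finer, coarser in zip(RANKS[:-1], RANKS[1:]):
            resolved[coarser] = resolved[coarser].fillna(resolved[finer])
        self._resolved = resolved.set_index(self._frame["species"])
        self._genus_sizes = self._frame.groupby("genus", sort=False)["species"].count()

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        dup = frame["species"][frame["species"].duplicated()]
        if not dup.empty:
            raise TaxonomyError(f"duplicate species name(s): {sorted(set(dup))}")
        for rank in REQUIRED_RANKS:
            if frame[rank].isna().any():
                missing = frame.loc[frame[rank].isna(), "species"].tolist()
                raise TaxonomyError(f"rank {rank!r} absent for species {missing}")
        # Strict-tree check: a taxon at a finer rank may map to at most one
        # (present) taxon at every coarser rank.
        for i, finer in enumerate(RANKS[1:-1], start=1):
            for coarser in RANKS[i + 1:]:
                sub = frame[[finer, coarser]].dropna()
                n_parents = sub.groupby(finer)[coarser].nunique()
                bad = n_parents[n_parents > 1]
                if not bad.empty:
                    name = bad.index[0]
                    raise TaxonomyError(
                        f"{finer} {name!r} maps to multiple {coarser} values: "
                        f"{sorted(sub.loc[sub[finer] == name, coarser].unique())}"
                    )

    # -- basic accessors ----------------------------------------------------

    @property
    def species(self) -> list[str]:
        """Species names in table order."""
        return self._frame["species"].tolist()

    @property
    def n_species(self) -> int:
        return len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        """Raw table (absent ranks as NA), one row per species."""
        return self._frame.copy()

    def __contains__(self, species: str) -> bool:
        return species in self._resolved.index

    def __len__(self) -> int:
        return len(self._frame)

    # -- lineage queries ----------------------------------------------------

    def _check_species(self, species: str) -> None:
        if species not in self._resolved.index:
            raise KeyError(f"unknown species: {species!r}")

    def ancestor_at_rank(self, species: str, rank: str) -> str:
        """Return the species' taxon at ``rank``.

        If the rank is absent for the species, the class at the nearest finer
        present rank is returned, so the result is always defined.
        """
        if rank not in RANKS:
            raise ValueError(f"unknown rank: {rank!r}")
        self._check_species(species)
        return self._resolved.at[species, rank]

    def lineage_at_rank(self, rank: str) -> pd.Series:
        """Series mapping every species to its (resolved) taxon at ``rank``."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank: {rank!r}")
        return self._resolved[rank].copy()

    def genus_size(self, species: str) -> int:
        """Number of species sharing the query species' genus (inclusive)."""
        self._check_species(species)
        return int(self._genus_sizes[self._resolved.at[species, "genus"]])

    def taxa_at_rank(self, rank: str) -> list[str]:
        """Distinct resolved taxa at ``rank``, lexically sorted."""
        return sorted(self.lineage_at_rank(rank).unique())

    def subset(self, species: Sequence[str]) -> "TaxonomyTable":
        """Taxonomy restricted to the given species (e.g. after curation)."""
        keep = set(species)
        unknown = keep - set(self._frame["species"])
        if unknown:
            raise KeyError(f"unknown species: {sorted(unknown)}")
        return TaxonomyTable(self._frame[self._frame["species"].isin(keep)])


def load_taxonomy(path) -> TaxonomyTable:
    """Load and validate a taxonomy CSV.

    The CSV must have a header with at least ``species``, ``genus`` and
    ``family`` columns; empty cells mark absent ranks.
    """
    frame = pd.read_csv(path, dtype="string")
    required = {"species", "genus", "family"}
    missing = required - set(frame.columns)
    if missing:
        raise TaxonomyError(f"taxonomy CSV missing column(s): {sorted(missing)}")
    return TaxonomyTable(frame)


def save_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    taxonomy.frame.to_csv(path, index=False)
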