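"""Confidence roll-up across taxonomic ranks and threshold backoff.

A species-level classifier emits a softmax vector per image. Confidence in a
higher-rank taxon is the sum of the confidences of its member species
(mass-conserving roll-up). The backoff procedure walks the rank ladder from
species toward family and emits the prediction at the first rank whose
maximum rolled-up confidence reaches the threshold; at family the mass is 1,
so the walk always terminates. Correctness is judged at the emitted rank:
the predicted taxon is compared with the ground-truth species' taxon at that
rank.

Note a deliberate property of the method: the argmax at a coarser rank need
not contain the species-level argmax, because many middling congeners can
out-sum a single confident outsider.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import RANKS, TaxonomyTable

#: Tolerance within which a softmax row must sum to 1 before renormalization.
ROW_SUM_TOL = 1e-6


@dataclass
class ConfidenceMatrix:
    """Per-image softmax vectors over the species classes.

    Rows must sum to 1 within 1e-6; they are renormalized to sum to exactly 1
    on construction (malformed rows raise). Column order is preserved.
    """

    image_ids: list[str]
    class_names: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.image_ids), len(self.class_names)):
            raise ValueError("values shape does not match ids/classes")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("duplicate class names")
        if self.values.size:
            sums = self.values.sum(axis=1)
            bad = np.abs(sums - 1.0) > ROW_SUM_TOL
            if bad.any():
                raise ValueError(
                    f"{bad.sum()} row(s) do not sum to 1 within {ROW_SUM_TOL} "
                    f"(first: {self.image_ids[int(np.argmax(bad))]!r})"
                )
            self.values = self.values / sums[:, None]

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    def row(self, image_id: str) -> pd.Series:
        i = self.image_ids.index(image_id)
        return pd.Series(self.values[i], index=self.class_names, name=image_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.image_ids, name="image_id"),
                            columns=self.class_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConfidenceMatrix":
        return cls(list(frame.index.astype(str)), list(frame.columns), frame.to_numpy(dtype=float))

    @classmethod
    def read_csv(cls, path, sep: str = ",") -> "ConfidenceMatrix":
        """First column ``image_id``, remaining columns species names."""
        return cls.from_frame(pd.read_csv(path, sep=sep, index_col="image_id"))

    def write_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep)


@dataclass(frozen=True)
class BackoffPrediction:
    image_id: str
    predicted_taxon: str
    predicted_rank: str
    confidence: float
    truth_species: str
    correct: bool


def _column_index(matrix: ConfidenceMatrix, taxonomy: TaxonomyTable) -> list[str]:
    if set(matrix.class_names) != set(taxonomy.species):
        raise ValueError("confidence matrix classes do not match taxonomy species")
    return matrix.class_names


def rollup(row: pd.Series, taxonomy: TaxonomyTable, rank: str) -> pd.Series:
    """Sum species confidences into rank-level taxa (mass preserving).

    ``row`` is indexed by species names. The result is indexed by the taxa at
    ``rank`` in lexical order.
    """
    lineage = taxonomy.lineage_at_rank(rank)  # raises on unknown rank
    if set(row.index) != set(lineage.index):
        raise ValueError("row index does not match taxonomy species")
    taxa = row.groupby(row.index.map(lineage)).sum()
    return taxa.sort_index()


def rollup_matrix(
    matrix: ConfidenceMatrix, taxonomy: TaxonomyTable, rank: str
) -> tuple[list[str], np.ndarray]:
    """Vectorized roll-up of every row; returns (sorted taxa, n x t array)."""
    classes = _column_index(matrix, taxonomy)
    lineage = taxonomy.lineage_at_rank(rank)
    taxa = sorted(set(lineage))
    pos = {t: j for j, t in enumerate(taxa)}
    col_to_taxon = np.array([pos[lineage[c]] for c in classes])
    out = np.zeros((matrix.n_images, len(taxa)))
    np.add.at(out.T, col_to_taxon, matrix.values.T)
    return taxa, out


def top_k(row: pd.Series, k: int) -> list[tuple[str, float]]:
    """The ``k`` highest-confidence classes, descending.

    Ties are broken by class-name lexical order. If ``k`` exceeds the number
    of classes, the full ranking is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(zip(row.index, row.to_numpy(dtype=float)), key=lambda t: (-t[1], t[0]))
    return [(name, float(v)) for name, v in ranked[:k]]


def predict_backoff(
    row: pd.Series, taxonomy: TaxonomyTable, threshold: float, truth: str
) -> BackoffPrediction:
    """Backoff prediction for a single image.

    Walks the ladder finest-to-coarsest and stops at the first rank whose
    maximum rolled-up confidence is >= ``threshold`` (family always stops,
    its mass being 1). Argmax ties break toward the lexically first taxon.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if truth not in taxonomy:
        raise KeyError(f"unknown truth species: {truth!r}")
    image_id = str(row.name) if row.name is not None else ""
    for rank in RANKS:
        rolled = rollup(row, taxonomy, rank)
        best = rolled.idxmax()  # sorted index -> lexically first among ties
        conf = float(rolled.loc[best])
        if conf >= threshold or rank == RANKS[-1]:
            truth_taxon = taxonomy.ancestor_at_rank(truth, rank)
            return BackoffPrediction(image_id, str(best), rank, conf, truth, str(best) == truth_taxon)
    raise AssertionError("unreachable: family rank always emits")


def predict_backoff_batch(
    matrix: ConfidenceMatrix,
    taxonomy: TaxonomyTable,
    threshold: float,
    truths: pd.Series | dict,
) -> pd.DataFrame:
    """Vectorized backoff over all rows.

    ``truths`` maps image_id to ground-truth species. Returns a DataFrame
    with columns ``image_id, predicted_taxon, predicted_rank, confidence,
    truth_species, correct``, one row per image in matrix order.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    truths = pd.Series(truths)
    missing = [i for i in matrix.image_ids if i not in truths.index]
    if missing:
        raise KeyError(f"no truth for image(s): {missing[:5]}")
    truth_species = truths.loc[matrix.image_ids]
    unknown = set(truth_species) - set(taxonomy.species)
    if unknown:
        raise KeyError(f"truth species not in taxonomy: {sorted(unknown)[:5]}")

    n = matrix.n_images
    pred_taxon = np.empty(n, dtype=object)
    pred_rank = np.empty(n, dtype=object)
    confidence = np.zeros(n)
    remaining = np.ones(n, dtype=bool)
    for rank in RANKS:
        if not remaining.any():
            break
        taxa, rolled = rollup_matrix(matrix, taxonomy, rank)
        best = rolled.argmax(axis=1)  # first max = lexically first (sorted taxa)
        conf = rolled[np.arange(n), best]
        stop = remaining & ((conf >= threshold) | (rank == RANKS[-1]))
        idx = np.flatnonzero(stop)
        pred_taxon[idx] = np.asarray(taxa, dtype=object)[best[idx]]
        pred_rank[idx] = rank
        confidence[idx] = conf[idx]
        remaining &= ~stop

    truth_at_rank = np.array(
        [taxonomy.ancestor_at_rank(s, r) for s, r in zip(truth_species, pred_rank)],
        dtype=object,
    )
    return pd.DataFrame(
        {
            "image_id": matrix.image_ids,
            "predicted_taxon": pred_taxon,
            "predicted_rank": pd.Categorical(pred_rank, categories=list(RANKS), ordered=True),
            "confidence": confidence,
            "truth_species": truth_species.to_numpy(),
            "correct": pred_taxon == truth_at_rank,
        }
    )


def filter_min_top1(
    matrix: ConfidenceMatrix, min_top1: float
) -> tuple[ConfidenceMatrix, dict[str, int]]:
    """Drop rows whose top-1 confidence is below ``min_top1``.

    An independent pre-filter (usable with either fixed species-level
    evaluation or backoff). Returns the filtered matrix and a
    ``{"kept": .., "dropped": ..}`` log.
    """
    if not 0.0 <= min_top1 <= 1.0:
        raise ValueError("min_top1 must be in [0, 1]")
    keep = matrix.values.max(axis=1) >= min_top1 if matrix.n_images else np.zeros(0, bool)
    kept = ConfidenceMatrix(
        [i for i, k in zip(matrix.image_ids, keep) if k],
        list(matrix.class_names),
        matrix.values[keep],
    )
    return kept, {"kept": int(keep.sum()), "dropped": int((~keep).sum())}


def topk_accuracy(matrix: ConfidenceMatrix, truths: pd.Series | dict, k: int) -> float:
    """Fraction of images whose ground-truth species is among the top k."""
    truths = pd.Series(truths)
    frame = matrix.to_frame()
    hits = 0
    for image_id, row in frame.iterrows():
        names = [name for name, _ in top_k(row, k)]
        hits += truths.loc[image_id] in names
    return hits / matrix.n_images
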