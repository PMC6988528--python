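"""One-vs-rest evaluation metrics, multi-rank confusion matrices and summaries.

Each taxon is scored one-vs-rest over the evaluated images: tp (truth is the
taxon and predicted as it), fp (not the taxon but predicted as it), tn
(neither), fn (the taxon but predicted otherwise). Derived measures:

    precision = tp/(tp+fp)        recall = TPR = tp/(tp+fn)
    accuracy  = (tp+tn)/total     TNR = tn/(tn+fp)
    balanced accuracy = (TPR+TNR)/2

A zero denominator makes a measure undefined; undefined values are carried
as ``None`` (never coerced to 0) and excluded from the unweighted per-rank
means and from the specimen-weighted column means, matching the NA handling
of tabulated per-rank summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .taxonomy import RANKS, TaxonomyTable

Counts = tuple[int, int, int, int]


@dataclass(frozen=True)
class ClassMetrics:
    class_name: str | None
    rank: str | None
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float | None
    recall: float | None
    accuracy: float | None
    balanced_accuracy: float | None
    tpr: float | None
    tnr: float | None


@dataclass(frozen=True)
class RankSummary:
    """Per-rank aggregate; means are percentages, ``None`` when undefined."""

    rank: str
    n_specimens: int
    mean_balanced_accuracy: float | None
    mean_precision: float | None
    mean_recall: float | None


def predictions_frame(predictions) -> pd.DataFrame:
    """Normalize a prediction collection to the canonical DataFrame layout."""
    if isinstance(predictions, pd.DataFrame):
        return predictions
    return pd.DataFrame([asdict(p) for p in predictions])


def _resolve_at_rank(frame: pd.DataFrame, rank: str, taxonomy: TaxonomyTable):
    """Map truths and predictions to ``rank``-level taxa.

    Predictions emitted at a rank finer than or equal to ``rank`` are rolled
    up along the ladder; a prediction emitted at a coarser rank cannot be
    resolved and raises.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank: {rank!r}")
    truth = frame["truth_species"].map(lambda s: taxonomy.ancestor_at_rank(s, rank))
    rank_pos = {r: i for i, r in enumerate(RANKS)}
    target = rank_pos[rank]

    taxon_up: dict[tuple[str, str], str] = {}
    for from_rank in RANKS[: target + 1]:
        fine = taxonomy.lineage_at_rank(from_rank)
        coarse = taxonomy.lineage_at_rank(rank)
        for sp in fine.index:
            taxon_up[(from_rank, fine[sp])] = coarse[sp]

    pred = []
    for taxon, prank in zip(frame["predicted_taxon"], frame["predicted_rank"]):
        prank = str(prank)
        if rank_pos[prank] > target:
            raise ValueError(
                f"prediction at rank {prank!r} cannot be evaluated at finer rank {rank!r}"
            )
        pred.append(taxon_up[(prank, taxon)])
    return truth.to_numpy(), np.array(pred, dtype=object)


def confusion_counts(
    predictions, class_name: str, rank: str, taxonomy: TaxonomyTable
) -> Counts:
    """One-vs-rest (tp, fp, tn, fn) for ``class_name`` at ``rank``."""
    if class_name not in taxonomy.taxa_at_rank(rank):
        raise KeyError(f"{class_name!r} is not a taxon at rank {rank!r}")
    frame = predictions_frame(predictions)
    truth, pred = _resolve_at_rank(frame, rank, taxonomy)
    is_truth = truth == class_name
    is_pred = pred == class_name
    tp = int((is_truth & is_pred).sum())
    fp = int((~is_truth & is_pred).sum())
    fn = int((is_truth & ~is_pred).sum())
    tn = len(frame) - tp - fp - fn
    return tp, fp, tn, fn


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def class_metrics(
    counts: Counts, class_name: str | None = None, rank: str | None = None
) -> ClassMetrics:
    """Derive the metric set from one-vs-rest counts (undefined stays None)."""
    tp, fp, tn, fn = (int(c) for c in counts)
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be non-negative")
    tpr = _ratio(tp, tp + fn)
    tnr = _ratio(tn, tn + fp)
    balanced = (tpr + tnr) / 2 if tpr is not None and tnr is not None else None
    return ClassMetrics(
        class_name=class_name,
        rank=rank,
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=_ratio(tp, tp + fp),
        recall=tpr,
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        balanced_accuracy=balanced,
        tpr=tpr,
        tnr=tnr,
    )


def confusion_matrix(predictions, rank: str, taxonomy: TaxonomyTable) -> pd.DataFrame:
    """Square truth x predicted matrix at ``rank`` (rows = truth taxa)."""
    frame = predictions_frame(predictions)
    truth, pred = _resolve_at_rank(frame, rank, taxonomy)
    taxa = taxonomy.taxa_at_rank(rank)
    out = pd.DataFrame(0, index=pd.Index(taxa, name="truth"), columns=taxa)
    for t, p in zip(truth, pred):
        out.at[t, p] += 1
    return out


def per_class_metrics(predictions, rank: str, taxonomy: TaxonomyTable) -> list[ClassMetrics]:
    """One-vs-rest metrics for every taxon at ``rank`` over the predictions."""
    cm = confusion_matrix(predictions, rank, taxonomy)
    total = int(cm.to_numpy().sum())
    out = []
    for taxon in cm.index:
        tp = int(cm.at[taxon, taxon])
        fp = int(cm[taxon].sum()) - tp
        fn = int(cm.loc[taxon].sum()) - tp
        tn = total - tp - fp - fn
        out.append(class_metrics((tp, fp, tn, fn), class_name=taxon, rank=rank))
    return out


def _mean_pct(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return 100.0 * float(np.mean(defined)) if defined else None


def rank_summaries(backoff_predictions, taxonomy: TaxonomyTable) -> list[RankSummary]:
    """Partition images by emitted rank and summarize each partition.

    Within a rank, every taxon with at least one specimen (as truth or as
    prediction) among the images emitted there is scored one-vs-rest against
    that partition, and defined per-class values are averaged unweighted.
    Ranks with no images are omitted.
    """
    frame = predictions_frame(backoff_predictions)
    summaries = []
    for rank in RANKS:
        part = frame[frame["predicted_rank"].astype(str) == rank]
        if part.empty:
            continue
        truth, pred = _resolve_at_rank(part, rank, taxonomy)
        seen = sorted(set(truth) | set(pred))
        per_class = []
        for taxon in seen:
            is_truth = truth == taxon
            is_pred = pred == taxon
            tp = int((is_truth & is_pred).sum())
            fp = int((~is_truth & is_pred).sum())
            fn = int((is_truth & ~is_pred).sum())
            tn = len(part) - tp - fp - fn
            per_class.append(class_metrics((tp, fp, tn, fn), class_name=taxon, rank=rank))
        summaries.append(
            RankSummary(
                rank=rank,
                n_specimens=len(part),
                mean_balanced_accuracy=_mean_pct([m.balanced_accuracy for m in per_class]),
                mean_precision=_mean_pct([m.precision for m in per_class]),
                mean_recall=_mean_pct([m.recall for m in per_class]),
            )
        )
    return summaries


def weighted_mean_summary(
    summaries: list[RankSummary],
) -> tuple[float | None, float | None, float | None]:
    """Specimen-weighted means of (balanced accuracy, precision, recall).

    Weights are each summary's ``n_specimens``; a rank whose value is
    undefined in a column is excluded from that column's weights (so an NA
    row does not drag the mean). Returns percentages.
    """
    if not summaries:
        raise ValueError("no summaries to aggregate")

    def column(getter):
        pairs = [(s.n_specimens, getter(s)) for s in summaries if getter(s) is not None]
        if not pairs:
            return None
        weights = np.array([w for w, _ in pairs], dtype=float)
        values = np.array([v for _, v in pairs], dtype=float)
        return float(np.average(values, weights=weights))

    return (
        column(lambda s: s.mean_balanced_accuracy),
        column(lambda s: s.mean_precision),
        column(lambda s: s.mean_recall),
    )


@dataclass(frozen=True)
class DistributionSummary:
    mean: float
    min: float
    max: float
    sd: float | None
    se: float | None


def recall_distribution(per_species_recalls) -> DistributionSummary:
    """Mean/min/max/sample-SD/SE of a per-species recall list (percent)."""
    values = np.asarray(list(per_species_recalls), dtype=float)
    if values.size == 0:
        raise ValueError("empty recall list")
    sd = float(np.std(values, ddof=1)) if values.size >= 2 else None
    return DistributionSummary(
        mean=float(values.mean()),
        min=float(values.min()),
        max=float(values.max()),
        sd=sd,
        se=sd / math.sqrt(values.size) if sd is not None else None,
    )


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as report tables print percentages."""
    factor = 10 ** ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)
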