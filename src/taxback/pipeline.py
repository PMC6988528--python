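"""End-to-end orchestration: curate -> split -> backoff -> metrics -> GLM.

The pipeline mirrors the evaluation workflow for a species-level classifier
on a curated museum image set: specimens are filtered (quality tags,
unlabeled records, rare species), assigned deterministically to
training/validation/test by their filename hash, the test images' softmax
rows are (optionally pre-filtered on top-1 and) pushed through threshold
backoff, per-class and per-rank metrics are aggregated, and the correctness
GLMs are fitted. Every artifact is written to the output directory together
with a manifest that reproduces the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .backoff import ConfidenceMatrix, filter_min_top1, predict_backoff_batch
from .curation import filter_specimens, load_specimens, specimens_to_frame
from .glm import build_design, fit_model
from .metrics import (
    per_class_metrics,
    rank_summaries,
    recall_distribution,
    weighted_mean_summary,
)
from .taxonomy import load_taxonomy

log = logging.getLogger("taxback")


@dataclass
class PipelineConfig:
    taxonomy_path: str
    specimens_path: str
    confidences_path: str
    out_dir: str
    threshold: float = 0.5
    min_top1: float = 0.0
    min_per_species: int = 50
    seed: int = 0
    fit_model1: bool = True

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0 or not 0.0 <= self.min_top1 <= 1.0:
            raise ValueError("threshold and min_top1 must be in [0, 1]")


def _setup_logging():
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
        log.addHandler(handler)
        log.setLevel(logging.INFO)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report bundle as a dict.

    Writes into ``config.out_dir``: the curated specimen table with split
    assignments, backoff predictions, species-level per-class metrics,
    per-rank summaries with specimen-weighted means, the recall
    distribution, GLM fit reports and a run manifest.
    """
    _setup_logging()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    taxonomy = load_taxonomy(config.taxonomy_path)
    records = load_specimens(config.specimens_path)
    log.info("loaded %d specimens, %d species in taxonomy", len(records), taxonomy.n_species)

    kept, removal_log = filter_specimens(records, config.min_per_species)
    for reason, count in removal_log.items():
        log.info("curation removed %d record(s): %s", count, reason)
    taxonomy = taxonomy.subset(sorted({r.species_label for r in kept}))

    table = specimens_to_frame(kept, with_split=True)
    table.to_csv(out / "specimens_split.csv", index=False)
    subset_counts = table["subset"].value_counts().to_dict()
    log.info("split: %s", subset_counts)

    matrix = ConfidenceMatrix.read_csv(config.confidences_path)
    test_ids = set(table.loc[table["subset"] == "test", "image_id"])
    keep_rows = [i for i, img in enumerate(matrix.image_ids) if img in test_ids]
    matrix = ConfidenceMatrix(
        [matrix.image_ids[i] for i in keep_rows], matrix.class_names, matrix.values[keep_rows]
    )
    log.info("evaluating %d test images", matrix.n_images)

    if config.min_top1 > 0:
        matrix, top1_log = filter_min_top1(matrix, config.min_top1)
        log.info("min-top1 filter: %s", top1_log)
    else:
        top1_log = {"kept": matrix.n_images, "dropped": 0}

    truths = table.set_index("image_id")["species"]
    species_preds = predict_backoff_batch(matrix, taxonomy, 0.0, truths)
    backoff_preds = predict_backoff_batch(matrix, taxonomy, config.threshold, truths)
    backoff_preds.to_csv(out / "backoff_predictions.csv", index=False)

    species_cm = per_class_metrics(species_preds, "species", taxonomy)
    pd.DataFrame([m.__dict__ for m in species_cm]).to_csv(out / "species_class_metrics.csv", index=False)

    summaries = rank_summaries(backoff_preds, taxonomy)
    wb, wp, wr = weighted_mean_summary(summaries)
    summary_frame = pd.DataFrame([s.__dict__ for s in summaries])
    summary_frame.to_csv(out / "rank_summaries.csv", index=False)

    recalls = [100.0 * m.recall for m in species_cm if m.recall is not None]
    dist = recall_distribution(recalls)

    training_ids = set(table.loc[table["subset"] == "training", "image_id"])
    training_counts = (
        table[table["image_id"].isin(training_ids)].groupby("species")["image_id"].count()
    )
    training_counts = training_counts.reindex(taxonomy.species, fill_value=0)
    design = build_design(species_preds, kept, taxonomy, training_counts)
    design.to_csv(out / "glm_design.csv", index=False)

    fits = {}
    try:
        fits["model2"] = fit_model(design, "model2")
        if config.fit_model1:
            fits["model1"] = fit_model(design, "model1")
    except ValueError as exc:
        log.warning("GLM stage skipped: %s", exc)

    report = {
        "n_test_images": int(matrix.n_images),
        "curation_log": removal_log,
        "split_counts": {k: int(v) for k, v in subset_counts.items()},
        "min_top1_log": top1_log,
        "species_top1_accuracy_pct": 100.0 * float(species_preds["correct"].mean()),
        "backoff_correct_pct": 100.0 * float(backoff_preds["correct"].mean()),
        "rank_summaries": [s.__dict__ for s in summaries],
        "weighted_means": {"balanced_accuracy": wb, "precision": wp, "recall": wr},
        "recall_distribution": dist.__dict__,
        "glm": {mid: f.to_records() for mid, f in fits.items()},
        "glm_separation": {mid: f.separated_terms for mid, f in fits.items()},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))

    manifest = {
        "config": dataclasses.asdict(config),
        "taxback_version": __version__,
        "versions": {m.__name__: m.__version__ for m in _version_modules()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _version_modules():
    import numpy, pandas, scipy, statsmodels  # noqa: E401

    return (numpy, pandas, scipy, statsmodels)
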