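"""Binomial GLMs for per-image classification correctness.

Two logistic-regression models explain whether an image was classified to
the correct species: model 1 uses species identity as a categorical
predictor; model 2 uses four numeric covariates — the classifier's top-1
value, body size in megapixels (a proxy for true body size under fixed
camera geometry), the number of species in the ground-truth genus, and the
number of training images of that species.

Numeric covariates are standardized (z-scored) before fitting for numerical
stability; estimates and Wald 95% intervals are reported on both the
standardized and the raw covariate scale (the transform is exact for the
linear predictor). Complete separation — e.g. a species whose images are all
correct in model 1 — is flagged by inspecting link-scale magnitudes rather
than silently reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .curation import SpecimenRecord
from .taxonomy import TaxonomyTable

MODEL2_COVARIATES = ("top1", "body_size_mpx", "n_congeners", "n_training_images")

#: |coefficient| on the link scale beyond which separation is suspected.
SEPARATION_LIMIT = 15.0


@dataclass(frozen=True)
class Term:
    name: str
    estimate: float
    ci_low: float
    ci_high: float


@dataclass
class GlmFit:
    """Fitted correctness model with terms on the link (log-odds) scale."""

    model_id: str
    terms: list[Term]
    terms_raw: list[Term] = field(default_factory=list)
    covariates: tuple[str, ...] = ()
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    separated_terms: list[str] = field(default_factory=list)
    n_obs: int = 0

    @property
    def separation_flag(self) -> bool:
        return bool(self.separated_terms)

    def term(self, name: str, raw: bool = False) -> Term:
        for t in (self.terms_raw if raw else self.terms):
            if t.name == name:
                return t
        raise KeyError(f"no term {name!r} in {self.model_id}")

    def to_records(self) -> list[dict]:
        recs = [dict(scale="standardized", **t.__dict__) for t in self.terms]
        recs += [dict(scale="raw", **t.__dict__) for t in self.terms_raw]
        return recs


def build_design(
    predictions,
    specimens: list[SpecimenRecord],
    taxonomy: TaxonomyTable,
    training_counts: dict[str, int] | pd.Series,
) -> pd.DataFrame:
    """Assemble one correctness row per evaluated image.

    ``predictions`` are species-level predictions (the backoff frame at
    threshold 0, or any frame with ``image_id, confidence, truth_species,
    correct``); ``training_counts`` maps species to its number of training
    images. Body size is ``width_px * height_px / 1e6`` megapixels.
    """
    from .metrics import predictions_frame

    frame = predictions_frame(predictions)
    by_id = {r.image_id: r for r in specimens}
    training_counts = pd.Series(training_counts)
    rows = []
    for rec in frame.itertuples(index=False):
        spec = by_id.get(rec.image_id)
        if spec is None:
            raise KeyError(f"no specimen metadata for image {rec.image_id!r}")
        species = rec.truth_species
        if species not in training_counts.index:
            raise KeyError(f"no training-image count for species of image {rec.image_id!r}")
        rows.append(
            {
                "image_id": rec.image_id,
                "correct": bool(rec.correct),
                "top1": float(rec.confidence),
                "body_size_mpx": spec.megapixels,
                "n_congeners": taxonomy.genus_size(species),
                "n_training_images": int(training_counts[species]),
                "species": species,
            }
        )
    design = pd.DataFrame(rows)
    design["log_n_congeners"] = np.log(design["n_congeners"])
    return design


def fit_model(
    rows: pd.DataFrame,
    model_id: str,
    covariates: tuple[str, ...] | None = None,
    standardize: bool = True,
) -> GlmFit:
    """Maximum-likelihood logistic regression with Wald 95% intervals.

    ``model1`` regresses correctness on species identity (treatment coding
    against the alphabetically first species); ``model2`` on the numeric
    covariates (default :data:`MODEL2_COVARIATES`, overridable for
    e.g. log-transformed genus size).
    """
    y = rows["correct"].astype(float)
    if y.nunique() < 2:
        raise ValueError("correctness is constant; the model cannot be fitted")

    if model_id == "model1":
        X = pd.get_dummies(rows["species"], prefix="species", drop_first=True, dtype=float)
        X = sm.add_constant(X)
        center, scale = {}, {}
        names = list(X.columns)
    elif model_id == "model2":
        covs = tuple(covariates) if covariates else MODEL2_COVARIATES
        Z = rows.loc[:, list(covs)].astype(float).copy()
        center = {c: float(Z[c].mean()) for c in covs} if standardize else {c: 0.0 for c in covs}
        scale = {c: float(Z[c].std(ddof=0)) or 1.0 for c in covs} if standardize else {c: 1.0 for c in covs}
        for c in covs:
            Z[c] = (Z[c] - center[c]) / scale[c]
        X = sm.add_constant(Z)
        names = list(X.columns)
    else:
        raise ValueError(f"unknown model_id: {model_id!r}")

    result = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    ci = result.conf_int(alpha=0.05)
    terms = [
        Term(name, float(result.params[name]), float(ci.loc[name, 0]), float(ci.loc[name, 1]))
        for name in names
    ]
    separated = [t.name for t in terms if abs(t.estimate) > SEPARATION_LIMIT]

    terms_raw: list[Term] = []
    if model_id == "model2":
        covs = tuple(c for c in names if c != "const")
        shift = sum(result.params[c] * center[c] / scale[c] for c in covs)
        b0 = result.params["const"] - shift
        # Intervals for the raw intercept would need the full covariance; the
        # slope transform (divide by the covariate SD) is exact.
        terms_raw.append(Term("const", float(b0), float("nan"), float("nan")))
        for c in covs:
            terms_raw.append(
                Term(c, float(result.params[c] / scale[c]),
                     float(ci.loc[c, 0] / scale[c]), float(ci.loc[c, 1] / scale[c]))
            )

    fit = GlmFit(
        model_id=model_id,
        terms=terms,
        terms_raw=terms_raw,
        covariates=tuple(c for c in names if c != "const"),
        center=center,
        scale=scale,
        separated_terms=separated,
        n_obs=len(rows),
    )
    fit._result = result  # keep the statsmodels result for prediction
    return fit


def sensitivity_profile(
    fit: GlmFit, rows: pd.DataFrame, vary: str, n_points: int = 50
) -> pd.DataFrame:
    """Predicted correctness probability along one covariate.

    All other covariates are held at their mean — except the genus-size term,
    held at its median — while ``vary`` sweeps its observed range. Returns a
    frame with columns ``(vary, probability)``.
    """
    if fit.model_id != "model2":
        raise ValueError("sensitivity profiles are defined for model2")
    if vary not in fit.covariates:
        raise KeyError(f"{vary!r} is not a covariate of {fit.model_id}")

    fixed = {}
    for c in fit.covariates:
        col = rows[c].astype(float)
        fixed[c] = float(col.median()) if c in ("n_congeners", "log_n_congeners") else float(col.mean())

    grid = np.linspace(rows[vary].astype(float).min(), rows[vary].astype(float).max(), n_points)
    result = fit._result
    eta = np.full(n_points, float(result.params["const"]))
    for c in fit.covariates:
        z = (grid if c == vary else np.full(n_points, fixed[c]))
        eta = eta + result.params[c] * (z - fit.center[c]) / fit.scale[c]
    return pd.DataFrame({vary: grid, "probability": expit(eta)})
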