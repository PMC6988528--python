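"""Synthetic taxonomies, specimen tables and softmax confidence matrices.

Stands in for a trained species-level CNN so the roll-up/backoff/metrics/GLM
stages can be exercised without images. The generative model is deliberately
simple but reproduces the statistical structure the analysis assumes:

* each image has a latent correctness propensity
  ``p = expit(beta0 + beta_size * megapixels - beta_genus * log(genus_size))``
  — larger-bodied species are easier, species in speciose genera harder;
* with probability ``p`` the Dirichlet concentration for the softmax row is
  centred on the true species, otherwise on a uniformly drawn congener (or,
  for a monotypic genus, a random other species) — confusion mass is thus
  concentrated within the true genus;
* the remaining concentration is ``alpha_genus`` split over the other genus
  members and ``alpha_bg`` split over all species outside the genus, and the
  row is a Dirichlet draw from that concentration vector, so rows sum to 1.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .backoff import ConfidenceMatrix
from .curation import SpecimenRecord
from .taxonomy import TaxonomyTable

#: Small fixed pools of higher taxa; genera are dealt to tribes round-robin
#: and each tribe belongs to exactly one subfamily, under a single family.
_TRIBES = tuple(f"Tribe{i:02d}" for i in range(1, 9))
_SUBFAMILY_OF_TRIBE = {t: f"Subfamily{(i // 2) + 1}" for i, t in enumerate(_TRIBES)}
_FAMILY = "Carabidae"


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for synthetic classifier outputs.

    Defaults emulate the study system: 80 genera holding ~291 species (mean
    3.6 species per genus, geometric law), ~66 images per species (the test
    set's mean), log-normal body sizes in megapixels, strong within-genus
    confusion leakage and correctness that improves with body size and
    degrades with genus size.
    """

    n_genera: int = 80
    genus_size_law: tuple = ("geometric", 291 / 80)
    images_per_species: int | tuple = 66
    alpha_true: float = 3.0
    alpha_genus: float = 2.0
    alpha_bg: float = 1.5
    beta0: float = 0.5
    beta_size: float = 1.0
    beta_genus: float = 0.5
    size_law: tuple = ("lognormal", -1.2, 0.7)
    seed: int = 0

    def __post_init__(self):
        if self.n_genera < 1:
            raise ValueError("n_genera must be >= 1")
        alphas = (self.alpha_true, self.alpha_genus, self.alpha_bg)
        if any(a < 0 for a in alphas) or not any(a > 0 for a in alphas):
            raise ValueError("alpha weights must be >= 0 and not all zero")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent generator for one stage (taxonomy 0, specimens 1, softmax 2)."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


def _draw_counts(law, size: int, rng: np.random.Generator) -> np.ndarray:
    """Integer draws (>= 1) from a named law: constant / geometric / uniform_int."""
    if isinstance(law, int):
        law = ("constant", law)
    name, *params = law
    if name == "constant":
        out = np.full(size, int(params[0]))
    elif name == "geometric":
        mean = float(params[0])
        if mean < 1:
            raise ValueError("geometric mean must be >= 1")
        out = rng.geometric(1.0 / mean, size)
    elif name == "uniform_int":
        lo, hi = int(params[0]), int(params[1])
        out = rng.integers(lo, hi + 1, size)
    else:
        raise ValueError(f"unknown count law: {name!r}")
    if (out < 1).any():
        raise ValueError("count law produced a value < 1")
    return out


def _draw_sizes(law, size: int, rng: np.random.Generator) -> np.ndarray:
    """Positive continuous draws (megapixels): constant / lognormal."""
    name, *params = law
    if name == "constant":
        return np.full(size, float(params[0]))
    if name == "lognormal":
        mu, sigma = float(params[0]), float(params[1])
        return rng.lognormal(mu, sigma, size)
    raise ValueError(f"unknown size law: {name!r}")


def simulate_taxonomy(config: SimulationConfig) -> TaxonomyTable:
    """Generate a taxonomy of ``n_genera`` genera under one family.

    Genus sizes follow ``genus_size_law``; genera are assigned round-robin
    to the fixed tribe pool. In genera of three or more species, the first
    half of the species are placed in a nominate subgenus and the rest have
    no subgenus, exercising the absent-rank inheritance rule downstream.
    """
    rng = config.rng(0)
    sizes = _draw_counts(config.genus_size_law, config.n_genera, rng)
    rows = []
    for g in range(config.n_genera):
        genus = f"Genus{g + 1:03d}"
        tribe = _TRIBES[g % len(_TRIBES)]
        for s in range(int(sizes[g])):
            has_subgenus = sizes[g] >= 3 and s < sizes[g] // 2
            rows.append(
                {
                    "species": f"{genus}_sp{s + 1:02d}",
                    "subgenus": f"{genus}_subg1" if has_subgenus else None,
                    "genus": genus,
                    "tribe": tribe,
                    "subfamily": _SUBFAMILY_OF_TRIBE[tribe],
                    "family": _FAMILY,
                }
            )
    return TaxonomyTable(pd.DataFrame(rows))


def simulate_specimens(
    taxonomy: TaxonomyTable, config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[SpecimenRecord]:
    """Generate specimen records with log-normal body sizes.

    Image pixel dimensions are derived from the drawn megapixel area with a
    2:1 (length:width) beetle aspect ratio.
    """
    rng = config.rng(1) if rng is None else rng
    records = []
    for species in taxonomy.species:
        n_img = int(_draw_counts(config.images_per_species, 1, rng)[0])
        mpx = _draw_sizes(config.size_law, n_img, rng)
        for i in range(n_img):
            width = max(1, int(round(np.sqrt(mpx[i] * 1e6 / 2.0))))
            records.append(
                SpecimenRecord(
                    image_id=f"{species}_{i + 1:04d}.jpg",
                    species_label=species,
                    tags=frozenset(),
                    width_px=width,
                    height_px=2 * width,
                )
            )
    return records


def correctness_propensity(
    specimens: list[SpecimenRecord], taxonomy: TaxonomyTable, config: SimulationConfig
) -> np.ndarray:
    """Per-image probability that the concentration targets the true species."""
    from scipy.special import expit

    mpx = np.array([r.megapixels for r in specimens])
    log_g = np.log([taxonomy.genus_size(r.species_label) for r in specimens])
    return expit(config.beta0 + config.beta_size * mpx - config.beta_genus * log_g)


def draw_correctness(
    specimens: list[SpecimenRecord],
    taxonomy: TaxonomyTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw the latent per-image correctness indicator.

    Returns a frame with ``image_id, species, megapixels, genus_size, p,
    latent_correct``. The indicator is the Bernoulli(p) draw deciding whether
    the Dirichlet concentration is placed on the true species; it is the
    variable the generator's correctness coefficients govern directly.
    """
    rng = config.rng(2) if rng is None else rng
    unknown = {r.species_label for r in specimens} - set(taxonomy.species)
    if unknown:
        raise KeyError(f"specimen species not in taxonomy: {sorted(unknown)[:5]}")
    p = correctness_propensity(specimens, taxonomy, config)
    latent = rng.random(len(specimens)) < p
    return pd.DataFrame(
        {
            "image_id": [r.image_id for r in specimens],
            "species": [r.species_label for r in specimens],
            "megapixels": [r.megapixels for r in specimens],
            "genus_size": [taxonomy.genus_size(r.species_label) for r in specimens],
            "p": p,
            "latent_correct": latent,
        }
    )


def simulate_confidences(
    taxonomy: TaxonomyTable,
    specimens: list[SpecimenRecord],
    config: SimulationConfig,
    return_latent: bool = False,
) -> ConfidenceMatrix | tuple[ConfidenceMatrix, pd.DataFrame]:
    """Draw one softmax row per specimen from the generative model.

    With ``return_latent=True`` also returns the frame from
    :func:`draw_correctness` augmented with the drawn target species.
    """
    rng = config.rng(2)
    latent = draw_correctness(specimens, taxonomy, config, rng)

    species = taxonomy.species
    n_sp = len(species)
    col = {s: j for j, s in enumerate(species)}
    genus_members: dict[str, np.ndarray] = {}
    lineage = taxonomy.lineage_at_rank("genus")
    for genus, members in lineage.groupby(lineage).groups.items():
        genus_members[genus] = np.array([col[s] for s in members])

    n_img = len(specimens)
    alpha = np.zeros((n_img, n_sp))
    targets = np.empty(n_img, dtype=int)
    for i, rec in enumerate(specimens):
        s_col = col[rec.species_label]
        members = genus_members[taxonomy.ancestor_at_rank(rec.species_label, "genus")]
        g = len(members)
        if latent["latent_correct"].iat[i]:
            target = s_col
        elif g > 1:
            others = members[members != s_col]
            target = int(others[rng.integers(len(others))])
        else:
            target = int((s_col + 1 + rng.integers(n_sp - 1)) % n_sp)
        if n_sp > g:
            alpha[i, :] = config.alpha_bg / (n_sp - g)
        if g > 1:
            alpha[i, members] = config.alpha_genus / (g - 1)
        alpha[i, target] = config.alpha_true
        targets[i] = target

    raw = rng.standard_gamma(alpha)
    values = raw / raw.sum(axis=1, keepdims=True)
    matrix = ConfidenceMatrix([r.image_id for r in specimens], list(species), values)
    if return_latent:
        latent = latent.assign(target_species=[species[t] for t in targets])
        return matrix, latent
    return matrix


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[TaxonomyTable, list[SpecimenRecord], ConfidenceMatrix, pd.DataFrame]:
    """Convenience wrapper: taxonomy, specimens, confidences, latent frame."""
    taxonomy = simulate_taxonomy(config)
    specimens = simulate_specimens(taxonomy, config)
    matrix, latent = simulate_confidences(taxonomy, specimens, config, return_latent=True)
    return taxonomy, specimens, matrix, latent
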