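"""Seeded generator of synthetic assessments and cohorts.

No real assessment data is distributable, so every other module is exercised
against draws from this generator.  Each subcategory is sampled
independently: Blank with probability ``blank_rate``, otherwise N/A with
(unconditional) probability ``na_rate``, otherwise Answered at a level drawn
from ``level_distribution`` (optionally overridden per area).

Reproducibility rule: laboratory ``i`` of a cohort uses
``numpy.random.SeedSequence([seed, i])``, so any single lab can be
regenerated without drawing the rest of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .scoring import NA, Assessment
from .taxonomy import Taxonomy

__all__ = ["GeneratorConfig", "generate_assessment", "generate_cohort"]

_PROB_TOL = 1e-9


@dataclass
class GeneratorConfig:
    seed: int = 0
    level_distribution: tuple[float, float, float, float] = (
        0.25, 0.25, 0.25, 0.25)
    area_level_distribution: dict[str, Sequence[float]] = field(
        default_factory=dict)
    blank_rate: float = 0.0
    na_rate: float = 0.0
    n_labs: int = 1
    label_prefix: str = "lab"

    def validate(self) -> None:
        for name, dist in [("level_distribution", self.level_distribution),
                           *((f"area_level_distribution[{a!r}]", d)
                             for a, d in self.area_level_distribution.items())]:
            if len(dist) != 4:
                raise ConfigError(f"{name}: need 4 probabilities, "
                                  f"got {len(dist)}")
            if any(p < 0 for p in dist):
                raise ConfigError(f"{name}: probabilities must be >= 0")
            if abs(sum(dist) - 1.0) > _PROB_TOL:
                raise ConfigError(f"{name}: probabilities sum to "
                                  f"{sum(dist)!r}, not 1")
        for name, rate in (("blank_rate", self.blank_rate),
                           ("na_rate", self.na_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {rate!r}")
        if self.blank_rate + self.na_rate > 1.0 + _PROB_TOL:
            raise ConfigError("blank_rate + na_rate must be <= 1")
        if self.n_labs < 1:
            raise ConfigError(f"n_labs must be >= 1, got {self.n_labs}")


def _lab_rng(cfg: GeneratorConfig, lab_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(lab_index)]))


def generate_assessment(cfg: GeneratorConfig, t: Taxonomy,
                        lab_index: int = 0) -> Assessment:
    """Draw one laboratory's assessment; deterministic under fixed inputs."""
    cfg.validate()
    rng = _lab_rng(cfg, lab_index)
    label = f"{cfg.label_prefix}-{lab_index + 1:03d}"

    levels: dict[str, int | str | None] = {}
    for area in t.areas:
        dist = np.asarray(
            cfg.area_level_distribution.get(area.id, cfg.level_distribution),
            dtype=float)
        for sid in t.subcategory_ids_in_area(area.id):
            u = rng.random()
            if u < cfg.blank_rate:
                continue  # blank: no recorded response
            if u < cfg.blank_rate + cfg.na_rate:
                levels[sid] = NA
            else:
                levels[sid] = int(rng.choice(4, p=dist)) + 1
    return Assessment.from_levels(
        levels, label=label, assessor_role="synthetic",
        lab_info={"name": label, "generator_seed": str(cfg.seed),
                  "lab_index": str(lab_index)})


def generate_cohort(cfg: GeneratorConfig, t: Taxonomy) -> list[Assessment]:
    """Draw ``cfg.n_labs`` independent laboratories."""
    cfg.validate()
    return [generate_assessment(cfg, t, lab_index=i)
            for i in range(cfg.n_labs)]
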