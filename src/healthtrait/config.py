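"""Configuration for the synthetic-cohort generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import yaml

#: Ordinal covariates generated per person: name -> (level probabilities).
#: Levels are coded 0, 1, 2, ... and enter latent ill-health linearly.
DEFAULT_COVARIATE_LEVELS: dict[str, tuple[float, ...]] = {
    "gender": (0.45, 0.55),              # 0 male, 1 female
    "age_group": (0.55, 0.35, 0.10),     # <65, 65-79, 80+
    "wealth_quintile": (0.2, 0.2, 0.2, 0.2, 0.2),  # 0 = richest
    "education": (0.7, 0.3),             # 0 qualified, 1 no qualification
    "activity": (0.45, 0.30, 0.25),      # 0 active, 1 moderate, 2 inactive
    "smoking": (0.45, 0.35, 0.20),       # never, former, current
    "drinking": (0.30, 0.45, 0.25),      # none, <=2/wk, >2/wk
    "falls": (0.7, 0.3),                 # 0 no, 1 yes
    "social_network": (0.35, 0.40, 0.25),  # large, moderate, small
    "employment": (0.45, 0.55),          # 0 in work, 1 not in work
}

#: Per-level shift of latent ill-health (theta); physical activity dominates,
#: matching the ordering of associations the analysis is meant to detect.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "gender": 0.12,
    "age_group": 0.35,
    "wealth_quintile": 0.12,
    "education": 0.12,
    "activity": 0.80,
    "smoking": 0.12,
    "drinking": -0.10,
    "falls": 0.25,
    "social_network": 0.06,
    "employment": 0.30,
}


@dataclass
class GeneratorConfig:
    """Study-design parameters of a synthetic longitudinal cohort.

    Defaults emulate the design the analysis targets: 45 ordinal items
    (2-5 categories) on 5 correlated first-order factors under one general
    factor, 6 waves, 6 wave-varying items (39 anchors), item-level MCAR
    missingness capped at 25% per person at baseline, wave-level drift in
    item parameters, 10 person-level covariates and binary outcomes
    (mortality, institutionalisation, 8 chronic conditions) driven by
    latent health.
    """

    n_persons: int = 500
    n_waves: int = 6
    n_items: int = 45
    n_first_order_factors: int = 5
    n_varying_items: int = 6
    varying_items: Optional[Sequence[int]] = None  # explicit indices override count
    categories_per_item: Optional[Sequence[int]] = None  # default: cycled 3,4,2,5,3
    n_cross_loading_items: int = 3
    mcar_rate: float = 0.05
    baseline_missing_cap: float = 0.25
    wave_drift_sd_b: float = 0.30
    wave_drift_sd_a: float = 0.15
    wave_effect_sd: float = 0.70   # sigma_u, SD of the wave random effect
    person_resid_sd: float = 0.70  # sigma_theta, SD of the person-wave residual
    second_order_loadings: Optional[Sequence[float]] = None  # default U(0.6, 0.9)
    covariate_levels: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_LEVELS))
    covariate_effects: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    mortality_base_rate: float = 0.20
    mortality_slope: float = 0.50
    institutionalisation_base_rate: float = 0.05
    institutionalisation_slope: float = 0.50
    n_chronic_conditions: int = 8
    chronic_base_rate: float = 0.20
    chronic_slope: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_waves < 2:
            raise ValueError("n_waves must be >= 2")
        if not (0 <= self.mcar_rate < 1):
            raise ValueError("mcar_rate must lie in [0, 1)")
        for name in ("wave_drift_sd_b", "wave_drift_sd_a", "wave_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.person_resid_sd <= 0:
            raise ValueError("person_resid_sd must be > 0")
        if self.categories_per_item is not None:
            cats = list(self.categories_per_item)
            if len(cats) != self.n_items:
                raise ValueError("categories_per_item length must equal n_items")
            if any(k < 2 for k in cats):
                raise ValueError("every item needs >= 2 categories")
        n_var = (
            len(self.varying_items) if self.varying_items is not None else self.n_varying_items
        )
        if n_var >= self.n_items:
            raise ValueError("varying-item count must be smaller than n_items")
        if set(self.covariate_effects) - set(self.covariate_levels):
            raise ValueError("covariate_effects references unknown covariates")

    def resolved_categories(self) -> list[int]:
        if self.categories_per_item is not None:
            return list(self.categories_per_item)
        pattern = [3, 4, 2, 5, 3]
        return [pattern[i % len(pattern)] for i in range(self.n_items)]

    def resolved_varying(self) -> list[int]:
        if self.varying_items is not None:
            return sorted(int(i) for i in self.varying_items)
        # last block of items, spread over factors by the round-robin assignment
        return list(range(self.n_items - self.n_varying_items, self.n_items))

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["varying_items"] = list(d["varying_items"]) if d["varying_items"] is not None else None
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
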