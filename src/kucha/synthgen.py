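"""Seeded synthetic-survey generator.

Emulates the statistical structure of a Taiwanese bitter-tea formulation
survey: ~32 store formulations drawing on ~73 plant materials with a
long-tailed popularity distribution (top material in ~10 of 32 recipes),
mean recipe size 5.7, a north > central > south richness gradient, and
realistic attribute marginals (cold-property ~46.5%, bitter-flavor ~69%,
whole-plant ~41%). It reproduces summary structure only, never the actual
surveyed recipes, so every pipeline stage is testable without field data.

Model choices:

* material popularity follows a Zipf-like law, weight(rank r) ∝ r^(−s);
  the default exponent is calibrated so the most popular material appears
  in roughly 10 of 32 formulations at the default survey size;
* formulation sizes are Poisson conditioned on ≥ 1, with the rate solved
  so the truncated mean equals ``mean_size``;
* attributes are sampled independently per material from the configured
  marginals; a single optional knob couples the cold property with the
  bitter flavor.

Everything is driven by one ``numpy`` Generator, so identical
(config, seed) pairs give identical datasets regardless of dict iteration
order.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from .survey_data import Formulation, PlantMaterial, SurveyDataset

__all__ = ["GeneratorConfig", "generate_survey", "plant_core_structure"]


def _norm(d: dict[str, float]) -> dict[str, float]:
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Survey-generator parameters; defaults emulate the bitter-tea study."""

    n_stores: int = 32
    n_species: int = 73          # number of materials (one species is split
                                 # into stem + leaf materials when >= 2)
    mean_size: float = 5.7       # mean materials per formulation
    popularity_exponent: float = 0.44  # Zipf exponent of material popularity
    # store-count mix across regions, proportional to the north > central >
    # south material-richness gradient (49/34/20)
    region_mix: dict[str, float] = field(
        default_factory=lambda: {"north": 49 / 103, "central": 34 / 103,
                                 "south": 20 / 103})
    n_families: int = 33
    family_exponent: float = 1.1  # skew of the family-size distribution
    part_shares: dict[str, float] = field(default_factory=lambda: {
        "whole_plant": 0.411, "root_rhizome": 0.206, "leaf": 0.14,
        "stem": 0.08, "fruit_seed": 0.08, "flower": 0.045, "bark": 0.028,
        "other": 0.01})
    property_shares: dict[str, float] = field(default_factory=lambda: {
        "cold": 0.465, "cool": 0.268, "neutral": 0.12, "warm": 0.11,
        "hot": 0.037})
    unknown_property_rate: float = 2 / 73
    flavor_probs: dict[str, float] = field(default_factory=lambda: {
        "bitter": 0.69, "sweet": 0.30, "plain": 0.20, "spicy": 0.08,
        "sour": 0.05, "salty": 0.02})
    cold_bitter_coupling: float = 0.0  # 0 = independent; 1 = cold forces bitter
    source_cell_probs: dict[str, float] = field(default_factory=lambda: {
        "both": 0.37, "cultivated_only": 0.23, "wild_only": 0.26,
        "neither": 0.14})
    function_tag_probs: dict[str, float] = field(default_factory=lambda: {
        "heat-clearing": 0.639, "detoxification": 0.548,
        "detumescence": 0.25, "diuresis": 0.25})

    def validate(self) -> None:
        if self.n_stores < 1:
            raise ValueError("n_stores must be >= 1")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.mean_size >= self.n_species:
            raise ValueError("mean_size must be < n_species")
        if self.mean_size <= 0:
            raise ValueError("mean_size must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8")


def _truncated_poisson_rate(mean: float) -> float:
    """Rate lambda with zero-truncated-Poisson mean equal to ``mean``."""
    if mean <= 1.0:
        return max(mean, 1e-9)

    def f(lam: float) -> float:
        return lam / (1.0 - math.exp(-lam)) - mean

    return brentq(f, 1e-9, mean + 1.0)


def _sample_sizes(rng: np.random.Generator, cfg: GeneratorConfig,
                  n: int) -> np.ndarray:
    lam = _truncated_poisson_rate(cfg.mean_size)
    sizes = np.empty(n, dtype=int)
    for i in range(n):
        while True:
            s = rng.poisson(lam)
            if 1 <= s <= cfg.n_species:
                sizes[i] = s
                break
    return sizes


def _material_registry(rng: np.random.Generator,
                       cfg: GeneratorConfig) -> dict[str, PlantMaterial]:
    n = cfg.n_species
    mids = [f"m{i + 1:03d}" for i in range(n)]
    # synthetic binomials; the last material re-uses the first species with a
    # different part, mirroring inventories where one plant yields two
    # materials (e.g. stem and leaf)
    species = [f"Genus{i + 1:03d} species{i + 1:03d}" for i in range(n)]
    parts = list(rng.choice(list(cfg.part_shares), size=n,
                            p=list(_norm(cfg.part_shares).values())))
    if n >= 2:
        species[-1] = species[0]
        parts[0], parts[-1] = "stem", "leaf"

    fam_w = np.arange(1, cfg.n_families + 1, dtype=float) ** (-cfg.family_exponent)
    fam_w /= fam_w.sum()
    fam_of_species: dict[str, str] = {}
    for sp in species:
        if sp not in fam_of_species:
            fam_of_species[sp] = f"Family{rng.choice(cfg.n_families, p=fam_w) + 1:02d}"

    props = _norm(cfg.property_shares)
    src = _norm(cfg.source_cell_probs)
    registry: dict[str, PlantMaterial] = {}
    for i, mid in enumerate(mids):
        if rng.random() < cfg.unknown_property_rate:
            prop = "unknown"
        else:
            prop = str(rng.choice(list(props), p=list(props.values())))
        flavors = set()
        for fl, p in cfg.flavor_probs.items():
            pp = p
            if fl == "bitter" and prop == "cold":
                pp = p + cfg.cold_bitter_coupling * (1.0 - p)
            if rng.random() < pp:
                flavors.add(fl)
        if not flavors:
            flavors.add("plain")
        cell = str(rng.choice(list(src), p=list(src.values())))
        tags = {t for t, p in cfg.function_tag_probs.items() if rng.random() < p}
        registry[mid] = PlantMaterial(
            material_id=mid,
            scientific_name=species[i],
            family=fam_of_species[species[i]],
            part_used=parts[i],
            local_name=f"local-{mid}",
            cultivated=cell in ("both", "cultivated_only"),
            wild=cell in ("both", "wild_only"),
            property=prop,
            flavors=frozenset(flavors),
            function_tags=frozenset(tags),
        )
    return registry


def generate_survey(config: GeneratorConfig | None = None,
                    seed: int = 0) -> SurveyDataset:
    """Draw a complete synthetic survey; identical (config, seed) pairs
    give identical datasets."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    registry = _material_registry(rng, cfg)
    mids = list(registry)

    pop = np.arange(1, cfg.n_species + 1, dtype=float) ** (-cfg.popularity_exponent)
    pop /= pop.sum()

    mix = _norm(cfg.region_mix)
    regions = list(rng.choice(list(mix), size=cfg.n_stores,
                              p=list(mix.values())))
    sizes = _sample_sizes(rng, cfg, cfg.n_stores)

    formulations = []
    for i in range(cfg.n_stores):
        chosen = rng.choice(cfg.n_species, size=sizes[i], replace=False, p=pop)
        formulations.append(Formulation(
            store_id=f"s{i + 1:03d}",
            region=regions[i],
            materials=frozenset(mids[j] for j in chosen),
        ))
    dataset = SurveyDataset(materials=registry, formulations=tuple(formulations))
    dataset.validate()
    return dataset


def plant_core_structure(dataset: SurveyDataset, pair: tuple[str, str],
                         target_count: int, seed: int = 0) -> SurveyDataset:
    """Minimally edit formulations so ``pair`` co-occurs in exactly
    ``target_count`` of them.

    Excess co-occurrences are broken by dropping one endpoint from a
    formulation; deficits are filled by adding both endpoints to
    formulations currently lacking the pair. All dataset invariants are
    preserved; an infeasible target (negative, or above N) is an error.
    """
    a, b = pair
    for end in (a, b):
        if end not in dataset.materials:
            raise KeyError(f"pair material {end!r} not in dataset")
    if not 0 <= target_count <= dataset.N:
        raise ValueError(
            f"target co-occurrence {target_count} infeasible for N={dataset.N}")

    rng = np.random.default_rng(seed)
    forms = list(dataset.formulations)
    has_pair = [i for i, f in enumerate(forms) if {a, b} <= f.materials]

    if len(has_pair) > target_count:
        excess = rng.permutation(has_pair)[: len(has_pair) - target_count]
        for i in excess:
            drop = a if rng.random() < 0.5 else b
            forms[i] = replace(forms[i], materials=forms[i].materials - {drop})
    elif len(has_pair) < target_count:
        candidates = [i for i in range(len(forms)) if i not in has_pair]
        chosen = rng.permutation(candidates)[: target_count - len(has_pair)]
        for i in chosen:
            forms[i] = replace(forms[i], materials=forms[i].materials | {a, b})

    out = SurveyDataset(materials=dataset.materials, formulations=tuple(forms))
    out.validate()
    return out
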