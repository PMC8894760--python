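"""Quantitative ethnobotany indices for formulation surveys.

Core quantities, following standard survey practice:

* **frequency** Ui — the number of stores (formulations) whose recipe
  contains material *i*; binary per store, so within-recipe quantity is
  irrelevant;
* **use value** UV = Ui / N, with N the total number of formulations
  surveyed — the standard relative-importance index;
* **Shannon diversity** H = −Σ Pi·log2(Pi), where Pi is material *i*'s
  share of all material occurrences (not of N);
* attribute distributions over the material inventory: family, plant part,
  cultivated/wild source, traditional property (nature) and flavor, and
  free-text function tags.

Internal values are exact ratios evaluated in floating point; display
rounding (half-to-even, matching how survey tables are conventionally
printed) lives in the ``display_*`` helpers and never feeds back into
computation.
"""

from __future__ import annotations

import logging
import math
from decimal import ROUND_HALF_EVEN, Decimal

from .survey_data import AbundanceVector, FrequencyTable, SurveyDataset

logger = logging.getLogger("kucha")

__all__ = [
    "compute_frequencies",
    "compute_use_values",
    "abundance_vector",
    "shannon_diversity",
    "mean_formulation_size",
    "family_distribution",
    "part_distribution",
    "source_distribution",
    "property_flavor_crosstab",
    "tag_prevalence",
    "round_half_even",
    "display_uv",
    "display_percent",
]


def round_half_even(x: float, ndigits: int) -> float:
    """Decimal round-half-to-even on the printed value of ``x``.

    Python's built-in ``round`` operates on the binary representation and
    can break ties the wrong way after radix conversion; quantizing the
    shortest decimal repr avoids that (0.3125 -> 0.312 at 3 digits).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_EVEN))


def display_uv(uv: float) -> str:
    """UV formatted at 3 decimals, half-to-even, trailing zeros trimmed
    (10/32 -> '0.312', 8/32 -> '0.25')."""
    return f"{round_half_even(uv, 3):g}"


def display_percent(share: float, decimals: int = 1) -> str:
    """A share formatted as a percentage at the given precision."""
    pct = round_half_even(share * 100.0, decimals)
    return f"{pct:.{decimals}f}%" if decimals else f"{pct:g}%"


def compute_frequencies(dataset: SurveyDataset) -> FrequencyTable:
    """Count, for every registered material, the formulations containing it.

    Materials in the registry but used nowhere get an explicit count of 0.
    """
    counts = {mid: 0 for mid in dataset.materials}
    for f in dataset.formulations:
        for mid in f.materials:
            counts[mid] += 1
    return FrequencyTable(counts=counts, N=dataset.N)


def compute_use_values(freq: FrequencyTable) -> dict[str, float]:
    """UV(m) = count(m) / N for every material in the table."""
    if freq.N < 1:
        raise ValueError("use values undefined for an empty survey (N=0)")
    return {mid: c / freq.N for mid, c in freq.counts.items()}


def abundance_vector(freq: FrequencyTable) -> AbundanceVector:
    """Occurrence shares Pi over nonzero-count materials (they sum to 1)."""
    total = freq.total_occurrences
    if total == 0:
        raise ValueError("all counts are zero; abundances undefined")
    props = {mid: c / total for mid, c in freq.counts.items() if c > 0}
    return AbundanceVector(proportions=props)


def shannon_diversity(freq: FrequencyTable, base: float = 2.0) -> float:
    """H = −Σ Pi·log_base(Pi) over nonzero-count materials.

    Pi is each material's share of total occurrences. Zero-count materials
    carry no occurrence mass and drop out. Defaults to bits (base 2).
    """
    abund = abundance_vector(freq)
    lb = math.log(base)
    h = -sum(p * math.log(p) / lb for p in abund.proportions.values())
    return max(h, 0.0)  # clamp -0.0 from a single material


def mean_formulation_size(dataset: SurveyDataset) -> float:
    """Average number of materials per formulation (183/32 -> 5.71875)."""
    return dataset.total_occurrences / dataset.N


def family_distribution(dataset: SurveyDataset) -> dict[str, dict[str, float]]:
    """Per-family species share and formulation share.

    ``species_share`` counts distinct botanical species (by scientific
    name, so stem and leaf of one species count once) in the family over
    all distinct species; ``formulation_share`` is the fraction of
    formulations containing at least one material of the family.
    """
    species_by_family: dict[str, set[str]] = {}
    family_of: dict[str, str] = {}
    for m in dataset.materials.values():
        species_by_family.setdefault(m.family, set()).add(m.scientific_name)
        family_of[m.material_id] = m.family
    n_species = len({m.scientific_name for m in dataset.materials.values()})

    form_hits: dict[str, int] = {fam: 0 for fam in species_by_family}
    for f in dataset.formulations:
        for fam in {family_of[mid] for mid in f.materials}:
            form_hits[fam] += 1

    return {
        fam: {
            "species_share": len(species) / n_species,
            "formulation_share": form_hits[fam] / dataset.N,
        }
        for fam, species in species_by_family.items()
    }


def part_distribution(dataset: SurveyDataset) -> dict[str, float]:
    """Share of materials per plant part; shares sum to 1."""
    n = len(dataset.materials)
    counts: dict[str, int] = {}
    for m in dataset.materials.values():
        counts[m.part_used] = counts.get(m.part_used, 0) + 1
    return {part: c / n for part, c in counts.items()}


def source_distribution(dataset: SurveyDataset) -> dict[str, float]:
    """Cultivated / wild / both shares of the material inventory.

    Cultivated and wild are independent flags, so the first two shares may
    sum above 1; ``both_share`` counts materials carrying both flags.
    """
    n = len(dataset.materials)
    cult = sum(m.cultivated for m in dataset.materials.values())
    wild = sum(m.wild for m in dataset.materials.values())
    both = sum(m.cultivated and m.wild for m in dataset.materials.values())
    return {
        "cultivated_share": cult / n,
        "wild_share": wild / n,
        "both_share": both / n,
    }


def property_flavor_crosstab(
    dataset: SurveyDataset,
) -> dict[str, dict]:
    """Property shares, flavor shares, and their joint shares.

    The denominator is the set of materials whose property is annotated
    (``property != 'unknown'``): surveys routinely carry a few materials
    with no compendium record, and those are excluded from both the
    property and the flavor tables. A material counts once per flavor it
    carries (multi-membership), so flavor shares may sum above 1.
    """
    annotated = [m for m in dataset.materials.values() if m.property != "unknown"]
    n = len(annotated)
    if n == 0:
        logger.warning("no materials with annotated property; crosstab empty")
        return {"property_shares": {}, "flavor_shares": {}, "joint_shares": {}}

    prop_counts: dict[str, int] = {}
    flav_counts: dict[str, int] = {}
    joint_counts: dict[tuple[str, str], int] = {}
    for m in annotated:
        prop_counts[m.property] = prop_counts.get(m.property, 0) + 1
        for v in m.flavors:
            flav_counts[v] = flav_counts.get(v, 0) + 1
            key = (m.property, v)
            joint_counts[key] = joint_counts.get(key, 0) + 1

    return {
        "property_shares": {p: c / n for p, c in prop_counts.items()},
        "flavor_shares": {v: c / n for v, c in flav_counts.items()},
        "joint_shares": {k: c / n for k, c in joint_counts.items()},
        "n_annotated": n,
    }


def tag_prevalence(
    dataset: SurveyDataset,
    tag_field: str = "function_tags",
    denominator: str = "all",
) -> dict[str, float]:
    """Share of materials carrying each tag in ``function_tags`` or
    ``pharmacology_tags``.

    ``denominator='all'`` uses every material; ``'tagged'`` restricts to
    materials carrying at least one tag in the chosen field.
    """
    if tag_field not in ("function_tags", "pharmacology_tags"):
        raise ValueError(f"unknown tag_field {tag_field!r}")
    if denominator not in ("all", "tagged"):
        raise ValueError(f"unknown denominator {denominator!r}")
    mats = list(dataset.materials.values())
    if denominator == "tagged":
        mats = [m for m in mats if getattr(m, tag_field)]
    n = len(mats)
    if n == 0:
        return {}
    counts: dict[str, int] = {}
    for m in mats:
        for tag in getattr(m, tag_field):
            counts[tag] = counts.get(tag, 0) + 1
    return {tag: c / n for tag, c in counts.items()}
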