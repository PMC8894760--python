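"""Regional stratification and k-way inventory overlap (Venn) analysis.

Two kinds of comparison arise in herbal-tea surveys: splitting one survey
by region and re-running the indices per stratum, and intersecting whole
material inventories (the surveyed tea against other published tea
traditions). Cross-inventory matching uses normalized scientific names,
since independent inventories do not share material ids.
"""

from __future__ import annotations

import logging
import re

from .survey_data import Formulation, SurveyDataset, VennPartition

logger = logging.getLogger("kucha")

__all__ = [
    "regional_subsets",
    "shared_materials",
    "venn_partition",
    "top_k_overlap",
    "normalize_name",
]

# Botanical-authority tokens: capitalized abbreviations, "ex", "&", parenthesized
# authors. Matching keeps only the first two Latin words (genus + epithet) plus
# any trailing lowercase part qualifier such as "(stem)".
_PAREN = re.compile(r"\([^)]*\)")


def normalize_name(name: str) -> str:
    """Normalize a scientific name for cross-inventory matching.

    Lowercases, strips authority strings, and keeps the genus + specific
    epithet (plus an infraspecific epithet after var./subsp. if present):
    ``"Andrographis paniculata (Burm. f.) Nees"`` ->
    ``"andrographis paniculata"``.
    """
    s = _PAREN.sub(" ", name).strip()
    tokens = s.split()
    kept: list[str] = []
    for tok in tokens:
        if len(kept) >= 2:
            low = tok.lower().rstrip(".")
            if low in ("var", "subsp", "ssp", "f") and len(tokens) > len(kept):
                continue
            if kept and kept[-1] != tok.lower() and tok.islower() and len(kept) == 2:
                kept.append(tok)  # infraspecific epithet
            break
        kept.append(tok.lower().strip(",."))
    return " ".join(kept[:3])


def regional_subsets(dataset: SurveyDataset) -> dict[str, SurveyDataset]:
    """Split a survey by region, keeping per-region formulations and the
    materials they use. Regions with no formulations are omitted with a
    warning."""
    by_region: dict[str, list[Formulation]] = {}
    for f in dataset.formulations:
        by_region.setdefault(f.region, []).append(f)

    subsets: dict[str, SurveyDataset] = {}
    for region in ("north", "central", "south", "unknown"):
        forms = by_region.get(region)
        if not forms:
            if region != "unknown":
                logger.warning("region %r has no formulations; omitted", region)
            continue
        used = set().union(*(f.materials for f in forms))
        subsets[region] = SurveyDataset(
            materials={mid: dataset.materials[mid] for mid in sorted(used)},
            formulations=tuple(forms),
        )
    return subsets


def shared_materials(subsets: dict[str, SurveyDataset]) -> set[str]:
    """Materials present in every one of the given region subsets."""
    if len(subsets) < 2:
        raise ValueError("need at least two subsets to intersect")
    sets = [set(d.materials) for d in subsets.values()]
    return set.intersection(*sets)


def venn_partition(inventories: dict[str, set[str]]) -> VennPartition:
    """Classify every element of the union by its k-bit membership
    signature across 2–5 named inventories.

    Signature bit *j* (in ``labels`` order) is 1 iff the element belongs to
    inventory *j*; empty inventories are allowed.
    """
    labels = tuple(inventories)
    k = len(labels)
    if not 2 <= k <= 5:
        raise ValueError(f"venn_partition supports 2-5 inventories, got {k}")
    sets = [set(inventories[lab]) for lab in labels]
    union = set().union(*sets)
    counts: dict[str, int] = {}
    for el in union:
        sig = "".join("1" if el in s else "0" for s in sets)
        counts[sig] = counts.get(sig, 0) + 1
    return VennPartition(
        labels=labels,
        signature_counts=counts,
        sizes=tuple(len(s) for s in sets),
    )


def top_k_materials(uv: dict[str, float], k: int,
                    freq: dict[str, int] | None = None) -> list[str]:
    """The k highest-UV materials; ties broken by frequency desc then name
    asc. Returns all materials (with a warning) if fewer than k exist."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(uv) < k:
        logger.warning("only %d materials available for top-%d; using all",
                       len(uv), k)
        k = len(uv)
    freq = freq or {}
    ranked = sorted(uv, key=lambda m: (-uv[m], -freq.get(m, 0), m))
    return ranked[:k]


def top_k_overlap(uv_a: dict[str, float], uv_b: dict[str, float],
                  k: int = 15,
                  labels: tuple[str, str] = ("a", "b")) -> VennPartition:
    """Venn partition of the two inventories' top-k highest-UV materials."""
    top_a = set(top_k_materials(uv_a, k))
    top_b = set(top_k_materials(uv_b, k))
    return venn_partition({labels[0]: top_a, labels[1]: top_b})
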