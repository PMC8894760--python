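"""Domain types and file IO for herbal-tea formulation surveys.

A survey consists of two tables:

* a **formulation table** — one row per (store, material) occurrence, i.e.
  long form, with columns ``store_id``, ``region``, ``material_id``; a wide
  variant with a semicolon-separated ``materials`` column is also accepted
  and normalized on read;
* an **attribute table** keyed by ``material_id``, carrying the botanical
  identity (scientific name, family, local name), the plant part used,
  cultivated/wild source flags, the traditional property (nature) and
  flavors, and free-text function / pharmacology tags.

A *plant material* is a specific part of a botanical species: the stem and
the leaf of one species are two distinct materials sharing one
``scientific_name``. All text IO is UTF-8 (local names contain Han
characters).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("kucha")

PARTS = (
    "whole_plant",
    "root_rhizome",
    "stem",
    "leaf",
    "flower",
    "fruit_seed",
    "bark",
    "other",
)
PROPERTIES = ("cold", "cool", "neutral", "warm", "hot", "unknown")
FLAVORS = ("sour", "bitter", "sweet", "spicy", "salty", "plain")
REGIONS = ("north", "central", "south", "unknown")

__all__ = [
    "PlantMaterial",
    "Formulation",
    "SurveyDataset",
    "FrequencyTable",
    "AbundanceVector",
    "VennPartition",
    "CoreNetwork",
    "load_survey",
    "write_report",
    "PARTS",
    "PROPERTIES",
    "FLAVORS",
    "REGIONS",
]


class ValidationError(ValueError):
    """A record violates a dataset invariant; the message names it."""


@dataclass(frozen=True)
class PlantMaterial:
    """One medicinal material: a plant part with its survey attributes."""

    material_id: str
    scientific_name: str
    family: str
    part_used: str = "other"
    local_name: str = ""
    cultivated: bool = False
    wild: bool = False
    property: str = "unknown"
    flavors: frozenset[str] = frozenset()
    function_tags: frozenset[str] = frozenset()
    pharmacology_tags: frozenset[str] = frozenset()

    def validate(self) -> None:
        if not self.material_id:
            raise ValidationError("material with empty material_id")
        if self.part_used not in PARTS:
            raise ValidationError(
                f"material {self.material_id!r}: unknown part_used {self.part_used!r}"
            )
        if self.property not in PROPERTIES:
            raise ValidationError(
                f"material {self.material_id!r}: unknown property {self.property!r}"
            )
        bad = set(self.flavors) - set(FLAVORS)
        if bad:
            raise ValidationError(
                f"material {self.material_id!r}: unknown flavors {sorted(bad)}"
            )


@dataclass(frozen=True)
class Formulation:
    """One store's recipe: the set of materials it combines."""

    store_id: str
    region: str
    materials: frozenset[str]

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(
                f"formulation {self.store_id!r}: unknown region {self.region!r}"
            )
        if len(self.materials) < 1:
            raise ValidationError(f"formulation {self.store_id!r} is empty")


@dataclass(frozen=True)
class SurveyDataset:
    """Material registry plus the list of formulations (N = its length)."""

    materials: Mapping[str, PlantMaterial]
    formulations: tuple[Formulation, ...]

    @property
    def N(self) -> int:
        return len(self.formulations)

    @property
    def total_occurrences(self) -> int:
        return sum(len(f.materials) for f in self.formulations)

    def validate(self) -> None:
        if self.N < 1:
            raise ValidationError("dataset has no formulations")
        for m in self.materials.values():
            m.validate()
        seen: set[str] = set()
        for f in self.formulations:
            f.validate()
            if f.store_id in seen:
                raise ValidationError(f"duplicate store_id {f.store_id!r}")
            seen.add(f.store_id)
            missing = f.materials - self.materials.keys()
            if missing:
                raise ValidationError(
                    f"formulation {f.store_id!r} references unknown material "
                    f"{sorted(missing)[0]!r}"
                )


@dataclass(frozen=True)
class FrequencyTable:
    """Per-material store counts Ui, with the survey size N."""

    counts: Mapping[str, int]
    N: int

    @property
    def total_occurrences(self) -> int:
        return sum(self.counts.values())

    def validate(self) -> None:
        for mid, c in self.counts.items():
            if not 0 <= c <= self.N:
                raise ValidationError(
                    f"material {mid!r}: count {c} outside [0, N={self.N}]"
                )


@dataclass(frozen=True)
class AbundanceVector:
    """Normalized occurrence proportions Pi over nonzero-count materials."""

    proportions: Mapping[str, float]

    def validate(self) -> None:
        total = sum(self.proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(f"proportions sum to {total}, not 1")
        for mid, p in self.proportions.items():
            if p <= 0:
                raise ValidationError(f"material {mid!r}: non-positive proportion {p}")


@dataclass(frozen=True)
class VennPartition:
    """Counts per k-bit membership signature across k named inventories.

    ``signature_counts`` maps strings like ``"101"`` (element in inventories
    0 and 2 but not 1, in ``labels`` order) to the number of elements of the
    union carrying that signature.
    """

    labels: tuple[str, ...]
    signature_counts: Mapping[str, int]
    sizes: tuple[int, ...]

    @property
    def union_size(self) -> int:
        return sum(self.signature_counts.values())

    def exclusive_count(self, label: str) -> int:
        j = self.labels.index(label)
        sig = "".join("1" if i == j else "0" for i in range(len(self.labels)))
        return self.signature_counts.get(sig, 0)

    def exclusive_share(self, label: str) -> float:
        """Fraction of an inventory found in no other inventory."""
        size = self.sizes[self.labels.index(label)]
        return self.exclusive_count(label) / size if size else 0.0

    def shared_by_all(self) -> int:
        return self.signature_counts.get("1" * len(self.labels), 0)

    def validate(self) -> None:
        k = len(self.labels)
        for sig, c in self.signature_counts.items():
            if len(sig) != k or set(sig) - {"0", "1"} or "1" not in sig:
                raise ValidationError(f"bad signature {sig!r} for k={k}")
            if c < 0:
                raise ValidationError(f"signature {sig!r}: negative count {c}")


@dataclass(frozen=True)
class CoreNetwork:
    """Thresholded drug-pair graph: UV-weighted nodes, count-weighted edges."""

    nodes: Mapping[str, float]
    edges: Mapping[tuple[str, str], int]
    threshold: int

    def validate(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise ValidationError(f"self-edge on {a!r}")
            if a > b:
                raise ValidationError(f"edge ({a!r}, {b!r}) not canonically ordered")
            if w <= self.threshold:
                raise ValidationError(
                    f"edge ({a!r}, {b!r}) weight {w} not above threshold {self.threshold}"
                )
            for end in (a, b):
                if end not in self.nodes:
                    raise ValidationError(f"edge endpoint {end!r} missing from nodes")


# ---------------------------------------------------------------------------
# Readers / writers


def _split_field(raw: object) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return frozenset()
    parts = (p.strip() for p in str(raw).split(";"))
    return frozenset(p for p in parts if p)


def _parse_bool(raw: object) -> bool:
    return str(raw).strip().lower() in {"1", "true", "yes", "y", "t"}


def _read_table(path: str | Path) -> pd.DataFrame:
    """CSV or TSV with auto-detected delimiter, UTF-8."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, encoding="utf-8")


def read_attributes(path: str | Path) -> dict[str, PlantMaterial]:
    df = _read_table(path)
    required = {"material_id", "scientific_name", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"attribute file missing columns {sorted(missing)}")
    materials: dict[str, PlantMaterial] = {}
    for _, row in df.iterrows():
        mid = str(row["material_id"]).strip()
        if mid in materials:
            raise ValidationError(f"duplicate material_id {mid!r} in attribute file")
        part = str(row.get("part_used", "") or "").strip() or "other"
        prop = str(row.get("property", "") or "").strip() or "unknown"
        materials[mid] = PlantMaterial(
            material_id=mid,
            scientific_name=str(row["scientific_name"]).strip(),
            family=str(row["family"]).strip(),
            part_used=part,
            local_name=str(row.get("local_name", "") or "").strip(),
            cultivated=_parse_bool(row.get("cultivated", "")),
            wild=_parse_bool(row.get("wild", "")),
            property=prop,
            flavors=_split_field(row.get("flavors")),
            function_tags=_split_field(row.get("function_tags")),
            pharmacology_tags=_split_field(row.get("pharmacology_tags")),
        )
    return materials


def read_formulations(path: str | Path) -> list[Formulation]:
    df = _read_table(path)
    if {"store_id", "region", "material_id"} <= set(df.columns):
        long = df
    elif {"store_id", "region", "materials"} <= set(df.columns):
        rows = []
        for _, row in df.iterrows():
            for mid in sorted(_split_field(row["materials"])):
                rows.append((row["store_id"], row["region"], mid))
        long = pd.DataFrame(rows, columns=["store_id", "region", "material_id"])
    else:
        raise ValidationError(
            "formulation file needs columns store_id, region, material_id "
            "(long form) or store_id, region, materials (wide form)"
        )

    formulations: list[Formulation] = []
    for store_id, group in long.groupby("store_id", sort=True):
        regions = set(group["region"].astype(str).str.strip())
        region = sorted(regions)[0]
        if len(regions) > 1:
            logger.warning("store %r lists multiple regions %s; using %r",
                           store_id, sorted(regions), region)
        if region not in REGIONS:
            logger.warning("store %r: unknown region %r mapped to 'unknown'",
                           store_id, region)
            region = "unknown"
        mids = [str(m).strip() for m in group["material_id"]]
        if len(mids) != len(set(mids)):
            dupes = sorted({m for m in mids if mids.count(m) > 1})
            logger.warning("store %r: duplicate material rows %s collapsed",
                           store_id, dupes)
        mats = frozenset(mids)
        if not mats:
            raise ValidationError(f"formulation {store_id!r} empty after deduplication")
        formulations.append(Formulation(str(store_id), region, mats))
    return formulations


def load_survey(formulations_file: str | Path,
                attributes_file: str | Path) -> SurveyDataset:
    """Read and cross-validate the two survey tables.

    Duplicate (store, material) rows collapse to one set membership with a
    warning; a formulation row naming a material absent from the attribute
    table is a hard error.
    """
    materials = read_attributes(attributes_file)
    formulations = read_formulations(formulations_file)
    dataset = SurveyDataset(materials=materials, formulations=tuple(formulations))
    dataset.validate()
    return dataset


def write_survey(dataset: SurveyDataset, formulations_file: str | Path,
                 attributes_file: str | Path) -> None:
    """Inverse of :func:`load_survey` (long-form formulation table)."""
    rows = [
        {"store_id": f.store_id, "region": f.region, "material_id": mid}
        for f in dataset.formulations
        for mid in sorted(f.materials)
    ]
    pd.DataFrame(rows).to_csv(formulations_file, index=False, encoding="utf-8")
    arows = []
    for m in sorted(dataset.materials.values(), key=lambda m: m.material_id):
        arows.append({
            "material_id": m.material_id,
            "scientific_name": m.scientific_name,
            "family": m.family,
            "local_name": m.local_name,
            "part_used": m.part_used,
            "cultivated": m.cultivated,
            "wild": m.wild,
            "property": m.property,
            "flavors": ";".join(sorted(m.flavors)),
            "function_tags": ";".join(sorted(m.function_tags)),
            "pharmacology_tags": ";".join(sorted(m.pharmacology_tags)),
        })
    pd.DataFrame(arows).to_csv(attributes_file, index=False, encoding="utf-8")


def write_report(result: object, path: str | Path) -> None:
    """Serialize a pipeline result to delimited text or JSON.

    Tables (FrequencyTable, plain mappings) go to CSV; nested results
    (VennPartition, CoreNetwork) go to JSON. Ordering is deterministic:
    frequency tables sort by count descending then material_id; everything
    else by key.
    """
    path = Path(path)
    if isinstance(result, FrequencyTable):
        rows = sorted(result.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        df = pd.DataFrame(rows, columns=["material_id", "count"])
        df["N"] = result.N
        df.to_csv(path, index=False, encoding="utf-8")
    elif isinstance(result, AbundanceVector):
        rows = sorted(result.proportions.items(), key=lambda kv: (-kv[1], kv[0]))
        pd.DataFrame(rows, columns=["material_id", "proportion"]).to_csv(
            path, index=False, encoding="utf-8")
    elif isinstance(result, VennPartition):
        payload = {
            "labels": list(result.labels),
            "sizes": list(result.sizes),
            "signature_counts": dict(sorted(result.signature_counts.items())),
        }
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    elif isinstance(result, CoreNetwork):
        payload = {
            "threshold": result.threshold,
            "nodes": dict(sorted(result.nodes.items())),
            "edges": [
                {"material_a": a, "material_b": b, "count": c}
                for (a, b), c in sorted(result.edges.items())
            ],
        }
        path.write_text(json.dumps(payload, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    elif isinstance(result, Mapping):
        rows = sorted(result.items())
        pd.DataFrame(rows, columns=["key", "value"]).to_csv(
            path, index=False, encoding="utf-8")
    else:
        raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def read_frequency_table(path: str | Path) -> FrequencyTable:
    df = pd.read_csv(path, dtype={"material_id": str}, encoding="utf-8")
    counts = {str(r.material_id): int(r.count) for r in df.itertuples()}
    n = int(df["N"].iloc[0]) if "N" in df.columns and len(df) else 0
    return FrequencyTable(counts=counts, N=n)


def read_venn_partition(path: str | Path) -> VennPartition:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return VennPartition(
        labels=tuple(payload["labels"]),
        signature_counts=dict(payload["signature_counts"]),
        sizes=tuple(payload["sizes"]),
    )


def read_core_network(path: str | Path) -> CoreNetwork:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    edges = {(e["material_a"], e["material_b"]): int(e["count"])
             for e in payload["edges"]}
    return CoreNetwork(nodes=dict(payload["nodes"]), edges=edges,
                       threshold=int(payload["threshold"]))
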