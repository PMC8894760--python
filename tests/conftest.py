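from __future__ import annotations

import pytest

from kucha.survey_data import Formulation, PlantMaterial, SurveyDataset


def make_material(mid: str, **kw) -> PlantMaterial:
    defaults = dict(
        material_id=mid,
        scientific_name=f"Genus {mid}",
        family="Family01",
        part_used="whole_plant",
    )
    defaults.update(kw)
    return PlantMaterial(**defaults)


def make_dataset(formulations: dict[str, tuple[str, set[str]]],
                 materials: dict[str, dict] | None = None) -> SurveyDataset:
    """Build a small validated dataset.

    ``formulations`` maps store_id -> (region, material-id set); material
    attributes default to a plain whole-plant record unless overridden via
    ``materials`` (material_id -> PlantMaterial kwargs).
    """
    materials = materials or {}
    all_mids = set(materials) | {m for _, (_, mats) in sorted(formulations.items())
                                 for m in mats}
    registry = {mid: make_material(mid, **materials.get(mid, {}))
                for mid in sorted(all_mids)}
    forms = tuple(
        Formulation(store_id=sid, region=region, materials=frozenset(mats))
        for sid, (region, mats) in sorted(formulations.items())
    )
    ds = SurveyDataset(materials=registry, formulations=forms)
    ds.validate()
    return ds


@pytest.fixture
def toy_dataset() -> SurveyDataset:
    """Three formulations over four materials: A in all, D unused."""
    return make_dataset(
        {"s1": ("north", {"A", "B"}),
         "s2": ("central", {"A", "C"}),
         "s3": ("south", {"A"})},
        materials={"D": {}},
    )
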