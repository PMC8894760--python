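#!/usr/bin/env python
"""Inventory comparisons: regional overlap and cross-tradition Venn.

Stratifies the survey by region (species richness, Shannon diversity,
materials common to all regions), then compares the bitter-tea inventory
with the synthetic green-herb-tea survey from 01_simulate.py: full-
inventory Venn partition and the overlap of the two top-15 UV lists.
"""

from pathlib import Path

from kucha.indices import (
    compute_frequencies,
    compute_use_values,
    display_percent,
    shannon_diversity,
)
from kucha.set_comparison import (
    normalize_name,
    regional_subsets,
    shared_materials,
    top_k_overlap,
    venn_partition,
)
from kucha.survey_data import load_survey, write_report

SURVEY = Path("results/survey")
OUT = Path("results/compare")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bitter = load_survey(SURVEY / "formulations.csv",
                         SURVEY / "attributes.csv")
    green = load_survey(SURVEY / "green_formulations.csv",
                        SURVEY / "green_attributes.csv")

    subsets = regional_subsets(bitter)
    for region, sub in subsets.items():
        h = shannon_diversity(compute_frequencies(sub))
        print(f"{region}: {sub.N} formulations, {len(sub.materials)} "
              f"materials, Shannon {h:.2f} bits")
    named = {r: s for r, s in subsets.items() if r != "unknown"}
    if len(named) >= 2:
        common = shared_materials(named)
        print(f"materials used in every region: {len(common)}")
        regional = venn_partition({r: set(s.materials)
                                   for r, s in named.items()})
        write_report(regional, OUT / "regional_venn.json")

    # cross-tradition comparison keyed by normalized scientific name
    names = {
        label: {normalize_name(m.scientific_name)
                for m in ds.materials.values()}
        for label, ds in (("bitter", bitter), ("green", green))
    }
    venn = venn_partition(names)
    write_report(venn, OUT / "tradition_venn.json")
    excl = venn.exclusive_share("bitter")
    print(f"bitter-tea-only species: {venn.exclusive_count('bitter')} of "
          f"{venn.sizes[0]} ({display_percent(excl, decimals=0)})")

    uv_b = compute_use_values(compute_frequencies(bitter))
    uv_g = compute_use_values(compute_frequencies(green))
    top15 = top_k_overlap(uv_b, uv_g, k=15, labels=("bitter", "green"))
    write_report(top15, OUT / "top15_venn.json")
    print(f"top-15 UV lists share {top15.shared_by_all()} materials")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
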