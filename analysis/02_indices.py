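#!/usr/bin/env python
"""Survey indices: frequency/UV table, Shannon diversity, attribute tables.

Loads the survey written by 01_simulate.py, computes every material-level
index, and writes the tables under results/indices/ (same fixed file names
the `kucha all` bundle uses).
"""

from pathlib import Path

from kucha.cli import _write_indices
from kucha.indices import display_uv
from kucha.survey_data import load_survey

SURVEY = Path("results/survey")
OUT = Path("results/indices")


def main() -> None:
    ds = load_survey(SURVEY / "formulations.csv", SURVEY / "attributes.csv")
    OUT.mkdir(parents=True, exist_ok=True)
    stats = _write_indices(ds, OUT)

    print(f"N={stats['n_formulations']}, materials={stats['n_materials']}, "
          f"occurrences={stats['total_occurrences']}")
    print(f"mean formulation size: {stats['mean_formulation_size']:.4f}")
    for region, h in stats["shannon"].items():
        print(f"Shannon ({region}): {h:.2f} bits")
    import pandas as pd
    top = pd.read_csv(OUT / "frequency_uv.csv").head(5)
    print("top five materials by UV:")
    for _, r in top.iterrows():
        print(f"  {r['material_id']}: {r['count']} of "
              f"{stats['n_formulations']} (UV {display_uv(r['uv'])})")
    print(f"tables written to {OUT}/")


if __name__ == "__main__":
    main()
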