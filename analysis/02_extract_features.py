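"""Extract the 95-feature panel from the simulated cohorts.

Reads the NIfTI cohorts written by 01_simulate_cohorts.py through the
same I/O path an external cohort would use, quantizes each map at the
operating point Ng = 64, and writes one feature matrix per regime under
results/.
"""

from pathlib import Path

import pandas as pd

from hcc_radiomics.io_model import read_cohort, read_lesion
from hcc_radiomics.texture.panel import extract_all

ROOT = Path(__file__).resolve().parents[1]
NG = 64


def main() -> None:
    for regime_dir in ("mean_texture", "texture-only"):
        csv_path = ROOT / "scratch" / "cohorts" / regime_dir / "cohort.csv"
        if not csv_path.exists():
            raise SystemExit(f"{csv_path} missing - run 01_simulate_cohorts.py first")
        rows = []
        for rec in read_cohort(csv_path):
            adc, ve, mask = read_lesion(rec)
            fv = extract_all(adc, ve, mask, ng=NG, lesion_id=rec.lesion_id)
            rows.append(fv.as_series())
        table = pd.DataFrame(rows)
        table.index.name = "lesion_id"
        out = ROOT / "results" / f"features_{regime_dir}.csv"
        out.parent.mkdir(exist_ok=True)
        table.to_csv(out)
        print(f"{regime_dir}: {table.shape[0]} lesions x {table.shape[1]} "
              f"features -> {out}")
        print("  adc_global_mean range:",
              round(table.adc_global_mean.min(), 3), "-",
              round(table.adc_global_mean.max(), 3))


if __name__ == "__main__":
    main()
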