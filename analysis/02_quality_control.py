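#!/usr/bin/env python
"""Marker and sample quality control on the simulated panel.

Filters: autosomes only (done at read), marker call rate >= 95%,
MAF >= 1%, then animal missingness <= 2% — equality retains throughout,
and no LD pruning anywhere. Writes the filtered panel and the attrition
report to results/qc/.
"""

from pathlib import Path

import pandas as pd

from rohscan.io import read_metadata, read_ped_map, write_metadata, write_ped_map
from rohscan.qc import apply_qc

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = read_ped_map(ROOT / "panel" / "panel.ped", ROOT / "panel" / "panel.map")
    meta = read_metadata(ROOT / "panel" / "metadata.tsv")
    panel, report = apply_qc(panel)
    meta = meta[meta["animal_id"].isin(set(panel.animal_ids))]

    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    write_ped_map(panel, out / "qc.ped", out / "qc.map", meta)
    write_metadata(meta, out / "metadata.tsv")
    pd.DataFrame([report.as_dict()]).to_csv(out / "qc_report.tsv", sep="\t", index=False)

    r = report
    print(f"markers: {r.n_snps_in} -> {r.n_snps_out} "
          f"(call rate -{r.removed_snps_callrate}, MAF -{r.removed_snps_maf})")
    print(f"animals: {r.n_animals_in} -> {r.n_animals_out} "
          f"(missingness -{r.removed_animals_missing})")
    print(f"wrote filtered panel under {out}")


if __name__ == "__main__":
    main()
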