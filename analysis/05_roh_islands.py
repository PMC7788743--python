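#!/usr/bin/env python
"""ROH islands: per-marker incidence of common runs, island calling,
population-sharing classes and the breed-effect model per island.

An island is a maximal stretch of consecutive markers covered by runs in
strictly more than 20 animals, spanning >1 Mb with >=30 markers.
Sharing classes: unique (1 population), shared (2-3), common (>3).
Per island, the proportion of member markers each sample covers is
modelled as proportion = mu + breed + error (one-way ANOVA).
Writes incidence, island and ANOVA tables to results/islands/.
"""

from pathlib import Path

import pandas as pd

from rohscan.io import read_metadata, read_ped_map, read_roh_table
from rohscan.islands import (
    analyze_islands,
    annotate_islands,
    call_islands,
    incidence_per_snp,
    islands_to_frame,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    panel = read_ped_map(ROOT / "qc" / "qc.ped", ROOT / "qc" / "qc.map")
    meta = read_metadata(ROOT / "qc" / "metadata.tsv")
    runs = read_roh_table(ROOT / "roh" / "roh.tsv")

    inc = incidence_per_snp(runs, panel.snp_map, meta)
    islands = annotate_islands(call_islands(inc), runs, panel.snp_map, meta)
    anova = analyze_islands(islands, runs, panel.snp_map, meta)

    out = ROOT / "islands"
    out.mkdir(parents=True, exist_ok=True)
    inc.to_csv(out / "incidence.tsv", sep="\t", index=False)
    tab = islands_to_frame(islands)
    tab.to_csv(out / "islands.tsv", sep="\t", index=False)
    anova.to_csv(out / "island_anova.tsv", sep="\t", index=False)

    peak = inc.loc[inc["incidence"].idxmax()]
    print(f"peak incidence {peak['incidence']} animals at "
          f"chr{peak['chrom']}:{peak['pos_bp']}")
    if len(tab):
        classes = tab["sharing_class"].value_counts().to_dict()
        print(f"{len(tab)} islands called; sharing classes: {classes}")
        show = tab.merge(anova[["island_id", "f_stat", "p_value"]], on="island_id")
        cols = ["island_id", "chrom", "start_bp", "end_bp", "n_snps",
                "max_incidence", "sharing_class", "f_stat", "p_value"]
        with pd.option_context("display.width", 140):
            print(show[cols].round(3).to_string(index=False))
    else:
        print("no islands exceeded the sample threshold")
    print(f"wrote island tables under {out}")


if __name__ == "__main__":
    main()
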