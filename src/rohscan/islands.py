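"""ROH islands: per-marker run incidence, island calling, population
sharing, and the breed-effect model on per-sample island SNP proportions.

The incidence of common runs at a marker is the number of distinct
animals with at least one run covering its position. An island is a
maximal stretch of consecutive markers whose incidence exceeds the sample
threshold (default: strictly more than 20 animals), spanning more than
1 Mb and holding at least 30 markers. Islands are classified by the
populations contributing runs: unique (1 population), shared (2-3),
common (more than 3).

For each sample and island, the proportion of the island's member markers
covered by that sample's runs is the response in a one-way fixed-effects
model, proportion = mu + B_i + e, with B_i the breed effects under a
sum-to-zero constraint, fitted by ordinary least squares with an F-test
for the breed term.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class IslandRecord:
    island_id: str
    chrom: int
    start_bp: int
    end_bp: int
    start_idx: int  # panel-wide marker index bounds, inclusive
    end_idx: int
    n_snps: int
    min_incidence: int
    max_incidence: int
    mean_incidence: float
    contributing_populations: list[str] = field(default_factory=list)
    sharing_class: str = ""

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _merged_intervals_per_animal(runs: pd.DataFrame, chrom: int):
    """{animal_id: [(start, end), ...]} with per-animal intervals merged."""
    out: dict[str, list[tuple[int, int]]] = {}
    sub = runs[runs["chrom"] == chrom]
    for animal, grp in sub.groupby("animal_id", sort=False):
        ivals = sorted(zip(grp["start_bp"], grp["end_bp"]))
        merged = [list(ivals[0])]
        for s, e in ivals[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[animal] = [(int(s), int(e)) for s, e in merged]
    return out


def incidence_per_snp(
    runs: pd.DataFrame,
    snp_map: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Count, per marker, the distinct animals whose runs cover it.

    ``group`` restricts the count to animals of one production system
    (requires ``meta``). Overlapping runs of one animal count once.
    Returns the marker table with an added ``incidence`` column.
    """
    if group is not None:
        if meta is None:
            raise ValueError("group incidence requires metadata")
        keep = set(meta.loc[meta["production_system"] == group, "animal_id"])
        runs = runs[runs["animal_id"].isin(keep)]
    bad = set(runs["chrom"]) - set(snp_map["chrom"])
    if bad:
        raise ValueError(f"runs on chromosomes absent from the marker map: {sorted(bad)}")

    incidence = np.zeros(len(snp_map), dtype=np.int64)
    chroms = snp_map["chrom"].to_numpy()
    positions = snp_map["pos_bp"].to_numpy(np.int64)
    for chrom in np.unique(runs["chrom"]) if len(runs) else []:
        cmask = chroms == chrom
        cpos = positions[cmask]
        offset = int(np.flatnonzero(cmask)[0])
        diff = np.zeros(len(cpos) + 1, dtype=np.int64)
        for ivals in _merged_intervals_per_animal(runs, int(chrom)).values():
            for s, e in ivals:
                lo = int(np.searchsorted(cpos, s, side="left"))
                hi = int(np.searchsorted(cpos, e, side="right"))
                diff[lo] += 1
                diff[hi] -= 1
        incidence[offset : offset + len(cpos)] = np.cumsum(diff[:-1])
    out = snp_map.copy()
    out["incidence"] = incidence
    return out


def call_islands(
    inc: pd.DataFrame,
    min_samples: int = 20,
    min_span_bp: int = 1_000_000,
    min_snps: int = 30,
    max_gap_bp: int = 0,
) -> list[IslandRecord]:
    """Call islands from the per-marker incidence table.

    A candidate is a maximal stretch of consecutive markers with
    incidence strictly greater than ``min_samples``; candidates separated
    only by sub-threshold stretches no wider than ``max_gap_bp`` (bp
    between the flanking above-threshold markers; default 0 = strict
    consecutiveness) are merged. A candidate is reported iff its span is
    strictly greater than ``min_span_bp`` and it has at least ``min_snps``
    markers. Islands are returned sorted by (chrom, start) and numbered
    ROH1, ROH2, ... in that order.
    """
    above = (inc["incidence"] > min_samples).to_numpy()
    chroms = inc["chrom"].to_numpy()
    positions = inc["pos_bp"].to_numpy(np.int64)
    inc_arr = inc["incidence"].to_numpy()

    # maximal above-threshold stretches as (start_idx, end_idx) inclusive
    stretches: list[list[int]] = []
    for k in np.flatnonzero(above):
        if stretches and stretches[-1][1] == k - 1 and chroms[k] == chroms[stretches[-1][0]]:
            stretches[-1][1] = k
        else:
            stretches.append([int(k), int(k)])
    if max_gap_bp > 0:
        merged: list[list[int]] = []
        for s, e in stretches:
            if (
                merged
                and chroms[s] == chroms[merged[-1][0]]
                and positions[s] - positions[merged[-1][1]] <= max_gap_bp
            ):
                merged[-1][1] = e
            else:
                merged.append([s, e])
        stretches = merged

    islands: list[IslandRecord] = []
    for s, e in stretches:
        span = int(positions[e] - positions[s] + 1)
        n = e - s + 1
        if span > min_span_bp and n >= min_snps:
            member_inc = inc_arr[s : e + 1]
            islands.append(
                IslandRecord(
                    island_id="",
                    chrom=int(chroms[s]),
                    start_bp=int(positions[s]),
                    end_bp=int(positions[e]),
                    start_idx=s,
                    end_idx=e,
                    n_snps=n,
                    min_incidence=int(member_inc.min()),
                    max_incidence=int(member_inc.max()),
                    mean_incidence=float(member_inc.mean()),
                )
            )
    islands.sort(key=lambda isl: (isl.chrom, isl.start_bp))
    for k, isl in enumerate(islands, start=1):
        isl.island_id = f"ROH{k}"
    return islands


def _covered_member_count(island: IslandRecord, member_pos: np.ndarray, ivals) -> int:
    """Number of island member markers covered by the animal's intervals."""
    covered = 0
    for s, e in ivals:
        lo = int(np.searchsorted(member_pos, s, side="left"))
        hi = int(np.searchsorted(member_pos, e, side="right"))
        covered += max(0, hi - lo)
    return covered


def classify_island_sharing(
    island: IslandRecord, runs: pd.DataFrame, snp_map: pd.DataFrame, meta: pd.DataFrame
) -> IslandRecord:
    """Attach contributing populations and the sharing class to an island.

    A population contributes iff at least one of its animals has a run
    covering at least one member marker of the island. Classes: 1
    contributing population = unique; 2-3 = shared; more than 3 = common.
    """
    pop_of = dict(zip(meta["animal_id"], meta["population"]))
    positions = snp_map["pos_bp"].to_numpy(np.int64)
    member_pos = positions[island.start_idx : island.end_idx + 1]
    sub = runs[
        (runs["chrom"] == island.chrom)
        & (runs["start_bp"] <= island.end_bp)
        & (runs["end_bp"] >= island.start_bp)
    ]
    pops: set[str] = set()
    for row in sub.itertuples(index=False):
        if _covered_member_count(island, member_pos, [(row.start_bp, row.end_bp)]) > 0:
            pops.add(pop_of[row.animal_id])
    island.contributing_populations = sorted(pops)
    n = len(pops)
    island.sharing_class = "unique" if n == 1 else ("shared" if n <= 3 else "common")
    return island


def annotate_islands(
    islands: list[IslandRecord],
    runs: pd.DataFrame,
    snp_map: pd.DataFrame,
    meta: pd.DataFrame,
) -> list[IslandRecord]:
    """Classify every island's population sharing in place."""
    for island in islands:
        classify_island_sharing(island, runs, snp_map, meta)
    return islands


def island_snp_proportions(
    island: IslandRecord,
    runs: pd.DataFrame,
    snp_map: pd.DataFrame,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-sample fraction of the island's member markers inside the
    sample's runs, for every sample in the metadata (0 if none).

    Columns: animal_id, population, proportion.
    """
    positions = snp_map["pos_bp"].to_numpy(np.int64)
    member_pos = positions[island.start_idx : island.end_idx + 1]
    by_animal = _merged_intervals_per_animal(runs, island.chrom)
    rows = []
    for row in meta.itertuples(index=False):
        covered = _covered_member_count(
            island, member_pos, by_animal.get(row.animal_id, [])
        )
        rows.append(
            {
                "animal_id": row.animal_id,
                "population": row.population,
                "proportion": covered / island.n_snps,
            }
        )
    return pd.DataFrame(rows)


def island_breed_means(prop: pd.DataFrame) -> pd.DataFrame:
    """Per-breed mean and sample SD of the island SNP proportion."""
    rows = []
    for pop, grp in prop.groupby("population", sort=True):
        rows.append(
            {
                "population": pop,
                "n": len(grp),
                "mean_proportion": grp["proportion"].mean(),
                "sd_proportion": grp["proportion"].std(ddof=1) if len(grp) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def fit_breed_model(prop: pd.DataFrame) -> dict:
    """One-way fixed-effects fit of proportion = mu + B_i + e.

    Breed effects carry a sum-to-zero constraint, so ``mu`` is the
    unweighted mean of breed means. Requires at least two breeds with at
    least two samples each; otherwise returns ``{"skipped": reason}``.

    Returns mu, effects (dict breed -> B_i), resid_var (residual mean
    square), f_stat, p_value, df_breed, df_resid.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = prop.groupby("population")["proportion"].count()
    if len(counts) < 2 or (counts < 2).any():
        reason = "fewer than 2 breeds" if len(counts) < 2 else "a breed with <2 samples"
        logger.info("fit_breed_model skipped: %s", reason)
        return {"skipped": reason}
    model = smf.ols("proportion ~ C(population, Sum)", data=prop).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    breeds = sorted(prop["population"].unique())
    effects = {}
    for b in breeds[:-1]:
        effects[b] = float(model.params[f"C(population, Sum)[S.{b}]"])
    effects[breeds[-1]] = -float(sum(effects.values()))
    return {
        "mu": float(model.params["Intercept"]),
        "effects": effects,
        "resid_var": float(model.mse_resid),
        "f_stat": float(anova.loc["C(population, Sum)", "F"]),
        "p_value": float(anova.loc["C(population, Sum)", "PR(>F)"]),
        "df_breed": float(anova.loc["C(population, Sum)", "df"]),
        "df_resid": float(anova.loc["Residual", "df"]),
    }


def islands_to_frame(islands: list[IslandRecord]) -> pd.DataFrame:
    """Flatten island records to a writable table."""
    rows = []
    for isl in islands:
        rows.append(
            {
                "island_id": isl.island_id,
                "chrom": isl.chrom,
                "start_bp": isl.start_bp,
                "end_bp": isl.end_bp,
                "length_bp": isl.length_bp,
                "n_snps": isl.n_snps,
                "min_incidence": isl.min_incidence,
                "max_incidence": isl.max_incidence,
                "mean_incidence": round(isl.mean_incidence, 3),
                "n_populations": len(isl.contributing_populations),
                "sharing_class": isl.sharing_class,
                "contributing_populations": ",".join(isl.contributing_populations),
            }
        )
    cols = [
        "island_id", "chrom", "start_bp", "end_bp", "length_bp", "n_snps",
        "min_incidence", "max_incidence", "mean_incidence",
        "n_populations", "sharing_class", "contributing_populations",
    ]
    return pd.DataFrame(rows, columns=cols)


def analyze_islands(
    islands: list[IslandRecord],
    runs: pd.DataFrame,
    snp_map: pd.DataFrame,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-island ANOVA table (one row per island; NaN where skipped)."""
    rows = []
    for isl in islands:
        prop = island_snp_proportions(isl, runs, snp_map, meta)
        fit = fit_breed_model(prop)
        rows.append(
            {
                "island_id": isl.island_id,
                "chrom": isl.chrom,
                "start_bp": isl.start_bp,
                "end_bp": isl.end_bp,
                "grand_mean": fit.get("mu", np.nan),
                "f_stat": fit.get("f_stat", np.nan),
                "p_value": fit.get("p_value", np.nan),
                "note": fit.get("skipped", ""),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["island_id", "chrom", "start_bp", "end_bp", "grand_mean", "f_stat", "p_value", "note"],
    )
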