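"""Per-marker incidence, island calling, sharing classes and the
breed-effect model on island SNP proportions."""

import numpy as np
import pandas as pd
import pytest

from rohscan.islands import (
    annotate_islands,
    call_islands,
    classify_island_sharing,
    fit_breed_model,
    incidence_per_snp,
    island_breed_means,
    island_snp_proportions,
)


def snp_map_chrom(n_snps, spacing=50_000, chrom=1, start=1):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": start + np.arange(n_snps) * spacing,
            "snp_id": [f"c{chrom}s{k}" for k in range(n_snps)],
        }
    )


def run_row(animal, pop, chrom, start, end):
    return {
        "animal_id": animal, "population": pop, "chrom": chrom,
        "start_bp": start, "end_bp": end,
        "n_snps": 30, "n_het": 0, "n_missing": 0,
        "length_bp": end - start + 1, "length_class": "1-6Mb",
    }


def meta_rows(pops):
    """pops: {population: [animal ids]}"""
    rows = []
    for pop, animals in pops.items():
        for a in animals:
            rows.append({"animal_id": a, "population": pop, "production_system": None})
    return pd.DataFrame(rows)


class TestIncidence:
    def test_single_run_counts_once_per_covered_snp(self):
        snp_map = snp_map_chrom(50)
        pos = snp_map["pos_bp"]
        runs = pd.DataFrame([run_row("a1", "P", 1, pos[5], pos[40])])
        meta = meta_rows({"P": ["a1"]})
        inc = incidence_per_snp(runs, snp_map, meta)["incidence"].to_numpy()
        assert (inc[5:41] == 1).all()
        assert (inc[:5] == 0).all() and (inc[41:] == 0).all()

    def test_same_animal_overlapping_runs_count_once(self):
        snp_map = snp_map_chrom(50)
        pos = snp_map["pos_bp"]
        runs = pd.DataFrame(
            [run_row("a1", "P", 1, pos[5], pos[30]), run_row("a1", "P", 1, pos[20], pos[40])]
        )
        inc = incidence_per_snp(runs, snp_map)["incidence"].to_numpy()
        assert inc.max() == 1

    def test_matches_bruteforce_double_loop(self, rng):
        snp_map = pd.concat(
            [snp_map_chrom(60, chrom=1), snp_map_chrom(40, chrom=2)], ignore_index=True
        )
        rows = []
        for a in range(8):
            for _ in range(rng.integers(0, 4)):
                chrom = int(rng.integers(1, 3))
                sub = snp_map[snp_map["chrom"] == chrom]["pos_bp"].to_numpy()
                i, j = sorted(rng.integers(0, len(sub), 2))
                rows.append(run_row(f"a{a}", "P", chrom, int(sub[i]), int(sub[j])))
        runs = pd.DataFrame(rows, columns=list(run_row("x", "P", 1, 1, 2).keys()))
        inc = incidence_per_snp(runs, snp_map)["incidence"].to_numpy()
        # independent O(animals x markers) recount
        expected = np.zeros(len(snp_map), dtype=int)
        for k, (chrom, pos) in enumerate(zip(snp_map["chrom"], snp_map["pos_bp"])):
            for animal in runs["animal_id"].unique():
                sub = runs[(runs["animal_id"] == animal) & (runs["chrom"] == chrom)]
                if ((sub["start_bp"] <= pos) & (sub["end_bp"] >= pos)).any():
                    expected[k] += 1
        np.testing.assert_array_equal(inc, expected)

    def test_conservation_of_total_incidence(self, rng):
        """Sum of incidence over markers equals the summed member-marker
        counts of per-animal merged intervals."""
        snp_map = snp_map_chrom(80)
        pos = snp_map["pos_bp"].to_numpy()
        rows = []
        for a in range(6):
            i, j = sorted(rng.integers(0, 80, 2))
            rows.append(run_row(f"a{a}", "P", 1, int(pos[i]), int(pos[j])))
        runs = pd.DataFrame(rows)
        inc = incidence_per_snp(runs, snp_map)["incidence"].to_numpy()
        member_count = sum(
            int(np.sum((pos >= r["start_bp"]) & (pos <= r["end_bp"]))) for _, r in runs.iterrows()
        )
        assert inc.sum() == member_count  # runs here never overlap within an animal? they might
        # (single run per animal in this fixture, so no double counting)

    def test_group_restriction(self):
        snp_map = snp_map_chrom(40)
        pos = snp_map["pos_bp"]
        runs = pd.DataFrame(
            [run_row("a1", "P", 1, pos[0], pos[30]), run_row("a2", "P", 1, pos[0], pos[30])]
        )
        meta = meta_rows({"P": ["a1", "a2"]})
        meta.loc[meta["animal_id"] == "a1", "production_system"] = "wool"
        meta.loc[meta["animal_id"] == "a2", "production_system"] = "pelt"
        inc = incidence_per_snp(runs, snp_map, meta, group="wool")["incidence"]
        assert inc.max() == 1

    def test_unknown_chromosome_rejected(self):
        snp_map = snp_map_chrom(10)
        runs = pd.DataFrame([run_row("a1", "P", 9, 1, 2)])
        with pytest.raises(ValueError, match="chromosomes absent"):
            incidence_per_snp(runs, snp_map)


def incidence_frame(values, spacing=50_000, chrom=1):
    snp_map = snp_map_chrom(len(values), spacing=spacing, chrom=chrom)
    snp_map["incidence"] = values
    return snp_map


class TestCallIslands:
    def test_clean_island(self):
        # 35 consecutive markers over 1.2 Mb above threshold
        inc = incidence_frame([0] * 5 + [25] * 35 + [0] * 5, spacing=35_000)
        (island,) = call_islands(inc)
        assert island.n_snps == 35
        assert island.island_id == "ROH1"
        assert island.min_incidence == 25

    def test_span_rule_is_strict(self):
        # 35 markers spanning under 1 Mb: rejected on span
        inc = incidence_frame([25] * 35, spacing=26_000)  # span 884,001 bp
        assert call_islands(inc) == []

    def test_snp_count_rule(self):
        inc = incidence_frame([0] + [25] * 29 + [0], spacing=55_000)  # 1.54 Mb, 29 markers
        assert call_islands(inc) == []

    def test_threshold_is_strictly_more_than(self):
        inc = incidence_frame([20] * 40, spacing=50_000)
        assert call_islands(inc, min_samples=20) == []
        inc2 = incidence_frame([21] * 40, spacing=50_000)
        assert len(call_islands(inc2, min_samples=20)) == 1

    def test_islands_are_maximal(self):
        values = [0] * 3 + [30] * 40 + [5] + [30] * 40 + [0]
        inc = incidence_frame(values)
        islands = call_islands(inc)
        assert [i.n_snps for i in islands] == [40, 40]
        for island in islands:
            # the marker on either side is below threshold or absent
            for edge in (island.start_idx - 1, island.end_idx + 1):
                if 0 <= edge < len(values):
                    assert values[edge] <= 20

    def test_gap_merging_is_off_by_default(self):
        values = [30] * 20 + [0] + [30] * 20
        strict = call_islands(incidence_frame(values))
        assert strict == []  # each half has only 20 markers
        merged = call_islands(incidence_frame(values), max_gap_bp=200_000)
        assert len(merged) == 1 and merged[0].n_snps == 41

    def test_multiple_chromosomes_sorted_ids(self):
        inc = pd.concat(
            [incidence_frame([25] * 40, chrom=2), incidence_frame([25] * 40, chrom=1)],
            ignore_index=True,
        ).sort_values(["chrom", "pos_bp"]).reset_index(drop=True)
        islands = call_islands(inc)
        assert [i.island_id for i in islands] == ["ROH1", "ROH2"]
        assert [i.chrom for i in islands] == [1, 2]


def _island_fixture():
    """One island over markers 10..49 (40 markers, 2 Mb at 50 kb)."""
    snp_map = snp_map_chrom(60)
    pos = snp_map["pos_bp"].to_numpy()
    inc = snp_map.copy()
    inc["incidence"] = [0] * 10 + [25] * 40 + [0] * 10
    (island,) = call_islands(inc)
    return island, snp_map, pos


class TestSharing:
    def test_unique_shared_common_classes(self):
        island, snp_map, pos = _island_fixture()
        meta = meta_rows({p: [f"{p}_1"] for p in "ABCDE"})

        def runs_for(pops):
            return pd.DataFrame(
                [run_row(f"{p}_1", p, 1, int(pos[12]), int(pos[30])) for p in pops]
            )

        for pops, expected in [("A", "unique"), ("ABC", "shared"), ("ABCDE", "common")]:
            isl = classify_island_sharing(island, runs_for(list(pops)), snp_map, meta)
            assert isl.sharing_class == expected
            assert isl.contributing_populations == sorted(pops)

    def test_contribution_requires_member_snp_overlap(self):
        island, snp_map, pos = _island_fixture()
        meta = meta_rows({"A": ["A_1"], "B": ["B_1"]})
        runs = pd.DataFrame(
            [
                run_row("A_1", "A", 1, int(pos[15]), int(pos[20])),
                run_row("B_1", "B", 1, int(pos[0]), int(pos[5])),  # outside the island
            ]
        )
        isl = classify_island_sharing(island, runs, snp_map, meta)
        assert isl.contributing_populations == ["A"]

    def test_sharing_classes_partition_island_set(self, rng):
        snp_map = snp_map_chrom(200)
        pos = snp_map["pos_bp"].to_numpy()
        meta = meta_rows({p: [f"{p}_{k}" for k in range(8)] for p in "ABCD"})
        rows = []
        for animal in meta["animal_id"]:
            for _ in range(int(rng.integers(1, 3))):
                i = int(rng.integers(0, 150))
                j = min(199, i + int(rng.integers(30, 60)))
                rows.append(run_row(animal, animal.split("_")[0], 1, int(pos[i]), int(pos[j])))
        runs = pd.DataFrame(rows)
        inc = incidence_per_snp(runs, snp_map, meta)
        islands = annotate_islands(call_islands(inc, min_samples=5), runs, snp_map, meta)
        assert islands, "fixture should yield at least one island"
        counts = pd.Series([i.sharing_class for i in islands]).value_counts()
        assert counts.sum() == len(islands)
        assert set(counts.index) <= {"unique", "shared", "common"}


class TestProportions:
    def test_full_none_and_half_coverage(self):
        island, snp_map, pos = _island_fixture()
        meta = meta_rows({"A": ["full", "half", "none"]})
        runs = pd.DataFrame(
            [
                run_row("full", "A", 1, int(pos[10]), int(pos[49])),
                run_row("half", "A", 1, int(pos[10]), int(pos[29])),  # 20 of 40 members
            ]
        )
        prop = island_snp_proportions(island, runs, snp_map, meta).set_index("animal_id")
        assert prop.loc["full", "proportion"] == 1.0
        assert prop.loc["half", "proportion"] == 0.5
        assert prop.loc["none", "proportion"] == 0.0
        means = island_breed_means(prop.reset_index())
        assert means.loc[0, "mean_proportion"] == pytest.approx(0.5)

    def test_proportions_bounded_and_breed_means_within_range(self, rng):
        island, snp_map, pos = _island_fixture()
        meta = meta_rows({"A": [f"a{k}" for k in range(5)], "B": [f"b{k}" for k in range(5)]})
        rows = []
        for animal in meta["animal_id"]:
            i = int(rng.integers(0, 40))
            j = min(59, i + int(rng.integers(5, 50)))
            rows.append(run_row(animal, animal[0].upper(), 1, int(pos[i]), int(pos[j])))
        prop = island_snp_proportions(island, pd.DataFrame(rows), snp_map, meta)
        assert prop["proportion"].between(0, 1).all()
        for row in island_breed_means(prop).itertuples(index=False):
            vals = prop.loc[prop["population"] == row.population, "proportion"]
            assert vals.min() <= row.mean_proportion <= vals.max()


class TestBreedModel:
    def test_two_breed_hand_example(self):
        prop = pd.DataFrame(
            {
                "animal_id": list("abcd"),
                "population": ["P1", "P1", "P2", "P2"],
                "proportion": [0.2, 0.2, 0.8, 0.8],
            }
        )
        fit = fit_breed_model(prop)
        assert fit["mu"] == pytest.approx(0.5)
        assert fit["effects"]["P1"] == pytest.approx(-0.3)
        assert fit["effects"]["P2"] == pytest.approx(0.3)
        assert sum(fit["effects"].values()) == pytest.approx(0.0, abs=1e-12)

    def test_single_breed_skipped(self):
        prop = pd.DataFrame(
            {"animal_id": ["a", "b"], "population": "P1", "proportion": [0.1, 0.2]}
        )
        assert "skipped" in fit_breed_model(prop)

    def test_tiny_breed_skipped(self):
        prop = pd.DataFrame(
            {"animal_id": ["a", "b", "c"], "population": ["P1", "P1", "P2"],
             "proportion": [0.1, 0.2, 0.3]}
        )
        assert "skipped" in fit_breed_model(prop)

    def test_null_f_statistic_is_moderate(self, rng):
        prop = pd.DataFrame(
            {
                "animal_id": [f"x{k}" for k in range(40)],
                "population": ["P1"] * 20 + ["P2"] * 20,
                "proportion": rng.normal(0.3, 0.1, 40),
            }
        )
        fit = fit_breed_model(prop)
        assert fit["p_value"] > 0.001  # no planted effect
        assert fit["df_breed"] == 1 and fit["df_resid"] == 38
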