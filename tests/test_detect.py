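"""Consecutive-runs detector: worked cases, brute-force equivalence,
maximality, monotonicity and the post-hoc validator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rohscan.detect import (
    RohParams,
    classify_length,
    detect_roh,
    detect_runs_animal_chrom,
    summarize_by_breed,
    validate_segments,
)
from rohscan.io import LENGTH_CLASS_LABELS

from _utils import bruteforce_runs, make_panel, meta_for, random_chromosome, statuses


def runs_as_index_pairs(runs):
    return [(r["start_idx"], r["end_idx"]) for r in runs]


class TestWorkedCases:
    def test_clean_homozygous_stretch_is_one_run(self):
        calls = statuses("H" * 40)
        positions = np.arange(40) * 50_000 + 1  # spans 1.95 Mb, gaps 50 kb
        (run,) = detect_runs_animal_chrom(calls, positions)
        assert (run["n_snps"], run["n_het"], run["n_missing"]) == (40, 0, 0)
        assert run["length_class"] == "1-6Mb"
        assert run["start_bp"] == 1 and run["end_bp"] == positions[-1]

    def test_29_homozygous_snps_is_no_run(self):
        calls = statuses("H" * 29)
        positions = np.arange(29) * 100_000 + 1  # 2.8 Mb but only 29 markers
        assert detect_runs_animal_chrom(calls, positions) == []

    def test_single_het_allowed_inside_two_hets_split(self):
        positions = np.arange(40) * 50_000 + 1
        one_het = statuses("H" * 20 + "e" + "H" * 19)
        (run,) = detect_runs_animal_chrom(one_het, positions)
        assert run["n_snps"] == 40 and run["n_het"] == 1
        # two hets: no 30-marker window with <=1 het exists in 40 markers
        two_hets = statuses("H" * 10 + "e" + "H" * 15 + "e" + "H" * 13)
        assert detect_runs_animal_chrom(two_hets, positions) == []
        assert bruteforce_runs(two_hets, positions) == []

    def test_oversized_gap_splits_candidate(self):
        # 35 homozygous markers, one 300 kb gap: fragments of 17 and 18
        # markers are tested separately and both fail the 30-marker rule
        spacing = np.full(34, 150_000)
        spacing[16] = 300_000
        positions = np.concatenate([[1], 1 + np.cumsum(spacing)])
        calls = statuses("H" * 35)
        assert detect_runs_animal_chrom(calls, positions) == []
        assert bruteforce_runs(calls, positions) == []

    def test_het_and_missing_never_terminal(self):
        # compliant core flanked by het/missing: run must end on homozygous
        calls = statuses("e" + "H" * 35 + ".")
        positions = np.arange(37) * 60_000 + 1
        (run,) = detect_runs_animal_chrom(calls, positions)
        assert run["start_idx"] == 1 and run["end_idx"] == 35

    def test_density_rule_rejects_sparse_run(self):
        # 30 markers spanning 3.48 Mb: 120 kb per marker on average
        calls = statuses("H" * 30)
        positions = np.arange(30) * 120_000 + 1
        assert detect_runs_animal_chrom(calls, positions) == []

    def test_missing_member_does_not_split_gap_distance(self):
        # 240 kb between genotyped neighbours with a missing marker in
        # between: still within the 250 kb gap rule
        positions = np.arange(35) * 60_000 + 1
        calls = statuses("H" * 17 + "." + "H" * 17)
        positions[17] = positions[16] + 30_000  # missing marker mid-gap
        positions[18:] = positions[17] + 210_000 + np.arange(17) * 60_000
        (run,) = detect_runs_animal_chrom(calls, positions)
        assert run["n_missing"] == 1

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            detect_runs_animal_chrom(statuses("HH"), np.array([200, 100]))
        with pytest.raises(ValueError, match="equal length"):
            detect_runs_animal_chrom(statuses("HH"), np.array([100]))


class TestClassifyLength:
    @pytest.mark.parametrize(
        "length_bp,label",
        [
            (1_000_000, "1-6Mb"),
            (5_880_000, "1-6Mb"),   # mean run length scale of real panels
            (6_000_000, "6-12Mb"),  # lower-inclusive boundary
            (12_000_000, "12-24Mb"),
            (24_000_000, "24-48Mb"),
            (47_999_999, "24-48Mb"),
            (48_000_000, ">48Mb"),
            (50_000_000, ">48Mb"),
        ],
    )
    def test_half_open_bins(self, length_bp, label):
        assert classify_length(length_bp) == label

    def test_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            classify_length(999_999)


class TestBruteforceEquivalence:
    def test_random_chromosomes_match_enumeration(self, rng):
        params = RohParams()
        for _ in range(40):
            n = int(rng.integers(50, 400))
            calls, positions = random_chromosome(
                rng, n, p_het=float(rng.uniform(0.02, 0.4)),
                p_missing=float(rng.uniform(0, 0.06)),
            )
            fast = runs_as_index_pairs(detect_runs_animal_chrom(calls, positions, params))
            slow = bruteforce_runs(calls, positions)
            assert fast == slow

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        pattern=st.text(alphabet="Hhe.", min_size=1, max_size=70),
        seed=st.integers(0, 10_000),
    )
    def test_tiny_chromosomes_match_enumeration(self, pattern, seed):
        """Short hand-reachable inputs, permissive thresholds so tiny
        windows can qualify, against the same enumeration reference."""
        rng = np.random.default_rng(seed)
        calls = statuses(pattern)
        positions = np.cumsum(rng.integers(10_000, 300_000, len(calls))) + 1
        params = RohParams(min_length_bp=100_000, min_snps=4, max_bp_per_snp=150_000)
        fast = runs_as_index_pairs(detect_runs_animal_chrom(calls, positions, params))
        slow = bruteforce_runs(
            calls, positions, min_length_bp=100_000, min_snps=4, max_bp_per_snp=150_000
        )
        assert fast == slow


class TestProperties:
    def test_relaxing_a_threshold_never_loses_runs(self, rng):
        calls, positions = random_chromosome(rng, 500, p_het=0.15)
        base = RohParams()
        n_base = len(detect_runs_animal_chrom(calls, positions, base))
        relaxed = [
            RohParams(min_snps=20),
            RohParams(min_length_bp=500_000),
            RohParams(max_het=2),
            RohParams(max_missing=2),
            RohParams(max_gap_bp=400_000),
            RohParams(max_bp_per_snp=200_000),
        ]
        for params in relaxed:
            assert len(detect_runs_animal_chrom(calls, positions, params)) >= n_base

    def test_every_emitted_segment_passes_validator(self, small_noisy_panel):
        panel, meta, _ = small_noisy_panel
        runs = detect_roh(panel, meta)
        assert len(runs) > 0
        assert validate_segments(runs, panel) == []

    def test_validator_flags_corrupted_segment(self, small_noisy_panel):
        panel, meta, _ = small_noisy_panel
        runs = detect_roh(panel, meta)
        bad = runs.copy()
        bad.loc[bad.index[0], "length_bp"] += 1
        assert any("length arithmetic" in v for v in validate_segments(bad, panel))


class TestBreedSummary:
    def _runs(self):
        rows = []
        for animal, n, first in [("a1", 3, 2), ("a2", 5, 4)]:
            for k in range(n):
                length = (first if k % 2 == 0 else 6 - first) * 1_000_000
                rows.append(
                    {
                        "animal_id": animal, "population": "P1", "chrom": 1,
                        "start_bp": 1 + 10_000_000 * k, "end_bp": 10_000_000 * k + length,
                        "n_snps": 40, "n_het": 0, "n_missing": 0,
                        "length_bp": length, "length_class": "1-6Mb",
                        "start_idx": 0, "end_idx": 39,
                    }
                )
        return pd.DataFrame(rows)

    def test_mean_counts_and_lengths(self):
        runs = self._runs()
        meta = pd.DataFrame(
            {"animal_id": ["a1", "a2"], "population": "P1", "production_system": None}
        )
        (row,) = summarize_by_breed(runs, meta).to_dict("records")
        assert row["mn_roh"] == 4.0  # (3 + 5) / 2 animals
        assert row["al_roh_mb"] == pytest.approx(3.0, abs=1e-9)  # mean of 2,4 Mb
        assert row["n_1-6Mb"] == 8

    def test_class_counts_equal_recount_of_run_table(self, small_noisy_panel):
        panel, meta, _ = small_noisy_panel
        runs = detect_roh(panel, meta)
        summary = summarize_by_breed(runs, meta).set_index("population")
        for pop, row in summary.iterrows():
            # independent recount straight off the run table
            pop_runs = runs[runs["population"] == pop]
            counts = pop_runs["length_class"].value_counts()
            assert row["n_roh"] == len(pop_runs)
            assert sum(row[f"n_{label}"] for label in LENGTH_CLASS_LABELS) == len(pop_runs)
            for label in LENGTH_CLASS_LABELS:
                assert row[f"n_{label}"] == counts.get(label, 0)

    def test_animal_without_metadata_is_an_error(self):
        runs = self._runs()
        meta = pd.DataFrame({"animal_id": ["a1"], "population": "P1", "production_system": None})
        with pytest.raises(ValueError, match="a2"):
            summarize_by_breed(runs, meta)
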