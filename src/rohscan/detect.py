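"""Consecutive-runs detection of runs of homozygosity (ROH).

A run is a maximal stretch of markers in one animal on one chromosome that
jointly satisfies every criterion below (defaults in :class:`RohParams`):

* at most one heterozygous and at most one missing call inside the run
  (independent budgets);
* at least 30 markers;
* spans at least 1 Mb (1-based inclusive: ``end - start + 1``);
* average marker density of at least one marker per 100 kb over the run
  (``span / n_snps <= 100_000``);
* no gap larger than 250 kb between consecutive *genotyped* member
  markers (a missing member marker does not split the distance);
* the first and last member markers are homozygous, non-missing.

The scan is greedy left-to-right: the leftmost marker from which any
compliant window starts opens a run, the run is extended to the largest
compliant end, emitted, and the scan resumes past it. Emitted runs are
therefore maximal (no compliant window starts left of an emitted run, and
its end cannot be advanced) and never overlap. Heterozygous or missing
calls may sit strictly inside a run, never at its ends.

This is detection by scanning consecutive markers against the criteria
directly — no fixed-size sliding window is involved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    GenotypePanel,
    HET,
    MISSING,
    LENGTH_CLASS_LABELS,
    ROH_TABLE_COLUMNS,
)


@dataclass(frozen=True)
class RohParams:
    """Run criteria; defaults are the package's standard settings."""

    min_length_bp: int = 1_000_000
    min_snps: int = 30
    max_het: int = 1
    max_missing: int = 1
    #: maximum average bp per marker over the run (density >= 1 SNP / 100 kb)
    max_bp_per_snp: int = 100_000
    max_gap_bp: int = 250_000

    def __post_init__(self) -> None:
        if min(self.min_length_bp, self.min_snps, self.max_bp_per_snp, self.max_gap_bp) <= 0:
            raise ValueError("length, SNP-count, density and gap limits must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("het/missing budgets must be >= 0")


#: length-class bin edges in bp; half-open, lower-inclusive
_CLASS_EDGES = np.array([1, 6, 12, 24, 48], dtype=np.int64) * 1_000_000


def classify_length(length_bp: int) -> str:
    """Bin a run length into 1-6 / 6-12 / 12-24 / 24-48 / >48 Mb.

    Bins are half-open and lower-inclusive: exactly 6 Mb falls in 6-12 Mb.
    """
    if length_bp < _CLASS_EDGES[0]:
        raise ValueError(f"run length {length_bp} below the 1 Mb minimum")
    idx = int(np.searchsorted(_CLASS_EDGES, length_bp, side="right")) - 1
    return LENGTH_CLASS_LABELS[idx]


def detect_runs_animal_chrom(
    calls: np.ndarray, positions: np.ndarray, params: RohParams | None = None
) -> list[dict]:
    """Detect all maximal compliant runs on one chromosome of one animal.

    Parameters
    ----------
    calls : array of status codes (HOM_A/HET/HOM_B/MISSING)
    positions : strictly increasing bp positions aligned to ``calls``
    params : run criteria (defaults: :class:`RohParams`)

    Returns a list of dicts with keys start_idx, end_idx, start_bp, end_bp,
    n_snps, n_het, n_missing, length_bp, length_class.
    """
    p = params or RohParams()
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.int64)
    if calls.shape != positions.shape:
        raise ValueError("calls and positions must have equal length")
    n = len(calls)
    if n and not (np.diff(positions) > 0).all():
        raise ValueError("positions must be strictly increasing")

    is_missing = calls == MISSING
    is_het = calls == HET
    is_hom = ~is_missing & ~is_het

    runs: list[dict] = []
    i = 0
    while i < n:
        if not is_hom[i]:
            i += 1
            continue
        # extend right from candidate start i to the largest compliant end
        best = -1
        best_stats = None
        n_het = n_miss = 0
        last_genotyped = positions[i]
        j = i
        while j < n:
            if is_missing[j]:
                n_miss += 1
                if n_miss > p.max_missing:
                    break
            else:
                if j > i and positions[j] - last_genotyped > p.max_gap_bp:
                    break
                last_genotyped = positions[j]
                if is_het[j]:
                    n_het += 1
                    if n_het > p.max_het:
                        break
                else:  # homozygous: candidate run end
                    span = positions[j] - positions[i] + 1
                    count = j - i + 1
                    if (
                        count >= p.min_snps
                        and span >= p.min_length_bp
                        and span <= p.max_bp_per_snp * count
                    ):
                        best = j
                        # running budgets equal the counts over [i, j] here;
                        # trailing het/missing past j never join the run
                        best_stats = (n_het, n_miss)
            j += 1
        if best >= 0:
            span = int(positions[best] - positions[i] + 1)
            # sub-1 Mb runs only exist under a relaxed min_length_bp and
            # fall below the standard reporting bins
            label = classify_length(span) if span >= _CLASS_EDGES[0] else "<1Mb"
            runs.append(
                {
                    "start_idx": i,
                    "end_idx": int(best),
                    "start_bp": int(positions[i]),
                    "end_bp": int(positions[best]),
                    "n_snps": int(best - i + 1),
                    "n_het": best_stats[0],
                    "n_missing": best_stats[1],
                    "length_bp": span,
                    "length_class": label,
                }
            )
            i = best + 1
        else:
            i += 1
    return runs


def detect_roh(
    panel: GenotypePanel,
    meta: pd.DataFrame | None = None,
    params: RohParams | None = None,
) -> pd.DataFrame:
    """Detect runs for every animal on every chromosome of the panel.

    Returns a DataFrame with :data:`rohscan.io.ROH_TABLE_COLUMNS` plus the
    member-marker index bounds (start_idx/end_idx, panel-wide), sorted by
    (animal_id, chrom, start_bp).
    """
    params = params or RohParams()
    pop_of = {}
    if meta is not None:
        pop_of = dict(zip(meta["animal_id"], meta["population"]))
    positions = panel.snp_map["pos_bp"].to_numpy(np.int64)
    records: list[dict] = []
    for chrom, sl in panel.chrom_slices.items():
        pos_c = positions[sl]
        for i, animal in enumerate(panel.animal_ids):
            for run in detect_runs_animal_chrom(panel.calls[i, sl], pos_c, params):
                run["animal_id"] = animal
                run["population"] = pop_of.get(animal, "NA")
                run["chrom"] = chrom
                run["start_idx"] += sl.start
                run["end_idx"] += sl.start
                records.append(run)
    cols = ROH_TABLE_COLUMNS + ["start_idx", "end_idx"]
    runs = pd.DataFrame(records, columns=cols)
    return runs.sort_values(["animal_id", "chrom", "start_bp"], kind="mergesort").reset_index(
        drop=True
    )


# ---------------------------------------------------------------------------
# post-hoc validation
# ---------------------------------------------------------------------------

def validate_segments(
    runs: pd.DataFrame, panel: GenotypePanel, params: RohParams | None = None
) -> list[str]:
    """Re-check every emitted run against the full criterion set.

    Returns a list of human-readable violation messages (empty = clean).
    Checks: length arithmetic and minimum, marker count, het/missing
    budgets, density, gap rule between genotyped members, homozygous
    non-missing terminals, and per-animal non-overlap.
    """
    p = params or RohParams()
    problems: list[str] = []
    positions = panel.snp_map["pos_bp"].to_numpy(np.int64)
    idx_of_animal = {a: i for i, a in enumerate(panel.animal_ids)}
    for row in runs.itertuples(index=False):
        tag = f"{row.animal_id} chr{row.chrom} {row.start_bp}-{row.end_bp}"
        s, e = int(row.start_idx), int(row.end_idx)
        seg_calls = panel.calls[idx_of_animal[row.animal_id], s : e + 1]
        seg_pos = positions[s : e + 1]
        span = int(seg_pos[-1] - seg_pos[0] + 1)
        if not (row.length_bp == row.end_bp - row.start_bp + 1 == span):
            problems.append(f"{tag}: length arithmetic broken")
        if row.length_bp < p.min_length_bp:
            problems.append(f"{tag}: below minimum length")
        if row.n_snps != len(seg_calls) or row.n_snps < p.min_snps:
            problems.append(f"{tag}: marker count {row.n_snps} wrong or too small")
        n_het = int((seg_calls == HET).sum())
        n_miss = int((seg_calls == MISSING).sum())
        if n_het != row.n_het or n_het > p.max_het:
            problems.append(f"{tag}: het budget violated ({n_het})")
        if n_miss != row.n_missing or n_miss > p.max_missing:
            problems.append(f"{tag}: missing budget violated ({n_miss})")
        if row.length_bp > p.max_bp_per_snp * row.n_snps:
            problems.append(f"{tag}: density below 1 SNP per {p.max_bp_per_snp} bp")
        geno_pos = seg_pos[seg_calls != MISSING]
        if len(geno_pos) and (np.diff(geno_pos) > p.max_gap_bp).any():
            problems.append(f"{tag}: gap over {p.max_gap_bp} bp between genotyped members")
        if seg_calls[0] in (HET, MISSING) or seg_calls[-1] in (HET, MISSING):
            problems.append(f"{tag}: non-homozygous terminal marker")
        expected_label = (
            classify_length(int(row.length_bp)) if row.length_bp >= _CLASS_EDGES[0] else "<1Mb"
        )
        if expected_label != row.length_class:
            problems.append(f"{tag}: wrong length class")
    for (animal, chrom), grp in runs.groupby(["animal_id", "chrom"], sort=False):
        g = grp.sort_values("start_bp")
        if (g["start_bp"].to_numpy()[1:] <= g["end_bp"].to_numpy()[:-1]).any():
            problems.append(f"{animal} chr{chrom}: overlapping runs")
    return problems


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_by_breed(runs: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-breed ROH summary.

    Columns: population, n_animals, n_roh, mn_roh (mean runs per animal,
    over ALL animals of the breed including run-free ones), al_roh_mb
    (mean run length in Mb), sum_roh_mb (mean per-animal total run length,
    Mb), and per-length-class counts.
    """
    unknown = sorted(set(runs["animal_id"]) - set(meta["animal_id"]))
    if unknown:
        raise ValueError(f"runs reference animals without metadata: {unknown}")
    rows = []
    runs_by_animal = runs.groupby("animal_id")
    for pop, grp in meta.groupby("population", sort=True):
        animals = grp["animal_id"].tolist()
        pop_runs = runs[runs["animal_id"].isin(animals)]
        n_runs = len(pop_runs)
        per_animal_sum = [
            runs_by_animal.get_group(a)["length_bp"].sum() / 1e6
            if a in runs_by_animal.groups
            else 0.0
            for a in animals
        ]
        row = {
            "population": pop,
            "n_animals": len(animals),
            "n_roh": n_runs,
            "mn_roh": n_runs / len(animals) if animals else np.nan,
            "al_roh_mb": pop_runs["length_bp"].mean() / 1e6 if n_runs else np.nan,
            "sum_roh_mb": float(np.mean(per_animal_sum)) if animals else np.nan,
        }
        counts = pop_runs["length_class"].value_counts()
        for label in LENGTH_CLASS_LABELS:
            row[f"n_{label}"] = int(counts.get(label, 0))
        rows.append(row)
    return pd.DataFrame(rows)


def runs_per_chromosome(runs: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Breed x chromosome run-count matrix (rows breeds, columns chroms)."""
    pop_of = dict(zip(meta["animal_id"], meta["population"]))
    tab = runs.assign(population=runs["animal_id"].map(pop_of))
    out = tab.pivot_table(
        index="population", columns="chrom", values="animal_id", aggfunc="count", fill_value=0
    )
    out.columns.name = "chrom"
    return out
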