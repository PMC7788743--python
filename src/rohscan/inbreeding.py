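"""Genomic inbreeding from ROH (F_ROH) and from excess homozygosity (F_HOM).

F_ROH for an animal is the summed length of its autosomal runs divided by
the SNP-covered autosome length L_AUTO. L_AUTO may be supplied as a
constant (default 2453 Mb, the standard value for the ovine autosomes) or
computed from the post-QC map as sum over chromosomes of
(max position - min position + 1); the mode used is recorded in output.

F_HOM is the method-of-moments excess-homozygosity estimator

    F_HOM = (O_hom - E_hom) / (N - E_hom),    E_hom = sum_j (1 - 2 p_j q_j)

where the sum runs over the animal's N non-missing markers and p_j is the
allele frequency estimated from the full post-QC panel. No small-sample
correction is applied to E_hom.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GenotypePanel, HET, HOM_B, MISSING

logger = logging.getLogger(__name__)

#: default SNP-covered autosome length (bp): 2453 Mb
DEFAULT_L_AUTO: int = 2_453_000_000


def l_auto_from_map(snp_map: pd.DataFrame) -> int:
    """SNP-covered autosome length: sum per chromosome of span of markers."""
    spans = snp_map.groupby("chrom")["pos_bp"].agg(["min", "max"])
    return int((spans["max"] - spans["min"] + 1).sum())


def f_roh(run_lengths_bp, l_auto: int = DEFAULT_L_AUTO) -> float:
    """Total run length over L_AUTO for one animal's validated runs."""
    total = int(np.sum(run_lengths_bp)) if len(run_lengths_bp) else 0
    if total > l_auto:
        raise ValueError(f"total ROH length {total} exceeds L_AUTO {l_auto}")
    return total / l_auto


def allele_frequencies(panel: GenotypePanel) -> np.ndarray:
    """Frequency of the HOM_B allele per marker, from non-missing calls."""
    calls = panel.calls
    n_b = ((calls == HOM_B) * 2 + (calls == HET)).sum(axis=0).astype(float)
    n_obs = 2.0 * (calls != MISSING).sum(axis=0)
    return np.where(n_obs > 0, n_b / np.maximum(n_obs, 1.0), np.nan)


def f_hom(calls_row: np.ndarray, freqs: np.ndarray) -> float:
    """Excess-homozygosity inbreeding for one animal.

    Only markers non-missing in the animal contribute. Returns NaN when
    every contributing marker is monomorphic (N == E_hom, degenerate).
    """
    calls_row = np.asarray(calls_row)
    nm = calls_row != MISSING
    p = freqs[nm]
    ok = ~np.isnan(p)
    p = p[ok]
    n = int(p.size)
    if n == 0:
        return float("nan")
    e_hom = float(np.sum(1.0 - 2.0 * p * (1.0 - p)))
    o_hom = int((calls_row[nm][ok] != HET).sum())
    denom = n - e_hom
    if denom <= 0:
        logger.warning("f_hom: degenerate animal (all markers monomorphic)")
        return float("nan")
    return (o_hom - e_hom) / denom


def inbreeding_table(
    runs: pd.DataFrame,
    panel: GenotypePanel,
    meta: pd.DataFrame,
    l_auto: int | None = DEFAULT_L_AUTO,
) -> pd.DataFrame:
    """Per-animal inbreeding table over ALL panel animals.

    Pass ``l_auto=None`` to compute L_AUTO from the panel map (the natural
    mode for synthetic panels whose genome span differs from the default
    constant). Columns: animal_id, population, n_roh, l_roh_bp, l_auto_bp,
    l_auto_mode, f_roh, f_hom.
    """
    mode = "constant"
    if l_auto is None:
        l_auto = l_auto_from_map(panel.snp_map)
        mode = "from_map"
    freqs = allele_frequencies(panel)
    pop_of = dict(zip(meta["animal_id"], meta["population"]))
    by_animal = runs.groupby("animal_id")["length_bp"] if len(runs) else None
    sums = by_animal.sum() if by_animal is not None else pd.Series(dtype=float)
    counts = by_animal.count() if by_animal is not None else pd.Series(dtype=int)
    rows = []
    for i, animal in enumerate(panel.animal_ids):
        l_roh = int(sums.get(animal, 0))
        rows.append(
            {
                "animal_id": animal,
                "population": pop_of.get(animal, "NA"),
                "n_roh": int(counts.get(animal, 0)),
                "l_roh_bp": l_roh,
                "l_auto_bp": l_auto,
                "l_auto_mode": mode,
                "f_roh": f_roh([l_roh], l_auto),
                "f_hom": f_hom(panel.calls[i], freqs),
            }
        )
    return pd.DataFrame(rows)


def summarize_inbreeding(records: pd.DataFrame) -> pd.DataFrame:
    """Per-breed mean and sample SD (n-1) of F_ROH and F_HOM.

    A breed with a single animal gets SD reported as missing.
    """
    rows = []
    for pop, grp in records.groupby("population", sort=True):
        rows.append(
            {
                "population": pop,
                "n_animals": len(grp),
                "mean_f_roh": grp["f_roh"].mean(),
                "sd_f_roh": grp["f_roh"].std(ddof=1) if len(grp) > 1 else np.nan,
                "mean_f_hom": grp["f_hom"].mean(),
                "sd_f_hom": grp["f_hom"].std(ddof=1) if len(grp) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
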