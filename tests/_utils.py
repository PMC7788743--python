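"""Shared test helpers: toy-panel builders and the independent
brute-force reference for the consecutive-runs detector.

The brute-force route enumerates every candidate window with plain
per-window tallies and then replays the greedy leftmost/longest selection
on the enumerated set; it shares no code with the production scanner.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rohscan.io import GenotypePanel, HOM_A, HET, HOM_B, MISSING

# compact status notation for hand-written fixtures
STATUS = {"H": HOM_A, "h": HOM_B, "e": HET, ".": MISSING}


def statuses(pattern: str) -> np.ndarray:
    """'HHeH.h' -> status codes (H/h the two homozygotes, e het, . missing)."""
    return np.array([STATUS[c] for c in pattern], dtype=np.int8)


def make_panel(rows, positions, chrom=1, animal_ids=None) -> GenotypePanel:
    """Build a one-chromosome panel from status rows and bp positions."""
    calls = np.vstack([statuses(r) if isinstance(r, str) else np.asarray(r, np.int8) for r in rows])
    positions = np.asarray(positions, dtype=np.int64)
    snp_map = pd.DataFrame(
        {
            "chrom": chrom,
            "pos_bp": positions,
            "snp_id": [f"s{k}" for k in range(1, len(positions) + 1)],
        }
    )
    ids = animal_ids or [f"a{k}" for k in range(1, len(calls) + 1)]
    return GenotypePanel(snp_map=snp_map, calls=calls, animal_ids=np.asarray(ids, object))


def meta_for(panel: GenotypePanel, population="P1", system=None) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": list(panel.animal_ids),
            "population": population if isinstance(population, list) else [population] * panel.n_animals,
            "production_system": [system] * panel.n_animals,
        }
    )


# ---------------------------------------------------------------------------
# brute-force reference detector
# ---------------------------------------------------------------------------

def _window_compliant(calls, positions, i, j, *, min_length_bp, min_snps,
                      max_het, max_missing, max_bp_per_snp, max_gap_bp) -> bool:
    w = calls[i : j + 1]
    hom = (w == HOM_A) | (w == HOM_B)
    if not (hom[0] and hom[-1]):
        return False
    if (w == HET).sum() > max_het or (w == MISSING).sum() > max_missing:
        return False
    if len(w) < min_snps:
        return False
    span = positions[j] - positions[i] + 1
    if span < min_length_bp or span / len(w) > max_bp_per_snp:
        return False
    geno_pos = positions[i : j + 1][w != MISSING]
    if len(geno_pos) > 1 and np.max(np.diff(geno_pos)) > max_gap_bp:
        return False
    return True


def bruteforce_runs(
    calls,
    positions,
    min_length_bp=1_000_000,
    min_snps=30,
    max_het=1,
    max_missing=1,
    max_bp_per_snp=100_000,
    max_gap_bp=250_000,
) -> list[tuple[int, int]]:
    """All maximal non-overlapping compliant windows, as (start, end) index
    pairs, by full enumeration plus greedy leftmost-start/longest-end
    selection."""
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.int64)
    n = len(calls)
    kw = dict(
        min_length_bp=min_length_bp,
        min_snps=min_snps,
        max_het=max_het,
        max_missing=max_missing,
        max_bp_per_snp=max_bp_per_snp,
        max_gap_bp=max_gap_bp,
    )
    windows: list[tuple[int, int]] = []
    for i in range(n):
        # a window with budgets already blown or a too-wide gap cannot
        # recover at larger j, so enumeration may stop early there
        for j in range(i, n):
            w = calls[i : j + 1]
            if (w == HET).sum() > max_het or (w == MISSING).sum() > max_missing:
                break
            geno_pos = positions[i : j + 1][w != MISSING]
            if len(geno_pos) > 1 and np.max(np.diff(geno_pos)) > max_gap_bp:
                break
            if _window_compliant(calls, positions, i, j, **kw):
                windows.append((i, j))

    selected: list[tuple[int, int]] = []
    prev_end = -1
    for i, j in sorted(windows, key=lambda w: (w[0], -w[1])):
        if i > prev_end:
            selected.append((i, j))
            prev_end = j
    return selected


from rohscan.experiments import random_status_chromosome as random_chromosome  # noqa: E402
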