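"""Marker and sample quality control for SNP-array panels.

The filters mirror routine PLINK-style QC with literal boundary semantics:
a marker is *removed* when its call rate is strictly below the threshold
or its MAF strictly below the threshold, and an animal is removed when its
missing fraction is strictly above the threshold — equality always retains.
No LD pruning is applied anywhere in the package.

Default pipeline order: autosome restriction (done at read time) →
SNP call rate → MAF → animal missingness. The order is configurable and
logged because marginal removal counts depend on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GenotypePanel, MISSING, HET, HOM_A, HOM_B

logger = logging.getLogger(__name__)


@dataclass
class QcParams:
    min_call_rate: float = 0.95
    min_maf: float = 0.01
    max_animal_missing: float = 0.02
    #: marker filters applied in this order, then the animal filter
    snp_filter_order: tuple[str, ...] = ("call_rate", "maf")

    def __post_init__(self) -> None:
        if not (0 < self.min_call_rate <= 1):
            raise ValueError("min_call_rate must be in (0, 1]")
        if not (0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")
        if not (0 <= self.max_animal_missing <= 1):
            raise ValueError("max_animal_missing must be in [0, 1]")


@dataclass
class QcReport:
    """Per-stage attrition counts; reconciles exactly with panel shapes."""

    n_snps_in: int = 0
    n_snps_out: int = 0
    n_animals_in: int = 0
    n_animals_out: int = 0
    removed_nonautosomal: int = 0
    removed_snps_callrate: int = 0
    removed_snps_maf: int = 0
    removed_animals_missing: int = 0
    filter_order: tuple[str, ...] = field(default_factory=tuple)

    def check(self) -> None:
        assert self.n_snps_out == (
            self.n_snps_in
            - self.removed_snps_callrate
            - self.removed_snps_maf
        ), "SNP counts do not reconcile"
        assert self.n_animals_out == self.n_animals_in - self.removed_animals_missing

    def as_dict(self) -> dict:
        return {
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "n_animals_in": self.n_animals_in,
            "n_animals_out": self.n_animals_out,
            "removed_nonautosomal": self.removed_nonautosomal,
            "removed_snps_callrate": self.removed_snps_callrate,
            "removed_snps_maf": self.removed_snps_maf,
            "removed_animals_missing": self.removed_animals_missing,
            "filter_order": list(self.filter_order),
        }


def snp_call_rates(panel: GenotypePanel) -> np.ndarray:
    if panel.n_animals == 0:
        return np.zeros(panel.n_snps)
    return 1.0 - (panel.calls == MISSING).mean(axis=0)


def snp_maf(panel: GenotypePanel) -> np.ndarray:
    """Minor allele frequency per marker, from non-missing calls only.

    Markers with zero non-missing calls get MAF 0 (they are expected to be
    gone after the call-rate filter; if still present they are removed by
    the MAF filter with a warning).
    """
    calls = panel.calls
    n_b = ((calls == HOM_B) * 2 + (calls == HET)).sum(axis=0).astype(float)
    n_obs = 2.0 * (calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, n_b / np.maximum(n_obs, 1), 0.0)
    return np.minimum(p, 1.0 - p)


def animal_missing_fraction(panel: GenotypePanel) -> np.ndarray:
    if panel.n_snps == 0:
        return np.zeros(panel.n_animals)
    return (panel.calls == MISSING).mean(axis=1)


def filter_snps_call_rate(panel: GenotypePanel, min_rate: float = 0.95):
    """Retain marker j iff call_rate_j >= min_rate (strict '<' removal)."""
    if panel.n_snps == 0 or panel.n_animals == 0:
        logger.warning("filter_snps_call_rate: empty panel")
        return panel, 0
    keep = snp_call_rates(panel) >= min_rate
    return panel.subset(snp_mask=keep), int((~keep).sum())


def filter_snps_maf(panel: GenotypePanel, min_maf: float = 0.01):
    """Retain marker iff MAF >= min_maf; monomorphic markers are removed."""
    if panel.n_snps == 0:
        return panel, 0
    maf = snp_maf(panel)
    dead = (panel.calls != MISSING).sum(axis=0) == 0
    if dead.any():
        logger.warning(
            "filter_snps_maf: %d marker(s) with zero calls reached the MAF "
            "filter (call-rate filter normally removes them first)",
            int(dead.sum()),
        )
    keep = (maf >= min_maf) & (maf > 0) & ~dead
    if min_maf == 0:  # still drop monomorphic markers
        keep = (maf > 0) & ~dead
    return panel.subset(snp_mask=keep), int((~keep).sum())


def filter_animals_missingness(panel: GenotypePanel, max_missing: float = 0.02):
    """Retain animal iff missing fraction <= max_missing (strict '>' removal)."""
    if panel.n_animals == 0 or panel.n_snps == 0:
        return panel, 0
    keep = animal_missing_fraction(panel) <= max_missing
    return panel.subset(animal_mask=keep), int((~keep).sum())


_SNP_FILTERS = {
    "call_rate": lambda panel, p: filter_snps_call_rate(panel, p.min_call_rate),
    "maf": lambda panel, p: filter_snps_maf(panel, p.min_maf),
}


def apply_qc(panel: GenotypePanel, params: QcParams | None = None):
    """Run the full QC pipeline; returns (filtered panel, QcReport).

    Marker filters run in ``params.snp_filter_order``, then the animal
    missingness filter on the post-marker panel.
    """
    params = params or QcParams()
    report = QcReport(
        n_snps_in=panel.n_snps,
        n_animals_in=panel.n_animals,
        removed_nonautosomal=panel.dropped_nonautosomal,
        filter_order=tuple(params.snp_filter_order) + ("animal_missingness",),
    )
    for name in params.snp_filter_order:
        panel, n = _SNP_FILTERS[name](panel, params)
        if name == "call_rate":
            report.removed_snps_callrate = n
        else:
            report.removed_snps_maf = n
        logger.info("qc: %s removed %d markers", name, n)
    panel, n = filter_animals_missingness(panel, params.max_animal_missing)
    report.removed_animals_missing = n
    logger.info("qc: animal missingness removed %d animals", n)
    report.n_snps_out = panel.n_snps
    report.n_animals_out = panel.n_animals
    report.check()
    return panel, report
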