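"""Synthetic multi-breed SNP-array panels with planted autozygosity.

The generator emulates a medium-density genotyping array on a sheep-like
genome: 26 autosomes of 94 Mb (total 2444 Mb, close to the 2453 Mb
SNP-covered autosome constant used for F_ROH), markers at a mean spacing
of 50 kb with jitter, and a couple of oversized inter-marker gaps per
chromosome to exercise the detector's gap rule.

Each animal is built as two haplotypes drawn independently from its
breed's per-marker allele frequencies (Balding-Nichols drift around an
ancestral frequency). Autozygosity is planted by copying haplotype 1 over
haplotype 2 inside non-overlapping intervals — guaranteeing identity by
descent — whose lengths are drawn from a configurable mixture over the
five reporting bins until the summed length reaches the breed's target
inbreeding F_true = sum(lengths) / genome length. Genotyping errors flip
one allele of a call; missingness blanks calls. Everything is
reproducible from the mandatory seed.

No linkage disequilibrium is simulated: marker genotypes are exchangeable
given the planted intervals, so chance short runs are rarer than on a
real chip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypePanel, MISSING

GENOME_DEFAULT_N_CHROMS = 26
GENOME_DEFAULT_CHROM_BP = 94_000_000

#: default planted-length mixture over the five reporting bins (Mb);
#: heavily short-biased so synthetic bin histograms resemble real panels
DEFAULT_SEGMENT_BINS_MB: tuple[tuple[float, float], ...] = (
    (1, 6), (6, 12), (12, 24), (24, 48), (48, 60),
)
DEFAULT_SEGMENT_WEIGHTS: tuple[float, ...] = (0.882, 0.080, 0.025, 0.010, 0.003)


@dataclass(frozen=True)
class Hotspot:
    """A region where a breed's animals preferentially plant a segment.

    Used to create run pile-ups (islands). Each animal of the breed
    independently plants one segment overlapping ``center_bp`` with
    probability ``p_member``; its length is uniform over
    ``length_range_mb`` and its centre jitters by up to ``jitter_bp``.
    """

    chrom: int
    center_bp: int
    p_member: float = 0.9
    length_range_mb: tuple[float, float] = (2.0, 4.0)
    jitter_bp: int = 400_000


@dataclass
class BreedConfig:
    name: str
    n_animals: int
    f_target: float = 0.0
    production_system: str | None = None
    #: per-breed override of the planted length mixture (bins_mb, weights)
    segment_bins_mb: tuple | None = None
    segment_weights: tuple | None = None
    hotspots: tuple[Hotspot, ...] = ()


@dataclass
class SimConfig:
    breeds: list[BreedConfig]
    seed: int
    n_chroms: int = GENOME_DEFAULT_N_CHROMS
    chrom_length_bp: int = GENOME_DEFAULT_CHROM_BP
    mean_spacing_bp: int = 50_000
    #: spacing drawn uniform in mean*(1 +/- jitter); 0.6 -> 20-80 kb
    spacing_jitter: float = 0.6
    n_large_gaps_per_chrom: int = 2
    large_gap_range_bp: tuple[int, int] = (300_000, 500_000)
    #: ancestral allele frequencies drawn uniform over this range
    #: (array-like ascertainment toward intermediate frequencies)
    maf_range: tuple[float, float] = (0.2, 0.8)
    #: Balding-Nichols differentiation of breed frequencies; 0 = none
    fst: float = 0.1
    error_rate: float = 0.0
    missing_rate: float = 0.0
    segment_bins_mb: tuple = DEFAULT_SEGMENT_BINS_MB
    segment_weights: tuple = DEFAULT_SEGMENT_WEIGHTS

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for b in self.breeds:
            if not (0 <= b.f_target <= 0.9):
                raise ValueError(f"breed {b.name}: f_target must be in [0, 0.9]")
        for rate in (self.error_rate, self.missing_rate):
            if not (0 <= rate <= 1):
                raise ValueError("error/missing rates must be in [0, 1]")
        if abs(sum(self.segment_weights) - 1.0) > 1e-9:
            raise ValueError("segment_weights must sum to 1")

    @property
    def genome_length_bp(self) -> int:
        return self.n_chroms * self.chrom_length_bp


@dataclass
class SyntheticTruth:
    """Planted intervals and true inbreeding — the recovery oracle.

    ``intervals``: animal_id, chrom, start_bp, end_bp, length_bp.
    ``f_true``: animal_id, f_true (= summed planted length / genome).
    ``allele_freqs``: breed name -> per-marker true allele frequency.
    """

    intervals: pd.DataFrame
    f_true: pd.DataFrame
    genome_length_bp: int
    allele_freqs: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------

def _draw_positions(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    lo = max(1, int(cfg.mean_spacing_bp * (1 - cfg.spacing_jitter)))
    hi = int(cfg.mean_spacing_bp * (1 + cfg.spacing_jitter))
    rows = []
    for chrom in range(1, cfg.n_chroms + 1):
        est = int(cfg.chrom_length_bp / cfg.mean_spacing_bp * 1.5) + 10
        spacings = rng.integers(lo, hi + 1, est)
        if cfg.n_large_gaps_per_chrom > 0:
            idx = rng.choice(est, cfg.n_large_gaps_per_chrom, replace=False)
            g_lo, g_hi = cfg.large_gap_range_bp
            spacings[idx] = rng.integers(g_lo, g_hi + 1, cfg.n_large_gaps_per_chrom)
        pos = int(rng.integers(1, cfg.mean_spacing_bp + 1)) + np.cumsum(spacings)
        pos = pos[pos <= cfg.chrom_length_bp]
        for k, p in enumerate(pos, start=1):
            rows.append((chrom, int(p), f"snp{chrom}_{k}"))
    return pd.DataFrame(rows, columns=["chrom", "pos_bp", "snp_id"])


def _breed_frequencies(cfg: SimConfig, n_snps: int, rng: np.random.Generator):
    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], n_snps)
    freqs: dict[str, np.ndarray] = {}
    for breed in cfg.breeds:
        if cfg.fst > 0:
            a = p_anc * (1 - cfg.fst) / cfg.fst
            b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
            freqs[breed.name] = np.clip(rng.beta(a, b), 0.001, 0.999)
        else:
            freqs[breed.name] = p_anc.copy()
    return p_anc, freqs


# ---------------------------------------------------------------------------
# planted intervals
# ---------------------------------------------------------------------------

def _draw_segment_length(bins_mb, weights, rng: np.random.Generator) -> int:
    k = rng.choice(len(weights), p=np.asarray(weights) / np.sum(weights))
    lo, hi = bins_mb[k]
    return int(rng.uniform(lo, hi) * 1e6)


def _overlaps(ivals: list[tuple[int, int, int]], chrom: int, s: int, e: int) -> bool:
    return any(c == chrom and s <= ee and e >= ss for c, ss, ee in ivals)


def _plant_animal(
    cfg: SimConfig, breed: BreedConfig, rng: np.random.Generator
) -> list[tuple[int, int, int]]:
    """Choose one animal's non-overlapping autozygous intervals."""
    bins_mb = breed.segment_bins_mb or cfg.segment_bins_mb
    weights = breed.segment_weights or cfg.segment_weights
    ivals: list[tuple[int, int, int]] = []
    placed = 0

    for hs in breed.hotspots:
        if rng.random() >= hs.p_member:
            continue
        length = int(rng.uniform(*hs.length_range_mb) * 1e6)
        center = hs.center_bp + int(rng.integers(-hs.jitter_bp, hs.jitter_bp + 1))
        s = max(1, center - length // 2)
        e = min(cfg.chrom_length_bp, s + length - 1)
        if not _overlaps(ivals, hs.chrom, s, e):
            ivals.append((hs.chrom, s, e))
            placed += e - s + 1

    target = int(breed.f_target * cfg.genome_length_bp)
    min_len = int(bins_mb[0][0] * 1e6)
    attempts = 0
    while target - placed > min_len // 2:
        length = _draw_segment_length(bins_mb, weights, rng)
        if length > target - placed:
            length = max(min_len, target - placed)
        length = min(length, cfg.chrom_length_bp)
        chrom = int(rng.integers(1, cfg.n_chroms + 1))
        max_start = cfg.chrom_length_bp - length + 1
        s = 1 if max_start <= 1 else int(rng.integers(1, max_start))
        e = s + length - 1
        if _overlaps(ivals, chrom, s, e):
            attempts += 1
            if attempts > 5000:
                raise ValueError(
                    f"breed {breed.name}: f_target {breed.f_target} unattainable "
                    "given the segment length distribution and genome size"
                )
            continue
        ivals.append((chrom, s, e))
        placed += length
    return sorted(ivals)


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------

def simulate_panel(cfg: SimConfig):
    """Generate (GenotypePanel, metadata, SyntheticTruth) from a config.

    Draw order is fixed (markers, frequencies, then per breed per animal
    haplotypes and planted intervals, then errors, then missingness), so a
    given seed always yields the same panel, byte for byte, when written.
    """
    rng = np.random.default_rng(cfg.seed)
    snp_map = _draw_positions(cfg, rng)
    n_snps = len(snp_map)
    chrom_arr = snp_map["chrom"].to_numpy()
    pos_arr = snp_map["pos_bp"].to_numpy(np.int64)
    chrom_index = {
        c: (np.flatnonzero(chrom_arr == c)[0], np.flatnonzero(chrom_arr == c)[-1] + 1)
        for c in range(1, cfg.n_chroms + 1)
    }

    p_anc, freqs = _breed_frequencies(cfg, n_snps, rng)

    calls_rows: list[np.ndarray] = []
    animal_ids: list[str] = []
    meta_rows: list[dict] = []
    interval_rows: list[dict] = []
    f_true_rows: list[dict] = []

    for breed in cfg.breeds:
        p = freqs[breed.name]
        for k in range(1, breed.n_animals + 1):
            animal = f"{breed.name}_{k:03d}"
            hap1 = (rng.random(n_snps) < p).astype(np.int8)
            hap2 = (rng.random(n_snps) < p).astype(np.int8)
            ivals = _plant_animal(cfg, breed, rng)
            total = 0
            for chrom, s, e in ivals:
                c0, c1 = chrom_index[chrom]
                lo = c0 + np.searchsorted(pos_arr[c0:c1], s, side="left")
                hi = c0 + np.searchsorted(pos_arr[c0:c1], e, side="right")
                hap2[lo:hi] = hap1[lo:hi]
                total += e - s + 1
                interval_rows.append(
                    {
                        "animal_id": animal,
                        "chrom": chrom,
                        "start_bp": s,
                        "end_bp": e,
                        "length_bp": e - s + 1,
                    }
                )
            f_true_rows.append(
                {"animal_id": animal, "f_true": total / cfg.genome_length_bp}
            )
            calls_rows.append(hap1 + hap2)
            animal_ids.append(animal)
            meta_rows.append(
                {
                    "animal_id": animal,
                    "population": breed.name,
                    "production_system": breed.production_system,
                }
            )

    calls = np.vstack(calls_rows).astype(np.int8)

    if cfg.error_rate > 0:
        err = rng.random(calls.shape) < cfg.error_rate
        side = rng.random(calls.shape) < 0.5  # which allele an error flips
        flipped = np.where(
            calls == 1, np.where(side, 0, 2), 1  # HET -> either HOM; HOM -> HET
        ).astype(np.int8)
        calls = np.where(err, flipped, calls)
    if cfg.missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < cfg.missing_rate, MISSING, calls)

    panel = GenotypePanel(
        snp_map=snp_map, calls=calls.astype(np.int8), animal_ids=np.asarray(animal_ids, object)
    )
    meta = pd.DataFrame(meta_rows, columns=["animal_id", "population", "production_system"])
    truth = SyntheticTruth(
        intervals=pd.DataFrame(
            interval_rows, columns=["animal_id", "chrom", "start_bp", "end_bp", "length_bp"]
        ),
        f_true=pd.DataFrame(f_true_rows, columns=["animal_id", "f_true"]),
        genome_length_bp=cfg.genome_length_bp,
        allele_freqs=freqs,
    )
    return panel, meta, truth


# ---------------------------------------------------------------------------
# truth I/O (schema v1)
# ---------------------------------------------------------------------------

_TRUTH_HEADER = "# rohscan-truth v1"
_TRUTH_COLUMNS = ["record", "animal_id", "chrom", "start_bp", "end_bp", "length_bp", "f_true"]


def write_truth(truth: SyntheticTruth, path) -> None:
    """Write planted intervals and per-animal F_true as one versioned TSV."""
    rows = []
    for r in truth.intervals.itertuples(index=False):
        rows.append(
            {
                "record": "interval",
                "animal_id": r.animal_id,
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_bp": r.length_bp,
                "f_true": "",
            }
        )
    for r in truth.f_true.itertuples(index=False):
        rows.append(
            {
                "record": "animal",
                "animal_id": r.animal_id,
                "chrom": "",
                "start_bp": "",
                "end_bp": "",
                "length_bp": "",
                "f_true": repr(float(r.f_true)),
            }
        )
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + f"\tgenome_length_bp={truth.genome_length_bp}\n")
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in _TRUTH_COLUMNS) + "\n")


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(_TRUTH_HEADER):
            raise ValueError(f"{path}: not a rohscan-truth v1 file")
        genome = int(header.split("genome_length_bp=")[1])
        table = pd.read_csv(fh, sep="\t", dtype={"animal_id": str})
    ivals = table[table["record"] == "interval"]
    animals = table[table["record"] == "animal"]
    intervals = pd.DataFrame(
        {
            "animal_id": ivals["animal_id"].to_numpy(),
            "chrom": ivals["chrom"].astype(int).to_numpy(),
            "start_bp": ivals["start_bp"].astype(np.int64).to_numpy(),
            "end_bp": ivals["end_bp"].astype(np.int64).to_numpy(),
            "length_bp": ivals["length_bp"].astype(np.int64).to_numpy(),
        }
    )
    f_true = pd.DataFrame(
        {
            "animal_id": animals["animal_id"].to_numpy(),
            "f_true": animals["f_true"].astype(float).to_numpy(),
        }
    )
    return SyntheticTruth(intervals=intervals, f_true=f_true, genome_length_bp=genome)


# ---------------------------------------------------------------------------
# canned configurations
# ---------------------------------------------------------------------------

def default_config(seed: int, error_rate: float = 0.001, missing_rate: float = 0.005) -> SimConfig:
    """A five-breed study design spanning low to high inbreeding across
    production systems, with hotspot regions shared by all breeds, by two
    breeds, and private to one breed, so run pile-ups of every sharing
    class (unique / shared / common) can arise."""
    shared_all = Hotspot(chrom=1, center_bp=20_000_000, p_member=0.8)
    shared_two = Hotspot(chrom=2, center_bp=50_000_000, p_member=0.8)
    private = Hotspot(chrom=3, center_bp=30_000_000, p_member=0.95)
    breeds = [
        BreedConfig("Pelthill", 28, 0.25, "pelt", hotspots=(shared_all, private)),
        BreedConfig("Woolford", 20, 0.15, "wool", hotspots=(shared_all, shared_two)),
        BreedConfig("Muttonvale", 20, 0.10, "mutton", hotspots=(shared_all, shared_two)),
        BreedConfig("Lowveld", 15, 0.05, "mutton", hotspots=(shared_all,)),
        BreedConfig("Dualkop", 15, 0.20, "dual", hotspots=(shared_all,)),
    ]
    return SimConfig(
        breeds=breeds, seed=seed, error_rate=error_rate, missing_rate=missing_rate
    )
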