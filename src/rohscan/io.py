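"""PLINK text PED/MAP input, metadata input, and result-table output.

Genotypes are held as per-marker *status* codes relative to the
lexicographically smaller observed allele at each marker:

====  =========  =======================================
code  name       meaning
====  =========  =======================================
0     HOM_A      homozygous for the smaller allele
1     HET        heterozygous
2     HOM_B      homozygous for the larger allele
-1    MISSING    no call (``0 0``, or half-missing)
====  =========  =======================================

Which homozygote is HOM_A is arbitrary and carries no meaning downstream:
run detection and both inbreeding estimators depend only on the
HOM/HET/MISSING status of a call, never on allele identity.

Coordinates are 1-based and inclusive throughout the package, matching
PLINK MAP positions; an interval's length is ``end - start + 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = -1

#: default autosome set for sheep (OAR 1..26)
DEFAULT_AUTOSOMES: tuple[int, ...] = tuple(range(1, 27))

VALID_ALLELES = frozenset("ACGT12")

LENGTH_CLASS_LABELS = ["1-6Mb", "6-12Mb", "12-24Mb", "24-48Mb", ">48Mb"]

ROH_TABLE_COLUMNS = [
    "animal_id",
    "population",
    "chrom",
    "start_bp",
    "end_bp",
    "n_snps",
    "n_het",
    "n_missing",
    "length_bp",
    "length_class",
]


class FormatError(ValueError):
    """Raised when a PED/MAP/metadata file violates its expected layout."""


@dataclass
class GenotypePanel:
    """An ordered marker panel plus the animals-by-markers call matrix.

    Attributes
    ----------
    snp_map : pandas.DataFrame
        One row per marker with columns ``chrom`` (int), ``pos_bp`` (int,
        1-based) and ``snp_id`` (str), strictly sorted by (chrom, pos_bp).
    calls : numpy.ndarray
        int8 matrix of shape (n_animals, n_snps) holding status codes;
        column ``j`` corresponds to row ``j`` of ``snp_map``.
    animal_ids : numpy.ndarray
        Unique animal identifiers, one per row of ``calls``.
    """

    snp_map: pd.DataFrame
    calls: np.ndarray
    animal_ids: np.ndarray
    dropped_nonautosomal: int = 0
    half_missing_calls: int = 0
    chrom_slices: dict[int, slice] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.validate()
        if not self.chrom_slices:
            self.chrom_slices = _chrom_slices(self.snp_map)

    # -- basic facts -------------------------------------------------
    @property
    def n_animals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def chromosomes(self) -> list[int]:
        return list(self.chrom_slices)

    def validate(self) -> None:
        m = self.snp_map
        if list(m.columns[:3]) != ["chrom", "pos_bp", "snp_id"]:
            raise ValueError("snp_map must have columns chrom, pos_bp, snp_id")
        if self.calls.shape != (len(self.animal_ids), len(m)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.animal_ids)} animals x {len(m)} markers"
            )
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise ValueError("animal_ids are not unique")
        if (m["pos_bp"] < 1).any():
            raise ValueError("marker positions must be >= 1")
        key = m["chrom"].to_numpy() * np.int64(2**40) + m["pos_bp"].to_numpy()
        if not (np.diff(key) > 0).all():
            raise ValueError("snp_map must be strictly sorted by (chrom, pos_bp)")

    # -- convenience masks -------------------------------------------
    def is_hom(self) -> np.ndarray:
        return (self.calls == HOM_A) | (self.calls == HOM_B)

    def is_het(self) -> np.ndarray:
        return self.calls == HET

    def is_missing(self) -> np.ndarray:
        return self.calls == MISSING

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypePanel":
        """Return a new panel restricted to the selected animals/markers."""
        a = np.ones(self.n_animals, bool) if animal_mask is None else np.asarray(animal_mask)
        s = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        return GenotypePanel(
            snp_map=self.snp_map.loc[s].reset_index(drop=True),
            calls=self.calls[np.ix_(a, s)],
            animal_ids=self.animal_ids[a],
            dropped_nonautosomal=self.dropped_nonautosomal,
            half_missing_calls=self.half_missing_calls,
        )


def _chrom_slices(snp_map: pd.DataFrame) -> dict[int, slice]:
    slices: dict[int, slice] = {}
    chroms = snp_map["chrom"].to_numpy()
    if len(chroms) == 0:
        return slices
    bounds = np.flatnonzero(np.diff(chroms)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(chroms)]])
    for s, e in zip(starts, ends):
        slices[int(chroms[s])] = slice(int(s), int(e))
    return slices


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_chrom(token: str) -> int | None:
    try:
        return int(token)
    except ValueError:
        return None  # X/Y/contig names: not an autosome label


def read_map(map_path, autosomes=DEFAULT_AUTOSOMES) -> pd.DataFrame:
    """Read a 4-column PLINK MAP file; returns ALL markers in file order.

    Columns out: chrom (int, -1 for non-numeric labels), pos_bp, snp_id.
    """
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise FormatError(
                    f"{map_path}: line {lineno}: expected 4 columns "
                    f"(chrom, snp_id, cM, bp), got {len(tok)}"
                )
            chrom = _parse_chrom(tok[0])
            try:
                pos = int(tok[3])
            except ValueError as err:
                raise FormatError(
                    f"{map_path}: line {lineno}: non-numeric bp position {tok[3]!r}"
                ) from err
            rows.append((-1 if chrom is None else chrom, pos, tok[1]))
    return pd.DataFrame(rows, columns=["chrom", "pos_bp", "snp_id"])


def read_ped_map(ped_path, map_path, autosomes=DEFAULT_AUTOSOMES) -> GenotypePanel:
    """Read PLINK text PED + MAP into a :class:`GenotypePanel`.

    Markers on chromosomes outside ``autosomes`` (sex chromosomes, unmapped
    contigs, chromosome 0) are dropped at read time and counted in
    ``panel.dropped_nonautosomal``. Markers are returned sorted by
    (chrom, pos_bp); PED columns are reordered to match. Animals keep file
    order. Half-missing calls (e.g. ``A 0``) become MISSING and are counted.
    """
    raw_map = read_map(map_path, autosomes)
    n_file_snps = len(raw_map)

    auto = set(int(a) for a in autosomes)
    keep = raw_map["chrom"].isin(auto).to_numpy()
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_ped_map: dropped %d non-autosomal/unmapped markers", dropped)

    a1_rows: list[np.ndarray] = []
    a2_rows: list[np.ndarray] = []
    animal_ids: list[str] = []
    populations: list[str] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_file_snps:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_file_snps} "
                    f"columns for {n_file_snps} MAP markers, got {len(tok)}"
                )
            populations.append(tok[0])
            animal_ids.append(tok[1])
            alleles = np.asarray(tok[6:], dtype=object)
            a1_rows.append(alleles[0::2])
            a2_rows.append(alleles[1::2])
    if not animal_ids:
        raise FormatError(f"{ped_path}: no genotype rows")

    a1 = np.vstack(a1_rows)[:, keep]
    a2 = np.vstack(a2_rows)[:, keep]
    snp_map = raw_map.loc[keep].reset_index(drop=True)

    order = np.lexsort((snp_map["pos_bp"].to_numpy(), snp_map["chrom"].to_numpy()))
    snp_map = snp_map.iloc[order].reset_index(drop=True)
    dup = snp_map.duplicated(subset=["chrom", "pos_bp"])
    if dup.any():
        first = snp_map.loc[dup.idxmax()]
        raise FormatError(
            f"{map_path}: duplicate marker position chrom {first['chrom']} "
            f"bp {first['pos_bp']}"
        )
    a1 = a1[:, order]
    a2 = a2[:, order]

    calls, half_missing = _code_genotypes(a1, a2, snp_map["snp_id"].to_numpy())
    if half_missing:
        logger.warning(
            "read_ped_map: %d half-missing genotype(s) treated as MISSING",
            half_missing,
        )
    return GenotypePanel(
        snp_map=snp_map,
        calls=calls,
        animal_ids=np.asarray(animal_ids, dtype=object),
        dropped_nonautosomal=dropped,
        half_missing_calls=half_missing,
    )


def _code_genotypes(a1: np.ndarray, a2: np.ndarray, snp_ids: np.ndarray):
    n_animals, n_snps = a1.shape
    calls = np.full((n_animals, n_snps), MISSING, dtype=np.int8)
    half_missing = 0
    for j in range(n_snps):
        c1, c2 = a1[:, j], a2[:, j]
        miss1 = c1 == "0"
        miss2 = c2 == "0"
        half = miss1 ^ miss2
        half_missing += int(half.sum())
        missing = miss1 | miss2
        observed = sorted(set(c1[~missing]) | set(c2[~missing]))
        bad = [al for al in observed if al not in VALID_ALLELES]
        if bad:
            raise FormatError(f"marker {snp_ids[j]}: invalid allele code(s) {bad}")
        if len(observed) > 2:
            raise FormatError(
                f"marker {snp_ids[j]}: more than two alleles observed {observed}"
            )
        if not observed:
            continue  # all-missing marker
        ref = observed[0]
        het = (~missing) & (c1 != c2)
        hom_ref = (~missing) & (c1 == ref) & (c2 == ref)
        hom_alt = (~missing) & (~het) & (~hom_ref)
        calls[hom_ref, j] = HOM_A
        calls[het, j] = HET
        calls[hom_alt, j] = HOM_B
    return calls, half_missing


def read_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata TSV: animal_id, population[, production_system]."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"animal_id", "population"}
    if not required.issubset(meta.columns):
        raise FormatError(
            f"{path}: metadata requires columns {sorted(required)}, "
            f"found {list(meta.columns)}"
        )
    if "production_system" not in meta.columns:
        meta["production_system"] = pd.NA
    if meta["animal_id"].duplicated().any():
        dups = meta.loc[meta["animal_id"].duplicated(), "animal_id"].tolist()
        raise FormatError(f"{path}: duplicate animal_id(s) {dups[:5]}")
    return meta[["animal_id", "population", "production_system"]]


def check_metadata_covers(panel: GenotypePanel, meta: pd.DataFrame) -> None:
    missing = sorted(set(panel.animal_ids) - set(meta["animal_id"]))
    if missing:
        raise ValueError(f"animals without metadata: {missing}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

#: allele pair written per status code (codes '1'/'2' are valid PED alleles)
_STATUS_TO_ALLELES = {HOM_A: ("1", "1"), HET: ("1", "2"), HOM_B: ("2", "2"), MISSING: ("0", "0")}


def write_ped_map(panel: GenotypePanel, ped_path, map_path, meta: pd.DataFrame | None = None) -> None:
    """Write the panel as PLINK text PED/MAP.

    Status codes are emitted with synthetic allele labels 1/2 (HET as
    ``1 2``); re-reading reproduces the HOM/HET/MISSING pattern exactly.
    The PED family column carries the population when metadata is given.
    """
    m = panel.snp_map
    with open(map_path, "w") as fh:
        for chrom, snp_id, pos in zip(m["chrom"], m["snp_id"], m["pos_bp"]):
            fh.write(f"{chrom}\t{snp_id}\t0\t{pos}\n")

    pop_of = {}
    if meta is not None:
        pop_of = dict(zip(meta["animal_id"], meta["population"]))
    allele_strings = {code: f"{x} {y}" for code, (x, y) in _STATUS_TO_ALLELES.items()}
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(panel.animal_ids):
            fam = pop_of.get(animal, "0")
            lead = f"{fam}\t{animal}\t0\t0\t0\t-9"
            genos = "\t".join(allele_strings[int(c)] for c in panel.calls[i])
            fh.write(f"{lead}\t{genos}\n")


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_roh_table(runs: pd.DataFrame, path) -> None:
    """Write the detected-runs table as TSV.

    Columns follow :data:`ROH_TABLE_COLUMNS`; rows sorted by
    (animal_id, chrom, start_bp); coordinates 1-based inclusive.
    An empty run list yields a header-only file.
    """
    if runs is None or len(runs) == 0:
        runs = pd.DataFrame(columns=ROH_TABLE_COLUMNS)
    out = runs[ROH_TABLE_COLUMNS].sort_values(
        ["animal_id", "chrom", "start_bp"], kind="mergesort"
    )
    out.to_csv(path, sep="\t", index=False)


def read_roh_table(path) -> pd.DataFrame:
    runs = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "population": str})
    missing = set(ROH_TABLE_COLUMNS) - set(runs.columns)
    if missing:
        raise FormatError(f"{path}: ROH table missing columns {sorted(missing)}")
    return runs


def roh_to_bed(runs: pd.DataFrame) -> pd.DataFrame:
    """Convert run intervals to BED convention (0-based, half-open).

    start_bed = start_bp - 1, end_bed = end_bp: a 1-based inclusive
    interval [s, e] and the BED interval [s-1, e) cover the same bases.
    """
    bed = pd.DataFrame(
        {
            "chrom": runs["chrom"],
            "start": runs["start_bp"] - 1,
            "end": runs["end_bp"],
            "name": runs["animal_id"],
        }
    )
    return bed.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
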