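"""Genotype and phenotype I/O.

Reads and writes the PLINK1 binary trio (``.bed``/``.bim``/``.fam``) and
tab-separated phenotype/result tables.  The in-memory genotype convention
throughout the package is

* ``0`` — homozygous for the minor allele,
* ``1`` — heterozygous,
* ``2`` — homozygous for the major allele,

which corresponds to PLINK's native A1-allele dosage when A1 is the minor
allele (the usual PLINK orientation).  The ``.bed`` two-bit codes map as
``00 -> 0`` (hom. A1), ``10 -> 1`` (het), ``11 -> 2`` (hom. A2) and ``01``
is missing.

The ``.bed`` reader supports block-wise iteration over subjects through a
memory map, so cohorts larger than memory can be consumed batch-wise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_MISSING = -1  # internal sentinel for the PLINK 01 code


class PlinkFormatError(ValueError):
    """Raised when a .bed/.bim/.fam file violates the PLINK1 format."""


class GenotypeValidationError(ValueError):
    """Raised when genotype or phenotype content violates the data contract."""


def _build_decode_lut() -> np.ndarray:
    """256 x 4 table: byte -> four genotypes (low bit-pair first)."""
    code_map = np.array([0, _MISSING, 1, 2], dtype=np.int8)  # 00,01,10,11
    lut = np.empty((256, 4), dtype=np.int8)
    for byte in range(256):
        for k in range(4):
            lut[byte, k] = code_map[(byte >> (2 * k)) & 0b11]
    return lut


_DECODE_LUT = _build_decode_lut()
_ENCODE_CODE = np.array([0b00, 0b10, 0b11], dtype=np.uint8)  # geno -> bit pair


@dataclass
class GenotypeDataset:
    """A cohort of ``n`` subjects genotyped at ``m`` biallelic SNPs.

    ``genotypes`` is an ``(n, m)`` integer matrix with entries in {0, 1, 2}
    (0 = homozygous minor).  ``alleles`` holds (minor, major) pairs per SNP.
    ``is_decoy`` marks synthetic negative-control SNPs; data loaded from disk
    always has it all-False (decoys are created by :func:`linaprs.simdata.make_decoys`).
    """

    genotypes: np.ndarray
    snp_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    alleles: np.ndarray
    sample_ids: np.ndarray
    is_decoy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.is_decoy is None:
            self.is_decoy = np.zeros(self.n_snps, dtype=bool)
        self.is_decoy = np.asarray(self.is_decoy, dtype=bool)
        self.validate()

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        n, m = self.genotypes.shape
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise GenotypeValidationError("genotype entries must be 0, 1 or 2")
        for name, arr, size in (
            ("snp_ids", self.snp_ids, m),
            ("chromosomes", self.chromosomes, m),
            ("positions", self.positions, m),
            ("is_decoy", self.is_decoy, m),
            ("sample_ids", self.sample_ids, n),
        ):
            if arr.shape[0] != size:
                raise GenotypeValidationError(f"{name} has length {arr.shape[0]}, expected {size}")
        if self.alleles.shape != (m, 2):
            raise GenotypeValidationError(f"alleles must be (m, 2), got {self.alleles.shape}")
        if len(set(self.snp_ids)) != m:
            raise GenotypeValidationError("snp_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise GenotypeValidationError("sample_ids must be unique")

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return GenotypeDataset(
            genotypes=self.genotypes[:, mask],
            snp_ids=self.snp_ids[mask],
            chromosomes=self.chromosomes[mask],
            positions=self.positions[mask],
            alleles=self.alleles[mask],
            sample_ids=self.sample_ids,
            is_decoy=self.is_decoy[mask],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.snp_ids, other.snp_ids)
            and np.array_equal(self.chromosomes, other.chromosomes)
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.alleles, other.alleles)
            and np.array_equal(self.sample_ids, other.sample_ids)
            and np.array_equal(self.is_decoy, other.is_decoy)
        )


@dataclass
class PhenotypeMatrix:
    """Binary outcomes for ``n`` subjects across ``d`` traits.

    ``prevalences`` are the column means of ``outcomes``; rows align with the
    companion :class:`GenotypeDataset`'s ``sample_ids``.
    """

    outcomes: np.ndarray
    trait_names: np.ndarray
    prevalences: np.ndarray
    sample_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=np.int8)
        self.trait_names = np.asarray(self.trait_names, dtype=object)
        self.prevalences = np.asarray(self.prevalences, dtype=float)
        if not np.isin(self.outcomes, (0, 1)).all():
            raise GenotypeValidationError("phenotype entries must be 0 or 1")
        if self.outcomes.shape[1] != len(self.trait_names):
            raise GenotypeValidationError("trait_names length mismatch")
        if not np.allclose(self.prevalences, self.outcomes.mean(axis=0)):
            raise GenotypeValidationError("prevalences must equal column means of outcomes")
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
            if len(self.sample_ids) != self.outcomes.shape[0]:
                raise GenotypeValidationError("sample_ids length mismatch")

    @classmethod
    def from_outcomes(
        cls,
        outcomes: np.ndarray,
        trait_names: Sequence[str],
        sample_ids: Sequence[str] | None = None,
    ) -> "PhenotypeMatrix":
        outcomes = np.asarray(outcomes, dtype=np.int8)
        prev = outcomes.mean(axis=0)
        for t, p in zip(trait_names, prev):
            if p == 0.0:
                logger.warning("trait %r has no cases (prevalence 0)", t)
        return cls(outcomes, np.asarray(trait_names, dtype=object), prev,
                   None if sample_ids is None else np.asarray(sample_ids, dtype=object))

    @property
    def n_traits(self) -> int:
        return self.outcomes.shape[1]


# ---------------------------------------------------------------------------
# PLINK1 binary trio
# ---------------------------------------------------------------------------

def _bed_paths(prefix: str | Path) -> tuple[Path, Path, Path]:
    prefix = Path(prefix)
    return (prefix.with_suffix(".bed"), prefix.with_suffix(".bim"), prefix.with_suffix(".fam"))


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str})
    return bim


def _read_fam(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None,
                       names=["fid", "iid", "father", "mother", "sex", "pheno"],
                       dtype={"fid": str, "iid": str})


def _decode_snp_major(raw: np.ndarray, n: int) -> np.ndarray:
    """Decode an (m, bytes_per_snp) uint8 block to an (n, m) int8 genotype matrix."""
    geno = _DECODE_LUT[raw].reshape(raw.shape[0], -1)[:, :n]
    return np.ascontiguousarray(geno.T)


def _impute_missing(geno: np.ndarray, policy: str, snp_modes: np.ndarray | None = None) -> np.ndarray:
    """Resolve missing entries (sentinel -1) per the configured policy."""
    miss = geno == _MISSING
    if not miss.any():
        return geno
    if policy == "strict":
        raise GenotypeValidationError(
            f"{int(miss.sum())} missing genotype call(s) under strict missing policy"
        )
    if policy != "mode":
        raise ValueError(f"unknown missing policy {policy!r}")
    if snp_modes is None:
        snp_modes = _column_modes(geno)
    cols = np.where(miss.any(axis=0))[0]
    for j in cols:
        geno[miss[:, j], j] = snp_modes[j]
    return geno


def _column_modes(geno: np.ndarray) -> np.ndarray:
    """Per-SNP modal genotype among non-missing calls; ties break toward the
    smaller code; all-missing columns fall back to 0."""
    modes = np.zeros(geno.shape[1], dtype=np.int8)
    for j in range(geno.shape[1]):
        col = geno[:, j]
        counts = np.bincount(col[col != _MISSING] + 0, minlength=3) if (col != _MISSING).any() else None
        if counts is not None:
            modes[j] = int(np.argmax(counts[:3]))
    return modes


def read_plink(prefix: str | Path, missing: str = "mode") -> GenotypeDataset:
    """Read a PLINK1 ``.bed/.bim/.fam`` trio into a :class:`GenotypeDataset`.

    Parameters
    ----------
    prefix:
        Path stem shared by the three files.
    missing:
        ``"mode"`` (default) imputes missing calls to the per-SNP modal
        genotype; ``"strict"`` raises on any missing call.
    """
    bed, bim_p, fam_p = _bed_paths(prefix)
    for p in (bed, bim_p, fam_p):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK file: {p}")
    bim = _read_bim(bim_p)
    fam = _read_fam(fam_p)
    n, m = len(fam), len(bim)
    with open(bed, "rb") as fh:
        magic = fh.read(3)
        if magic != BED_MAGIC:
            raise PlinkFormatError(
                f"bad .bed magic bytes {magic!r}; expected SNP-major PLINK1 (6c 1b 01)"
            )
        raw = np.fromfile(fh, dtype=np.uint8)
    bps = (n + 3) // 4
    if raw.size != m * bps:
        raise PlinkFormatError(f".bed payload is {raw.size} bytes, expected {m * bps}")
    geno = _decode_snp_major(raw.reshape(m, bps), n)
    geno = _impute_missing(geno, missing)
    return GenotypeDataset(
        genotypes=geno,
        snp_ids=bim["snp_id"].to_numpy(dtype=object),
        chromosomes=bim["chrom"].to_numpy(dtype=object),
        positions=bim["pos"].to_numpy(),
        alleles=bim[["a1", "a2"]].to_numpy(dtype=object),
        sample_ids=fam["iid"].to_numpy(dtype=object),
    )


def iter_plink_subjects(
    prefix: str | Path, batch_size: int, missing: str = "mode"
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Iterate subject blocks of a ``.bed`` without materializing the matrix.

    Yields ``(sample_ids_block, genotype_block)`` pairs.  The ``.bed`` payload
    is memory-mapped (SNP-major), so each block touches only the byte columns
    covering its subjects.  Under the ``"mode"`` missing policy the per-SNP
    modes are computed in a preliminary SNP-row-block scan.
    """
    bed, bim_p, fam_p = _bed_paths(prefix)
    bim = _read_bim(bim_p)
    fam = _read_fam(fam_p)
    n, m = len(fam), len(bim)
    bps = (n + 3) // 4
    with open(bed, "rb") as fh:
        if fh.read(3) != BED_MAGIC:
            raise PlinkFormatError("bad .bed magic bytes")
    mm = np.memmap(bed, dtype=np.uint8, mode="r", offset=3, shape=(m, bps))

    snp_modes = None
    if missing == "mode":
        # row-block scan for per-SNP modes (cheap; avoids holding n x m)
        modes = np.zeros(m, dtype=np.int8)
        any_missing = False
        for j0 in range(0, m, 1024):
            j1 = min(j0 + 1024, m)
            block = _decode_snp_major(np.asarray(mm[j0:j1]), n)
            if (block == _MISSING).any():
                any_missing = True
            modes[j0:j1] = _column_modes(block)
        snp_modes = modes if any_missing else None

    sample_ids = fam["iid"].to_numpy(dtype=object)
    for i0 in range(0, n, batch_size):
        i1 = min(i0 + batch_size, n)
        b0, b1 = i0 // 4, (i1 + 3) // 4
        chunk = np.asarray(mm[:, b0:b1])
        geno = _DECODE_LUT[chunk].reshape(m, -1)[:, i0 - 4 * b0 : i1 - 4 * b0]
        geno = np.ascontiguousarray(geno.T)
        geno = _impute_missing(geno, missing, snp_modes)
        yield sample_ids[i0:i1], geno


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write a :class:`GenotypeDataset` as a PLINK1 SNP-major trio.

    The minor allele is written as A1 and the major as A2, preserving the
    0 = homozygous-minor orientation on round trip.
    """
    bed, bim_p, fam_p = _bed_paths(prefix)
    bed.parent.mkdir(parents=True, exist_ok=True)
    n, m = dataset.genotypes.shape
    codes = _ENCODE_CODE[dataset.genotypes.T]  # (m, n) bit pairs
    pad = (-n) % 4
    if pad:
        # pad with 00 (hom A1); padding bits are ignored on read
        codes = np.concatenate([codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    codes = codes.reshape(m, -1, 4)
    packed = (codes[:, :, 0] | codes[:, :, 1] << 2 | codes[:, :, 2] << 4 | codes[:, :, 3] << 6)
    with open(bed, "wb") as fh:
        fh.write(BED_MAGIC)
        packed.astype(np.uint8).tofile(fh)
    bim = pd.DataFrame({
        "chrom": dataset.chromosomes,
        "snp_id": dataset.snp_ids,
        "cm": 0,
        "pos": dataset.positions,
        "a1": dataset.alleles[:, 0],
        "a2": dataset.alleles[:, 1],
    })
    bim.to_csv(bim_p, sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": dataset.sample_ids,
        "iid": dataset.sample_ids,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(fam_p, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Phenotype and generic tables
# ---------------------------------------------------------------------------

def read_phenotypes(path: str | Path, genotypes: GenotypeDataset | None = None) -> PhenotypeMatrix:
    """Read a subjects x traits binary outcome TSV (header = trait names).

    A leading ``sample_id`` column, if present, is used for alignment; when
    ``genotypes`` is given the subject sets must match in order.
    """
    df = pd.read_csv(path, sep="\t")
    sample_ids = None
    if "sample_id" in df.columns:
        sample_ids = df.pop("sample_id").astype(str).to_numpy(dtype=object)
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise GenotypeValidationError(f"non-binary phenotype cell in {path}")
    if genotypes is not None:
        if sample_ids is None or not np.array_equal(sample_ids, genotypes.sample_ids):
            raise GenotypeValidationError("phenotype subjects do not align with genotype sample_ids")
    return PhenotypeMatrix.from_outcomes(values, list(df.columns), sample_ids)


def write_phenotypes(phenotypes: PhenotypeMatrix, path: str | Path,
                     sample_ids: Sequence[str] | None = None) -> None:
    ids = phenotypes.sample_ids if sample_ids is None else np.asarray(sample_ids, dtype=object)
    df = pd.DataFrame(phenotypes.outcomes, columns=phenotypes.trait_names)
    if ids is not None:
        df.insert(0, "sample_id", ids)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_table(rows, path: str | Path) -> None:
    """Write a rectangular record table as TSV with header.

    Accepts a DataFrame or a sequence of dicts (all with identical keys).
    Floats keep >= 12 significant digits; row order is preserved as given.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if not rows:
            raise GenotypeValidationError("empty record table")
        keys = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != keys:
                raise GenotypeValidationError("ragged records: inconsistent keys")
        df = pd.DataFrame(rows, columns=keys)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.15g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
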