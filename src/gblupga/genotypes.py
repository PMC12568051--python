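"""Genotype container, PLINK/CSV I/O and quality control.

Genotypes are stored as allele counts in {0, 1, 2} (copies of the counted
allele, PLINK allele-1) with ``numpy.nan`` marking missing calls.  Allele
frequencies are always observed sample frequencies of the counted allele,
computed over non-missing calls, and are recomputed whenever the panel
changes (QC, subsetting).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "GenotypeFormatError",
    "EmptyPanelError",
    "read_genotypes",
    "write_genotypes",
    "qc_filter",
]


class GenotypeFormatError(ValueError):
    """Raised when genotype files are malformed or mutually inconsistent."""


class EmptyPanelError(ValueError):
    """Raised when an operation would leave no SNPs (or individuals)."""


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with its marker map.

    Parameters
    ----------
    individual_ids : list of str
        Ordered, unique individual identifiers (rows of ``codes``).
    snp_ids : list of str
        Ordered, unique SNP identifiers (columns of ``codes``).
    snp_chrom, snp_pos : ndarray
        Per-SNP chromosome label and base-pair position.
    codes : ndarray, shape (n, s), float
        Counts of the counted allele; ``nan`` = missing.  After QC
        imputation entries may be fractional (the mean code ``2 p_i``).
    """

    individual_ids: list
    snp_ids: list
    snp_chrom: np.ndarray
    snp_pos: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.snp_chrom = np.asarray(self.snp_chrom)
        self.snp_pos = np.asarray(self.snp_pos, dtype=int)
        n, s = self.codes.shape
        if len(self.individual_ids) != n:
            raise GenotypeFormatError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if not (len(self.snp_ids) == len(self.snp_chrom) == len(self.snp_pos) == s):
            raise GenotypeFormatError("SNP map length does not match matrix columns")
        if len(set(self.individual_ids)) != n:
            raise GenotypeFormatError("duplicate individual ids")
        if len(set(self.snp_ids)) != s:
            raise GenotypeFormatError("duplicate SNP ids")
        valid = np.isnan(self.codes) | np.isin(self.codes, (0.0, 1.0, 2.0))
        # fractional imputed codes are allowed only via qc_filter, which sets
        # this flag; raw input must be {0,1,2,nan}
        if not getattr(self, "_imputed", False) and not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise GenotypeFormatError(
                f"invalid genotype code {self.codes[i, j]!r} at individual "
                f"{self.individual_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency p_i of the counted allele, from non-missing calls."""
        return np.nanmean(self.codes, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def snp_indexer(self, snp_set) -> np.ndarray:
        """Column indices for a SNP id collection (or "all"), in panel order."""
        if isinstance(snp_set, str) and snp_set == "all":
            return np.arange(self.n_snps)
        wanted = set(snp_set)
        missing = wanted - set(self.snp_ids)
        if missing:
            raise KeyError(f"SNPs not in panel: {sorted(missing)[:5]} ...")
        return np.array([j for j, s in enumerate(self.snp_ids) if s in wanted])

    def subset(self, individuals=None, snps=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals)
        if individuals is not None:
            pos = {iid: i for i, iid in enumerate(self.individual_ids)}
            rows = np.array([pos[i] for i in individuals])
        cols = self.snp_indexer(snps) if snps is not None else np.arange(self.n_snps)
        out = GenotypeMatrix.__new__(GenotypeMatrix)
        out._imputed = getattr(self, "_imputed", False)
        out.individual_ids = [self.individual_ids[i] for i in rows]
        out.snp_ids = [self.snp_ids[j] for j in cols]
        out.snp_chrom = self.snp_chrom[cols]
        out.snp_pos = self.snp_pos[cols]
        out.codes = self.codes[np.ix_(rows, cols)]
        return out


@dataclasses.dataclass
class QCReport:
    n_snps_in: int
    n_snps_out: int
    n_removed_maf: int
    n_removed_callrate: int
    n_individuals_removed: int
    n_imputed: int
    maf_min: float
    snp_callrate_min: float
    ind_callrate_min: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


# ---------------------------------------------------------------------------
# PLINK BED v1.0 (SNP-major) codec.
#
# 2 bits per call, individuals packed 4/byte, LSB first.  Bit pairs:
#   00 = hom A1A1 (code 2),  10 = het (1),  11 = hom A2A2 (0),  01 = missing.
# The counted allele is PLINK allele-1, so G built from these codes is
# reproducible across round-trips.
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# bit-pair value -> allele count
_PAIR2CODE = np.array([2.0, np.nan, 1.0, 0.0])
_CODE2PAIR = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}


def _write_bed(geno: GenotypeMatrix, prefix: Path) -> None:
    n, s = geno.codes.shape
    nbytes = (n + 3) // 4
    pairs = np.full((s, n), 0b01, dtype=np.uint8)  # default missing
    for code, bits in _CODE2PAIR.items():
        pairs[(geno.codes.T == code)] = bits
    # fractional (imputed) codes round to nearest integer code on export
    frac = ~np.isnan(geno.codes.T) & ~np.isin(geno.codes.T, (0.0, 1.0, 2.0))
    if frac.any():
        rounded = np.clip(np.rint(geno.codes.T[frac]), 0, 2)
        pairs[frac] = np.array([_CODE2PAIR[c] for c in rounded], dtype=np.uint8)
    shifts = (np.arange(n) % 4) * 2
    byte_idx = np.arange(n) // 4
    packed = np.zeros((s, nbytes), dtype=np.uint8)
    np.add.at(packed, (slice(None), byte_idx), pairs << shifts)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": geno.snp_chrom,
            "snp": geno.snp_ids,
            "cm": 0,
            "pos": geno.snp_pos,
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.individual_ids,
            "iid": geno.individual_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str, "chrom": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, s = len(fam), len(bim)
    nbytes = (n + 3) // 4
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeFormatError(f"{prefix}.bed: bad magic (not SNP-major BED v1.0)")
    body = raw[3:]
    if body.size != s * nbytes:
        raise GenotypeFormatError(
            f"{prefix}.bed: {body.size} data bytes, expected {s * nbytes} "
            f"for {n} individuals x {s} SNPs"
        )
    packed = body.reshape(s, nbytes)
    shifts = (np.arange(n) % 4) * 2
    pairs = (packed[:, np.arange(n) // 4] >> shifts) & 0b11
    codes = _PAIR2CODE[pairs].T  # (n, s)
    return GenotypeMatrix(
        individual_ids=list(fam["iid"]),
        snp_ids=list(bim["snp"]),
        snp_chrom=bim["chrom"].to_numpy(),
        snp_pos=bim["pos"].to_numpy(),
        codes=codes,
    )


# ---------------------------------------------------------------------------
# Headered CSV dialect: rows = individuals (first column `individual_id`),
# remaining columns = SNP ids, cells in {0,1,2,NA}.  The map is synthesized
# (chrom "0", pos = column index) unless a `<stem>.map.csv` sidecar exists
# with columns snp_id,chrom,pos.
# ---------------------------------------------------------------------------


def _write_csv(geno: GenotypeMatrix, path: Path) -> None:
    df = pd.DataFrame(geno.codes, columns=geno.snp_ids)
    df.insert(0, "individual_id", geno.individual_ids)
    df.to_csv(path, index=False)
    pd.DataFrame(
        {"snp_id": geno.snp_ids, "chrom": geno.snp_chrom, "pos": geno.snp_pos}
    ).to_csv(path.with_suffix(".map.csv"), index=False)


def _read_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype={"individual_id": str})
    if df.columns[0] != "individual_id":
        raise GenotypeFormatError(f"{path}: first column must be 'individual_id'")
    ids = list(df["individual_id"])
    snp_ids = list(df.columns[1:])
    codes = df[snp_ids].to_numpy(dtype=float)
    bad = ~(np.isnan(codes) | np.isin(codes, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise GenotypeFormatError(
            f"{path}: invalid code {codes[i, j]!r} at row {ids[i]!r}, "
            f"column {snp_ids[j]!r}"
        )
    mapfile = path.with_suffix(".map.csv")
    if mapfile.exists():
        m = pd.read_csv(mapfile, dtype={"snp_id": str, "chrom": str})
        m = m.set_index("snp_id").reindex(snp_ids)
        if m["pos"].isna().any():
            raise GenotypeFormatError(f"{mapfile}: map does not cover all SNPs")
        chrom, pos = m["chrom"].to_numpy(), m["pos"].to_numpy(int)
    else:
        chrom = np.array(["0"] * len(snp_ids))
        pos = np.arange(1, len(snp_ids) + 1)
    return GenotypeMatrix(ids, snp_ids, chrom, pos, codes)


def read_genotypes(path, format: str = "plink-bed") -> GenotypeMatrix:
    """Load a genotype panel from PLINK BED/BIM/FAM or the CSV dialect.

    ``path`` is the file-set prefix for PLINK, the .csv file for CSV.
    """
    path = Path(path)
    if format == "plink-bed":
        return _read_bed(path.with_suffix("") if path.suffix == ".bed" else path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(geno: GenotypeMatrix, path, format: str = "plink-bed") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "plink-bed":
        _write_bed(geno, path.with_suffix("") if path.suffix == ".bed" else path)
    elif format == "csv":
        _write_csv(geno, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.01,
    snp_callrate_min: float = 0.90,
    ind_callrate_min: float = 0.90,
) -> tuple[GenotypeMatrix, QCReport]:
    """Filter individuals by call rate, then SNPs by call rate and MAF.

    Remaining missing calls are imputed to the SNP mean code ``2 p_i`` so
    that centred-score matrices treat them as exactly average (zero
    contribution to G).  Retained id order is preserved.
    """
    for t in (maf_min, snp_callrate_min, ind_callrate_min):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    codes = geno.codes
    n_in, s_in = codes.shape

    ind_call = 1.0 - np.isnan(codes).mean(axis=1)
    keep_ind = ind_call >= ind_callrate_min
    codes = codes[keep_ind]
    n_ind_removed = int((~keep_ind).sum())

    snp_call = 1.0 - np.isnan(codes).mean(axis=0)
    keep_call = snp_call >= snp_callrate_min
    n_removed_callrate = int((~keep_call).sum())

    import warnings as _warnings

    with _warnings.catch_warnings():
        # all-missing columns yield nan means; they were already dropped by
        # the call-rate filter, so the warning is noise
        _warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(codes, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep_maf = keep_call & ~(np.nan_to_num(maf, nan=-1.0) < maf_min)
    n_removed_maf = int(keep_call.sum() - keep_maf.sum())

    keep_snp = keep_maf
    if not keep_snp.any():
        raise EmptyPanelError("QC removed every SNP")

    codes = codes[:, keep_snp]
    miss = np.isnan(codes)
    n_imputed = int(miss.sum())
    if n_imputed:
        mean_code = np.nanmean(codes, axis=0)
        codes = np.where(miss, mean_code[None, :], codes)

    out = GenotypeMatrix.__new__(GenotypeMatrix)
    out._imputed = True
    out.individual_ids = [
        iid for iid, k in zip(geno.individual_ids, keep_ind) if k
    ]
    out.snp_ids = [sid for sid, k in zip(geno.snp_ids, keep_snp) if k]
    out.snp_chrom = geno.snp_chrom[keep_snp]
    out.snp_pos = geno.snp_pos[keep_snp]
    out.codes = codes

    report = QCReport(
        n_snps_in=s_in,
        n_snps_out=int(keep_snp.sum()),
        n_removed_maf=n_removed_maf,
        n_removed_callrate=n_removed_callrate,
        n_individuals_removed=n_ind_removed,
        n_imputed=n_imputed,
        maf_min=maf_min,
        snp_callrate_min=snp_callrate_min,
        ind_callrate_min=ind_callrate_min,
    )
    return out, report
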