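"""Reading and writing of SNP genotype data and tabular results.

Genotypes are held in a :class:`GenotypeMatrix`: an individuals x SNPs
matrix of allele-B dosages (0, 1, 2) with ``MISSING`` (-1) as the missing
sentinel, plus a SNP metadata table (id, chromosome, bp, cM, alleles).
The on-disk representation is the PLINK bed/bim/fam triple (binary,
SNP-major), the de-facto standard for array genotypes.

Coordinates are 1-based inclusive base-pair positions throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Missing-genotype sentinel.  0 is a valid homozygote, so missing is -1.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 2-bit codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2.
# Our dosage counts copies of allele B (= PLINK A2).
_BITS_TO_CODE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CODE_TO_BITS = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}

SNP_COLUMNS = ["snp_id", "chromosome", "bp", "cM", "alleleA", "alleleB"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs dosage matrix with SNP metadata.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, in row order of ``codes``.
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chromosome, bp, cM,
        alleleA, alleleB``, in column order of ``codes``.
    codes : numpy.ndarray of int8, shape (n_individuals, n_snps)
        Copies of allele B per genotype; ``MISSING`` where uncalled.
    """

    ids: list[str]
    snps: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.ids), len(self.snps)):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.ids)} individuals x {len(self.snps)} SNPs"
            )
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_freq(self) -> np.ndarray:
        """Allele-B frequency per SNP, ignoring missing calls."""
        called = self.codes != MISSING
        n = called.sum(axis=0)
        dose = np.where(called, self.codes, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, dose / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def snp_call_rate(self) -> np.ndarray:
        return (self.codes != MISSING).mean(axis=0)

    def individual_call_rate(self) -> np.ndarray:
        return (self.codes != MISSING).mean(axis=1)

    def sort_genomic(self) -> "GenotypeMatrix":
        """Return a copy with SNPs in (chromosome, bp) order."""
        order = np.lexsort((self.snps["bp"].to_numpy(), self.snps["chromosome"].to_numpy()))
        snps = self.snps.iloc[order].reset_index(drop=True)
        return GenotypeMatrix(list(self.ids), snps, self.codes[:, order])


def write_genotypes(g: GenotypeMatrix, path_prefix: str | Path) -> None:
    """Write ``g`` as a PLINK bed/bim/fam triple at ``path_prefix``."""
    prefix = Path(path_prefix)
    n, m = g.codes.shape

    bim = pd.DataFrame(
        {
            "chromosome": g.snps["chromosome"],
            "snp_id": g.snps["snp_id"],
            "cM": g.snps["cM"],
            "bp": g.snps["bp"],
            "alleleA": g.snps["alleleA"],
            "alleleB": g.snps["alleleB"],
        }
    )
    # fixed float format keeps write->read->write byte-stable
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False, float_format="%.10g")

    fam = pd.DataFrame(
        {"fid": g.ids, "iid": g.ids, "father": 0, "mother": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)

    # SNP-major packing: 4 individuals per byte, low bits first.
    bits = np.empty((m, n), dtype=np.uint8)
    for code, b in _CODE_TO_BITS.items():
        bits[g.codes.T == code] = b
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        packed[:, : len(cols)] |= bits[:, cols] << (2 * k)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_genotypes(path_prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triple into a :class:`GenotypeMatrix`.

    SNPs are returned in genomic (chromosome, bp) order regardless of
    file order.  Raises ``ValueError`` with file context on malformed
    magic bytes, dimension mismatch or duplicate SNP ids.
    """
    prefix = Path(path_prefix)
    bim_path, fam_path, bed_path = f"{prefix}.bim", f"{prefix}.fam", f"{prefix}.bed"
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "cM", "bp", "alleleA", "alleleB"],
        dtype={"snp_id": str, "alleleA": str, "alleleB": str},
    )
    if bim["snp_id"].duplicated().any():
        dup = bim.loc[bim["snp_id"].duplicated(), "snp_id"].iloc[0]
        raise ValueError(f"{bim_path}: duplicate snp_id {dup!r}")
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    ids = fam.iloc[:, 1].tolist()
    n, m = len(ids), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{bed_path}: malformed magic bytes {raw[:3].tobytes()!r}")
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if body.size != m * n_bytes:
        raise ValueError(
            f"{bed_path}: expected {m * n_bytes} data bytes for "
            f"{n} individuals x {m} SNPs, found {body.size}"
        )
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n), dtype=np.int8)
    for k in range(4):
        cols = np.arange(k, n, 4)
        codes[:, cols] = _BITS_TO_CODE[(body[:, : len(cols)] >> (2 * k)) & 0x3]

    snps = bim[SNP_COLUMNS].copy()
    g = GenotypeMatrix(ids, snps, codes.T)
    return g.sort_genomic()


@dataclass
class QcReport:
    """Per-record removal report from :func:`qc_filter`."""

    removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["kind", "id", "reason", "value"])
    )

    @property
    def n_snps_removed(self) -> int:
        return int((self.removed["kind"] == "snp").sum())

    @property
    def n_individuals_removed(self) -> int:
        return int((self.removed["kind"] == "individual").sum())


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.001,
    snp_call_min: float = 0.99,
    ind_call_min: float = 0.95,
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter SNPs then individuals on MAF and call rate.

    Retained SNPs have MAF strictly greater than ``maf_min`` (so
    monomorphic SNPs always drop when ``maf_min`` >= 0) and call rate
    strictly greater than ``snp_call_min``; retained individuals have
    call rate strictly greater than ``ind_call_min`` computed on the
    retained SNPs.  SNP filters run before individual filters, one pass
    each.  Thresholds of 0 (and MAF threshold < 0) leave the input
    unchanged.
    """
    for name, v in [("maf_min", maf_min), ("snp_call_min", snp_call_min), ("ind_call_min", ind_call_min)]:
        if not -1 <= v <= 1:
            raise ValueError(f"{name}={v} outside [0, 1]")
    records = []

    maf = g.maf()
    call = g.snp_call_rate()
    # maf_min == 0 with the strict inequality would still drop monomorphic
    # SNPs; "all thresholds 0 -> identity" therefore applies the MAF filter
    # only when maf_min > 0.
    keep_snp = call > snp_call_min if snp_call_min > 0 else np.ones(g.n_snps, bool)
    if maf_min > 0:
        keep_snp &= ~np.isnan(maf) & (maf > maf_min)
    for j in np.flatnonzero(~keep_snp):
        if snp_call_min > 0 and not call[j] > snp_call_min:
            records.append(("snp", g.snps["snp_id"].iloc[j], "call_rate", call[j]))
        else:
            records.append(("snp", g.snps["snp_id"].iloc[j], "maf", maf[j]))
    if not keep_snp.any():
        raise ValueError(
            f"no SNPs retained (maf_min={maf_min}, snp_call_min={snp_call_min})"
        )
    g2 = GenotypeMatrix(list(g.ids), g.snps.loc[keep_snp].reset_index(drop=True), g.codes[:, keep_snp])

    ind_call = g2.individual_call_rate()
    keep_ind = ind_call > ind_call_min if ind_call_min > 0 else np.ones(g2.n_individuals, bool)
    for i in np.flatnonzero(~keep_ind):
        records.append(("individual", g2.ids[i], "call_rate", ind_call[i]))
    if not keep_ind.any():
        raise ValueError(f"no individuals retained (ind_call_min={ind_call_min})")
    g3 = GenotypeMatrix(
        [x for x, k in zip(g2.ids, keep_ind) if k], g2.snps, g2.codes[keep_ind]
    )
    report = QcReport(pd.DataFrame(records, columns=["kind", "id", "reason", "value"]))
    return g3, report


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular result as TSV with a header row.

    Column order is the DataFrame's order, which every producer in this
    package fixes deterministically.
    """
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


HOM_COLUMNS = ["IID", "CHR", "SNP1", "SNP2", "POS1", "POS2", "KB", "NSNP", "NHET"]


def write_hom(segments: pd.DataFrame, g: GenotypeMatrix, path: str | Path) -> None:
    """Write ROH segments in a PLINK ``.hom``-style layout.

    Columns: individual id, chromosome, first/last SNP id, start/end bp,
    length in Kb, SNP count, heterozygote count.
    """
    rows = []
    snps = g.snps
    for _, s in segments.iterrows():
        on_chrom = snps[snps["chromosome"] == s["chromosome"]]
        inside = on_chrom[(on_chrom["bp"] >= s["start_bp"]) & (on_chrom["bp"] <= s["end_bp"])]
        rows.append(
            {
                "IID": s["id"],
                "CHR": s["chromosome"],
                "SNP1": inside["snp_id"].iloc[0] if len(inside) else ".",
                "SNP2": inside["snp_id"].iloc[-1] if len(inside) else ".",
                "POS1": s["start_bp"],
                "POS2": s["end_bp"],
                "KB": s["length_kb"],
                "NSNP": s["n_snps"],
                "NHET": s["n_het"],
            }
        )
    pd.DataFrame(rows, columns=HOM_COLUMNS).to_csv(path, sep="\t", index=False)
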