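"""Scanning-window detection of runs of homozygosity (ROH).

The algorithm mirrors the classic PLINK ``--homozyg`` procedure: a
window of ``window_snp`` consecutive SNPs "qualifies" as homozygous if
it contains at most ``window_het`` heterozygotes and ``window_missing``
missing calls; a SNP is a "hit" if at least ``hit_threshold`` of the
complete windows overlapping it qualify.  Maximal runs of hit SNPs are
split at inter-SNP gaps above ``max_gap_kb``, trimmed so both ends are
homozygous non-missing calls, and emitted as segments if they pass the
SNP-count, length, density and heterozygote filters.

Defaults are a widely used parameterisation for ~50K SNP-array data in
a livestock-density genome: 50-SNP windows, minimum 50 SNPs and 1200 Kb
per segment, 300 Kb maximum gap, 200 Kb/SNP maximum density, at most 2
heterozygotes and 2 missing calls per window and 2 heterozygotes per
segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

SEGMENT_COLUMNS = ["id", "chromosome", "start_bp", "end_bp", "n_snps", "n_het", "length_kb"]


@dataclass
class RohParams:
    """Parameters of the scanning-window ROH caller."""

    window_snp: int = 50
    min_snp: int = 50
    min_kb: float = 1200.0
    max_gap_kb: float = 300.0
    density_kb_per_snp: float = 200.0
    window_het: int = 2
    window_missing: int = 2
    segment_het: int = 2
    #: minimum fraction of overlapping windows that must qualify for a SNP
    #: to count as a hit (the cited implementation's default 0.05)
    hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.hit_threshold <= 1:
            raise ValueError(f"hit_threshold={self.hit_threshold} outside (0, 1]")
        for name in ("window_snp", "min_snp", "window_het", "window_missing", "segment_het"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def window_hits(codes: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-SNP hit flags for one individual on one chromosome.

    ``codes`` is a 1-d array of genotype codes in bp order.  SNPs near
    chromosome ends are evaluated over the complete windows that do
    exist; a chromosome with fewer SNPs than ``window_snp`` yields no
    hits (with a warning).
    """
    codes = np.asarray(codes)
    m = codes.size
    W = params.window_snp
    if m < W:
        warnings.warn(
            f"chromosome with {m} SNPs is shorter than the {W}-SNP window; no hits",
            stacklevel=2,
        )
        return np.zeros(m, dtype=bool)
    het = (codes == 1).astype(np.int64)
    mis = (codes == MISSING).astype(np.int64)
    # sliding sums over all m-W+1 complete windows
    cs_het = np.concatenate([[0], np.cumsum(het)])
    cs_mis = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - W + 1
    win_het = cs_het[W:] - cs_het[:n_win]
    win_mis = cs_mis[W:] - cs_mis[:n_win]
    qualifies = (win_het <= params.window_het) & (win_mis <= params.window_missing)
    # SNP j is overlapped by windows max(0, j-W+1) .. min(j, n_win-1)
    cq = np.concatenate([[0], np.cumsum(qualifies)])
    j = np.arange(m)
    lo = np.maximum(0, j - W + 1)
    hi = np.minimum(j, n_win - 1)
    n_overlap = hi - lo + 1
    n_qual = cq[hi + 1] - cq[lo]
    return n_qual / n_overlap >= params.hit_threshold


def _segments_one(
    codes: np.ndarray, bp: np.ndarray, params: RohParams
) -> list[tuple[int, int, int, int]]:
    """Candidate-to-final segments for one individual/chromosome.

    Returns (start_idx, end_idx, n_snps, n_het) tuples over SNP indices.
    """
    hits = window_hits(codes, params)
    out = []
    max_gap_bp = params.max_gap_kb * 1000.0
    # maximal runs of hit SNPs
    padded = np.concatenate([[False], hits, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:]) - 1
    for s0, e0 in zip(starts, ends):
        # split at gaps > max_gap_kb
        gap_breaks = np.flatnonzero(np.diff(bp[s0 : e0 + 1]) > max_gap_bp)
        bounds = []
        lo = s0
        for gb in gap_breaks:
            bounds.append((lo, s0 + gb))
            lo = s0 + gb + 1
        bounds.append((lo, e0))
        for s, e in bounds:
            # trim until both terminal SNPs are homozygous non-missing
            while s <= e and codes[s] not in (0, 2):
                s += 1
            while e >= s and codes[e] not in (0, 2):
                e -= 1
            if s > e:
                continue
            n_snps = e - s + 1
            n_het = int(np.sum(codes[s : e + 1] == 1))
            length_kb = (bp[e] - bp[s] + 1) / 1000.0
            if (
                n_snps >= params.min_snp
                and length_kb >= params.min_kb
                and length_kb / n_snps <= params.density_kb_per_snp
                and n_het <= params.segment_het
            ):
                out.append((s, e, n_snps, n_het))
    return out


def call_roh(g: GenotypeMatrix, params: RohParams | None = None) -> pd.DataFrame:
    """Call ROH segments for every individual in ``g``.

    Returns a DataFrame with columns ``id, chromosome, start_bp, end_bp,
    n_snps, n_het, length_kb``.  Segments of one individual on one
    chromosome are disjoint; runs separated by a single non-hit SNP are
    not merged.
    """
    params = params or RohParams()
    rows = []
    snps = g.snps
    with warnings.catch_warnings():
        warnings.simplefilter("once")
        for chrom, sub in snps.groupby("chromosome", sort=True):
            cols = sub.index.to_numpy()
            bp = sub["bp"].to_numpy()
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"chromosome {chrom}: bp positions not strictly increasing")
            block = g.codes[:, cols]
            for i, ind in enumerate(g.ids):
                for s, e, n_snps, n_het in _segments_one(block[i], bp, params):
                    rows.append(
                        (
                            ind,
                            chrom,
                            int(bp[s]),
                            int(bp[e]),
                            n_snps,
                            n_het,
                            (bp[e] - bp[s] + 1) / 1000.0,
                        )
                    )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
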