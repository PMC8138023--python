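"""Genomic inbreeding coefficients from ROH segments.

F_ROH is the fraction of the autosomal genome covered by called ROH.
Segments are also binned into length classes indexed by the expected
age of the underlying haplotypes: an IBD tract whose haplotypes
coalesce g generations ago has expected genetic length 100/(2g) cM,
converted to physical length with the genome-wide recombination rate
(default 1.28 cM/Mb, a sex-averaged sheep linkage-map rate).  The default
genome length is 2452 Mb (sheep autosomes); synthetic genomes pass
their own total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_GENOME_MB = 2452.0
DEFAULT_RATE_CM_PER_MB = 1.28


@dataclass
class LengthClassSpec:
    """Generations-to-MRCA grid defining ROH length classes."""

    g_values: tuple = (2, 4, 8, 16, 32)
    rate_cM_per_Mb: float = DEFAULT_RATE_CM_PER_MB
    genome_length_mb: float = DEFAULT_GENOME_MB

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.g_values):
            raise ValueError("g_values must be positive")
        if list(self.g_values) != sorted(self.g_values):
            raise ValueError("g_values must be increasing")
        if self.rate_cM_per_Mb <= 0:
            raise ValueError("rate_cM_per_Mb must be positive")


def mrca_expected_length(g: float, spec: LengthClassSpec | None = None) -> float:
    """Expected physical length (Mb) of an IBD tract coalescing ``g``
    generations ago: (100 / 2g) cM divided by the cM/Mb rate."""
    spec = spec or LengthClassSpec()
    if g <= 0:
        raise ValueError(f"g={g} must be positive")
    return (100.0 / (2.0 * g)) / spec.rate_cM_per_Mb


def _check_disjoint(segments: pd.DataFrame) -> None:
    for (ind, chrom), sub in segments.groupby(["id", "chromosome"], sort=False):
        s = sub.sort_values("start_bp")
        if (s["start_bp"].to_numpy()[1:] <= s["end_bp"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments for individual {ind!r} chromosome {chrom}")


def f_roh(segments: pd.DataFrame, genome_length_mb: float = DEFAULT_GENOME_MB) -> float:
    """Fraction of the genome in ROH for one individual's segments."""
    if len(segments) == 0:
        return 0.0
    if segments["id"].nunique() > 1:
        raise ValueError("f_roh expects segments of a single individual")
    _check_disjoint(segments)
    total_bp = (segments["end_bp"] - segments["start_bp"] + 1).sum()
    return float(total_bp / (genome_length_mb * 1e6))


def f_roh_excluding(
    segments: pd.DataFrame,
    focal_chromosome: int,
    chromosome_lengths_mb: dict,
) -> float:
    """F_ROH over all chromosomes except the focal one.

    ``chromosome_lengths_mb`` maps chromosome -> length in Mb and must
    cover every chromosome, focal included.
    """
    if focal_chromosome not in chromosome_lengths_mb:
        raise ValueError(f"unknown chromosome {focal_chromosome!r}")
    total_mb = sum(chromosome_lengths_mb.values()) - chromosome_lengths_mb[focal_chromosome]
    if len(segments) == 0:
        return 0.0
    _check_disjoint(segments)
    keep = segments[segments["chromosome"] != focal_chromosome]
    bp = (keep["end_bp"] - keep["start_bp"] + 1).sum()
    return float(bp / (total_mb * 1e6))


def class_bounds_mb(spec: LengthClassSpec | None = None) -> pd.DataFrame:
    """Length-class table: one row per class, longest (most recent MRCA)
    first, with physical bounds in Mb.

    Classes are half-open on length, [lower, upper), with boundary
    lengths assigned to the longer-length (shorter-MRCA) class; the
    longest class is unbounded above and a catch-all class collects
    segments shorter than the oldest boundary.
    """
    spec = spec or LengthClassSpec()
    lengths = [mrca_expected_length(g, spec) for g in spec.g_values]
    rows = []
    upper = np.inf
    prev_g = None
    for g, lo in zip(spec.g_values, lengths):
        label = f"g<={g}" if prev_g is None else f"g{prev_g}-{g}"
        rows.append({"label": label, "lower_mb": lo, "upper_mb": upper, "g_max": g})
        upper = lo
        prev_g = g
    rows.append({"label": f"g>{prev_g}", "lower_mb": 0.0, "upper_mb": upper, "g_max": np.inf})
    return pd.DataFrame(rows)


def classify_length_bins(
    segments: pd.DataFrame, spec: LengthClassSpec | None = None
) -> pd.Series:
    """Genome fraction per MRCA length class for one individual.

    Each segment falls in exactly one class by its physical length
    (half-open bins, boundary to the longer-length class); fractions are
    segment length sums over ``spec.genome_length_mb`` and add up to the
    individual's F_ROH.
    """
    spec = spec or LengthClassSpec()
    bounds = class_bounds_mb(spec)
    out = pd.Series(0.0, index=bounds["label"])
    if len(segments) == 0:
        return out
    _check_disjoint(segments)
    length_mb = (segments["end_bp"] - segments["start_bp"] + 1).to_numpy() / 1e6
    for _, row in bounds.iterrows():
        in_bin = (length_mb >= row["lower_mb"]) & (length_mb < row["upper_mb"])
        out[row["label"]] = length_mb[in_bin].sum() / spec.genome_length_mb
    return out


def froh_table(
    segments: pd.DataFrame,
    individuals: list,
    chromosome_lengths_mb: dict,
    genome_length_mb: float | None = None,
    spec: LengthClassSpec | None = None,
) -> pd.DataFrame:
    """Per-individual F_ROH summary over a population segment table.

    Returns one row per individual in ``individuals`` (zero rows of
    segments give F_ROH 0) with genome-wide ``f_roh``, per-chromosome
    leave-one-out ``f_roh_excl_<chrom>`` columns and length-class
    fractions.
    """
    genome_mb = genome_length_mb or sum(chromosome_lengths_mb.values())
    spec = spec or LengthClassSpec(genome_length_mb=genome_mb)
    chroms = sorted(chromosome_lengths_mb)
    rows = []
    by_id = dict(tuple(segments.groupby("id", sort=False))) if len(segments) else {}
    empty = segments.iloc[0:0]
    for ind in individuals:
        sub = by_id.get(ind, empty)
        rec = {"id": ind, "f_roh": f_roh(sub, genome_mb)}
        for c in chroms:
            rec[f"f_roh_excl_{c}"] = f_roh_excluding(sub, c, chromosome_lengths_mb)
        fractions = classify_length_bins(sub, spec)
        for label, val in fractions.items():
            rec[f"frac_{label}"] = val
        rows.append(rec)
    return pd.DataFrame(rows)
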