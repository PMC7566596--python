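"""Hi-C structure summaries: TAD concordance, distance decay, within-TAD mass.

This module consumes already-normalized binned contact matrices and
already-called TAD partitions; it performs no matrix balancing or TAD
calling of its own.

Measure of Concordance (MoC).  For two partitions P = {p_1..p_N} and
Q = {q_1..q_M} of a chromosome into domains,

    MoC(P, Q) = 1                                   if N = M = 1
              = (1 / (sqrt(N*M) - 1)) *
                (sum_{i,j} |p_i ∩ q_j|^2 / (|p_i| * |q_j|) - 1)   otherwise

with lengths in bp.  MoC is symmetric, equals 1 iff the partitions agree,
and 0 when one side is a single domain spanning many domains of the other.
Partitions with MoC > 0.75 are conventionally called highly concordant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotations import GenomicInterval, read_bed

#: MoC above this value is conventionally called "highly concordant".
MOC_CONCORDANT_CUTOFF = 0.75


@dataclass
class TADPartition:
    """Per-chromosome ordered, non-overlapping domain lists (gaps allowed)."""

    domains: dict[str, list[GenomicInterval]]

    def __post_init__(self) -> None:
        for chrom, ivs in self.domains.items():
            ivs.sort(key=lambda iv: iv.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"{chrom}: overlapping TADs {a.start}-{a.end} and {b.start}-{b.end}"
                    )

    @classmethod
    def from_bed(cls, path: str | Path) -> "TADPartition":
        domains: dict[str, list[GenomicInterval]] = {}
        for iv in read_bed(path):
            domains.setdefault(iv.chrom, []).append(iv)
        return cls(domains)

    @classmethod
    def from_intervals(cls, intervals: Sequence[GenomicInterval]) -> "TADPartition":
        domains: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            domains.setdefault(iv.chrom, []).append(iv)
        return cls(domains)

    def n_domains(self, chrom: str) -> int:
        return len(self.domains.get(chrom, []))


@dataclass
class ContactMatrix:
    """A symmetric, non-negative binned contact matrix for one chromosome."""

    chrom: str
    resolution: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"contact matrix must be square, got {m.shape}")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if not np.allclose(m, m.T, rtol=1e-6, atol=1e-9):
            raise ValueError(f"{self.chrom}: contact matrix is not symmetric")
        if (m < 0).any():
            raise ValueError(f"{self.chrom}: negative contact frequencies")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def to_tsv(self, path: str | Path) -> None:
        """Write as sparse triplets (bin_i, bin_j, value), upper triangle."""
        iu, ju = np.triu_indices(self.n_bins)
        vals = self.matrix[iu, ju]
        keep = vals != 0
        pd.DataFrame({"bin_i": iu[keep], "bin_j": ju[keep], "value": vals[keep]}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, chrom: str, resolution: int, n_bins: int | None = None
    ) -> "ContactMatrix":
        df = pd.read_csv(path, sep="\t")
        n = n_bins or int(max(df["bin_i"].max(), df["bin_j"].max())) + 1
        m = np.zeros((n, n))
        m[df["bin_i"], df["bin_j"]] = df["value"]
        m[df["bin_j"], df["bin_i"]] = df["value"]
        return cls(chrom, resolution, m)


@dataclass
class MocResult:
    per_chrom: dict[str, float]
    genome_weighted: float
    genome_unweighted: float


def _moc_one(p: list[GenomicInterval], q: list[GenomicInterval]) -> float:
    n, m = len(p), len(q)
    if n == 0 or m == 0:
        raise ValueError("MoC undefined for an empty partition")
    if n == 1 and m == 1:
        return 1.0
    total = 0.0
    for pi in p:
        for qj in q:
            inter = min(pi.end, qj.end) - max(pi.start, qj.start)
            if inter > 0:
                total += inter * inter / (pi.length * qj.length)
    return (total - 1.0) / (np.sqrt(n * m) - 1.0)


def moc(p: TADPartition, q: TADPartition) -> MocResult:
    """Measure of Concordance between two TAD partitions.

    Computed per shared chromosome; the genome-wide summary is returned both
    as a length-weighted mean (weight = mean covered bp of the two
    partitions on that chromosome, so short chromosomes are not
    over-weighted) and as the unweighted mean.
    """
    chroms = sorted(set(p.domains) & set(q.domains))
    if not chroms:
        raise ValueError("partitions share no chromosome")
    per_chrom: dict[str, float] = {}
    weights: dict[str, float] = {}
    for chrom in chroms:
        per_chrom[chrom] = _moc_one(p.domains[chrom], q.domains[chrom])
        weights[chrom] = 0.5 * (
            sum(iv.length for iv in p.domains[chrom])
            + sum(iv.length for iv in q.domains[chrom])
        )
    vals = np.array([per_chrom[c] for c in chroms])
    w = np.array([weights[c] for c in chroms])
    return MocResult(per_chrom, float(np.average(vals, weights=w)), float(vals.mean()))


def distance_decay(
    matrices: ContactMatrix | Sequence[ContactMatrix],
    min_d: int = 40_000,
    max_d: int = 20_000_000,
) -> pd.DataFrame:
    """Mean interaction frequency as a function of genomic distance.

    For each distance d = k * resolution with min_d <= d <= max_d, the mean
    of all off-diagonal entries at offset k, pooled across the supplied
    chromosomes.  A max_d beyond the matrix extent is truncated with a
    warning.
    """
    if isinstance(matrices, ContactMatrix):
        matrices = [matrices]
    if not matrices:
        raise ValueError("no contact matrices supplied")
    res = matrices[0].resolution
    if any(m.resolution != res for m in matrices):
        raise ValueError("all matrices must share one resolution")
    if min_d % res != 0:
        raise ValueError(f"resolution {res} does not divide min_d {min_d}")
    max_extent = max(m.n_bins - 1 for m in matrices) * res
    if max_d > max_extent:
        warnings.warn(
            f"max_d {max_d} beyond matrix extent {max_extent}; truncating",
            stacklevel=2,
        )
        max_d = max_extent
    rows = []
    for k in range(max(1, min_d // res), max_d // res + 1):
        sums = 0.0
        count = 0
        for m in matrices:
            if k < m.n_bins:
                diag = np.diagonal(m.matrix, offset=k)
                sums += diag.sum()
                count += diag.size
        if count:
            rows.append({"distance": k * res, "frequency": sums / count})
    return pd.DataFrame(rows)


def decay_slope(curve: pd.DataFrame) -> float:
    """Log-log regression slope of a distance-decay curve."""
    keep = curve["frequency"] > 0
    return float(
        sps.linregress(
            np.log(curve.loc[keep, "distance"]), np.log(curve.loc[keep, "frequency"])
        ).slope
    )


def within_tad_fraction(
    matrix: ContactMatrix,
    tads: TADPartition,
    sample_total_pairs: float,
) -> pd.DataFrame:
    """Per-TAD fraction of the sample's reads falling inside that TAD.

    TAD boundaries are snapped to the nearest bin edge; for each TAD the
    entries whose bins both fall inside it are summed and divided by the
    sample's total uniquely mapped pairs.  TADs narrower than one bin are
    skipped with a warning.
    """
    if sample_total_pairs <= 0:
        raise ValueError("sample_total_pairs must be positive")
    res = matrix.resolution
    rows = []
    for tad in tads.domains.get(matrix.chrom, []):
        b0 = int(round(tad.start / res))
        b1 = int(round(tad.end / res))
        b0, b1 = max(b0, 0), min(b1, matrix.n_bins)
        if b1 - b0 < 1:
            warnings.warn(
                f"TAD {matrix.chrom}:{tad.start}-{tad.end} smaller than one bin; skipped",
                stacklevel=2,
            )
            continue
        block = matrix.matrix[b0:b1, b0:b1]
        rows.append(
            {
                "chrom": matrix.chrom,
                "start": tad.start,
                "end": tad.end,
                "bin_start": b0,
                "bin_end": b1,
                "fraction": float(block.sum()) / sample_total_pairs,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "bin_start", "bin_end", "fraction"]
    )
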