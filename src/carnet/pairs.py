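"""RNA-DNA read-pair handling.

An RNA-chromatin proximity-ligation read pair has an RNA end (read 1, the
chromatin-associated transcript) and a DNA end (read 2, the genomic locus it
was ligated to).  Pairs arrive as BEDPE: columns 1-3 are the RNA end, 4-6
the DNA end.  In memory a sample is a pandas DataFrame with columns
``rna_chrom, rna_start, rna_end, dna_chrom, dna_start, dna_end`` plus a
:class:`SampleStats` record of uniquely mapped totals.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .annotations import GenomicInterval, SuperEnhancer

PAIR_COLUMNS = ["rna_chrom", "rna_start", "rna_end", "dna_chrom", "dna_start", "dna_end"]


@dataclass(frozen=True)
class RnaDnaPair:
    rna: GenomicInterval
    dna: GenomicInterval


@dataclass
class SampleStats:
    """Uniquely-mapped pair tallies for one sample.

    ``skipped`` counts records dropped because an end was unmapped ('.'
    chromosome); those never enter any denominator.
    """

    sample_id: str
    total_pairs: int
    inter_pairs: int
    skipped: int = 0

    @property
    def intra_pairs(self) -> int:
        return self.total_pairs - self.inter_pairs

    def __post_init__(self) -> None:
        if self.total_pairs < 0 or self.inter_pairs < 0 or self.skipped < 0:
            raise ValueError("counts must be non-negative")
        if self.inter_pairs > self.total_pairs:
            raise ValueError("inter_pairs cannot exceed total_pairs")


@dataclass
class FeatureAssignment:
    """Per-feature pair counts for one designated end mode.

    ``counts`` maps feature id -> number of pairs whose designated end
    overlaps that feature (a pair overlapping k features increments k
    entries); ``n_in_features`` counts each pair at most once.
    """

    end_mode: str
    counts: dict[str, int]
    n_in_features: int
    total_pairs: int


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def scan_bedpe(path: str | Path, chunksize: int = 500_000) -> Iterator[pd.DataFrame]:
    """Stream a BEDPE file as DataFrame chunks (constant memory).

    Records with a '.' chromosome on either end are dropped; each yielded
    chunk carries the number it dropped in ``chunk.attrs['skipped']``.
    """
    with _open_text(path) as fh:
        reader = pd.read_csv(
            fh,
            sep="\t",
            header=None,
            comment="#",
            chunksize=chunksize,
            dtype={0: str, 3: str},
        )
        for chunk in reader:
            if chunk.shape[1] < 6:
                raise ValueError(f"{path}: BEDPE requires >= 6 columns")
            chunk = chunk.iloc[:, :6].copy()
            chunk.columns = PAIR_COLUMNS
            mapped = (chunk["rna_chrom"] != ".") & (chunk["dna_chrom"] != ".")
            skipped = int((~mapped).sum())
            chunk = chunk.loc[mapped]
            try:
                for col in ("rna_start", "rna_end", "dna_start", "dna_end"):
                    chunk[col] = chunk[col].astype(np.int64)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed BEDPE coordinates") from exc
            if ((chunk["rna_start"] >= chunk["rna_end"])
                    | (chunk["dna_start"] >= chunk["dna_end"])).any():
                raise ValueError(f"{path}: BEDPE record with start >= end")
            chunk = chunk.reset_index(drop=True)
            chunk.attrs["skipped"] = skipped
            yield chunk


def read_bedpe(
    path: str | Path, sample_id: str | None = None
) -> tuple[pd.DataFrame, SampleStats]:
    """Read a whole BEDPE file and compute its :class:`SampleStats`."""
    chunks, skipped = [], 0
    for chunk in scan_bedpe(path):
        skipped += chunk.attrs["skipped"]
        chunks.append(chunk)
    if chunks:
        pairs = pd.concat(chunks, ignore_index=True)
    else:
        pairs = pd.DataFrame(columns=PAIR_COLUMNS)
    stats = compute_stats(pairs, sample_id=sample_id or str(path), skipped=skipped)
    return pairs, stats


def bedpe_stats(path: str | Path, sample_id: str | None = None) -> SampleStats:
    """Compute :class:`SampleStats` by streaming; memory constant in records."""
    total = inter = skipped = 0
    for chunk in scan_bedpe(path):
        skipped += chunk.attrs["skipped"]
        total += len(chunk)
        inter += int((chunk["rna_chrom"] != chunk["dna_chrom"]).sum())
    return SampleStats(sample_id or str(path), total, inter, skipped)


def compute_stats(
    pairs: pd.DataFrame, sample_id: str = "sample", skipped: int = 0
) -> SampleStats:
    inter = int((pairs["rna_chrom"] != pairs["dna_chrom"]).sum()) if len(pairs) else 0
    return SampleStats(sample_id, len(pairs), inter, skipped)


def write_bedpe(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", header=False, index=False, columns=PAIR_COLUMNS)


def interchromosomal_fraction(stats: SampleStats) -> float:
    """Fraction of uniquely mapped pairs whose two ends lie on different chromosomes."""
    if stats.total_pairs == 0:
        raise ValueError("interchromosomal fraction undefined for an empty sample")
    return stats.inter_pairs / stats.total_pairs


class FeatureIndex:
    """Overlap queries of query intervals against a fixed feature set.

    Features are grouped per chromosome; queries are resolved by chunked
    numpy broadcasting, which enumerates every (query, feature) overlap and
    therefore handles overlapping features and multi-feature hits exactly.
    Overlap is >= 1 bp intersection of half-open intervals.
    """

    def __init__(self, features: Sequence[SuperEnhancer | GenomicInterval]):
        self.ids: list[str] = []
        intervals: list[GenomicInterval] = []
        for i, f in enumerate(features):
            if isinstance(f, SuperEnhancer):
                self.ids.append(f.se_id)
                intervals.append(f.interval)
            else:
                self.ids.append(f.name if f.name is not None else f"feature_{i}")
                intervals.append(f)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in {iv.chrom for iv in intervals}:
            idx = np.array([i for i, iv in enumerate(intervals) if iv.chrom == chrom])
            starts = np.array([intervals[i].start for i in idx], dtype=np.int64)
            ends = np.array([intervals[i].end for i in idx], dtype=np.int64)
            self._by_chrom[chrom] = (starts, ends, idx)

    def __len__(self) -> int:
        return len(self.ids)

    def overlap_pairs(
        self,
        chroms: np.ndarray,
        starts: np.ndarray,
        ends: np.ndarray,
        chunk: int = 65_536,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Return (query_row_indices, feature_indices) of every overlap."""
        chroms = np.asarray(chroms)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        out_rows: list[np.ndarray] = []
        out_feats: list[np.ndarray] = []
        for chrom, (fs, fe, fidx) in self._by_chrom.items():
            rows = np.flatnonzero(chroms == chrom)
            for lo in range(0, rows.size, chunk):
                sub = rows[lo:lo + chunk]
                hit = (starts[sub][:, None] < fe[None, :]) & (
                    fs[None, :] < ends[sub][:, None]
                )
                qi, fi = np.nonzero(hit)
                out_rows.append(sub[qi])
                out_feats.append(fidx[fi])
        if not out_rows:
            empty = np.array([], dtype=np.int64)
            return empty, empty.copy()
        return np.concatenate(out_rows), np.concatenate(out_feats)


def _end_arrays(pairs: pd.DataFrame, which: str):
    return (
        pairs[f"{which}_chrom"].to_numpy(),
        pairs[f"{which}_start"].to_numpy(),
        pairs[f"{which}_end"].to_numpy(),
    )


def assign_end_to_features(
    pairs: pd.DataFrame,
    features: Sequence[SuperEnhancer | GenomicInterval] | FeatureIndex,
    end_mode: str = "rna",
) -> FeatureAssignment:
    """Count pairs whose designated end overlaps each feature.

    ``end_mode`` is 'rna', 'dna', or 'either'; with 'either' a pair counts
    once in ``n_in_features`` if any end hits any feature, while per-feature
    counts still count each pair at most once per feature.
    """
    if end_mode not in ("rna", "dna", "either"):
        raise ValueError(f"end_mode must be rna, dna or either, got {end_mode!r}")
    index = features if isinstance(features, FeatureIndex) else FeatureIndex(features)
    counts = dict.fromkeys(index.ids, 0)
    if len(index) == 0 or len(pairs) == 0:
        return FeatureAssignment(end_mode, counts, 0, len(pairs))

    ends = ("rna", "dna") if end_mode == "either" else (end_mode,)
    hit_rows = []
    seen: dict[int, set[int]] = {}
    for which in ends:
        rows, feats = index.overlap_pairs(*_end_arrays(pairs, which))
        hit_rows.append(rows)
        for r, f in zip(rows.tolist(), feats.tolist()):
            seen.setdefault(f, set()).add(r)
    for f, rowset in seen.items():
        counts[index.ids[f]] = len(rowset)
    n_in = int(np.unique(np.concatenate(hit_rows)).size) if hit_rows else 0
    return FeatureAssignment(end_mode, counts, n_in, len(pairs))


def subsample_pairs(pairs: pd.DataFrame, n: int, seed: int | np.random.Generator) -> pd.DataFrame:
    """Uniform sample of n pairs without replacement, reproducible by seed."""
    if n > len(pairs):
        raise ValueError(f"cannot sample {n} pairs from {len(pairs)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(pairs), size=n, replace=False))
    return pairs.iloc[idx].reset_index(drop=True)
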