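"""Super-enhancer interaction networks from RNA-DNA read pairs.

Per sample, read-pair contacts between every unordered pair of SEs are
counted and normalized by the sample's total uniquely mapped pairs, making
tables comparable across sequencing depths.  A pair of SEs is "interacting"
when its normalized count exceeds a reference threshold, conventionally the
95th percentile of the baseline (Day 0) sample's nonzero normalized counts.
Hubs are nodes whose degree reaches the 95th percentile of the degree
distribution; the degree distribution of these networks is heavy-tailed and
is summarized by a discrete maximum-likelihood power-law fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps

from .annotations import SuperEnhancer
from .pairs import FeatureIndex, _end_arrays


@dataclass
class SEContactTable:
    """Unordered SE-pair raw contact counts for one sample.

    Keys are (se_i, se_j) with se_i < se_j lexicographically; zeros are
    implicit.  ``total_pairs`` is the sample's uniquely mapped pair count,
    the normalization denominator.
    """

    sample_id: str
    counts: dict[tuple[str, str], int]
    total_pairs: int

    def norm_counts(self) -> dict[tuple[str, str], float]:
        if self.total_pairs <= 0:
            raise ValueError("total_pairs must be positive to normalize")
        return {k: v / self.total_pairs for k, v in self.counts.items()}


@dataclass
class HubSet:
    """SEs meeting the hub degree criterion, with the resolved cutoff."""

    degrees: dict[str, int]
    percentile: float
    resolved_min_degree: float

    @property
    def ids(self) -> set[str]:
        return set(self.degrees)

    def __len__(self) -> int:
        return len(self.degrees)


@dataclass
class PowerLawFit:
    """Discrete power-law fit p(x) ~ x^-alpha for x >= xmin."""

    alpha: float
    xmin: int
    ks_distance: float
    n_tail: int
    ccdf_slope: float
    plausible: bool


def count_se_pair_contacts(
    pairs: pd.DataFrame,
    ses: Sequence[SuperEnhancer] | FeatureIndex,
    total_pairs: int | None = None,
    sample_id: str = "sample",
) -> SEContactTable:
    """Count read pairs linking each unordered pair of distinct SEs.

    A pair contributes to {i, j} iff its RNA end overlaps SE i and its DNA
    end overlaps SE j (>= 1 bp each); direction is collapsed into the
    unordered key.  An end overlapping several SEs contributes to every
    qualifying combination; pairs with both ends in the same SE are dropped
    (self-transcription, not interaction).
    """
    index = ses if isinstance(ses, FeatureIndex) else FeatureIndex(ses)
    counts: dict[tuple[str, str], int] = {}
    if len(pairs) and len(index):
        r_rows, r_feats = index.overlap_pairs(*_end_arrays(pairs, "rna"))
        d_rows, d_feats = index.overlap_pairs(*_end_arrays(pairs, "dna"))
        rna = pd.DataFrame({"row": r_rows, "se_rna": r_feats})
        dna = pd.DataFrame({"row": d_rows, "se_dna": d_feats})
        hits = rna.merge(dna, on="row")
        hits = hits[hits["se_rna"] != hits["se_dna"]]
        if len(hits):
            lo = np.minimum(hits["se_rna"], hits["se_dna"])
            hi = np.maximum(hits["se_rna"], hits["se_dna"])
            grouped = pd.DataFrame({"lo": lo, "hi": hi}).value_counts()
            ids = index.ids
            for (i, j), c in grouped.items():
                counts[tuple(sorted((ids[i], ids[j])))] = int(c)
    return SEContactTable(
        sample_id=sample_id,
        counts=counts,
        total_pairs=len(pairs) if total_pairs is None else total_pairs,
    )


def se_end_totals(
    pairs: pd.DataFrame, ses: Sequence[SuperEnhancer] | FeatureIndex
) -> pd.DataFrame:
    """Per-SE counts of pairs hitting it with the RNA end vs the DNA end.

    Supports the directional view (SEs are more often the transcript source
    than the target) that the unordered network discards.
    """
    from .pairs import assign_end_to_features

    index = ses if isinstance(ses, FeatureIndex) else FeatureIndex(ses)
    rna = assign_end_to_features(pairs, index, end_mode="rna")
    dna = assign_end_to_features(pairs, index, end_mode="dna")
    return pd.DataFrame(
        {
            "se_id": list(index.ids),
            "rna_end_count": [rna.counts[i] for i in index.ids],
            "dna_end_count": [dna.counts[i] for i in index.ids],
        }
    )


def interaction_threshold(table: SEContactTable, percentile: float = 95.0) -> float:
    """Percentile (linear interpolation) of the nonzero normalized counts.

    Computed over SE pairs with at least one supporting read: the candidate
    universe of all possible SE pairs is overwhelmingly zeros, and a
    percentile over it would degenerate to 0.
    """
    values = np.array(list(table.norm_counts().values()))
    if values.size == 0:
        raise ValueError("cannot take a percentile of an empty contact table")
    return float(np.percentile(values, percentile))


def call_interactions(
    table: SEContactTable,
    threshold: float,
    ses: Sequence[SuperEnhancer] | None = None,
) -> nx.Graph:
    """Build the interaction network: edges strictly above the threshold.

    All SEs (when given) are retained as nodes so isolated SEs stay visible;
    nodes carry their chromosome, edges carry raw/normalized counts and an
    interchromosomal flag.
    """
    g = nx.Graph(threshold_used=threshold, sample_id=table.sample_id)
    chrom_of: dict[str, str] = {}
    if ses is not None:
        for se in ses:
            chrom_of[se.se_id] = se.interval.chrom
            g.add_node(se.se_id, chrom=se.interval.chrom)
    norm = table.norm_counts()
    for (i, j), nc in norm.items():
        if nc > threshold:
            inter = (
                chrom_of.get(i) != chrom_of.get(j)
                if (i in chrom_of and j in chrom_of)
                else None
            )
            g.add_edge(i, j, raw=table.counts[(i, j)], norm=nc, inter=inter)
    return g


def split_edges_by_chromosome(g: nx.Graph) -> tuple[list, list]:
    """Partition edges into (interchromosomal, intrachromosomal) lists."""
    inter, intra = [], []
    for u, v, data in g.edges(data=True):
        flag = data.get("inter")
        if flag is None:
            cu, cv = g.nodes[u].get("chrom"), g.nodes[v].get("chrom")
            if cu is None or cv is None:
                raise ValueError(f"edge ({u}, {v}) has no chromosome information")
            flag = cu != cv
        (inter if flag else intra).append((u, v))
    return inter, intra


def identify_hubs(
    g: nx.Graph,
    percentile: float = 95.0,
    min_degree_override: int | None = None,
) -> HubSet:
    """Hubs: nodes whose degree >= the degree-distribution percentile.

    The percentile is taken over nodes with degree >= 1 (isolated nodes are
    bookkeeping, not network participants).  ``min_degree_override`` pins
    the cutoff to an absolute degree instead.
    """
    degrees = {n: d for n, d in g.degree() if d >= 1}
    if not degrees:
        return HubSet({}, percentile, math.inf if min_degree_override is None
                      else min_degree_override)
    if min_degree_override is not None:
        cutoff = float(min_degree_override)
    else:
        cutoff = float(np.percentile(np.array(list(degrees.values())), percentile))
    hubs = {n: d for n, d in degrees.items() if d >= cutoff}
    return HubSet(hubs, percentile, cutoff)


def hub_continuity(hubsets: Sequence[HubSet]) -> tuple[bool, list[tuple[int, set[str]]]]:
    """Check that each time point's hub set is contained in the next.

    Returns (ok, violations) where violations lists, per transition index,
    the hubs of time point t missing at t+1.
    """
    violations: list[tuple[int, set[str]]] = []
    for t in range(len(hubsets) - 1):
        lost = hubsets[t].ids - hubsets[t + 1].ids
        if lost:
            violations.append((t, lost))
    return (not violations), violations


def network_edge_table(g: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (se_i, se_j, raw, norm, inter)."""
    rows = [
        {"se_i": u, "se_j": v, "raw": d.get("raw"), "norm": d.get("norm"),
         "inter": d.get("inter")}
        for u, v, d in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["se_i", "se_j", "raw", "norm", "inter"])


# --- discrete power-law fit -------------------------------------------------

def _discrete_alpha_mle(x: np.ndarray, xmin: int) -> float:
    """MLE of alpha for P(X=k) = k^-alpha / zeta(alpha, xmin), k >= xmin."""
    logsum = np.log(x).sum()
    n = x.size

    def nll(alpha: float) -> float:
        return n * math.log(special.zeta(alpha, xmin)) + alpha * logsum

    res = optimize.minimize_scalar(nll, bounds=(1.01, 10.0), method="bounded")
    return float(res.x)


def _ks_distance(x: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.sort(x)
    n = xs.size
    z_min = special.zeta(alpha, xmin)
    uniq, counts = np.unique(xs, return_counts=True)
    ecdf = np.cumsum(counts) / n
    # theoretical CDF at each observed value: 1 - zeta(alpha, k+1)/zeta(alpha, xmin)
    tcdf = 1.0 - special.zeta(alpha, uniq + 1) / z_min
    return float(np.abs(ecdf - tcdf).max())


def fit_power_law(
    network_or_degrees: nx.Graph | Iterable[int],
    xmin: int | None = None,
    max_xmin_candidates: int = 50,
) -> PowerLawFit:
    """Fit a discrete power law to the (nonzero) degree distribution.

    The exponent is estimated by maximum likelihood under the Hurwitz-zeta
    normalized discrete power law; xmin, unless given, is chosen among the
    observed degree values to minimize the KS distance between the tail
    empirical CDF and the fitted model.  A log-log CCDF regression slope is
    reported as a secondary diagnostic (CCDF slope ~ -(alpha - 1)).  The fit
    is flagged implausible when the KS distance is large or the tail is
    degenerate.
    """
    if isinstance(network_or_degrees, nx.Graph):
        degrees = np.array([d for _, d in network_or_degrees.degree() if d >= 1])
    else:
        degrees = np.asarray(list(network_or_degrees), dtype=np.int64)
        degrees = degrees[degrees >= 1]
    if degrees.size < 10:
        raise ValueError(f"need >= 10 nonzero degrees, got {degrees.size}")

    if np.unique(degrees).size == 1:
        # Constant degrees: no scale-free tail; report a degenerate fit.
        return PowerLawFit(
            alpha=math.inf, xmin=int(degrees[0]), ks_distance=1.0,
            n_tail=int(degrees.size), ccdf_slope=0.0, plausible=False,
        )

    if xmin is not None:
        candidates = [int(xmin)]
    else:
        uniq = np.unique(degrees)
        # keep at least 10 tail points per candidate
        uniq = uniq[uniq <= np.sort(degrees)[-10]]
        if uniq.size > max_xmin_candidates:
            uniq = uniq[np.linspace(0, uniq.size - 1, max_xmin_candidates).astype(int)]
        candidates = [int(v) for v in uniq]

    best: tuple[float, float, int, int] | None = None  # (ks, alpha, xmin, n_tail)
    for xm in candidates:
        tail = degrees[degrees >= xm]
        if tail.size < 10 or np.unique(tail).size < 2:
            continue
        alpha = _discrete_alpha_mle(tail, xm)
        ks = _ks_distance(tail, alpha, xm)
        if best is None or ks < best[0]:
            best = (ks, alpha, xm, tail.size)
    if best is None:
        raise ValueError("no viable xmin candidate with a >= 10-point tail")
    ks, alpha, xm, n_tail = best

    tail = degrees[degrees >= xm]
    uniq = np.unique(tail)
    ccdf = np.array([(tail >= u).mean() for u in uniq])
    slope = float(sps.linregress(np.log(uniq), np.log(ccdf)).slope)

    return PowerLawFit(
        alpha=alpha, xmin=xm, ks_distance=ks, n_tail=n_tail,
        ccdf_slope=slope, plausible=bool(ks < 0.1),
    )
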