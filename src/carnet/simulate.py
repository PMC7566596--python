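"""Synthetic data generators for every input the pipeline consumes.

The generators emulate the statistical structure the analysis assumes, at
desk scale, so every stage runs without external downloads:

* annotations — non-overlapping genes, SEs either embedded in genes or
  intergenic, on a small multi-chromosome genome;
* RNA-DNA read pairs — RNA-end density uniform except multiplied by the
  enrichment factor E inside SEs; DNA end on the same chromosome with
  probability 1 - p_inter, else a uniformly chosen other chromosome;
  designated hub SEs receive a target-mass multiplier on the DNA end;
* single-cell counts — anchor/partner positivity generated at the
  Bernoulli level so the treated-vs-control contingency odds ratio equals
  its target exactly in expectation;
* contact matrices — power-law distance decay with optional block-diagonal
  TAD boost and optional Poisson sampling noise.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .annotations import GeneModel, GenomicInterval, SuperEnhancer, classify_se
from .pairs import PAIR_COLUMNS
from .structure import ContactMatrix, TADPartition


@dataclass
class CoexprSimConfig:
    """Per-condition co-expression generator settings.

    Among anchor-positive cells the control partner-detection rate is
    ``partner_base_rate`` r; the treated rate is set to w*r / (1 - r + w*r)
    per partner so the anchor-conditioned contingency OR is w exactly in
    expectation.
    """

    n_cells_treated: int = 20_000
    n_cells_control: int = 20_000
    anchor_rate_treated: float = 0.5
    anchor_rate_control: float = 0.5
    partner_base_rate: float = 0.1
    partner_or: dict[str, float] = field(default_factory=lambda: {"PARTNER": 40.0})
    n_background_genes: int = 20
    background_rate: float = 0.1
    count_lambda: float = 1.0


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic experiment.

    The default interchromosomal fraction (0.344) and SE RNA enrichment
    (giving read-proportion enrichment on the order of the real assay) match
    the baseline condition; time-course drivers override p_inter and
    hub_spec per time point.
    """

    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("chr1", 30_000_000),
            ("chr2", 25_000_000),
            ("chr3", 20_000_000),
            ("chr4", 15_000_000),
        ]
    )
    n_genes: int = 200
    n_ses: int = 60
    embed_fraction: float = 0.6
    gene_length: int = 50_000
    se_length: int = 20_000
    n_pairs: int = 100_000
    p_inter: float = 0.344
    se_rna_enrichment: float = 9.0
    hub_spec: dict[str, float] = field(default_factory=dict)
    read_span: int = 50
    coexpr: CoexprSimConfig = field(default_factory=CoexprSimConfig)
    decay_exponent: float = 1.0
    tad_boost: float = 0.0
    hic_resolution: int = 40_000
    tad_blocks: dict[str, list[int]] = field(
        default_factory=lambda: {"chr1": [4_000_000, 6_000_000, 3_000_000,
                                          5_000_000, 7_000_000, 5_000_000]}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_inter <= 1 or not 0 <= self.embed_fraction <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.se_rna_enrichment < 1:
            raise ValueError("se_rna_enrichment must be >= 1")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if self.se_length >= self.gene_length:
            raise ValueError("se_length must be smaller than gene_length")


@dataclass
class Annotations:
    genome: list[tuple[str, int]]
    genes: list[GeneModel]
    ses: list[SuperEnhancer]


class _SegmentSet:
    """Uniform bp sampling over a set of genomic segments."""

    def __init__(self, segments: Sequence[tuple[str, int, int]]):
        self.segments = [s for s in segments if s[2] > s[1]]
        lengths = np.array([e - s for _, s, e in self.segments], dtype=np.int64)
        self.cum = np.concatenate([[0], np.cumsum(lengths)])
        self.total = int(self.cum[-1])

    def sample(self, n: int, rng: np.random.Generator):
        if self.total == 0:
            raise ValueError("cannot sample from an empty segment set")
        offsets = rng.integers(0, self.total, size=n)
        seg_idx = np.searchsorted(self.cum, offsets, side="right") - 1
        within = offsets - self.cum[seg_idx]
        chroms = np.array([self.segments[i][0] for i in seg_idx])
        pos = np.array([self.segments[i][1] for i in seg_idx]) + within
        return chroms, pos


def _complement(
    chrom: str, length: int, intervals: Sequence[GenomicInterval]
) -> list[tuple[str, int, int]]:
    segs = []
    cursor = 0
    for iv in sorted((iv for iv in intervals if iv.chrom == chrom), key=lambda v: v.start):
        if iv.start > cursor:
            segs.append((chrom, cursor, iv.start))
        cursor = max(cursor, iv.end)
    if cursor < length:
        segs.append((chrom, cursor, length))
    return segs


def make_annotations(config: SimConfig) -> Annotations:
    """Generate genes and SEs; deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    glen, selen = config.gene_length, config.se_length

    # allocate genes to chromosomes proportional to length
    lengths = np.array([length for _, length in config.genome], dtype=float)
    alloc = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    while alloc.sum() < config.n_genes:
        alloc[int(np.argmax(lengths / (alloc + 1)))] += 1

    genes: list[GeneModel] = []
    gid = 0
    for (chrom, length), k in zip(config.genome, alloc):
        if k * glen > length:
            raise ValueError(f"{chrom}: {k} genes of {glen} bp exceed chromosome capacity")
        raw = np.sort(rng.integers(0, length - k * glen + 1, size=k))
        starts = raw + np.arange(k) * glen
        for s in starts:
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"G{gid:04d}", GenomicInterval(chrom, int(s), int(s) + glen), strand)
            )

    n_embed = int(round(config.embed_fraction * config.n_ses))
    if n_embed > len(genes):
        raise ValueError("more embedded SEs requested than genes available")
    ses: list[SuperEnhancer] = []
    host_idx = rng.choice(len(genes), size=n_embed, replace=False)
    for i, hi in enumerate(host_idx, start=1):
        g = genes[hi].interval
        offset = int(rng.integers(0, g.length - selen + 1))
        iv = GenomicInterval(g.chrom, g.start + offset, g.start + offset + selen)
        ses.append(SuperEnhancer(f"SE{i:03d}", iv))

    # intergenic SEs: rejection-sample from the gene complement
    gene_complement = _SegmentSet(
        [seg for chrom, length in config.genome
         for seg in _complement(chrom, length, [g.interval for g in genes])]
    )
    placed = [se.interval for se in ses]
    i = n_embed
    attempts = 0
    while i < config.n_ses:
        attempts += 1
        if attempts > 200 * config.n_ses:
            raise ValueError("could not place intergenic SEs; genome too crowded")
        chroms, pos = gene_complement.sample(1, rng)
        chrom, start = str(chroms[0]), int(pos[0])
        cand = GenomicInterval(chrom, start, start + selen)
        chrom_len = dict(config.genome)[chrom]
        if cand.end > chrom_len:
            continue
        if any(cand.overlaps(g.interval) for g in genes):
            continue  # keep these strictly intergenic
        if any(cand.overlaps(p) for p in placed):
            continue
        i += 1
        ses.append(SuperEnhancer(f"SE{i:03d}", cand))
        placed.append(cand)

    for se in ses:
        classify_se(se, genes)
    return Annotations(list(config.genome), genes, ses)


def write_annotations(ann: Annotations, outdir: str | Path) -> dict[str, Path]:
    """Write genome table (TSV), SE BED and gene GTF; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.tsv",
        "ses": outdir / "ses.bed",
        "genes": outdir / "genes.gtf",
    }
    with open(paths["genome"], "w") as fh:
        for chrom, length in ann.genome:
            fh.write(f"{chrom}\t{length}\n")
    with open(paths["ses"], "w") as fh:
        for se in ann.ses:
            iv = se.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{se.se_id}\n")
    with open(paths["genes"], "w") as fh:
        for g in ann.genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tcarnet_sim\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
            )
    return paths


def simulate_read_pairs(
    config: SimConfig,
    ann: Annotations,
    n_pairs: int | None = None,
    p_inter: float | None = None,
    hub_spec: dict[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate RNA-DNA read pairs (see module docstring for the model).

    ``n_pairs``, ``p_inter``, ``hub_spec`` and ``seed`` override the config,
    which lets a time-course driver vary conditions against one annotation
    set.
    """
    n = config.n_pairs if n_pairs is None else n_pairs
    pi = config.p_inter if p_inter is None else p_inter
    hubs = config.hub_spec if hub_spec is None else hub_spec
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    span = config.read_span
    e_factor = config.se_rna_enrichment
    chrom_len = dict(ann.genome)
    chrom_names = [c for c, _ in ann.genome]

    se_ivs = [se.interval for se in ann.ses]
    se_set = _SegmentSet([(iv.chrom, iv.start, iv.end) for iv in se_ivs])
    non_se_set = _SegmentSet(
        [seg for chrom, length in ann.genome for seg in _complement(chrom, length, se_ivs)]
    )

    # RNA end: global mixture weighted E on SE bp
    w_se = e_factor * se_set.total
    p_in_se = w_se / (w_se + non_se_set.total)
    in_se = rng.random(n) < p_in_se
    rna_chrom = np.empty(n, dtype=object)
    rna_pos = np.empty(n, dtype=np.int64)
    if in_se.any():
        c, p = se_set.sample(int(in_se.sum()), rng)
        rna_chrom[in_se], rna_pos[in_se] = c, p
    if (~in_se).any():
        c, p = non_se_set.sample(int((~in_se).sum()), rng)
        rna_chrom[~in_se], rna_pos[~in_se] = c, p

    # DNA chromosome: same as RNA with prob 1 - p_inter, else a uniform other
    inter = rng.random(n) < pi
    dna_chrom = rna_chrom.copy()
    if inter.any():
        rows = np.flatnonzero(inter)
        name_to_i = {c: i for i, c in enumerate(chrom_names)}
        own = np.array([name_to_i[c] for c in rna_chrom[rows]])
        pick = rng.integers(0, len(chrom_names) - 1, size=rows.size)
        pick = np.where(pick >= own, pick + 1, pick)
        dna_chrom[rows] = np.array(chrom_names, dtype=object)[pick]

    # DNA position: per chromosome, hub SEs carry multiplied mass
    hub_ses = [se for se in ann.ses if se.se_id in hubs]
    dna_pos = np.empty(n, dtype=np.int64)
    for chrom in chrom_names:
        rows = np.flatnonzero(dna_chrom == chrom)
        if rows.size == 0:
            continue
        chrom_hubs = [se for se in hub_ses if se.interval.chrom == chrom]
        hub_ivs = [se.interval for se in chrom_hubs]
        comp = _SegmentSet(_complement(chrom, chrom_len[chrom], hub_ivs))
        weights = [comp.total] + [
            hubs[se.se_id] * se.interval.length for se in chrom_hubs
        ]
        cumw = np.cumsum(weights)
        cat = np.searchsorted(cumw, rng.random(rows.size) * cumw[-1], side="right")
        free = rows[cat == 0]
        if free.size:
            _, p = comp.sample(free.size, rng)
            dna_pos[free] = p
        for k, se in enumerate(chrom_hubs, start=1):
            sel = rows[cat == k]
            if sel.size:
                dna_pos[sel] = rng.integers(
                    se.interval.start, se.interval.end, size=sel.size
                )

    def _clip(chroms, pos):
        lens = np.array([chrom_len[c] for c in chroms])
        start = np.minimum(pos, lens - span)
        return start, start + span

    rs, re = _clip(rna_chrom, rna_pos)
    ds, de = _clip(dna_chrom, dna_pos)
    return pd.DataFrame(
        dict(zip(PAIR_COLUMNS, [rna_chrom, rs, re, dna_chrom, ds, de]))
    )


def expected_rna_in_se_fraction(config: SimConfig, ann: Annotations) -> float:
    """Closed-form expected fraction of RNA ends starting inside an SE."""
    se_total = sum(se.interval.length for se in ann.ses)
    genome_total = sum(length for _, length in ann.genome)
    e = config.se_rna_enrichment
    w_se = e * se_total
    return w_se / (w_se + (genome_total - se_total))


def simulate_cell_counts(
    config: SimConfig, seed: int | None = None
) -> tuple[ad.AnnData, ad.AnnData]:
    """Simulate treated and control raw UMI matrices (AnnData, cells x genes)."""
    cx = config.coexpr
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    r = cx.partner_base_rate
    if not 0 < r < 1:
        raise ValueError("partner_base_rate must be in (0, 1)")
    treated_rates = {}
    for gene, omega in cx.partner_or.items():
        if omega <= 0:
            raise ValueError(f"target OR for {gene} must be > 0")
        pt = omega * r / (1 - r + omega * r)
        if not 0 < pt < 1:
            raise ValueError(
                f"target OR {omega} for {gene} pushes the treated rate outside (0,1)"
            )
        treated_rates[gene] = pt

    genes = ["ANCHOR"] + list(cx.partner_or) + [
        f"BG{i + 1:03d}" for i in range(cx.n_background_genes)
    ] + ["MT-SIM1"]

    def one_condition(n_cells: int, anchor_rate: float, treated: bool, label: str) -> ad.AnnData:
        x = np.zeros((n_cells, len(genes)), dtype=np.int64)
        col = {g: j for j, g in enumerate(genes)}
        anchor_pos = rng.random(n_cells) < anchor_rate
        x[anchor_pos, col["ANCHOR"]] = 1 + rng.poisson(cx.count_lambda, int(anchor_pos.sum()))
        for gene in cx.partner_or:
            rate = treated_rates[gene] if treated else r
            pos = np.where(anchor_pos, rng.random(n_cells) < rate,
                           rng.random(n_cells) < r)
            x[pos, col[gene]] = 1 + rng.poisson(cx.count_lambda, int(pos.sum()))
        for i in range(cx.n_background_genes):
            pos = rng.random(n_cells) < cx.background_rate
            x[pos, col[f"BG{i + 1:03d}"]] = 1 + rng.poisson(cx.count_lambda, int(pos.sum()))
        x[:, col["MT-SIM1"]] = rng.poisson(0.2, n_cells)
        adata = ad.AnnData(X=x)
        adata.var_names = genes
        adata.obs_names = [f"{label}_cell{i}" for i in range(n_cells)]
        adata.obs["condition"] = label
        return adata

    treated = one_condition(cx.n_cells_treated, cx.anchor_rate_treated, True, "treated")
    control = one_condition(cx.n_cells_control, cx.anchor_rate_control, False, "control")
    return treated, control


def simulate_contact_matrix(
    config: SimConfig,
    chrom: str,
    noise: bool = False,
    noise_depth: float = 50.0,
    seed: int | None = None,
) -> tuple[ContactMatrix, TADPartition]:
    """Simulate a normalized binned contact matrix plus its true TADs.

    entry(i, j) = (|i - j|)^(-beta) * (1 + tau * inTAD(i, j)) with beta the
    decay exponent and tau the within-TAD boost; the diagonal is set to the
    1-bin value (it never enters decay curves, which start at one bin).
    With ``noise`` the matrix is Poisson-resampled at the given mean depth
    and rescaled, preserving expectation.
    """
    chrom_len = dict(config.genome).get(chrom)
    if chrom_len is None:
        raise KeyError(f"{chrom} not in the simulated genome")
    res = config.hic_resolution
    n_bins = chrom_len // res
    beta, tau = config.decay_exponent, config.tad_boost

    blocks = config.tad_blocks.get(chrom, [])
    if sum(blocks) > chrom_len:
        raise ValueError(f"{chrom}: TAD blocks exceed chromosome length")
    tad_ivs = []
    cursor = 0
    for b in blocks:
        tad_ivs.append(GenomicInterval(chrom, cursor, cursor + b))
        cursor += b
    tads = TADPartition({chrom: tad_ivs} if tad_ivs else {chrom: []})

    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :]).astype(float)
    dist[dist == 0] = 1.0
    m = dist ** (-beta)

    in_tad = np.zeros((n_bins, n_bins), dtype=bool)
    for iv in tad_ivs:
        b0, b1 = int(round(iv.start / res)), min(int(round(iv.end / res)), n_bins)
        in_tad[b0:b1, b0:b1] = True
    m = m * (1.0 + tau * in_tad)

    if noise:
        rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
        iu, ju = np.triu_indices(n_bins)
        sampled = rng.poisson(m[iu, ju] * noise_depth) / noise_depth
        m = np.zeros_like(m)
        m[iu, ju] = sampled
        m[ju, iu] = sampled
    return ContactMatrix(chrom, res, m), tads
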