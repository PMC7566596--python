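"""Single-cell co-expression contingency analysis.

Given raw UMI count matrices (AnnData, cells x genes) from a treated and a
control condition, the question is whether an anchor gene (a candidate
regulatory lncRNA) and a partner gene are detected in the *same* single
cells more often under treatment.  Restricting to anchor-positive cells,
the 2x2 table

                 partner+   partner-
    treated         a          b
    control         c          d

yields OR = (a*d)/(b*c), tested by a df=1 chi-square.  "Expressing" means
raw UMI count > 0 — detection, not a normalized threshold.

The partner screen repeats the test for every gene embedded in the super
enhancers that interact with the anchor's SE in the interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annotations import GeneModel, SuperEnhancer
from .enrichment import ContingencyResult, contingency_chisq


@dataclass
class QCParams:
    """Cell quality-control thresholds.

    gene_count_upper_percentile: per-sample upper percentile on detected
        genes per cell (doublet guard); 99 for cultured cells, 98 for
        tissue-derived samples in the reference workflow.
    mito_upper: mitochondrial threshold — interpreted as an absolute
        fraction when <= 1 (e.g. 0.20), as a per-sample percentile when > 1
        (e.g. 99).
    min_genes: minimum detected genes per cell (empty-droplet guard).
    mito_prefix: gene-name prefix identifying mitochondrial genes.
    """

    gene_count_upper_percentile: float = 99.0
    mito_upper: float = 0.20
    min_genes: int = 300
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if not 0 < self.gene_count_upper_percentile <= 100:
            raise ValueError("gene_count_upper_percentile must be in (0, 100]")
        if self.min_genes < 0:
            raise ValueError("min_genes must be >= 0")


@dataclass
class CoexprContingency:
    """Anchor-conditioned co-expression table (see module docstring)."""

    a: int  # treated, anchor+ partner+
    b: int  # treated, anchor+ partner-
    c: int  # control, anchor+ partner+
    d: int  # control, anchor+ partner-

    def as_table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _counts_matrix(adata: ad.AnnData) -> np.ndarray | sp.spmatrix:
    return adata.X


def _per_cell_metrics(adata: ad.AnnData, mito_prefix: str) -> tuple[np.ndarray, np.ndarray]:
    x = _counts_matrix(adata)
    if sp.issparse(x):
        n_genes = np.asarray((x > 0).sum(axis=1)).ravel()
        total = np.asarray(x.sum(axis=1)).ravel()
        mito_mask = np.array([g.startswith(mito_prefix) for g in adata.var_names])
        mito = np.asarray(x[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() else np.zeros(adata.n_obs)
    else:
        x = np.asarray(x)
        n_genes = (x > 0).sum(axis=1)
        total = x.sum(axis=1)
        mito_mask = np.array([g.startswith(mito_prefix) for g in adata.var_names])
        mito = x[:, mito_mask].sum(axis=1) if mito_mask.any() else np.zeros(adata.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return n_genes, mito_frac


def qc_filter_cells(
    adata: ad.AnnData,
    params: QCParams | None = None,
    sample_key: str | None = None,
) -> ad.AnnData:
    """Apply cell QC and return the filtered copy.

    Removes cells with detected-gene count strictly above the per-sample
    upper percentile, mitochondrial fraction above the cap (absolute or
    per-sample percentile), or fewer than ``min_genes`` detected genes.
    Percentiles are computed independently within each sample (grouping by
    ``sample_key`` in obs; the whole matrix is one sample when None).
    obs gains ``n_genes_detected`` and ``mito_fraction`` columns.
    """
    params = params or QCParams()
    n_genes, mito_frac = _per_cell_metrics(adata, params.mito_prefix)
    adata = adata.copy()
    adata.obs["n_genes_detected"] = n_genes
    adata.obs["mito_fraction"] = mito_frac

    if sample_key is None:
        groups = pd.Series("all", index=adata.obs_names)
    else:
        groups = adata.obs[sample_key].astype(str)

    keep = np.ones(adata.n_obs, dtype=bool)
    for _, idx in groups.groupby(groups).groups.items():
        loc = adata.obs_names.get_indexer(idx)
        g = n_genes[loc]
        upper = np.percentile(g, params.gene_count_upper_percentile)
        ok = g <= upper
        if params.mito_upper > 1:
            mito_cap = np.percentile(mito_frac[loc], params.mito_upper)
        else:
            mito_cap = params.mito_upper
        ok &= mito_frac[loc] <= mito_cap
        ok &= g >= params.min_genes
        keep[loc] = ok

    if not keep.any():
        raise ValueError("QC filtering removed every cell; check thresholds")
    return adata[keep].copy()


def positivity(adata: ad.AnnData, gene: str) -> np.ndarray:
    """Boolean vector over cells: raw count of ``gene`` > 0."""
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not present in the matrix")
    col = adata[:, gene].X
    if sp.issparse(col):
        col = np.asarray(col.todense())
    return np.asarray(col).ravel() > 0


def coexpression_contingency(
    treated: ad.AnnData,
    control: ad.AnnData,
    anchor: str,
    partner: str,
) -> tuple[CoexprContingency, ContingencyResult]:
    """Anchor-conditioned co-expression odds ratio between two conditions."""
    tables = {}
    for label, adata in (("treated", treated), ("control", control)):
        anchor_pos = positivity(adata, anchor)
        if not anchor_pos.any():
            raise ValueError(f"no anchor-positive cells in the {label} condition")
        partner_pos = positivity(adata, partner)
        both = int((anchor_pos & partner_pos).sum())
        only = int((anchor_pos & ~partner_pos).sum())
        tables[label] = (both, only)
    cont = CoexprContingency(
        a=tables["treated"][0], b=tables["treated"][1],
        c=tables["control"][0], d=tables["control"][1],
    )
    return cont, contingency_chisq(cont.as_table())


def genes_in_interacting_ses(
    network,
    anchor_se: str,
    genes: Sequence[GeneModel],
    ses: Sequence[SuperEnhancer],
) -> list[str]:
    """Genes overlapping any SE adjacent to ``anchor_se`` in the network.

    The anchor SE's own genes are excluded; genes overlapping several
    adjacent SEs are listed once.  Overlap is >= 1 bp against the SEs'
    current (extended) intervals.
    """
    if anchor_se not in network:
        raise KeyError(f"anchor SE {anchor_se!r} is not a node of the network")
    se_by_id = {se.se_id: se for se in ses}
    neighbors = [se_by_id[n] for n in network.neighbors(anchor_se) if n in se_by_id]
    anchor = se_by_id.get(anchor_se)
    anchor_genes = (
        {g.gene_id for g in genes if anchor and g.interval.overlaps(anchor.interval)}
    )
    found: list[str] = []
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in anchor_genes or g.gene_id in seen:
            continue
        if any(g.interval.overlaps(se.interval) for se in neighbors):
            found.append(g.gene_id)
            seen.add(g.gene_id)
    return found


def partner_gene_screen(
    treated: ad.AnnData,
    control: ad.AnnData,
    anchor_gene: str,
    candidate_genes: Sequence[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Run the co-expression test for each candidate partner and rank by OR.

    Candidates missing from either matrix are skipped and reported in the
    second return value.  Ties in OR break by smaller p-value, then by
    gene id.
    """
    rows = []
    skipped: list[str] = []
    for gene in candidate_genes:
        if gene not in treated.var_names or gene not in control.var_names:
            skipped.append(gene)
            continue
        cont, res = coexpression_contingency(treated, control, anchor_gene, gene)
        rows.append(
            {
                "gene": gene, "a": cont.a, "b": cont.b, "c": cont.c, "d": cont.d,
                "odds_ratio": res.odds_ratio, "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene", "a", "b", "c", "d", "odds_ratio", "p_value"]
    )
    if len(df):
        df = df.sort_values(
            ["odds_ratio", "p_value", "gene"], ascending=[False, True, True]
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
    else:
        df["rank"] = pd.Series(dtype=int)
    return df, skipped
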