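"""Two-topology log-likelihood comparison at gene and site granularity.

Given two trees that are identical except for the placement of one
lineage (say, two hypotheses for the position of a plastid-bearing
group),
every gene is scored by ΔlnL = lnL(T1) − lnL(T2), normalized by its
alignment length; genes preferring T2 sort first.  A site-wise scan holds
branch lengths at their per-alignment optima under each tree and reports
the per-column lnL difference, whose running cumulative sum localizes
topology-discordant segments (the chimeric-gene diagnostic).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .likelihood import (
    optimize_branch_lengths,
    optimize_parameters,
    site_log_likelihoods,
)
from .models import SubstitutionModel
from .supermatrix import GeneAlignmentSet
from .treeops import PhyloTree, TreeError, restrict_tree


@dataclass
class DeltaLnLReport:
    """Per-gene two-topology comparison.

    table columns: gene, n_sites, lnl_t1, lnl_t2, delta (lnl_t1 − lnl_t2)
    and delta_per_site (delta / gene length), sorted ascending by
    delta_per_site so T2-preferring genes come first.  Genes overlapping
    fewer than 4 tree leaves are listed in `skipped`.
    """

    table: pd.DataFrame
    mode: str
    skipped: list[str] = field(default_factory=list)

    def top(self, n: int) -> pd.DataFrame:
        """The n genes most favouring T2 (no error if n exceeds the count)."""
        return self.table.head(n)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _fit_lnl(gene, tree, model, mode: str, optimize_alpha: bool) -> float:
    sub = restrict_tree(tree, gene.taxa)
    if mode == "fixed":
        return site_log_likelihoods(gene, sub, model)[1]
    if optimize_alpha and model.k >= 2:
        _, _, lnl = optimize_parameters(gene, sub, model, optimize_alpha=True)
    else:
        _, lnl = optimize_branch_lengths(gene, sub, model)
    return lnl


def per_gene_delta_lnl(
    genes: GeneAlignmentSet,
    t1: PhyloTree,
    t2: PhyloTree,
    model: SubstitutionModel,
    mode: str = "optimized",
    optimize_alpha: bool = True,
) -> DeltaLnLReport:
    """Score every gene under both topologies.

    mode "optimized" (the default) refits branch lengths — and the gamma
    shape when `optimize_alpha` — independently per gene under each
    topology; "fixed" keeps the branch lengths carried by the input trees
    (paths merged when the tree is restricted to a gene's taxa).
    """
    if set(t1.labels.values()) != set(t2.labels.values()):
        raise TreeError("the two test trees must share their leaf set")
    if mode not in ("optimized", "fixed"):
        raise ValueError(f"unknown mode {mode!r}")
    tree_taxa = set(t1.labels.values())
    rows, skipped = [], []
    for g in genes:
        overlap = [t for t in g.taxa if t in tree_taxa]
        if len(overlap) < 4:
            skipped.append(g.name)
            continue
        sub = g.restrict(overlap)
        lnl1 = _fit_lnl(sub, t1, model, mode, optimize_alpha)
        lnl2 = _fit_lnl(sub, t2, model, mode, optimize_alpha)
        rows.append(
            {
                "gene": g.name,
                "n_sites": g.length,
                "lnl_t1": lnl1,
                "lnl_t2": lnl2,
                "delta": lnl1 - lnl2,
                "delta_per_site": (lnl1 - lnl2) / g.length,
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["delta_per_site", "gene"], kind="stable")
        .reset_index(drop=True)
    )
    return DeltaLnLReport(table=table, mode=mode, skipped=skipped)


def per_site_delta_lnl(
    aln,
    t1: PhyloTree,
    t2: PhyloTree,
    model: SubstitutionModel,
    optimize: bool = True,
    optimize_alpha: bool = False,
) -> np.ndarray:
    """Site-wise lnL(T1) − lnL(T2).

    Branch lengths are optimized per tree on the whole alignment and then
    held fixed during the scan (a per-site refit would make the comparison
    meaningless); `optimize=False` keeps the input branch lengths.  The
    vector sums to the per-alignment ΔlnL.
    """
    if set(t1.labels.values()) != set(t2.labels.values()):
        raise TreeError("the two test trees must share their leaf set")
    if hasattr(aln, "as_alignment"):
        aln = aln.as_alignment()
    taxa = set(aln.taxa)
    r1 = restrict_tree(t1, [t for t in t1.labels.values() if t in taxa])
    r2 = restrict_tree(t2, [t for t in t2.labels.values() if t in taxa])
    if optimize:
        if optimize_alpha and model.k >= 2:
            m1, r1, _ = optimize_parameters(aln, r1, model)
            m2, r2, _ = optimize_parameters(aln, r2, model)
        else:
            m1 = m2 = model
            r1, _ = optimize_branch_lengths(aln, r1, model)
            r2, _ = optimize_branch_lengths(aln, r2, model)
    else:
        m1 = m2 = model
    s1, _ = site_log_likelihoods(aln, r1, m1)
    s2, _ = site_log_likelihoods(aln, r2, m2)
    return s1 - s2


def cumulative_scan(site_delta: np.ndarray) -> np.ndarray:
    """Running cumulative sum of the site-wise ΔlnL (for scan plots)."""
    return np.cumsum(site_delta)


def rank_and_flag(
    report: DeltaLnLReport, top_n: int = 10, z_threshold: float = 3.0
) -> pd.DataFrame:
    """Ranked table with outlier flags.

    Stable ascending sort by normalized ΔlnL (ties by gene name); a gene is
    flagged when its delta_per_site lies beyond `z_threshold` standard
    deviations of the report's distribution.  `top_n` only annotates
    membership of the top block; it may exceed the gene count.
    """
    if report.table.empty:
        raise ValueError("empty report")
    table = report.table.copy()
    values = table["delta_per_site"].to_numpy()
    sd = values.std(ddof=0)
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    table["rank"] = np.arange(1, len(table) + 1)
    table["z"] = z
    table["flagged"] = np.abs(z) >= z_threshold
    table["in_top"] = table["rank"] <= top_n
    return table
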