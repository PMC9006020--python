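"""Perturbation designs over the likelihood engine: nonparametric bootstrap,
fast-evolving-position removal (FPR), random gene sampling (RGS) and
taxon-deletion series.

Support is the standard Felsenstein bootstrap percentage of a clade's
bipartition among replicate ML trees (NJ start + NNI per replicate).

Seed schedule (all derived seeds stay small integers):

* bootstrap replicate i of a run with base seed ``s`` uses ``s + i``;
* FPR fraction index ``j`` uses base ``s + 10_000 * j`` (so the f = 0 row
  is bitwise identical to a plain bootstrap run at seed ``s``);
* RGS size index ``j`` (1-based), replicate ``r``: the gene subsample uses
  ``s + 1_000_000 * j + 1_000 * r`` and its internal bootstrap
  ``s + 1_000_000 * j + 1_000 * r + 500``;
* taxon-deletion scheme index ``m`` offsets the downstream run by
  ``97_000 * m``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .likelihood import (
    SearchSettings,
    SiteRateVector,
    estimate_site_rates,
    ml_tree_search,
)
from .models import SubstitutionModel
from .supermatrix import GeneAlignment, GeneAlignmentSet, concatenate
from .treeops import PhyloTree, TreeError, clade_support


class PlanError(ValueError):
    pass


# ---------------------------------------------------------------------------
# plans


@dataclass
class FPRPlan:
    """Fast-evolving-position-removal schedule.

    fractions must be strictly increasing and in [0, 1); the removal sets
    are nested by construction (one ranking, prefix removal).
    """

    fractions: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8)
    n_bootstrap: int = 100

    def __post_init__(self):
        fr = list(self.fractions)
        if any(not (0 <= f < 1) for f in fr):
            raise PlanError("FPR fractions must lie in [0, 1)")
        if any(b <= a for a, b in zip(fr, fr[1:])):
            raise PlanError("FPR fractions must be strictly increasing")


@dataclass
class RGSPlan:
    """Random-gene-sampling schedule: subsample sizes with replicate counts.

    The default plan draws 50 replicates each of 50- and 100-gene
    subsamples and 10 each of 150- and 200-gene subsamples.
    """

    sizes: dict = field(
        default_factory=lambda: {50: 50, 100: 50, 150: 10, 200: 10}
    )
    n_bootstrap: int = 100

    def __post_init__(self):
        for size, reps in self.sizes.items():
            if size < 1 or reps < 1:
                raise PlanError("RGS sizes and replicate counts must be >= 1")


# ---------------------------------------------------------------------------
# results container


@dataclass
class SupportSeries:
    """Tidy support table: (scheme, condition, clade, replicate, support).

    `support` is a bootstrap percentage in [0, 100]; NaN marks a clade not
    evaluable under a taxon-deletion scheme.  Replicate-level rows are
    retained so RGS distributions can be plotted directly.
    """

    table: pd.DataFrame

    def medians(self) -> pd.DataFrame:
        return (
            self.table.dropna(subset=["support"])
            .groupby(["scheme", "condition", "clade"], sort=False)["support"]
            .median()
            .reset_index()
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, kind: str = "line"):
        """Quick support-vs-condition figure (one line/box group per clade)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if kind == "line":
            med = self.medians()
            for clade, sub in med.groupby("clade", sort=False):
                ax.plot(sub["condition"], sub["support"], marker="o", label=clade)
        else:
            for clade, sub in self.table.groupby("clade", sort=False):
                conds = sorted(sub["condition"].unique())
                data = [
                    sub.loc[sub["condition"] == c, "support"].dropna() for c in conds
                ]
                ax.boxplot(data, tick_labels=[str(c) for c in conds])
        ax.set_ylabel("bootstrap support (%)")
        ax.set_xlabel("condition")
        if kind == "line":
            ax.legend()
        return ax

    @staticmethod
    def concat(series: Sequence["SupportSeries"]) -> "SupportSeries":
        return SupportSeries(pd.concat([s.table for s in series], ignore_index=True))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_alignment(aln, seed: int) -> GeneAlignment:
    """Resample columns uniformly with replacement; deterministic per seed."""
    if hasattr(aln, "as_alignment"):
        aln = aln.as_alignment()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, aln.length, size=aln.length)
    return aln.select_columns(idx)


def bootstrap_support(
    aln,
    model: SubstitutionModel,
    n_reps: int,
    clades: dict,
    seed: int = 0,
    settings: Optional[SearchSettings] = None,
    start: Optional[PhyloTree] = None,
) -> tuple[dict, list[PhyloTree]]:
    """Standard nonparametric bootstrap: resample, search, count bipartitions.

    Returns ({clade name: support %}, replicate trees).  Replicate i uses
    seed ``seed + i``.  A clade not evaluable on this taxon set maps to NaN.
    `start` seeds every replicate's search with a given tree (e.g. the
    full-data ML tree) instead of a per-replicate NJ start.
    """
    if n_reps < 1:
        raise PlanError("n_reps must be >= 1")
    if hasattr(aln, "as_alignment"):
        aln = aln.as_alignment()
    settings = settings or SearchSettings.fast()
    trees = []
    for i in range(n_reps):
        rep = bootstrap_alignment(aln, seed=seed + i)
        tree, _ = ml_tree_search(
            rep, model, start=start, seed=seed + i, settings=settings
        )
        trees.append(tree)
    taxa = frozenset(aln.taxa)
    supports = {}
    for name, clade in clades.items():
        c = frozenset(clade) & taxa
        if len(c) < 2 or len(taxa - c) < 2:
            supports[name] = float("nan")
        else:
            supports[name] = clade_support(trees, c)
    return supports, trees


# ---------------------------------------------------------------------------
# FPR series


def fpr_series(
    aln,
    tree: PhyloTree,
    model: SubstitutionModel,
    plan: FPRPlan,
    clades: dict,
    seed: int = 0,
    rank_model: Optional[SubstitutionModel] = None,
    rank_rates: Optional[SiteRateVector] = None,
    settings: Optional[SearchSettings] = None,
    scheme: str = "baseline",
) -> SupportSeries:
    """Rank sites once on the guide tree, then bootstrap each truncation.

    The ranking model must have k >= 2 even when the analysis model is
    rate-homogeneous (`rank_model` defaults to the analysis model); ties
    in the ranking remove the lower column index first.
    """
    if hasattr(aln, "as_alignment"):
        aln = aln.as_alignment()
    if rank_rates is None:
        rmodel = rank_model or model
        rank_rates = estimate_site_rates(aln, tree, rmodel)
    rows = []
    for j, f in enumerate(plan.fractions):
        kept = rank_rates.kept_indices(f)
        sub = aln.select_columns(kept)
        supports, _ = bootstrap_support(
            sub, model, plan.n_bootstrap, clades,
            seed=seed + 10_000 * j, settings=settings,
        )
        for clade, support in supports.items():
            rows.append(
                {
                    "scheme": scheme,
                    "condition": f,
                    "clade": clade,
                    "replicate": 0,
                    "support": support,
                }
            )
    return SupportSeries(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# RGS series


def sample_genes(
    genes: GeneAlignmentSet, size: int, rng: np.random.Generator
) -> GeneAlignmentSet:
    """Sample `size` genes without replacement, keeping original order."""
    names = genes.names
    if size > len(names):
        raise PlanError(f"cannot sample {size} genes from {len(names)}")
    chosen = rng.choice(len(names), size=size, replace=False)
    chosen.sort()
    return genes.subset([names[i] for i in chosen])


def rgs_seeds(seed: int, size_index: int, replicate: int) -> tuple[int, int]:
    """(gene-sampling seed, bootstrap seed) for one RGS replicate."""
    base = seed + 1_000_000 * (size_index + 1) + 1_000 * replicate
    return base, base + 500


def rgs_series(
    genes: GeneAlignmentSet,
    model: SubstitutionModel,
    plan: RGSPlan,
    clades: dict,
    seed: int = 0,
    settings: Optional[SearchSettings] = None,
    scheme: str = "baseline",
) -> SupportSeries:
    """For each size and replicate: sample genes, concatenate, bootstrap.

    Emits one row per (size, replicate, clade) so the support distribution
    over replicates is box-plot-ready.
    """
    rows = []
    for j, size in enumerate(sorted(plan.sizes)):
        n_reps = plan.sizes[size]
        for r in range(n_reps):
            sample_seed, boot_seed = rgs_seeds(seed, j, r)
            subset = sample_genes(genes, size, np.random.default_rng(sample_seed))
            sm = concatenate(subset)
            supports, _ = bootstrap_support(
                sm, model, plan.n_bootstrap, clades,
                seed=boot_seed, settings=settings,
            )
            for clade, support in supports.items():
                rows.append(
                    {
                        "scheme": scheme,
                        "condition": size,
                        "clade": clade,
                        "replicate": r,
                        "support": support,
                    }
                )
    return SupportSeries(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# taxon-deletion series


def taxon_deletion_series(
    genes: GeneAlignmentSet,
    model: SubstitutionModel,
    schemes: dict,
    clades: dict,
    seed: int = 0,
    downstream: Union[int, FPRPlan, RGSPlan] = 100,
    rank_model: Optional[SubstitutionModel] = None,
    settings: Optional[SearchSettings] = None,
) -> SupportSeries:
    """Apply each named taxon-removal scheme, re-run the downstream design.

    `downstream` is either a bootstrap replicate count, an FPRPlan (the
    guide tree is re-inferred on each pruned concatenation) or an RGSPlan.
    Monitored clades are restricted to the surviving taxa; a clade left
    with fewer than 2 members (or complement) is reported as NaN
    ("not evaluable"), never as 0.
    """
    out = []
    for m, (scheme_name, remove) in enumerate(schemes.items()):
        remove = set(remove)
        pruned = []
        for g in genes:
            keep = [t for t in g.taxa if t not in remove]
            if len(keep) >= 4:
                pruned.append(g.restrict(keep))
        if not pruned:
            raise PlanError(f"scheme {scheme_name!r} leaves no usable genes")
        sub = GeneAlignmentSet(pruned)
        scheme_seed = seed + 97_000 * m
        if isinstance(downstream, FPRPlan):
            sm = concatenate(sub)
            rmodel = rank_model or model
            guide, _ = ml_tree_search(
                sm, rmodel, seed=scheme_seed, settings=settings or SearchSettings.fast()
            )
            series = fpr_series(
                sm, guide, model, downstream, clades, seed=scheme_seed,
                rank_model=rmodel, settings=settings, scheme=scheme_name,
            )
        elif isinstance(downstream, RGSPlan):
            series = rgs_series(
                sub, model, downstream, clades, seed=scheme_seed,
                settings=settings, scheme=scheme_name,
            )
        else:
            sm = concatenate(sub)
            supports, _ = bootstrap_support(
                sm, model, int(downstream), clades, seed=scheme_seed,
                settings=settings,
            )
            series = SupportSeries(
                pd.DataFrame(
                    [
                        {
                            "scheme": scheme_name,
                            "condition": "bootstrap",
                            "clade": clade,
                            "replicate": 0,
                            "support": support,
                        }
                        for clade, support in supports.items()
                    ]
                )
            )
        out.append(series)
    return SupportSeries.concat(out)
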