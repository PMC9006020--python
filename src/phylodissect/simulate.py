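"""Synthetic gene sets with the statistical structure the pipeline assumes.

Sequences evolve along a known tree under a reversible amino-acid model
with discrete-gamma rate heterogeneity (one category drawn per site).
Scenario builders provide the two canonical trouble geometries:

* a long-branch-attraction (LBA) fixture — two long terminal branches on
  either side of a short internal branch, each with a short-branch
  "breaker" sister; simulated under strong rate heterogeneity so that a
  rate-homogeneous re-analysis elicits the artefactual long-branch clade,
  while correct-model inference recovers the truth;
* endosymbiotic-transfer-style chimeric genes whose sites are split
  between a host topology and a donor topology;

plus coverage-profile missingness (per-taxon gene presence probabilities,
at least 4 taxa forced per gene).  Every output is reproducible bit for
bit from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import AMINO_ACIDS, SubstitutionModel
from .supermatrix import GeneAlignment, GeneAlignmentSet
from .treeops import PhyloTree, TreeError


@dataclass
class GroundTruth:
    """What the generator knows: per-site source topology and rates,
    chimeric segment coordinates, per-taxon presence."""

    site_topology: np.ndarray  # label per site ("host"/"donor" or tree name)
    site_rates: np.ndarray  # true relative rate drawn per site
    segments: list[tuple[int, int, str]] = field(default_factory=list)  # 1-based inclusive
    presence: Optional[dict] = None  # taxon -> per-gene bool list


@dataclass
class ScenarioSpec:
    """Declarative description of an LBA / chimera simulation scenario."""

    tree: str  # newick
    model: SubstitutionModel = None
    n_genes: int = 1
    gene_length: int = 300
    donor_tree: Optional[str] = None
    chimeric_fraction: float = 0.0
    chimera_layout: str = "block"
    missingness: Optional[dict] = None  # taxon -> presence probability
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.chimeric_fraction <= 1):
            raise ValueError("chimeric fraction must be in [0, 1]")


def _sample_states(rng, probs_rows: np.ndarray) -> np.ndarray:
    """Draw one categorical state per row of a stack of probability rows."""
    cum = np.cumsum(probs_rows, axis=1)
    u = rng.random(probs_rows.shape[0])
    return (u[:, None] > cum).sum(axis=1).clip(max=probs_rows.shape[1] - 1)


def simulate_alignment(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    name: str = "sim",
) -> tuple[GeneAlignment, GroundTruth]:
    """Evolve `n_sites` columns along the tree.

    Root states are drawn from the stationary frequencies; each site draws
    one gamma category (rate held along all branches of that site), then
    states propagate with P(t * r) along every edge.
    """
    if n_sites < 1:
        raise ValueError(f"n_sites must be >= 1, got {n_sites}")
    if rng is None:
        rng = np.random.default_rng(seed)
    cat = rng.integers(0, model.k, size=n_sites)
    rates = model.rates[cat]
    root = next(
        (n for n in tree.adj if n not in tree.labels), tree.leaves[0]
    )
    states = {root: _sample_states(rng, np.tile(model.frequencies, (n_sites, 1)))}
    order = tree.postorder(root)
    for node, parent in reversed(order):  # preorder
        if parent is None:
            continue
        pmats = model.transition_matrices(tree.adj[parent][node])  # (k,20,20)
        rows = pmats[cat, states[parent], :]
        states[node] = _sample_states(rng, rows)
    taxa, rows = [], []
    lookup = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for leaf in tree.leaves:
        taxa.append(tree.labels[leaf])
        rows.append(bytes(lookup[states[leaf]]).decode("ascii"))
    aln = GeneAlignment(name, taxa, rows)
    truth = GroundTruth(
        site_topology=np.full(n_sites, "host", dtype=object),
        site_rates=rates,
        segments=[(1, n_sites, "host")],
    )
    return aln, truth


def simulate_chimeric_gene(
    host_tree: PhyloTree,
    donor_tree: PhyloTree,
    length: int,
    fraction: float,
    model: SubstitutionModel,
    seed: int = 0,
    layout: str = "block",
    rng: Optional[np.random.Generator] = None,
    name: str = "chimera",
) -> tuple[GeneAlignment, GroundTruth]:
    """A gene whose trailing ceil(fraction*length) sites evolved on the
    donor tree ("block" layout) or whose donor sites interleave evenly
    ("interleaved"); the remainder evolves on the host tree."""
    if set(host_tree.labels.values()) != set(donor_tree.labels.values()):
        raise TreeError("host and donor trees must share their leaf set")
    if not (0 <= fraction <= 1):
        raise ValueError("chimeric fraction must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_donor = int(np.ceil(fraction * length))
    n_host = length - n_donor
    host_aln = donor_aln = None
    truth_rates = np.empty(length)
    if n_host:
        host_aln, th = simulate_alignment(host_tree, model, n_host, rng=rng, name=name)
    if n_donor:
        donor_aln, td = simulate_alignment(donor_tree, model, n_donor, rng=rng, name=name)
    taxa = host_aln.taxa if host_aln else donor_aln.taxa
    site_topology = np.empty(length, dtype=object)
    rows = []
    if layout == "block":
        for t in taxa:
            h = host_aln.row(t) if host_aln else ""
            d = donor_aln.row(t) if donor_aln else ""
            rows.append(h + d)
        site_topology[:n_host] = "host"
        site_topology[n_host:] = "donor"
        if n_host:
            truth_rates[:n_host] = th.site_rates
        if n_donor:
            truth_rates[n_host:] = td.site_rates
        segments = []
        if n_host:
            segments.append((1, n_host, "host"))
        if n_donor:
            segments.append((n_host + 1, length, "donor"))
    elif layout == "interleaved":
        donor_pos = np.linspace(0, length - 1, n_donor).round().astype(int) if n_donor else np.array([], int)
        is_donor = np.zeros(length, dtype=bool)
        is_donor[donor_pos] = True
        # linspace rounding can collide; pad with first free slots
        deficit = n_donor - int(is_donor.sum())
        if deficit:
            free = np.flatnonzero(~is_donor)[:deficit]
            is_donor[free] = True
        for t in taxa:
            h = iter(host_aln.row(t) if host_aln else "")
            d = iter(donor_aln.row(t) if donor_aln else "")
            rows.append("".join(next(d) if f else next(h) for f in is_donor))
        site_topology[:] = "host"
        site_topology[is_donor] = "donor"
        hr = iter(th.site_rates if n_host else [])
        dr = iter(td.site_rates if n_donor else [])
        truth_rates[:] = [next(dr) if f else next(hr) for f in is_donor]
        segments = _runs_to_segments(site_topology)
    else:
        raise ValueError(f"unknown chimera layout {layout!r}")
    aln = GeneAlignment(name, list(taxa), rows)
    truth = GroundTruth(
        site_topology=site_topology, site_rates=truth_rates, segments=segments
    )
    return aln, truth


def _runs_to_segments(labels: np.ndarray) -> list[tuple[int, int, str]]:
    segments = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append((start + 1, i, str(labels[start])))
            start = i
    return segments


def simulate_gene_set(
    tree: PhyloTree,
    model: SubstitutionModel,
    n_genes: int,
    gene_length: int,
    seed: int = 0,
    donor_tree: Optional[PhyloTree] = None,
    chimeric_fraction: float = 0.0,
    layout: str = "block",
) -> tuple[GeneAlignmentSet, dict[str, GroundTruth]]:
    """A set of genes (optionally all chimeric) with per-gene ground truth."""
    genes, truths = [], {}
    for i in range(n_genes):
        name = f"gene{i + 1:03d}"
        rng = np.random.default_rng([seed, i])
        if donor_tree is not None and chimeric_fraction > 0:
            g, t = simulate_chimeric_gene(
                tree, donor_tree, gene_length, chimeric_fraction, model,
                layout=layout, rng=rng, name=name,
            )
        else:
            g, t = simulate_alignment(tree, model, gene_length, rng=rng, name=name)
        genes.append(g)
        truths[name] = t
    return GeneAlignmentSet(genes), truths


# ---------------------------------------------------------------------------
# LBA scenario


#: Default LBA geometry (14 taxa).  The two "long branches" are the long
#: terminal L1 and the stem of the (R1, R2) clade, which is exposed when
#: its short-branch breaker B2 is deleted; B1 is the breaker sister of L1.
#: The true clade displaced by the artefact is the six-taxon group
#: {R1, R2, C1, C2, G1, G2} (stem 0.15); the artefactual clade unites L1
#: with R1+R2.  Simulated under strong heterogeneity (alpha 0.3); a
#: rate-homogeneous (k=1) re-analysis of the breaker-deleted alignment
#: elicits the artefact, which fast-site removal then suppresses.
LBA_LONG = 1.5
LBA_INTERNAL = 0.02
LBA_ALPHA = 0.3
LBA_N_SITES = 5000

LBA_ARTEFACT_CLADE = frozenset({"L1", "R1", "R2"})
LBA_TRUE_CLADE = frozenset({"R1", "R2", "C1", "C2", "G1", "G2"})
LBA_BREAKERS = ("B1", "B2")


def lba_tree(
    lam_long: float = LBA_LONG,
    lam_internal: float = LBA_INTERNAL,
) -> PhyloTree:
    """The true 14-taxon LBA topology.

    `lam_internal` is the short internal branch between the long terminal
    L1 (length `lam_long`) and the clade bearing the second long branch
    (the R stem); the remaining branch lengths are fixed fixture geometry.
    """
    nwk = (
        f"((((B2:0.1,(R1:1.1,R2:1.1):0.35):0.3,"
        f"((C1:0.5,C2:0.5):0.12,(G1:0.5,G2:0.5):0.12):0.15):0.08,"
        f"(L1:{lam_long},B1:0.1):{lam_internal}):0.05,"
        f"((O1:0.55,O2:0.55):0.1,(O3:0.55,(O4:0.55,O5:0.55):0.1):0.1):0.08);"
    )
    return PhyloTree.from_newick(nwk)


def simulate_lba_case(
    model: SubstitutionModel,
    n_sites: int = LBA_N_SITES,
    seed: int = 0,
    lam_long: float = LBA_LONG,
    lam_internal: float = LBA_INTERNAL,
) -> tuple[GeneAlignment, GroundTruth, PhyloTree]:
    """Simulate the LBA fixture; returns (alignment, truth, true tree).

    The supplied model should carry strong rate heterogeneity (the fixture
    default is alpha 0.3, k 4); analysing the output with k = 1 is the
    mis-specification that elicits the artefactual clade, most visibly
    after deleting the breaker taxa B1 and B2.
    """
    tree = lba_tree(lam_long=lam_long, lam_internal=lam_internal)
    for label in ("L1", "R1", "R2") + LBA_BREAKERS:
        tree.node_of(label)  # raises if the designated leaves are absent
    aln, truth = simulate_alignment(tree, model, n_sites, seed=seed, name="lba")
    return aln, truth, tree


# ---------------------------------------------------------------------------
# chimera (endosymbiotic-transfer) scenario


#: Host tree for the chimera experiments: the "query" lineage Cry hangs
#: off an unresolved central backbone (as when its vertical neighbours
#: have been deleted from the alignment), so vertical sites carry no
#: directional signal for its position.  The donor tree places Cry next
#: to the (Rho1, Rho2) clade across a short but positive edge, so
#: donor-derived sites all point the same way.
CHIMERA_HOST_NEWICK = (
    "((Rho1:0.3,Rho2:0.3):0.08,Cry:0.7,(Glau:0.3,Out3:0.3):0.12,"
    "(Out1:0.3,Out2:0.3):0.1,Out4:0.4,Out5:0.4);"
)
CHIMERA_DONOR_NEWICK = (
    "(((Rho1:0.3,Rho2:0.3):0.05,Cry:0.7):0.03,(Glau:0.3,Out3:0.3):0.12,"
    "(Out1:0.3,Out2:0.3):0.1,Out4:0.4,Out5:0.4);"
)
#: Resolved "Tree 1" for two-topology comparisons (the vertical placement:
#: Cry with the Out1/Out2 pair).  The host simulation tree above is its
#: unresolved counterpart; a per-gene lnL comparison needs two resolved
#: alternatives (a host/vertical tree 1 vs the donor tree 2).
CHIMERA_TREE1_NEWICK = (
    "(((Out1:0.3,Out2:0.3):0.1,Cry:0.7):0.02,(Rho1:0.3,Rho2:0.3):0.08,"
    "(Glau:0.3,Out3:0.3):0.12,Out4:0.4,Out5:0.4);"
)
#: History of a gene transferred wholly from the donor lineage: same
#: topology as the donor tree but a deep shared branch with (Rho1, Rho2).
#: Genes simulated here are unambiguously donor-derived, whereas the
#: donor tree above models the faint per-segment signal of chimeras
#: (whose short donor edge makes a 300-site gene T2-preferring only on
#: average, not in every draw).
CHIMERA_TRANSFER_NEWICK = (
    "(((Rho1:0.3,Rho2:0.3):0.1,Cry:0.7):0.15,(Glau:0.3,Out3:0.3):0.12,"
    "(Out1:0.3,Out2:0.3):0.1,Out4:0.4,Out5:0.4);"
)
CHIMERA_DONOR_CLADE = frozenset({"Rho1", "Rho2", "Cry"})
CHIMERA_FRACTION = 0.3
CHIMERA_GENE_LENGTH = 100
CHIMERA_ALPHA = 0.8


def chimera_trees() -> tuple[PhyloTree, PhyloTree]:
    """(host, donor) trees of the default chimera scenario."""
    return (
        PhyloTree.from_newick(CHIMERA_HOST_NEWICK),
        PhyloTree.from_newick(CHIMERA_DONOR_NEWICK),
    )


# ---------------------------------------------------------------------------
# missingness


def apply_missingness(
    genes: GeneAlignmentSet,
    profile,
    seed: int = 0,
) -> tuple[GeneAlignmentSet, dict]:
    """Drop (taxon, gene) pairs independently with per-taxon retention
    probability; genes are redrawn until at least 4 taxa survive.

    `profile` is either a scalar probability or a mapping taxon -> p.
    Returns the thinned gene set and the realized presence mask.
    """
    rng = np.random.default_rng(seed)
    out = []
    presence: dict[str, dict[str, bool]] = {}
    for g in genes:
        if isinstance(profile, dict):
            probs = np.array([float(profile.get(t, 1.0)) for t in g.taxa])
        else:
            probs = np.full(g.n_taxa, float(profile))
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("presence probabilities must be in [0, 1]")
        for _ in range(10_000):
            mask = rng.random(g.n_taxa) < probs
            if mask.sum() >= 4:
                break
        else:
            mask = np.ones(g.n_taxa, dtype=bool)  # degenerate profile: keep all
        keep = [t for t, m in zip(g.taxa, mask) if m]
        out.append(g.restrict(keep))
        presence[g.name] = dict(zip(g.taxa, mask.tolist()))
    return GeneAlignmentSet(out), presence
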