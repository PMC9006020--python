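"""Per-gene protein alignments and their concatenation into a supermatrix.

The pipeline input is a set of aligned per-gene FASTA files.  Genes are
optionally screened against a set of well-established monophyletic
assemblages (a quick gene tree is built and bootstrap support for splits
that conflict with any constraint clade is measured; strongly supported
conflict excludes the gene), then concatenated into a single matrix with
1-based inclusive RAxML-style partition ranges and per-taxon coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .models import AA_INDEX, MISSING_CHARS

#: code used for a missing / fully ambiguous character in encoded matrices
MISSING_CODE = 20

_VALID_CHARS = frozenset(AA_INDEX) | MISSING_CHARS


class AlignmentFormatError(ValueError):
    """Malformed alignment input (ragged rows, bad characters, duplicates)."""


@dataclass
class GeneAlignment:
    """One aligned gene: ordered taxa and equal-length amino-acid rows."""

    name: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise AlignmentFormatError(f"gene {self.name!r}: empty alignment")
        if len(self.taxa) != len(self.rows):
            raise AlignmentFormatError(f"gene {self.name!r}: taxa/rows mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentFormatError(
                f"gene {self.name!r}: duplicate taxon labels {dupes}"
            )
        width = len(self.rows[0])
        if width < 1:
            raise AlignmentFormatError(f"gene {self.name!r}: zero-length alignment")
        for taxon, row in zip(self.taxa, self.rows):
            if len(row) != width:
                raise AlignmentFormatError(
                    f"gene {self.name!r}: row for {taxon!r} has length "
                    f"{len(row)}, expected {width} (ragged alignment)"
                )
            bad = set(row) - _VALID_CHARS
            if bad:
                raise AlignmentFormatError(
                    f"gene {self.name!r}: invalid characters {sorted(bad)} "
                    f"in row for {taxon!r}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def to_codes(self) -> np.ndarray:
        """Integer encoding, shape (n_taxa, length); missing -> 20."""
        lut = np.full(128, MISSING_CODE, dtype=np.int8)
        for aa, i in AA_INDEX.items():
            lut[ord(aa)] = i
        data = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_taxa, self.length)
        return lut[data]

    def restrict(self, taxa: Iterable[str]) -> "GeneAlignment":
        """Keep only the given taxa (in this alignment's order)."""
        keep = set(taxa)
        pairs = [(t, r) for t, r in zip(self.taxa, self.rows) if t in keep]
        if not pairs:
            raise AlignmentFormatError(f"gene {self.name!r}: no taxa left")
        return GeneAlignment(self.name, [t for t, _ in pairs], [r for _, r in pairs])

    def select_columns(self, idx: Sequence[int]) -> "GeneAlignment":
        """New alignment from the given 0-based column indices, in order."""
        idx = np.asarray(idx, dtype=int)
        arr = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_taxa, self.length)
        sub = arr[:, idx]
        rows = [bytes(r).decode("ascii") for r in sub]
        return GeneAlignment(self.name, list(self.taxa), rows)

    def missing_fraction(self) -> float:
        total = self.n_taxa * self.length
        missing = sum(sum(ch in MISSING_CHARS for ch in row) for row in self.rows)
        return missing / total

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, row in zip(self.taxa, self.rows):
                fh.write(f">{taxon}\n{row}\n")


class GeneAlignmentSet:
    """Ordered collection of named gene alignments."""

    def __init__(self, genes: Iterable[GeneAlignment]):
        self._genes: dict[str, GeneAlignment] = {}
        for g in genes:
            if g.name in self._genes:
                raise AlignmentFormatError(f"duplicate gene name {g.name!r}")
            self._genes[g.name] = g
        if not self._genes:
            raise AlignmentFormatError("empty gene set")

    def __iter__(self) -> Iterator[GeneAlignment]:
        return iter(self._genes.values())

    def __len__(self) -> int:
        return len(self._genes)

    def __getitem__(self, name: str) -> GeneAlignment:
        return self._genes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._genes

    @property
    def names(self) -> list[str]:
        return list(self._genes)

    @property
    def taxon_union(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self:
            for t in g.taxa:
                seen.setdefault(t)
        return sorted(seen)

    def subset(self, names: Sequence[str]) -> "GeneAlignmentSet":
        return GeneAlignmentSet([self._genes[n] for n in names])


def load_gene_alignments(paths: Sequence) -> GeneAlignmentSet:
    """Read aligned FASTA files, one gene per file.

    Gene names derive from file stems; lowercase residues are uppercased;
    duplicate taxon labels within a file, ragged rows, invalid characters
    and empty files are format errors naming the file.
    """
    genes = []
    for path in paths:
        path = Path(path)
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentFormatError(f"{path}: empty or unparseable FASTA")
        taxa = [r.id for r in records]
        rows = [str(r.seq).upper() for r in records]
        try:
            genes.append(GeneAlignment(path.stem, taxa, rows))
        except AlignmentFormatError as exc:
            raise AlignmentFormatError(f"{path}: {exc}") from exc
    return GeneAlignmentSet(genes)


# ---------------------------------------------------------------------------
# supermatrix


@dataclass
class Supermatrix:
    """Concatenated gene matrix with partition bookkeeping.

    partitions are (gene name, start, end), 1-based inclusive, tiling 1..L
    in input gene order; gene_taxa records which taxa actually had data for
    each gene (taxa absent from a gene are padded with '-').
    """

    taxa: list[str]
    rows: list[str]
    partitions: list[tuple[str, int, int]]
    gene_taxa: dict[str, tuple[str, ...]]

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def gene_names(self) -> list[str]:
        return [name for name, _, _ in self.partitions]

    def to_codes(self) -> np.ndarray:
        return GeneAlignment("_sm", list(self.taxa), list(self.rows)).to_codes()

    def as_alignment(self, name: str = "supermatrix") -> GeneAlignment:
        return GeneAlignment(name, list(self.taxa), list(self.rows))

    def coverage(self) -> pd.Series:
        """Per-taxon % of non-missing cells."""
        codes = self.to_codes()
        frac = (codes != MISSING_CODE).mean(axis=1)
        return pd.Series(100.0 * frac, index=self.taxa, name="coverage_pct")

    def extract_gene(self, name: str) -> GeneAlignment:
        """Recover a member gene (restricted to the taxa that had it)."""
        for gname, start, end in self.partitions:
            if gname == name:
                taxa = [t for t in self.gene_taxa[name] if t in self.taxa]
                rows = [
                    self.rows[self.taxa.index(t)][start - 1 : end] for t in taxa
                ]
                return GeneAlignment(name, taxa, rows)
        raise KeyError(f"no partition named {name!r}")

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, row in zip(self.taxa, self.rows):
                fh.write(f">{taxon}\n{row}\n")

    def write_phylip(self, path) -> None:
        """Relaxed PHYLIP (label, two spaces, sequence)."""
        with open(path, "w") as fh:
            fh.write(f"{self.n_taxa} {self.length}\n")
            for taxon, row in zip(self.taxa, self.rows):
                fh.write(f"{taxon}  {row}\n")

    def write_partition_file(self, path, model: str = "LG") -> None:
        """RAxML-style partition file: "LG, gene1 = 1-303"."""
        with open(path, "w") as fh:
            for name, start, end in self.partitions:
                fh.write(f"{model}, {name} = {start}-{end}\n")


def concatenate(
    genes: GeneAlignmentSet, taxon_universe: Optional[Sequence[str]] = None
) -> Supermatrix:
    """Concatenate genes into a supermatrix.

    Rows cover the union of gene taxa (or the supplied universe, which must
    be a superset); a taxon absent from a gene gets '-' across that
    partition.  Partitions follow input gene order.
    """
    if taxon_universe is None:
        taxa = genes.taxon_union
    else:
        taxa = list(taxon_universe)
        if len(set(taxa)) != len(taxa):
            raise AlignmentFormatError("taxon universe has duplicates")
        universe = set(taxa)
        for g in genes:
            extra = set(g.taxa) - universe
            if extra:
                raise AlignmentFormatError(
                    f"gene {g.name!r}: taxa {sorted(extra)} not in supplied universe"
                )
    parts: list[tuple[str, int, int]] = []
    gene_taxa: dict[str, tuple[str, ...]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 1
    for g in genes:
        parts.append((g.name, pos, pos + g.length - 1))
        pos += g.length
        gene_taxa[g.name] = tuple(g.taxa)
        lookup = dict(zip(g.taxa, g.rows))
        pad = "-" * g.length
        for t in taxa:
            chunks[t].append(lookup.get(t, pad))
    rows = ["".join(chunks[t]) for t in taxa]
    return Supermatrix(taxa=taxa, rows=rows, partitions=parts, gene_taxa=gene_taxa)


def coverage_table(sm: Supermatrix) -> pd.DataFrame:
    """Per-taxon coverage % plus per-gene presence flags."""
    df = pd.DataFrame({"coverage_pct": sm.coverage()})
    for name in sm.gene_names:
        present_taxa = set(sm.gene_taxa[name])
        df[name] = [t in present_taxa for t in sm.taxa]
    return df


def subset_taxa(sm: Supermatrix, remove: Sequence[str]) -> Supermatrix:
    """Drop taxa from the supermatrix; columns and partitions unchanged.

    Constant or empty columns created by the removal are retained.
    """
    remove = list(remove)
    unknown = set(remove) - set(sm.taxa)
    if unknown:
        raise AlignmentFormatError(f"cannot remove unknown taxa: {sorted(unknown)}")
    keep = [t for t in sm.taxa if t not in set(remove)]
    if len(keep) < 4:
        raise AlignmentFormatError(
            f"removal would leave {len(keep)} taxa; at least 4 required"
        )
    rows = [sm.rows[sm.taxa.index(t)] for t in keep]
    return Supermatrix(
        taxa=keep,
        rows=rows,
        partitions=list(sm.partitions),
        gene_taxa=dict(sm.gene_taxa),
    )


# ---------------------------------------------------------------------------
# constraint-based gene screening


@dataclass
class CladeConstraintSet:
    """Named well-established clades plus the support threshold tau for
    declaring strong conflict."""

    clades: dict[str, frozenset[str]]
    tau: float = 0.95

    def __post_init__(self):
        if not (0 < self.tau <= 1):
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        self.clades = {k: frozenset(v) for k, v in self.clades.items()}
        for name, members in self.clades.items():
            if len(members) < 2:
                raise ValueError(f"constraint clade {name!r} needs >= 2 members")


@dataclass
class ScreenReport:
    """Verdict of constraint screening for one gene."""

    gene: str
    verdict: str  # "keep" | "exclude" | "unscreenable"
    conflicts: list[dict] = field(default_factory=list)
    tree: Optional[object] = None

    @property
    def keep(self) -> bool:
        return self.verdict == "keep"


def _splits_conflict(side: frozenset, clade: frozenset, universe: frozenset) -> bool:
    """Incompatibility of split side|universe-side with clade|universe-clade:
    all four pairwise intersections non-empty."""
    other = universe - side
    rest = universe - clade
    return bool(side & clade) and bool(side & rest) and bool(other & clade) and bool(other & rest)


def screen_gene(
    gene: GeneAlignment,
    constraints: CladeConstraintSet,
    n_bootstrap: int = 100,
    seed: int = 0,
    model_spec: str = "LG+G4",
) -> ScreenReport:
    """Screen one gene for strongly supported conflict with constraint clades.

    Builds a quick gene tree (NJ from ML pairwise distances, NNI refinement),
    then measures bootstrap support for each of its splits that is
    incompatible with a constraint clade restricted to the gene's taxa.
    Verdict is "exclude" iff some conflicting split reaches support >= tau.
    Genes overlapping fewer than 4 constraint-universe taxa are
    "unscreenable" rather than an error.
    """
    from . import likelihood
    from .models import parse_model_spec
    from .resampling import bootstrap_alignment
    from .treeops import Bipartition, restricted_bipartitions

    universe = set().union(*constraints.clades.values())
    usable = [t for t in gene.taxa if t in universe]
    if len(usable) < 4:
        return ScreenReport(gene=gene.name, verdict="unscreenable")

    model = parse_model_spec(model_spec, alignment=gene)
    settings = likelihood.SearchSettings.fast()
    tree, _ = likelihood.ml_tree_search(gene, model, seed=seed, settings=settings)
    gene_taxa = frozenset(gene.taxa)

    # splits of the quick tree conflicting with any restricted constraint clade
    suspects: list[tuple[str, Bipartition]] = []
    for bip in restricted_bipartitions(tree, gene_taxa):
        for cname, clade in constraints.clades.items():
            c = clade & gene_taxa
            if len(c) < 2 or len(gene_taxa - c) < 2:
                continue
            if _splits_conflict(bip.side, c, gene_taxa):
                suspects.append((cname, bip))
    if not suspects:
        return ScreenReport(gene=gene.name, verdict="keep", tree=tree)

    boot_bips = []
    for rep in range(n_bootstrap):
        rep_aln = bootstrap_alignment(gene, seed=seed + 1 + rep)
        rep_tree, _ = likelihood.ml_tree_search(
            rep_aln, model, seed=seed + 1 + rep, settings=settings
        )
        boot_bips.append(restricted_bipartitions(rep_tree, gene_taxa))

    conflicts = []
    for cname, bip in suspects:
        support = sum(bip in bb for bb in boot_bips) / n_bootstrap
        conflicts.append(
            {
                "clade": cname,
                "split": tuple(sorted(bip.side)),
                "support": support,
            }
        )
    strong = [c for c in conflicts if c["support"] >= constraints.tau]
    verdict = "exclude" if strong else "keep"
    return ScreenReport(gene=gene.name, verdict=verdict, conflicts=conflicts, tree=tree)


def screen_genes(
    genes: GeneAlignmentSet,
    constraints: CladeConstraintSet,
    n_bootstrap: int = 100,
    seed: int = 0,
    model_spec: str = "LG+G4",
) -> pd.DataFrame:
    """Screen every gene; returns a tidy report (gene, verdict, worst conflict)."""
    rows = []
    for i, g in enumerate(genes):
        rep = screen_gene(
            g, constraints, n_bootstrap=n_bootstrap, seed=seed + 997 * i,
            model_spec=model_spec,
        )
        worst = max((c["support"] for c in rep.conflicts), default=0.0)
        rows.append(
            {
                "gene": g.name,
                "verdict": rep.verdict,
                "n_conflicts": len(rep.conflicts),
                "max_conflict_support": worst,
            }
        )
    return pd.DataFrame(rows)
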