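"""Comparative analyses over species: Dollo gain/loss, clusters, regression.

Dollo parsimony allows each miRNA family a single evolutionary gain and
any number of subsequent losses.  On a fixed rooted species tree the
optimal mapping is direct: the gain sits on the edge subtending the last
common ancestor of all species carrying the family (or at the root, for
families constrained to be ancestral), and the losses are the edges
subtending the maximal all-absent subtrees inside the gain clade.

Genomic clusters are runs of precursor loci chained single-linkage along a
contig with inter-locus gaps up to ``max_gap`` (default 20 kb: wide enough
to keep a cluster with one >12 kb internal gap intact, narrow enough not
to chain typical intergenic distances).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from scipy import stats

from .core_io import ContractError, Locus

ABSENT = "absent"
PRESENT = "present"
PRESENT_NO_EXPRESSION = "present_no_expression"  # genomic hit, no reads

_STATE_CODE = {ABSENT: 0, PRESENT: 1, PRESENT_NO_EXPRESSION: 2}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}

ROOT_EDGE = "root"


@dataclass(frozen=True)
class PresenceMatrix:
    """Species x family presence states.

    ``present_no_expression`` (a family found in a genome assembly without
    read support) counts as present for parsimony purposes.
    """

    species: tuple[str, ...]
    families: tuple[str, ...]
    state: Mapping[tuple[str, str], str]

    def __post_init__(self) -> None:
        for sp in self.species:
            for fam in self.families:
                s = self.state.get((sp, fam))
                if s not in _STATE_CODE:
                    raise ContractError(
                        f"cell ({sp}, {fam}) undefined or invalid: {s!r}"
                    )

    def is_present(self, sp: str, fam: str) -> bool:
        return self.state[(sp, fam)] != ABSENT

    def present_species(self, fam: str) -> frozenset[str]:
        return frozenset(sp for sp in self.species if self.is_present(sp, fam))

    def families_of(self, sp: str) -> frozenset[str]:
        return frozenset(f for f in self.families if self.is_present(sp, f))

    def to_frame(self) -> pd.DataFrame:
        """Families x species frame coded 0/1/2 (absent/present/genomic-only)."""
        data = {
            sp: [_STATE_CODE[self.state[(sp, f)]] for f in self.families]
            for sp in self.species
        }
        return pd.DataFrame(data, index=list(self.families))


def build_presence_matrix(
    per_species_families: Mapping[str, Iterable[str]],
    genomic_only: Mapping[str, Iterable[str]] | None = None,
) -> PresenceMatrix:
    """Assemble a presence/absence matrix from per-species family sets.

    ``genomic_only`` marks families found in a genome but lacking
    expression evidence (state ``present_no_expression``).
    """
    if len(per_species_families) < 2:
        raise ContractError("need at least 2 species")
    genomic_only = {k: set(v) for k, v in (genomic_only or {}).items()}
    species = tuple(per_species_families)
    all_fams: set[str] = set()
    for fams in per_species_families.values():
        all_fams |= set(fams)
    for fams in genomic_only.values():
        all_fams |= set(fams)
    families = tuple(sorted(all_fams))
    state: dict[tuple[str, str], str] = {}
    for sp in species:
        fams = set(per_species_families[sp])
        gen = genomic_only.get(sp, set())
        for fam in families:
            if fam in gen:
                state[(sp, fam)] = PRESENT_NO_EXPRESSION
            elif fam in fams:
                state[(sp, fam)] = PRESENT
            else:
                state[(sp, fam)] = ABSENT
    return PresenceMatrix(species, families, state)


def write_matrix_tsv(matrix: PresenceMatrix, path) -> None:
    matrix.to_frame().rename_axis("family").to_csv(path, sep="\t")


def read_matrix_tsv(path) -> PresenceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    species = tuple(frame.columns)
    families = tuple(frame.index)
    state = {
        (sp, fam): _CODE_STATE[int(frame.at[fam, sp])]
        for sp in species
        for fam in families
    }
    return PresenceMatrix(species, families, state)


# ---------------------------------------------------------------------------
# Dollo gain/loss
# ---------------------------------------------------------------------------


@dataclass
class GainLoss:
    """Per-edge gained and lost families.

    Edges are keyed by the leaf label (terminal edges), by the ``+``-joined
    sorted leaf set of the subtended clade (internal edges), or by
    ``"root"`` for characters mapped to the root or earlier.
    """

    gains: dict[str, list[str]] = field(default_factory=dict)
    losses: dict[str, list[str]] = field(default_factory=dict)

    def n_gains(self, edge: str) -> int:
        return len(self.gains.get(edge, []))

    def n_losses(self, edge: str) -> int:
        return len(self.losses.get(edge, []))

    @property
    def total_gains(self) -> int:
        return sum(len(v) for v in self.gains.values())

    @property
    def total_losses(self) -> int:
        return sum(len(v) for v in self.losses.values())


def edge_key(node: dendropy.Node) -> str:
    """Stable identifier for the edge subtending ``node``."""
    if node.parent_node is None:
        return ROOT_EDGE
    leaves = [l.taxon.label for l in node.leaf_iter()]
    if len(leaves) == 1:
        return leaves[0]
    return "+".join(sorted(leaves))


def clade_edge_key(tree: dendropy.Tree, *labels: str) -> str:
    """Edge key of the smallest clade containing the given leaf labels."""
    node = tree.mrca(taxon_labels=list(labels))
    return edge_key(node)


def _subtree_has_present(node: dendropy.Node, present: frozenset[str]) -> bool:
    return any(l.taxon.label in present for l in node.leaf_iter())


def _maximal_absent_subtrees(
    node: dendropy.Node, present: frozenset[str]
) -> list[dendropy.Node]:
    """Roots of maximal subtrees below ``node`` containing no present leaf."""
    if not _subtree_has_present(node, present):
        return [node]
    out: list[dendropy.Node] = []
    for child in node.child_nodes():
        out.extend(_maximal_absent_subtrees(child, present))
    return out


def dollo_gain_loss(
    matrix: PresenceMatrix,
    tree: dendropy.Tree,
    root_present: Iterable[str] = (),
) -> GainLoss:
    """Dollo mapping of every family in ``matrix`` onto ``tree``.

    Families in ``root_present`` are constrained to be ancestral: no gain
    is recorded (it predates the tree) and only losses are inferred.  Every
    other family gains once, on the edge subtending the LCA of its present
    species, and loses on the minimal edge set explaining all absences
    inside that clade.  A family present in no species yields a warning and
    no events.
    """
    leaf_labels = {l.taxon.label for l in tree.leaf_node_iter()}
    if set(matrix.species) != leaf_labels:
        raise ContractError(
            f"matrix species {sorted(matrix.species)} do not match tree "
            f"leaves {sorted(leaf_labels)}"
        )
    root_present = set(root_present)
    result = GainLoss()
    for fam in matrix.families:
        present = matrix.present_species(fam)
        constrained = fam in root_present
        if not present and not constrained:
            warnings.warn(f"family {fam} present in no species; skipped")
            continue
        if constrained:
            loss_nodes = _maximal_absent_subtrees(tree.seed_node, present)
        else:
            mrca = tree.mrca(taxon_labels=sorted(present))
            result.gains.setdefault(edge_key(mrca), []).append(fam)
            loss_nodes = _maximal_absent_subtrees(mrca, present)
        for node in loss_nodes:
            result.losses.setdefault(edge_key(node), []).append(fam)
    return result


def gain_loss_table(gl: GainLoss) -> pd.DataFrame:
    edges = sorted(set(gl.gains) | set(gl.losses))
    return pd.DataFrame(
        {
            "edge": edges,
            "n_gains": [gl.n_gains(e) for e in edges],
            "n_losses": [gl.n_losses(e) for e in edges],
            "gained": [",".join(sorted(gl.gains.get(e, []))) for e in edges],
            "lost": [",".join(sorted(gl.losses.get(e, []))) for e in edges],
        }
    )


# ---------------------------------------------------------------------------
# Genomic clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MiRNACluster:
    members: tuple[Locus, ...]

    def __post_init__(self) -> None:
        ids = {m.seq_id for m in self.members}
        if len(ids) != 1:
            raise ContractError("cluster members span multiple contigs")

    @property
    def span_bp(self) -> int:
        return max(m.end for m in self.members) - min(m.start for m in self.members)

    @property
    def seq_id(self) -> str:
        return self.members[0].seq_id


def detect_clusters(
    loci: Sequence[Locus],
    max_gap: int = 20_000,
    min_members: int = 2,
) -> list[MiRNACluster]:
    """Chain loci on each contig into clusters (strand-agnostic).

    Consecutive loci whose gap (next start minus running max end) is at
    most ``max_gap`` join a cluster; singletons are dropped unless
    ``min_members`` says otherwise.  Output is independent of input order.
    """
    by_contig: dict[str, list[Locus]] = {}
    for locus in loci:
        by_contig.setdefault(locus.seq_id, []).append(locus)
    clusters: list[MiRNACluster] = []
    for sid in sorted(by_contig):
        chain: list[Locus] = []
        chain_end = None
        for locus in sorted(by_contig[sid], key=lambda l: (l.start, l.end)):
            if chain and locus.start - chain_end > max_gap:
                if len(chain) >= min_members:
                    clusters.append(MiRNACluster(tuple(chain)))
                chain = []
                chain_end = None
            chain.append(locus)
            chain_end = locus.end if chain_end is None else max(chain_end, locus.end)
        if len(chain) >= min_members:
            clusters.append(MiRNACluster(tuple(chain)))
    return clusters


def cluster_size_regression(
    points: Sequence[tuple[float, float]]
) -> tuple[float, float, float]:
    """OLS of mean cluster length (kb) on genome size (Gbp).

    Returns (slope, intercept, r_squared) where r_squared is the squared
    Pearson correlation.
    """
    if len(points) < 3:
        raise ContractError("regression needs at least 3 points")
    x = [p[0] for p in points]
    y = [p[1] for p in points]
    if len(set(x)) < 2:
        raise ContractError("zero variance in genome size")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)
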