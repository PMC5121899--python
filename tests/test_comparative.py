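"""Presence matrices, Dollo gain/loss (with exhaustive oracle), clusters."""

import itertools

import numpy as np
import pytest

from mircurate import comparative
from mircurate.comparative import (
    build_presence_matrix,
    clade_edge_key,
    cluster_size_regression,
    detect_clusters,
    dollo_gain_loss,
    edge_key,
)
from mircurate.core_io import ContractError, Locus, parse_tree

from .conftest import ENDO_PRESENCE, SPECIES_TREE_NEWICK

SPECIES = ["Bge", "Lmi", "Api", "Ame", "Tca", "Bmo", "Dme"]

# the same topology as SPECIES_TREE_NEWICK, as nested tuples for the oracle
NESTED = (("Bge", "Lmi"), ("Api", ("Ame", ("Tca", ("Bmo", "Dme")))))


def _matrix(per_family: dict[str, set[str]]):
    return build_presence_matrix(
        {s: {f for f, v in per_family.items() if s in v} for s in SPECIES}
    )


def dollo_cost_oracle(pattern: frozenset[str], root_constrained: bool) -> int:
    """Exhaustive minimum of gains+losses under the single-gain rule.

    Enumerates every presence/absence assignment to internal nodes of the
    fixed 7-leaf topology; a gain is a 0->1 edge (or presence at the root),
    a loss a 1->0 edge; at most one gain per character, none if the root
    state is constrained present.
    """
    nodes: list = []

    def collect(t):
        nodes.append(t)
        if isinstance(t, tuple):
            for c in t:
                collect(c)

    collect(NESTED)
    internals = [n for n in nodes if isinstance(n, tuple)]

    def leaf_state(leaf):
        return 1 if leaf in pattern else 0

    best = None
    for states in itertools.product([0, 1], repeat=len(internals)):
        assign = dict(zip(map(id, internals), states))

        def state(n):
            return assign[id(n)] if isinstance(n, tuple) else leaf_state(n)

        root_state = state(NESTED)
        if root_constrained and root_state != 1:
            continue
        gains = 0 if root_constrained else root_state
        losses = 0
        ok = True
        for parent in internals:
            for child in parent:
                ps, cs = state(parent), state(child)
                if cs > ps:
                    gains += 1
                elif cs < ps:
                    losses += 1
        if root_constrained and gains > 0:
            ok = False
        if not root_constrained and gains != 1:
            ok = False  # a character observed somewhere must arise exactly once
        if ok:
            cost = gains + losses
            if best is None or cost < best:
                best = cost
    return best


class TestPresenceMatrix:
    def test_union_and_explicit_absence(self):
        m = build_presence_matrix({"A": {"f1"}, "B": {"f1", "f2"}})
        assert m.state[("A", "f2")] == "absent"
        assert m.is_present("B", "f2")

    def test_all_absent_row(self):
        m = build_presence_matrix({"A": set(), "B": {"f1"}})
        assert m.families_of("A") == frozenset()

    def test_published_endopterygote_pattern(self):
        m = _matrix(ENDO_PRESENCE)
        assert [int(m.is_present(s, "MIR-989")) for s in SPECIES] == [
            0, 0, 0, 1, 1, 1, 1,
        ]

    def test_genomic_only_counts_as_present(self):
        m = build_presence_matrix(
            {"A": {"f1"}, "B": set()}, genomic_only={"B": {"f1"}}
        )
        assert m.state[("B", "f1")] == "present_no_expression"
        assert m.is_present("B", "f1")

    def test_tsv_roundtrip(self, tmp_path):
        m = build_presence_matrix(
            {"A": {"f1"}, "B": {"f2"}}, genomic_only={"A": {"f2"}}
        )
        p = tmp_path / "m.tsv"
        comparative.write_matrix_tsv(m, p)
        back = comparative.read_matrix_tsv(p)
        assert back.state == m.state


class TestDollo:
    def test_endopterygote_origin_single_gain(self):
        tree = parse_tree(SPECIES_TREE_NEWICK)
        gl = dollo_gain_loss(_matrix({"MIR-989": ENDO_PRESENCE["MIR-989"]}), tree)
        endo = clade_edge_key(tree, "Ame", "Tca", "Bmo", "Dme")
        assert gl.gains[endo] == ["MIR-989"]
        assert gl.total_losses == 0

    def test_root_constrained_family_lost_once(self):
        tree = parse_tree(SPECIES_TREE_NEWICK)
        gl = dollo_gain_loss(
            _matrix({"MIR-bg5": ENDO_PRESENCE["MIR-bg5"]}),
            tree,
            root_present={"MIR-bg5"},
        )
        endo = clade_edge_key(tree, "Ame", "Tca", "Bmo", "Dme")
        assert gl.total_gains == 0
        assert gl.losses[endo] == ["MIR-bg5"]

    def test_two_terminal_losses(self):
        tree = parse_tree(SPECIES_TREE_NEWICK)
        gl = dollo_gain_loss(_matrix({"MIR-1007": {"Ame", "Dme"}}), tree)
        assert gl.n_losses("Tca") == 1
        assert gl.n_losses("Bmo") == 1
        assert gl.total_gains == 1 and gl.total_losses == 2

    def test_family_in_all_leaves_gains_at_root(self):
        tree = parse_tree(SPECIES_TREE_NEWICK)
        gl = dollo_gain_loss(_matrix({"MIR-2": set(SPECIES)}), tree)
        assert gl.gains[comparative.ROOT_EDGE] == ["MIR-2"]
        assert gl.total_losses == 0

    def test_absent_family_warns_and_skips(self):
        tree = parse_tree(SPECIES_TREE_NEWICK)
        m = comparative.PresenceMatrix(
            tuple(SPECIES),
            ("MIR-x",),
            {(s, "MIR-x"): "absent" for s in SPECIES},
        )
        with pytest.warns(UserWarning):
            gl = dollo_gain_loss(m, tree)
        assert gl.total_gains == 0 and gl.total_losses == 0

    def test_leaf_mismatch_rejected(self):
        tree = parse_tree("(A,B);")
        with pytest.raises(ContractError):
            dollo_gain_loss(_matrix({"f": {"Bge"}}), tree)

    def test_exhaustive_oracle_all_patterns(self):
        """Gain+loss totals equal the enumeration minimum for all 2^7
        presence patterns, with and without the root constraint."""
        tree = parse_tree(SPECIES_TREE_NEWICK)
        for bits in range(1, 2**7):
            pattern = frozenset(
                s for k, s in enumerate(SPECIES) if bits >> k & 1
            )
            m = _matrix({"fam": set(pattern)})
            gl = dollo_gain_loss(m, tree)
            assert gl.total_gains + gl.total_losses == dollo_cost_oracle(
                pattern, root_constrained=False
            ), pattern
            gl_rc = dollo_gain_loss(m, tree, root_present={"fam"})
            assert gl_rc.total_gains + gl_rc.total_losses == dollo_cost_oracle(
                pattern, root_constrained=True
            ), pattern

    def test_total_gains_conserved(self):
        tree = parse_tree(SPECIES_TREE_NEWICK)
        m = _matrix(ENDO_PRESENCE)
        gl = dollo_gain_loss(m, tree, root_present={"MIR-bg5"})
        non_root = [f for f in m.families if f != "MIR-bg5"]
        assert gl.total_gains == len(non_root)


def _loci_with_gaps(gaps_kb):
    loci = []
    pos = 1000
    for i, gap in enumerate([0.0] + list(gaps_kb)):
        pos += int(gap * 1000)
        loci.append(Locus("scf1", pos, pos + 80))
        pos += 80
    return loci


class TestClusters:
    def test_large_internal_gap_kept_at_default(self):
        loci = _loci_with_gaps([0.5, 1, 12.5, 0.8, 1.2])
        clusters = detect_clusters(loci, max_gap=20_000)
        assert len(clusters) == 1
        assert len(clusters[0].members) == 6

    def test_split_at_tighter_gap(self):
        loci = _loci_with_gaps([0.5, 1, 12.5, 0.8, 1.2])
        clusters = detect_clusters(loci, max_gap=10_000)
        assert [len(c.members) for c in clusters] == [3, 3]

    def test_singleton_not_emitted(self):
        assert detect_clusters([Locus("scf1", 10, 90)]) == []

    def test_order_invariance(self):
        loci = _loci_with_gaps([1, 2, 30, 1])
        shuffled = [loci[i] for i in (3, 0, 4, 2, 1)]
        assert detect_clusters(loci) == detect_clusters(shuffled)

    def test_monotone_in_max_gap(self):
        """Growing max_gap only merges clusters, never splits them."""
        rng = np.random.default_rng(5)
        loci = _loci_with_gaps(rng.integers(1, 40, size=12).tolist())
        prev = None
        for gap in (2_000, 5_000, 10_000, 20_000, 50_000):
            clusters = detect_clusters(loci, max_gap=gap)
            if prev is not None:
                # every previous cluster is contained in one current cluster
                # (singletons may newly join, so the count is not monotone)
                for old in prev:
                    assert any(
                        set(old.members) <= set(new.members) for new in clusters
                    )
            prev = clusters

    def test_span(self):
        loci = [Locus("s", 100, 180), Locus("s", 1000, 1100)]
        (c,) = detect_clusters(loci, max_gap=2_000)
        assert c.span_bp == 1000


class TestRegression:
    def test_collinear(self):
        slope, intercept, r2 = cluster_size_regression([(1, 2), (2, 4), (3, 6)])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0)
        assert r2 == pytest.approx(1.0)

    def test_hand_computed(self):
        _s, _i, r2 = cluster_size_regression([(1, 2), (2, 3), (3, 5)])
        assert r2 == pytest.approx(0.9643, abs=1e-4)

    def test_noise_degrades_fit_in_expectation(self):
        rng = np.random.default_rng(0)
        x = np.array([0.12, 0.2, 0.25, 0.39, 0.48, 2.0])
        y = 6 * x + 1
        r2_small, r2_big = [], []
        for _ in range(30):
            r2_small.append(
                cluster_size_regression(
                    list(zip(x, y + rng.normal(0, 0.2, size=6)))
                )[2]
            )
            r2_big.append(
                cluster_size_regression(
                    list(zip(x, y + rng.normal(0, 3.0, size=6)))
                )[2]
            )
        assert np.mean(r2_small) > np.mean(r2_big)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ContractError):
            cluster_size_regression([(1, 2), (1, 3), (1, 4)])
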