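import itertools

import numpy as np
import pytest

from cocult.phylogeny import (
    DistanceMatrix,
    SaturationError,
    Supermatrix,
    bootstrap_support,
    concatenate,
    distance_matrix,
    logdet_distance,
    nj_tree,
)
from cocult.seq_io import SeqRecord, newick_to_tree, tree_to_newick


def bipartitions(tree):
    leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    anchor = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


# ---------------------------------------------------------------------------
# concatenate
# ---------------------------------------------------------------------------

class TestConcatenate:
    def test_widths_add_up(self):
        blocks = {
            "f1": [SeqRecord("a", "A" * 10), SeqRecord("b", "C" * 10)],
            "f2": [SeqRecord("a", "G" * 20), SeqRecord("b", "T" * 20)],
        }
        m = concatenate(blocks, ["a", "b"], ["f1", "f2"])
        assert m.n_columns == 30
        assert m.boundaries == [("f1", 1, 10), ("f2", 11, 30)]

    def test_absent_genome_gets_gap_segment(self):
        blocks = {
            "f1": [SeqRecord("a", "ACGTACGTAC"), SeqRecord("b", "ACGTACGTAC")],
            "f2": [SeqRecord("a", "G" * 20)],
        }
        m = concatenate(blocks, ["a", "b"], ["f1", "f2"])
        assert m.rows["b"][10:30] == "-" * 20

    def test_duplicate_genome_in_block_rejected(self):
        blocks = {"f1": [SeqRecord("a", "ACGT"), SeqRecord("a", "TTTT")]}
        with pytest.raises(ValueError, match="duplicate"):
            concatenate(blocks, ["a"], ["f1"])

    def test_columns_match_direct_lookup(self, rng):
        bases = np.array(list("ACGT-"))
        genomes = [f"g{i}" for i in range(6)]
        blocks = {}
        widths = {}
        for j in range(5):
            fam = f"f{j}"
            widths[fam] = int(rng.integers(5, 30))
            present = [g for g in genomes if rng.random() < 0.8]
            blocks[fam] = [
                SeqRecord(g, "".join(bases[rng.integers(0, 5, widths[fam])]))
                for g in present
            ]
        order = sorted(blocks)
        m = concatenate(blocks, genomes, order)
        for fam, start, end in m.boundaries:
            rows = {r.id: r.sequence for r in blocks[fam]}
            for g in genomes:
                seg = m.rows[g][start - 1 : end]
                assert seg == rows.get(g, "-" * widths[fam])


# ---------------------------------------------------------------------------
# LogDet
# ---------------------------------------------------------------------------

def brute_force_logdet(x, y):
    """Independent formula evaluation: build F, marginals and determinant
    directly from pair counts."""
    idx = {b: i for i, b in enumerate("ACGT")}
    F = np.zeros((4, 4))
    for a, b in zip(x, y):
        if a in idx and b in idx:
            F[idx[a], idx[b]] += 1
    F /= F.sum()
    r, c = F.sum(axis=1), F.sum(axis=0)
    keep = (r > 0) | (c > 0)
    F = F[np.ix_(keep, keep)]
    r, c = r[keep], c[keep]
    return -0.25 * (np.log(np.linalg.det(F)) - 0.5 * np.sum(np.log(r * c)))


def simulate_pair(rng, n_sites, p_sub):
    bases = np.array(list("ACGT"))
    x = rng.integers(0, 4, n_sites)
    mask = rng.random(n_sites) < p_sub
    y = x.copy()
    y[mask] = (y[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    return "".join(bases[x]), "".join(bases[y])


class TestLogDet:
    @pytest.mark.parametrize("seq", ["ACGTACGT", "AAAACCCC", "ACACACAC"])
    def test_identical_sequences_have_zero_distance(self, seq):
        assert logdet_distance(seq, seq) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        x, y = simulate_pair(rng, 500, 0.2)
        assert logdet_distance(x, y) == pytest.approx(logdet_distance(y, x))

    def test_matches_independent_formula_evaluation(self, rng):
        for p in (0.05, 0.2, 0.5):
            x, y = simulate_pair(rng, 1000, p)
            assert logdet_distance(x, y) == pytest.approx(
                brute_force_logdet(x, y), abs=1e-10
            )

    def test_gapped_sites_excluded_pairwise(self, rng):
        x, y = simulate_pair(rng, 400, 0.1)
        xg = "--" + x[2:]
        yg = y[:-2] + "NN"
        usable = [
            (a, b) for a, b in zip(xg, yg) if a in "ACGT" and b in "ACGT"
        ]
        expected = brute_force_logdet(
            "".join(a for a, _ in usable), "".join(b for _, b in usable)
        )
        assert logdet_distance(xg, yg) == pytest.approx(expected, abs=1e-10)

    def test_approaches_jukes_cantor_at_low_divergence(self, rng):
        """Under equal base frequencies LogDet and the JC distance
        -(3/4) ln(1 - 4p/3) agree within 5% relative at p <= 0.1."""
        for p in (0.02, 0.05, 0.1):
            x, y = simulate_pair(rng, 200_000, p)
            observed_p = sum(a != b for a, b in zip(x, y)) / len(x)
            jc = -0.75 * np.log(1 - 4 * observed_p / 3)
            ld = logdet_distance(x, y)
            assert abs(ld - jc) / jc < 0.05

    def test_no_usable_sites_is_an_error(self):
        with pytest.raises(SaturationError):
            logdet_distance("----", "ACGT")

    def test_saturation_is_an_error(self):
        # maximally scrambled pair: det F <= 0
        x = "A" * 50 + "C" * 50
        y = "C" * 50 + "A" * 50
        with pytest.raises(SaturationError):
            logdet_distance(x, y)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            logdet_distance("ACGT", "ACG")


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies by recursive edge insertion.

    Trees are nested frozensets of leaf names (an unrooted tree is the set
    of its non-trivial bipartitions here)."""
    # start from the 3-leaf star, attach each further leaf to every edge of
    # every tree generated so far
    trees = [f"({taxa[0]},{taxa[1]},{taxa[2]})"]
    for leaf in taxa[3:]:
        nxt = []
        for t in trees:
            # edges correspond to every node position; simplest: parse and
            # re-serialise via tuples
            nxt.extend(_insert_everywhere(_parse(t), leaf))
        trees = [_fmt(t) for t in nxt]
    return trees


def _parse(s):
    s = s.strip().rstrip(";")
    if not s.startswith("("):
        return s
    depth, parts, cur = 0, [], ""
    for ch in s[1:-1]:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            parts.append(cur)
            cur = ""
        else:
            cur += ch
    parts.append(cur)
    return tuple(_parse(p) for p in parts)


def _fmt(t):
    if isinstance(t, str):
        return t
    return "(" + ",".join(_fmt(c) for c in t) + ")"


def _insert_everywhere(tree, leaf):
    """Attach ``leaf`` to every edge of the unrooted tree."""
    out = []

    def walk(node, rebuild):
        # replace this subtree S by (S, leaf)
        out.append(rebuild((node, leaf)))
        if isinstance(node, tuple):
            for i, child in enumerate(node):
                walk(
                    child,
                    lambda sub, i=i, node=node: rebuild(
                        tuple(sub if j == i else c for j, c in enumerate(node))
                    ),
                )

    assert isinstance(tree, tuple) and len(tree) == 3
    for i, child in enumerate(tree):
        walk(
            child,
            lambda sub, i=i: tuple(
                sub if j == i else c for j, c in enumerate(tree)
            ),
        )
    return out


def additive_matrix_from_newick(nwk, taxa):
    tree = newick_to_tree(nwk + ";")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(taxa)
    d = np.zeros((n, n))
    tax = {t.label: t for t in tree.taxon_namespace}
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(tax[a], tax[taxa[j]])
    return DistanceMatrix(taxa, d)


def with_lengths(t, rng):
    if isinstance(t, str):
        return f"{t}:{rng.uniform(0.1, 1.0):.6f}"
    inner = ",".join(with_lengths(c, rng) for c in t)
    return f"({inner}):{rng.uniform(0.1, 1.0):.6f}"


class TestNeighbourJoining:
    def test_three_taxa_closed_form(self):
        d = DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float),
        )
        tree = nj_tree(d)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        # la = (dab + dac - dbc)/2 etc.
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # tree ((a:1,b:2):3,(c:4,d:5)) -> additive distances
        taxa = ["a", "b", "c", "d"]
        d = additive_matrix_from_newick("((a:1,b:2):3,c:4,d:5)", taxa)
        tree = nj_tree(d)
        # the only non-trivial unrooted split is ab|cd
        assert bipartitions(tree) == {frozenset({"c", "d"})}
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        for i, a in enumerate(taxa):
            for b in taxa[i + 1 :]:
                assert pdm.distance(tax[a], tax[b]) == pytest.approx(
                    d.values[taxa.index(a), taxa.index(b)]
                )

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_exact_recovery_for_every_topology(self, rng, n_taxa):
        taxa = [f"t{i}" for i in range(n_taxa)]
        topologies = enumerate_unrooted_topologies(taxa)
        assert len(topologies) == {4: 3, 5: 15}[n_taxa]
        for topo in topologies:
            nwk = with_lengths(_parse(topo), rng).rsplit(":", 1)[0]
            d = additive_matrix_from_newick(nwk, taxa)
            expected = bipartitions(newick_to_tree(nwk + ";"))
            assert bipartitions(nj_tree(d)) == expected

    @pytest.mark.parametrize("seed", range(50))
    def test_eight_taxon_additive_matrices_recovered(self, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(8)]
        nodes = list(taxa)
        while len(nodes) > 3:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            nodes.append(
                f"({a}:{rng.uniform(0.1, 1):.5f},{b}:{rng.uniform(0.1, 1):.5f})"
            )
        nwk = (
            "("
            + ",".join(f"{n}:{rng.uniform(0.1, 1):.5f}" for n in nodes)
            + ")"
        )
        d = additive_matrix_from_newick(nwk, taxa)
        assert bipartitions(nj_tree(d)) == bipartitions(newick_to_tree(nwk + ";"))

    def test_agrees_with_scikit_bio_on_random_matrix(self, rng):
        import skbio

        taxa = [f"t{i}" for i in range(7)]
        m = rng.uniform(0.2, 1.0, size=(7, 7))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        ours = nj_tree(DistanceMatrix(taxa, m))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(m, ids=taxa))
        theirs_dendropy = newick_to_tree(str(theirs))
        assert bipartitions(ours) == bipartitions(theirs_dendropy)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_negative_branch_lengths_clamped(self, rng):
        # a strongly non-additive matrix can push an NJ branch negative
        for _ in range(20):
            m = rng.uniform(0.1, 1.0, size=(5, 5))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            tree = nj_tree(DistanceMatrix([f"t{i}" for i in range(5)], m))
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    assert edge.length >= 0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def duplicated_clade_matrix(rng, n_per_clade=4, n_cols=400):
    """Two clades of identical sequences with strong between-clade signal."""
    bases = np.array(list("ACGT"))
    a = bases[rng.integers(0, 4, n_cols)]
    b = a.copy()
    flip = rng.random(n_cols) < 0.35
    b[flip] = bases[(np.searchsorted(bases, b[flip]) + 2) % 4]
    rows = {}
    for i in range(n_per_clade):
        noise_a = a.copy()
        noise_b = b.copy()
        for arr in (noise_a, noise_b):
            m = rng.random(n_cols) < 0.02
            arr[m] = bases[rng.integers(0, 4, int(m.sum()))]
        rows[f"a{i}"] = "".join(noise_a)
        rows[f"b{i}"] = "".join(noise_b)
    return Supermatrix(sorted(rows), rows, [("f", 1, n_cols)])


class TestBootstrap:
    def test_supports_are_integer_percentages(self, rng):
        m = duplicated_clade_matrix(rng)
        tree = bootstrap_support(m, n_reps=20, seed=1)
        for node in tree.preorder_node_iter():
            if not node.is_leaf() and node.parent_node is not None and node.label:
                assert 0 <= int(node.label) <= 100

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_split_gets_high_support(self, seed):
        rng = np.random.default_rng(seed + 1000)
        m = duplicated_clade_matrix(rng)
        tree = bootstrap_support(m, n_reps=50, seed=seed)
        split = frozenset({"b0", "b1", "b2", "b3"})
        found = None
        leaves = {l.taxon.label for l in tree.leaf_node_iter()}
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if side == split or side == frozenset(leaves - split):
                found = int(node.label)
        assert found is not None and found >= 95

    def test_zero_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_support(duplicated_clade_matrix(rng), n_reps=0, seed=1)

    def test_same_seed_gives_identical_supports(self, rng):
        m = duplicated_clade_matrix(rng)
        t1 = bootstrap_support(m, n_reps=30, seed=7)
        t2 = bootstrap_support(m, n_reps=30, seed=7)
        assert tree_to_newick(t1) == tree_to_newick(t2)

    def test_too_few_taxa_rejected(self):
        m = Supermatrix(["a", "b", "c"], {"a": "ACGT", "b": "ACGT", "c": "ACGT"},
                        [("f", 1, 4)])
        with pytest.raises(ValueError):
            bootstrap_support(m, n_reps=10, seed=1)


class TestEndToEndPlacement:
    @pytest.mark.parametrize("seed", range(10))
    def test_planted_genome_lands_in_its_sister_clade(self, seed):
        """On a generated marker scenario the concatenated NJ tree must
        place each genome with its conspecific partner (the planted
        sister-clade analogue of a correct phylogenomic placement)."""
        from cocult import generate_marker_scenario, select_markers
        from conftest import small_marker_params

        ms = generate_marker_scenario(small_marker_params(seed=seed))
        sel = select_markers(ms.presence, ms.gene_tree_objects())
        blocks = {f: ms.blocks[f] for f in sel.retained}
        matrix = concatenate(blocks, ms.presence.genomes, sel.retained)
        tree = nj_tree(distance_matrix(matrix))
        bps = bipartitions(tree)
        leaves = frozenset(ms.presence.genomes)
        # every species' genome pair should be a recovered cherry (either
        # side of the split may be the stored representative)
        pairs = {}
        for g, s in ms.truth.species.items():
            pairs.setdefault(s, []).append(g)
        recovered = sum(
            1
            for gs in pairs.values()
            if len(gs) < 2
            or frozenset(gs) in bps
            or leaves - frozenset(gs) in bps
        )
        assert recovered / len(pairs) >= 0.95
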