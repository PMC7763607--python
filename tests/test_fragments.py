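"""Fragment enumeration against an independent brute-force oracle."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from fragbb.fragments import (
    BOND_SYMBOL,
    DescriptorMatrix,
    FragmentFeaturizer,
    atom_labels,
    build_matrix,
    enumerate_fragments,
    filter_rare,
)
from fragbb.molgraph import CompoundRecord, MolecularGraph, parse_structure
from fragbb.synthdata import SyntheticSpec, generate_dataset, make_toy_fixtures

from conftest import DRUGLIKE_SMILES


# ---------------------------------------------------------------------------
# independent oracle: exhaustive subset enumeration + its own canonicalization

def oracle_counts(graph: MolecularGraph, max_atoms: int, level: int):
    """Brute force over all atom subsets; independent of the package's
    root-anchored enumerator and of its string canonicalization."""
    labels = atom_labels(graph, level)
    lut = graph.bond_lookup()
    n = graph.n_atoms
    counts = {}
    for size in range(1, max_atoms + 1):
        for subset in itertools.combinations(range(n), size):
            sub = set(subset)
            edges = [
                (i, j) for i, j in itertools.combinations(sorted(sub), 2)
                if (i, j) in lut
            ]
            if not _connected(sub, edges):
                continue
            frag = _oracle_key(sub, edges, labels, lut)
            if frag is not None:
                counts[frag] = counts.get(frag, 0) + 1
    return counts


def _connected(sub, edges):
    if len(sub) == 1:
        return True
    adj = {v: set() for v in sub}
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen = set()
    stack = [next(iter(sub))]
    while stack:
        v = stack.pop()
        if v in seen:
            continue
        seen.add(v)
        stack.extend(adj[v] - seen)
    return seen == sub


def _oracle_key(sub, edges, labels, lut):
    """Classify and canonicalize as nested tuples (not strings)."""
    deg = {v: 0 for v in sub}
    adj = {v: [] for v in sub}
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
        adj[i].append(j)
        adj[j].append(i)
    bond = lambda a, b: BOND_SYMBOL[lut[(min(a, b), max(a, b))]]
    n, m = len(sub), len(edges)
    if m == n - 1:
        branching = [v for v in sub if deg[v] >= 3]
        if not branching:
            if n == 1:
                return ("path", (labels[next(iter(sub))],))
            ends = [v for v in sub if deg[v] <= 1]
            seqs = []
            for start in ends:
                seq, prev, cur = [labels[start]], None, start
                while True:
                    nxt = [u for u in adj[cur] if u != prev]
                    if not nxt:
                        break
                    seq.extend([bond(cur, nxt[0]), labels[nxt[0]]])
                    prev, cur = cur, nxt[0]
                seqs.append(tuple(seq))
            return ("path", min(seqs))
        if len(branching) == 1:
            center = branching[0]
            rays = []
            for first in adj[center]:
                ray, prev, cur = [bond(center, first), labels[first]], center, first
                while True:
                    nxt = [u for u in adj[cur] if u != prev]
                    if not nxt:
                        break
                    ray.extend([bond(cur, nxt[0]), labels[nxt[0]]])
                    prev, cur = cur, nxt[0]
                rays.append(tuple(ray))
            return ("branch", labels[center], tuple(sorted(rays)))
        return None
    if m == n and n >= 3 and all(d == 2 for d in deg.values()):
        # all closed walks, both directions, every start
        best = None
        for start in sub:
            for first in adj[start]:
                walk, prev, cur = [start], start, first
                while cur != start:
                    walk.append(cur)
                    nxt = [u for u in adj[cur] if u != prev][0]
                    prev, cur = cur, nxt
                seq = []
                for k, v in enumerate(walk):
                    seq.append(labels[v])
                    seq.append(bond(v, walk[(k + 1) % n]))
                seq = tuple(seq)
                if best is None or seq < best:
                    best = seq
        return ("cycle", best)
    return None


def _compare(impl, oracle):
    """Exact agreement between implementation and oracle: total counts,
    per-topology totals, and the multiset of per-fragment counts within
    each topology (canonical forms differ in representation — strings vs
    tuples — so fragments are matched by their count distribution)."""
    assert sum(impl.values()) == sum(oracle.values())
    for topo in ("path", "cycle", "branch"):
        impl_topo = sorted(
            v for k, v in impl.items() if f"|{topo}|" in k
        )
        oracle_topo = sorted(v for k, v in oracle.items() if k[0] == topo)
        assert impl_topo == oracle_topo, f"{topo} fragments disagree"


ORACLE_MOLECULES = [
    "C1CC1", "C1CCC1", "C1CCCC1", "CC1CC1C",
    "C1CC2CC12", "c1ccc2ccccc2c1", "C(C)(C)(C)C", "CC(C)(C)CC(C)(C)C",
    "O=C1CCCCC1", "C1COCCN1", "c1cc[nH]c1", "OCC(O)CO",
    "CC(=O)NC", "FC(F)(F)c1ccccc1", "O=S(=O)(N)C", "c1ccncc1C(=O)O",
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("level", [1, 2, 3])
    @pytest.mark.parametrize("smiles", ORACLE_MOLECULES)
    def test_fixed_molecules(self, smiles, level):
        g = parse_structure(smiles)
        impl = enumerate_fragments(g, min(10, g.n_atoms), (level,))
        oracle = oracle_counts(g, min(10, g.n_atoms), level)
        _compare(impl, oracle)

    def test_many_random_graphs(self):
        """>=200 random molecular graphs of <=10 atoms, exact count match."""
        records, _ = generate_dataset(
            SyntheticSpec(n_compounds=500, noise_sd=0.0, seed=11)
        )
        graphs = [r.graph for r in records if r.graph.n_atoms <= 10][:200]
        assert len(graphs) >= 200
        for g in graphs:
            _compare(
                enumerate_fragments(g, 10, (1,)), oracle_counts(g, 10, 1)
            )


class TestToyFixtures:
    def test_fixture_suite_size(self):
        assert len(make_toy_fixtures()) >= 10

    @pytest.mark.parametrize(
        "fixture", make_toy_fixtures(), ids=lambda f: f.name
    )
    def test_hand_enumerated_counts(self, fixture):
        g = parse_structure(fixture.smiles, "smiles", fixture.name)
        got = enumerate_fragments(g, fixture.max_atoms, (fixture.level,))
        assert got == dict(fixture.expected_counts)


class TestEnumerationProperties:
    @pytest.mark.parametrize("smiles", DRUGLIKE_SMILES[:10])
    def test_permutation_invariance(self, smiles):
        mol = Chem.MolFromSmiles(smiles)
        order = list(range(mol.GetNumAtoms()))[::-1]
        shuffled = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order),
                                    canonical=False)
        a = enumerate_fragments(parse_structure(smiles), 6)
        b = enumerate_fragments(parse_structure(shuffled), 6)
        assert a == b

    @pytest.mark.parametrize("smiles", DRUGLIKE_SMILES[:10])
    def test_level_refinement(self, smiles):
        """Level-3 counts, summed over refinements, reproduce level-1 counts."""
        g = parse_structure(smiles)
        l1 = enumerate_fragments(g, 5, (1,))
        l3 = enumerate_fragments(g, 5, (3,))
        assert sum(l1.values()) == sum(l3.values())
        # per-topology totals must also agree
        for topo in ("path", "cycle", "branch"):
            t1 = sum(v for k, v in l1.items() if f"|{topo}|" in k)
            t3 = sum(v for k, v in l3.items() if f"|{topo}|" in k)
            assert t1 == t3

    @pytest.mark.parametrize("smiles", DRUGLIKE_SMILES[:10])
    def test_monotonicity_in_max_atoms(self, smiles):
        g = parse_structure(smiles)
        small = enumerate_fragments(g, 4, (1,))
        large = enumerate_fragments(g, 7, (1,))
        for key, count in small.items():
            assert large.get(key) == count

    def test_direction_symmetry_of_path_keys(self):
        counts = enumerate_fragments(parse_structure("NCO"), 3, (1,))
        keys = [k for k in counts if k.count("|") == 2]
        # N-C-O written in either direction is one fragment
        assert counts.get("L1|path|N-C-O", 0) == 1
        assert "L1|path|O-C-N" not in counts

    def test_bond_order_distinguishes(self):
        sat = enumerate_fragments(parse_structure("CCO"), 3, (1,))
        uns = enumerate_fragments(parse_structure("CC=O"), 3, (1,))
        assert "L1|path|C-C-O" in sat
        assert "L1|path|C-C=O" in uns
        assert "L1|path|C-C=O" not in sat

    def test_methane_single_fragment(self):
        for level in (1, 2, 3):
            counts = enumerate_fragments(parse_structure("C"), 3, (level,))
            assert len(counts) == 1
            assert list(counts.values()) == [1]

    @pytest.mark.parametrize("level", [2, 3])
    @pytest.mark.parametrize(
        "smiles",
        ["CC(=O)Oc1ccccc1C(=O)O", "CC(=O)[O-]", "C[N+](C)(C)C",
         "O=S(=O)(N)c1ccccc1", "CC(C)NCC(O)COc1ccccc1"],
    )
    def test_level1_projection_aggregates_refinements(self, smiles, level):
        """Summing level-2/3 counts over their level-1 projection reproduces
        the level-1 counts key-by-key (including charged atoms)."""
        from collections import Counter

        from fragbb.fragments import project_to_level1

        g = parse_structure(smiles)
        l1 = enumerate_fragments(g, 6, (1,))
        lx = enumerate_fragments(g, 6, (level,))
        agg = Counter()
        for key, count in lx.items():
            agg[project_to_level1(key)] += count
        assert dict(agg) == l1

    def test_max_atoms_bounds(self):
        g = parse_structure("CC")
        with pytest.raises(ValueError):
            enumerate_fragments(g, 0)
        with pytest.raises(ValueError):
            enumerate_fragments(g, 13)


class TestDescriptorMatrix:
    def _records(self, smiles_list):
        return [
            CompoundRecord(f"c{i}", parse_structure(s))
            for i, s in enumerate(smiles_list)
        ]

    def test_methane_ethane_catalog(self):
        matrix, rejects = build_matrix(self._records(["C", "CC"]), 2, (1,))
        assert rejects == []
        assert matrix.fragment_keys == ["L1|path|C", "L1|path|C-C"]
        assert matrix.counts.tolist() == [[1, 0], [2, 1]]

    def test_single_compound_all_nonzero(self):
        matrix, _ = build_matrix(self._records(["CCO"]), 3, (1,))
        assert (matrix.counts > 0).all()

    def test_duplicate_rows_identical(self):
        matrix, _ = build_matrix(self._records(["CCN", "CCN"]), 3)
        assert (matrix.counts[0] == matrix.counts[1]).all()

    def test_column_order_sorted(self):
        matrix, _ = build_matrix(self._records(DRUGLIKE_SMILES[:5]), 4)
        assert matrix.fragment_keys == sorted(matrix.fragment_keys)

    def test_tsv_round_trip(self, tmp_path):
        matrix, _ = build_matrix(self._records(["CCO", "CCN"]), 3, (1,))
        path = tmp_path / "m.tsv"
        matrix.to_tsv(path)
        back = DescriptorMatrix.from_tsv(path)
        assert back.fragment_keys == matrix.fragment_keys
        assert (back.counts == matrix.counts).all()


class TestFilterRare:
    def _matrix(self, support_per_column):
        n = max(support_per_column) + 1
        counts = np.zeros((n, len(support_per_column)), dtype=int)
        for j, s in enumerate(support_per_column):
            counts[:s, j] = 1
        return DescriptorMatrix(
            [f"c{i}" for i in range(n)],
            [f"L1|path|F{j}" for j in range(len(support_per_column))],
            counts,
        )

    def test_boundary_four_removed_five_kept(self):
        matrix = self._matrix([4, 5, 6])
        filtered = filter_rare(matrix, min_support=5)
        assert filtered.fragment_keys == ["L1|path|F1", "L1|path|F2"]

    def test_all_zero_column_removed(self):
        matrix = self._matrix([0, 7])
        filtered = filter_rare(matrix)
        assert filtered.fragment_keys == ["L1|path|F1"]

    def test_rows_unchanged(self):
        matrix = self._matrix([2, 8])
        filtered = filter_rare(matrix)
        assert filtered.compound_ids == matrix.compound_ids


class TestFragmentFeaturizer:
    def test_transform_matches_fit_matrix(self, small_synth):
        records, _ = small_synth
        feat = FragmentFeaturizer(max_atoms=4, min_support=5).fit(records)
        X = feat.transform(records)
        assert X.shape == (len(records), len(feat.catalog_))
        # every catalog fragment occurs in >= min_support training compounds
        assert ((X > 0).sum(axis=0) >= 5).all()

    def test_unknown_fragments_ignored(self, small_synth):
        records, _ = small_synth
        feat = FragmentFeaturizer(max_atoms=3, min_support=5).fit(records)
        exotic = [CompoundRecord("x", parse_structure("C(I)(I)I"))]
        X = feat.transform(exotic)
        assert X.shape == (1, len(feat.catalog_))
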