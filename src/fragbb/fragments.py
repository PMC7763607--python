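"""Substructural fragment enumeration and the descriptor matrix.

A fragment is an *induced* connected heavy-atom subgraph of a molecule,
classified by topology:

* **path** — a tree whose vertices all have degree ≤ 2 (includes single atoms);
* **cycle** — a connected subgraph in which every vertex has degree exactly 2
  (a chordless/simple ring);
* **branch** — a tree with exactly one vertex of degree ≥ 3 (a star whose
  rays are paths).

Atom subsets inducing any other topology (e.g. trees with two branching
vertices, fused ring perimeters whose induced subgraph carries a chord) are
not counted.  Because the subgraph is induced, every atom subset maps to at
most one fragment, so the occurrence number of a fragment is the number of
distinct atom subsets realizing it.

Atoms are labeled at three refinement levels:

* level 1 — element symbol only;
* level 2 — element + aromaticity + sorted pattern of incident heavy-atom
  bond orders (in the parent molecule);
* level 3 — level 2 + valence state (total bond-order sum) + number of
  attached hydrogens.

Each finer label determines the coarser ones, so level-3 counts sum to the
corresponding level-2 and level-1 counts.  Bond orders within a fragment
are part of its canonical key at every level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .molgraph import CompoundRecord, MolecularGraph

logger = logging.getLogger(__name__)

BOND_SYMBOL = {"single": "-", "double": "=", "triple": "#", "aromatic": ":"}

LEVELS = (1, 2, 3)


# ---------------------------------------------------------------------------
# atom labels

def atom_labels(graph: MolecularGraph, level: int) -> list[str]:
    """Per-atom label strings at the requested classification level."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    adj_orders: list[list[str]] = [[] for _ in graph.atoms]
    for b in graph.bonds:
        sym = BOND_SYMBOL[b.order]
        adj_orders[b.i].append(sym)
        adj_orders[b.j].append(sym)
    labels = []
    for idx, a in enumerate(graph.atoms):
        elem = a.element.lower() if a.aromatic else a.element
        if level == 1:
            labels.append(a.element)
        elif level == 2:
            pattern = "".join(sorted(adj_orders[idx]))
            labels.append(f"{elem}{{{pattern}}}")
        else:
            pattern = "".join(sorted(adj_orders[idx]))
            charge = f"{a.formal_charge:+d}" if a.formal_charge else ""
            labels.append(
                f"{elem}{{{pattern}}}v{a.valence_state}h{a.n_hydrogens}{charge}"
            )
    return labels


# ---------------------------------------------------------------------------
# fragments and canonical keys

@dataclass(frozen=True)
class Fragment:
    """A canonical labeled fragment."""

    topology: str  # path | cycle | branch
    level: int
    canonical_key: str
    n_atoms: int


def _path_body(labels: Sequence[str], bonds: Sequence[str]) -> str:
    """Lexicographic minimum of the forward vs reversed (label, bond) writing."""
    fwd = _interleave(labels, bonds)
    rev = _interleave(list(reversed(labels)), list(reversed(bonds)))
    return min(fwd, rev)


def _interleave(labels: Sequence[str], bonds: Sequence[str]) -> str:
    out = [labels[0]]
    for lab, bond in zip(labels[1:], bonds):
        out.append(bond)
        out.append(lab)
    return "".join(out)


def _cycle_body(labels: Sequence[str], bonds: Sequence[str]) -> str:
    """Minimum over all rotations and both directions.

    ``bonds[k]`` joins atom k to atom (k+1) mod n.
    """
    n = len(labels)
    best = None
    for start in range(n):
        for step in (1, -1):
            atoms_seq = [labels[(start + step * k) % n] for k in range(n)]
            if step == 1:
                bond_seq = [bonds[(start + k) % n] for k in range(n)]
            else:
                bond_seq = [bonds[(start - 1 - k) % n] for k in range(n)]
            body = "".join(
                a + b for a, b in zip(atoms_seq, bond_seq)
            )
            if best is None or body < best:
                best = body
    return best


def _branch_body(center: str, rays: Sequence[str]) -> str:
    return center + "(" + ",".join(sorted(rays)) + ")"


def make_key(topology: str, level: int, body: str) -> str:
    return f"L{level}|{topology}|{body}"


# ---------------------------------------------------------------------------
# induced-subgraph enumeration (each connected subset exactly once)

def _connected_induced_subsets(
    adj: Sequence[Sequence[int]], max_size: int
) -> Iterator[frozenset[int]]:
    """Enumerate every connected induced subset of up to ``max_size`` vertices.

    Uses root-anchored extension (ESU-style): subsets are grown only with
    vertices greater than the root, and each extension vertex is added from
    the exclusive neighborhood, so every subset is produced exactly once.
    """
    n = len(adj)
    neigh = [set(a) for a in adj]

    def extend(sub: set[int], ext: set[int], root: int) -> Iterator[frozenset[int]]:
        yield frozenset(sub)
        if len(sub) == max_size:
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            sub_neigh = set().union(*(neigh[v] for v in sub)) | sub
            new_ext = ext | {
                u for u in neigh[w] if u > root and u not in sub_neigh
            }
            sub.add(w)
            yield from extend(sub, new_ext, root)
            sub.remove(w)

    for v in range(n):
        yield from extend({v}, {u for u in neigh[v] if u > v}, v)


def _classify(
    subset: frozenset[int],
    bond_lut: Mapping[tuple[int, int], str],
) -> tuple[str, list[tuple[int, int]]] | None:
    """Classify the induced subgraph on ``subset``; None if not path/cycle/branch."""
    verts = sorted(subset)
    edges = [
        (i, j)
        for k, i in enumerate(verts)
        for j in verts[k + 1:]
        if (i, j) in bond_lut
    ]
    n, m = len(verts), len(edges)
    deg = dict.fromkeys(verts, 0)
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    if m == n - 1:  # tree (connectivity guaranteed by the enumerator)
        n_branching = sum(1 for d in deg.values() if d >= 3)
        if n_branching == 0:
            return ("path", edges)
        if n_branching == 1:
            return ("branch", edges)
        return None
    if m == n and n >= 3 and all(d == 2 for d in deg.values()):
        return ("cycle", edges)
    return None


def _fragment_key(
    topology: str,
    subset: frozenset[int],
    edges: list[tuple[int, int]],
    labels: Sequence[str],
    bond_lut: Mapping[tuple[int, int], str],
    level: int,
) -> str:
    sub_adj: dict[int, list[int]] = {v: [] for v in subset}
    for i, j in edges:
        sub_adj[i].append(j)
        sub_adj[j].append(i)
    bond_sym = lambda i, j: BOND_SYMBOL[bond_lut[(min(i, j), max(i, j))]]

    if topology == "path":
        if len(subset) == 1:
            body = labels[next(iter(subset))]
        else:
            start = next(v for v in sorted(subset) if len(sub_adj[v]) == 1)
            order = _walk_path(start, sub_adj)
            body = _path_body(
                [labels[v] for v in order],
                [bond_sym(a, b) for a, b in zip(order, order[1:])],
            )
    elif topology == "cycle":
        start = min(subset)
        order = _walk_cycle(start, sub_adj)
        bonds = [
            bond_sym(order[k], order[(k + 1) % len(order)])
            for k in range(len(order))
        ]
        body = _cycle_body([labels[v] for v in order], bonds)
    else:  # branch
        center = next(v for v in subset if len(sub_adj[v]) >= 3)
        rays = []
        for first in sub_adj[center]:
            ray = [center, first]
            while True:
                nxt = [u for u in sub_adj[ray[-1]] if u != ray[-2]]
                if not nxt:
                    break
                ray.append(nxt[0])
            rays.append(
                "".join(
                    bond_sym(a, b) + labels[b]
                    for a, b in zip(ray, ray[1:])
                )
            )
        body = _branch_body(labels[center], rays)
    return make_key(topology, level, body)


def _walk_path(start: int, sub_adj: Mapping[int, list[int]]) -> list[int]:
    order = [start]
    prev = None
    while True:
        nxt = [u for u in sub_adj[order[-1]] if u != prev]
        if not nxt:
            return order
        prev = order[-1]
        order.append(nxt[0])


def _walk_cycle(start: int, sub_adj: Mapping[int, list[int]]) -> list[int]:
    order = [start]
    prev, cur = None, start
    while True:
        nxt = next(u for u in sub_adj[cur] if u != prev)
        if nxt == start:
            return order
        order.append(nxt)
        prev, cur = cur, nxt


def enumerate_fragments(
    graph: MolecularGraph,
    max_atoms: int = 8,
    levels: Iterable[int] = LEVELS,
) -> dict[str, int]:
    """Count all path/cycle/branch fragments of up to ``max_atoms`` heavy atoms.

    Each distinct atom subset is counted once, regardless of traversal
    direction or starting atom; the same subset contributes one count at
    every requested labeling level.
    """
    if not 1 <= max_atoms <= 12:
        raise ValueError("max_atoms must be in [1, 12]")
    levels = sorted(set(levels))
    if any(l not in LEVELS for l in levels):
        raise ValueError(f"levels must be within {LEVELS}")
    if graph.n_atoms == 0:
        return {}
    adj = graph.adjacency()
    bond_lut = graph.bond_lookup()
    level_labels = {l: atom_labels(graph, l) for l in levels}
    counts: dict[str, int] = {}
    for subset in _connected_induced_subsets(adj, max_atoms):
        result = _classify(subset, bond_lut)
        if result is None:
            continue
        topology, edges = result
        for level in levels:
            key = _fragment_key(
                topology, subset, edges, level_labels[level], bond_lut, level
            )
            counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# level-1 projection of canonical keys (groups refinements for interpretation)

_LABEL_RE = __import__("re").compile(
    r"(?P<elem>[A-Z][a-z]?|[a-z][a-z]?)"
    r"(?:\{[-=#:]*\})?"
    r"(?:v\d+h\d+(?:[+-]\d+)?)?"
)


def _tokenize_body(body: str) -> tuple[list[str], list[str]]:
    """Split a path/cycle body into element labels and bond symbols."""
    labels, bonds = [], []
    pos = 0
    expect_label = True
    while pos < len(body):
        if expect_label:
            m = _LABEL_RE.match(body, pos)
            if not m:
                raise ValueError(f"cannot parse fragment body {body!r} at {pos}")
            labels.append(m.group("elem").capitalize())
            pos = m.end()
        else:
            bonds.append(body[pos])
            pos += 1
        expect_label = not expect_label
    return labels, bonds


def project_to_level1(key: str) -> str:
    """Project any canonical fragment key onto its level-1 (element-only)
    form, re-canonicalizing the symmetry after label coarsening.

    Summing counts (or contributions) of all catalog fragments sharing a
    level-1 projection reproduces the level-1 quantity — the refinement
    hierarchy in aggregate form.
    """
    level_tag, topology, body = key.split("|", 2)
    if level_tag == "L1":
        return key
    if topology == "path":
        labels, bonds = _tokenize_body(body)
        new_body = _path_body(labels, bonds)
    elif topology == "cycle":
        labels, bonds = _tokenize_body(body)
        # cycle bodies interleave label+bond with a trailing bond
        new_body = _cycle_body(labels, bonds)
    else:  # branch: center label then parenthesized rays
        head, rays_str = body.split("(", 1)
        center = _LABEL_RE.match(head).group("elem").capitalize()
        rays = []
        for ray in rays_str.rstrip(")").split(","):
            bond_syms, elems = [], []
            pos = 0
            while pos < len(ray):
                bond_syms.append(ray[pos])
                m = _LABEL_RE.match(ray, pos + 1)
                elems.append(m.group("elem").capitalize())
                pos = m.end()
            rays.append(
                "".join(b + e for b, e in zip(bond_syms, elems))
            )
        new_body = _branch_body(center, rays)
    return make_key(topology, 1, new_body)


# ---------------------------------------------------------------------------
# descriptor matrix

@dataclass
class DescriptorMatrix:
    """Compounds × fragments integer occurrence-count matrix."""

    compound_ids: list[str]
    fragment_keys: list[str]
    counts: np.ndarray  # int, shape (n_compounds, n_fragments)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.compound_ids), len(self.fragment_keys)):
            raise ValueError("counts shape does not match ids/keys")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.compound_ids, columns=self.fragment_keys
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DescriptorMatrix":
        df = pd.read_csv(path, sep="\t", index_col="id")
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())

    def to_triplets(self, path: str | Path) -> None:
        """Sparse triplet export: row-id, fragment key, count."""
        rows, cols = np.nonzero(self.counts)
        with open(path, "w") as fh:
            fh.write(f"# {len(self.compound_ids)} {len(self.fragment_keys)}\n")
            for r, c in zip(rows, cols):
                fh.write(
                    f"{self.compound_ids[r]}\t{self.fragment_keys[c]}\t"
                    f"{self.counts[r, c]}\n"
                )


def build_matrix(
    dataset: Sequence[CompoundRecord],
    max_atoms: int = 8,
    levels: Iterable[int] = LEVELS,
) -> tuple[DescriptorMatrix, list[dict]]:
    """Build the descriptor matrix over a dataset.

    The fragment catalog is the union over all compounds, in sorted
    canonical-key order.  Compounds whose fragment enumeration fails are
    excluded with a warning and listed in the rejects report.
    """
    if not dataset:
        raise ValueError("dataset must be non-empty")
    per_compound: list[dict[str, int]] = []
    kept_ids: list[str] = []
    rejects: list[dict] = []
    for rec in dataset:
        try:
            per_compound.append(enumerate_fragments(rec.graph, max_atoms, levels))
            kept_ids.append(rec.id)
        except Exception as exc:  # route to rejects, never abort the batch
            logger.warning("fragment enumeration failed for %s: %s", rec.id, exc)
            rejects.append({"id": rec.id, "reason": "enumeration_failure",
                            "detail": str(exc)})
    catalog = sorted(set().union(*per_compound)) if per_compound else []
    key_idx = {k: i for i, k in enumerate(catalog)}
    counts = np.zeros((len(per_compound), len(catalog)), dtype=np.int64)
    for r, cmap in enumerate(per_compound):
        for k, v in cmap.items():
            counts[r, key_idx[k]] = v
    return DescriptorMatrix(kept_ids, catalog, counts), rejects


def filter_rare(matrix: DescriptorMatrix, min_support: int = 5) -> DescriptorMatrix:
    """Drop fragments present (nonzero) in fewer than ``min_support`` compounds.

    The default keeps fragments occurring in at least five compounds, i.e.
    removes those present in four or fewer — rare substructures that cannot
    support general predictive relationships.
    """
    support = (matrix.counts > 0).sum(axis=0)
    keep = support >= min_support
    return DescriptorMatrix(
        matrix.compound_ids,
        [k for k, m in zip(matrix.fragment_keys, keep) if m],
        matrix.counts[:, keep],
    )


class FragmentFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from compound records to fragment-count feature matrices.

    ``fit`` builds the fragment catalog from the training compounds and
    applies the rare-fragment support filter; ``transform`` counts catalog
    fragments in (possibly new) compounds, ignoring fragments outside the
    catalog.

    Parameters
    ----------
    max_atoms : largest fragment size in heavy atoms (paper-style default 8).
    levels : atom classification levels pooled into the catalog.
    min_support : minimum number of training compounds a fragment must occur
        in to enter the catalog (5 ⇒ fragments in ≤4 compounds are removed).
    """

    def __init__(self, max_atoms: int = 8, levels: tuple[int, ...] = LEVELS,
                 min_support: int = 5):
        self.max_atoms = max_atoms
        self.levels = levels
        self.min_support = min_support

    def fit(self, X: Sequence[CompoundRecord], y=None):
        matrix, rejects = build_matrix(X, self.max_atoms, self.levels)
        matrix = filter_rare(matrix, self.min_support)
        self.catalog_ = list(matrix.fragment_keys)
        self.rejects_ = rejects
        return self

    def transform(self, X: Sequence[CompoundRecord]) -> np.ndarray:
        check_is_fitted(self, "catalog_")
        key_idx = {k: i for i, k in enumerate(self.catalog_)}
        out = np.zeros((len(X), len(self.catalog_)), dtype=np.int64)
        for r, rec in enumerate(X):
            for k, v in enumerate_fragments(
                rec.graph, self.max_atoms, self.levels
            ).items():
                j = key_idx.get(k)
                if j is not None:
                    out[r, j] = v
        return out

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "catalog_")
        return np.asarray(self.catalog_, dtype=object)
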