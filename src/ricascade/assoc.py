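"""Association between total reproductive isolation and phylogenetic distance.

Patristic distances (total branch length on the path between two leaves) are
extracted from a Newick tree, and their correlation with the pairwise
total-RI matrix is tested with a permutation Mantel test: the Pearson
correlation of the strictly-lower-triangle entries, with a null built by
jointly permuting rows and columns of the second matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .barriers import SchemaError


@dataclass
class DistanceMatrix:
    """Labelled square matrix of pairwise distances (or RI values)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")

    def reorder(self, labels: list[str]) -> "DistanceMatrix":
        if set(labels) != set(self.labels):
            raise SchemaError(
                f"label mismatch: {sorted(labels)} vs {sorted(self.labels)}"
            )
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise SchemaError("matrix rows and columns must carry the same labels")
        return cls(list(df.index), df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string (branch lengths required) into a tree."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate leaf labels in tree: {sorted(labels)}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                f"missing branch length above node {edge.head_node}"
            )
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
    return out.getvalue().strip()


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise patristic distances: total branch length connecting each pair
    of leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels, mat)


def _lower_triangle(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices_from(m, k=-1)]


def mantel_test(
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    n_permutations: int = 9999,
    rng_seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Permutation Mantel test between two labelled square matrices.

    The statistic is the Pearson correlation r of the strictly-lower-triangle
    entries; the null distribution comes from jointly permuting the rows and
    columns of ``m2``.  The p-value uses the add-one convention,
    p = (1 + #{r_perm at-least-as-extreme}) / (1 + n_permutations).
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if len(m1.labels) < 3:
        raise ValueError("Mantel test needs at least 3 labels")
    m2 = m2.reorder(m1.labels)
    a = _lower_triangle(m1.values)
    if np.std(a) == 0 or np.std(_lower_triangle(m2.values)) == 0:
        raise ValueError("constant lower triangle: correlation undefined")

    def corr(mat_b: np.ndarray) -> float:
        b = _lower_triangle(mat_b)
        return float(np.corrcoef(a, b)[0, 1])

    r_obs = corr(m2.values)
    rng = np.random.default_rng(rng_seed)
    n = len(m1.labels)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = corr(m2.values[np.ix_(perm, perm)])
        if alternative == "greater":
            hit = r_perm >= r_obs
        elif alternative == "less":
            hit = r_perm <= r_obs
        else:
            hit = abs(r_perm) >= abs(r_obs)
        hits += int(hit)
    p = (1 + hits) / (1 + n_permutations)
    return r_obs, float(p)


def symmetrize_ri(ri_matrix: pd.DataFrame, how: str = "mean") -> DistanceMatrix:
    """Collapse a directed total-RI matrix to a symmetric one.

    Total RI is direction-dependent (acceptor vs donor); the Mantel test
    needs one value per unordered pair.  Default: arithmetic mean of the two
    directions; 'max'/'min' available.
    """
    m = DistanceMatrix.from_frame(ri_matrix)
    v = m.values
    if how == "mean":
        sym = (v + v.T) / 2.0
    elif how == "max":
        sym = np.fmax(v, v.T)
    elif how == "min":
        sym = np.fmin(v, v.T)
    else:
        raise ValueError(f"unknown symmetrization {how!r}")
    np.fill_diagonal(sym, 0.0)
    return DistanceMatrix(m.labels, sym)


def ri_distance_report(
    ri_garden: pd.DataFrame,
    ri_wild: pd.DataFrame,
    tree: dendropy.Tree,
    n_permutations: int = 9999,
    rng_seed: int = 0,
    alternative: str = "greater",
    symmetrize: str = "mean",
) -> dict:
    """Mantel tests of total RI (garden- and wild-phenology variants) against
    patristic distance; returns a JSON-ready report."""
    pat = patristic_distances(tree)
    report: dict = {
        "n_permutations": n_permutations,
        "rng_seed": rng_seed,
        "alternative": alternative,
        "symmetrization": symmetrize,
        "tests": {},
    }
    for name, ri in (("garden", ri_garden), ("wild", ri_wild)):
        sym = symmetrize_ri(ri, how=symmetrize)
        missing = set(sym.labels) - set(pat.labels)
        if missing:
            raise SchemaError(f"species absent from tree: {sorted(missing)}")
        pat_sub = pat.reorder(sym.labels)
        r, p = mantel_test(
            pat_sub, sym, n_permutations=n_permutations,
            rng_seed=rng_seed, alternative=alternative,
        )
        report["tests"][name] = {"r": r, "p_value": p, "n_species": len(sym.labels)}
    return report
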