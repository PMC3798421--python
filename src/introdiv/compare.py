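"""Sympatric-vs-allopatric comparison layer.

Takes a per-locus FST panel for the two species pairs and computes the
contrast statistics: mean-FST t contrast, the ranked normalized-difference
Spearman correlation, exceedance counts, and a locus-bootstrapped
neighbor-joining tree on the mean pairwise-FST distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO
from itertools import combinations

import numpy as np
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj


@dataclass(frozen=True)
class FstPanel:
    """Per-locus FST values for the sympatric and allopatric pairs."""

    loci: tuple[str, ...]
    fst_symp: np.ndarray
    fst_allo: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "fst_symp", np.asarray(self.fst_symp, dtype=float))
        object.__setattr__(self, "fst_allo", np.asarray(self.fst_allo, dtype=float))
        if len(self.loci) != len(set(self.loci)):
            raise ValueError("panel locus names must be unique")
        if not (len(self.loci) == self.fst_symp.size == self.fst_allo.size):
            raise ValueError("panel vectors must have one value per locus")


@dataclass(frozen=True)
class MeanFstContrast:
    mean_symp: float
    sd_symp: float
    mean_allo: float
    sd_allo: float
    t: float
    p: float


def mean_fst_contrast(panel: FstPanel) -> MeanFstContrast:
    """Pooled-variance two-sample t contrast of the two FST vectors.

    Sign convention t = (mean_symp - mean_allo)/SE, negative when the
    sympatric pair is less differentiated.
    """
    if len(panel.loci) < 2:
        raise ValueError("need at least 2 loci")
    t, p = stats.ttest_ind(panel.fst_symp, panel.fst_allo, equal_var=True)
    return MeanFstContrast(
        mean_symp=float(panel.fst_symp.mean()),
        sd_symp=float(panel.fst_symp.std(ddof=1)),
        mean_allo=float(panel.fst_allo.mean()),
        sd_allo=float(panel.fst_allo.std(ddof=1)),
        t=float(t),
        p=float(p),
    )


def normalized_diff_rank_correlation(
    panel: FstPanel, direction: str = "vs_symp"
) -> tuple[float, float]:
    """Spearman correlation of the normalized FST difference with an FST rank.

    d_i = (allo_i - symp_i)/allo_i measures how much smaller sympatric
    differentiation is at locus i; it is rank-correlated (average ranks on
    ties) against the sympatric (``vs_symp``) or allopatric (``vs_allo``) FST
    vector.  A strongly negative vs_symp correlation is the differential
    introgression signature: loci that resist introgression in sympatry lose
    little differentiation relative to allopatry.
    """
    if np.any(panel.fst_allo == 0):
        raise ValueError("normalized difference undefined: allopatric FST of 0")
    if len(panel.loci) < 3:
        raise ValueError("need at least 3 loci")
    d = (panel.fst_allo - panel.fst_symp) / panel.fst_allo
    other = {"vs_symp": panel.fst_symp, "vs_allo": panel.fst_allo}[direction]
    if np.unique(d).size == 1 or np.unique(other).size == 1:
        raise ValueError("constant vector: rank correlation undefined")
    r, p = stats.spearmanr(d, other)
    return float(r), float(p)


def count_sympatric_exceed(panel: FstPanel) -> int:
    """Number of loci where sympatric FST exceeds allopatric FST."""
    return int(np.sum(panel.fst_symp > panel.fst_allo))


@dataclass(frozen=True)
class PopDistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray
    floored: bool = False  # True when negative mean FSTs were floored at 0

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        object.__setattr__(self, "d", d)


def mean_fst_matrix(
    per_locus: list[dict[tuple[str, str], float]], labels: tuple[str, ...]
) -> PopDistanceMatrix:
    """Entrywise mean FST across loci for every population pair.

    ``per_locus`` holds one dict per locus mapping unordered pair tuples to
    FST.  Negative means are floored at 0 (flagged) so the matrix is usable
    as a tree-building distance.
    """
    k = len(labels)
    d = np.zeros((k, k))
    for i, j in combinations(range(k), 2):
        vals = []
        for locus in per_locus:
            pair = (labels[i], labels[j])
            if pair in locus:
                vals.append(locus[pair])
            elif pair[::-1] in locus:
                vals.append(locus[pair[::-1]])
            else:
                raise ValueError(f"locus missing pair {pair}")
        d[i, j] = d[j, i] = float(np.mean(vals))
    floored = bool(np.any(d < 0))
    d = np.maximum(d, 0.0)
    return PopDistanceMatrix(labels=labels, d=d, floored=floored)


def nj_tree(dm: PopDistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining on the mean-FST matrix (unrooted)."""
    if len(dm.labels) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    skdm = DistanceMatrix(dm.d, ids=list(dm.labels))
    return _skbio_nj(skdm)


def tree_newick(tree: TreeNode) -> str:
    buf = StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def tree_splits(tree: TreeNode, labels: tuple[str, ...]) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized to the
    smaller side (ties broken by sorted label tuple)."""
    all_labels = frozenset(labels)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_labels - side
        if len(side) < 2 or len(other) < 2:
            continue
        if (len(side), tuple(sorted(side))) <= (len(other), tuple(sorted(other))):
            splits.add(side)
        else:
            splits.add(other)
    return splits


def locus_bootstrap_support(
    per_locus: list[dict[tuple[str, str], float]],
    labels: tuple[str, ...],
    B: int = 100,
    seed: int | np.random.Generator | None = None,
) -> dict[frozenset[str], float]:
    """Split support from bootstrapping loci (not sequences).

    Resamples the loci with replacement B times, rebuilds the mean-FST NJ
    tree each time, and reports the percentage of replicates containing each
    split of the point tree.
    """
    if B <= 0:
        raise ValueError("bootstrap replicate count must be positive")
    if len(per_locus) < 2:
        raise ValueError("need at least 2 loci to bootstrap")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    point_tree = nj_tree(mean_fst_matrix(per_locus, labels))
    point_splits = tree_splits(point_tree, labels)
    hits = {s: 0 for s in point_splits}
    n_loci = len(per_locus)
    for _ in range(B):
        sample = [per_locus[i] for i in rng.integers(0, n_loci, size=n_loci)]
        rep_tree = nj_tree(mean_fst_matrix(sample, labels))
        rep_splits = tree_splits(rep_tree, labels)
        for s in point_splits:
            if s in rep_splits:
                hits[s] += 1
    return {s: 100.0 * h / B for s, h in hits.items()}
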