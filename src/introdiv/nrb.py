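"""Non-recombining block (NRB) extraction via the four-gamete criterion.

A pair of biallelic sites showing all four haplotypic combinations cannot
descend from a single genealogy without recombination.  The extractor searches
contiguous windows combined with sequence removal for the configuration that
maximizes ``retained_sites * retained_sequences**seq_weight`` subject to the
block being four-gamete compatible.

Sites with more than two residues or any residual gap/N are excluded from
compatibility testing but are retained inside the emitted block.  Within a
window the minimum sequence-removal set is found exactly by branch-and-bound
over the gamete classes of the violating site pairs (each violation can only
be resolved by emptying one of its four classes), falling back to a greedy
cover on adversarially large instances.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .alignments import LocusAlignment

_GAP = ord("-")
_N = ord("N")

_BB_NODE_CAP = 200_000


def _test_site_positions(mat: np.ndarray) -> np.ndarray:
    """Kept-column indices usable for four-gamete tests: exactly two residues,
    no gap or ambiguity."""
    ok = ~np.any((mat == _GAP) | (mat == _N), axis=0)
    n_alleles = np.array([np.unique(mat[:, c]).size for c in range(mat.shape[1])])
    return np.flatnonzero(ok & (n_alleles == 2))


def _gamete_classes(mat: np.ndarray, i: int, j: int) -> list[frozenset[int]] | None:
    """The four gamete classes (row sets) for site pair (i, j), or None if the
    pair does not exhibit all four gametes."""
    a = mat[:, i]
    b = mat[:, j]
    a1 = a == a[0]
    b1 = b == b[0]
    classes = [
        frozenset(np.flatnonzero(a1 & b1).tolist()),
        frozenset(np.flatnonzero(a1 & ~b1).tolist()),
        frozenset(np.flatnonzero(~a1 & b1).tolist()),
        frozenset(np.flatnonzero(~a1 & ~b1).tolist()),
    ]
    if all(classes):
        return classes
    return None


def four_gamete_violations(aln: LocusAlignment) -> list[tuple[int, int]]:
    """All pairs of kept biallelic sites exhibiting all four gametes.

    Returned as (i, j) original column index pairs, i < j.
    """
    mat = aln.matrix()
    test = _test_site_positions(mat)
    out = []
    for ki, kj in combinations(test, 2):
        if _gamete_classes(mat, int(ki), int(kj)) is not None:
            out.append((int(aln.kept_sites[ki]), int(aln.kept_sites[kj])))
    return out


def _violated(classes: list[frozenset[int]], removed: frozenset[int]) -> bool:
    return all(not c <= removed for c in classes)


def _min_removal_sets(
    pair_classes: list[list[frozenset[int]]],
    n: int,
    node_cap: int = _BB_NODE_CAP,
) -> frozenset[int]:
    """Smallest sequence set whose removal resolves every violation.

    Branch-and-bound: pick an unresolved violation, branch over emptying each
    of its four gamete classes.  Ties between equal-size optima are broken by
    dropping the later row indices (callers translate to id order).  Falls
    back to a greedy cover if the search exceeds ``node_cap`` nodes.
    """
    best: frozenset[int] | None = None
    nodes = 0

    def better(cand: frozenset[int]) -> bool:
        if best is None or len(cand) < len(best):
            return True
        if len(cand) == len(best):
            return tuple(sorted(cand, reverse=True)) > tuple(sorted(best, reverse=True))
        return False

    def solve(removed: frozenset[int]) -> None:
        nonlocal best, nodes
        nodes += 1
        if nodes > node_cap:
            raise _NodeCapExceeded
        open_pair = next((cl for cl in pair_classes if _violated(cl, removed)), None)
        if open_pair is None:
            if better(removed):
                best = removed
            return
        if best is not None and len(removed) >= len(best):
            return  # any completion is strictly larger than the incumbent
        for cl in sorted(open_pair, key=lambda c: (len(c - removed), sorted(c))):
            solve(removed | cl)

    try:
        solve(frozenset())
    except _NodeCapExceeded:
        return _greedy_removal(pair_classes)
    assert best is not None
    return best


class _NodeCapExceeded(Exception):
    pass


def _greedy_removal(pair_classes: list[list[frozenset[int]]]) -> frozenset[int]:
    removed: frozenset[int] = frozenset()
    while True:
        open_pairs = [cl for cl in pair_classes if _violated(cl, removed)]
        if not open_pairs:
            return removed
        # candidate moves: empty the cheapest class of each open violation;
        # take the move resolving the most violations per removed sequence
        best_move: frozenset[int] | None = None
        best_gain = -1.0
        for cl in open_pairs:
            for c in cl:
                extra = c - removed
                trial = removed | c
                gain = sum(1 for x in open_pairs if not _violated(x, trial)) / max(len(extra), 1)
                if gain > best_gain:
                    best_gain, best_move = gain, trial
        removed = best_move  # type: ignore[assignment]


@dataclass(frozen=True)
class NrbResult:
    """A four-gamete-compatible block with the sequences retained in it."""

    locus_name: str
    block: tuple[int, int]  # original-column half-open interval
    retained_ids: tuple[str, ...]
    dropped_ids: tuple[str, ...]
    n_sites: int  # kept columns inside the block
    score: float
    degenerate: bool
    alignment: LocusAlignment


def extract_nrb(
    aln: LocusAlignment,
    seq_weight: float = 1.0,
    min_sequences: int = 4,
) -> NrbResult:
    """Extract the highest-scoring non-recombining block.

    Scores ``n_sites * n_sequences**seq_weight`` over all contiguous windows
    and minimal sequence-removal sets; ties keep the earlier window and drop
    lexicographically last ids.  If no violation-free configuration with at
    least ``min_sequences`` sequences and one site exists, the whole filtered
    alignment is returned flagged degenerate.
    """
    mat = aln.matrix()
    n, n_kept = mat.shape
    test = _test_site_positions(mat)

    # cache gamete classes for violating pairs only (in test-site index space)
    viol: dict[tuple[int, int], list[frozenset[int]]] = {}
    for a, b in combinations(range(test.size), 2):
        cl = _gamete_classes(mat, int(test[a]), int(test[b]))
        if cl is not None:
            viol[(a, b)] = cl

    def window_bounds(a: int, b: int) -> tuple[int, int]:
        lo = 0 if a == 0 else int(test[a - 1]) + 1
        hi = n_kept - 1 if b == test.size - 1 else int(test[b + 1]) - 1
        return lo, hi

    candidates: list[tuple[int, int, int, int]] = []  # (lo_k, hi_k, a, b); a>b = empty
    if test.size == 0:
        candidates.append((0, n_kept - 1, 0, -1))
    else:
        for a in range(test.size):
            for b in range(a, test.size):
                lo, hi = window_bounds(a, b)
                candidates.append((lo, hi, a, b))
        # windows containing no test site: gaps around them
        edges = [-1] + [int(t) for t in test] + [n_kept]
        for prev, nxt in zip(edges[:-1], edges[1:]):
            if nxt - prev > 1:
                candidates.append((prev + 1, nxt - 1, 0, -1))

    best: tuple[float, int, int, frozenset[int]] | None = None  # score, lo, hi, removed

    def score_of(sites: int, kept_seqs: int) -> float:
        return sites * kept_seqs**seq_weight

    # big windows first so the no-removal bound prunes aggressively
    candidates.sort(key=lambda c: (-(c[1] - c[0] + 1), c[0], c[1]))
    for lo, hi, a, b in candidates:
        sites = hi - lo + 1
        if sites < 1:
            continue
        bound = score_of(sites, n)
        if best is not None and bound < best[0]:
            continue
        pairs = [cl for (i, j), cl in viol.items() if a <= i and j <= b] if b >= a else []
        removed = _min_removal_sets(pairs, n) if pairs else frozenset()
        kept_seqs = n - len(removed)
        if kept_seqs < min_sequences:
            continue
        sc = score_of(sites, kept_seqs)
        if best is None or sc > best[0] or (sc == best[0] and lo < best[1]):
            best = (sc, lo, hi, removed)

    if best is None:
        empty = NrbResult(
            locus_name=aln.locus_name,
            block=(int(aln.kept_sites[0]), int(aln.kept_sites[-1]) + 1) if n_kept else (0, 0),
            retained_ids=aln.ids,
            dropped_ids=(),
            n_sites=n_kept,
            score=0.0,
            degenerate=True,
            alignment=aln,
        )
        return empty

    sc, lo, hi, removed = best
    keep_rows = [r for r in range(n) if r not in removed]
    start = int(aln.kept_sites[lo])
    end = int(aln.kept_sites[hi]) + 1
    sub = aln.subset_indices(keep_rows)
    kept_in_block = aln.kept_sites[(aln.kept_sites >= start) & (aln.kept_sites < end)]
    from dataclasses import replace

    block_aln = replace(sub, kept_sites=kept_in_block)
    return NrbResult(
        locus_name=aln.locus_name,
        block=(start, end),
        retained_ids=tuple(aln.ids[r] for r in keep_rows),
        dropped_ids=tuple(aln.ids[r] for r in sorted(removed)),
        n_sites=hi - lo + 1,
        score=sc,
        degenerate=False,
        alignment=block_aln,
    )


def apply_block(
    aln: LocusAlignment, block: tuple[int, int], drop_ids: tuple[str, ...] = ()
) -> LocusAlignment:
    """Force a block interval (and optional sequence drops) computed on one
    dataset onto another — mirrors selecting consistent blocks across pairs."""
    from dataclasses import replace

    keep_rows = [i for i, sid in enumerate(aln.ids) if sid not in set(drop_ids)]
    sub = aln.subset_indices(keep_rows)
    kept = aln.kept_sites[(aln.kept_sites >= block[0]) & (aln.kept_sites < block[1])]
    return replace(sub, kept_sites=kept)
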