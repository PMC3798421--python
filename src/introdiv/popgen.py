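"""Per-locus polymorphism, neutrality and two-population differentiation statistics.

All statistics operate on the filtered column set (``kept_sites``) of a
:class:`~introdiv.alignments.LocusAlignment`.  Columns are summarised through
allele counts, so every pairwise quantity (pi, Dxy, Hudson FST) is an exact
closed form over the C(n,2) sequence pairs rather than an explicit pair loop.

Conventions
-----------
* pi and theta_W are reported per site; the unnormalised mean pairwise
  difference (``pi_total``, count scale) feeds Tajima's D, Fu's Fs and R2.
* Statistics undefined for the data at hand (S = 0, no variation anywhere)
  return NaN rather than 0 so that report layers can print a dash.
* Neutrality-test significance comes from coalescent simulation conditional
  on the sample size and the observed number of segregating sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np

from .alignments import LocusAlignment

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# column summaries


def allele_counts(matrix: np.ndarray) -> np.ndarray:
    """(4, n_cols) counts of A, C, G, T per column; gaps/N are not counted."""
    return np.stack([(matrix == b).sum(axis=0) for b in _ACGT])


def _require(aln: LocusAlignment) -> np.ndarray:
    if aln.n < 2:
        raise ValueError(f"{aln.locus_name}: need at least 2 sequences")
    if aln.kept_sites.size == 0:
        raise ValueError(f"{aln.locus_name}: no kept sites; statistics undefined")
    return aln.matrix()


def segregating_sites(aln: LocusAlignment) -> tuple[int, np.ndarray]:
    """Count of kept columns with >=2 distinct residues, plus their indices."""
    counts = allele_counts(_require(aln))
    seg = (counts > 0).sum(axis=0) >= 2
    return int(seg.sum()), aln.kept_sites[seg]


def pi_total(aln: LocusAlignment) -> float:
    """Mean number of pairwise differences over all sequence pairs (count scale)."""
    counts = allele_counts(_require(aln))
    n_col = counts.sum(axis=0)
    pairs = n_col * (n_col - 1) / 2.0
    same = (counts * (counts - 1) / 2.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_col = np.where(pairs > 0, 1.0 - same / np.where(pairs > 0, pairs, 1.0), 0.0)
    return float(per_col.sum())


def nucleotide_diversity(aln: LocusAlignment) -> float:
    """pi per site: mean pairwise differences divided by the kept length."""
    return pi_total(aln) / aln.kept_sites.size


def watterson_theta(aln: LocusAlignment) -> float:
    """Watterson's estimator per site, S / (a1 * L_kept)."""
    s, _ = segregating_sites(aln)
    return s / (_a1(aln.n) * aln.kept_sites.size)


def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def singleton_counts(aln: LocusAlignment) -> np.ndarray:
    """Number of singleton alleles carried by each sequence (for R2)."""
    mat = _require(aln)
    counts = allele_counts(mat)
    u = np.zeros(aln.n, dtype=np.intp)
    singleton_cols = np.flatnonzero((counts == 1).any(axis=0))
    for col in singleton_cols:
        for a_idx in np.flatnonzero(counts[:, col] == 1):
            row = int(np.flatnonzero(mat[:, col] == _ACGT[a_idx])[0])
            u[row] += 1
    return u


def haplotype_count(aln: LocusAlignment) -> int:
    """Distinct haplotypes on the kept columns."""
    mat = _require(aln)
    return len({m.tobytes() for m in mat})


@dataclass(frozen=True)
class PolymorphismSummary:
    """Per-population polymorphism summary for one locus."""

    locus_name: str
    n: int
    length_kept: int
    S: int
    pi: float
    theta_w: float
    pi_total: float
    k_haplotypes: int


def summarize_polymorphism(aln: LocusAlignment) -> PolymorphismSummary:
    s, _ = segregating_sites(aln)
    pt = pi_total(aln)
    L = int(aln.kept_sites.size)
    return PolymorphismSummary(
        locus_name=aln.locus_name,
        n=aln.n,
        length_kept=L,
        S=s,
        pi=pt / L,
        theta_w=s / (_a1(aln.n) * L),
        pi_total=pt,
        k_haplotypes=haplotype_count(aln),
    )


# ---------------------------------------------------------------------------
# neutrality statistics


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = _a1(n)
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(aln: LocusAlignment) -> float:
    """Tajima's D; NaN when S = 0 (report layers print a dash)."""
    s, _ = segregating_sites(aln)
    return _tajimas_d_from(aln.n, s, pi_total(aln))


def _tajimas_d_from(n: int, s: int, pi_tot: float) -> float:
    if s == 0:
        return math.nan
    e1, e2 = _tajima_constants(n)
    return (pi_tot - s / _a1(n)) / math.sqrt(e1 * s + e2 * s * (s - 1))


@lru_cache(maxsize=None)
def _stirling_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |s(n, k)| for k = 0..n."""
    row = [1]
    for m in range(n):
        # |s(m+1, k)| = m*|s(m, k)| + |s(m, k-1)|
        nxt = [0] * (m + 2)
        for k, v in enumerate(row):
            nxt[k] += m * v
            nxt[k + 1] += v
        row = nxt
    return tuple(row)


def ewens_k_tail(n: int, k_obs: int, theta: float, exact: bool = True) -> float:
    """P(K >= k_obs) for the haplotype count K under the Ewens sampling formula.

    Exact rational arithmetic (n <= 64) avoids the catastrophic cancellation
    that float Stirling sums suffer; the float path serves bulk simulation.
    """
    if theta <= 0:
        return 1.0 if k_obs <= 1 else 0.0
    row = _stirling_row(n)
    if exact and n <= 64:
        th = Fraction(theta)
        rising = Fraction(1)
        for i in range(n):
            rising *= th + i
        tail = sum(Fraction(row[k]) * th**k for k in range(k_obs, n + 1)) / rising
        return tail  # type: ignore[return-value]  # Fraction; callers log it
    rising_f = 1.0
    for i in range(n):
        rising_f *= theta + i
    return sum(row[k] * theta**k for k in range(k_obs, n + 1)) / rising_f


@dataclass(frozen=True)
class FuFs:
    fs: float
    s_prime: float
    clamped: bool


_LOG_ODDS_CLAMP = 700.0


def fus_fs(aln: LocusAlignment) -> FuFs:
    """Fu's Fs from the Ewens distribution of the haplotype count.

    S' = P(K >= k_obs | theta = pi_total); Fs = ln(S' / (1 - S')).  When S'
    hits 0 or 1 (e.g. every sequence is one haplotype) the log-odds is clamped
    and flagged.
    """
    s, _ = segregating_sites(aln)
    if s == 0:
        raise ValueError(f"{aln.locus_name}: Fu's Fs undefined for S = 0")
    if aln.n < 3:
        raise ValueError(f"{aln.locus_name}: Fu's Fs needs n >= 3")
    return _fus_fs_from(aln.n, haplotype_count(aln), pi_total(aln))


def _fus_fs_from(n: int, k_obs: int, theta: float, exact: bool = True) -> FuFs:
    sp = ewens_k_tail(n, k_obs, theta, exact=exact)
    if isinstance(sp, Fraction):
        if sp == 1:
            return FuFs(_LOG_ODDS_CLAMP, 1.0, True)
        if sp == 0:
            return FuFs(-_LOG_ODDS_CLAMP, 0.0, True)
        fs = (math.log(sp.numerator) - math.log(sp.denominator)) - (
            math.log((1 - sp).numerator) - math.log((1 - sp).denominator)
        )
        return FuFs(fs, float(sp), False)
    if sp >= 1.0:
        return FuFs(_LOG_ODDS_CLAMP, 1.0, True)
    if sp <= 0.0:
        return FuFs(-_LOG_ODDS_CLAMP, 0.0, True)
    return FuFs(math.log(sp / (1.0 - sp)), sp, False)


def ramos_onsins_r2(aln: LocusAlignment) -> float:
    """Ramos-Onsins & Rozas R2: singleton load contrasted with pi."""
    s, _ = segregating_sites(aln)
    if s == 0:
        return math.nan
    u = singleton_counts(aln)
    return _r2_from(u, pi_total(aln), s)


def _r2_from(u: np.ndarray, pi_tot: float, s: int) -> float:
    n = u.size
    return float(math.sqrt(np.sum((u - pi_tot / 2.0) ** 2) / n) / s)


# ---------------------------------------------------------------------------
# two-population differentiation


def _check_pair(alnA: LocusAlignment, alnB: LocusAlignment) -> None:
    if not np.array_equal(alnA.kept_sites, alnB.kept_sites):
        raise ValueError(
            f"{alnA.locus_name}/{alnB.locus_name}: kept_sites universes differ"
        )


def dxy(alnA: LocusAlignment, alnB: LocusAlignment) -> float:
    """Average between-population pairwise substitutions per site."""
    _check_pair(alnA, alnB)
    ca = allele_counts(_require(alnA)).astype(float)
    cb = allele_counts(_require(alnB)).astype(float)
    na = ca.sum(axis=0)
    nb = cb.sum(axis=0)
    pairs = na * nb
    same = (ca * cb).sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_col = np.where(pairs > 0, 1.0 - same / np.where(pairs > 0, pairs, 1.0), 0.0)
    return float(per_col.sum()) / alnA.kept_sites.size


@dataclass(frozen=True)
class SiteClasses:
    """Counts of shared, fixed and exclusive polymorphic columns."""

    ss: int
    sf: int
    sx1: int
    sx2: int


def classify_polymorphisms(alnA: LocusAlignment, alnB: LocusAlignment) -> SiteClasses:
    """Classify each kept column as shared / fixed / exclusive.

    Shared requires >= 2 residues segregating in *both* populations (the
    same-residues definition).  A column polymorphic in both populations with
    fewer than two common residues is a multi-allelic corner case that cannot
    occur under infinite sites; it is assigned to the exclusive class of the
    population with more distinct residues (ties to population 1) so that the
    four classes always partition the non-monomorphic-identical columns.
    """
    _check_pair(alnA, alnB)
    ca = allele_counts(_require(alnA)) > 0
    cb = allele_counts(_require(alnB)) > 0
    ss = sf = sx1 = sx2 = 0
    for col in range(ca.shape[1]):
        a = ca[:, col]
        b = cb[:, col]
        ka, kb = int(a.sum()), int(b.sum())
        if ka == 0 or kb == 0:  # column entirely missing in one side
            continue
        poly_a, poly_b = ka >= 2, kb >= 2
        common = int((a & b).sum())
        if not poly_a and not poly_b:
            if common == 0:
                sf += 1
        elif poly_a and poly_b:
            if common >= 2:
                ss += 1
            elif ka >= kb:
                sx1 += 1
            else:
                sx2 += 1
        elif poly_a:
            sx1 += 1
        else:
            sx2 += 1
    return SiteClasses(ss=ss, sf=sf, sx1=sx1, sx2=sx2)


def hudson_fst(alnA: LocusAlignment, alnB: LocusAlignment) -> float:
    """Hudson-type FST = 1 - Hw/Hb on mean pairwise differences.

    Hw averages the two within-population mean pairwise difference counts, Hb
    is the between-population mean.  Slightly negative estimates are reported
    as computed; NaN when there is no variation anywhere (Hb = 0).
    """
    _check_pair(alnA, alnB)
    return _fst_from_counts(
        allele_counts(_require(alnA)).astype(float),
        allele_counts(_require(alnB)).astype(float),
    )


def _fst_from_counts(ca: np.ndarray, cb: np.ndarray) -> float:
    na = ca.sum(axis=0)
    nb = cb.sum(axis=0)

    def within(c: np.ndarray, n: np.ndarray) -> float:
        pairs = n * (n - 1) / 2.0
        same = (c * (c - 1) / 2.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            per = np.where(pairs > 0, 1.0 - same / np.where(pairs > 0, pairs, 1.0), 0.0)
        return float(per.sum())

    hw = 0.5 * (within(ca, na) + within(cb, nb))
    pairs_b = na * nb
    same_b = (ca * cb).sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_b = np.where(pairs_b > 0, 1.0 - same_b / np.where(pairs_b > 0, pairs_b, 1.0), 0.0)
    hb = float(per_b.sum())
    if hb == 0.0:
        return math.nan
    return 1.0 - hw / hb


@dataclass(frozen=True)
class FstPermutation:
    fst: float
    p: float
    n_perm: int


def fst_permutation_test(
    alnA: LocusAlignment,
    alnB: LocusAlignment,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> FstPermutation:
    """Permutation p-value for Hudson FST, shuffling sequences between labels.

    Uses the add-one estimator p = (1 + #{FST* >= FST}) / (n_perm + 1).
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    observed = hudson_fst(alnA, alnB)
    if math.isnan(observed):
        return FstPermutation(observed, math.nan, n_perm)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    matA, matB = alnA.matrix(), alnB.matrix()
    pooled = np.vstack([matA, matB])
    na = matA.shape[0]
    n_total = pooled.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        ca = allele_counts(pooled[perm[:na]]).astype(float)
        cb = allele_counts(pooled[perm[na:]]).astype(float)
        f = _fst_from_counts(ca, cb)
        if not math.isnan(f) and f >= observed:
            count += 1
    return FstPermutation(observed, (1 + count) / (n_perm + 1), n_perm)


@dataclass(frozen=True)
class PopPairDiff:
    """Per-locus differentiation record for one population pair."""

    locus_name: str
    fst: float
    fst_p: float
    ss: int
    sf: int
    sx1: int
    sx2: int
    dxy: float


def pair_differentiation(
    aln: LocusAlignment,
    pop1: str,
    pop2: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PopPairDiff:
    """Full differentiation record between two populations of one alignment."""
    a = aln.subset_population(pop1)
    b = aln.subset_population(pop2)
    perm = fst_permutation_test(a, b, n_perm=n_perm, seed=seed)
    classes = classify_polymorphisms(a, b)
    return PopPairDiff(
        locus_name=aln.locus_name,
        fst=perm.fst,
        fst_p=perm.p,
        ss=classes.ss,
        sf=classes.sf,
        sx1=classes.sx1,
        sx2=classes.sx2,
        dxy=dxy(a, b),
    )


# ---------------------------------------------------------------------------
# neutral null distributions (conditional on n and S)


def _simulate_branch_pool(n: int, rng: np.random.Generator) -> tuple[list[frozenset[int]], np.ndarray]:
    """One Kingman genealogy: branches as (leaf set, length) pairs."""
    active: list[tuple[frozenset[int], float]] = [(frozenset([i]), 0.0) for i in range(n)]
    branches: list[frozenset[int]] = []
    lengths: list[float] = []
    k = n
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        active = [(s, ln + t) for s, ln in active]
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        si, li = active[i]
        sj, lj = active[j]
        branches.extend([si, sj])
        lengths.extend([li, lj])
        del active[j], active[i]
        active.append((si | sj, 0.0))
        k -= 1
    return branches, np.asarray(lengths)


def simulate_neutral_stats(
    n: int,
    S: int,
    n_reps: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Null distributions of D, Fs and R2 under the standard neutral coalescent
    conditional on the sample size and number of segregating sites.
    """
    if S <= 0:
        raise ValueError("conditional simulation needs S > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = np.empty(n_reps)
    fs = np.empty(n_reps)
    r2 = np.empty(n_reps)
    for rep in range(n_reps):
        branches, lengths = _simulate_branch_pool(n, rng)
        probs = lengths / lengths.sum()
        alloc = rng.multinomial(S, probs)
        derived = [b for b, c in zip(branches, alloc) for _ in range(int(c))]
        counts = np.array([len(b) for b in derived])
        pi_tot = float(np.sum(2.0 * counts * (n - counts)) / (n * (n - 1)))
        d[rep] = _tajimas_d_from(n, S, pi_tot)
        u = np.zeros(n, dtype=np.intp)
        for b, c in zip(derived, counts):
            if c == 1:
                u[next(iter(b))] += 1
            elif c == n - 1:
                missing = next(iter(frozenset(range(n)) - b))
                u[missing] += 1
        r2[rep] = _r2_from(u, pi_tot, S)
        haplos = {tuple(sorted(i for i, b in enumerate(derived) if leaf in b)) for leaf in range(n)}
        fs[rep] = _fus_fs_from(n, len(haplos), pi_tot, exact=False).fs
    return {"D": d, "Fs": fs, "R2": r2}


def neutrality_pvalues(
    aln: LocusAlignment,
    n_reps: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> dict[str, float]:
    """Simulation p-values for D (two-sided), Fs (lower tail), R2 (lower tail)."""
    s, _ = segregating_sites(aln)
    if s == 0:
        return {"D": math.nan, "Fs": math.nan, "R2": math.nan}
    null = simulate_neutral_stats(aln.n, s, n_reps=n_reps, seed=seed)
    d_obs = tajimas_d(aln)
    fs_obs = fus_fs(aln).fs
    r2_obs = ramos_onsins_r2(aln)
    n_reps = len(null["D"])
    p_lo = (1 + np.sum(null["D"] <= d_obs)) / (n_reps + 1)
    p_hi = (1 + np.sum(null["D"] >= d_obs)) / (n_reps + 1)
    return {
        "D": min(1.0, 2 * min(p_lo, p_hi)),
        "Fs": (1 + np.sum(null["Fs"] <= fs_obs)) / (n_reps + 1),
        "R2": (1 + np.sum(null["R2"] <= r2_obs)) / (n_reps + 1),
    }
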