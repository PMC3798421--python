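"""Two-population isolation-with-migration (IM) model.

The model: an ancestral population (mutation-scaled size ``thetaA``) splits at
time ``t`` into two populations of sizes ``theta1`` and ``theta2`` that then
exchange migrants at rates ``m1`` and ``m2``.  All parameters are in
mutational units — theta_j = 4 N_j mu per locus, t = t_years * mu_year, and
m_j = m_gen / mu is the rate at which lineages sampled in population j trace
their ancestry to the other population.  On this time scale a pair of
lineages in population j coalesces at rate 2/theta_j, each lineage migrates
at rate m_j, and mutations fall on the genealogy as a Poisson process of rate
1 per unit branch length, so that for a sample of two E[pi] = theta.

Ancestry is generated with msprime (haploid samples, population size
theta_j/2, split into the ancestral population at time t) and mutations under
the infinite-sites model are mapped onto distinct alignment columns, yielding
ordinary alignments the statistics layer consumes.

Estimation replaces the genealogy-sampling MCMC of the original IM machinery
with rejection ABC over the identical six-parameter model: draw parameters
from box priors, simulate the full multilocus design, and keep the draws
whose summary statistics are closest to the observed ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import msprime
import numpy as np
import tskit

from .alignments import LocusAlignment
from . import popgen

STAT_NAMES = (
    "pi1", "pi2", "fst", "ss", "sf", "sx1", "sx2", "dxy",
    "pi_contrast", "sx_contrast", "min12", "min21", "min_contrast",
)

DEFAULT_PRIORS: dict[str, tuple[float, float]] = {
    "theta1": (0.0, 10.0),
    "theta2": (0.0, 10.0),
    "thetaA": (0.0, 10.0),
    "t": (0.0, 5.0),
    "m1": (0.0, 25.0),
    "m2": (0.0, 25.0),
}

_PARAM_ORDER = ("theta1", "theta2", "thetaA", "t", "m1", "m2")


class InfiniteSitesViolation(RuntimeError):
    """More mutations than alignment columns; retry or enlarge the locus."""


@dataclass(frozen=True)
class IMParams:
    """Six-parameter IM model state, all in mutational units."""

    theta1: float
    theta2: float
    thetaA: float
    t: float
    m1: float
    m2: float

    def __post_init__(self) -> None:
        for name in _PARAM_ORDER:
            if getattr(self, name) < 0:
                raise ValueError(f"IM parameter {name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in _PARAM_ORDER])

    @staticmethod
    def from_array(x: np.ndarray) -> "IMParams":
        return IMParams(**dict(zip(_PARAM_ORDER, map(float, x))))


@dataclass(frozen=True)
class SimLocusSpec:
    n1: int
    n2: int
    length: int
    inheritance: float = 1.0

    def __post_init__(self) -> None:
        if self.n1 + self.n2 < 2:
            raise ValueError("need at least 2 sampled sequences")


def _demography(p: IMParams) -> msprime.Demography:
    d = msprime.Demography()
    eps = 1e-6  # msprime rejects zero sizes/split times; negligible vs O(1) params
    d.add_population(name="p1", initial_size=max(p.theta1, eps) / 2)
    d.add_population(name="p2", initial_size=max(p.theta2, eps) / 2)
    d.add_population(name="anc", initial_size=max(p.thetaA, eps) / 2)
    # backwards-time lineage movement: a lineage in p1 jumps to p2 at rate m1
    d.set_migration_rate(source="p1", dest="p2", rate=p.m1)
    d.set_migration_rate(source="p2", dest="p1", rate=p.m2)
    d.add_population_split(time=max(p.t, eps), derived=["p1", "p2"], ancestral="anc")
    return d


def _drop_mutations(ts: "tskit.TreeSequence", rng: np.random.Generator) -> np.ndarray:
    """Poisson(rate 1 per unit branch length) infinite-sites mutations on the
    single genealogy, as a (sites, samples) 0/1 derived-allele matrix."""
    tree = ts.first()
    nodes = [u for u in tree.nodes() if tree.parent(u) != tskit.NULL]
    blen = np.array([tree.branch_length(u) for u in nodes])
    total = float(blen.sum())
    k = int(rng.poisson(total))
    g = np.zeros((k, ts.num_samples), dtype=np.uint8)
    if k:
        chosen = rng.choice(len(nodes), size=k, p=blen / total)
        for row, idx in enumerate(chosen):
            g[row, list(tree.samples(nodes[int(idx)]))] = 1
    return g


def simulate_im_genotypes(
    p: IMParams,
    spec: SimLocusSpec,
    seed: int,
    record_migrations: bool = False,
) -> tuple[np.ndarray, int]:
    """Simulate one locus; returns a (sites, n1+n2) 0/1 derived-allele matrix
    (population-1 samples first) and the realized migration-event count."""
    ts = msprime.sim_ancestry(
        samples={"p1": spec.n1, "p2": spec.n2},
        demography=_demography(p),
        ploidy=1,
        random_seed=seed,
        record_migrations=record_migrations,
    )
    rng = np.random.default_rng(seed)
    return _drop_mutations(ts, rng), int(ts.num_migrations)


def simulate_im_genotypes_batch(
    p: IMParams,
    spec: SimLocusSpec,
    n_reps: int,
    seed: int,
):
    """Yield ``n_reps`` independent genotype matrices for one locus design.

    Amortizes the per-call ancestry-simulation setup; identical model to
    :func:`simulate_im_genotypes`.
    """
    rng = np.random.default_rng(seed)
    reps = msprime.sim_ancestry(
        samples={"p1": spec.n1, "p2": spec.n2},
        demography=_demography(p),
        ploidy=1,
        random_seed=seed,
        num_replicates=n_reps,
    )
    for ts in reps:
        yield _drop_mutations(ts, rng)


_BASES = "ACGT"


def genotypes_to_alignment(
    g: np.ndarray,
    spec: SimLocusSpec,
    rng: np.random.Generator,
    locus_name: str = "locus",
    pop_labels: tuple[str, str] = ("pop1", "pop2"),
    id_prefix: str = "",
) -> LocusAlignment:
    """Map infinite-sites 0/1 genotypes onto a nucleotide alignment.

    Each segregating site is assigned a distinct uniformly chosen column; the
    derived state is a random base different from the ancestral one.
    """
    s, n = g.shape
    if s > spec.length:
        raise InfiniteSitesViolation(
            f"{locus_name}: {s} mutations exceed {spec.length} columns"
        )
    ref = rng.integers(0, 4, size=spec.length)
    cols = rng.choice(spec.length, size=s, replace=False) if s else np.array([], dtype=int)
    mat = np.tile(ref, (n, 1))
    for k in range(s):
        derived = (ref[cols[k]] + rng.integers(1, 4)) % 4
        mat[g[k] == 1, cols[k]] = derived
    seqs = tuple("".join(_BASES[b] for b in row) for row in mat)
    ids = tuple(
        f"{id_prefix}{pop_labels[0]}_{i}" for i in range(spec.n1)
    ) + tuple(f"{id_prefix}{pop_labels[1]}_{i}" for i in range(spec.n2))
    pops = (pop_labels[0],) * spec.n1 + (pop_labels[1],) * spec.n2
    return LocusAlignment(locus_name=locus_name, ids=ids, populations=pops, sequences=seqs)


def simulate_im_locus(
    p: IMParams,
    spec: SimLocusSpec,
    seed: int,
    locus_name: str = "locus",
    pop_labels: tuple[str, str] = ("pop1", "pop2"),
    max_retries: int = 20,
) -> tuple[LocusAlignment, int]:
    """Simulate one locus as an alignment; retries fresh seeds on the rare
    infinite-sites overflow.  Returns (alignment, migration event count)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        msp_seed = int(rng.integers(1, 2**31))
        g, n_mig = simulate_im_genotypes(p, spec, msp_seed, record_migrations=True)
        try:
            aln = genotypes_to_alignment(
                g, spec, rng, locus_name=locus_name, pop_labels=pop_labels
            )
        except InfiniteSitesViolation:
            continue
        return aln, n_mig
    raise InfiniteSitesViolation(
        f"{locus_name}: could not fit mutations into {spec.length} columns "
        f"after {max_retries} attempts"
    )


def ms_style_text(genotype_matrices: list[np.ndarray], seed: int | None = None) -> str:
    """Render simulated loci in the classic ms segregating-sites text format
    (``segsites:`` / ``positions:`` / 0-1 haplotype rows), for cross-checking
    against external coalescent simulators."""
    rng = np.random.default_rng(seed)
    out = ["introdiv-im", ""]
    for g in genotype_matrices:
        s, n = g.shape
        out.append("//")
        out.append(f"segsites: {s}")
        if s:
            pos = np.sort(rng.uniform(size=s))
            out.append("positions: " + " ".join(f"{p:.5f}" for p in pos))
            for hap in g.T:
                out.append("".join(map(str, hap)))
        out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# summary statistics


def _min_cross_distances(d: np.ndarray) -> tuple[float, float]:
    """(min12, min21): mean over each population's sequences of the Hamming
    distance to the nearest sequence of the other population, from a
    (n2, n1) cross-distance matrix."""
    return float(d.min(axis=0).mean()), float(d.min(axis=1).mean())


def locus_pair_stats(g: np.ndarray, n1: int, length: int) -> np.ndarray:
    """The per-locus summary statistics from a 0/1 genotype matrix.

    (pi1, pi2, fst, ss, sf, sx1, sx2, dxy, pi_contrast, sx_contrast, min12,
    min21, min_contrast); pi and dxy per site, site-class counts on the count
    scale, FST NaN when there is no variation at all.

    The contrasts and the nearest-neighbour distances are directional
    statistics for asymmetric gene flow: introgression into population 2
    pulls its diversity toward the donor's, inflates its private
    polymorphism, and — because migrant haplotypes are near-copies of donor
    haplotypes — collapses the distance from each donor sequence to its
    nearest counterpart in the recipient (min12 small when flow is into
    population 2, min21 small when into population 1; both per site).
    """
    n = g.shape[1]
    n2 = n - n1
    c1 = g[:, :n1].sum(axis=1).astype(float)
    c2 = g[:, n1:].sum(axis=1).astype(float)
    pi1_tot = float(np.sum(2 * c1 * (n1 - c1)) / (n1 * (n1 - 1))) if n1 > 1 else 0.0
    pi2_tot = float(np.sum(2 * c2 * (n2 - c2)) / (n2 * (n2 - 1))) if n2 > 1 else 0.0
    dxy_tot = float(np.sum(c1 * (n2 - c2) + (n1 - c1) * c2) / (n1 * n2))
    poly1 = (c1 > 0) & (c1 < n1)
    poly2 = (c2 > 0) & (c2 < n2)
    ss = int(np.sum(poly1 & poly2))
    sf = int(np.sum(((c1 == 0) & (c2 == n2)) | ((c1 == n1) & (c2 == 0))))
    sx1 = int(np.sum(poly1 & ~poly2))
    sx2 = int(np.sum(poly2 & ~poly1))
    hw = 0.5 * (pi1_tot + pi2_tot)
    fst = 1.0 - hw / dxy_tot if dxy_tot > 0 else math.nan
    pi1, pi2 = pi1_tot / length, pi2_tot / length
    cross = (g[:, n1:, None] != g[:, None, :n1]).sum(axis=0)  # (n2, n1)
    min12, min21 = _min_cross_distances(cross)
    min12 /= length
    min21 /= length
    return np.array(
        [
            pi1, pi2, fst, ss, sf, sx1, sx2, dxy_tot / length,
            pi2 - pi1, sx2 - sx1, min12, min21, min12 - min21,
        ]
    )


def locus_pair_stats_from_alignments(
    alnA: LocusAlignment, alnB: LocusAlignment
) -> np.ndarray:
    """Same eight statistics computed through the alignment statistics layer."""
    L = alnA.kept_sites.size
    classes = popgen.classify_polymorphisms(alnA, alnB)
    pi1 = popgen.pi_total(alnA) / L
    pi2 = popgen.pi_total(alnB) / L
    ma = alnA.matrix()
    mb = alnB.matrix()
    cross = (mb[:, None, :] != ma[None, :, :]).sum(axis=2)  # (n2, n1)
    min12, min21 = _min_cross_distances(cross)
    min12 /= L
    min21 /= L
    return np.array(
        [
            pi1,
            pi2,
            popgen.hudson_fst(alnA, alnB),
            classes.ss,
            classes.sf,
            classes.sx1,
            classes.sx2,
            popgen.dxy(alnA, alnB),
            pi2 - pi1,
            classes.sx2 - classes.sx1,
            min12,
            min21,
            min12 - min21,
        ]
    )


def dataset_summary_stats(pairs: list[tuple[LocusAlignment, LocusAlignment]]) -> np.ndarray:
    """(mean, variance) across loci of the eight per-locus statistics.

    NaN FSTs (invariant loci) are excluded from the moments; an all-NaN
    component is reported as 0 (the flagging happens at the ABC layer).
    """
    if not pairs:
        raise ValueError("need at least one locus")
    table = np.array([locus_pair_stats_from_alignments(a, b) for a, b in pairs])
    return _moments(table)


def _moments(table: np.ndarray) -> np.ndarray:
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(table, axis=0)
        var = np.nanvar(table, axis=0)
    means = np.nan_to_num(means, nan=0.0)
    var = np.nan_to_num(var, nan=0.0)
    return np.concatenate([means, var])


# ---------------------------------------------------------------------------
# rejection ABC


@dataclass(frozen=True)
class ABCResult:
    """Accepted parameter draws (rows) with their distances."""

    param_names: tuple[str, ...]
    accepted: np.ndarray
    distances: np.ndarray
    n_sims: int
    accept_frac: float

    def posterior_mean(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.accepted.mean(axis=0)))

    def posterior_median(self) -> dict[str, float]:
        return dict(zip(self.param_names, np.median(self.accepted, axis=0)))

    def quantiles(self, q: tuple[float, float] = (0.05, 0.95)) -> dict[str, tuple[float, float]]:
        lo = np.quantile(self.accepted, q[0], axis=0)
        hi = np.quantile(self.accepted, q[1], axis=0)
        return {n: (float(a), float(b)) for n, a, b in zip(self.param_names, lo, hi)}

    def to_dataframe(self):
        """Accepted draws plus distances as a pandas DataFrame (TSV-ready)."""
        import pandas as pd

        df = pd.DataFrame(self.accepted, columns=list(self.param_names))
        df["distance"] = self.distances
        return df


def _simulate_dataset_stats(
    p: IMParams, specs: list[SimLocusSpec], rng: np.random.Generator
) -> np.ndarray:
    groups: dict[tuple[int, int], list[int]] = {}
    for i, spec in enumerate(specs):
        groups.setdefault((spec.n1, spec.n2), []).append(i)
    rows: list[np.ndarray | None] = [None] * len(specs)
    for idx in groups.values():
        spec0 = specs[idx[0]]
        gen = simulate_im_genotypes_batch(
            p, spec0, n_reps=len(idx), seed=int(rng.integers(1, 2**31))
        )
        for i, g in zip(idx, gen):
            rows[i] = locus_pair_stats(g, specs[i].n1, specs[i].length)
    return _moments(np.array(rows))


def _reject_and_adjust(
    draws: np.ndarray,
    sims: np.ndarray,
    observed: np.ndarray,
    accept_frac: float,
    bounds: np.ndarray,
    adjust: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection step with optional local-linear regression adjustment.

    The adjustment regresses accepted parameter draws on the normalized
    statistic mismatch and shifts them to the observed point (clipped back
    into the prior box) — the standard sharpening of plain rejection.
    """
    sims = np.where(np.isfinite(sims), sims, 0.0)
    observed = np.where(np.isfinite(observed), observed, 0.0)
    sd = sims.std(axis=0)
    sd[sd == 0] = 1.0
    dist = np.sqrt(np.sum(((sims - observed) / sd) ** 2, axis=1))
    n_keep = max(2, int(round(accept_frac * len(draws))))
    order = np.argsort(dist, kind="stable")[:n_keep]
    acc = draws[order].copy()
    if adjust and n_keep > observed.size + 2:
        x = (sims[order] - observed) / sd
        design = np.column_stack([np.ones(n_keep), x])
        beta, *_ = np.linalg.lstsq(design, acc, rcond=None)
        acc = acc - x @ beta[1:]
        acc = np.clip(acc, bounds[:, 0], bounds[:, 1])
    return acc, dist[order]


def abc_estimate(
    observed: np.ndarray,
    specs: list[SimLocusSpec],
    priors: dict[str, tuple[float, float]] | None = None,
    n_sims: int = 10000,
    accept_frac: float = 0.02,
    seed: int | None = None,
    adjust: bool = True,
) -> ABCResult:
    """Rejection ABC over the six IM parameters.

    Draws parameters from uniform box priors, simulates the full multilocus
    design for each draw, and keeps the ``accept_frac`` fraction of draws
    closest to ``observed`` in SD-normalized Euclidean distance over the
    summary-statistic vector, optionally regression-adjusted
    (``adjust=False`` gives plain rejection; ``accept_frac=1`` with no
    adjustment returns the prior draws).
    """
    observed = np.asarray(observed, dtype=float)
    if np.all(~np.isfinite(observed)) or np.all(observed == 0):
        raise ValueError("observed summary statistics are degenerate")
    priors = dict(DEFAULT_PRIORS if priors is None else priors)
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.column_stack(
        [rng.uniform(*priors[name], size=n_sims) for name in _PARAM_ORDER]
    )
    sims = np.empty((n_sims, observed.size))
    for i in range(n_sims):
        p = IMParams.from_array(draws[i])
        sims[i] = _simulate_dataset_stats(p, specs, rng)
    bounds = np.array([priors[name] for name in _PARAM_ORDER])
    acc, dist = _reject_and_adjust(draws, sims, observed, accept_frac, bounds, adjust)
    return ABCResult(
        param_names=_PARAM_ORDER,
        accepted=acc,
        distances=dist,
        n_sims=n_sims,
        accept_frac=accept_frac,
    )


def abc_migration_estimate(
    observed: np.ndarray,
    base: IMParams,
    specs: list[SimLocusSpec],
    priors: dict[str, tuple[float, float]] | None = None,
    n_sims: int = 2000,
    accept_frac: float = 0.1,
    seed: int | None = None,
    adjust: bool = True,
) -> ABCResult:
    """Dataset-level ABC over (m1, m2) with the shared demography fixed.

    Mirrors the estimation design of running separate passes for the
    population migration rates once the size/split parameters are pinned
    down; with only two free dimensions the same simulation budget resolves
    the direction of gene flow far better than the joint fit.
    """
    observed = np.asarray(observed, dtype=float)
    priors = dict(DEFAULT_PRIORS if priors is None else priors)
    rng = np.random.default_rng(seed)
    draws = np.column_stack(
        [rng.uniform(*priors[k], size=n_sims) for k in ("m1", "m2")]
    )
    sims = np.empty((n_sims, observed.size))
    for i in range(n_sims):
        p = IMParams(
            base.theta1, base.theta2, base.thetaA, base.t,
            float(draws[i, 0]), float(draws[i, 1]),
        )
        sims[i] = _simulate_dataset_stats(p, specs, rng)
    bounds = np.array([priors[k] for k in ("m1", "m2")])
    acc, dist = _reject_and_adjust(draws, sims, observed, accept_frac, bounds, adjust)
    return ABCResult(
        param_names=("m1", "m2"),
        accepted=acc,
        distances=dist,
        n_sims=n_sims,
        accept_frac=accept_frac,
    )


@dataclass(frozen=True)
class LocusMigrationPosterior:
    locus_name: str
    m1: np.ndarray
    m2: np.ndarray
    flat: bool


def per_locus_migration_profile(
    observed_per_locus: list[np.ndarray],
    base: IMParams,
    specs: list[SimLocusSpec],
    locus_names: list[str] | None = None,
    priors: dict[str, tuple[float, float]] | None = None,
    n_sims: int = 2000,
    accept_frac: float = 0.05,
    seed: int | None = None,
    flat_iqr_ratio: float = 0.8,
) -> list[LocusMigrationPosterior]:
    """Per-locus rejection ABC over (m1, m2) with the shared demography fixed.

    A locus is flagged flat when the accepted draws span nearly the whole
    prior (mean posterior/prior IQR ratio above ``flat_iqr_ratio``) — weakly
    divergent, freely introgressing loci carry almost no information about
    their migration rates.
    """
    priors = dict(DEFAULT_PRIORS if priors is None else priors)
    rng = np.random.default_rng(seed)
    names = locus_names or [f"locus{i}" for i in range(len(specs))]
    out = []
    for obs, spec, name in zip(observed_per_locus, specs, names):
        obs = np.asarray(obs, dtype=float)
        draws = np.column_stack(
            [
                rng.uniform(*priors["m1"], size=n_sims),
                rng.uniform(*priors["m2"], size=n_sims),
            ]
        )
        sims = np.empty((n_sims, obs.size))
        for i in range(n_sims):
            p = IMParams(
                base.theta1, base.theta2, base.thetaA, base.t,
                float(draws[i, 0]), float(draws[i, 1]),
            )
            g, _ = simulate_im_genotypes(p, spec, int(rng.integers(1, 2**31)))
            sims[i] = locus_pair_stats(g, spec.n1, spec.length)
        finite_obs = np.where(np.isfinite(obs), obs, 0.0)
        sims = np.where(np.isfinite(sims), sims, 0.0)
        sd = sims.std(axis=0)
        sd[sd == 0] = 1.0
        dist = np.sqrt(np.sum(((sims - finite_obs) / sd) ** 2, axis=1))
        n_keep = max(1, int(round(accept_frac * n_sims)))
        order = np.argsort(dist, kind="stable")[:n_keep]
        acc = draws[order]
        ratios = []
        for k, pname in enumerate(("m1", "m2")):
            prior_iqr = 0.5 * (priors[pname][1] - priors[pname][0])
            post_iqr = np.subtract(*np.quantile(acc[:, k], [0.75, 0.25]))
            ratios.append(post_iqr / prior_iqr if prior_iqr > 0 else 0.0)
        out.append(
            LocusMigrationPosterior(
                locus_name=name,
                m1=acc[:, 0],
                m2=acc[:, 1],
                flat=bool(np.mean(ratios) > flat_iqr_ratio),
            )
        )
    return out


# ---------------------------------------------------------------------------
# demographic unit conversion


@dataclass(frozen=True)
class MutationRateModel:
    """Per-year mutation rates used to rescale IM parameter estimates.

    Per-locus rates combine synonymous and non-synonymous site classes:
    mu_i = L_i * (f_syn_i * syn_rate + (1 - f_syn_i) * nonsyn_rate); their
    geometric mean converts mutational units to years and individuals.  When
    no per-locus annotation is supplied, ``mu_override`` (default 1.77e-6
    per locus per year) is used directly.
    """

    syn_rate: float = 1.56e-8
    nonsyn_rate: float = 1.91e-9
    generations_per_year: float = 10.0
    lengths: tuple[int, ...] | None = None
    syn_fractions: tuple[float, ...] | None = None
    mu_override: float | None = 1.77e-6

    def mu_locus(self) -> np.ndarray:
        if self.lengths is None or self.syn_fractions is None:
            raise ValueError("per-locus rates need lengths and syn_fractions")
        L = np.asarray(self.lengths, dtype=float)
        if np.any(L <= 0):
            raise ValueError("locus lengths must be positive")
        f = np.asarray(self.syn_fractions, dtype=float)
        return L * (f * self.syn_rate + (1.0 - f) * self.nonsyn_rate)

    @property
    def mu_gm(self) -> float:
        if self.lengths is not None and self.syn_fractions is not None:
            return geometric_mean_mu(self)
        if self.mu_override is None:
            raise ValueError("no mutation-rate information supplied")
        return self.mu_override


def geometric_mean_mu(rates: MutationRateModel) -> float:
    """Geometric mean of the per-locus per-year mutation rates."""
    mu = rates.mu_locus()
    return float(np.exp(np.mean(np.log(mu))))


@dataclass(frozen=True)
class DemographicEstimates:
    """IM parameters converted to demographic units."""

    N1: float
    N2: float
    NA: float
    t_years: float
    nm1: float  # 2Nm toward population 1
    nm2: float


def convert_units(p: IMParams, rates: MutationRateModel) -> DemographicEstimates:
    """Convert mutational-unit IM parameters to individuals, years and 2Nm.

    N_j = theta_j * g / (4 mu), t_years = t / mu (mu per locus per year, g
    generations per year), and the effective number of migrant gene copies
    per generation in each direction is 2Nm_j = theta_j * m_j / 2.
    """
    mu = rates.mu_gm
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    g = rates.generations_per_year
    return DemographicEstimates(
        N1=p.theta1 * g / (4.0 * mu),
        N2=p.theta2 * g / (4.0 * mu),
        NA=p.thetaA * g / (4.0 * mu),
        t_years=p.t / mu,
        nm1=p.theta1 * p.m1 / 2.0,
        nm2=p.theta2 * p.m2 / 2.0,
    )


def invert_units(d: DemographicEstimates, rates: MutationRateModel) -> IMParams:
    """Inverse of :func:`convert_units` (round-trip identity check)."""
    mu = rates.mu_gm
    g = rates.generations_per_year
    theta1 = d.N1 * 4.0 * mu / g
    theta2 = d.N2 * 4.0 * mu / g
    return IMParams(
        theta1=theta1,
        theta2=theta2,
        thetaA=d.NA * 4.0 * mu / g,
        t=d.t_years * mu,
        m1=2.0 * d.nm1 / theta1 if theta1 > 0 else 0.0,
        m2=2.0 * d.nm2 / theta2 if theta2 > 0 else 0.0,
    )
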