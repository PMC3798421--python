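"""Multilocus HKA goodness-of-fit test for two populations.

Under neutrality, polymorphism within each population and divergence between
them should be proportional across loci, all driven by the per-locus mutation
parameter theta_i.  The three observation cells per locus are

    E[S1_i] = theta_i * a(n1_i)
    E[S2_i] = f * theta_i * a(n2_i)
    E[D_i]  = theta_i * (T + (1 + f) / 2)

with a(n) = sum_{i<n} 1/i, f the population-2/population-1 size ratio and T
the scaled divergence time.  D_i is the mean between-population pairwise
difference on the count scale (it includes within-species polymorphism, hence
the (1+f)/2 term).  Variances follow the standard formulation: each cell's
variance is its expectation plus the square of the coalescent-scale part
(theta_i a2(n) for polymorphism cells, (theta_i (1+f)/2)^2 for divergence).

The moment system is solved exactly: given (T, f) each theta_i comes from the
per-locus totals, and the two aggregate equations for sum(S2) and sum(D) are
solved for (T, f) with a damped Newton iteration.  The statistic is referred
to a chi-square distribution with df = 2L - 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats


@dataclass(frozen=True)
class HkaLocus:
    """Observed cells for one locus: polymorphism in each population, divergence."""

    name: str
    S1: float
    S2: float
    D: float
    n1: int
    n2: int
    L: int = 0


@dataclass(frozen=True)
class HkaResult:
    chi2: float
    df: int
    p_value: float
    T_hat: float
    f_hat: float
    theta_hat: dict[str, float]
    expected: dict[str, tuple[float, float, float]]  # name -> (E[S1], E[S2], E[D])
    excluded: tuple[str, ...]


def _a1(n: int) -> float:
    return sum(1.0 / i for i in range(1, n))


def _a2(n: int) -> float:
    return sum(1.0 / i**2 for i in range(1, n))


def _thetas(loci: list[HkaLocus], T: float, f: float) -> np.ndarray:
    tot = np.array([loc.S1 + loc.S2 + loc.D for loc in loci])
    denom = np.array(
        [_a1(loc.n1) + f * _a1(loc.n2) + T + (1.0 + f) / 2.0 for loc in loci]
    )
    return tot / denom


def hka_fit(loci: list[HkaLocus]) -> HkaResult:
    """Fit the multilocus HKA moment system and return the chi-square summary.

    Loci with S1 = S2 = D = 0 carry no information and are excluded with a
    warning.  Raises if the (T, f) solver fails to reduce the moment residuals
    below tolerance.
    """
    kept = [loc for loc in loci if (loc.S1 + loc.S2 + loc.D) > 0]
    excluded = tuple(loc.name for loc in loci if (loc.S1 + loc.S2 + loc.D) <= 0)
    if excluded:
        warnings.warn(f"HKA: excluding uninformative loci {excluded}", stacklevel=2)
    if len(kept) < 2:
        raise ValueError("HKA needs at least 2 informative loci")
    sum_s2 = sum(loc.S2 for loc in kept)
    sum_d = sum(loc.D for loc in kept)

    def residuals(x: np.ndarray) -> np.ndarray:
        T, f = x
        th = _thetas(kept, T, f)
        r1 = sum_s2 - f * sum(t * _a1(loc.n2) for t, loc in zip(th, kept))
        r2 = sum_d - sum(t * (T + (1.0 + f) / 2.0) for t in th)
        return np.array([r2, r1])

    sum_s1 = sum(loc.S1 for loc in kept)
    f0 = max(sum_s2 / sum_s1, 1e-3) if sum_s1 > 0 else 1.0
    T0 = max(sum_d / max(sum_s1, 1e-9), 0.1)
    sol = optimize.root(residuals, x0=[T0, f0], method="hybr", tol=1e-12)
    T_hat, f_hat = sol.x
    resid = residuals(sol.x)
    scale = max(sum_s1 + sum_s2 + sum_d, 1.0)
    if not sol.success or np.max(np.abs(resid)) / scale > 1e-8:
        raise RuntimeError(f"HKA solver did not converge: residuals {resid}")
    th = _thetas(kept, T_hat, f_hat)

    chi2 = 0.0
    expected: dict[str, tuple[float, float, float]] = {}
    for t, loc in zip(th, kept):
        e_s1 = t * _a1(loc.n1)
        e_s2 = f_hat * t * _a1(loc.n2)
        e_d = t * (T_hat + (1.0 + f_hat) / 2.0)
        v_s1 = e_s1 + (t**2) * _a2(loc.n1)
        v_s2 = e_s2 + (f_hat * t) ** 2 * _a2(loc.n2)
        v_d = e_d + (t * (1.0 + f_hat) / 2.0) ** 2
        for obs, exp, var in (
            (loc.S1, e_s1, v_s1),
            (loc.S2, e_s2, v_s2),
            (loc.D, e_d, v_d),
        ):
            if var > 0:
                chi2 += (obs - exp) ** 2 / var
        expected[loc.name] = (e_s1, e_s2, e_d)
    df = 2 * len(kept) - 2
    return HkaResult(
        chi2=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        T_hat=float(T_hat),
        f_hat=float(f_hat),
        theta_hat={loc.name: float(t) for t, loc in zip(th, kept)},
        expected=expected,
        excluded=excluded,
    )


def expected_cells(theta: float, T: float, f: float, n1: int, n2: int) -> tuple[float, float, float]:
    """Model expectations (E[S1], E[S2], E[D]) for one locus — test utility."""
    return (
        theta * _a1(n1),
        f * theta * _a1(n2),
        theta * (T + (1.0 + f) / 2.0),
    )


def hka_from_alignments(alignment_pairs, pop1: str, pop2: str) -> HkaResult:
    """Build HKA input cells from filtered alignments and fit.

    ``alignment_pairs`` is an iterable of four-population (or two-population)
    :class:`LocusAlignment` objects carrying both *pop1* and *pop2*.
    """
    from . import popgen

    loci = []
    for aln in alignment_pairs:
        a = aln.subset_population(pop1)
        b = aln.subset_population(pop2)
        s1, _ = popgen.segregating_sites(a)
        s2, _ = popgen.segregating_sites(b)
        d = popgen.dxy(a, b) * a.kept_sites.size  # count scale
        loci.append(
            HkaLocus(name=aln.locus_name, S1=s1, S2=s2, D=d, n1=a.n, n2=b.n, L=int(a.kept_sites.size))
        )
    return hka_fit(loci)
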