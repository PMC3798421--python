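"""Synthetic four-population, 21-locus study generator with known ground truth.

Each locus gets two independent IM simulations — one for the sympatric pair,
one for the allopatric pair — sharing the locus length and a common reference
sequence.  The sympatric history uses per-locus migration multipliers to
emulate differential introgression (some loci are complete barriers, others
introgress freely) and the strong direction bias of the study system; the
allopatric history has uniformly low gene flow.  Defaults take the published
IM point estimates, locus lengths and the 10-42 sample-size range, so the
generated data lives on the scale of the real study.

The four-population joint history is deliberately NOT modelled: the two
pairs are independent draws, so cross-pair statistics carry no signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from . import study_data
from .alignments import LocusAlignment, PopulationMap, write_locus_alignment, write_popmap
from .im import (
    IMParams,
    InfiniteSitesViolation,
    SimLocusSpec,
    genotypes_to_alignment,
    simulate_im_genotypes,
)


@dataclass(frozen=True)
class StudyConfig:
    """Design of a synthetic study; defaults mirror the published design."""

    locus_names: tuple[str, ...] = study_data.LOCI
    lengths: tuple[int, ...] = tuple(study_data.LENGTHS_BP[x] for x in study_data.LOCI)
    populations: tuple[str, ...] = study_data.POPULATIONS
    sympatric_pair: tuple[str, str] = study_data.SYMPATRIC_PAIR
    allopatric_pair: tuple[str, str] = study_data.ALLOPATRIC_PAIR
    im_sympatric: IMParams = study_data.IM_SYMPATRIC
    im_allopatric: IMParams = study_data.IM_ALLOPATRIC
    sample_size_range: tuple[int, int] = (10, 42)
    sample_sizes: dict[str, tuple[int, ...]] | None = None  # pop -> per-locus n
    barrier_fraction: float = 0.3  # loci with migration shut off in sympatry
    multiplier_mean: float = 1.0  # exponential mean of non-barrier multipliers
    asymmetry_factor: float = 1.0  # extra bias applied to m2 of the sympatric pair
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.locus_names) != len(self.lengths):
            raise ValueError("locus_names and lengths must align")
        if not (0.0 <= self.barrier_fraction <= 1.0):
            raise ValueError("barrier_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth serialized alongside every generated dataset."""

    config: StudyConfig
    migration_multipliers: tuple[float, ...]
    sample_sizes: dict[str, tuple[int, ...]]
    realized_migrations_sympatric: tuple[int, ...]
    realized_migrations_allopatric: tuple[int, ...]

    def to_json(self) -> str:
        d = {
            "config": asdict(self.config),
            "migration_multipliers": list(self.migration_multipliers),
            "sample_sizes": {k: list(v) for k, v in self.sample_sizes.items()},
            "realized_migrations_sympatric": list(self.realized_migrations_sympatric),
            "realized_migrations_allopatric": list(self.realized_migrations_allopatric),
        }
        return json.dumps(d, indent=2, default=lambda o: o.__dict__)


@dataclass(frozen=True)
class SyntheticStudy:
    config: StudyConfig
    alignments: tuple[LocusAlignment, ...]  # four populations per locus
    popmap: PopulationMap
    truth: SyntheticTruth


def _draw_sample_sizes(config: StudyConfig, rng: np.random.Generator) -> dict[str, tuple[int, ...]]:
    if config.sample_sizes is not None:
        return config.sample_sizes
    lo, hi = config.sample_size_range
    return {
        pop: tuple(int(x) for x in rng.integers(lo, hi + 1, size=len(config.locus_names)))
        for pop in config.populations
    }


def _merge_pairs(
    locus: str,
    aln_symp: LocusAlignment,
    aln_allo: LocusAlignment,
) -> LocusAlignment:
    return LocusAlignment(
        locus_name=locus,
        ids=aln_symp.ids + aln_allo.ids,
        populations=aln_symp.populations + aln_allo.populations,
        sequences=aln_symp.sequences + aln_allo.sequences,
    )


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate the full dataset plus ground truth; deterministic in the seed.

    Per-locus sympatric migration rates are ``m_j * multiplier_i`` with
    multipliers drawn as 0 (barrier loci, probability ``barrier_fraction``)
    or Exponential(``multiplier_mean``); the sympatric m2 additionally gets
    ``asymmetry_factor``.  The rare infinite-sites overflow at a locus is
    retried on a fresh substream (bounded retries).
    """
    rng = np.random.default_rng(config.seed)
    sizes = _draw_sample_sizes(config, rng)
    is_barrier = rng.random(len(config.locus_names)) < config.barrier_fraction
    mult = np.where(
        is_barrier, 0.0, rng.exponential(config.multiplier_mean, size=len(config.locus_names))
    )
    alignments: list[LocusAlignment] = []
    mig_symp: list[int] = []
    mig_allo: list[int] = []
    p_sym_base = config.im_sympatric
    p_allo = config.im_allopatric
    for i, (locus, length) in enumerate(zip(config.locus_names, config.lengths)):
        p_sym = replace(
            p_sym_base,
            m1=p_sym_base.m1 * float(mult[i]),
            m2=p_sym_base.m2 * float(mult[i]) * config.asymmetry_factor,
        )
        spec_sym = SimLocusSpec(
            n1=sizes[config.sympatric_pair[0]][i],
            n2=sizes[config.sympatric_pair[1]][i],
            length=length,
        )
        spec_allo = SimLocusSpec(
            n1=sizes[config.allopatric_pair[0]][i],
            n2=sizes[config.allopatric_pair[1]][i],
            length=length,
        )
        aln_s, n_ms = _simulate_pair(
            p_sym, spec_sym, rng, locus, config.sympatric_pair, id_prefix=f"{locus}_"
        )
        aln_a, n_ma = _simulate_pair(
            p_allo, spec_allo, rng, locus, config.allopatric_pair, id_prefix=f"{locus}_"
        )
        alignments.append(_merge_pairs(locus, aln_s, aln_a))
        mig_symp.append(n_ms)
        mig_allo.append(n_ma)
    assignments = {
        sid: pop
        for aln in alignments
        for sid, pop in zip(aln.ids, aln.populations)
    }
    popmap = PopulationMap(assignments=assignments, populations=config.populations)
    truth = SyntheticTruth(
        config=config,
        migration_multipliers=tuple(float(x) for x in mult),
        sample_sizes=sizes,
        realized_migrations_sympatric=tuple(mig_symp),
        realized_migrations_allopatric=tuple(mig_allo),
    )
    return SyntheticStudy(
        config=config, alignments=tuple(alignments), popmap=popmap, truth=truth
    )


def _simulate_pair(
    p: IMParams,
    spec: SimLocusSpec,
    rng: np.random.Generator,
    locus: str,
    pair: tuple[str, str],
    id_prefix: str,
    max_retries: int = 20,
) -> tuple[LocusAlignment, int]:
    for _ in range(max_retries):
        seed = int(rng.integers(1, 2**31))
        g, n_mig = simulate_im_genotypes(p, spec, seed, record_migrations=True)
        try:
            aln = genotypes_to_alignment(
                g, spec, rng, locus_name=locus, pop_labels=pair, id_prefix=id_prefix
            )
        except InfiniteSitesViolation:
            continue
        return aln, n_mig
    raise InfiniteSitesViolation(f"{locus}: persistent infinite-sites overflow")


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write the same FASTA + popmap layout the ingestion layer reads, plus
    the ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for aln in study.alignments:
        write_locus_alignment(aln, out / f"{aln.locus_name}.fasta")
    write_popmap(study.popmap, out / "popmap.tsv")
    (out / "truth.json").write_text(study.truth.to_json())


@dataclass(frozen=True)
class ShapeReport:
    """Conformance of a generated dataset to the published data envelope."""

    n_cells: int
    n_inside: int
    violations: tuple[tuple[str, str, float, int], ...]  # locus, pop, pi, S

    @property
    def fraction_inside(self) -> float:
        return self.n_inside / self.n_cells if self.n_cells else 0.0


def check_shape_envelope(study: SyntheticStudy) -> ShapeReport:
    """Check per-population pi and S per locus against the published envelope
    (pi in [0, 0.05], S in [0, 60]), reporting violating cells."""
    from . import popgen

    if not study.alignments:
        raise ValueError("empty dataset")
    pi_lo, pi_hi = study_data.PI_ENVELOPE
    s_lo, s_hi = study_data.S_ENVELOPE
    n_cells = 0
    n_inside = 0
    violations = []
    for aln in study.alignments:
        for pop in study.config.populations:
            sub = aln.subset_population(pop)
            s, _ = popgen.segregating_sites(sub)
            pi = popgen.nucleotide_diversity(sub)
            n_cells += 1
            if pi_lo <= pi <= pi_hi and s_lo <= s <= s_hi:
                n_inside += 1
            else:
                violations.append((aln.locus_name, pop, float(pi), int(s)))
    return ShapeReport(
        n_cells=n_cells, n_inside=n_inside, violations=tuple(violations)
    )
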