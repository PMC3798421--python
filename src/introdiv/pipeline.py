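"""Full-analysis orchestration: ingest -> per-locus stats -> HKA ->
comparisons -> NRB -> ABC -> unit conversions, emitting TSV report tables.

Stages are pure functions of their declared inputs plus the run seed; each
stage's failure is recorded and independent stages still run.  A panel-bypass
mode accepts a precomputed per-locus FST table so the comparison layer can be
driven without sequences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, hka, im, nrb, popgen, study_data
from .alignments import LocusAlignment, PopulationMap, filter_sites, read_locus_alignment, read_popmap

log = logging.getLogger("introdiv")


@dataclass
class RunConfig:
    input_dir: str | None = None  # directory of per-locus FASTA + popmap.tsv
    populations: tuple[str, ...] = study_data.POPULATIONS
    sympatric_pair: tuple[str, str] = study_data.SYMPATRIC_PAIR
    allopatric_pair: tuple[str, str] = study_data.ALLOPATRIC_PAIR
    n_perm: int = 1000
    n_boot: int = 100
    n_null_reps: int = 1000  # neutrality-test null replicates per locus
    abc_n_sims: int = 2000
    abc_accept_frac: float = 0.02
    rates: im.MutationRateModel = field(default_factory=im.MutationRateModel)
    panel_path: str | None = None  # bypass: TSV with locus, fst_symp, fst_allo
    seed: int = 0

    def __post_init__(self) -> None:
        for pair in (self.sympatric_pair, self.allopatric_pair):
            for pop in pair:
                if pop not in self.populations:
                    raise ValueError(f"pair population {pop!r} not declared")
        if self.n_perm <= 0 or self.n_boot <= 0:
            raise ValueError("permutation and bootstrap counts must be positive")


@dataclass
class ReportBundle:
    out_dir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    newick: str | None = None
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def load_alignments(input_dir: str | Path, populations: tuple[str, ...]) -> tuple[list[LocusAlignment], PopulationMap]:
    indir = Path(input_dir)
    popmap = read_popmap(indir / "popmap.tsv", populations)
    alns = []
    for fasta in sorted(indir.glob("*.fasta")):
        alns.append(filter_sites(read_locus_alignment(fasta, popmap)))
    if not alns:
        raise FileNotFoundError(f"no .fasta loci under {indir}")
    return alns, popmap


def _load_panel(cfg: RunConfig) -> compare.FstPanel:
    if cfg.panel_path is not None:
        df = pd.read_csv(cfg.panel_path, sep="\t")
        return compare.FstPanel(
            loci=tuple(df["locus"]),
            fst_symp=df["fst_symp"].to_numpy(),
            fst_allo=df["fst_allo"].to_numpy(),
        )
    raise ValueError("no panel path configured")


def run_full_analysis(cfg: RunConfig, out_dir: str | Path) -> ReportBundle:
    """Run every stage and write report tables under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    rng = np.random.default_rng(cfg.seed)
    log.info("run_full_analysis seed=%d", cfg.seed)

    alns: list[LocusAlignment] = []
    if cfg.input_dir is not None:
        alns, _ = load_alignments(cfg.input_dir, cfg.populations)

    per_locus_pair_fst: list[dict[tuple[str, str], float]] = []
    diffs_symp: list[popgen.PopPairDiff] = []
    diffs_allo: list[popgen.PopPairDiff] = []

    if alns:
        # polymorphism summary per locus x population
        try:
            rows = []
            for aln in alns:
                for pop in cfg.populations:
                    s = popgen.summarize_polymorphism(aln.subset_population(pop))
                    rows.append(
                        dict(locus=s.locus_name, population=pop, length=s.length_kept,
                             n=s.n, S=s.S, pi=round(s.pi, 5), theta_w=round(s.theta_w, 5))
                    )
            bundle.tables["table1"] = pd.DataFrame(rows)
        except Exception as exc:  # noqa: BLE001 - stage isolation
            bundle.errors["table1"] = str(exc)

        # neutrality statistics with simulated null p-values
        try:
            rows = []
            for aln in alns:
                for pop in cfg.populations:
                    sub = aln.subset_population(pop)
                    s, _ = popgen.segregating_sites(sub)
                    d = popgen.tajimas_d(sub)
                    if s > 0:
                        fs = popgen.fus_fs(sub).fs
                        r2 = popgen.ramos_onsins_r2(sub)
                        pvals = popgen.neutrality_pvalues(
                            sub, n_reps=cfg.n_null_reps, seed=rng
                        )
                    else:
                        fs = r2 = math.nan
                        pvals = {"D": math.nan, "Fs": math.nan, "R2": math.nan}
                    rows.append(
                        dict(locus=aln.locus_name, population=pop, S=s,
                             tajimas_d=d, fus_fs=fs, r2=r2,
                             p_d=pvals["D"], p_fs=pvals["Fs"], p_r2=pvals["R2"],
                             p_d_bonferroni=min(1.0, pvals["D"] * len(alns))
                             if not math.isnan(pvals["D"]) else math.nan)
                    )
            bundle.tables["table2"] = pd.DataFrame(rows)
        except Exception as exc:  # noqa: BLE001
            bundle.errors["table2"] = str(exc)

        # pairwise differentiation + all-pairs FST for the tree
        try:
            rows = []
            from itertools import combinations

            for aln in alns:
                pair_fst: dict[tuple[str, str], float] = {}
                for p1, p2 in combinations(cfg.populations, 2):
                    a, b = aln.subset_population(p1), aln.subset_population(p2)
                    pair_fst[(p1, p2)] = popgen.hudson_fst(a, b)
                per_locus_pair_fst.append(pair_fst)
                ds = popgen.pair_differentiation(
                    aln, *cfg.sympatric_pair, n_perm=cfg.n_perm, seed=rng
                )
                da = popgen.pair_differentiation(
                    aln, *cfg.allopatric_pair, n_perm=cfg.n_perm, seed=rng
                )
                diffs_symp.append(ds)
                diffs_allo.append(da)
                rows.append(
                    dict(locus=aln.locus_name,
                         fst_symp=ds.fst, fst_symp_p=ds.fst_p, ss_symp=ds.ss, sf_symp=ds.sf,
                         dxy_symp=ds.dxy,
                         fst_allo=da.fst, fst_allo_p=da.fst_p, ss_allo=da.ss, sf_allo=da.sf,
                         dxy_allo=da.dxy)
                )
            bundle.tables["table3"] = pd.DataFrame(rows)
        except Exception as exc:  # noqa: BLE001
            bundle.errors["table3"] = str(exc)

        # HKA per pair
        try:
            rows = []
            for label, pair in (("sympatric", cfg.sympatric_pair), ("allopatric", cfg.allopatric_pair)):
                res = hka.hka_from_alignments(alns, *pair)
                rows.append(dict(pair=label, chi2=res.chi2, df=res.df, p=res.p_value,
                                 T_hat=res.T_hat, f_hat=res.f_hat))
            bundle.tables["hka"] = pd.DataFrame(rows)
        except Exception as exc:  # noqa: BLE001
            bundle.errors["hka"] = str(exc)

        # NRB ledger + trimmed FASTA per locus
        try:
            from .alignments import write_locus_alignment

            nrb_dir = out / "nrb"
            nrb_dir.mkdir(exist_ok=True)
            rows = []
            nrb_alns = []
            for aln in alns:
                res = nrb.extract_nrb(aln)
                nrb_alns.append(res.alignment)
                write_locus_alignment(
                    res.alignment, nrb_dir / f"{aln.locus_name}.fasta", kept_only=True
                )
                rows.append(
                    dict(locus=aln.locus_name, start_1based=res.block[0] + 1,
                         end=res.block[1], n_sites=res.n_sites,
                         n_retained=len(res.retained_ids),
                         dropped=",".join(res.dropped_ids) or "-",
                         degenerate=res.degenerate)
                )
            bundle.tables["nrb"] = pd.DataFrame(rows)
        except Exception as exc:  # noqa: BLE001
            bundle.errors["nrb"] = str(exc)
            nrb_alns = alns

        # ABC on the NRB alignments for both pairs + unit conversion
        try:
            rows = []
            for label, pair in (("sympatric", cfg.sympatric_pair), ("allopatric", cfg.allopatric_pair)):
                pairs = []
                specs = []
                for aln in nrb_alns:
                    a, b = aln.subset_population(pair[0]), aln.subset_population(pair[1])
                    pairs.append((a, b))
                    specs.append(im.SimLocusSpec(n1=a.n, n2=b.n, length=int(a.kept_sites.size)))
                observed = im.dataset_summary_stats(pairs)
                res = im.abc_estimate(
                    observed, specs, n_sims=cfg.abc_n_sims,
                    accept_frac=cfg.abc_accept_frac,
                    seed=int(rng.integers(0, 2**31)),
                )
                post = res.posterior_mean()
                params = im.IMParams(**post)
                demo = im.convert_units(params, cfg.rates)
                rows.append(dict(pair=label, **post, N1=demo.N1, N2=demo.N2,
                                 NA=demo.NA, t_years=demo.t_years,
                                 nm1=demo.nm1, nm2=demo.nm2))
            bundle.tables["table4"] = pd.DataFrame(rows)
        except Exception as exc:  # noqa: BLE001
            bundle.errors["table4"] = str(exc)

        # NJ tree + locus bootstrap
        try:
            dm = compare.mean_fst_matrix(per_locus_pair_fst, cfg.populations)
            tree = compare.nj_tree(dm)
            support = compare.locus_bootstrap_support(
                per_locus_pair_fst, cfg.populations, B=cfg.n_boot,
                seed=int(rng.integers(0, 2**31)),
            )
            bundle.newick = compare.tree_newick(tree)
            (out / "fig2.nwk").write_text(bundle.newick + "\n")
            bundle.tables["fig2_support"] = pd.DataFrame(
                [dict(split="|".join(sorted(s)), support_pct=v) for s, v in support.items()]
            )
        except Exception as exc:  # noqa: BLE001
            bundle.errors["tree"] = str(exc)

    # comparison layer: from computed FSTs or from a bypass panel
    try:
        if cfg.panel_path is not None:
            panel = _load_panel(cfg)
        elif diffs_symp:
            panel = compare.FstPanel(
                loci=tuple(d.locus_name for d in diffs_symp),
                fst_symp=np.array([d.fst for d in diffs_symp]),
                fst_allo=np.array([d.fst for d in diffs_allo]),
            )
        else:
            raise ValueError("no FST panel available (no input and no bypass panel)")
        contrast = compare.mean_fst_contrast(panel)
        r, p = compare.normalized_diff_rank_correlation(panel, "vs_symp")
        bundle.tables["fig4"] = pd.DataFrame(
            [dict(statistic="mean_fst_symp", value=contrast.mean_symp),
             dict(statistic="sd_fst_symp", value=contrast.sd_symp),
             dict(statistic="mean_fst_allo", value=contrast.mean_allo),
             dict(statistic="sd_fst_allo", value=contrast.sd_allo),
             dict(statistic="t", value=contrast.t),
             dict(statistic="t_p", value=contrast.p),
             dict(statistic="spearman_r_vs_symp", value=r),
             dict(statistic="spearman_p_vs_symp", value=p),
             dict(statistic="n_sympatric_exceed", value=compare.count_sympatric_exceed(panel))]
        )
    except Exception as exc:  # noqa: BLE001
        bundle.errors["fig4"] = str(exc)

    for name, df in bundle.tables.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    if bundle.errors:
        log.error("stages failed: %s", bundle.errors)
    return bundle
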