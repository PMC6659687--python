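"""End-to-end orchestration: score -> reconstruct -> correlate -> diversify -> calibrate.

A single declarative :class:`RunConfig` names the inputs, the trait pairs
and the per-stage sampling effort; :func:`run_pipeline` executes the
stages in dependency order, writes every table with the seed that produced
it, and records a manifest.  Stage sizes default to desk scale (minutes on
a 50-tip data set); published-scale chain lengths are a config change, not
a code change.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import mk, pagel, robustness, scoring, sse, traits_io
from .trees import TimeTree, prune_to_taxa, read_tree, scale_branch_lengths

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "summarize_branch_lengths"]


@dataclasses.dataclass
class RunConfig:
    tree: str
    traits: str
    outdir: str
    broods: str | None = None
    drop_species: tuple = ()
    asr_traits: tuple = ("placentotrophy", "superfetation")
    pagel_pairs: tuple = (("placentotrophy", "courtship"),)
    bisse_traits: tuple = ("placentotrophy", "courtship")
    multitrait_pairs: tuple = (("placentotrophy", "courtship"),)
    musse_trait: str | None = "sexual_selection_index"
    n_described: int | None = None      # for the sampling fraction
    r: float | None = None              # char-independent diversification rate
    seed: int = 1
    # desk-scale stage efforts
    n_maps: int = 200
    rj_iters: int = 60_000
    rj_burnin: int = 6_000
    rj_thin: int = 50
    rj_chains: int = 2
    ss_stones: int = 40
    ss_iters: int = 400
    sse_n_gen: int = 2_000
    fisse_sims: int = 200
    calibrate_reps: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("drop_species", "asr_traits", "bisse_traits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        for key in ("pagel_pairs", "multitrait_pairs"):
            if key in raw:
                raw[key] = tuple(tuple(p) for p in raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        d["pagel_pairs"] = [list(p) for p in self.pagel_pairs]
        d["multitrait_pairs"] = [list(p) for p in self.multitrait_pairs]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def summarize_branch_lengths(tree: TimeTree, index: Mapping) -> pd.DataFrame:
    """Terminal-branch-length mean and sd per sexual-selection-index class.

    ``index`` maps species to 0-3 (NaN allowed).  Species whose index class
    is empty are reported with n = 0.  A column of means over all edges of
    the induced subtree per class is included as an alternative statistic.
    """
    term = dict(zip(tree.tip_labels, tree.terminal_edge_lengths()))
    rows = []
    for cls in (0, 1, 2, 3):
        sp = [s for s, v in index.items()
              if s in term and v is not None and not (isinstance(v, float) and np.isnan(v))
              and int(v) == cls]
        lens = np.array([term[s] for s in sp])
        row = dict(index_class=cls, n=len(sp),
                   mean_terminal=float(lens.mean()) if len(sp) else np.nan,
                   sd_terminal=float(lens.std(ddof=1)) if len(sp) > 1 else np.nan)
        if len(sp) >= 2:
            sub = prune_to_taxa(tree, sp)
            row["mean_subtree_edge"] = float(sub.edge_length[
                np.arange(sub.n_nodes) != sub.root].mean())
        else:
            row["mean_subtree_edge"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("index_class")


class _Run:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.manifest = []
        outdir.mkdir(parents=True, exist_ok=True)

    def write_df(self, df: pd.DataFrame, name: str, stage: str, seed):
        path = self.outdir / name
        df.to_csv(path)
        self.manifest.append(dict(file=name, stage=stage, seed=seed))

    def write_json(self, obj, name: str, stage: str, seed):
        path = self.outdir / name

        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        path.write_text(json.dumps(obj, indent=1, default=default))
        self.manifest.append(dict(file=name, stage=stage, seed=seed))


def _trait_map(traits: pd.DataFrame, name: str) -> dict:
    if name == "sexual_selection_index" and name not in traits.columns:
        return traits_io.sexual_selection_index_column(traits).to_dict()
    return traits[name].to_dict()


def _binary_map(traits, name):
    return {sp: v for sp, v in _trait_map(traits, name).items()
            if v is not None and not (isinstance(v, float) and np.isnan(v))}


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory.

    Any stage failure aborts with the stage name; outputs of completed
    stages are preserved.
    """
    t_start = time.time()
    run = _Run(Path(config.outdir))
    stage = "setup"
    try:
        tree = read_tree(config.tree)
        traits = traits_io.read_trait_table(config.traits,
                                            drop_species=list(config.drop_species))

        stage = "score"
        if config.broods:
            broods = scoring.read_brood_table(config.broods)
            audit = scoring.score_species_table(broods)
            run.write_df(audit, "placentotrophy_scores.csv", stage, None)
            scored = audit["placentotrophy"].astype(float)
            traits = traits.copy()
            traits.loc[scored.index.intersection(traits.index), "placentotrophy"] = \
                scored[scored.index.intersection(traits.index)]
        else:
            logger.info("no brood data: using provided placentotrophy column")

        stage = "asr"
        asr_summary = {}
        for trait in config.asr_traits:
            tm = _binary_map(traits, trait)
            sub = prune_to_taxa(tree, set(tm) & set(tree.tip_labels))
            fit = mk.fit_mk_ml(sub, tm, seed=config.seed)
            rec = mk.marginal_ancestral_states(sub, tm, fit.selected_model)
            run.write_df(rec.to_table().set_index("node_id"),
                         f"asr_{trait}.csv", stage, config.seed)
            gains_ml, losses_ml = mk.count_origins(rec)
            maps = mk.sample_stochastic_maps(sub, tm, fit.selected_model,
                                             n_maps=config.n_maps,
                                             seed=config.seed)
            gains_sm, losses_sm = mk.count_origins(maps)
            pars_count, _ = mk.fitch_parsimony(sub, tm, states=(0, 1))
            asr_summary[trait] = dict(
                model=fit.selected, aic=fit.aic,
                origins_ml=gains_ml, losses_ml=losses_ml,
                origins_simmap_mean=gains_sm, losses_simmap_mean=losses_sm,
                parsimony_changes=pars_count)
        run.write_json(asr_summary, "asr_summary.json", stage, config.seed)

        stage = "pagel"
        pagel_summary = {}
        for t1_name, t2_name in config.pagel_pairs:
            data = pagel.encode_joint_states(_trait_map(traits, t1_name),
                                             _trait_map(traits, t2_name))
            keep = set(data) & set(tree.tip_labels)
            sub = prune_to_taxa(tree, keep)
            scaled = scale_branch_lengths(sub)
            cfg = pagel.RJConfig(n_iter=config.rj_iters,
                                 burnin=config.rj_burnin,
                                 thin=config.rj_thin,
                                 n_chains=config.rj_chains)
            post = pagel.rjmcmc_sample(scaled.tree, data, "dependent", cfg,
                                       seed=config.seed)
            pair = f"{t1_name}__{t2_name}"
            run.write_df(post.to_frame(), f"pagel_{pair}_posterior.csv",
                         stage, config.seed)
            ztab = pagel.z_scores(post)
            run.write_df(ztab, f"pagel_{pair}_zscores.csv", stage, config.seed)
            ml_dep = pagel.stepping_stone_ml(scaled.tree, data, "dependent",
                                            n_stones=config.ss_stones,
                                            iters_per_stone=config.ss_iters,
                                            seed=config.seed)
            ml_ind = pagel.stepping_stone_ml(scaled.tree, data, "independent",
                                            n_stones=config.ss_stones,
                                            iters_per_stone=config.ss_iters,
                                            seed=config.seed + 1)
            bf = pagel.bayes_factor(ml_dep, ml_ind, "dependent", "independent")
            pagel_summary[pair] = dict(
                log_ml_dependent=ml_dep.log_ml, log_ml_independent=ml_ind.log_ml,
                **bf, scale_factor=scaled.scale_factor)
        run.write_json(pagel_summary, "pagel_summary.json", stage, config.seed)

        stage = "sse"
        f = 1.0
        if config.n_described:
            f = sse.sampling_fraction(len(set(tree.tip_labels) & set(traits.index)),
                                      config.n_described)
        sse_summary = {}
        for trait in config.bisse_traits:
            tm = _binary_map(traits, trait)
            sub = prune_to_taxa(tree, set(tm) & set(tree.tip_labels))
            full = sse.fit_sse_ml(sub, tm, sse.bisse_spec(f=f), seed=config.seed)
            cons = sse.fit_sse_ml(
                sub, tm, sse.bisse_spec(constraints=("lambda1==lambda0",
                                                     "mu1==mu0"), f=f),
                seed=config.seed)
            lrt = sse.likelihood_ratio_test(full, cons)
            r = config.r or max(cons.params["lambda0"] - cons.params["mu0"], 1e-3)
            post = sse.sse_mcmc(sub, tm, sse.bisse_spec(f=f), r=r,
                                n_gen=config.sse_n_gen, seed=config.seed,
                                start=full.params)
            run.write_df(post.samples, f"bisse_{trait}_posterior.csv",
                         stage, config.seed)
            sse_summary[trait] = dict(
                mle=full.params, loglik=full.loglik, lrt=lrt,
                net_diversification=sse.net_diversification(post),
                ci=post.credibility_intervals(), r=r, f=f)
        if config.musse_trait:
            tm = {sp: int(v) for sp, v in _binary_map(traits,
                                                      config.musse_trait).items()}
            sub = prune_to_taxa(tree, set(tm) & set(tree.tip_labels))
            fit4 = sse.fit_sse_ml(sub, tm, sse.musse_spec(4, f=f),
                                  seed=config.seed, n_starts=2)
            run.write_json(dict(mle=fit4.params, loglik=fit4.loglik,
                                aic=fit4.aic,
                                net_diversification=fit4.net_diversification()),
                           f"musse_{config.musse_trait}.json", stage, config.seed)
            blen = summarize_branch_lengths(sub, tm)
            run.write_df(blen, "branch_lengths_by_index.csv", stage, None)
        for tA, tB in config.multitrait_pairs:
            a, b = _binary_map(traits, tA), _binary_map(traits, tB)
            joint = sse.encode_two_traits(a, b)
            sub = prune_to_taxa(tree, set(joint) & set(tree.tip_labels))
            full = sse.fit_sse_ml(sub, (a, b), sse.multitrait_spec(f=f),
                                  seed=config.seed)
            r = config.r or max(full.params["lambda0"] - full.params["mu0"], 1e-3)
            post = sse.sse_mcmc(sub, (a, b), sse.multitrait_spec(f=f), r=r,
                                n_gen=config.sse_n_gen, seed=config.seed,
                                start=full.params)
            ci = post.credibility_intervals()
            pair = f"{tA}__{tB}"
            run.write_df(post.samples, f"multitrait_{pair}_posterior.csv",
                         stage, config.seed)
            sse_summary[f"multitrait_{pair}"] = dict(
                mle=full.params, ci=ci,
                lambdaA_significant=not (ci["lambdaA"][0] <= 0 <= ci["lambdaA"][1]),
                lambdaB_significant=not (ci["lambdaB"][0] <= 0 <= ci["lambdaB"][1]),
                r=r, f=f)
        run.write_json(sse_summary, "sse_summary.json", stage, config.seed)

        stage = "robustness"
        robust_summary = {}
        for trait in config.bisse_traits:
            tm = _binary_map(traits, trait)
            sub = prune_to_taxa(tree, set(tm) & set(tree.tip_labels))
            fr = robustness.fisse_test(sub, tm, n_sim=config.fisse_sims,
                                       seed=config.seed)
            cal = robustness.calibrate_lrt(sub, tm, n_rep=config.calibrate_reps,
                                           seed=config.seed, f=f)
            run.write_df(pd.DataFrame(dict(replicate=range(len(cal.null_ps)),
                                           p=cal.null_ps)).set_index("replicate"),
                         f"calibration_{trait}_null_ps.csv", stage, config.seed)
            robust_summary[trait] = dict(
                fisse_observed=fr.observed, fisse_p=fr.p,
                calibration_observed_p=cal.observed_p,
                calibration_cutoff=cal.cutoff,
                calibration_significant=cal.significant)
        run.write_json(robust_summary, "robustness_summary.json", stage,
                       config.seed)
    except Exception as exc:
        run.write_json(dict(failed_stage=stage, error=str(exc),
                            manifest=run.manifest),
                       "manifest.json", "manifest", config.seed)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run.write_json(dict(wall_time_s=time.time() - t_start, seed=config.seed,
                        config=dataclasses.asdict(config),
                        files=run.manifest),
                   "manifest.json", "manifest", config.seed)
    return run.outdir
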