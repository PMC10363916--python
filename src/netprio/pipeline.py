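"""End-to-end benchmark: simulate -> score -> diffuse -> map targets ->
enrich -> aggregate.

``run_benchmark`` evaluates every trait x method x database (x restart
parameter) cell with a Fisher enrichment and an AUC, adds the degree
and random-p0 baselines, and aggregates log-ORs and AUCs per method
with the Kronecker correlation model.  All stages derive their
randomness from one seed; rerunning with the same configuration is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import aggregation, enrichment, synthetic, targets
from .diffusion import DiffusionConfig, diffuse, degree_scores, initial_distribution, random_initial
from .synthetic import METHODS, SyntheticCohort, SyntheticConfig

__all__ = ["RunConfig", "ResultsBundle", "run_benchmark", "report"]

log = logging.getLogger("netprio")

DEFAULT_R_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class RunConfig:
    """Configuration of one benchmark run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    methods: tuple[str, ...] = METHODS
    r_grid: tuple[float, ...] = DEFAULT_R_GRID
    background_policy: str = "per_method"   # per_method | common | network
    diffusion: bool = True
    baselines: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0.0 <= r <= 1.0) for r in self.r_grid):
            raise ValueError("r grid must lie in [0, 1]")
        if self.background_policy not in ("per_method", "common", "network"):
            raise ValueError(f"unknown background policy {self.background_policy!r}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        # the cohort inherits the run seed so one integer drives everything
        if self.synthetic.seed != self.seed:
            self.synthetic.seed = self.seed

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "methods": list(self.methods),
                "r_grid": list(self.r_grid),
                "background_policy": self.background_policy,
                "seed": self.seed,
                "n_genes": self.synthetic.n_genes,
                "n_traits": self.synthetic.n_traits,
                "n_databases": self.synthetic.n_databases,
                "or": self.synthetic.target_enrichment_or,
                "hub_bias": self.synthetic.hub_bias,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ResultsBundle:
    """Tidy per-cell results plus per-method aggregates and the manifest."""

    cells: pd.DataFrame
    aggregates: pd.DataFrame
    manifest: dict
    cohort: SyntheticCohort

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.tsv", sep="\t", index=False)
        self.aggregates.to_csv(out / "aggregates.tsv", sep="\t", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)


def _method_background(
    cohort: SyntheticCohort, method: str, policy: str, methods: Sequence[str]
) -> frozenset[str]:
    if policy == "per_method":
        return cohort.backgrounds[method]
    if policy == "common":
        common = set(cohort.universe)
        for m in methods:
            common &= cohort.backgrounds[m]
        return frozenset(common)
    raise ValueError(policy)


def _evaluate(
    scores: pd.Series,
    target_set: frozenset[str],
    background: frozenset[str],
    q: float,
    higher_is_better: bool,
) -> dict:
    """One cell: Fisher enrichment of the top-q set, plus the AUC."""
    bg_scores = scores.loc[scores.index.isin(background)]
    tgt = target_set & frozenset(bg_scores.index)
    row: dict = {"n_targets_testable": len(tgt)}
    if not tgt or len(tgt) == len(bg_scores):
        row.update(or_value=1.0, log_or=0.0, se_log_or=np.nan, fisher_p=1.0,
                   adjusted=True, n_targets_identified=0,
                   auc=np.nan, se_auc=np.nan)
        return row
    top = enrichment.top_genes(bg_scores, q, higher_is_better=higher_is_better)
    enr = enrichment.fisher_enrichment(top, tgt, frozenset(bg_scores.index))
    auc = enrichment.roc_auc(bg_scores, tgt, higher_is_better=higher_is_better)
    row.update(
        or_value=enr.or_value, log_or=enr.log_or, se_log_or=enr.se_log_or,
        fisher_p=enr.p, adjusted=enr.adjusted, n_targets_identified=enr.table[0],
        auc=auc.auc, se_auc=auc.se_auc,
    )
    return row


def _aggregate_metric(
    cells: pd.DataFrame,
    model: aggregation.CorrelationModel,
    traits: Sequence[str],
    databases: Sequence[str],
    value_col: str,
    se_col: str,
    is_log_or: bool,
) -> dict:
    # database-major, trait-minor order to match the Kronecker convention
    idx = [(t, d) for d in databases for t in traits]
    sub = cells.set_index(["trait", "database"])
    b = np.array([sub.loc[(t, d), value_col] for t, d in idx], float)
    se = np.array([sub.loc[(t, d), se_col] for t, d in idx], float)
    obs = aggregation.fill_fallback_se(
        aggregation.ObservationVector(b=b, se=se, index=idx)
    )
    res = aggregation.aggregate(obs, model, is_log_or=is_log_or)
    lo, hi = res.confidence_interval()
    return {
        "estimate": res.b_bar, "se": res.se, "ci_lo": lo, "ci_hi": hi,
        "overall_or": res.overall_or,
    }


def run_benchmark(config: RunConfig) -> ResultsBundle:
    """Run the full synthetic benchmark described by ``config``."""
    t0 = time.time()
    syn = config.synthetic
    log.info("simulating cohort (n_genes=%d, seed=%d)", syn.n_genes, config.seed)
    cohort = synthetic.generate_cohort(
        syn, methods=tuple(config.methods),
        build_network=config.diffusion or config.baselines,
    )

    # observed drug-target sets per database, through the filter pipeline
    target_sets: dict[str, dict[str, targets.TargetGeneSet]] = {}
    for name, (ind, tgt) in cohort.drug_tables.items():
        target_sets[name] = targets.build_target_sets(ind, tgt, universe=cohort.universe)
    databases = sorted(target_sets)

    net = next(iter(cohort.networks.values())) if cohort.networks else None
    net_bg = frozenset(net.nodes) if net is not None else frozenset()
    model = aggregation.CorrelationModel(R_db=syn.db_corr, R_trait=syn.trait_corr)

    rows = []
    for method in config.methods:
        q = syn.top_fraction(method)
        bg = (net_bg if config.background_policy == "network"
              else _method_background(cohort, method, config.background_policy,
                                      config.methods))
        for trait in cohort.traits:
            tab = cohort.score_tables[(trait, method)]
            pvals = tab.pvalues()
            for db in databases:
                tset = frozenset(target_sets[db][trait].genes)
                # undiffused cells (equivalently r = 1 on the method background)
                row = _evaluate(pvals, tset, bg, q, higher_is_better=False)
                rows.append({"method": method, "trait": trait, "database": db,
                             "network": "none", "r": 1.0, **row})
        if config.diffusion and net is not None:
            for trait in cohort.traits:
                tab = cohort.score_tables[(trait, method)]
                p0, dnet = initial_distribution(tab, net)
                for r in config.r_grid:
                    if r == 1.0:
                        pinf = pd.Series(p0, index=dnet.nodes)
                    else:
                        pinf = diffuse(p0, dnet, DiffusionConfig(r=r))
                    for db in databases:
                        tset = frozenset(target_sets[db][trait].genes)
                        row = _evaluate(pinf, tset, net_bg, q, higher_is_better=True)
                        rows.append({"method": method, "trait": trait,
                                     "database": db, "network": syn.network_model,
                                     "r": r, **row})

    if config.baselines and net is not None:
        deg = degree_scores(net)
        for t_idx, trait in enumerate(cohort.traits):
            rnd = pd.Series(random_initial(net, config.seed, t_idx), index=net.nodes)
            for db in databases:
                tset = frozenset(target_sets[db][trait].genes)
                row = _evaluate(deg, tset, net_bg, synthetic.DEFAULT_TOP_FRACTION,
                                higher_is_better=True)
                rows.append({"method": "degree", "trait": trait, "database": db,
                             "network": syn.network_model, "r": np.nan, **row})
            for r in (config.r_grid if config.diffusion else (1.0,)):
                if r == 1.0:
                    rnd_inf = rnd
                else:
                    rnd_inf = diffuse(rnd.to_numpy(), net, DiffusionConfig(r=r))
                for db in databases:
                    tset = frozenset(target_sets[db][trait].genes)
                    row = _evaluate(rnd_inf, tset, net_bg,
                                    synthetic.DEFAULT_TOP_FRACTION,
                                    higher_is_better=True)
                    rows.append({"method": "random", "trait": trait,
                                 "database": db, "network": syn.network_model,
                                 "r": r, **row})

    cells = pd.DataFrame(rows)

    agg_rows = []
    for (method, network, r), grp in cells.groupby(["method", "network", "r"],
                                                   dropna=False, sort=True):
        if len(grp) != len(cohort.traits) * len(databases):
            continue
        try:
            ag_or = _aggregate_metric(grp, model, cohort.traits, databases,
                                      "log_or", "se_log_or", is_log_or=True)
            ag_auc = _aggregate_metric(grp, model, cohort.traits, databases,
                                       "auc", "se_auc", is_log_or=False)
        except ValueError:
            continue
        agg_rows.append({
            "method": method, "network": network, "r": r,
            "log_or": ag_or["estimate"], "log_or_se": ag_or["se"],
            "log_or_ci_lo": ag_or["ci_lo"], "log_or_ci_hi": ag_or["ci_hi"],
            "overall_or": ag_or["overall_or"],
            "auc": ag_auc["estimate"], "auc_se": ag_auc["se"],
            "auc_ci_lo": ag_auc["ci_lo"], "auc_ci_hi": ag_auc["ci_hi"],
        })
    aggregates = pd.DataFrame(agg_rows)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes": syn.n_genes,
        "n_traits": syn.n_traits,
        "n_databases": syn.n_databases,
        "methods": list(config.methods),
        "r_grid": list(config.r_grid),
        "background_policy": config.background_policy,
        "runtime_s": round(time.time() - t0, 3),
    }
    log.info("benchmark finished in %.1fs (%d cells)", manifest["runtime_s"], len(cells))
    return ResultsBundle(cells=cells, aggregates=aggregates, manifest=manifest,
                         cohort=cohort)


def report(bundle: ResultsBundle) -> dict[str, pd.DataFrame]:
    """Summary tables: per-method overall OR/AUC with CIs, method-difference
    p-value matrix (undiffused AUCs), and baseline rows."""
    agg = bundle.aggregates
    if agg.empty:
        raise ValueError("empty results bundle")
    methods = [m for m in bundle.manifest["methods"]]
    if not methods:
        raise ValueError("empty method list")
    overall = agg.loc[(agg["network"] == "none")].copy()
    baselines = agg.loc[agg["method"].isin(["degree", "random"])].copy()

    # pairwise AUC difference tests on the undiffused cells
    cells = bundle.cells
    syn = bundle.cohort.config
    model = aggregation.CorrelationModel(R_db=syn.db_corr, R_trait=syn.trait_corr)
    traits = bundle.cohort.traits
    databases = sorted(cells["database"].unique())
    idx = [(t, d) for d in databases for t in traits]

    def obs_for(method: str) -> aggregation.ObservationVector:
        sub = cells.loc[(cells["method"] == method) & (cells["network"] == "none")]
        sub = sub.set_index(["trait", "database"])
        b = np.array([sub.loc[(t, d), "auc"] for t, d in idx], float)
        se = np.array([sub.loc[(t, d), "se_auc"] for t, d in idx], float)
        return aggregation.fill_fallback_se(
            aggregation.ObservationVector(b=b, se=se, index=idx)
        )

    pmat = pd.DataFrame(np.nan, index=methods, columns=methods)
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            try:
                _, p = aggregation.difference_test(obs_for(m1), obs_for(m2), model)
            except ValueError:
                continue
            pmat.loc[m1, m2] = pmat.loc[m2, m1] = p
    return {"overall": overall, "baselines": baselines, "auc_difference_p": pmat}
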