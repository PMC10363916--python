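"""Synthetic cohorts with planted ground truth for the benchmark.

No public generative model exists for the real inputs (GWAS/QTL summary
statistics, burden tables, interaction networks, drug databases), so
this module plants a minimal, analytically tractable structure that the
downstream pipeline should recover:

* a gene universe with per-method *testable backgrounds* of very
  different sizes, mirroring the real analyses (GWAS ~99%, eQTL-GWAS
  ~65%, Exome ~97%, pQTL-GWAS ~10% of protein-coding genes);
* per-trait *disease genes* whose scores come from a non-central normal
  z mapped through the null (p = 2 Phi(-|z|)), with the non-centrality
  calibrated numerically so the expected top-q x drug-target 2x2 table
  hits a configured odds ratio; all other genes are uniform;
* per-trait *drug-target genes*, a configurable minority of which are
  disease genes (drug targets only partly enjoy direct genetic
  support);
* weighted networks (preferential attachment or Erdos-Renyi) in which
  target genes receive a hub bias -- an attachment-probability
  multiplier of ``1 + hub_bias`` -- emulating the hub-likeness of drug
  targets in literature-derived interaction networks;
* indication -> drug -> target tables per database, with confidence
  scores and interaction types so the filter semantics are exercised;
* paired exposure/outcome summary statistics for Mendelian
  randomization recovery tests, with optional planted contaminants
  (palindromic SNPs, allele-frequency mismatches, reverse-causal
  instruments).

Everything derives from a single integer seed through
``numpy.random.SeedSequence`` spawn keys, so regeneration is
byte-for-byte reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .aggregation import exchangeable_corr, validate_correlation
from .diffusion import Network
from .scoring import GeneScoreTable

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_universe",
    "generate_score_table",
    "generate_network",
    "generate_drug_tables",
    "generate_mr_dataset",
    "generate_cohort",
    "calibrate_noncentrality",
    "write_cohort",
]

METHODS = ("GWAS", "eQTL-GWAS", "pQTL-GWAS", "Exome")

#: Testable-background fractions emulating the real per-method counts
#: (~19,150 / ~12,550 / ~1,870 / ~18,800 genes out of 19,430).
DEFAULT_TESTABLE_FRACTIONS = {
    "GWAS": 0.986,
    "eQTL-GWAS": 0.646,
    "pQTL-GWAS": 0.096,
    "Exome": 0.968,
}

DEFAULT_TOP_FRACTIONS = {"pQTL-GWAS": 0.05}
DEFAULT_TOP_FRACTION = 0.01

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic benchmark; defaults are the study conditions."""

    n_genes: int = 19_430
    n_traits: int = 10
    n_databases: int = 2
    testable_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TESTABLE_FRACTIONS)
    )
    frac_disease_genes: float = 0.025
    frac_target_genes: float = 0.02
    #: fraction of a trait's drug targets that are also disease genes
    #: (i.e. carry direct genetic support).
    frac_targets_genetic: float = 0.15
    target_enrichment_or: float = 3.0
    hub_bias: float = 1.0
    network_model: str = "preferential_attachment"
    pa_edges_per_node: int = 3
    er_edge_prob: float | None = None
    edge_weight_range: tuple[float, float] = (0.15, 1.0)
    confidence_range: tuple[int, int] = (700, 1000)
    interaction_types: tuple[str, ...] = ("inhibition", "activation")
    targets_per_drug: int = 3
    db_retention: float = 0.95
    trait_rho: float = 0.1
    db_rho: float = 0.9
    trait_corr: np.ndarray | None = None
    db_corr: np.ndarray | None = None
    top_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TOP_FRACTIONS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 3:
            raise ValueError("n_genes must be at least 3")
        if not (0.0 < self.frac_disease_genes < 1.0):
            raise ValueError("frac_disease_genes must lie in (0, 1)")
        if not (0.0 < self.frac_target_genes < 1.0):
            raise ValueError("frac_target_genes must lie in (0, 1)")
        if not (0.0 <= self.frac_targets_genetic <= 1.0):
            raise ValueError("frac_targets_genetic must lie in [0, 1]")
        if self.target_enrichment_or <= 0:
            raise ValueError("target_enrichment_or must be positive")
        if self.hub_bias < 0:
            raise ValueError("hub_bias must be nonnegative")
        if self.network_model not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown network model {self.network_model!r}")
        for m, f in self.testable_fractions.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"testable fraction for {m} must lie in (0, 1]")
        if self.trait_corr is None:
            self.trait_corr = exchangeable_corr(self.n_traits, self.trait_rho)
        if self.db_corr is None:
            self.db_corr = exchangeable_corr(self.n_databases, self.db_rho)
        self.trait_corr = validate_correlation(self.trait_corr, "trait_corr")
        self.db_corr = validate_correlation(self.db_corr, "db_corr")
        for name, R, n in (
            ("trait_corr", self.trait_corr, self.n_traits),
            ("db_corr", self.db_corr, self.n_databases),
        ):
            if R.shape[0] != n:
                raise ValueError(f"{name} dimension does not match configuration")
            if float(np.linalg.eigvalsh(R).min()) < -1e-8:
                raise ValueError(f"{name} is not positive semi-definite")

    def top_fraction(self, method: str) -> float:
        return float(self.top_fractions.get(method, DEFAULT_TOP_FRACTION))

    def rng(self, *key: int) -> np.random.Generator:
        """Child generator derived deterministically from the global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))


# stage identifiers for child-seed derivation
_STAGE_BACKGROUNDS = 1
_STAGE_TRUTH = 2
_STAGE_SCORES = 3
_STAGE_NETWORK = 4
_STAGE_DRUGS = 5
_STAGE_MR = 6


@dataclass
class SyntheticCohort:
    """Generated universe, backgrounds, truth, and (once filled) artifacts."""

    config: SyntheticConfig
    universe: list[str]
    backgrounds: dict[str, frozenset[str]]
    truth: dict
    traits: list[str] = field(default_factory=list)
    score_tables: dict[tuple[str, str], GeneScoreTable] = field(default_factory=dict)
    networks: dict[str, Network] = field(default_factory=dict)
    drug_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = field(default_factory=dict)

    def target_genes(self, trait: str) -> frozenset[str]:
        return frozenset(self.truth["target_genes"][trait])

    def disease_genes(self, trait: str) -> frozenset[str]:
        return frozenset(self.truth["disease_genes"][trait])

    def all_targets(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.truth["target_genes"].values():
            out |= set(genes)
        return frozenset(out)


# ---------------------------------------------------------------------------
# Universe, backgrounds and planted truth
# ---------------------------------------------------------------------------

def generate_universe(config: SyntheticConfig) -> SyntheticCohort:
    """Create the gene universe, per-method backgrounds and planted truth.

    Disease genes are drawn per trait around a shared core (fraction
    ``trait_rho`` of each disease set is common to all traits, inducing
    a mild between-trait correlation of downstream observations); each
    trait's drug-target set takes ``frac_targets_genetic`` of its genes
    from the trait's disease genes and the rest from null genes.
    """
    n = config.n_genes
    universe = [f"G{i:05d}" for i in range(n)]

    backgrounds: dict[str, frozenset[str]] = {}
    for k, method in enumerate(METHODS):
        frac = config.testable_fractions.get(method, 1.0)
        size = int(round(frac * n))
        rng = config.rng(_STAGE_BACKGROUNDS, k)
        backgrounds[method] = frozenset(
            rng.choice(universe, size=size, replace=False)
        )

    n_dis = max(1, int(round(config.frac_disease_genes * n)))
    n_tgt = max(1, int(round(config.frac_target_genes * n)))
    n_shared = int(round(config.trait_rho * n_dis))
    rng = config.rng(_STAGE_TRUTH)
    shared_core = list(rng.choice(universe, size=n_shared, replace=False))

    traits = [f"trait{t:02d}" for t in range(config.n_traits)]
    disease: dict[str, list[str]] = {}
    target: dict[str, list[str]] = {}
    for t, trait in enumerate(traits):
        rng_t = config.rng(_STAGE_TRUTH, t)
        rest = sorted(set(universe) - set(shared_core))
        specific = list(rng_t.choice(rest, size=n_dis - n_shared, replace=False))
        dis = sorted(set(shared_core) | set(specific))
        n_gen = int(round(config.frac_targets_genetic * n_tgt))
        tgt_gen = list(rng_t.choice(dis, size=min(n_gen, len(dis)), replace=False))
        nondis = sorted(set(universe) - set(dis))
        tgt_null = list(rng_t.choice(nondis, size=n_tgt - len(tgt_gen), replace=False))
        disease[trait] = dis
        target[trait] = sorted(set(tgt_gen) | set(tgt_null))

    truth = {
        "disease_genes": disease,
        "target_genes": target,
        "target_enrichment_or": config.target_enrichment_or,
        "hub_bias": config.hub_bias,
        "frac_targets_genetic": config.frac_targets_genetic,
    }
    return SyntheticCohort(
        config=config, universe=universe, backgrounds=backgrounds,
        truth=truth, traits=traits,
    )


# ---------------------------------------------------------------------------
# Score tables with calibrated planted enrichment
# ---------------------------------------------------------------------------

def _alt_tail(p_star: float, mu: float) -> float:
    """P(2 Phi(-|Z|) <= p_star) for Z ~ N(mu, 1)."""
    c = stats.norm.isf(p_star / 2.0)
    return float(stats.norm.sf(c - mu) + stats.norm.sf(c + mu))


def _expected_or(mu: float, f_dis: float, f_tgt: float, g: float, q: float) -> float:
    """Expected top-q x target odds ratio under the mixture model.

    ``f_dis``/``f_tgt`` are disease-gene and target fractions of the
    background, ``g`` the fraction of targets that are disease genes.
    """
    def mass(p_star: float) -> float:
        return f_dis * _alt_tail(p_star, mu) + (1.0 - f_dis) * p_star

    # solve for the top-q p-value threshold in log space: the mass is
    # nearly flat in p over hundreds of orders of magnitude when mu is large
    lu = brentq(lambda u: mass(np.exp(u)) - q, np.log(1e-280), np.log(q), xtol=1e-12)
    p_star = float(np.exp(lu))
    A = _alt_tail(p_star, mu)
    p1 = g * A + (1.0 - g) * p_star
    p0 = ((f_dis - g * f_tgt) * A + (1.0 - f_dis - (1.0 - g) * f_tgt) * p_star) / (
        1.0 - f_tgt
    )
    return (p1 / (1.0 - p1)) / (p0 / (1.0 - p0))


def calibrate_noncentrality(
    or_target: float, f_dis: float, f_tgt: float, g: float, q: float
) -> float:
    """Non-centrality mu of disease-gene z-scores hitting a planted OR.

    Solved numerically; ``mu = 0`` reproduces the null (uniform
    p-values, OR = 1).  Raises when the requested OR is unreachable --
    with only a fraction ``g`` of targets genetically supported the
    achievable OR is bounded above.
    """
    if or_target == 1.0:
        return 0.0
    if g == 0.0:
        raise ValueError("cannot plant OR != 1 when no target is a disease gene")
    f = lambda mu: _expected_or(mu, f_dis, f_tgt, g, q) - or_target
    hi = 20.0
    if f(hi) < 0:
        raise ValueError(
            f"target OR {or_target} unreachable with g={g}, f_dis={f_dis}, q={q}"
        )
    return float(brentq(f, 0.0, hi, xtol=1e-10))


def generate_score_table(
    cohort: SyntheticCohort,
    trait: str,
    method: str,
    config: SyntheticConfig | None = None,
) -> GeneScoreTable:
    """Seeded per-trait, per-method gene p-values with planted enrichment.

    Null genes get uniform p-values; disease genes in the method's
    background get ``p = 2 Phi(-|N(mu, 1)|)`` with ``mu`` calibrated on
    the realized background fractions so that the expected top-q x
    target table has odds ratio ``target_enrichment_or``.
    """
    config = config or cohort.config
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if trait not in cohort.traits:
        raise ValueError(f"unknown trait {trait!r}")
    bg = sorted(cohort.backgrounds[method])
    bg_set = set(bg)
    dis = sorted(set(cohort.disease_genes(trait)) & bg_set)
    tgt = set(cohort.target_genes(trait)) & bg_set

    f_dis = len(dis) / len(bg)
    f_tgt = len(tgt) / len(bg)
    g = len(tgt & set(dis)) / len(tgt) if tgt else 0.0
    q = config.top_fraction(method)
    if config.target_enrichment_or == 1.0 or not tgt or g == 0.0:
        mu = 0.0
    else:
        mu = calibrate_noncentrality(config.target_enrichment_or, f_dis, f_tgt, g, q)

    t_idx = cohort.traits.index(trait)
    m_idx = METHODS.index(method)
    rng = config.rng(_STAGE_SCORES, t_idx, m_idx)
    p = 1.0 - rng.random(len(bg))  # uniform in (0, 1]
    if mu > 0.0 and dis:
        pos = {gid: i for i, gid in enumerate(bg)}
        idx = np.array([pos[gid] for gid in dis])
        z = rng.normal(mu, 1.0, size=len(idx))
        p[idx] = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 1e-300)
    table = pd.DataFrame({"gene_id": bg, "p": p})
    return GeneScoreTable(
        table=table, method=method, background=frozenset(bg), trait=trait
    )


# ---------------------------------------------------------------------------
# Networks with planted hub bias
# ---------------------------------------------------------------------------

def _preferential_attachment(
    n: int,
    m: int,
    mult: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Barabasi-Albert growth with per-node attachment multipliers.

    Attachment probability is proportional to degree times ``mult``;
    sampling uses the random-edge-endpoint trick with rejection against
    ``mult / mult.max()``.
    """
    order = rng.permutation(n)
    m0 = m + 1
    edges: list[tuple[int, int]] = []
    endpoints: list[int] = []
    for i in range(m0):
        for j in range(i + 1, m0):
            a, b = int(order[i]), int(order[j])
            edges.append((a, b))
            endpoints.extend((a, b))
    mult_max = float(mult.max())
    for step in range(m0, n):
        node = int(order[step])
        chosen: set[int] = set()
        tries = 0
        while len(chosen) < m:
            cand = endpoints[int(rng.integers(len(endpoints)))]
            tries += 1
            if cand in chosen:
                continue
            if rng.random() < mult[cand] / mult_max:
                chosen.add(cand)
            if tries > 200 * m:  # pathological fallback: uniform fill
                pool = [int(x) for x in order[:step] if int(x) not in chosen]
                take = rng.choice(len(pool), size=m - len(chosen), replace=False)
                chosen.update(pool[int(t)] for t in take)
        for cand in sorted(chosen):
            edges.append((node, cand))
            endpoints.extend((node, cand))
    return edges


def generate_network(
    cohort: SyntheticCohort,
    config: SyntheticConfig | None = None,
    model: str | None = None,
) -> Network:
    """Weighted undirected gene network with hub-biased target genes.

    Under ``preferential_attachment`` target genes get an attachment
    multiplier of ``1 + hub_bias`` (doubled expected degree at the
    default, matching the hub-likeness of drug targets in curated PPI
    networks); under ``erdos_renyi`` the bias multiplies the weights of
    target-incident edges instead.  Edge weights are uniform on
    ``edge_weight_range``.  Disconnected components are joined to the
    giant component by minimum-weight bridges so the restart-free
    diffusion limit exists.
    """
    config = config or cohort.config
    model = model or config.network_model
    n = len(cohort.universe)
    if n < 3:
        raise ValueError("need at least 3 genes to build a network")
    targets = cohort.all_targets()
    is_target = np.array([g in targets for g in cohort.universe])
    rng = config.rng(_STAGE_NETWORK, 0 if model == "preferential_attachment" else 1)
    w_lo, w_hi = config.edge_weight_range

    if model == "preferential_attachment":
        mult = np.where(is_target, 1.0 + config.hub_bias, 1.0)
        pairs = _preferential_attachment(n, config.pa_edges_per_node, mult, rng)
        weights = w_lo + (w_hi - w_lo) * rng.random(len(pairs))
    elif model == "erdos_renyi":
        p_edge = config.er_edge_prob
        if p_edge is None:
            p_edge = min(1.0, 2.0 * config.pa_edges_per_node / max(n - 1, 1))
        iu, ju = np.triu_indices(n, k=1)
        keep = rng.random(len(iu)) < p_edge
        pairs = list(zip(iu[keep].tolist(), ju[keep].tolist()))
        weights = w_lo + (w_hi - w_lo) * rng.random(len(pairs))
        if config.hub_bias > 0:
            boost = np.array(
                [is_target[a] or is_target[b] for a, b in pairs], dtype=bool
            )
            weights = np.where(boost, weights * (1.0 + config.hub_bias), weights)
    else:
        raise ValueError(f"unknown network model {model!r}")

    names = cohort.universe
    net = Network((names[a], names[b], float(w)) for (a, b), w in zip(pairs, weights))

    # connectivity repair: bridge every smaller component into the giant one
    from scipy.sparse import csgraph

    ncomp, labels = csgraph.connected_components(net.adjacency, directed=False)
    present = set(net.nodes)
    missing = [g for g in names if g not in present]
    if ncomp > 1 or missing:
        comp_nodes: dict[int, list[str]] = {}
        for node, lab in zip(net.nodes, labels):
            comp_nodes.setdefault(int(lab), []).append(node)
        giant = max(comp_nodes.values(), key=len)
        bridges = []
        for lab, members in sorted(comp_nodes.items()):
            if members is giant:
                continue
            a = members[int(rng.integers(len(members)))]
            b = giant[int(rng.integers(len(giant)))]
            bridges.append((a, b, w_lo))
        for g in missing:
            b = giant[int(rng.integers(len(giant)))]
            bridges.append((g, b, w_lo))
        all_edges = [(a, b, w) for (a, b), w in net.edges.items()] + bridges
        net = Network(all_edges)
    return net


# ---------------------------------------------------------------------------
# Drug tables
# ---------------------------------------------------------------------------

def generate_drug_tables(
    cohort: SyntheticCohort,
    config: SyntheticConfig | None = None,
    database: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Indication and drug-target tables for one database index.

    Each database observes a seeded ``db_retention`` subset of every
    trait's planted target genes, partitioned over drugs
    (``targets_per_drug`` genes each); confidence scores and interaction
    types are drawn from the configured distributions so that the
    default filters (confidence >= 700, inhibition/activation) are
    exercised.  Every trait maps to at least one drug and every drug to
    at least one gene.
    """
    config = config or cohort.config
    ind_rows = []
    tgt_rows = []
    c_lo, c_hi = config.confidence_range
    for t_idx, trait in enumerate(cohort.traits):
        rng = config.rng(_STAGE_DRUGS, database, t_idx)
        core = sorted(cohort.target_genes(trait))
        keep = rng.random(len(core)) < config.db_retention
        genes = [g for g, k in zip(core, keep) if k]
        if not genes and core:
            genes = [core[int(rng.integers(len(core)))]]
        rng.shuffle(genes)
        n_drugs = max(1, int(np.ceil(len(genes) / config.targets_per_drug)))
        for j in range(n_drugs):
            drug = f"DB{database}_{trait}_drug{j:03d}"
            ind_rows.append((trait, drug))
            members = genes[j * config.targets_per_drug:(j + 1) * config.targets_per_drug]
            for gid in members:
                conf = int(rng.integers(c_lo, c_hi + 1))
                itype = config.interaction_types[
                    int(rng.integers(len(config.interaction_types)))
                ]
                tgt_rows.append((drug, gid, conf, itype))
    indications = pd.DataFrame(ind_rows, columns=["trait_id", "drug_id"])
    drug_targets = pd.DataFrame(
        tgt_rows, columns=["drug_id", "gene_id", "confidence", "interaction_type"]
    )
    return indications, drug_targets


# ---------------------------------------------------------------------------
# MR datasets
# ---------------------------------------------------------------------------

def generate_mr_dataset(
    n_iv: int,
    true_beta: float,
    n_exp: float,
    n_out: float,
    contamination: Mapping[str, int] | None = None,
    seed: int = 0,
    noise: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired exposure/outcome summary statistics with a planted causal effect.

    Clean instruments have strong exposure associations (|z| uniform on
    20--60, realistic for cis-QTL top hits) and outcome effects
    ``beta_out = true_beta * beta_exp`` plus sampling noise at the
    stated sample sizes (``se = 1/sqrt(n)``, standardized traits;
    ``noise=0`` gives the noiseless limit).  ``contamination`` may plant
    ``n_palindromic`` A/T-C/G SNPs, ``n_freq_mismatch`` SNPs with an
    allele-frequency discrepancy > 0.05, and ``n_reverse``
    reverse-causal instruments (outcome z far exceeding exposure z).
    Returns (exposure, outcome, truth) where truth labels each SNP.
    """
    if n_iv < 0:
        raise ValueError("n_iv must be >= 0")
    if n_exp <= 0 or n_out <= 0:
        raise ValueError("sample sizes must be positive")
    contamination = dict(contamination or {})
    n_pal = int(contamination.get("n_palindromic", 0))
    n_freq = int(contamination.get("n_freq_mismatch", 0))
    n_rev = int(contamination.get("n_reverse", 0))

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE_MR,)))
    se_exp = 1.0 / np.sqrt(n_exp)
    se_out = 1.0 / np.sqrt(n_out)

    rows_exp, rows_out, rows_truth = [], [], []
    counter = 0

    def add_snp(kind: str) -> None:
        nonlocal counter
        snp = f"rs{counter:06d}"
        counter += 1
        if kind == "palindromic":
            a1, a2 = _PALINDROMIC_PAIRS[int(rng.integers(len(_PALINDROMIC_PAIRS)))]
        else:
            a1, a2 = _NONPALINDROMIC_PAIRS[int(rng.integers(len(_NONPALINDROMIC_PAIRS)))]
        freq = float(rng.uniform(0.05, 0.95))
        sign = 1.0 if rng.random() < 0.5 else -1.0

        if kind == "reverse":
            # strong enough to clear the instrument p-threshold even with
            # sampling noise, yet far weaker than the outcome association
            z_exp_true = float(rng.uniform(9.0, 12.0)) * sign
            z_out_true = float(rng.uniform(25.0, 40.0)) * sign
            b_exp_true = z_exp_true * se_exp
            b_out_true = z_out_true * se_out
        else:
            z_exp_true = float(rng.uniform(20.0, 60.0)) * sign
            b_exp_true = z_exp_true * se_exp
            b_out_true = true_beta * b_exp_true

        b_exp = b_exp_true + noise * float(rng.normal(0.0, se_exp))
        b_out = b_out_true + noise * float(rng.normal(0.0, se_out))

        freq_out = freq
        if kind == "freq_mismatch":
            shift = float(rng.uniform(0.08, 0.2))
            freq_out = freq + shift if freq < 0.5 else freq - shift

        # occasionally report the outcome with swapped alleles so that
        # harmonization's re-alignment path is exercised
        if kind == "clean" and rng.random() < 0.3:
            out_a1, out_a2 = a2, a1
            b_out_rep, freq_out_rep = -b_out, 1.0 - freq_out
        else:
            out_a1, out_a2 = a1, a2
            b_out_rep, freq_out_rep = b_out, freq_out

        z_e = b_exp / se_exp
        z_o = b_out_rep / se_out
        rows_exp.append((snp, "1", counter, a1, a2, freq, b_exp, se_exp,
                         float(max(2 * stats.norm.sf(abs(z_e)), 1e-300)), n_exp))
        rows_out.append((snp, "1", counter, out_a1, out_a2, freq_out_rep, b_out_rep,
                         se_out, float(max(2 * stats.norm.sf(abs(z_o)), 1e-300)), n_out))
        rows_truth.append((snp, kind))

    for _ in range(n_iv):
        add_snp("clean")
    for _ in range(n_pal):
        add_snp("palindromic")
    for _ in range(n_freq):
        add_snp("freq_mismatch")
    for _ in range(n_rev):
        add_snp("reverse")

    cols = ["snp", "chr", "pos", "a1", "a2", "freq", "beta", "se", "p", "n"]
    exposure = pd.DataFrame(rows_exp, columns=cols)
    outcome = pd.DataFrame(rows_out, columns=cols)
    truth = pd.DataFrame(rows_truth, columns=["snp", "kind"])
    return exposure, outcome, truth


# ---------------------------------------------------------------------------
# Full cohort and serialization
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SyntheticConfig,
    methods: tuple[str, ...] = METHODS,
    build_network: bool = True,
) -> SyntheticCohort:
    """Generate a complete cohort: scores, networks, and drug tables."""
    cohort = generate_universe(config)
    for trait in cohort.traits:
        for method in methods:
            cohort.score_tables[(trait, method)] = generate_score_table(
                cohort, trait, method, config
            )
    if build_network:
        cohort.networks[config.network_model] = generate_network(cohort, config)
    for d in range(config.n_databases):
        cohort.drug_tables[f"db{d}"] = generate_drug_tables(cohort, config, database=d)
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    """Serialize a cohort to TSV/JSON in the formats the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for (trait, method), tab in sorted(cohort.score_tables.items()):
        tab.table.to_csv(out / f"scores_{trait}_{method}.tsv", sep="\t", index=False)
    for name, net in sorted(cohort.networks.items()):
        rows = [(a, b, w) for (a, b), w in net.edges.items()]
        pd.DataFrame(rows, columns=["node_a", "node_b", "weight"]).to_csv(
            out / f"network_{name}.tsv", sep="\t", index=False
        )
    for name, (ind, tgt) in sorted(cohort.drug_tables.items()):
        ind.to_csv(out / f"indications_{name}.tsv", sep="\t", index=False)
        tgt.to_csv(out / f"drug_targets_{name}.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    pd.DataFrame({"gene_id": cohort.universe}).to_csv(
        out / "universe.tsv", sep="\t", index=False
    )
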