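"""Gene-level prioritization scores from association summary statistics.

Three families of gene scores are supported:

* **GWAS scores** -- for each gene, the sum of squared SNP z-scores
  (``Tsum``) over the SNPs assigned to the gene (gene body +/- a window,
  50 kb by default).  Under the null, ``Tsum`` follows a weighted
  chi-square distribution whose weights are the eigenvalues of the local
  LD (genotype correlation) matrix; the gene p-value is its upper tail.
* **QTL-GWAS scores** -- two-sample Mendelian randomization combining a
  molecular-QTL exposure (transcript or protein level) with a disease
  GWAS outcome: allele harmonization, instrument selection (exposure
  p < 1e-6, LD r^2 < 0.01), Steiger filtering of likely reverse-causal
  instruments, and fixed-effect inverse-variance-weighted (IVW)
  combination of per-instrument Wald ratios.  Tissue-level results are
  aggregated by taking the minimum-p tissue.
* **Exome scores** -- gene-level rare-variant burden p-values are
  consumed as precomputed tables (validated ingestion only).

All tabular inputs/outputs are pandas DataFrames; summary statistics use
the column convention ``snp, chr, pos, a1, a2, freq, beta, se, p, n``
(a1 = effect allele).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "SUMSTAT_COLUMNS",
    "GeneScore",
    "GeneScoreTable",
    "LdBlock",
    "assign_snps_to_genes",
    "weighted_chisq_sf",
    "gwas_gene_score",
    "harmonize",
    "select_instruments",
    "steiger_filter",
    "mr_ivw",
    "aggregate_tissues",
    "ingest_gene_pvalues",
]

#: Header of a summary-statistics table (TSV on disk).
SUMSTAT_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "freq", "beta", "se", "p", "n"]

#: p-values of exactly zero are clamped to this floor so downstream
#: z-transforms stay finite.
P_FLOOR = 1e-300

#: Default gene window in base pairs (gene body +/- 50 kb).
DEFAULT_WINDOW = 50_000

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneScore:
    """A single gene's prioritization result for one method (and tissue)."""

    gene_id: str
    p: float
    statistic: float
    method: str
    tissue: str | None = None
    n_snps_or_ivs: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"gene p-value must be in (0, 1], got {self.p}")


@dataclass
class GeneScoreTable:
    """Per-trait, per-method table of gene p-values over a background.

    ``table`` has columns ``gene_id`` and ``p`` (plus optional extras);
    ``background`` is the set of genes testable by the method -- scored
    genes must be a subset of it.
    """

    table: pd.DataFrame
    method: str
    background: frozenset[str]
    trait: str | None = None

    def __post_init__(self) -> None:
        missing = {"gene_id", "p"} - set(self.table.columns)
        if missing:
            raise ValueError(f"score table missing columns: {sorted(missing)}")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in score table")
        p = self.table["p"].to_numpy(float)
        if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
            raise ValueError("score-table p-values must lie in (0, 1]")
        self.background = frozenset(self.background)
        stray = set(self.table["gene_id"]) - self.background
        if stray:
            raise ValueError(f"{len(stray)} scored genes outside background")

    def __len__(self) -> int:
        return len(self.table)

    def pvalues(self) -> pd.Series:
        return self.table.set_index("gene_id")["p"]

    def ranked(self) -> pd.DataFrame:
        """Rows sorted by ascending p (ties broken by gene id), rank added."""
        out = self.table.sort_values(["p", "gene_id"], kind="mergesort").reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
        return out


@dataclass
class LdBlock:
    """LD correlation matrix for the SNPs assigned to one gene."""

    snp_ids: list[str]
    corr: np.ndarray
    _eigenvalues: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, float)
        k = len(self.snp_ids)
        if self.corr.shape != (k, k):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.corr, self.corr.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")

    @property
    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of the LD matrix, clipped at zero below 1e-10."""
        if self._eigenvalues is None:
            lam = np.linalg.eigvalsh(self.corr)
            lam[lam < 1e-10] = 0.0
            self._eigenvalues = lam[::-1].copy()
        return self._eigenvalues


# ---------------------------------------------------------------------------
# SNP-to-gene assignment
# ---------------------------------------------------------------------------

def assign_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> dict[str, list[str]]:
    """Map each gene to the SNPs within ``start - window .. end + window``.

    Coordinates are 1-based and the window is inclusive at both ends; a
    SNP may be assigned to several overlapping genes.  ``snps`` needs
    columns ``snp, chr, pos``; ``genes`` needs ``gene_id, chr, start,
    end``.  Chromosomes with no SNPs yield empty maps (with a warning
    when nothing matches at all).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    out: dict[str, list[str]] = {}
    snps_by_chr = {str(c): g for c, g in snps.groupby(snps["chr"].astype(str))}
    any_hit = False
    for row in genes.itertuples(index=False):
        chrom = str(row.chr)
        sub = snps_by_chr.get(chrom)
        if sub is None:
            out[row.gene_id] = []
            continue
        lo, hi = row.start - window, row.end + window
        pos = sub["pos"].to_numpy()
        mask = (pos >= lo) & (pos <= hi)
        hits = sub.loc[mask, "snp"].tolist()
        out[row.gene_id] = hits
        any_hit = any_hit or bool(hits)
    if len(genes) and not any_hit:
        warnings.warn("no SNP mapped to any gene (chromosome name mismatch?)")
    return out


# ---------------------------------------------------------------------------
# Weighted chi-square survival function (Imhof + saddlepoint)
# ---------------------------------------------------------------------------

def _imhof_sf(t: float, lam: np.ndarray, epsabs: float = 1e-13) -> tuple[float, float]:
    # Imhof (1961): P(Q > t) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u rho(u)) du
    def integrand(u: np.ndarray) -> np.ndarray:
        theta = 0.5 * np.sum(np.arctan(np.outer(u, lam)), axis=1) - 0.5 * t * u
        rho = np.exp(0.25 * np.sum(np.log1p(np.outer(u, lam) ** 2), axis=1))
        return np.sin(theta) / (u * rho)

    val, err = integrate.quad(
        lambda u: float(integrand(np.atleast_1d(u))[0]),
        0.0,
        np.inf,
        epsabs=epsabs,
        epsrel=1e-12,
        limit=500,
    )
    return 0.5 + val / np.pi, err / np.pi


def _saddlepoint_sf(t: float, lam: np.ndarray) -> float:
    # Kuonen (1999) Lugannani-Rice approximation for Q = sum lam_j chi2_1.
    lam_max = lam.max()
    mean = lam.sum()
    if abs(t - mean) < 1e-12 * max(mean, 1.0):
        return 0.5

    def kprime(s: float) -> float:
        return float(np.sum(lam / (1.0 - 2.0 * s * lam)))

    hi = 0.5 / lam_max
    lo = -1e4 / max(t, 1e-12)
    a, b = (0.0, hi * (1 - 1e-12)) if t > mean else (lo, 0.0)
    from scipy.optimize import brentq

    s_hat = brentq(lambda s: kprime(s) - t, a, b, xtol=1e-16)
    k = -0.5 * float(np.sum(np.log1p(-2.0 * s_hat * lam)))
    kpp = float(np.sum(2.0 * lam**2 / (1.0 - 2.0 * s_hat * lam) ** 2))
    w = np.sign(s_hat) * np.sqrt(max(2.0 * (s_hat * t - k), 0.0))
    v = s_hat * np.sqrt(kpp)
    if w == 0 or v == 0:
        return 0.5
    return float(stats.norm.sf(w + np.log(v / w) / w))


def weighted_chisq_sf(t: float, lam: Sequence[float]) -> float:
    """Upper tail P(sum_j lam_j * chi2_1 >= t) of a weighted chi-square.

    Computed by Imhof-type numerical inversion of the characteristic
    function (absolute tolerance ~1e-12), falling back to a
    Lugannani-Rice saddlepoint approximation in the extreme tail
    (p < 1e-14) where the oscillatory integral loses accuracy.

    Reduces to the chi-square_k survival function when all weights are
    one.  Zero weights are dropped; all-zero weights raise.
    """
    lam = np.asarray(lam, float)
    if lam.size == 0 or np.any(lam < 0):
        raise ValueError("weights must be nonnegative and nonempty")
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("all weights are zero: distribution undefined")
    if t < 0:
        raise ValueError("statistic must be >= 0")
    if t == 0:
        return 1.0
    if np.allclose(lam, lam[0]):
        return float(stats.chi2.sf(t / lam[0], df=lam.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        p, err = _imhof_sf(t, lam)
    # the oscillatory integral loses all relative accuracy in the far tail:
    # fall back to the saddlepoint when the estimate is within the
    # quadrature's own error band or beyond the reliable range
    if not np.isfinite(p) or p < 1e-14 or p <= 10.0 * err:
        return _saddlepoint_sf(t, lam)
    return float(min(max(p, 0.0), 1.0))


def gwas_gene_score(z: Sequence[float], ld: LdBlock, gene_id: str = "") -> GeneScore:
    """GWAS gene score: ``Tsum`` = sum of squared SNP z-scores.

    The p-value is the weighted chi-square upper tail at ``Tsum`` with
    weights given by the eigenvalues of the gene's LD matrix.  An empty
    z-vector means the gene is untestable and raises.
    """
    z = np.asarray(z, float)
    if z.size == 0:
        raise ValueError("empty z-vector: gene untestable")
    if z.size != len(ld.snp_ids):
        raise ValueError("z length does not match LD block dimension")
    tsum = float(np.sum(z**2))
    p = weighted_chisq_sf(tsum, ld.eigenvalues)
    return GeneScore(
        gene_id=gene_id, p=max(p, P_FLOOR), statistic=tsum,
        method="GWAS", n_snps_or_ivs=int(z.size),
    )


# ---------------------------------------------------------------------------
# Mendelian randomization: harmonization, instruments, Steiger, IVW
# ---------------------------------------------------------------------------

def _is_palindromic(a1: pd.Series, a2: pd.Series) -> np.ndarray:
    pairs = [frozenset((x, y)) for x, y in zip(a1.str.upper(), a2.str.upper())]
    return np.array([p in PALINDROMIC for p in pairs])


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    max_freq_diff: float = 0.05,
) -> pd.DataFrame:
    """Align exposure and outcome summary statistics on shared SNPs.

    Effect alleles are matched; when the outcome lists the alleles
    swapped, its beta is sign-flipped and its frequency complemented.
    Palindromic (A/T, C/G) SNPs are removed, as are pairs whose aligned
    effect-allele frequencies differ by more than ``max_freq_diff`` and
    pairs with irreconcilable alleles (counted in a warning).

    Returns the paired table with ``_exp``/``_out`` suffixed columns;
    the operation is idempotent.
    """
    m = exposure.merge(outcome, on="snp", suffixes=("_exp", "_out"))
    if m.empty:
        return m
    for c in ("a1_exp", "a2_exp", "a1_out", "a2_out"):
        m[c] = m[c].str.upper()

    same = (m["a1_exp"] == m["a1_out"]) & (m["a2_exp"] == m["a2_out"])
    swapped = (m["a1_exp"] == m["a2_out"]) & (m["a2_exp"] == m["a1_out"])
    bad = ~(same | swapped)
    if bad.any():
        warnings.warn(f"removed {int(bad.sum())} SNPs with irreconcilable alleles")
        m = m.loc[~bad].copy()
        same, swapped = same.loc[~bad], swapped.loc[~bad]
    if m.empty:
        return m

    m.loc[swapped, "beta_out"] = -m.loc[swapped, "beta_out"]
    m.loc[swapped, "freq_out"] = 1.0 - m.loc[swapped, "freq_out"]
    m.loc[swapped, ["a1_out", "a2_out"]] = m.loc[swapped, ["a2_out", "a1_out"]].to_numpy()

    pal = _is_palindromic(m["a1_exp"], m["a2_exp"])
    freq_bad = (m["freq_exp"] - m["freq_out"]).abs() > max_freq_diff
    keep = ~pal & ~freq_bad.to_numpy()
    return m.loc[keep].reset_index(drop=True)


def select_instruments(
    pairs: pd.DataFrame,
    ld: pd.DataFrame | np.ndarray | None = None,
    p_qtl_threshold: float = 1e-6,
    r2_max: float = 0.01,
) -> pd.DataFrame:
    """Greedy selection of independent instruments for MR.

    Candidates with exposure p below ``p_qtl_threshold`` are ranked by
    ascending exposure p and retained greedily when their LD r^2 with
    every previously retained instrument is below ``r2_max``.  ``ld`` is
    a SNP x SNP correlation matrix (DataFrame indexed by SNP id, or an
    array in the row order of ``pairs``); ``None`` treats candidates as
    uncorrelated.  Returns the retained rows (possibly empty).
    """
    cand = pairs.loc[pairs["p_exp"] < p_qtl_threshold]
    cand = cand.sort_values(["p_exp", "snp"], kind="mergesort")
    if cand.empty or ld is None:
        return cand.reset_index(drop=True)
    if isinstance(ld, pd.DataFrame):
        sub = ld.loc[cand["snp"], cand["snp"]].to_numpy(float)
    else:
        ld = np.asarray(ld, float)
        order = cand.index.to_numpy()
        sub = ld[np.ix_(order, order)]
    kept: list[int] = []
    for i in range(len(cand)):
        if all(sub[i, j] ** 2 < r2_max for j in kept):
            kept.append(i)
    return cand.iloc[kept].reset_index(drop=True)


def steiger_filter(
    pairs: pd.DataFrame,
    n_exp: float | None = None,
    n_out: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Drop instruments with significantly stronger outcome association.

    The variance explained on each side is approximated by
    ``r^2 = z^2 / (z^2 + n)``.  An instrument is removed iff the outcome
    r^2 exceeds the exposure r^2 *and* a one-sided z-test on the
    Fisher-transformed correlations (independent samples) is significant
    at ``alpha`` -- i.e. likely reverse causation.  Instruments with
    missing sample size on either side are retained with a warning.
    """
    if pairs.empty:
        return pairs
    ne = pairs["n_exp"] if "n_exp" in pairs else pd.Series(n_exp, index=pairs.index)
    no = pairs["n_out"] if "n_out" in pairs else pd.Series(n_out, index=pairs.index)
    if n_exp is not None:
        ne = ne.fillna(n_exp)
    if n_out is not None:
        no = no.fillna(n_out)
    missing = ne.isna() | no.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} instruments lack sample size; retained")
    ne_v = ne.to_numpy(float)
    no_v = no.to_numpy(float)
    if np.any((ne_v[~missing] <= 0) | (no_v[~missing] <= 0)):
        raise ValueError("sample sizes must be positive")

    z_exp = (pairs["beta_exp"] / pairs["se_exp"]).to_numpy(float)
    z_out = (pairs["beta_out"] / pairs["se_out"]).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_exp = np.sqrt(z_exp**2 / (z_exp**2 + ne_v))
        r_out = np.sqrt(z_out**2 / (z_out**2 + no_v))
        stat = (np.arctanh(r_out) - np.arctanh(r_exp)) / np.sqrt(
            1.0 / (no_v - 3.0) + 1.0 / (ne_v - 3.0)
        )
        p_one_sided = stats.norm.sf(stat)
    remove = (r_out**2 > r_exp**2) & (p_one_sided < alpha) & ~missing.to_numpy()
    return pairs.loc[~remove].reset_index(drop=True)


def mr_ivw(
    pairs: pd.DataFrame,
    gene_id: str = "",
    method: str = "eQTL-GWAS",
    tissue: str | None = None,
) -> GeneScore:
    """Fixed-effect IVW Mendelian randomization estimate for one gene.

    Per-instrument Wald ratios ``beta_out / beta_exp`` are combined with
    inverse-variance weights using first-order ratio standard errors
    ``se_out / |beta_exp|``; the two-sided p comes from the normal
    approximation.  Instruments with a zero exposure effect are dropped
    with a warning; at least one instrument must remain.
    """
    if pairs.empty:
        raise ValueError("IVW requires at least one instrument")
    b_exp = pairs["beta_exp"].to_numpy(float)
    zero = b_exp == 0.0
    if zero.any():
        warnings.warn(f"dropped {int(zero.sum())} instruments with beta_exp == 0")
        pairs = pairs.loc[~zero]
        b_exp = b_exp[~zero]
    if pairs.empty:
        raise ValueError("no usable instruments after dropping beta_exp == 0")
    wald = pairs["beta_out"].to_numpy(float) / b_exp
    se_wald = pairs["se_out"].to_numpy(float) / np.abs(b_exp)
    w = 1.0 / se_wald**2
    beta = float(np.sum(w * wald) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    p = float(max(2.0 * stats.norm.sf(abs(z)), P_FLOOR))
    return GeneScore(
        gene_id=gene_id, p=p, statistic=beta, method=method,
        tissue=tissue, n_snps_or_ivs=len(pairs),
    )


def aggregate_tissues(scores: Iterable[GeneScore]) -> GeneScore:
    """Keep the tissue result with the lowest p-value for a gene.

    Ties are broken by tissue label for determinism; an empty input
    raises (the gene is then simply absent from the table).
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no tissue results to aggregate")
    return min(scores, key=lambda s: (s.p, s.tissue or ""))


# ---------------------------------------------------------------------------
# Exome burden ingestion
# ---------------------------------------------------------------------------

def ingest_gene_pvalues(
    source: str | pd.DataFrame,
    method: str = "Exome",
    trait: str | None = None,
    background: Iterable[str] | None = None,
    p_floor: float = P_FLOOR,
) -> GeneScoreTable:
    """Load and validate a precomputed gene p-value table (e.g. burden tests).

    ``source`` is a TSV path or a DataFrame with columns ``gene_id, p``.
    Duplicate gene ids raise; p-values outside (0, 1] raise, except
    exact zeros, which are clamped to ``p_floor`` with a warning.  The
    background defaults to the ingested genes themselves.
    """
    df = pd.read_csv(source, sep="\t") if isinstance(source, str) else source.copy()
    missing = {"gene_id", "p"} - set(df.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    p = df["p"].to_numpy(float)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1] (0 is clamped)")
    if np.any(p == 0):
        warnings.warn(f"clamped {int((p == 0).sum())} zero p-values to {p_floor}")
        df = df.copy()
        df.loc[df["p"] == 0, "p"] = p_floor
    bg = frozenset(background) if background is not None else frozenset(df["gene_id"])
    return GeneScoreTable(table=df, method=method, background=bg, trait=trait)
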