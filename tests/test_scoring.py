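"""Gene scoring: SNP windows, weighted chi-square tails, MR machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netprio.scoring import (
    LdBlock,
    aggregate_tissues,
    assign_snps_to_genes,
    GeneScore,
    gwas_gene_score,
    harmonize,
    ingest_gene_pvalues,
    mr_ivw,
    select_instruments,
    steiger_filter,
    weighted_chisq_sf,
)


def snp_df(rows):
    return pd.DataFrame(rows, columns=["snp", "chr", "pos"])


class TestSnpAssignment:
    def test_window_boundaries_inclusive(self):
        genes = pd.DataFrame([("g1", "1", 100, 200)],
                             columns=["gene_id", "chr", "start", "end"])
        snps = snp_df([("in_lo", "1", 50), ("out_lo", "1", 49),
                       ("in_hi", "1", 250), ("out_hi", "1", 251)])
        got = assign_snps_to_genes(snps, genes, window=50)
        assert got["g1"] == ["in_lo", "in_hi"]

    def test_snp_maps_to_overlapping_genes(self):
        genes = pd.DataFrame([("g1", "1", 100, 200), ("g2", "1", 150, 300)],
                             columns=["gene_id", "chr", "start", "end"])
        got = assign_snps_to_genes(snp_df([("s", "1", 180)]), genes, window=0)
        assert got["g1"] == ["s"] and got["g2"] == ["s"]

    def test_default_window_is_50kb(self):
        genes = pd.DataFrame([("g1", "1", 100_000, 110_000)],
                             columns=["gene_id", "chr", "start", "end"])
        got = assign_snps_to_genes(snp_df([("s", "1", 50_000)]), genes)
        assert got["g1"] == ["s"]

    def test_chromosome_mismatch_warns_empty(self):
        genes = pd.DataFrame([("g1", "chr1", 100, 200)],
                             columns=["gene_id", "chr", "start", "end"])
        with pytest.warns(UserWarning, match="no SNP mapped"):
            got = assign_snps_to_genes(snp_df([("s", "1", 150)]), genes, window=0)
        assert got["g1"] == []


class TestWeightedChisq:
    @pytest.mark.parametrize("lam,t,df", [([1.0], 3.8416, 1), ([1.0, 1.0], 5.9915, 2)])
    def test_reduces_to_chi2_tail(self, lam, t, df):
        assert weighted_chisq_sf(t, lam) == pytest.approx(stats.chi2.sf(t, df), abs=1e-12)

    def test_equal_weights_scale(self):
        assert weighted_chisq_sf(7.0, [2.0, 2.0, 2.0]) == pytest.approx(
            stats.chi2.sf(3.5, 3), rel=1e-10)

    def test_matches_monte_carlo_oracle(self, rng):
        lam, t = np.array([1.5, 0.5]), 4.0
        n = 2_000_000
        draws = lam[0] * rng.chisquare(1, n) + lam[1] * rng.chisquare(1, n)
        phat = float((draws >= t).mean())
        mc_se = np.sqrt(phat * (1 - phat) / n)
        assert abs(weighted_chisq_sf(t, lam) - phat) < 3 * mc_se

    def test_monotone_decreasing_in_t(self):
        lam = [2.0, 1.0, 0.3]
        ps = [weighted_chisq_sf(t, lam) for t in (0.5, 1, 2, 5, 10, 30, 80)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_extreme_tail_is_sane(self):
        # deep tail must be below the single-largest-component bound and positive
        p = weighted_chisq_sf(200.0, [1.5, 0.5, 0.2])
        assert 0 < p < stats.chi2.sf(200.0 / 2.2, 1)
        assert p > stats.chi2.sf(200.0 / 1.5, 1) * 0.5

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            weighted_chisq_sf(1.0, [0.0, 0.0])
        with pytest.raises(ValueError):
            weighted_chisq_sf(1.0, [])
        with pytest.raises(ValueError):
            weighted_chisq_sf(-1.0, [1.0])
        assert weighted_chisq_sf(1.0, [1.0, 0.0]) == pytest.approx(
            stats.chi2.sf(1.0, 1))  # zero weights dropped


class TestGwasGeneScore:
    def test_single_snp_reduction(self):
        ld = LdBlock(["s1"], np.eye(1))
        gs = gwas_gene_score([2.0], ld, "g")
        assert gs.statistic == 4.0
        assert gs.p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-10)

    def test_perfect_ld_rank_one(self):
        ld = LdBlock(["s1", "s2"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        gs = gwas_gene_score([2.0, 2.0], ld)
        # eigenvalues (2, 0): P(2 chi2_1 >= 8)
        assert gs.p == pytest.approx(stats.chi2.sf(4.0, 1), rel=1e-8)

    def test_order_and_sign_invariance(self, rng):
        k = 4
        A = rng.normal(size=(k, k))
        corr = A @ A.T
        dd = np.sqrt(np.diag(corr))
        corr = corr / np.outer(dd, dd)
        np.fill_diagonal(corr, 1.0)
        z = rng.normal(size=k)
        ld = LdBlock([f"s{i}" for i in range(k)], corr)
        perm = rng.permutation(k)
        ld_p = LdBlock([f"s{i}" for i in perm], corr[np.ix_(perm, perm)])
        base = gwas_gene_score(z, ld)
        assert gwas_gene_score(z[perm], ld_p).p == pytest.approx(base.p, rel=1e-9)
        assert gwas_gene_score(-z, ld).p == pytest.approx(base.p, rel=1e-12)

    def test_empty_z_raises(self):
        with pytest.raises(ValueError, match="untestable"):
            gwas_gene_score([], LdBlock([], np.zeros((0, 0))))

    def test_null_calibration_ar1(self, rng):
        # z ~ MVN(0, LD) must give uniform gene p-values; checked via the
        # alpha=0.05 critical value of Tsum (inverted once, then counted)
        k, rho, n_rep, alpha = 5, 0.5, 20_000, 0.05
        corr = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        ld = LdBlock([f"s{i}" for i in range(k)], corr)
        from scipy.optimize import brentq
        t_crit = brentq(lambda t: weighted_chisq_sf(t, ld.eigenvalues) - alpha, 1e-6, 200)
        L = np.linalg.cholesky(corr)
        z = rng.standard_normal((n_rep, k)) @ L.T
        rate = float((np.sum(z**2, axis=1) > t_crit).mean())
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / n_rep)


def sumstat(snp, a1, a2, freq, beta, se=0.1, n=10_000):
    z = beta / se
    return dict(snp=snp, chr="1", pos=1, a1=a1, a2=a2, freq=freq, beta=beta,
                se=se, p=float(2 * stats.norm.sf(abs(z))), n=n)


class TestHarmonize:
    def test_palindromic_removed(self):
        exp = pd.DataFrame([sumstat("s1", "A", "T", 0.3, 0.5),
                            sumstat("s2", "A", "G", 0.3, 0.5)])
        out = pd.DataFrame([sumstat("s1", "A", "T", 0.3, 0.2),
                            sumstat("s2", "A", "G", 0.3, 0.2)])
        got = harmonize(exp, out)
        assert list(got["snp"]) == ["s2"]

    @pytest.mark.parametrize("f_out,kept", [(0.36, False), (0.34, True)])
    def test_frequency_difference_filter(self, f_out, kept):
        exp = pd.DataFrame([sumstat("s", "A", "G", 0.30, 0.5)])
        out = pd.DataFrame([sumstat("s", "A", "G", f_out, 0.2)])
        assert (len(harmonize(exp, out)) == 1) is kept

    def test_swapped_alleles_flip_beta_and_freq(self):
        exp = pd.DataFrame([sumstat("s", "A", "G", 0.30, 0.5)])
        out = pd.DataFrame([sumstat("s", "G", "A", 0.72, 0.2)])
        got = harmonize(exp, out)
        assert len(got) == 1
        assert got.loc[0, "beta_out"] == pytest.approx(-0.2)
        assert got.loc[0, "freq_out"] == pytest.approx(0.28)

    def test_irreconcilable_removed_with_warning(self):
        exp = pd.DataFrame([sumstat("s", "A", "C", 0.3, 0.5)])
        out = pd.DataFrame([sumstat("s", "A", "G", 0.3, 0.2)])
        with pytest.warns(UserWarning, match="irreconcilable"):
            got = harmonize(exp, out)
        assert got.empty

    def test_idempotent(self, rng):
        exp = pd.DataFrame([sumstat(f"s{i}", "A", "G", 0.2 + 0.05 * i, 0.3)
                            for i in range(6)])
        out = pd.DataFrame([sumstat(f"s{i}", "G" if i % 2 else "A",
                                    "A" if i % 2 else "G",
                                    0.8 - 0.05 * i if i % 2 else 0.2 + 0.05 * i, 0.1)
                            for i in range(6)])
        once = harmonize(exp, out)
        exp2 = once[["snp", "a1_exp", "a2_exp", "freq_exp", "beta_exp", "se_exp",
                     "p_exp", "n_exp"]].rename(columns=lambda c: c.replace("_exp", ""))
        out2 = once[["snp", "a1_out", "a2_out", "freq_out", "beta_out", "se_out",
                     "p_out", "n_out"]].rename(columns=lambda c: c.replace("_out", ""))
        exp2 = exp2.assign(chr="1", pos=1)
        out2 = out2.assign(chr="1", pos=1)
        twice = harmonize(exp2, out2)
        assert list(twice["snp"]) == list(once["snp"])
        assert np.allclose(twice["beta_out"], once["beta_out"])


class TestSelectInstruments:
    def make_pairs(self, pvals):
        return pd.DataFrame({"snp": [f"s{i}" for i in range(len(pvals))],
                             "p_exp": pvals})

    def test_exposure_p_threshold(self):
        got = select_instruments(self.make_pairs([1e-8, 1e-7, 1e-5]))
        assert list(got["snp"]) == ["s0", "s1"]

    def test_ld_pruning_keeps_strongest(self):
        pairs = self.make_pairs([1e-9, 1e-8])
        ld = pd.DataFrame(np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]]),
                          index=["s0", "s1"], columns=["s0", "s1"])
        got = select_instruments(pairs, ld)
        assert list(got["snp"]) == ["s0"]

    def test_greedy_output_is_valid_independent_set(self, rng):
        # brute-force check on <= 8 candidates: the greedy set is pairwise
        # independent and every rejected candidate conflicts with an
        # earlier-ranked retained one
        for _ in range(20):
            k = int(rng.integers(2, 9))
            A = rng.normal(size=(k, k))
            corr = A @ A.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
            snps = [f"s{i}" for i in range(k)]
            pairs = pd.DataFrame({"snp": snps, "p_exp": rng.uniform(1e-12, 1e-7, k)})
            ld = pd.DataFrame(corr, index=snps, columns=snps)
            got = set(select_instruments(pairs, ld)["snp"])
            order = pairs.sort_values(["p_exp", "snp"])["snp"].tolist()
            kept: list[str] = []
            for s in order:
                if all(ld.loc[s, t] ** 2 < 0.01 for t in kept):
                    kept.append(s)
            assert got == set(kept)

    def test_none_qualifying_empty(self):
        assert select_instruments(self.make_pairs([1e-3])).empty


class TestSteigerFilter:
    def make(self, z_exp, z_out, n=30_000):
        return pd.DataFrame({
            "snp": ["s"], "beta_exp": [z_exp * 0.01], "se_exp": [0.01],
            "beta_out": [z_out * 0.01], "se_out": [0.01],
            "n_exp": [n], "n_out": [n],
        })

    def test_exposure_dominates_retained(self):
        assert len(steiger_filter(self.make(10, 2))) == 1

    def test_outcome_dominates_removed(self):
        assert len(steiger_filter(self.make(2, 10))) == 0

    def test_insignificant_difference_retained(self):
        # matches the direct Fisher-z oracle: p ~ 0.46, far from alpha
        df = self.make(5.0, 5.1)
        n = 30_000
        r_e = np.sqrt(25.0 / (25.0 + n))
        r_o = np.sqrt(5.1**2 / (5.1**2 + n))
        z = (np.arctanh(r_o) - np.arctanh(r_e)) / np.sqrt(2.0 / (n - 3.0))
        assert stats.norm.sf(z) > 0.05
        assert len(steiger_filter(df)) == 1

    def test_missing_n_retained_with_warning(self):
        df = self.make(2, 10).drop(columns=["n_exp", "n_out"])
        with pytest.warns(UserWarning, match="lack sample size"):
            assert len(steiger_filter(df)) == 1


class TestMrIvw:
    def make(self, b_exp, b_out, se_out=None):
        b_exp, b_out = np.asarray(b_exp, float), np.asarray(b_out, float)
        se_out = np.full(len(b_exp), 0.05) if se_out is None else np.asarray(se_out)
        return pd.DataFrame({"snp": [f"s{i}" for i in range(len(b_exp))],
                             "beta_exp": b_exp, "se_exp": 0.01,
                             "beta_out": b_out, "se_out": se_out})

    def test_single_iv_wald_ratio(self):
        gs = mr_ivw(self.make([0.5], [0.25]))
        assert gs.statistic == pytest.approx(0.5)

    def test_duplicate_iv_halves_variance(self):
        one = mr_ivw(self.make([0.5], [0.25]))
        two = mr_ivw(self.make([0.5, 0.5], [0.25, 0.25]))
        se1 = 0.05 / 0.5
        z1 = one.statistic / se1
        # identical estimate, se shrinks by sqrt(2) => |z| grows by sqrt(2)
        assert two.statistic == pytest.approx(one.statistic)
        z2 = stats.norm.isf(two.p / 2)
        assert z2 == pytest.approx(abs(z1) * np.sqrt(2), rel=1e-6)

    def test_matches_closed_form_oracle(self, rng):
        b_exp = rng.uniform(0.2, 0.8, 5) * rng.choice([-1, 1], 5)
        b_out = rng.normal(0.3 * b_exp, 0.02)
        se_out = rng.uniform(0.02, 0.1, 5)
        gs = mr_ivw(self.make(b_exp, b_out, se_out))
        wald = b_out / b_exp
        w = (np.abs(b_exp) / se_out) ** 2
        assert gs.statistic == pytest.approx(np.sum(w * wald) / np.sum(w), abs=1e-12)

    def test_zero_exposure_effect_dropped(self):
        with pytest.warns(UserWarning, match="beta_exp == 0"):
            gs = mr_ivw(self.make([0.0, 0.5], [0.1, 0.25]))
        assert gs.n_snps_or_ivs == 1
        assert gs.statistic == pytest.approx(0.5)


class TestAggregateTissues:
    def test_lowest_p_wins(self):
        blood = GeneScore("g", 0.01, 0.1, "eQTL-GWAS", tissue="blood")
        brain = GeneScore("g", 0.001, 0.2, "eQTL-GWAS", tissue="brain")
        assert aggregate_tissues([blood, brain]).tissue == "brain"

    def test_single_tissue_identity(self):
        s = GeneScore("g", 0.5, 0.0, "eQTL-GWAS", tissue="liver")
        assert aggregate_tissues([s]) is s

    def test_matches_min_p_enumeration(self, rng):
        scores = [GeneScore("g", float(p), 0.0, "eQTL-GWAS", tissue=f"t{i}")
                  for i, p in enumerate(rng.uniform(0.001, 1, 10))]
        best = aggregate_tissues(scores)
        assert best.p == min(s.p for s in scores)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_tissues([])


class TestIngest:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({"gene_id": ["a", "b", "c"], "p": [0.3, 0.01, 0.8]})
        path = tmp_path / "scores.tsv"
        df.to_csv(path, sep="\t", index=False)
        tab = ingest_gene_pvalues(str(path), method="Exome")
        assert tab.table[["gene_id", "p"]].equals(df)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            ingest_gene_pvalues(pd.DataFrame({"gene_id": ["a"], "p": [1.5]}))

    def test_duplicate_gene_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            ingest_gene_pvalues(pd.DataFrame({"gene_id": ["a", "a"], "p": [0.1, 0.2]}))

    def test_zero_p_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            tab = ingest_gene_pvalues(pd.DataFrame({"gene_id": ["a"], "p": [0.0]}))
        assert tab.table.loc[0, "p"] == 1e-300

    def test_ranks_ascending_p(self):
        tab = ingest_gene_pvalues(
            pd.DataFrame({"gene_id": ["a", "b", "c"], "p": [0.5, 0.01, 0.2]}))
        assert list(tab.ranked()["gene_id"]) == ["b", "c", "a"]
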