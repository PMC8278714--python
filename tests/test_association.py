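import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from boat.association import (
    annotate_candidates,
    encode_dosage,
    gem_scan,
    genomic_inflation,
    gwas_scan,
    ld_decay,
    ld_window_r2,
    manhattan_table,
    qvalues,
    significant_hits,
)
from boat.io import AnnotationTable, ExpressionMatrix, QMatrix
from boat.synth import make_panel, make_truth, simulate_genotypes
from conftest import build_marker_table


# ---------------------------------------------------------------------------
# independent oracle: explicit normal equations + F tail
# ---------------------------------------------------------------------------

def oracle_glm(y, covariates, x):
    """Brute-force partial F-test via explicit projection matrices."""
    n = len(y)
    ones = np.ones((n, 1))
    Xr = ones if covariates is None else np.hstack([ones, covariates])
    Xf = np.hstack([Xr, np.asarray(x, dtype=float)[:, None]])
    Pr = Xr @ np.linalg.pinv(Xr.T @ Xr) @ Xr.T
    Pf = Xf @ np.linalg.pinv(Xf.T @ Xf) @ Xf.T
    rss_r = float(y @ (np.eye(n) - Pr) @ y)
    rss_f = float(y @ (np.eye(n) - Pf) @ y)
    df_den = n - np.linalg.matrix_rank(Xf)
    f = (rss_r - rss_f) / (rss_f / df_den)
    p = float(stats.f.sf(f, 1, df_den))
    tss = float(np.sum((y - y.mean()) ** 2))
    return p, (rss_r - rss_f) / tss


# ---------------------------------------------------------------------------
# dosage encoding
# ---------------------------------------------------------------------------

class TestDosage:
    def test_hemi_snp_counts_one(self):
        t = build_marker_table([("g:1:T", "C01", list("CCTY"))], ["a", "b", "c", "d"])
        d = encode_dosage(t, "g:1:T")
        assert list(d) == [0.0, 0.0, 2.0, 1.0]

    def test_monomorphic_all_zero(self):
        t = build_marker_table([("g:1:A", "C01", list("AAAN"))], ["a", "b", "c", "d"])
        d = encode_dosage(t, "g:1:A")
        assert list(d[:3]) == [0.0, 0.0, 0.0] and np.isnan(d[3])

    def test_exact_tie_minor_is_alphabetical(self):
        t = build_marker_table([("g:1:T", "C01", list("CCTT"))], ["a", "b", "c", "d"])
        d = encode_dosage(t, "g:1:T")
        assert list(d) == [2.0, 2.0, 0.0, 0.0]  # C is minor by the tie rule

    def test_multiallelic_rejected(self):
        t = build_marker_table([("g:1:A", "C01", list("ACGT"))], ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="two underlying alleles"):
            encode_dosage(t, "g:1:A")


# ---------------------------------------------------------------------------
# GWAS scan
# ---------------------------------------------------------------------------

class TestGwasScan:
    def test_trait_equal_to_dosage_is_perfect_fit(self):
        acc = [f"a{i}" for i in range(12)]
        t = build_marker_table([("g:1:T", "C01", list("CCCCCCTTTTTY"))], acc)
        d = encode_dosage(t, "g:1:T")
        res = gwas_scan(pd.Series(d, index=acc), t, correction=None, min_maf=0.0)
        assert res.iloc[0]["marker_r2"] == pytest.approx(1.0, abs=1e-12)
        assert res.iloc[0]["p_value"] < 1e-12

    def test_matches_projection_oracle_with_and_without_covariates(self):
        """p and marker R^2 agree with an explicit normal-equations oracle to 1e-10."""
        rng = np.random.default_rng(123)
        truth = make_truth(n_accessions=25, k=3, f=0.3, seed=5)
        geno, _ = simulate_genotypes(truth, n_markers=40)
        acc = geno.accessions
        y = pd.Series(rng.normal(size=25), index=acc)
        qmat = QMatrix(truth.q_true)
        for correction in (None, qmat):
            res = gwas_scan(y, geno, correction=correction, min_maf=0.05)
            cov = None if correction is None else truth.q_true.to_numpy()[:, :-1]
            assert len(res) > 10
            for _, row in res.iterrows():
                d = encode_dosage(geno, row["unit_id"])
                use = ~np.isnan(d)
                p_or, r2_or = oracle_glm(
                    y.to_numpy()[use], None if cov is None else cov[use], d[use]
                )
                assert row["p_value"] == pytest.approx(p_or, abs=1e-10)
                assert row["marker_r2"] == pytest.approx(r2_or, abs=1e-10)

    def test_null_type_one_error_close_to_nominal(self):
        """Small null scan: p < 0.05 fraction within loose binomial bounds."""
        hits, total = 0, 0
        for seed in range(5):
            panel = make_panel("null", seed=100 + seed)
            res = gwas_scan(panel.pheno.trait("NV DTB"), panel.geno, correction=None)
            hits += int((res["p_value"] < 0.05).sum())
            total += len(res)
        frac = hits / total
        bound = 3 * np.sqrt(0.05 * 0.95 / total)
        assert abs(frac - 0.05) < bound + 0.005

    def test_structure_correction_removes_inflation(self):
        """Pool scans over seeds so the median-chi2 inflation estimate is stable."""
        raw_p, corr_p = [], []
        for seed in range(10):
            panel = make_panel("structured_confounded", seed=200 + seed)
            trait = panel.pheno.trait("NV DTB")
            raw = gwas_scan(trait, panel.geno, correction=None, compute_q=False)
            corrected = gwas_scan(
                trait, panel.geno, correction=QMatrix(panel.truth.q_true), compute_q=False
            )
            raw_p.append(raw["p_value"].to_numpy())
            corr_p.append(corrected["p_value"].to_numpy())
        assert genomic_inflation(np.concatenate(raw_p)) > 1.2
        assert 0.85 < genomic_inflation(np.concatenate(corr_p)) < 1.15

    def test_causal_marker_is_top_hit(self, causal_panel):
        res = gwas_scan(
            causal_panel.pheno.trait("NV DTB"),
            causal_panel.geno,
            correction=QMatrix(causal_panel.truth.q_true),
        )
        top = res.sort_values("p_value").iloc[0]
        assert top["unit_id"] == causal_panel.truth.causal_marker

    def test_all_missing_trait_rejected(self, tiny_table):
        y = pd.Series(np.nan, index=tiny_table.accessions)
        with pytest.raises(ValueError, match="no observed values"):
            gwas_scan(y, tiny_table)


# ---------------------------------------------------------------------------
# GEM scan
# ---------------------------------------------------------------------------

class TestGemScan:
    def _expr(self, arr, acc):
        genes = [f"G{i}" for i in range(arr.shape[0])]
        return ExpressionMatrix(pd.DataFrame(arr, index=pd.Index(genes, name="gene_id"), columns=acc))

    def test_low_expression_floor(self):
        acc = [f"a{i}" for i in range(12)]
        rng = np.random.default_rng(0)
        arr = np.vstack([np.full(12, 0.4), rng.uniform(1, 5, 12)])
        expr = self._expr(arr, acc)
        y = pd.Series(rng.normal(size=12), index=acc)
        res = gem_scan(y, expr)
        assert list(res["unit_id"]) == ["G1"]  # mean 0.4 gene excluded

    def test_exact_linear_relation_recovers_slope(self):
        acc = [f"a{i}" for i in range(12)]
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, 12)
        expr = self._expr(x[None, :], acc)
        y = pd.Series(2.0 * x + rng.normal(0, 1e-8, 12), index=acc)
        res = gem_scan(y, expr)
        assert res.iloc[0]["slope"] == pytest.approx(2.0, abs=1e-6)
        assert res.iloc[0]["p_value"] < 1e-20

    def test_slope_recovery_under_noise(self):
        """gamma = 1.5 with unit noise at n = 69: estimate within +-0.5 nearly always."""
        ok = 0
        for seed in range(20):
            panel = make_panel("causal_gem", seed=300 + seed)
            res = gem_scan(panel.pheno.trait("NV DTB"), panel.expr)
            row = res[res["unit_id"] == panel.truth.causal_gene].iloc[0]
            ok += int(abs(row["slope"] - panel.truth.gamma) < 0.5)
        assert ok >= 19

    def test_empty_result_when_nothing_passes_floor(self):
        acc = ["a", "b", "c", "d"]
        expr = self._expr(np.full((2, 4), 0.1), acc)
        y = pd.Series([1.0, 2.0, 3.0, 4.0], index=acc)
        res = gem_scan(y, expr)
        assert len(res) == 0


# ---------------------------------------------------------------------------
# q-values
# ---------------------------------------------------------------------------

class TestQValues:
    def test_equals_bh_with_pi0_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(3, 200))
            q = qvalues(p, pi0=1.0).q
            bh = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(q, bh, atol=1e-12)

    def test_bh_example_direct_enumeration(self):
        q = qvalues([0.01, 0.02, 0.03, 0.04], pi0=1.0).q
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_bounded_by_itself(self):
        res = qvalues([0.2])
        assert res.q[0] <= 0.2 + 1e-12 and 0 < res.pi0 <= 1

    def test_identical_ps_identical_qs(self):
        res = qvalues([0.3] * 8)
        assert len(set(np.round(res.q, 15))) == 1

    def test_q_order_consistent_with_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=500) ** 2
        res = qvalues(p)
        order = np.argsort(p)
        assert (np.diff(res.q[order]) >= -1e-12).all()
        assert 0 < res.pi0 <= 1

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qvalues([0.5, 1.2])


class TestSignificantHits:
    def _table(self, p, q):
        return pd.DataFrame(
            {"unit_id": [f"m{i}" for i in range(len(p))], "p_value": p, "q_value": q}
        )

    def test_empty_and_all_insignificant(self):
        empty, thr = significant_hits(self._table([], []))
        assert len(empty) == 0 and thr is None
        none_sig, thr = significant_hits(self._table([0.5, 0.9], [0.9, 0.9]))
        assert len(none_sig) == 0 and thr is None

    def test_threshold_line_at_least_every_hit(self):
        table = self._table([1e-5, 1e-3, 0.2], [1e-4, 0.01, 0.3])
        hits, thr = significant_hits(table, fdr=0.05)
        assert len(hits) == 2
        assert (thr <= -np.log10(hits["p_value"])).all()
        assert thr == pytest.approx(-np.log10(1e-3))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

class TestLD:
    def test_duplicated_marker_r2_one_and_window_rule(self):
        rng = np.random.default_rng(4)
        acc = [f"a{i}" for i in range(20)]
        base = list(rng.choice(list("AC"), size=20))
        recs = [(f"g{j}:{j + 1}:A", "C01", base) for j in range(2)]
        for j in range(2, 60):
            recs.append((f"g{j}:{j + 1}:A", "C01", list(rng.choice(list("AC"), size=20))))
        t = build_marker_table(recs, acc)
        res = ld_window_r2(t, window=50, min_maf=0.0)
        dup = res.pairs[(res.pairs.marker_i == "g0:1:A") & (res.pairs.marker_j == "g1:2:A")]
        assert dup.iloc[0]["r2"] == pytest.approx(1.0)
        assert res.pairs["index_distance"].max() <= 50
        # markers 1 and 52 (index distance 51) are never paired
        assert not (
            (res.pairs.marker_i == "g0:1:A") & (res.pairs.marker_j == "g51:52:A")
        ).any()

    def test_equals_bruteforce_and_symmetric_under_allele_flip(self):
        rng = np.random.default_rng(5)
        truth = make_truth(n_accessions=30, k=2, f=0.3, seed=9)
        geno, _ = simulate_genotypes(truth, n_markers=25)
        res = ld_window_r2(geno, window=10, min_maf=0.05)
        from boat.association import dosage_matrix

        from boat.qc import marker_stats_table

        stats_t = marker_stats_table(geno)
        keep = stats_t.index[(stats_t["maf"].fillna(0) > 0.05) & (stats_t["n_alleles"] <= 2)]
        X, kept = dosage_matrix(geno.subset(keep))
        for _, row in res.pairs.iterrows():
            i, j = kept.index(row.marker_i), kept.index(row.marker_j)
            a, b = X[:, i], X[:, j]
            use = ~np.isnan(a) & ~np.isnan(b)
            r = np.corrcoef(a[use], b[use])[0, 1]
            assert row.r2 == pytest.approx(r * r, abs=1e-10)
            rf = np.corrcoef(2 - a[use], b[use])[0, 1]  # allele-label flip
            assert row.r2 == pytest.approx(rf * rf, abs=1e-10)

    def test_null_mean_r2_near_one_over_n_minus_one(self):
        truth = make_truth(n_accessions=69, k=1, f=0.3, seed=21)
        geno, _ = simulate_genotypes(truth, n_markers=200, missing_rate=0.0, ambiguity_rate=0.0)
        res = ld_window_r2(geno, window=50, min_maf=0.05)
        n_pairs = len(res.pairs)
        expected = 1.0 / 68
        se = np.sqrt(2.0) * expected  # var of r2 under null approx 2/(n-1)^2
        assert abs(res.mean_r2 - expected) < 3 * se / np.sqrt(n_pairs) + 0.002

    def test_decay_series_contains_self_and_skips_disjoint(self):
        acc = [f"a{i}" for i in range(10)]
        recs = [
            ("g0:1:A", "C01", list("AAAACCCCAC")),
            ("g1:1:A", "C01", list("AACCAACCAC")),
            ("g2:1:A", "C01", list("NNNNNNNNNN")),
        ]
        t = build_marker_table(recs, acc)
        out = ld_decay(t, "g0:1:A", max_index_distance=5)
        assert out.iloc[0]["index_distance"] == 0 and out.iloc[0]["r2"] == 1.0
        assert "g2:1:A" not in set(out["marker_id"])


# ---------------------------------------------------------------------------
# Manhattan layout and annotation join
# ---------------------------------------------------------------------------

class TestManhattan:
    def _results(self, chroms_orders):
        return pd.DataFrame(
            {
                "unit_id": [f"m{i}" for i in range(len(chroms_orders))],
                "chromosome": [c for c, _ in chroms_orders],
                "order_index": [o for _, o in chroms_orders],
                "minus_log10_p": np.linspace(1, 2, len(chroms_orders)),
            }
        )

    def test_single_chromosome_x_is_order(self):
        table, offsets = manhattan_table(self._results([("C03", 2), ("C03", 1), ("C03", 3)]))
        assert list(table["x"]) == [1, 2, 3]
        assert list(table["order_index"]) == [1, 2, 3]

    def test_offsets_increase_and_unanchored_last(self):
        table, offsets = manhattan_table(
            self._results([("C00", 1), ("C02", 1), ("C01", 1), ("C02", 2)])
        )
        assert list(table["chromosome"]) == ["C01", "C02", "C02", "C00"]
        vals = [offsets[c] for c in ["C01", "C02", "C00"]]
        assert vals == sorted(vals) and len(set(vals)) == 3


class TestAnnotate:
    def test_join_and_blank_for_unknown(self):
        hits = pd.DataFrame({"unit_id": ["Bo2g009460.1:894:T", "BoX:1:A"]})
        ann = AnnotationTable(
            pd.DataFrame(
                {"arabidopsis_id": ["AT5G10140.4"], "orthologue": ["FLC.C2"]},
                index=pd.Index(["Bo2g009460.1"], name="gene_id"),
            )
        )
        out = annotate_candidates(hits, ann)
        assert len(out) == len(hits)
        assert out.iloc[0]["orthologue"] == "FLC.C2"
        assert out.iloc[1]["orthologue"] == ""
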