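"""Taxa-table operations, ZINB interaction test, FDR and diversity."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from neurobiota.microbiome import (
    TaxaTable,
    aggregate_rank,
    alpha_diversity,
    beta_diversity_pcoa,
    bh_fdr,
    differential_abundance,
    diversity_tests,
    fit_zinb_interaction,
    normalize_library,
    prevalence_filter,
)
from neurobiota.synthetic import CountSimSpec, simulate_taxa_counts


class TestAggregateRank:
    def test_same_genus_merged(self, small_taxa_table):
        out = aggregate_rank(small_taxa_table, "genus")
        assert "Blautia" in out.counts.index
        np.testing.assert_array_equal(
            out.counts.loc["Blautia"],
            small_taxa_table.counts.loc[["t0", "t1"]].sum(),
        )

    def test_library_sizes_conserved(self, small_taxa_table):
        for rank in ("phylum", "order", "genus"):
            out = aggregate_rank(small_taxa_table, rank)
            np.testing.assert_array_equal(
                out.library_sizes, small_taxa_table.library_sizes
            )

    def test_matches_groupby_oracle_at_phylum(self, small_taxa_table):
        out = aggregate_rank(small_taxa_table, "phylum")
        labels = small_taxa_table.taxonomy.str.split(";").str[1]
        oracle = small_taxa_table.counts.groupby(labels).sum()
        pd.testing.assert_frame_equal(out.counts.sort_index(), oracle.sort_index())

    def test_unclassified_pooled(self, small_taxa_table):
        tax = small_taxa_table.taxonomy.copy()
        tax.iloc[0] = "Bacteria"
        tbl = TaxaTable(small_taxa_table.counts, tax, small_taxa_table.sample_meta)
        out = aggregate_rank(tbl, "genus")
        assert "unclassified_genus" in out.counts.index

    def test_unknown_rank_rejected(self, small_taxa_table):
        with pytest.raises(ValueError, match="unknown rank"):
            aggregate_rank(small_taxa_table, "kingdomish")


class TestNormalizeLibrary:
    def test_equal_libraries_unchanged(self, small_taxa_table):
        tbl = small_taxa_table
        tbl.counts.loc[:] = 5
        out = normalize_library(tbl)
        np.testing.assert_allclose(out.counts, tbl.counts)

    def test_double_depth_halved(self, small_taxa_table):
        counts = small_taxa_table.counts.copy().astype(float)
        counts["A"] = counts["B"] * 2
        tbl = TaxaTable(counts, small_taxa_table.taxonomy, small_taxa_table.sample_meta)
        out = normalize_library(tbl, target=float(counts["B"].sum()))
        np.testing.assert_allclose(out.counts["A"], counts["B"])

    def test_proportions_invariant(self, small_taxa_table):
        out = normalize_library(small_taxa_table)
        before = small_taxa_table.counts / small_taxa_table.library_sizes
        after = out.counts / out.library_sizes
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_all_zero_sample_named(self, small_taxa_table):
        counts = small_taxa_table.counts.copy()
        counts["C"] = 0
        tbl = TaxaTable(counts, small_taxa_table.taxonomy, small_taxa_table.sample_meta)
        with pytest.raises(ValueError, match="C"):
            normalize_library(tbl)


class TestPrevalenceFilter:
    def _table(self, zero_fracs, n_samples=40):
        rows = []
        for f in zero_fracs:
            n_zero = int(round(f * n_samples))
            rows.append([0] * n_zero + [5] * (n_samples - n_zero))
        counts = pd.DataFrame(
            rows,
            index=[f"t{i}" for i in range(len(zero_fracs))],
            columns=[f"s{i}" for i in range(n_samples)],
        )
        meta = pd.DataFrame(
            {
                "subject": [f"S{i//4}" for i in range(n_samples)],
                "TREAT": ["placebo", "probiotics"] * (n_samples // 2),
                "TIME": ["before", "before", "after", "after"] * (n_samples // 4),
            },
            index=counts.columns,
        )
        tax = pd.Series(["Bacteria"] * len(zero_fracs), index=counts.index)
        return TaxaTable(counts, tax, meta)

    def test_mostly_absent_taxon_removed(self):
        tbl = self._table([0.95, 0.0])
        out, removed = prevalence_filter(tbl)
        assert list(out.counts.index) == ["t1"]
        assert removed.iloc[0]["taxon"] == "t0"

    def test_boundary_taxon_kept(self):
        out, _ = prevalence_filter(self._table([0.85]))
        assert len(out.counts) == 1  # exactly 85% absent: strict inequality keeps it

    def test_ubiquitous_taxon_kept(self):
        out, _ = prevalence_filter(self._table([0.0]))
        assert len(out.counts) == 1

    def test_removed_summary_reports_group_prevalence(self):
        _, removed = prevalence_filter(self._table([0.95, 0.5]))
        assert {c for c in removed.columns if c.startswith("prevalence_")}


class TestZinbInteraction:
    def test_zinb_loglik_at_least_nb_submodel(self):
        spec = CountSimSpec(n_subjects=22, n_taxa=1, zero_inflation=0.0, seed=4)
        tbl, truth = simulate_taxa_counts(spec)
        fit = fit_zinb_interaction(
            tbl.counts.iloc[0], tbl.sample_meta, truth["library_sizes"]
        )
        # pi = 0 truth: either the NB fallback fires or the fitted
        # zero-inflation stays small (the ZINB nests the NB submodel)
        if not fit.nb_fallback:
            assert fit.zero_inflation_prob < 0.5
        assert np.isfinite(fit.interaction_p)

    def test_parameter_recovery_small(self):
        est = []
        for s in range(25):
            spec = CountSimSpec(
                n_subjects=22,
                n_taxa=1,
                zero_inflation=0.0,
                planted_taxa=[(0, 1.0)],
                seed=300 + s,
            )
            tbl, truth = simulate_taxa_counts(spec)
            fit = fit_zinb_interaction(
                tbl.counts.iloc[0], tbl.sample_meta, truth["library_sizes"]
            )
            if np.isfinite(fit.coefficients["TREAT_x_TIME"]):
                est.append(fit.coefficients["TREAT_x_TIME"])
        assert np.mean(est) == pytest.approx(1.0, abs=0.3)

    def test_too_few_samples_rejected(self, small_taxa_table):
        with pytest.raises(ValueError, match="8 samples"):
            fit_zinb_interaction(
                small_taxa_table.counts.iloc[0], small_taxa_table.sample_meta
            )

    def test_single_level_factor_rejected(self):
        meta = pd.DataFrame(
            {
                "subject": [f"S{i}" for i in range(10)],
                "TREAT": ["placebo"] * 10,
                "TIME": ["before", "after"] * 5,
            }
        )
        with pytest.raises(ValueError, match="TREAT"):
            fit_zinb_interaction(np.arange(10), meta)

    def test_planted_taxon_attains_minimum_fdr(self):
        """Positive control: a strong planted interaction among 40 null taxa
        wins the FDR ranking in nearly every replicate (moderate-dispersion
        configuration)."""
        top = 0
        n_rep = 10
        for s in range(n_rep):
            spec = CountSimSpec(
                n_subjects=22,
                n_taxa=41,
                planted_taxa=[(0, 1.5)],
                dispersion=5.0,
                baseline_logmean_sd=0.8,
                zero_inflation=0.1,
                seed=700 + s,
            )
            tbl, truth = simulate_taxa_counts(spec)
            filt, _ = prevalence_filter(tbl)
            da = differential_abundance(filt)
            top += da.iloc[0]["taxon"] == "taxon_000"
        assert top >= n_rep - 1


class TestBhFdr:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.03])), [0.03])

    def test_stepup_hand_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(1e-6, 1, 50)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-8, 1, rng.integers(3, 40))
        m = len(p)
        order = np.argsort(p)
        adj = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(bh_fdr(p), oracle, atol=1e-12)

    def test_nan_propagates(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and np.isfinite(q[0])


class TestAlphaDiversity:
    def test_uniform_shannon_is_log_richness(self):
        assert alpha_diversity(np.array([5, 5, 5, 5]), "shannon") == pytest.approx(
            np.log(4)
        )

    def test_single_taxon_zero_diversity(self):
        assert alpha_diversity(np.array([9, 0, 0]), "shannon") == 0.0
        assert alpha_diversity(np.array([9, 0, 0]), "simpson") == 0.0

    def test_hand_computed_values(self):
        c = np.array([1, 2, 3, 4])
        p = c / 10
        assert alpha_diversity(c, "shannon") == pytest.approx(-(p * np.log(p)).sum())
        assert alpha_diversity(c, "simpson") == pytest.approx(1 - (p**2).sum())

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity(np.zeros(3), "shannon")


class TestBetaDiversity:
    def test_identical_samples_zero_distance(self, small_taxa_table):
        tbl = small_taxa_table
        tbl.counts["B"] = tbl.counts["A"]
        D, _, _ = beta_diversity_pcoa(tbl)
        assert D.loc["A", "B"] == 0.0

    def test_disjoint_supports_unit_distance(self, small_taxa_table):
        counts = small_taxa_table.counts.copy()
        counts["A"] = [10, 10, 0, 0]
        counts["B"] = [0, 0, 10, 10]
        tbl = TaxaTable(counts, small_taxa_table.taxonomy, small_taxa_table.sample_meta)
        D, _, _ = beta_diversity_pcoa(tbl)
        assert D.loc["A", "B"] == 1.0

    def test_distance_matrix_properties(self, small_taxa_table):
        D, _, _ = beta_diversity_pcoa(small_taxa_table)
        arr = D.to_numpy()
        assert ((arr >= 0) & (arr <= 1)).all()
        np.testing.assert_allclose(arr, arr.T)
        assert np.diag(arr).max() == 0

    def test_coordinates_reproduce_distances(self, small_taxa_table):
        D, coords, evals = beta_diversity_pcoa(small_taxa_table)
        assert evals.min() > -1e-10  # this fixture embeds exactly
        rec = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(rec, D.to_numpy(), atol=1e-8)

    def test_agrees_with_skbio_pcoa(self, small_taxa_table):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.ordination import pcoa

        D, coords, evals = beta_diversity_pcoa(small_taxa_table)
        ref = pcoa(skbio.DistanceMatrix(D.to_numpy(), ids=list(D.index)))
        np.testing.assert_allclose(
            np.abs(coords.to_numpy()[:, :2]),
            np.abs(ref.samples.to_numpy()[:, :2]),
            atol=1e-8,
        )


class TestDiversityTests:
    def _alpha_frame(self, rng, shift=0.0):
        rows = []
        for s in range(22):
            base = rng.normal(3.0, 0.3)
            for treat in ("placebo", "probiotics"):
                for time in ("before", "after"):
                    v = base + rng.normal(0, 0.1)
                    if treat == "probiotics" and time == "after":
                        v += shift
                    rows.append(
                        {"subject": f"S{s}", "TREAT": treat, "TIME": time, "value": v}
                    )
        return pd.DataFrame(rows)

    def test_identical_before_after_reports_no_effect(self):
        rows = [
            {"subject": f"S{s}", "TREAT": t, "TIME": ti, "value": 1.0}
            for s in range(8)
            for t in ("placebo", "probiotics")
            for ti in ("before", "after")
        ]
        rep = diversity_tests(pd.DataFrame(rows))
        assert (rep["p"] == 1.0).all()
        assert rep.loc[rep["test"] == "friedman", "statistic"].iloc[0] == 0.0

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(0)
        detected = 0
        for _ in range(10):
            rep = diversity_tests(self._alpha_frame(rng, shift=0.4))
            p = rep.loc[rep["test"] == "wilcoxon_probiotics", "p"].iloc[0]
            detected += p < 0.05
        assert detected >= 9

    def test_broken_pairing_rejected(self):
        df = pd.DataFrame(
            [
                {"subject": "S0", "TREAT": "placebo", "TIME": "before", "value": 1.0},
                {"subject": "S0", "TREAT": "placebo", "TIME": "after", "value": 2.0},
            ]
        )
        with pytest.raises(ValueError, match="broken pairing"):
            diversity_tests(df)
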