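"""Fisher combination, fixed-effect pooling with Cochran's Q, vote counting,
and the three-method consensus rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from agemeta import diffexpr
from agemeta.meta import (
    consensus,
    direction_breakdown,
    fisher_combine,
    fixed_effect_combine,
    meta_analyze,
    vote_count,
)
from agemeta.synthetic import CompendiumSpec, generate_compendium


class TestFisherCombine:
    def test_all_ones(self):
        out = fisher_combine(np.array([[1.0, 1.0, 1.0]]))
        assert out.fisher_X.iloc[0] == 0.0
        assert out.fisher_p.iloc[0] == 1.0

    def test_single_study_identity(self):
        out = fisher_combine(np.array([[0.05]]))
        assert out.fisher_X.iloc[0] == pytest.approx(5.9915, abs=1e-4)
        assert out.fisher_df.iloc[0] == 2
        assert out.fisher_p.iloc[0] == pytest.approx(0.05, abs=1e-12)

    def test_two_half_pvalues(self):
        out = fisher_combine(np.array([[0.5, 0.5]]))
        assert out.fisher_X.iloc[0] == pytest.approx(2.7726, abs=1e-4)
        assert out.fisher_df.iloc[0] == 4
        assert out.fisher_p.iloc[0] == pytest.approx(stats.chi2.sf(-4 * np.log(0.5), 4), abs=1e-12)
        assert out.fisher_p.iloc[0] == pytest.approx(0.5966, abs=1e-4)

    def test_missing_study_reduces_df(self):
        out = fisher_combine(np.array([[0.1, np.nan, 0.2]]))
        assert out.fisher_df.iloc[0] == 4
        assert out.n_studies.iloc[0] == 2

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            out = fisher_combine(np.array([[0.0, 0.5]]))
        assert np.isfinite(out.fisher_X.iloc[0])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6), st.integers(0, 5),
           st.floats(0.1, 0.99))
    def test_monotone_in_each_study_p(self, pvals, idx, factor):
        idx = idx % len(pvals)
        lowered = list(pvals)
        lowered[idx] = pvals[idx] * factor
        p_hi = fisher_combine(np.array([pvals])).fisher_p.iloc[0]
        p_lo = fisher_combine(np.array([lowered])).fisher_p.iloc[0]
        assert p_lo <= p_hi + 1e-12


class TestFixedEffect:
    def test_symmetric_studies(self):
        out = fixed_effect_combine(np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]]))
        assert out.fe_effect.iloc[0] == pytest.approx(1.0)
        assert out.fe_se.iloc[0] == pytest.approx(1 / np.sqrt(2))
        assert out.Q.iloc[0] == pytest.approx(0.0)

    def test_hand_computed_q(self):
        out = fixed_effect_combine(np.array([[0.0, 2.0]]), np.array([[1.0, 1.0]]))
        assert out.fe_effect.iloc[0] == pytest.approx(1.0)
        assert out.Q.iloc[0] == pytest.approx(2.0)
        assert out.Q_df.iloc[0] == 1
        assert out.Q_p.iloc[0] == pytest.approx(0.1573, abs=1e-4)

    def test_single_study_q_missing(self):
        out = fixed_effect_combine(np.array([[1.5]]), np.array([[0.5]]))
        assert out.fe_effect.iloc[0] == 1.5
        assert np.isnan(out.Q.iloc[0])

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            fixed_effect_combine(np.array([[1.0, 2.0]]), np.array([[1.0, 0.0]]))

    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.05, 3)), min_size=2, max_size=6))
    def test_pooled_within_study_range(self, studies):
        e = np.array([[x for x, _ in studies]])
        s = np.array([[x for _, x in studies]])
        pooled = fixed_effect_combine(e, s).fe_effect.iloc[0]
        assert e.min() - 1e-9 <= pooled <= e.max() + 1e-9

    def test_q_chi_squared_under_homogeneity(self, rng):
        k, n = 5, 4000
        se = rng.uniform(0.2, 1.0, (n, k))
        effects = 0.7 + rng.normal(0.0, 1.0, (n, k)) * se
        out = fixed_effect_combine(effects, se)
        assert stats.kstest(out.Q, "chi2", args=(k - 1,)).pvalue > 0.01


class TestVoteCount:
    def test_direct_count(self):
        votes = vote_count(np.array([[0.01, 0.2, 0.04, 0.6, 0.03]]))
        assert votes[0] == 3

    def test_no_votes(self):
        assert vote_count(np.array([[0.9, 0.05, 0.5]]))[0] == 0

    def test_brute_force_oracle(self, rng):
        p = rng.uniform(0, 1, (1000, 5))
        votes = vote_count(p, threshold=0.05)
        expected = np.array([sum(1 for v in row if v < 0.05) for row in p])
        np.testing.assert_array_equal(votes, expected)

    def test_missing_studies_never_vote(self):
        votes = vote_count(np.array([[0.01, np.nan, 0.02]]))
        assert votes[0] == 2

    def test_direction_consistent_variant(self):
        p = np.array([[0.01, 0.01, 0.01]])
        d = np.array([[1.0, 1.0, -1.0]])
        assert vote_count(p, directions=d, direction_consistent=True)[0] == 2


class TestConsensus:
    def _table(self, fisher_p, fe_p, votes, fe_effect=1.0):
        return pd.DataFrame({
            "fisher_p": [fisher_p], "fe_p": [fe_p], "votes": [votes],
            "fe_effect": [fe_effect], "fe_z": [fe_effect / 0.1],
        }, index=["g1"])

    def test_all_three_significant(self):
        out = consensus(self._table(1e-5, 1e-4, 3))
        assert bool(out.consensus.iloc[0])
        assert out.direction.iloc[0] == "up"

    def test_vote_below_threshold_blocks_consensus(self):
        out = consensus(self._table(1e-5, 1e-4, 1))
        assert not bool(out.consensus.iloc[0])

    def test_direction_from_pooled_sign(self):
        out = consensus(self._table(1e-5, 1e-4, 3, fe_effect=-2.0))
        assert out.direction.iloc[0] == "down"

    def test_consensus_subset_of_each_method(self, small_compendium):
        studies, _ = small_compendium
        de = {s.study_id: diffexpr.moderated_t(s.matrix, s.groups.loc[s.matrix.columns])
              for s in studies}
        out = consensus(meta_analyze(de))
        cons = set(out.index[out.consensus])
        for flag in ("sig_fisher", "sig_fe", "sig_votes"):
            assert cons <= set(out.index[out[flag]])

    def test_breakdown_percentages(self):
        b = direction_breakdown(635, 625)
        assert b["down_pct"] == 50.4
        assert b["up_pct"] == 49.6
        with pytest.raises(ValueError):
            direction_breakdown(0, 0)


class TestMetaAnalyze:
    def test_planted_recovery(self):
        spec = CompendiumSpec(n_studies=5, genes_total=800, n_young=15, n_old=15,
                              frac_up=0.1, frac_down=0.1, effect_size_delta=1.0, seed=17)
        studies, truth = generate_compendium(spec)
        de = {s.study_id: diffexpr.moderated_t(s.matrix, s.groups.loc[s.matrix.columns])
              for s in studies}
        out = consensus(meta_analyze(de))
        cons = set(out.index[out.consensus])
        assert len(cons & truth.de_genes) / len(truth.de_genes) >= 0.90
        assert len(cons & truth.null_genes) / len(truth.null_genes) <= 0.01
        # directions match the planted signs
        for g in cons & truth.up_genes:
            assert out.loc[g, "direction"] == "up"
        for g in cons & truth.down_genes:
            assert out.loc[g, "direction"] == "down"

    def test_gene_dropped_when_in_too_few_studies(self, small_compendium):
        studies, _ = small_compendium
        de = {s.study_id: diffexpr.moderated_t(s.matrix, s.groups.loc[s.matrix.columns])
              for s in studies}
        # gene present in a single study only
        lone = de[studies[0].study_id].iloc[:1].rename(index={de[studies[0].study_id].index[0]: "LONE"})
        de["extra"] = lone
        out = meta_analyze(de)
        assert "LONE" not in out.index

    def test_fisher_null_type_one_at_strict_threshold(self, null_compendium):
        (study,), _ = null_compendium
        cols = study.matrix.columns
        # split one null study into two pseudo-studies (each keeps both groups)
        split_a = cols[:5].append(cols[10:15])
        split_b = cols[5:10].append(cols[15:20])
        de = {}
        for i, cols in enumerate((split_a, split_b)):
            sub = study.matrix[cols]
            de[f"s{i}"] = diffexpr.moderated_t(sub, study.groups.loc[cols])
        out = meta_analyze(de)
        assert (out.fisher_p < 0.001).mean() <= 0.005
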