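import numpy as np
import pandas as pd
import pytest

import strata_tx as st
from strata_tx.errors import ValidationError


def _metadata(n, rng, dx=None):
    if dx is None:
        dx = np.array(["CTL", "AD"])[rng.integers(0, 2, n)]
    df = pd.DataFrame(
        {
            "sex": "female",
            "diagnosis": dx,
            "Age": rng.uniform(60, 95, n),
            "RIN": rng.normal(7.5, 1.0, n),
            "PMI": rng.uniform(2, 30, n),
        },
        index=pd.Index([f"s{i:03d}" for i in range(n)], name="sample_id"),
    )
    return st.SampleMetadata(df)


class TestImputePmi:
    def test_missing_becomes_minus_one(self, tiny_metadata):
        out = st.impute_pmi(tiny_metadata)
        assert out.table.loc["s1", "PMI"] == -1.0
        assert out.table.loc["s2", "PMI"] == 12.0

    def test_identity_without_missing(self):
        rng = np.random.default_rng(0)
        meta = _metadata(10, rng)
        out = st.impute_pmi(meta)
        pd.testing.assert_frame_equal(out.table, meta.table)

    def test_all_missing(self):
        rng = np.random.default_rng(0)
        meta = _metadata(6, rng)
        table = meta.table.copy()
        table["PMI"] = np.nan
        out = st.impute_pmi(st.SampleMetadata(table))
        assert (out.table["PMI"] == -1.0).all()

    def test_other_columns_untouched(self, tiny_metadata):
        out = st.impute_pmi(tiny_metadata)
        pd.testing.assert_frame_equal(
            out.table.drop(columns="PMI"), tiny_metadata.table.drop(columns="PMI")
        )


class TestTransformCounts:
    def test_log2_values(self, tiny_counts):
        sf = pd.Series([1.0, 1.0], index=["s1", "s2"])
        expr = st.transform_counts(tiny_counts, sf)
        assert expr.loc["g2", "s1"] == 0.0  # log2(0/1 + 1)
        assert expr.loc["g3", "s1"] == pytest.approx(3.0)  # log2(7+1)

    def test_scale_invariance(self, tiny_counts):
        sf = pd.Series([1.0, 1.0], index=["s1", "s2"])
        doubled = st.CountMatrix(tiny_counts.counts * 2)
        sf2 = pd.Series([2.0, 2.0], index=["s1", "s2"])
        pd.testing.assert_frame_equal(
            st.transform_counts(tiny_counts, sf),
            st.transform_counts(doubled, sf2),
        )

    def test_nonpositive_size_factor_rejected(self, tiny_counts):
        sf = pd.Series([1.0, 0.0], index=["s1", "s2"])
        with pytest.raises(ValidationError, match="positive"):
            st.transform_counts(tiny_counts, sf)


class TestPartitionVariance:
    def test_pure_age_gene(self):
        rng = np.random.default_rng(1)
        meta = _metadata(60, rng)
        y = 0.05 * meta.table["Age"].to_numpy()
        expr = pd.DataFrame([y], index=["g"], columns=meta.sample_ids)
        fr = st.partition_variance(expr, meta)
        assert fr.loc["g", "age_frac"] >= 0.99
        assert fr.loc["g", "dx_frac"] <= 0.01

    def test_constant_gene_flagged(self):
        rng = np.random.default_rng(2)
        meta = _metadata(20, rng)
        expr = pd.DataFrame(
            [np.full(20, 3.0)], index=["g"], columns=meta.sample_ids
        )
        fr = st.partition_variance(expr, meta)
        assert bool(fr.loc["g", "flagged"])
        assert fr.loc["g", "residual"] == 1.0
        assert fr.loc["g", ["age_frac", "rin_frac", "pmi_frac", "dx_frac"]].sum() == 0.0

    def test_known_shares_recovered(self):
        """Planted generative shares (Diagnosis 0.4, Age 0.2, noise 0.4)
        recovered within +/-0.05 at n = 500."""
        rng = np.random.default_rng(3)
        n = 500
        meta = _metadata(n, rng)
        dxi = (meta.table["diagnosis"] == "AD").to_numpy(dtype=float)
        age = meta.table["Age"].to_numpy()

        def standardize(x):
            return (x - x.mean()) / x.std()

        y = (
            np.sqrt(0.4) * standardize(dxi)
            + np.sqrt(0.2) * standardize(age)
            + np.sqrt(0.4) * rng.normal(size=n)
        )
        expr = pd.DataFrame([y], index=["g"], columns=meta.sample_ids)
        fr = st.partition_variance(expr, meta)
        assert fr.loc["g", "dx_frac"] == pytest.approx(0.4, abs=0.05)
        assert fr.loc["g", "age_frac"] == pytest.approx(0.2, abs=0.05)
        assert fr.loc["g", "residual"] == pytest.approx(0.4, abs=0.05)

    def test_fractions_sum_to_one(self, small_cohort):
        _, counts, metadata, _ = small_cohort
        meta = st.impute_pmi(metadata)
        sf = st.estimate_size_factors(counts)
        expr = st.transform_counts(counts, sf)
        fr = st.partition_variance(expr, meta)
        sums = fr[["age_frac", "rin_frac", "pmi_frac", "dx_frac", "residual"]].sum(axis=1)
        assert np.allclose(sums[~fr["flagged"]], 1.0, atol=1e-8)
        assert ((fr[["age_frac", "rin_frac", "pmi_frac", "dx_frac"]] >= 0).all()).all()

    def test_sample_permutation_invariance(self, small_cohort):
        _, counts, metadata, _ = small_cohort
        meta = st.impute_pmi(metadata)
        sf = st.estimate_size_factors(counts)
        expr = st.transform_counts(counts, sf)
        fr = st.partition_variance(expr, meta)
        rng = np.random.default_rng(4)
        perm = list(rng.permutation(expr.columns))
        fr_perm = st.partition_variance(expr[perm], meta)
        pd.testing.assert_frame_equal(fr, fr_perm, check_exact=False, atol=1e-10)

    def test_constant_covariate_rejected_by_name(self):
        rng = np.random.default_rng(5)
        meta = _metadata(20, rng)
        table = meta.table.copy()
        table["RIN"] = 7.0
        expr = pd.DataFrame(
            rng.normal(size=(3, 20)), index=list("abc"), columns=meta.sample_ids
        )
        with pytest.raises(ValidationError, match="RIN"):
            st.partition_variance(expr, st.SampleMetadata(table))

    def test_unimputed_pmi_rejected(self, small_cohort):
        _, counts, metadata, _ = small_cohort
        sf = st.estimate_size_factors(counts)
        expr = st.transform_counts(counts, sf)
        if metadata.table["PMI"].isna().any():
            with pytest.raises(ValidationError, match="PMI"):
                st.partition_variance(expr, metadata)


class TestFilterGenes:
    @pytest.fixture()
    def fractions(self):
        return pd.DataFrame(
            {
                "age_frac": [0.1, 0.0, 0.0, 0.0],
                "rin_frac": [0.0, 0.0, 0.0, 0.0],
                "pmi_frac": [0.0, 0.0, 0.0, 0.0],
                "dx_frac": [0.2, 0.005, 0.0, 0.0],
                "residual": [0.7, 0.995, 1.0, 1.0],
                "flagged": [False, False, False, True],
            },
            index=["g1", "g2", "g3", "g4"],
        )

    def test_zero_threshold_retains_all_unflagged(self, fractions):
        assert st.filter_genes(fractions, 0.0) == ["g1", "g2", "g3"]

    def test_threshold_one_retains_nothing(self, fractions):
        assert st.filter_genes(fractions, 1.0) == []

    def test_default_threshold_and_order(self, fractions):
        assert st.filter_genes(fractions) == ["g1"]

    def test_planted_genes_enriched_among_retained(self, small_cohort):
        _, counts, metadata, truth = small_cohort
        meta = st.impute_pmi(metadata)
        sf = st.estimate_size_factors(counts)
        expr = st.transform_counts(counts, sf)
        fr = st.partition_variance(expr, meta)
        retained = set(st.filter_genes(fr, 0.01))
        planted = truth.de_genes("female")
        null_genes = set(counts.gene_ids) - planted
        rate_planted = len(retained & planted) / len(planted)
        rate_null = len(retained & null_genes) / len(null_genes)
        assert rate_planted > rate_null
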