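"""Normalization formulas, filters and ratio guards."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lpsprofiler import (
    clr_normalize,
    compute_cpm,
    compute_gcpm,
    cpm_pipeline,
    filter_rare_features,
    gene_ratio,
    hexa_penta_ratio,
    nonzero_subset,
    pseudolog_transform,
    simple_batch_adjust,
    weight_normalize,
)
from tests.conftest import random_count_matrix


def frame(rows, samples=("s1",)):
    return pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))],
                        columns=list(samples), dtype=float)


class TestGcpm:
    def test_hand_example(self):
        """q=(10,10), l=(100,200): length-normalized rates 0.1 and 0.05 split
        a million 2:1."""
        counts = frame([[10], [10]])
        lengths = pd.Series([100.0, 200.0], index=counts.index)
        g = compute_gcpm(counts, lengths)["s1"]
        assert g.iloc[0] == pytest.approx(666_666.67, abs=0.01)
        assert g.iloc[1] == pytest.approx(333_333.33, abs=0.01)

    def test_single_feature_forced_to_million(self):
        g = compute_gcpm(frame([[10]]), pd.Series([100.0], index=["f0"]))
        assert g.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_features_split_evenly(self):
        counts = frame([[7]] * 5)
        g = compute_gcpm(counts, pd.Series(250.0, index=counts.index))
        np.testing.assert_allclose(g["s1"], 2e5)

    def test_scale_invariance_and_column_sums(self, rng):
        counts = random_count_matrix(rng)
        lengths = pd.Series(rng.uniform(600, 3000, len(counts)), index=counts.index)
        g1 = compute_gcpm(counts, lengths)
        g2 = compute_gcpm(counts * 17, lengths)
        pd.testing.assert_frame_equal(g1, g2)
        np.testing.assert_allclose(g1.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_sample_named(self):
        counts = frame([[0, 5], [0, 5]], samples=("dead", "ok"))
        with pytest.raises(ValueError, match="dead"):
            compute_gcpm(counts, pd.Series(100.0, index=counts.index))

    def test_bad_length_rejected(self):
        counts = frame([[1]])
        with pytest.raises(ValueError, match="f0"):
            compute_gcpm(counts, pd.Series([0.0], index=["f0"]))


class TestCpm:
    def test_arithmetic(self):
        c = compute_cpm(frame([[1], [1], [2]]))["s1"]
        np.testing.assert_allclose(c, [250_000, 250_000, 500_000])

    def test_homogeneity(self, rng):
        counts = random_count_matrix(rng)
        pd.testing.assert_frame_equal(compute_cpm(counts), compute_cpm(counts * 3))

    def test_pseudolog_values(self):
        v = pseudolog_transform(pd.Series([0.0, 1 - 1e-6, 1.0, 10.0, 100.0]))
        assert v.iloc[0] == pytest.approx(np.log(1e-6))
        assert v.iloc[1] == pytest.approx(0.0)
        assert v.is_monotonic_increasing

    def test_pseudolog_rejects_negative(self):
        with pytest.raises(ValueError):
            pseudolog_transform(pd.Series([-1.0]))

    def test_pipeline_modes(self, rng):
        counts = random_count_matrix(rng)
        raw = cpm_pipeline(counts, mode="raw")
        pd.testing.assert_frame_equal(raw, compute_cpm(counts))
        plog = cpm_pipeline(counts, mode="pseudolog")
        np.testing.assert_allclose(plog.sum(axis=0), 1e6, rtol=1e-6)
        expected = pseudolog_transform(counts)
        expected = expected / expected.sum(axis=0) * 1e6
        pd.testing.assert_frame_equal(plog, expected)


class TestFilters:
    def _matrix(self, detected_in: int, n_samples: int = 100) -> pd.DataFrame:
        row = [1] * detected_in + [0] * (n_samples - detected_in)
        return pd.DataFrame([row, [1] * n_samples], index=["rare", "common"])

    def test_rare_boundary(self):
        """Nonzero in 4 of 100 samples is dropped; in exactly 5, retained."""
        kept, dropped = filter_rare_features(self._matrix(4))
        assert dropped == ["rare"] and list(kept.index) == ["common"]
        kept, dropped = filter_rare_features(self._matrix(5))
        assert dropped == [] and "rare" in kept.index

    def test_empty_matrix_passthrough(self):
        empty = pd.DataFrame()
        kept, dropped = filter_rare_features(empty)
        assert kept.empty and dropped == []

    def test_idempotent(self, rng):
        m = random_count_matrix(rng).where(lambda d: d > 25, 0)
        once, _ = filter_rare_features(m, 3)
        twice, dropped = filter_rare_features(once, 3)
        assert dropped == []
        pd.testing.assert_frame_equal(once, twice)

    def test_nonzero_subset(self):
        values = pd.Series([0.0, 3.2, 0.0, 7.0], index=list("abcd"))
        kept, n_excluded = nonzero_subset(values)
        assert list(kept.index) == ["b", "d"] and n_excluded == 2
        again, n2 = nonzero_subset(kept)
        assert n2 == 0
        pd.testing.assert_series_equal(again, kept)

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            kept, n = nonzero_subset(pd.Series([0.0, 0.0]))
        assert kept.empty and n == 2


class TestRatios:
    def _abund(self, hexa, penta, lpxM=None):
        return pd.DataFrame({
            "hexa_total": hexa, "penta": penta,
            "hexa_lpxM": lpxM if lpxM is not None else hexa,
        })

    def test_arithmetic_and_guards(self):
        ab = self._abund([0.4, 0.0, 0.1], [0.2, 0.3, 0.0])
        r = hexa_penta_ratio(ab)
        assert r.iloc[0] == pytest.approx(2.0)
        assert r.iloc[1] == pytest.approx(0.0)
        assert np.isnan(r.iloc[2])  # undefined: zero penta

    def test_numerator_choice(self):
        ab = self._abund([0.4], [0.2], lpxM=[0.1])
        assert hexa_penta_ratio(ab, "hexa_lpxM").iloc[0] == pytest.approx(0.5)
        with pytest.raises(ValueError):
            hexa_penta_ratio(ab, "tetra")

    def test_gene_ratio(self):
        num = pd.Series([500.0, 3.0], index=["a", "b"])
        den = pd.Series([1000.0, 3.0], index=["a", "b"])
        r = gene_ratio(num, den)
        assert r.iloc[0] == pytest.approx(0.5)
        assert r.iloc[1] == pytest.approx(1.0)
        with pytest.raises(ValueError, match="sample"):
            gene_ratio(num, den.rename({"b": "c"}))

    def test_ratio_scale_invariance(self, rng):
        num = pd.Series(rng.uniform(1, 5, 6))
        den = pd.Series(rng.uniform(1, 5, 6))
        pd.testing.assert_series_equal(
            gene_ratio(num, den), gene_ratio(num * 1e6, den * 1e6)
        )


class TestClr:
    def test_uniform_composition_maps_to_zero(self):
        clr = clr_normalize(frame([[1], [1], [1], [1]]))
        np.testing.assert_allclose(clr["s1"], 0.0, atol=1e-12)

    def test_two_part_closed_form(self):
        clr = clr_normalize(frame([[2], [8]]))["s1"]
        assert clr.iloc[0] == pytest.approx(-np.log(2))
        assert clr.iloc[1] == pytest.approx(np.log(2))

    def test_matches_reference_clr_without_zeros(self, rng):
        from skbio.stats.composition import clr as skbio_clr

        counts = random_count_matrix(rng)
        ours = clr_normalize(counts)
        for s in counts.columns:
            x = counts[s].to_numpy(dtype=float)
            np.testing.assert_allclose(
                ours[s], skbio_clr(x / x.sum()), atol=1e-10
            )

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.integers(min_value=0, max_value=1000), min_size=2,
                    max_size=30).filter(lambda v: sum(v) > 0))
    def test_columns_sum_to_zero(self, values):
        clr = clr_normalize(frame([[v] for v in values]))
        assert abs(clr["s1"].sum()) < 1e-9

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="s1"):
            clr_normalize(frame([[0], [0]]))


class TestWeightNormalize:
    def test_reads_per_mg(self):
        taxa = pd.DataFrame({"A": [1000]}, index=["m1"])
        out = weight_normalize(taxa, pd.Series({"m1": 10.0}))
        assert out.at["m1", "A"] == pytest.approx(100.0)

    def test_equal_weights_preserve_ordering(self, rng):
        taxa = pd.DataFrame({"A": rng.integers(1, 100, 5)},
                            index=[f"m{i}" for i in range(5)])
        out = weight_normalize(taxa, pd.Series(2.0, index=taxa.index))
        assert (out["A"].rank() == taxa["A"].rank()).all()

    @pytest.mark.parametrize("weight", [0.0, -1.0])
    def test_nonpositive_weight_rejected(self, weight):
        taxa = pd.DataFrame({"A": [1]}, index=["m1"])
        with pytest.raises(ValueError, match="m1"):
            weight_normalize(taxa, pd.Series({"m1": weight}))


class TestBatchAdjust:
    def test_single_batch_identity(self, rng):
        counts = random_count_matrix(rng)
        batches = pd.Series("b1", index=counts.columns)
        out = simple_batch_adjust(counts, batches)
        pd.testing.assert_frame_equal(out, counts.astype(float))

    def test_constant_log_shift_removed(self, rng):
        base = random_count_matrix(rng, n_features=15, n_samples=6)
        shifted = base * np.exp(0.8)
        counts = pd.concat([base, shifted.set_axis(
            [f"t{j}" for j in range(6)], axis=1)], axis=1)
        batches = pd.Series(["b1"] * 6 + ["b2"] * 6, index=counts.columns)
        out = simple_batch_adjust(counts, batches)
        logged = np.log(out.where(out > 0))
        med1 = logged.iloc[:, :6].median(axis=1)
        med2 = logged.iloc[:, 6:].median(axis=1)
        assert (med1 - med2).abs().max() < 1e-9

    def test_planted_batch_effect_variance_shrinks(self):
        from lpsprofiler import (SimulationConfig, default_gene_lengths,
                                 generate_gene_counts, generate_pangenomes,
                                 generate_taxa_profiles)

        cfg = SimulationConfig(n_species=30, n_samples_per_arm=15,
                               n_batches=3, batch_sd=0.8, seed=21)
        pangenome, truth = generate_pangenomes(cfg)
        taxa, metadata = generate_taxa_profiles(cfg, truth)
        genes = generate_gene_counts(taxa, pangenome,
                                     default_gene_lengths(cfg), cfg)
        counts = genes.drop(columns=["ko", "taxon", "length_bp"])
        adjusted = simple_batch_adjust(counts, metadata["study"])

        def between_batch_var(mat):
            logged = np.log(mat.where(mat > 0))
            meds = pd.DataFrame({
                b: logged.loc[:, metadata["study"] == b].median(axis=1)
                for b in metadata["study"].unique()
            })
            return meds.var(axis=1).mean()

        assert between_batch_var(adjusted) < between_batch_var(counts)

    def test_singleton_batch_left_unadjusted(self, rng):
        counts = random_count_matrix(rng, n_samples=5)
        batches = pd.Series(["b1"] * 4 + ["solo"], index=counts.columns)
        with pytest.warns(UserWarning, match="solo"):
            out = simple_batch_adjust(counts, batches)
        pd.testing.assert_series_equal(
            out.iloc[:, 4], counts.iloc[:, 4].astype(float)
        )

    def test_output_non_negative_and_zeros_preserved(self, rng):
        counts = random_count_matrix(rng).where(lambda d: d > 28, 0)
        batches = pd.Series(["b1"] * 4 + ["b2"] * 4, index=counts.columns)
        out = simple_batch_adjust(counts, batches)
        assert (out.to_numpy() >= 0).all()
        assert ((counts == 0) == (out == 0)).all().all()
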