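"""Data generation and the three response-format renderings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vasrrp import (
    generate_dataset,
    implied_covariance,
    rescale_common,
    to_likert,
    to_ranking,
    to_vasrrp,
    vas_item_score,
    read_dataset,
    write_dataset,
)
from vasrrp.reliability import cronbach_alpha
from vasrrp.synthetic_data import ContinuousDataset


class TestGeneration:
    def test_seed_determinism(self, spec_4l4i):
        a = generate_dataset(spec_4l4i, 200, seed=5)
        b = generate_dataset(spec_4l4i, 200, seed=5)
        c = generate_dataset(spec_4l4i, 200, seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_sample_covariance_matches_implied(self, spec_4l4i):
        raw = generate_dataset(spec_4l4i, 50_000, seed=20240, clip=False)
        S = np.cov(raw.values, rowvar=False)
        assert np.max(np.abs(S - implied_covariance(spec_4l4i))) < 0.05

    def test_clipping_only_attenuates(self, spec_4l4i, big_dataset):
        # clipping can only shrink variances, and not by much
        S = np.cov(big_dataset.values, rowvar=False)
        implied_var = np.diag(implied_covariance(spec_4l4i))
        shrink = implied_var - np.diag(S)
        assert np.all(shrink > -0.02)
        assert np.max(shrink) < 0.3

    def test_ct_mode_residuals_uncorrelated(self, spec_4l4i):
        ct = spec_4l4i.with_mode("CT")
        data = generate_dataset(ct, 50_000, seed=11)
        # partial out the latent structure: residual covariance of items in
        # the same testlet should vanish
        S = np.cov(data.values, rowvar=False)
        Lam = ct.lambda_matrix
        implied_common = Lam @ ct.latent_corr @ Lam.T
        resid = S - implied_common
        for t in range(ct.n_testlets):
            idx = ct.items_of_testlet(t)
            off = resid[np.ix_(idx, idx)][~np.eye(idx.size, dtype=bool)]
            assert np.max(np.abs(off)) < 0.05

    def test_clip_fraction_small_and_recorded(self, big_dataset):
        assert 0.0 < big_dataset.clip_fraction < 0.08

    def test_rejects_tiny_n(self, spec_4l4i):
        with pytest.raises(ValueError):
            generate_dataset(spec_4l4i, 1, seed=0)


class TestVasrrp:
    def test_endpoints_and_midpoint(self, spec_4l4i, small_dataset):
        vas = to_vasrrp(small_dataset)
        assert vas.values.min() >= 0 and vas.values.max() <= 1
        vals = np.zeros((2, 16))
        vals[0, 0], vals[1, 0] = -3.0, 3.0
        boundary = ContinuousDataset(values=vals, spec=spec_4l4i, seed=0)
        v = to_vasrrp(boundary).values
        assert v[0, 0] == 0.0 and v[1, 0] == 1.0 and v[0, 1] == 0.5

    def test_order_preserving(self, small_dataset):
        vas = to_vasrrp(small_dataset)
        flat_x = small_dataset.values.ravel()
        flat_v = vas.values.ravel()
        order = np.argsort(flat_x)
        assert np.all(np.diff(flat_v[order]) >= 0)

    def test_alpha_invariant_under_map(self, spec_4l4i, small_dataset):
        vas = to_vasrrp(small_dataset)
        idx = spec_4l4i.items_of_latent(0)
        assert cronbach_alpha(vas.values[:, idx]) == pytest.approx(
            cronbach_alpha(small_dataset.values[:, idx])
        )


class TestLikert:
    def test_direct_bucketing(self, spec_4l4i):
        vals = np.zeros((4, 16))
        vals[:, 0] = [-1.5, 0.0, 2.0, 0.5]
        data = ContinuousDataset(values=vals, spec=spec_4l4i, seed=0)
        lik = to_likert(data, [-1, 1])
        assert lik.values[:, 0].tolist() == [1, 2, 3, 2]
        assert lik.n_categories == 3

    def test_five_point_scale(self, small_dataset):
        lik = to_likert(small_dataset, [-3, -1, 1, 3])
        assert lik.n_categories == 5
        assert set(np.unique(lik.values)) <= {1, 2, 3, 4, 5}

    def test_monotone_up_to_ties(self, small_dataset):
        lik = to_likert(small_dataset, [-1, 1])
        x = small_dataset.values.ravel()
        c = lik.values.ravel()
        order = np.argsort(x, kind="stable")
        assert np.all(np.diff(c[order]) >= 0)

    def test_all_categories_occur_at_scale(self, spec_4l4i, big_dataset):
        lik = to_likert(big_dataset, [-1, 1])
        for j in range(spec_4l4i.n_items):
            assert set(np.unique(lik.values[:, j])) == {1, 2, 3}

    def test_empty_cuts_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            to_likert(small_dataset, [])
        with pytest.raises(ValueError):
            to_likert(small_dataset, [1, -1])


class TestRanking:
    def test_order_statistics(self, spec_4l4i):
        vals = np.zeros((1, 16))
        idx = spec_4l4i.items_of_testlet(0)
        vals[0, idx] = [0.8, 0.2, 0.6, 0.4]
        data = ContinuousDataset(values=vals, spec=spec_4l4i, seed=0)
        ranks = to_ranking(data)
        assert ranks.values[0, idx].tolist() == [4, 1, 3, 2]

    def test_constant_rank_sum(self, spec_4l4i, small_dataset):
        ranks = to_ranking(small_dataset)
        for t in range(4):
            idx = spec_4l4i.items_of_testlet(t)
            assert np.all(ranks.values[:, idx].sum(axis=1) == 10)

    def test_ipsative_covariance_singular(self, spec_4l4i, small_dataset):
        ranks = to_ranking(small_dataset)
        idx = spec_4l4i.items_of_testlet(0)
        S = np.cov(ranks.values[:, idx].astype(float), rowvar=False)
        assert np.allclose(S.sum(axis=1), 0.0, atol=1e-10)
        assert abs(np.linalg.det(S)) < 1e-10

    def test_invariant_under_monotone_transform(self, spec_4l4i, small_dataset):
        base = to_ranking(small_dataset)
        warped = ContinuousDataset(
            values=np.tanh(small_dataset.values) * 3,
            spec=spec_4l4i,
            seed=small_dataset.seed,
        )
        assert np.array_equal(to_ranking(warped).values, base.values)

    def test_vasrrp_input_equivalent(self, small_dataset):
        assert np.array_equal(
            to_ranking(to_vasrrp(small_dataset)).values,
            to_ranking(small_dataset).values,
        )


class TestVasItemScore:
    @pytest.mark.parametrize(
        "x1, x2, x3, expected",
        [(0, 100, 25, 0.25), (120, 920, 520, 0.5), (0, 10, 0, 0.0), (0, 10, 10, 1.0)],
    )
    def test_examples(self, x1, x2, x3, expected):
        assert vas_item_score(x1, x2, x3) == pytest.approx(expected)

    def test_degenerate_and_out_of_range(self):
        with pytest.raises(ValueError):
            vas_item_score(5, 5, 5)
        with pytest.raises(ValueError):
            vas_item_score(0, 100, 150)

    @settings(max_examples=30, derandomize=True)
    @given(
        offset=st.floats(-1e3, 1e3),
        scale=st.floats(0.01, 100),
        frac=st.floats(0, 1),
    )
    def test_invariant_under_pixel_offset_and_zoom(self, offset, scale, frac):
        x1, x2 = offset, offset + scale * 800
        x3 = x1 + frac * (x2 - x1)
        assert vas_item_score(x1, x2, x3) == pytest.approx(frac, abs=1e-9)


class TestRescaleCommon:
    def test_likert_and_rank_divisors(self, small_dataset):
        lik = rescale_common(to_likert(small_dataset, [-1.5, -0.5, 0.5, 1.5]))
        assert lik.values.max() <= 1.0 and lik.values.min() > 0
        assert np.max(lik.values) == pytest.approx(1.0)
        ranks = rescale_common(to_ranking(small_dataset))
        assert set(np.unique(ranks.values)) == {0.25, 0.5, 0.75, 1.0}

    def test_vasrrp_identity(self, small_dataset):
        vas = to_vasrrp(small_dataset)
        assert rescale_common(vas) is vas


class TestCsvRoundTrip:
    def test_continuous_and_formatted(self, tmp_path, spec_4l4i, small_dataset):
        path = tmp_path / "data.csv"
        write_dataset(small_dataset, path)
        back = read_dataset(path)
        assert np.allclose(back.values, small_dataset.values)
        assert back.spec.to_dict() == spec_4l4i.to_dict()
        assert back.seed == small_dataset.seed

        lik = to_likert(small_dataset, [-1, 1])
        write_dataset(lik, tmp_path / "lik.csv")
        back = read_dataset(tmp_path / "lik.csv")
        assert np.array_equal(back.values, lik.values)
        assert back.cut_points == lik.cut_points
        assert back.format == "likert"

    def test_header_encodes_testlet_and_latent(self, tmp_path, small_dataset):
        path = tmp_path / "data.csv"
        write_dataset(small_dataset, path)
        header = path.read_text().splitlines()[0].split(",")
        assert header[0] == "T1_L1" and header[4] == "T1_L2"
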