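"""Group consensus networks, interregional aggregation, mCD binomial tests
and the cohort statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ecpipe import (
    ChannelLayout, binomial_p_two_sided, compact_layout, contrast_ec,
    correlate_mmse, demographics_tests, group_network, mcd,
    subject_region_ec,
)
from ecpipe.bayesian import ConnectivityMatrix
from ecpipe.errors import GroupingError
from ecpipe.netstats import RegionNetwork


def _cm(strengths, mask=None, band="I", state="sitting", sid="S"):
    s = np.asarray(strengths, dtype=float)
    if mask is None:
        mask = np.ones_like(s, dtype=bool)
        np.fill_diagonal(mask, False)
    return ConnectivityMatrix(
        strengths=s, mask=np.asarray(mask, dtype=bool), band=band,
        state=state, subject_id=sid,
    )


def _uniform_cm(n, value, mask_value=True, **kw):
    s = np.full((n, n), float(value))
    np.fill_diagonal(s, np.nan)
    mask = np.full((n, n), mask_value)
    np.fill_diagonal(mask, False)
    return _cm(s, mask, **kw)


class TestGroupNetwork:
    def _cohort(self, n_subj, n_sig, n=4, edge=(0, 1)):
        """n_subj matrices; the edge is significant in the first n_sig."""
        cms = []
        for k in range(n_subj):
            mask = np.zeros((n, n), dtype=bool)
            if k < n_sig:
                mask[edge] = True
            s = np.full((n, n), 0.1)
            np.fill_diagonal(s, np.nan)
            cms.append(_cm(s, mask, sid=f"S{k}"))
        return cms

    def test_consensus_above_threshold(self):
        gn = group_network(self._cohort(17, 13))  # 13/17 = 76.5% > 75%
        assert gn.consensus_mask[0, 1]

    def test_consensus_below_threshold(self):
        gn = group_network(self._cohort(17, 12))  # 70.6%
        assert not gn.consensus_mask[0, 1]

    def test_exactly_75_percent_excluded(self):
        gn = group_network(self._cohort(20, 15))  # strict >
        assert not gn.consensus_mask[0, 1]

    def test_mean_over_all_subjects(self):
        cms = [_uniform_cm(4, v, sid=str(v)) for v in (0.1, 0.2, 0.3)]
        gn = group_network(cms)
        assert gn.mean_strengths[0, 1] == pytest.approx(0.2)

    def test_mixed_bands_rejected(self):
        a = _uniform_cm(4, 0.1, band="I")
        b = _uniform_cm(4, 0.1, band="II")
        with pytest.raises(GroupingError):
            group_network([a, b])


class TestSubjectRegionEC:
    def test_region_pair_count(self):
        layout = compact_layout(1)
        net = subject_region_ec(_uniform_cm(6, 0.3), layout)
        off = ~np.eye(6, dtype=bool)
        assert np.isfinite(net.ec[off]).sum() == 30

    def test_uniform_strength_propagates_exactly(self):
        layout = compact_layout(2)
        net = subject_region_ec(_uniform_cm(12, 0.42), layout)
        off = ~np.eye(6, dtype=bool)
        np.testing.assert_allclose(net.ec[off], 0.42)

    def test_all_masked_gives_all_missing(self):
        layout = compact_layout(1)
        net = subject_region_ec(
            _uniform_cm(6, 0.3, mask_value=False), layout
        )
        off = ~np.eye(6, dtype=bool)
        assert np.all(np.isnan(net.ec[off]))

    def test_hand_built_two_region_means(self):
        # 4 channels, 2 regions of 2; known strengths, partial mask
        layout = ChannelLayout(("A", "B"), (2, 2))
        s = np.full((4, 4), np.nan)
        # A -> B block: channels 0,1 -> 2,3
        s[0, 2], s[0, 3], s[1, 2], s[1, 3] = 0.1, 0.2, 0.3, 0.4
        s[2, 0], s[3, 1] = 0.5, 0.7  # B -> A
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 2] = mask[1, 3] = True  # only 0.1 and 0.4 significant
        mask[2, 0] = True
        net = subject_region_ec(_cm(s, mask), layout)
        assert net.ec[0, 1] == pytest.approx((0.1 + 0.4) / 2)
        assert net.ec[1, 0] == pytest.approx(0.5)


class TestMcd:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (10, 10, 2 * 0.5**10),       # ~0.00195
            (5, 10, 1.0),
            (8, 10, 0.109375),
            (0, 10, 2 * 0.5**10),
            (15, 20, None),              # checked against scipy below
        ],
    )
    def test_binomial_matches_closed_form(self, k, n, expected):
        p = binomial_p_two_sided(k, n)
        if expected is not None:
            assert p == pytest.approx(expected, abs=1e-12)
        # independent oracle: scipy's exact binomial test (p0=0.5 is
        # symmetric, so two-sided equals doubling the smaller tail)
        ref = stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def _two_region_cm(self, votes_ab, votes_ba):
        n = votes_ab + votes_ba
        layout = ChannelLayout(("A", "B"), (n, n))
        size = 2 * n
        s = np.full((size, size), np.nan)
        mask = np.zeros((size, size), dtype=bool)
        for i in range(n):
            j = n + i
            hi, lo = (0.9, 0.1) if i < votes_ab else (0.1, 0.9)
            s[i, j], s[j, i] = hi, lo
            mask[i, j] = True
        return _cm(s, mask), layout

    def test_unanimous_votes_unidirectional(self):
        cm, layout = self._two_region_cm(10, 0)
        res = mcd(cm, layout, ("A", "B"))
        assert res.direction == "r1->r2"
        assert res.p_value == pytest.approx(2 * 0.5**10, abs=1e-12)

    def test_split_votes_bidirectional(self):
        cm, layout = self._two_region_cm(5, 5)
        res = mcd(cm, layout, ("A", "B"))
        assert res.direction == "bidirectional"
        assert res.p_value == pytest.approx(1.0)

    def test_8_of_10_bidirectional_at_alpha_05(self):
        cm, layout = self._two_region_cm(8, 2)
        res = mcd(cm, layout, ("A", "B"))
        assert res.p_value == pytest.approx(0.109375, abs=1e-12)
        assert res.direction == "bidirectional"

    def test_no_significant_pairs_undefined(self):
        layout = compact_layout(1)
        cm = _uniform_cm(6, 0.3, mask_value=False)
        res = mcd(cm, layout, ("LPFC", "RPFC"))
        assert not res.defined

    def test_tie_dropped_with_warning(self):
        layout = ChannelLayout(("A", "B"), (1, 1))
        s = np.array([[np.nan, 0.3], [0.3, np.nan]])
        mask = np.array([[False, True], [False, False]])
        with pytest.warns(RuntimeWarning, match="tied"):
            res = mcd(_cm(s, mask), layout, ("A", "B"))
        assert res.n_votes == 0 and not res.defined


def _region_nets(values, labels=("A", "B"), **kw):
    """One RegionNetwork per subject with ec[0,1] = value, rest NaN."""
    nets = []
    for k, v in enumerate(values):
        ec = np.full((len(labels), len(labels)), np.nan)
        ec[0, 1] = v
        nets.append(RegionNetwork(ec=ec, labels=labels, subject_id=f"S{k}"))
    return nets


class TestContrastEc:
    def test_identical_samples_h_zero(self):
        a = _region_nets([1.0, 2.0, 3.0])
        b = _region_nets([1.0, 2.0, 3.0])
        df = contrast_ec(a, b)
        row = df[df["connection"] == "A->B"].iloc[0]
        assert row["H"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_hand_computed_kruskal_wallis(self):
        # ranks 1,2,3 vs 4,5,6: H = 12/(6*7) * 2 * 3 * 1.5^2 = 3.857...
        a = _region_nets([1.0, 2.0, 3.0])
        b = _region_nets([4.0, 5.0, 6.0])
        df = contrast_ec(a, b)
        row = df[df["connection"] == "A->B"].iloc[0]
        assert row["H"] == pytest.approx(27 / 7, abs=1e-6)
        assert row["p"] == pytest.approx(0.049535, abs=1e-4)

    def test_rank_test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        xa = rng.uniform(0.1, 1, 8)
        xb = rng.uniform(0.1, 1, 8)
        df1 = contrast_ec(_region_nets(xa), _region_nets(xb))
        df2 = contrast_ec(
            _region_nets(np.log(xa) ** 3 if False else np.log(xa)),
            _region_nets(np.log(xb)),
        )
        assert df1.iloc[0]["H"] == pytest.approx(df2.iloc[0]["H"])

    def test_missing_values_dropped_and_skipped(self):
        a = _region_nets([1.0, np.nan, np.nan])
        b = _region_nets([2.0, 3.0, 4.0])
        df = contrast_ec(a, b)
        row = df[df["connection"] == "A->B"].iloc[0]
        assert "skipped" in row["note"]


class TestCorrelateMmse:
    def test_exact_linear_relationship(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        nets = _region_nets(vals)
        df = correlate_mmse(nets, 2 * vals + 1)
        row = df[df["connection"] == "A->B"].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-6

    def test_constant_mmse_undefined(self):
        nets = _region_nets([1.0, 2.0, 3.0, 4.0])
        df = correlate_mmse(nets, np.full(4, 28.0))
        assert not df[df["connection"] == "A->B"].iloc[0]["defined"]

    def test_too_few_subjects_undefined(self):
        nets = _region_nets([1.0, 2.0, 3.0])
        df = correlate_mmse(nets, np.array([27.0, 28.0, 29.0]))
        assert not df[df["connection"] == "A->B"].iloc[0]["defined"]


class TestDemographics:
    def _manifest(self, age_a, age_b, sex_a=None, sex_b=None):
        na, nb = len(age_a), len(age_b)
        return pd.DataFrame(
            dict(
                subject_id=[f"S{i}" for i in range(na + nb)],
                group=["elderly"] * na + ["young"] * nb,
                age=list(age_a) + list(age_b),
                bmi=[20.0] * (na + nb),
                mmse=[27.0] * na + [29.0] * nb,
                sex=(sex_a or ["M"] * na) + (sex_b or ["M"] * nb),
            )
        )

    def test_pooled_t_statistic_oracle(self):
        # {1,2,3,4} vs {5,6,7,8}: pooled t = -4.38178
        df = demographics_tests(
            self._manifest([1, 2, 3, 4], [5, 6, 7, 8])
        )
        t = df[df["contrast"].str.startswith("age")].iloc[0]["statistic"]
        assert t == pytest.approx(-4.381780, abs=1e-5)

    def test_identical_groups_t_zero(self):
        df = demographics_tests(
            self._manifest([1, 2, 3, 4], [1, 2, 3, 4])
        )
        row = df[df["contrast"].str.startswith("age")].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_balanced_sex_table_chi2_zero(self):
        df = demographics_tests(
            self._manifest(
                [1, 2, 3, 4] * 5, [5, 6, 7, 8] * 5,
                sex_a=["M"] * 10 + ["F"] * 10,
                sex_b=["M"] * 10 + ["F"] * 10,
            )
        )
        row = df[df["test"] == "chi2"].iloc[0]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
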