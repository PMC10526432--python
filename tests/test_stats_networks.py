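"""Two-group ANOVA maps, differential networks, band shares."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from eegdiff.stats_networks import (DiffNetwork, anova_oneway, difference_map,
                                    differential_network,
                                    key_connection_share)

from conftest import GROUP_A, GROUP_B


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        f, p = anova_oneway([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # pooled t = sqrt(27/2), F = t^2 = 13.5
        f, p = anova_oneway([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert f == pytest.approx(13.5)

    def test_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.standard_normal(rng.integers(3, 20))
            b = rng.standard_normal(rng.integers(3, 20)) + rng.normal()
            f, p = anova_oneway(a, b)
            t, pt = sps.ttest_ind(a, b)
            assert f == pytest.approx(t**2, rel=1e-10)
            assert p == pytest.approx(pt, rel=1e-10)

    def test_degenerate_input_flagged(self):
        f, p = anova_oneway([2.0, 2.0], [2.0, 2.0])
        assert np.isnan(f) and np.isnan(p)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([1.0], [2.0, 3.0])


def _iid_table(rng, n_rows=120, n_subjects=12):
    """Exchangeable epoch rows: a valid null for epoch-level testing."""
    cols = {}
    for band in ("theta", "beta"):
        for ch in ("C3", "C4", "P3", "P4"):
            cols[f"PSD_{band}_{ch}"] = rng.standard_normal(n_rows)
    for band in ("theta", "beta"):
        cols[f"PLI_{band}_C3-C4"] = rng.uniform(0, 1, n_rows)
    df = pd.DataFrame(cols)
    subj = np.repeat(np.arange(n_subjects), n_rows // n_subjects)
    df.insert(0, "epoch", np.arange(n_rows))
    df.insert(0, "group", np.where(subj % 2 == 0, GROUP_A, GROUP_B))
    df.insert(0, "subject_id", [f"s{i}" for i in subj])
    return df


class TestDifferenceMap:
    def test_alpha_zero_flags_nothing(self):
        df = _iid_table(np.random.default_rng(0))
        res = difference_map(df, "PSD", alpha=0.0)
        assert not any(r.significant for r in res)

    def test_row_order_invariance(self):
        df = _iid_table(np.random.default_rng(1))
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        r1 = difference_map(df, "PSD")
        r2 = difference_map(shuffled, "PSD")
        for a, b in zip(r1, r2):
            assert a.feature_id == b.feature_id
            assert a.p_value == pytest.approx(b.p_value)

    def test_epoch_level_type_one_error_on_exchangeable_rows(self):
        """With iid rows the epoch-level map rejects at ~alpha."""
        rng = np.random.default_rng(2)
        flags = total = 0
        for _ in range(150):
            res = difference_map(_iid_table(rng), "PSD", unit="epoch")
            flags += sum(r.significant for r in res)
            total += len(res)
        rate = flags / total
        sd = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * sd

    def test_direction_matches_injected_shift(self):
        rng = np.random.default_rng(3)
        df = _iid_table(rng)
        df.loc[df.group == GROUP_B, "PSD_beta_C3"] += 3.0
        res = {r.feature_id: r for r in difference_map(df, "PSD")}
        r = res["PSD_beta_C3"]
        assert r.significant and r.direction == GROUP_B
        assert r.mean_b > r.mean_a

    def test_single_group_rejected(self):
        df = _iid_table(np.random.default_rng(4))
        with pytest.raises(ValueError, match="2 groups"):
            difference_map(df[df.group == GROUP_A], "PSD")

    def test_unknown_family_rejected(self):
        df = _iid_table(np.random.default_rng(5))
        with pytest.raises(ValueError):
            difference_map(df, "PLI")


class TestDifferentialNetwork:
    def test_alpha_zero_gives_empty_networks(self):
        df = _iid_table(np.random.default_rng(0))
        nets = differential_network(df, alpha=0.0)
        assert all(n.n_edges == 0 for n in nets.values())
        assert nets["beta"].ratio == "0/0"

    def test_injected_edge_recovered_with_direction(self):
        rng = np.random.default_rng(1)
        df = _iid_table(rng)
        df.loc[df.group == GROUP_B, "PLI_beta_C3-C4"] += 0.4
        nets = differential_network(df)
        edges = {e[0]: e[1] for e in nets["beta"].edges}
        assert edges.get("C3-C4") == GROUP_B
        assert nets["beta"].count_b_higher >= 1

    def test_fdr_suppresses_spurious_edges(self):
        """With many null pairs, uncorrected testing flags ~5% of them;
        the Benjamini-Hochberg switch keeps spurious edges near zero
        while retaining a strong injected edge."""
        rng = np.random.default_rng(7)
        cols = {f"PLI_beta_C{i}-C{j}": rng.uniform(0, 1, 400)
                for i in range(10) for j in range(i + 1, 10)}
        df = pd.DataFrame(cols)
        subj = np.repeat(np.arange(20), 20)
        df.insert(0, "epoch", np.arange(400))
        df.insert(0, "group", np.where(subj % 2 == 0, GROUP_A, GROUP_B))
        df.insert(0, "subject_id", [f"s{i}" for i in subj])
        df.loc[df.group == GROUP_B, "PLI_beta_C0-C1"] += 0.4
        plain = differential_network(df, unit="subject")["beta"]
        corrected = differential_network(df, unit="subject", fdr=True)["beta"]
        assert {e[0] for e in corrected.edges} >= {"C0-C1"}
        spurious = [e for e in corrected.edges if e[0] != "C0-C1"]
        assert len(spurious) <= 2
        assert len(corrected.edges) <= len(plain.edges)

    def test_counts_sum_to_edges(self):
        rng = np.random.default_rng(2)
        df = _iid_table(rng)
        df.loc[df.group == GROUP_B, "PLI_beta_C3-C4"] += 0.4
        df.loc[df.group == GROUP_A, "PLI_theta_C3-C4"] += 0.4
        nets = differential_network(df)
        for n in nets.values():
            assert n.count_a_higher + n.count_b_higher == n.n_edges


class TestKeyConnectionShare:
    def _nets(self, counts):
        return {band: DiffNetwork(band=band,
                                  edges=tuple(("C3-C4", GROUP_B, 0.01)
                                              for _ in range(c)),
                                  count_b_higher=c, count_a_higher=0)
                for band, c in counts.items()}

    def test_equal_counts_give_quarter_shares(self):
        shares = key_connection_share(
            self._nets({"theta": 1, "alpha1": 1, "alpha2": 1, "beta": 1}))
        assert all(v == pytest.approx(0.25) for v in shares.values())

    def test_dominant_beta_share(self):
        # 31 of 72 edges in beta -> 43.1%
        shares = key_connection_share(
            self._nets({"theta": 14, "alpha1": 15, "alpha2": 12, "beta": 31}))
        assert shares["beta"] == pytest.approx(31 / 72)
        assert round(100 * shares["beta"], 1) == 43.1
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_zero_edges_rejected(self):
        with pytest.raises(ValueError, match="no significant edges"):
            key_connection_share(self._nets({"beta": 0}))
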