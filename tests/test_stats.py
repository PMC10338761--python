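"""Group ANOVA: closed-form example, t-test equivalence, tiers, plotting."""
import numpy as np
import pytest
from scipy import stats as sps

import fcreeg as fc
from fcreeg.stats import (assign_tier, compare_groups, pairwise_anova,
                          plot_connectogram, significant_pairs)
from fcreeg.synth import DEFAULT_EFFECT_PAIRS


def test_anova_closed_form_example():
    """{1,2,3,4} vs {3,4,5,6}: SSB=8, SSW=10, df=(1,6) -> F=4.8."""
    f, p = pairwise_anova([1, 2, 3, 4], [3, 4, 5, 6])
    assert f == pytest.approx(4.8, abs=1e-9)
    assert p == pytest.approx(sps.f.sf(4.8, 1, 6), abs=1e-12)
    assert p == pytest.approx(0.071, abs=1e-3)


def test_identical_groups_give_f_zero():
    f, p = pairwise_anova([1, 2, 3], [1, 2, 3])
    assert f == 0.0
    assert p == 1.0


def test_degenerate_variance_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        pairwise_anova([2.0, 2.0, 2.0], [2.0, 2.0])
    with pytest.raises(ValueError):
        pairwise_anova([1.0], [2.0, 3.0])


def test_two_group_anova_equals_squared_t(rng):
    for _ in range(20):
        a = rng.standard_normal(rng.integers(5, 40))
        b = 0.3 + rng.standard_normal(rng.integers(5, 40))
        f, p_f = pairwise_anova(a, b)
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t ** 2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)


def test_tier_assignment_partition():
    assert assign_tier(0.5) == "ns"
    assert assign_tier(0.049) == "tier1"
    assert assign_tier(0.001) == "tier1"   # boundary: 0.001 <= p < 0.05
    assert assign_tier(0.0009) == "tier2"


def test_compare_groups_yields_120_sorted_pairs(beta_matrices):
    records = compare_groups(beta_matrices, band="beta")
    assert len(records) == 120  # C(16,2)
    keys = [(fc.channel_index(r.ch_i), fc.channel_index(r.ch_j))
            for r in records]
    assert keys == sorted(keys)
    assert all(k[0] < k[1] for k in keys)
    for r in records:
        assert 0.0 <= r.p <= 1.0
        assert r.tier == assign_tier(r.p)
        expect_dir = "SZ_higher" if r.mean_sz > r.mean_hc else "HC_higher"
        assert r.direction == expect_dir


def test_pair_statistics_match_direct_anova(beta_matrices):
    """Each record reproduces f_oneway on the raw epoch-level values,
    identically for (i,j) and (j,i) orderings."""
    records = compare_groups(beta_matrices, band="beta")
    rec = next(r for r in records if (r.ch_i, r.ch_j) == ("O1", "P3"))
    i, j = fc.channel_index("O1"), fc.channel_index("P3")
    for a, b in ((i, j), (j, i)):
        vs = [m.values[a, b] for m in beta_matrices if m.group == "SZ"]
        vh = [m.values[a, b] for m in beta_matrices if m.group == "HC"]
        f, p = sps.f_oneway(vs, vh)
        assert rec.F == pytest.approx(f, rel=1e-12)
        assert rec.p == pytest.approx(p, rel=1e-12)
        assert rec.mean_sz == pytest.approx(np.mean(vs), rel=1e-12)


def test_tier_sets_partition_p_below_005(beta_matrices):
    records = compare_groups(beta_matrices, band="beta")
    t1 = {(r.ch_i, r.ch_j) for r in records if r.tier == "tier1"}
    t2 = {(r.ch_i, r.ch_j) for r in records if r.tier == "tier2"}
    below = {(r.ch_i, r.ch_j) for r in records if r.p < 0.05}
    assert not t1 & t2
    assert t1 | t2 == below
    assert significant_pairs(records, "tier2") == \
        [r for r in records if r.tier == "tier2"]
    assert len(significant_pairs(records, "tier1")) == len(below)


def test_per_subject_aggregation_is_more_conservative(beta_matrices):
    epoch_level = compare_groups(beta_matrices, band="beta")
    subj_level = compare_groups(beta_matrices, band="beta", per_subject=True)
    assert len(subj_level) == 120
    # averaging within subject shrinks n, so significance can only drop
    n_sig_epoch = sum(r.p < 0.05 for r in epoch_level)
    n_sig_subj = sum(r.p < 0.05 for r in subj_level)
    assert n_sig_subj <= n_sig_epoch


def test_bonferroni_only_raises_p(beta_matrices):
    raw = compare_groups(beta_matrices, band="beta")
    adj = compare_groups(beta_matrices, band="beta", correction="bonferroni")
    for r_raw, r_adj in zip(raw, adj):
        assert r_adj.p >= r_raw.p - 1e-15


def test_compare_groups_requires_both_groups(beta_matrices):
    sz_only = [m for m in beta_matrices if m.group == "SZ"]
    with pytest.raises(ValueError, match="HC"):
        compare_groups(sz_only, band="beta")


def test_connectogram_deterministic_and_validates(tmp_path, beta_matrices):
    records = compare_groups(beta_matrices, band="beta")
    p1 = plot_connectogram(records, "tier2", tmp_path / "a.png")
    p2 = plot_connectogram(records, "tier2", tmp_path / "b.png")
    assert p1.read_bytes() == p2.read_bytes()
    bad = [fc.PairStats(ch_i="XX", ch_j="F3", band="beta", mean_sz=0.1,
                        sd_sz=0.1, mean_hc=0.1, sd_hc=0.1, F=1.0, p=0.5,
                        tier="ns", direction="SZ_higher")]
    with pytest.raises(ValueError, match="XX"):
        plot_connectogram(bad, "tier2", tmp_path / "c.png")
    with pytest.raises(ValueError):
        plot_connectogram([], "tier2", tmp_path / "d.png")


def test_connectogram_with_no_significant_edges(tmp_path):
    records = [fc.PairStats(ch_i="F3", ch_j="F4", band="beta", mean_sz=0.1,
                            sd_sz=0.1, mean_hc=0.1, sd_hc=0.1, F=0.1, p=0.9,
                            tier="ns", direction="SZ_higher")]
    assert significant_pairs(records, "tier2") == []
    path = plot_connectogram(records, "tier2", tmp_path / "empty.png")
    assert path.exists() and path.stat().st_size > 0
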