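"""ROI aggregation, exact Wilcoxon signed-rank, Benjamini-Hochberg."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from numerotune.roistats import (
    SubjectStats,
    bh_fdr,
    low_vs_high,
    positivity_tests,
    roi_table,
    signed_rank_sf,
    wilcoxon_one_sided,
)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def enumerate_p(values):
    """Literal 2^n enumeration oracle for the one-sided signed-rank test."""
    x = np.asarray(values, dtype=float)
    x = x[x != 0]
    n = len(x)
    absx = np.abs(x)
    order = np.argsort(absx, kind="mergesort")
    ranks = np.empty(n)
    sorted_abs = absx[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[x > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2**n


class TestWilcoxon:
    def test_seven_positive_values(self):
        res = wilcoxon_one_sided([0.5, 1.2, 0.1, 2.0, 0.7, 0.3, 1.1])
        assert res.p_value == pytest.approx(1 / 128)
        assert res.statistic == 28

    def test_single_value(self):
        assert wilcoxon_one_sided([3.0]).p_value == pytest.approx(0.5)
        assert wilcoxon_one_sided([-3.0]).p_value == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_one_sided([0.0, 0.0])
        with pytest.raises(ValueError):
            wilcoxon_one_sided([])

    def test_zeros_dropped_and_counted(self):
        res = wilcoxon_one_sided([0.0, 1.0, -2.0, 0.0, 3.0])
        assert res.n_zero == 2 and res.n_used == 3

    @pytest.mark.parametrize("n", range(1, 11))
    def test_exact_null_equals_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        # include ties in |value| to exercise midranks
        vals = rng.choice([-2.5, -1.0, 0.5, 1.0, 1.5, 2.5], size=n)
        if np.all(vals == 0):
            vals[0] = 1.0
        res = wilcoxon_one_sided(vals)
        assert res.p_value == pytest.approx(enumerate_p(vals), abs=1e-12)

    def test_null_cdf_matches_enumeration_everywhere(self):
        """P(W >= w) agrees with enumeration at every achievable w, n <= 10."""
        for n in range(1, 11):
            ranks = np.arange(1, n + 1).astype(float)
            all_w = sorted(
                {
                    sum(r for s, r in zip(signs, ranks) if s)
                    for signs in itertools.product([0, 1], repeat=n)
                }
            )
            for w in all_w:
                brute = (
                    sum(
                        1
                        for signs in itertools.product([0, 1], repeat=n)
                        if sum(r for s, r in zip(signs, ranks) if s) >= w
                    )
                    / 2**n
                )
                assert signed_rank_sf(ranks, w) == pytest.approx(brute, abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = rng.standard_normal(12)
            ours = wilcoxon_one_sided(vals).p_value
            ref = scipy_wilcoxon(vals, alternative="greater", method="exact").pvalue
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_normal_approximation_agrees_with_exact(self):
        rng = np.random.default_rng(5)
        vals = rng.standard_normal(24) + 0.4
        exact = wilcoxon_one_sided(vals, exact_max_n=25).p_value
        approx = wilcoxon_one_sided(vals, exact_max_n=10).p_value
        assert approx == pytest.approx(exact, rel=0.2)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_p_in_unit_interval(self, vals):
        if not any(v != 0 for v in vals):
            return
        p = wilcoxon_one_sided(vals).p_value
        assert 0 < p <= 1


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_bruteforce(p):
    """Loop-based step-up rule: adj_i = min_{j: rank_j >= rank_i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    for pos_i, i in enumerate(order):
        best = np.inf
        for pos_j in range(pos_i, m):
            j = order[pos_j]
            best = min(best, m * p[j] / (pos_j + 1))
        adj[i] = min(best, 1.0)
    return adj


class TestBH:
    def test_hand_example(self):
        adj, rej = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        assert rej.all()

    def test_single_p_identity(self):
        adj, _ = bh_fdr([0.123])
        assert adj[0] == pytest.approx(0.123)

    def test_against_bruteforce_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(1e-6, 1.0, size=m)
            np.testing.assert_allclose(bh_fdr(p)[0], bh_bruteforce(p), atol=1e-12)

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(2, 30)))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(bh_fdr(p)[0], ref, atol=1e-12)

    def test_order_equivariance(self, rng):
        p = rng.uniform(0.001, 1.0, size=9)
        perm = rng.permutation(9)
        adj = bh_fdr(p)[0]
        adj_perm = bh_fdr(p[perm])[0]
        np.testing.assert_allclose(adj_perm, adj[perm])

    def test_empty_and_invalid(self):
        adj, rej = bh_fdr([])
        assert adj.size == 0 and rej.size == 0
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_adjusted_at_least_raw(self, p):
        adj, _ = bh_fdr(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all(adj <= 1.0)


# ---------------------------------------------------------------------------
# ROI table and the two analysis families
# ---------------------------------------------------------------------------


def make_subject(sid, rng, nf=True, lo_minus_hi=1.0):
    rois = ["NPC1"] * 4 + ["V1"] * 4 + (["NF"] * 4 if nf else [])
    rois = np.array(rois)
    cats = ["nat_low", "nat_high", "nat_scenery", "dots_low", "dots_20", "dots_high"]
    base = rng.normal(1.0, 0.05, size=(len(rois), len(cats)))
    psc = pd.DataFrame(base, columns=cats)
    psc.loc[rois == "NPC1", "nat_low"] += lo_minus_hi
    tuned = np.concatenate(
        [np.flatnonzero(rois == "NPC1")[:3], np.flatnonzero(rois == "NF")[:3]]
    )
    return SubjectStats(
        subject_id=sid,
        psc=psc,
        rois=rois,
        tuned_indices=tuned.astype(int),
        scenery_mask=np.ones(len(rois), dtype=bool),
    )


class TestRoiTable:
    def test_shape_and_nf_rows(self, rng):
        subs = [make_subject(f"s{i}", rng, nf=i < 4) for i in range(7)]
        table = roi_table(subs)
        nf_rows = table[table["roi"] == "NF"]
        assert nf_rows["subject"].nunique() == 4
        one = table[table["subject"] == "s0"]
        assert len(one) == 3 * 6  # three ROIs x six categories

    def test_selection_applies_to_maps_only(self, rng):
        sub = make_subject("s0", rng)
        sub.scenery_mask[:] = True
        table = roi_table([sub])
        npc = table[(table["roi"] == "NPC1")]
        assert (npc["n_voxels"] == 3).all()  # tuned selection, not all 4
        v1 = table[(table["roi"] == "V1")]
        assert (v1["n_voxels"] == 4).all()  # controls keep every voxel

    def test_empty_voxel_set_yields_missing_mean(self, rng):
        sub = make_subject("s0", rng)
        sub.tuned_indices = np.array([], dtype=int)
        table = roi_table([sub])
        npc = table[table["roi"] == "NPC1"]
        assert (npc["n_voxels"] == 0).all()
        assert npc["mean_psc"].isna().all()

    def test_mask_toggle(self, rng):
        sub = make_subject("s0", rng)
        sub.scenery_mask = np.zeros(len(sub.rois), dtype=bool)
        masked = roi_table([sub], apply_scenery_mask=True)
        unmasked = roi_table([sub], apply_scenery_mask=False)
        assert (masked[masked["roi"] == "NPC1"]["n_voxels"] == 0).all()
        assert (unmasked[unmasked["roi"] == "NPC1"]["n_voxels"] == 3).all()
        # control ROI untouched by the mask
        assert (masked[masked["roi"] == "V1"]["n_voxels"] == 4).all()


class TestAnalyses:
    def test_positivity_direction(self, rng):
        subs = [make_subject(f"s{i}", rng) for i in range(7)]
        # make V1 dots responses negative for every subject
        for s in subs:
            s.psc.loc[s.rois == "V1", "dots_20"] = -1.0 + rng.normal(0, 0.01)
        table = roi_table(subs)
        res = positivity_tests(table, rois=("V1",))
        neg = res[(res["category"] == "dots_20")]
        pos = res[(res["category"] == "nat_low")]
        assert float(neg["p_value"].iloc[0]) > 0.5
        assert bool(pos["significant"].iloc[0])

    def test_low_power_flag(self, rng):
        subs = [make_subject(f"s{i}", rng, nf=i < 2) for i in range(7)]
        res = positivity_tests(roi_table(subs), rois=("NF",))
        assert res["low_power"].all()

    def test_low_vs_high_positive_direction(self, rng):
        subs = [make_subject(f"s{i}", rng, lo_minus_hi=1.0) for i in range(7)]
        res = low_vs_high(roi_table(subs), maps=("NPC1",))
        assert res["p_adjusted"].iloc[0] == pytest.approx(1 / 128)
        assert bool(res["significant"].iloc[0])

    def test_low_vs_high_excludes_nf_by_default(self, rng):
        subs = [make_subject(f"s{i}", rng) for i in range(7)]
        res = low_vs_high(roi_table(subs))
        assert "NF" not in set(res["roi"])

    def test_missing_category_raises(self, rng):
        table = roi_table([make_subject("s0", rng)])
        with pytest.raises(ValueError, match="nat_high"):
            low_vs_high(table[table["category"] != "nat_high"])

    def test_plot_renders_to_file(self, rng, tmp_path):
        from numerotune.roistats import plot_category_responses

        subs = [make_subject(f"s{i}", rng) for i in range(3)]
        out = tmp_path / "fig.png"
        plot_category_responses(roi_table(subs), rois=("NPC1", "V1"), path=out)
        assert out.stat().st_size > 0

    def test_identical_low_high_untestable(self, rng):
        subs = [make_subject(f"s{i}", rng, lo_minus_hi=0.0) for i in range(3)]
        for s in subs:
            s.psc["nat_high"] = s.psc["nat_low"]
        with pytest.raises(ValueError):
            low_vs_high(roi_table(subs), maps=("NPC1",))
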