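import statistics
from itertools import product
from math import comb

import numpy as np
import pytest
import scipy.stats as sps

from segrater.metrics import ChangeRecord, MetricRecord, Outcome
from segrater.model import Group
from segrater.stats import (
    ContingencyTable2x2,
    PairedSample,
    fisher_exact_2x2,
    mcnemar_exact,
    summarize_study,
    wilcoxon_signed_rank,
)


def brute_force_wilcoxon(pre, post):
    """Independent oracle: literal enumeration of all 2^n sign assignments."""
    d = np.asarray(post, float) - np.asarray(pre, float)
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(nz))
    w_obs = ranks[nz > 0].sum()
    ws = np.array([
        sum(r for r, bit in zip(ranks, bits) if bit)
        for bits in product([0, 1], repeat=n)
    ])
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _sample(pre, post):
    keys = tuple((f"a{i}", "img") for i in range(len(pre)))
    return PairedSample(keys=keys, pre=tuple(pre), post=tuple(post))


class TestWilcoxon:
    def test_all_positive_six(self):
        # W+ is maximal; only the all-plus and all-minus assignments are as
        # extreme, so two-sided p = 2/64
        res = wilcoxon_signed_rank(_sample([0] * 6, [1, 2, 3, 4, 5, 6]))
        assert res.p_value == pytest.approx(2 / 64)
        assert res.n_effective == 6

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank(_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.p_value == 1.0
        assert res.n_effective == 0
        assert "degenerate" in res.method_notes

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(_sample([], []))

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        pre = rng.normal(size=n)
        post = pre + rng.choice([-1, 0, 1], size=n) * rng.integers(1, 4, size=n)
        res = wilcoxon_signed_rank(_sample(pre, post), mode="exact")
        assert res.p_value == pytest.approx(brute_force_wilcoxon(pre, post), abs=1e-12)

    def test_exact_handles_midranks(self):
        # tied absolute differences -> half-integer ranks
        pre = [0, 0, 0, 0]
        post = [1, 1, -1, 2]
        res = wilcoxon_signed_rank(_sample(pre, post), mode="exact")
        assert res.p_value == pytest.approx(brute_force_wilcoxon(pre, post), abs=1e-12)

    def test_approximate_close_to_scipy(self):
        rng = np.random.default_rng(7)
        pre = rng.normal(size=60)
        post = pre + rng.normal(0.4, 1.0, size=60)
        res = wilcoxon_signed_rank(_sample(pre, post), mode="approximate")
        ref = sps.wilcoxon(post - pre, correction=False, mode="approx").pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-6)
        assert "approximation" in res.method_notes

    def test_auto_switches_at_threshold(self):
        rng = np.random.default_rng(1)
        small = wilcoxon_signed_rank(_sample(np.zeros(20), rng.normal(size=20)))
        large = wilcoxon_signed_rank(_sample(np.zeros(40), rng.normal(size=40)))
        assert "exact" in small.method_notes
        assert "approximation" in large.method_notes


class TestFisher:
    @pytest.mark.parametrize("table,printed", [
        ((136, 8, 144, 0), 0.007),
        ((31, 5, 36, 0), 0.054),
        ((34, 2, 36, 0), 0.493),
        ((35, 1, 36, 0), 1.0),
    ])
    def test_published_contingency_counts(self, table, printed):
        res = fisher_exact_2x2(ContingencyTable2x2(*table))
        assert round(res.p_value, 3) == printed

    def test_symmetric_table(self):
        assert fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1)).p_value == 1.0

    @pytest.mark.parametrize("k", [1, 2, 5, 8])
    def test_all_success_row_closed_form(self, k):
        # one all-success row, equal margins m: p = 2*C(m,k)/C(2m,k)
        m = 36
        res = fisher_exact_2x2(ContingencyTable2x2(m - k, k, m, 0))
        assert res.p_value == pytest.approx(min(1.0, 2 * comb(m, k) / comb(2 * m, k)))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_two_sided(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = rng.integers(0, 30, 4)
        if a + b + c + d == 0:
            a = 1
        res = fisher_exact_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
        ref = sps.fisher_exact([[a, b], [c, d]]).pvalue
        assert res.p_value == pytest.approx(ref, rel=1e-7, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_row_and_column_swap_invariance(self, seed):
        rng = np.random.default_rng(seed + 100)
        a, b, c, d = (int(x) for x in rng.integers(0, 25, 4) + 1)
        p1 = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d)).p_value
        p2 = fisher_exact_2x2(ContingencyTable2x2(d, c, b, a)).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestMcNemar:
    def test_five_zero(self):
        assert mcnemar_exact(5, 0).p_value == pytest.approx(2 / 32)

    def test_no_discordant(self):
        res = mcnemar_exact(0, 0)
        assert res.p_value == 1.0
        assert "degenerate" in res.method_notes

    def test_one_one_clamped(self):
        # 2*P(X<=1 | n=2) = 1.5 -> clamped to 1.0
        assert mcnemar_exact(1, 1).p_value == 1.0

    @pytest.mark.parametrize("b,c", [(b, c) for b in range(7) for c in range(7)])
    def test_binomial_closed_form(self, b, c):
        n = b + c
        if n == 0:
            return
        k = min(b, c)
        expected = min(1.0, 2 * sum(comb(n, i) for i in range(k + 1)) / 2**n)
        assert mcnemar_exact(b, c).p_value == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# summarize_study against a hand-built oracle
# ---------------------------------------------------------------------------

def _fpfn(d):
    # fractions consistent with the dice identity: fp = fn = (1-d)/(2-d)
    return (1 - d) / (2 - d)


def _record(aid, iid, rnd, d, hit=True):
    return MetricRecord(annotator_id=aid, image_id=iid, round=rnd, dice=d,
                        fp_frac=_fpfn(d), fn_frac=_fpfn(d), centroid_hit=hit)


def _hand_built():
    groups = {"s1": Group.STUDENT, "s2": Group.STUDENT,
              "e1": Group.EXPERT, "e2": Group.EXPERT}
    student_pre = {("s1", "i1"): 0.6, ("s1", "i2"): 0.7,
                   ("s2", "i1"): 0.5, ("s2", "i2"): 0.8}
    expert = {("e1", "i1"): 0.8, ("e1", "i2"): 0.8,
              ("e2", "i1"): 0.9, ("e2", "i2"): 0.9}
    records, changes = [], []
    for (aid, iid), d in student_pre.items():
        hit_pre = not (aid, iid) == ("s2", "i1")
        records.append(_record(aid, iid, "PRE", d, hit=hit_pre))
        records.append(_record(aid, iid, "POST", d + 0.1))
        changes.append(ChangeRecord(aid, iid, True, Outcome.IMPROVED))
    for (aid, iid), d in expert.items():
        records.append(_record(aid, iid, "PRE", d))
        records.append(_record(aid, iid, "POST", d))
        changes.append(ChangeRecord(aid, iid, False, Outcome.UNCHANGED))
    return records, changes, groups


class TestSummarizeStudy:
    def test_hand_built_means_and_tests(self):
        records, changes, groups = _hand_built()
        s = summarize_study(records, changes, groups)
        assert list(s.table2["stratum"]) == ["OVERALL", "STUDENT", "EXPERT"]

        t2 = s.table2.set_index("stratum")
        # hand arithmetic, sample SD (n-1)
        assert t2.loc["STUDENT", "pre_mean_pct"] == pytest.approx(
            statistics.mean([60, 70, 50, 80]))
        assert t2.loc["STUDENT", "pre_sd_pct"] == pytest.approx(
            statistics.stdev([60, 70, 50, 80]))
        assert t2.loc["STUDENT", "post_mean_pct"] == pytest.approx(75.0)
        assert t2.loc["STUDENT", "difference_pct"] == pytest.approx(10.0)
        # four tied positive diffs: two-sided exact p = 2/16
        assert t2.loc["STUDENT", "p_value"] == pytest.approx(0.125)
        assert t2.loc["EXPERT", "difference_pct"] == 0.0
        assert t2.loc["EXPERT", "p_value"] == 1.0
        assert t2.loc["OVERALL", "pre_mean_pct"] == pytest.approx(75.0)
        assert t2.loc["OVERALL", "post_mean_pct"] == pytest.approx(80.0)

        t1 = s.table1.set_index("stratum")
        assert t1.loc["STUDENT", "hits_pre"] == 3
        assert t1.loc["STUDENT", "hits_post"] == 4
        # [[3,1],[4,0]]: both tables with these margins have probability 1/2
        assert t1.loc["STUDENT", "p_value"] == pytest.approx(1.0)

        t3 = s.table3.set_index("stratum")
        exp_fp = statistics.mean(100 * _fpfn(d) for d in [0.6, 0.7, 0.5, 0.8])
        assert t3.loc["STUDENT", "fp_pre_mean_pct"] == pytest.approx(exp_fp)
        assert t3.loc["STUDENT", "fn_pre_mean_pct"] == pytest.approx(exp_fp)

        cs = s.change_summary.set_index("stratum")
        assert cs.loc["STUDENT", "n_changed"] == 4
        assert cs.loc["STUDENT", "improved"] == 4
        assert cs.loc["EXPERT", "n_changed"] == 0
        assert cs.loc["EXPERT", "unchanged"] == 4

        pc = s.participant_centroid.set_index("stratum")
        assert pc.loc["STUDENT", "all_hit_pre"] == 1
        assert pc.loc["STUDENT", "all_hit_post"] == 2
        assert pc.loc["STUDENT", "discordant_post_only"] == 1
        assert pc.loc["STUDENT", "p_value"] == 1.0  # 2*P(X<=0|n=1) = 1.0

    def test_identical_pre_post_all_zero(self):
        records, changes, groups = _hand_built()
        # overwrite: post == pre everywhere, nothing changed
        records = [r for r in records if r.round == "PRE"]
        records += [MetricRecord(r.annotator_id, r.image_id, "POST", r.dice,
                                 r.fp_frac, r.fn_frac, r.centroid_hit)
                    for r in records]
        changes = [ChangeRecord(c.annotator_id, c.image_id, False, Outcome.UNCHANGED)
                   for c in changes]
        s = summarize_study(records, changes, groups)
        assert (s.table2["difference_pct"] == 0).all()
        assert (s.change_summary["n_changed"] == 0).all()
        assert (s.table2["p_value"] == 1.0).all()

    def test_incomplete_pairs_excluded(self):
        records, changes, groups = _hand_built()
        records = [r for r in records
                   if not (r.annotator_id == "e2" and r.image_id == "i2"
                           and r.round == "POST")]
        s = summarize_study(records, changes, groups)
        assert s.n_excluded_pairs == 1
        assert s.table2.set_index("stratum").loc["EXPERT", "n"] == 3

    def test_empty_group_rejected(self):
        records, changes, groups = _hand_built()
        groups["ghost"] = Group.JUNIOR
        records = [r for r in records if groups[r.annotator_id] is not Group.JUNIOR]
        with pytest.raises(ValueError, match="JUNIOR"):
            summarize_study(records, changes, groups)
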