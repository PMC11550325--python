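"""Paired and contingency statistics, and the study summary tables.

Exact tests throughout: Wilcoxon signed-rank by full enumeration of the
signed-rank-sum distribution for small samples, Fisher's exact test by
minimum-likelihood summation of the hypergeometric, and McNemar's test by
the exact binomial on the discordant pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import ChangeRecord, MetricRecord, Outcome
from .model import GROUP_ORDER, Group, Round

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "PairedSample",
    "TestResult",
    "StudySummary",
    "wilcoxon_signed_rank",
    "fisher_exact_2x2",
    "mcnemar_exact",
    "summarize_study",
    "EXACT_WILCOXON_MAX_N",
]

#: largest n for which the Wilcoxon null distribution is fully enumerated
EXACT_WILCOXON_MAX_N = 25

#: relative tolerance when comparing hypergeometric likelihoods (Fisher)
_FISHER_RELTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are conditions, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class PairedSample:
    keys: tuple[tuple[str, str], ...]
    pre: tuple[float, ...]
    post: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.keys) == len(self.pre) == len(self.post)):
            raise ValueError("keys/pre/post must have equal length")
        if len(set(self.keys)) != len(self.keys):
            raise ValueError("pairing keys must be unique")


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_effective: int
    method_notes: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """PMF of W+ over doubled (integer) ranks under the sign-flip null.

    Index i holds P(2·W+ = i). Polynomial product of (1 + x^{2r}) / 2.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    return counts / counts.sum()


def wilcoxon_signed_rank(sample: PairedSample, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on post - pre differences.

    Zero differences are dropped before ranking (classic Wilcoxon); tied
    absolute differences receive mid-ranks. For n_effective <=
    ``EXACT_WILCOXON_MAX_N`` (or mode="exact") the p value is computed by
    exact enumeration of the 2^n sign assignments (via the rank-sum
    distribution, which handles mid-ranks correctly); otherwise a normal
    approximation with tie correction is used. All differences zero gives
    p = 1.0 with a degenerate flag.
    """
    if mode not in ("exact", "approximate", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(sample.keys) == 0:
        raise ValueError("empty paired sample")
    d = np.asarray(sample.post, dtype=float) - np.asarray(sample.pre, dtype=float)
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return TestResult(
            "wilcoxon_signed_rank", statistic=0.0, p_value=1.0, n_effective=0,
            method_notes="degenerate: all differences zero",
        )
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    use_exact = mode == "exact" or (mode == "auto" and n <= EXACT_WILCOXON_MAX_N)
    if use_exact:
        doubled = np.rint(2 * ranks).astype(np.int64)
        pmf = _signed_rank_distribution(doubled)
        w2 = int(round(2 * w_plus))
        p_le = float(pmf[: w2 + 1].sum())
        p_ge = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        notes = "exact sign-assignment enumeration"
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(np.abs(nz), return_counts=True)
        tie_term = float(((tie_counts**3 - tie_counts).sum())) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        notes = "normal approximation with tie correction"
    return TestResult(
        "wilcoxon_signed_rank", statistic=w_plus, p_value=p, n_effective=n,
        method_notes=notes,
    )


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher's exact test (minimum-likelihood summation).

    Sums the hypergeometric probability of every table with the observed
    margins whose likelihood is <= the observed table's (within relative
    tolerance), the standard two-sided definition.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    row1 = a + b
    col1 = a + c
    rv = sps.hypergeom(n, col1, row1)
    kmin = max(0, row1 - (n - col1))
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(min(1.0, pmf[pmf <= p_obs * (1.0 + _FISHER_RELTOL)].sum()))
    if p > 1.0 - 1e-12:  # full-support sums accumulate float dust
        p = 1.0
    odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
    return TestResult(
        "fisher_exact", statistic=float(odds), p_value=p,
        n_effective=n, method_notes="two-sided, minimum-likelihood",
    )


def mcnemar_exact(discordant_b: int, discordant_c: int) -> TestResult:
    """Exact two-sided McNemar test on discordant-pair counts.

    p = min(1, 2·P(X <= min(b, c))) for X ~ Binomial(b + c, 1/2);
    b + c = 0 gives p = 1.0 with a degenerate flag.
    """
    if discordant_b < 0 or discordant_c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = discordant_b + discordant_c
    if n == 0:
        return TestResult(
            "mcnemar_exact", statistic=0.0, p_value=1.0, n_effective=0,
            method_notes="degenerate: no discordant pairs",
        )
    k = min(discordant_b, discordant_c)
    p = float(min(1.0, 2.0 * sps.binom.cdf(k, n, 0.5)))
    return TestResult(
        "mcnemar_exact", statistic=float(k), p_value=p, n_effective=n,
        method_notes="exact binomial",
    )


# ---------------------------------------------------------------------------
# study summary tables
# ---------------------------------------------------------------------------

OVERALL = "OVERALL"


@dataclass
class StudySummary:
    """Tables of the comparative study.

    table1: per-stratum centroid-hit counts pre/post with Fisher p.
    table2: per-stratum mean/SD DICE (percent) pre/post with Wilcoxon p.
    table3: per-stratum mean/SD FP and FN percentages pre/post and changes.
    change_summary: changed / improved / worsened / unchanged counts.
    participant_centroid: per-participant all-images centroid-hit McNemar.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    change_summary: pd.DataFrame
    participant_centroid: pd.DataFrame
    n_excluded_pairs: int = 0


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else float("nan")
    return mean, sd


def _pair_records(
    records: Sequence[MetricRecord],
) -> tuple[list[tuple[MetricRecord, MetricRecord]], int]:
    by_key: dict[tuple[str, str, str], MetricRecord] = {}
    for rec in records:
        rnd = rec.round.value if isinstance(rec.round, Round) else str(rec.round)
        by_key[(rec.annotator_id, rec.image_id, rnd)] = rec
    pair_keys = {(aid, iid) for (aid, iid, _r) in by_key}
    pairs = []
    excluded = 0
    for aid, iid in sorted(pair_keys):
        pre = by_key.get((aid, iid, Round.PRE.value))
        post = by_key.get((aid, iid, Round.POST.value))
        if pre is None or post is None:
            excluded += 1
            continue
        pairs.append((pre, post))
    if excluded:
        logger.warning("excluded %d incomplete participant-image pairs", excluded)
    return pairs, excluded


def summarize_study(
    records: Sequence[MetricRecord],
    changes: Sequence[ChangeRecord],
    groups: Mapping[str, Group],
) -> StudySummary:
    """Aggregate per-annotation metrics into the study tables.

    Means and SDs (sample, n-1 denominator) are computed over all
    participant-image records in the stratum; percentages are 100x the
    per-record fractions. Differences are computed from unrounded means.
    """
    pairs, excluded = _pair_records(records)
    if not pairs:
        raise ValueError("no complete participant-image pairs")
    change_map = {(ch.annotator_id, ch.image_id): ch for ch in changes}

    strata: list[tuple[str, list[tuple[MetricRecord, MetricRecord]]]] = [
        (OVERALL, pairs)
    ]
    present_groups = [g for g in GROUP_ORDER if g in set(groups.values())]
    for g in present_groups:
        members = [p for p in pairs if groups[p[0].annotator_id] is g]
        if not members:
            raise ValueError(f"group {g.value} has no complete records")
        strata.append((g.value, members))

    t1, t2, t3, cs, pc = [], [], [], [], []
    for name, members in strata:
        pre = [p for p, _q in members]
        post = [q for _p, q in members]
        n = len(members)

        # --- centroid inclusion (per annotation, Fisher) ---
        hits_pre = sum(r.centroid_hit for r in pre)
        hits_post = sum(r.centroid_hit for r in post)
        fisher = fisher_exact_2x2(
            ContingencyTable2x2(hits_pre, n - hits_pre, hits_post, n - hits_post)
        )
        t1.append({
            "stratum": name,
            "n": n,
            "hits_pre": hits_pre,
            "pct_pre": 100.0 * hits_pre / n,
            "hits_post": hits_post,
            "pct_post": 100.0 * hits_post / n,
            "difference_pct": 100.0 * (hits_post - hits_pre) / n,
            "p_value": fisher.p_value,
        })

        # --- DICE (percent, Wilcoxon paired per participant-image) ---
        dice_pre = np.array([r.dice for r in pre])
        dice_post = np.array([r.dice for r in post])
        mp, sp = _mean_sd(100.0 * dice_pre)
        mq, sq = _mean_sd(100.0 * dice_post)
        wil = wilcoxon_signed_rank(
            PairedSample(
                keys=tuple((r.annotator_id, r.image_id) for r in pre),
                pre=tuple(dice_pre),
                post=tuple(dice_post),
            )
        )
        t2.append({
            "stratum": name,
            "n": n,
            "pre_mean_pct": mp,
            "pre_sd_pct": sp,
            "post_mean_pct": mq,
            "post_sd_pct": sq,
            "difference_pct": mq - mp,
            "p_value": wil.p_value,
            "wilcoxon_n_effective": wil.n_effective,
        })

        # --- FP/FN error fractions (percent of union) ---
        row: dict[str, object] = {"stratum": name, "n": n}
        for label, attr in (("fp", "fp_frac"), ("fn", "fn_frac")):
            vpre = 100.0 * np.array([getattr(r, attr) for r in pre])
            vpost = 100.0 * np.array([getattr(r, attr) for r in post])
            m0, s0 = _mean_sd(vpre)
            m1, s1 = _mean_sd(vpost)
            dm, ds = _mean_sd(vpost - vpre)
            row.update({
                f"{label}_pre_mean_pct": m0, f"{label}_pre_sd_pct": s0,
                f"{label}_post_mean_pct": m1, f"{label}_post_sd_pct": s1,
                f"{label}_change_pct": dm, f"{label}_change_sd_pct": ds,
            })
        t3.append(row)

        # --- change classification ---
        member_changes = [
            change_map[(p.annotator_id, p.image_id)]
            for p, _q in members
            if (p.annotator_id, p.image_id) in change_map
        ]
        nc = len(member_changes)
        n_changed = sum(ch.annotation_changed for ch in member_changes)
        outcome_counts = {
            o: sum(ch.dice_outcome is o for ch in member_changes) for o in Outcome
        }
        cs.append({
            "stratum": name,
            "n": nc,
            "n_changed": n_changed,
            "changed_pct": 100.0 * n_changed / nc if nc else float("nan"),
            "improved": outcome_counts[Outcome.IMPROVED],
            "improved_pct": 100.0 * outcome_counts[Outcome.IMPROVED] / nc if nc else float("nan"),
            "worsened": outcome_counts[Outcome.WORSENED],
            "worsened_pct": 100.0 * outcome_counts[Outcome.WORSENED] / nc if nc else float("nan"),
            "unchanged": outcome_counts[Outcome.UNCHANGED],
            "unchanged_pct": 100.0 * outcome_counts[Outcome.UNCHANGED] / nc if nc else float("nan"),
        })

        # --- per-participant all-images centroid hit (McNemar) ---
        participants = sorted({p.annotator_id for p, _q in members})
        all_pre, all_post = {}, {}
        for aid in participants:
            own = [(p, q) for p, q in members if p.annotator_id == aid]
            all_pre[aid] = all(p.centroid_hit for p, _q in own)
            all_post[aid] = all(q.centroid_hit for _p, q in own)
        b = sum(all_pre[a] and not all_post[a] for a in participants)
        c = sum(not all_pre[a] and all_post[a] for a in participants)
        mc = mcnemar_exact(b, c)
        pc.append({
            "stratum": name,
            "n_participants": len(participants),
            "all_hit_pre": sum(all_pre.values()),
            "all_hit_post": sum(all_post.values()),
            "discordant_pre_only": b,
            "discordant_post_only": c,
            "p_value": mc.p_value,
        })

    return StudySummary(
        table1=pd.DataFrame(t1),
        table2=pd.DataFrame(t2),
        table3=pd.DataFrame(t3),
        change_summary=pd.DataFrame(cs),
        participant_centroid=pd.DataFrame(pc),
        n_excluded_pairs=excluded,
    )
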