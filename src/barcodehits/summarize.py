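"""Accuracy, ambiguity and similarity summaries, with the supporting tests.

Accuracy at species level counts a query correct when its status is
reliable_correct or ambiguous_correct; accuracy at a shallower rank r
additionally counts misidentified queries whose deepest correct rank is at
least as deep as r. No-match queries stay in the denominator as incorrect,
so rank-wise accuracy is monotone (genus ≥ species) within any group.

Ambiguity is summarized among correct matches only:
100·|ambiguous| / (|ambiguous| + |reliable|) per group, with a cross-group
mean ± sample standard deviation. Two-sample t-tests (Welch by default) and
one-way ANOVA back the between-database and between-run comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InvalidInputError
from .taxonomy import RANKS, rank_depth

logger = logging.getLogger(__name__)

_CORRECT = ("reliable_correct", "ambiguous_correct")

GROUPABLE = ("taxon_group", "source_db", "locus", "run_id", "strategy")


def classifications_frame(classifications: Iterable) -> pd.DataFrame:
    """Flatten Classification / SpecimenClassification objects to a DataFrame."""
    rows = []
    for c in classifications:
        rows.append(
            {
                "query_id": getattr(c, "query_id", getattr(c, "specimen_id", "")),
                "locus": getattr(c, "locus", "+".join(sorted(getattr(c, "loci", ())))),
                "source_db": getattr(c, "source_db", ""),
                "run_id": getattr(c, "run_id", ""),
                "strategy": getattr(c, "strategy", ""),
                "taxon_group": getattr(c, "taxon_group", ""),
                "status": c.status,
                "deepest_correct_rank": c.deepest_correct_rank,
                "categories": ",".join(sorted(c.ambiguity_categories)),
                "top_similarity": getattr(c, "top_similarity", None),
                "low_confidence": getattr(c, "low_confidence", False),
                "tie_count": getattr(c, "tie_count", len(getattr(c, "candidates", ()))),
            }
        )
    return pd.DataFrame(rows)


def _correct_at_rank(df: pd.DataFrame, rank: str) -> pd.Series:
    depth = rank_depth(rank)
    species_ok = df["status"].isin(_CORRECT)
    rolled = df["deepest_correct_rank"].map(
        lambda r: r is not None and not (isinstance(r, float) and math.isnan(r))
        and rank_depth(r) >= depth
    )
    return species_ok | rolled


def accuracy_table(
    classifications,
    group_keys: Sequence[str] = ("source_db", "locus"),
    ranks: Sequence[str] = RANKS,
) -> pd.DataFrame:
    """Per-group, per-rank identification accuracy.

    Returns one row per (group × rank) with columns ``n``,
    ``percent_correct``, ``percent_ambiguous_of_correct`` and the mean/sd of
    the top similarity statistic over the group. Percentages are unrounded;
    round only at presentation.
    """
    df = classifications if isinstance(classifications, pd.DataFrame) else classifications_frame(classifications)
    if df.empty:
        raise DataError("no classifications to summarize")
    for key in group_keys:
        if key not in df.columns:
            raise InvalidInputError(f"unknown group key {key!r}")
    rows = []
    grouped = df.groupby(list(group_keys), dropna=False) if group_keys else [((), df)]
    for gkey, g in grouped:
        if len(g) == 0:
            continue
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        n_reliable = int((g["status"] == "reliable_correct").sum())
        n_ambiguous = int((g["status"] == "ambiguous_correct").sum())
        n_correct = n_reliable + n_ambiguous
        sims = g["top_similarity"].dropna().astype(float)
        for rank in ranks:
            ok = _correct_at_rank(g, rank)
            rows.append(
                dict(zip(group_keys, gkey))
                | {
                    "rank": rank,
                    "n": len(g),
                    "percent_correct": 100.0 * ok.sum() / len(g),
                    "percent_ambiguous_of_correct": (
                        100.0 * n_ambiguous / n_correct if n_correct else np.nan
                    ),
                    "similarity_mean": sims.mean() if len(sims) else np.nan,
                    "similarity_sd": sims.std(ddof=1) if len(sims) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AmbiguitySummary:
    per_group: pd.DataFrame
    mean: float
    sd: float | None  # None with a single contributing group


def ambiguity_summary(classifications, group_keys: Sequence[str] = ("source_db", "locus")) -> AmbiguitySummary:
    """Percent of correct matches that are ambiguous, per group and pooled.

    Groups without any correct match contribute no term (logged). The pooled
    figure is the cross-group mean ± sample sd (n−1 denominator).
    """
    df = classifications if isinstance(classifications, pd.DataFrame) else classifications_frame(classifications)
    if df.empty:
        raise DataError("no classifications to summarize")
    rows = []
    grouped = df.groupby(list(group_keys), dropna=False) if group_keys else [((), df)]
    for gkey, g in grouped:
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        n_rel = int((g["status"] == "reliable_correct").sum())
        n_amb = int((g["status"] == "ambiguous_correct").sum())
        if n_rel + n_amb == 0:
            logger.info("group %s has no correct matches; excluded from ambiguity summary", gkey)
            continue
        rows.append(
            dict(zip(group_keys, gkey))
            | {
                "n_correct": n_rel + n_amb,
                "percent_ambiguous": 100.0 * n_amb / (n_rel + n_amb),
            }
        )
    if not rows:
        raise DataError("no group has any correct match")
    per_group = pd.DataFrame(rows)
    rates = per_group["percent_ambiguous"].to_numpy()
    mean = float(np.mean(rates))
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else None
    return AmbiguitySummary(per_group=per_group, mean=mean, sd=sd)


class SimilaritySummary(NamedTuple):
    mean: float
    sd: float | None
    n: int


def similarity_summary(classifications, statuses: Sequence[str] | None = None) -> SimilaritySummary:
    """Mean ± sample sd of the top similarity statistic over selected queries.

    ``statuses`` restricts the selection (e.g. ``("misidentified",)`` for the
    similarity profile of wrong answers); None selects every query that has
    a similarity value.
    """
    df = classifications if isinstance(classifications, pd.DataFrame) else classifications_frame(classifications)
    if statuses is not None:
        df = df[df["status"].isin(statuses)]
    vals = df["top_similarity"].dropna().astype(float).to_numpy() if not df.empty else np.array([])
    if vals.size == 0:
        raise DataError("similarity summary over an empty selection")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else None
    return SimilaritySummary(mean=mean, sd=sd, n=int(vals.size))


class TTestResult(NamedTuple):
    t: float
    df: float
    p: float


def two_sample_t_test(x: Sequence[float], y: Sequence[float], variant: str = "welch") -> TTestResult:
    """Two-sided two-sample t-test (Welch by default, or pooled variance).

    Degenerate inputs with zero variance in both samples and equal means are
    defined as t=0, p=1 rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidInputError("each sample needs at least 2 observations")
    if variant not in ("welch", "pooled"):
        raise InvalidInputError(f"unknown t-test variant {variant!r}")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0 and x.mean() == y.mean():
        df = float(x.size + y.size - 2)
        return TTestResult(0.0, df, 1.0)
    import warnings

    with warnings.catch_warnings():
        # near-constant samples trip scipy's precision-loss warning; the
        # resulting statistic is still the defined one
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


class AnovaResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p: float


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA over ≥2 groups of ≥2 observations each.

    All-identical constant groups (zero between- and within-group variance)
    are defined as F=0, p=1.
    """
    if len(groups) < 2:
        raise InvalidInputError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise InvalidInputError("every ANOVA group needs at least 2 observations")
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    grand = np.concatenate(arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within == 0.0:
        if ss_between == 0.0:
            return AnovaResult(0.0, df1, df2, 1.0)
        return AnovaResult(float("inf"), df1, df2, 0.0)
    with np.errstate(invalid="ignore"):
        res = stats.f_oneway(*arrays)
    return AnovaResult(float(res.statistic), df1, df2, float(res.pvalue))


@dataclass
class RunComparison:
    """Cross-run agreement and significance for shared queries."""

    status_matrix: pd.DataFrame          # queries × runs, status strings
    per_run_accuracy: pd.Series          # percent species-correct per run
    pairwise_agreement: pd.DataFrame     # percent of shared queries with equal status
    anova: AnovaResult | None            # on per-query binary correctness
    t_test: TTestResult | None           # only when exactly two runs
    changed_queries: list[str]           # status differs across runs


def compare_runs(classifications_by_run: dict[str, list]) -> RunComparison:
    """Compare runs (parameter sets / sequence subsets) over shared queries.

    Runs are compared on the intersection of their query sets; disjoint runs
    are an error. The significance tests operate on per-query binary
    species-level correctness indicators, one group per run.
    """
    if len(classifications_by_run) < 2:
        raise InvalidInputError("compare_runs needs at least two runs")
    frames = {
        run: (cls if isinstance(cls, pd.DataFrame) else classifications_frame(cls)).set_index("query_id")
        for run, cls in classifications_by_run.items()
    }
    common = None
    for f in frames.values():
        ids = set(f.index)
        common = ids if common is None else (common & ids)
    if not common:
        raise DataError("runs share no query ids")
    common = sorted(common)
    status_matrix = pd.DataFrame(
        {run: f.loc[common, "status"] for run, f in frames.items()}, index=common
    )
    correct = pd.DataFrame(
        {run: f.loc[common, "status"].isin(_CORRECT).astype(int) for run, f in frames.items()},
        index=common,
    )
    per_run_accuracy = 100.0 * correct.mean(axis=0)
    runs = list(frames)
    agreement = pd.DataFrame(np.eye(len(runs)) * 100.0, index=runs, columns=runs)
    for i, a in enumerate(runs):
        for b in runs[i + 1:]:
            pct = 100.0 * float((status_matrix[a] == status_matrix[b]).mean())
            agreement.loc[a, b] = agreement.loc[b, a] = pct
    anova = one_way_anova([correct[r].to_numpy() for r in runs]) if len(common) >= 2 else None
    t_test = (
        two_sample_t_test(correct[runs[0]], correct[runs[1]])
        if len(runs) == 2 and len(common) >= 2
        else None
    )
    changed = [q for q in common if status_matrix.loc[q].nunique() > 1]
    return RunComparison(
        status_matrix=status_matrix, per_run_accuracy=per_run_accuracy,
        pairwise_agreement=agreement, anova=anova, t_test=t_test,
        changed_queries=changed,
    )
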