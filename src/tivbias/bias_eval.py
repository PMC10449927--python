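"""Auditing a sex classifier for brain-size (TIV) bias.

A TIV-biased model classifies large-brained subjects as male and
small-brained subjects as female, so its errors are ordered by TIV: men it
misclassifies have unusually low TIV, women it misclassifies unusually high
TIV.  The audit therefore partitions every group into subjects classified
*congruently* vs *incongruently* with their sex assigned at birth and
compares the TIV (and total-GMV) distributions of the two subsets with
Wilcoxon rank-sum tests, reporting the rank-based effect size eta^2 = z^2/N.
Prediction probabilities of cis- and transgender groups sharing a sex (CW vs
TM, CM vs TW) are compared with pooled-variance t tests and Cohen's d.

Conventions (chosen to be internally consistent and documented):
``T`` is the rank-sum of the congruent group; the normal approximation uses
mid-ranks for ties, a tie-corrected variance and a 0.5 continuity correction;
all tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import EvaluationConfig

__all__ = [
    "PerformanceReport",
    "RankTestResult",
    "MeanTestResult",
    "BiasReport",
    "performance_metrics",
    "congruence_partition",
    "ranksum_test",
    "probability_comparison",
    "bias_audit",
    "eta_squared",
    "cohens_d_from_t",
]

# sex assigned at birth per gender group; W/M are the hold-out cohort labels
GROUP_SEX = {"W": "F", "M": "M", "CW": "F", "CM": "M", "TM": "F", "TW": "M"}


def eta_squared(z: float, n_total: int) -> float:
    """Rank-test effect size: eta^2 = z^2 / N."""
    return float(z) ** 2 / float(n_total)


def cohens_d_from_t(t: float, n1: int, n2: int) -> float:
    """Pooled-variance consistency identity: d = t * sqrt(1/n1 + 1/n2)."""
    return float(t) * np.sqrt(1.0 / n1 + 1.0 / n2)


# --------------------------------------------------------------------------
# performance

@dataclass
class PerformanceReport:
    """Confusion counts and the derived metrics, male as positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    recall: float
    specificity: float
    f1: float
    balanced_accuracy: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def performance_metrics(predictions: pd.DataFrame, positive_class: str = "male") -> PerformanceReport:
    """Recall/specificity/F1/balanced accuracy from a prediction table.

    ``predictions`` needs columns ``true_sex`` (F/M) and ``pred_label``
    (female/male).  Metrics whose defining class is absent come out NaN.
    """
    if positive_class != "male":
        raise ValueError("the positive class is 'male' by convention")
    truth_pos = predictions["true_sex"].to_numpy() == "M"
    pred_pos = predictions["pred_label"].to_numpy() == "male"
    tp = int(np.sum(truth_pos & pred_pos))
    fn = int(np.sum(truth_pos & ~pred_pos))
    tn = int(np.sum(~truth_pos & ~pred_pos))
    fp = int(np.sum(~truth_pos & pred_pos))
    recall = tp / (tp + fn) if (tp + fn) else np.nan
    specificity = tn / (tn + fp) if (tn + fp) else np.nan
    precision = tp / (tp + fp) if (tp + fp) else np.nan
    f1 = (
        2 * precision * recall / (precision + recall)
        if np.isfinite(precision) and np.isfinite(recall) and (precision + recall) > 0
        else np.nan
    )
    ba = (recall + specificity) / 2.0
    return PerformanceReport(tp=tp, fp=fp, tn=tn, fn=fn, recall=recall,
                             specificity=specificity, f1=f1, balanced_accuracy=ba)


# --------------------------------------------------------------------------
# congruence partition

def congruence_partition(predictions: pd.DataFrame, subjects: pd.DataFrame) -> dict:
    """Split each group into congruently / incongruently classified ids.

    A prediction is congruent when the predicted label matches the subject's
    sex assigned at birth.  Groups are the gender groups (CW/CM/TM/TW) when
    transgender subjects are present, else the cohort labels W/M.  Each entry
    carries a ``marker`` string of the form "no X classified as Y" when its
    incongruent list is empty.
    """
    merged = predictions.merge(subjects[["id", "sex", "gender_group"]], on="id", validate="one_to_one")
    unknown = set(merged["gender_group"].unique()) - set(GROUP_SEX) - {"W", "M"}
    if unknown:
        raise ValueError(f"unknown gender_group values: {sorted(unknown)}")
    has_trans = merged["gender_group"].isin(["TM", "TW"]).any()
    if has_trans:
        merged["group"] = merged["gender_group"]
    else:
        merged["group"] = merged["sex"].map({"F": "W", "M": "M"})
    out: dict[str, dict] = {}
    for group, grp in merged.groupby("group", sort=True):
        sex = GROUP_SEX[group]
        congruent_label = "male" if sex == "M" else "female"
        incongruent_label = "female" if sex == "M" else "male"
        cong = grp.loc[grp["pred_label"] == congruent_label, "id"].tolist()
        incong = grp.loc[grp["pred_label"] != congruent_label, "id"].tolist()
        marker = None
        if not incong:
            marker = f"no {group} classified as {incongruent_label}"
        out[group] = {"congruent": cong, "incongruent": incong, "marker": marker}
    return out


# --------------------------------------------------------------------------
# rank-sum test

@dataclass
class RankTestResult:
    """Wilcoxon rank-sum of congruent vs incongruent values.

    ``T`` is the rank-sum of the congruent group; ``z`` the continuity-
    corrected, tie-adjusted normal approximation; ``eta_sq = z^2/N``.
    ``marker`` replaces the statistics when one group is empty.
    """

    T: float = np.nan
    z: float = np.nan
    p: float = np.nan
    eta_sq: float = np.nan
    n_congruent: int = 0
    n_incongruent: int = 0
    marker: str | None = None

    @property
    def n_total(self) -> int:
        return self.n_congruent + self.n_incongruent

    def to_dict(self) -> dict:
        return dict(self.__dict__)


_EXACT_N_MAX = 30


def _exact_two_sided_p(T: float, n1: int, N: int) -> float:
    """Exact two-sided p for a tie-free rank-sum via dynamic programming.

    Counts subsets of {1..N} of size n1 whose rank-sum deviates from the null
    mean at least as much as T does (the tie-free null distribution of T is
    symmetric, so deviation counting equals doubling the smaller tail).
    """
    max_sum = N * (N + 1) // 2
    # counts[k][s] = number of k-subsets of 1..N with rank-sum s
    counts = np.zeros((n1 + 1, max_sum + 1))
    counts[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            counts[k, r:] += counts[k - 1, :-r or None]
    dist = counts[n1]
    mu = n1 * (N + 1) / 2.0
    dev = abs(T - mu)
    sums = np.arange(max_sum + 1)
    mass = dist[np.abs(sums - mu) >= dev - 1e-9].sum()
    return float(mass / dist.sum())


def ranksum_test(values_congruent, values_incongruent) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum with mid-ranks, tie-corrected variance and
    a 0.5 continuity correction.

    For small tie-free samples (N <= 30) the p value comes from the exact
    permutation distribution, as in R's ``wilcox.test``; ``z`` (and hence
    eta^2) always reports the normal approximation used at study scale.
    Raises ``ValueError`` if either group is empty (callers wanting the
    "no X classified as Y" marker handle emptiness before calling).
    """
    a = np.asarray(values_congruent, float)
    b = np.asarray(values_incongruent, float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    N = n1 + n2
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined, method="average")
    T = float(ranks[:n1].sum())
    mu = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return RankTestResult(T=T, z=0.0, p=1.0, eta_sq=0.0,
                              n_congruent=n1, n_incongruent=n2)
    diff = T - mu
    cc = 0.5 * np.sign(diff)
    if abs(diff) < 0.5:
        z = 0.0
    else:
        z = (diff - cc) / np.sqrt(var)
    tie_free = tie_counts.max() == 1
    if tie_free and N <= _EXACT_N_MAX:
        p = _exact_two_sided_p(T, n1, N)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return RankTestResult(T=T, z=float(z), p=min(p, 1.0), eta_sq=eta_squared(z, N),
                          n_congruent=n1, n_incongruent=n2)


# --------------------------------------------------------------------------
# probability comparison

@dataclass
class MeanTestResult:
    """Pooled-variance two-sample t with Cohen's d via the t identity."""

    t: float = np.nan
    p: float = np.nan
    cohens_d: float = np.nan
    n1: int = 0
    n2: int = 0
    undefined: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def probability_comparison(probs_group_a, probs_group_b) -> MeanTestResult:
    a = np.asarray(probs_group_a, float)
    b = np.asarray(probs_group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 members")
    pooled_var = (
        (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0.0:
        if np.mean(a) == np.mean(b):
            return MeanTestResult(t=0.0, p=1.0, cohens_d=0.0, n1=len(a), n2=len(b))
        return MeanTestResult(n1=len(a), n2=len(b), undefined=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return MeanTestResult(t=float(t), p=float(p),
                          cohens_d=cohens_d_from_t(float(t), len(a), len(b)),
                          n1=len(a), n2=len(b))


# --------------------------------------------------------------------------
# the audit

@dataclass
class BiasReport:
    """Full audit of one model's predictions on one sample."""

    partition: dict
    tiv_tests: dict[str, RankTestResult]
    gmv_tests: dict[str, RankTestResult]
    probability_tests: dict[str, MeanTestResult] = field(default_factory=dict)
    verdict: str = ""
    config: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_dict(self) -> dict:
        return {
            "partition": {
                g: {"n_congruent": len(v["congruent"]),
                    "n_incongruent": len(v["incongruent"]),
                    "marker": v["marker"]}
                for g, v in self.partition.items()
            },
            "tiv_tests": {g: r.to_dict() for g, r in self.tiv_tests.items()},
            "gmv_tests": {g: r.to_dict() for g, r in self.gmv_tests.items()},
            "probability_tests": {k: r.to_dict() for k, r in self.probability_tests.items()},
            "verdict": self.verdict,
        }


def _group_tests(partition, subjects, column) -> dict[str, RankTestResult]:
    sub = subjects.set_index("id")
    out = {}
    for group, part in partition.items():
        if part["marker"] is not None:
            out[group] = RankTestResult(marker=part["marker"],
                                        n_congruent=len(part["congruent"]))
        elif not part["congruent"]:
            out[group] = RankTestResult(
                marker=f"no {group} classified congruently",
                n_incongruent=len(part["incongruent"]),
            )
        else:
            out[group] = ranksum_test(
                sub.loc[part["congruent"], column].to_numpy(float),
                sub.loc[part["incongruent"], column].to_numpy(float),
            )
    return out


def bias_audit(
    predictions: pd.DataFrame,
    subjects: pd.DataFrame,
    config: EvaluationConfig | None = None,
) -> BiasReport:
    """Run the complete TIV-bias audit on one prediction table.

    Per group: rank-sum tests of TIV and total GMV between congruently and
    incongruently classified subjects at the conservative distribution alpha.
    When transgender groups are present, prediction probabilities of CW vs TM
    and CM vs TW are compared at the probability alpha.  The verdict is
    "bias detected" iff some TIV test is significant in the biased direction
    (congruent men larger than incongruent men, or congruent women smaller
    than incongruent women); "not assessable from misclassifications" when no
    group has any misclassification.
    """
    config = config or EvaluationConfig()
    partition = congruence_partition(predictions, subjects)
    tiv_tests = _group_tests(partition, subjects, "tiv")
    gmv_tests = _group_tests(partition, subjects, "total_gmv")

    prob_tests: dict[str, MeanTestResult] = {}
    merged = predictions.merge(subjects[["id", "gender_group"]], on="id")
    by_group = {g: grp["prob_male"].to_numpy(float) for g, grp in merged.groupby("gender_group")}
    for name, (ga, gb) in {"CW_vs_TM": ("CW", "TM"), "CM_vs_TW": ("CM", "TW")}.items():
        if ga in by_group and gb in by_group and len(by_group[ga]) >= 2 and len(by_group[gb]) >= 2:
            prob_tests[name] = probability_comparison(by_group[ga], by_group[gb])

    sub = subjects.set_index("id")
    any_assessable = False
    biased = False
    for group, res in tiv_tests.items():
        if res.marker is not None:
            continue
        any_assessable = True
        if res.p < config.alpha_distribution_tests:
            part = partition[group]
            mean_c = sub.loc[part["congruent"], "tiv"].mean()
            mean_i = sub.loc[part["incongruent"], "tiv"].mean()
            sex = GROUP_SEX[group]
            if (sex == "M" and mean_c > mean_i) or (sex == "F" and mean_c < mean_i):
                biased = True
    if not any_assessable:
        verdict = "not assessable from misclassifications"
    elif biased:
        verdict = "bias detected"
    else:
        verdict = "no bias detected"
    return BiasReport(partition=partition, tiv_tests=tiv_tests, gmv_tests=gmv_tests,
                      probability_tests=prob_tests, verdict=verdict, config=config)
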