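"""Instrument scoring, inter-rater reliability, and difficulty classes.

Covers the study-design computations around the neural measures: summing
the NASA-TLX dimensions and PANAS affect subscales, validating Borg
observer ratings, the two-way random-effects intraclass correlation for
the instructors' scenario-difficulty ratings, and the Jenks natural-breaks
classification that turns mean difficulty ratings into low/medium/high
classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from dyadnirs.session import RatingRecord

#: PANAS positive-affect item positions (1-based, standard 20-item form)
PANAS_POSITIVE = (1, 3, 5, 9, 10, 12, 14, 16, 17, 19)
PANAS_NEGATIVE = (2, 4, 6, 7, 8, 11, 13, 15, 18, 20)


@dataclass
class IccResult:
    icc: float
    form: str  # "two_way_random_single" | "two_way_random_average"
    ms_targets: float
    ms_raters: float
    ms_error: float
    defined: bool = True


@dataclass
class DifficultyClassification:
    breaks: tuple[float, float]
    classes: list[str]  # low/medium/high per input value, input order
    goodness: float  # goodness of variance fit, 1 - SSD_within/SSD_total


def score_instruments(record: RatingRecord) -> dict[str, float]:
    """Score one participant's instrument responses.

    TLX overall is the unweighted sum of the six 0–100 dimensions
    (0–600); PANAS positive and negative affect are the sums of their
    ten designated items (10–50 each); the Borg rating passes through
    after range validation.
    """
    problems = record.violations()
    if problems:
        raise ValueError("; ".join(problems))
    out: dict[str, float] = {}
    if record.borg is not None:
        out["borg"] = float(record.borg)
    if record.tlx_dims is not None:
        out["tlx_overall"] = float(sum(record.tlx_dims))
    if record.panas_items is not None:
        items = np.asarray(record.panas_items, dtype=float)
        out["panas_positive"] = float(items[[i - 1 for i in PANAS_POSITIVE]].sum())
        out["panas_negative"] = float(items[[i - 1 for i in PANAS_NEGATIVE]].sum())
    return out


def icc(ratings: np.ndarray, form: str = "two_way_random_average") -> IccResult:
    """Two-way random-effects intraclass correlation from mean squares.

    ``ratings`` is a complete (targets x raters) matrix.  Mean squares
    come from the two-way target x rater decomposition; the single-
    measures form is ICC(2,1) and the average-measures form ICC(2,k)
    (absolute agreement).  The average-measures form is the default
    because downstream analyses use the mean of the raters' scores.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 2:
        raise ValueError("need at least 2 targets and 2 raters")
    if not np.all(np.isfinite(R)):
        raise ValueError("missing cells are not supported")
    n, k = R.shape
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if ss_total == 0:
        return IccResult(float("nan"), form, msr, msc, mse, defined=False)

    if form == "two_way_random_single":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        value = (msr - mse) / denom
    elif form == "two_way_random_average":
        denom = msr + (msc - mse) / n
        value = (msr - mse) / denom
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    return IccResult(float(value), form, float(msr), float(msc), float(mse))


def _ssd(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-class sum of squared deviations of sorted values [i, j)."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return s2 - s * s / n


def jenks_classify(values, k: int = 3) -> DifficultyClassification:
    """Jenks natural-breaks classification into k ordered classes.

    Partitions the sorted values into ``k`` contiguous classes
    minimizing the total within-class sum of squared deviations
    (dynamic programming over break positions).  Ties in the objective
    break toward the smaller lower class.  With ``k = 3`` the classes
    are labelled low/medium/high in order of class mean.
    """
    v = np.asarray(list(values), dtype=float)
    if np.unique(v).size < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")
    order = np.argsort(v, kind="stable")
    x = v[order]
    n = x.size
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])

    # dp[c][j]: minimal SSD of splitting x[:j] into c classes
    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    cut = np.zeros((k + 1, n + 1), dtype=int)
    dp[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, best_i = INF, -1
            for i in range(c - 1, j):
                cand = dp[c - 1][i] + _ssd(prefix, prefix2, i, j)
                # strict < keeps the earliest split: smaller lower class
                if cand < best - 1e-12:
                    best, best_i = cand, i
            dp[c][j] = best
            cut[c][j] = best_i

    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = cut[c][j]
        bounds.append(j)
    bounds = bounds[::-1]  # 0 = b0 < b1 < ... < bk = n

    labels_by_rank = ["low", "medium", "high"] if k == 3 else [str(i) for i in range(k)]
    class_of_sorted = np.empty(n, dtype=object)
    for c in range(k):
        class_of_sorted[bounds[c] : bounds[c + 1]] = labels_by_rank[c]
    classes = [None] * n
    for pos, orig in enumerate(order):
        classes[orig] = class_of_sorted[pos]

    breaks = tuple(float(x[bounds[c] - 1]) for c in range(1, k))
    total = _ssd(prefix, prefix2, 0, n)
    within = dp[k][n]
    goodness = 1.0 - within / total if total > 0 else 1.0
    return DifficultyClassification(breaks=breaks, classes=classes, goodness=goodness)


def jenks_objective_bruteforce(values, k: int = 3) -> float:
    """Exhaustive minimal within-class SSD over all contiguous k-partitions.

    Exponential in n; intended as an independent oracle for small inputs.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    n = x.size
    prefix = np.concatenate([[0.0], np.cumsum(x)])
    prefix2 = np.concatenate([[0.0], np.cumsum(x * x)])
    best = float("inf")
    for cuts in combinations(range(1, n), k - 1):
        bounds = (0, *cuts, n)
        total = sum(
            _ssd(prefix, prefix2, bounds[c], bounds[c + 1]) for c in range(k)
        )
        best = min(best, total)
    return best
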