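"""Paired statistics comparing acquisition paradigms across subjects.

Session accuracies form a subjects x condition grid (condition = paradigm,
classifier, window length, CAR on/off).  Paradigms are compared pairwise
with three paired tests at alpha = 0.05:

* an exact two-sided Wilcoxon signed-rank test, whose null distribution is
  enumerated over all 2^n sign assignments of the ranked absolute
  differences (the normal approximation is useless at n = 10);
* a paired t-test;
* a two-condition repeated-measures ANOVA, which for two conditions is the
  paired t-test in disguise (F = t^2) and is computed through the
  F(1, n-1) distribution as a cross-check;

followed by a Bonferroni correction over the family of paradigm pairs
(m = 3: arrow/picture, arrow/video, picture/video), applied to the ANOVA
probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
#: Number of paradigm pairs in the Bonferroni family.
N_COMPARISONS = 3

__all__ = [
    "PairedAccuracyTable",
    "ComparisonResult",
    "wilcoxon_exact",
    "paired_t_p",
    "paired_anova_p",
    "bonferroni",
    "compare_paradigms",
    "ParadigmComparison",
    "ComparisonResults",
]


@dataclass(frozen=True)
class PairedAccuracyTable:
    """Subjects x condition grid of session-accuracy percentages.

    ``frame`` is a long-format table with columns
    ``subject, paradigm, classifier, window_s, accuracy_pct``; ``car`` records
    whether the accuracies were obtained after common-average referencing.
    """

    frame: pd.DataFrame = field(repr=False)
    car: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        required = {"subject", "paradigm", "classifier", "window_s", "accuracy_pct"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"accuracy table missing columns: {sorted(missing)}")

    @property
    def subjects(self) -> list[str]:
        """Subject identifiers in first-appearance order."""
        return list(dict.fromkeys(self.frame["subject"]))

    def column(self, paradigm: str, classifier: str, window: float) -> np.ndarray:
        """Accuracies of one condition, aligned to ``self.subjects``.

        Raises
        ------
        KeyError
            If any subject is missing a cell for the condition.
        """
        sel = self.frame[
            (self.frame["paradigm"] == str(paradigm).upper())
            & (self.frame["classifier"] == str(classifier).upper())
            & (self.frame["window_s"] == window)
        ]
        by_subject = dict(zip(sel["subject"], sel["accuracy_pct"]))
        out = []
        for s in self.subjects:
            if s not in by_subject:
                raise KeyError(
                    f"missing cell: subject {s}, ({paradigm}, {classifier}, T={window})"
                )
            out.append(float(by_subject[s]))
        return np.array(out)

    def value(self, subject: str, paradigm: str, classifier: str, window: float) -> float:
        """Single cell of the grid."""
        col = self.column(paradigm, classifier, window)
        return float(col[self.subjects.index(subject)])


def _signed_rank_statistics(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Tie-aware ranks of |y - x| (zeros dropped) and the lesser rank sum W."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = y - x
    nonzero = d != 0
    if not np.all(nonzero):
        warnings.warn(
            f"dropping {int(np.sum(~nonzero))} zero difference(s) before ranking",
            stacklevel=3,
        )
    d = d[nonzero]
    if d.size == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    ranks = sps.rankdata(np.abs(d))  # average ranks for tied magnitudes
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return ranks, min(w_plus, w_minus)


def wilcoxon_exact(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Wilcoxon signed-rank probability for paired samples.

    W = min(W+, W-) of the signed ranks of ``|y - x|``; the p-value is
    ``2 P(W_null <= W)`` under the exact null in which each rank receives a
    random sign, enumerated over all ``2^n`` assignments (via the standard
    shift-convolution recursion, exact in integer arithmetic), capped at 1.
    Tied magnitudes receive average ranks; zero differences are dropped with
    a warning.  Intended for the exact regime ``n <= 25``.
    """
    ranks, w = _signed_rank_statistics(x, y)
    n = ranks.size
    if n > 25:
        raise ValueError("exact enumeration is restricted to n <= 25 pairs")
    # Average ranks are half-integers at worst: double to land on integers.
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=object)  # exact big-int counts
    counts[0] = 1
    for r in r2:
        counts[r:] = counts[r:] + counts[:-r]
    w2 = int(np.rint(2 * w))  # 2W is an exact integer (ranks are half-integers)
    tail = sum(counts[: w2 + 1])
    p = Fraction(2 * tail, 2**n)
    return float(min(p, Fraction(1)))


def paired_t_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired t-test probability (t distribution, n-1 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired t-test needs two 1-D samples of equal length >= 2")
    d = y - x
    if np.var(d, ddof=1) == 0:
        raise ValueError("paired differences have zero variance; t-test undefined")
    return float(sps.ttest_rel(y, x).pvalue)


def paired_anova_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-condition repeated-measures ANOVA probability.

    With two conditions the repeated-measures F statistic equals the square
    of the paired t statistic, so this routes through F(1, n-1); agreement
    with :func:`paired_t_p` is an identity, asserted in the test suite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("paired ANOVA needs two 1-D samples of equal length >= 2")
    d = y - x
    n = d.size
    var = np.var(d, ddof=1)
    if var == 0:
        raise ValueError("paired differences have zero variance; ANOVA undefined")
    f_stat = n * np.mean(d) ** 2 / var  # = t^2
    return float(sps.f.sf(f_stat, 1, n - 1))


def bonferroni(p: float, m: int = N_COMPARISONS) -> float:
    """Bonferroni-corrected probability ``min(1, m p)``."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of one paradigm pair under the three paired tests."""

    comparison: str
    p_anova: float
    p_wilcoxon: float
    p_t: float
    p_bonferroni: float
    alpha: float = ALPHA

    @property
    def significant(self) -> dict[str, bool]:
        return {
            "anova": self.p_anova < self.alpha,
            "wilcoxon": self.p_wilcoxon < self.alpha,
            "bonferroni": self.p_bonferroni < self.alpha,
        }


def compare_paradigms(
    table: PairedAccuracyTable,
    classifier: str,
    window: float,
    reference: str = "ARROW",
    others: tuple[str, ...] = ("PICTURE", "VIDEO"),
    m: int = N_COMPARISONS,
    on_degenerate: str = "raise",
) -> dict[str, ComparisonResult]:
    """Run the three paired tests for each (reference vs other) paradigm pair.

    The Bonferroni correction multiplies the ANOVA probability by ``m`` (the
    full family of paradigm pairs, default 3, even though only the
    reference-vs-other pairs are tabulated).  A degenerate pair (all
    differences zero, or zero variance) raises by default;
    ``on_degenerate="nan"`` records NaN probabilities instead, which lets a
    batch caller keep the remaining comparisons.
    """
    if on_degenerate not in {"raise", "nan"}:
        raise ValueError("on_degenerate must be 'raise' or 'nan'")
    out: dict[str, ComparisonResult] = {}
    ref = table.column(reference, classifier, window)
    for other in others:
        oth = table.column(other, classifier, window)
        name = f"{reference.capitalize()} vs. {other.capitalize()}"
        try:
            p_a = paired_anova_p(ref, oth)
            res = ComparisonResult(
                comparison=name,
                p_anova=p_a,
                p_wilcoxon=wilcoxon_exact(ref, oth),
                p_t=paired_t_p(ref, oth),
                p_bonferroni=bonferroni(p_a, m),
            )
        except ValueError:
            if on_degenerate == "raise":
                raise
            warnings.warn(
                f"degenerate comparison {name} ({classifier}, T={window:g}); "
                "recording NaN probabilities",
                stacklevel=2,
            )
            res = ComparisonResult(
                comparison=name,
                p_anova=float("nan"),
                p_wilcoxon=float("nan"),
                p_t=float("nan"),
                p_bonferroni=float("nan"),
            )
        out[other] = res
    return out


class ParadigmComparison:
    """Model: paired paradigm comparison over a session-accuracy grid.

    Parameters
    ----------
    table
        Subjects x condition accuracy grid.
    classifiers
        Classifier conditions to compare (default all three of the study).
    window
        Window length (s) selecting the grid columns.
    reference, others
        The reference paradigm and the paradigms compared against it.

    ``fit()`` returns a :class:`ComparisonResults` carrying one
    :class:`ComparisonResult` per (classifier, pair).
    """

    def __init__(
        self,
        table: PairedAccuracyTable,
        classifiers: tuple[str, ...] = ("LDA", "SVM_LINEAR", "SVM_POLY3"),
        window: float = 2,
        reference: str = "ARROW",
        others: tuple[str, ...] = ("PICTURE", "VIDEO"),
        on_degenerate: str = "raise",
    ) -> None:
        self.table = table
        self.classifiers = tuple(c.upper() for c in classifiers)
        self.window = window
        self.reference = reference.upper()
        self.others = tuple(o.upper() for o in others)
        self.on_degenerate = on_degenerate

    def fit(self) -> "ComparisonResults":
        results = {
            clf: compare_paradigms(
                self.table,
                clf,
                self.window,
                self.reference,
                self.others,
                on_degenerate=self.on_degenerate,
            )
            for clf in self.classifiers
        }
        return ComparisonResults(self, results)


class ComparisonResults:
    """Fitted paradigm-comparison results with a tabular summary."""

    def __init__(
        self,
        model: ParadigmComparison,
        results: dict[str, dict[str, ComparisonResult]],
    ) -> None:
        self.model = model
        self.results = results

    def summary(self) -> pd.DataFrame:
        """Long table: one row per (classifier, comparison) with the three p's."""
        rows = []
        for clf, per_pair in self.results.items():
            for res in per_pair.values():
                rows.append(
                    {
                        "classifier": clf,
                        "comparison": res.comparison,
                        "p_anova": round(res.p_anova, 4),
                        "p_wilcoxon": round(res.p_wilcoxon, 4),
                        "p_bonferroni": round(res.p_bonferroni, 4),
                        "significant_bonferroni": res.p_bonferroni < res.alpha,
                    }
                )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        return self.summary().to_string(index=False)
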