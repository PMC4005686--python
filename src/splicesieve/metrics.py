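"""Evaluation of junction detection and quantification.

Detection: expressed junctions spanned by at least one read are true
positives when called, false negatives when not; called junctions absent
from the truth are false positives. Quantification: per-junction absolute
difference between called and true counts — a false-negative junction
contributes its full true count, a false-positive junction its full called
count — plus relative errors for true positives. Without ground truth,
*pseudo*-metrics designate as pseudo-true the junctions whose median read
count across several methods is positive and score each method against that
consensus set.

Undefined ratios (0/0) are reported as NA (None / NaN), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Set

import numpy as np
import pandas as pd

from .core import ContractViolation, JunctionKey
from .simulate import TruthTable


@dataclass(frozen=True)
class DetectionReport:
    tp: int
    fp: int
    fn: int
    sensitivity: Optional[float]
    ppv: Optional[float]
    f1: Optional[float]


def _safe_div(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def _report(tp: int, fp: int, fn: int) -> DetectionReport:
    sens = _safe_div(tp, tp + fn)
    ppv = _safe_div(tp, tp + fp)
    if sens is None or ppv is None or sens + ppv == 0:
        f1 = None
    else:
        f1 = 2 * sens * ppv / (sens + ppv)
    return DetectionReport(tp=tp, fp=fp, fn=fn, sensitivity=sens, ppv=ppv, f1=f1)


def f1_score(sensitivity: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and positive predictive value."""
    if sensitivity + ppv == 0:
        raise ContractViolation("F1 undefined when both inputs are 0")
    return 2 * sensitivity * ppv / (sensitivity + ppv)


def detection_metrics(
    calls: Set[JunctionKey],
    truth: TruthTable,
    universe: Optional[Set[JunctionKey]] = None,
    strict: bool = False,
) -> DetectionReport:
    """Score a called junction set against the truth.

    ``universe`` is the set of junctions spanned by at least one read in the
    alignment; when given (and ``strict`` is False) false negatives are
    restricted to expressed junctions inside it — junctions the aligner
    never saw are not charged to the filter. Strict mode counts every
    missed expressed junction.
    """
    if not truth.expressed and not truth.artefactual:
        raise ContractViolation("truth table is empty")
    expressed = set(truth.expressed)
    tp = len(calls & expressed)
    fp = len(calls - expressed)
    fn_set = expressed - calls
    if universe is not None and not strict:
        fn_set &= universe
    return _report(tp, fp, len(fn_set))


@dataclass
class QuantReport:
    """Per-junction quantification errors and summary percentiles."""

    per_junction: pd.DataFrame  # columns: true_count, called_count, absolute_error, relative_error
    total_absolute_error: int
    percentiles: pd.Series

    @property
    def median_absolute_error(self) -> float:
        return float(self.per_junction["absolute_error"].median())


def quantification_error(
    calls: Mapping[JunctionKey, int],
    truth: TruthTable,
) -> QuantReport:
    """Absolute and relative per-junction count errors.

    The error universe comprises the union of called and expressed
    junctions: misses contribute their true count, spurious calls their
    called count. Relative errors are defined for expressed junctions only.
    """
    keys = sorted(set(calls) | set(truth.expressed))
    rows = []
    for key in keys:
        true = truth.expressed.get(key, 0)
        called = calls.get(key, 0)
        abs_err = abs(called - true)
        rel = abs_err / true if true > 0 else np.nan
        rows.append((str(key.reference), key.intron_start, key.intron_end,
                     key.strand, true, called, abs_err, rel))
    df = pd.DataFrame(
        rows,
        columns=["reference", "intron_start", "intron_end", "strand",
                 "true_count", "called_count", "absolute_error",
                 "relative_error"],
    )
    total = int(df["absolute_error"].sum()) if len(df) else 0
    if len(df):
        percentiles = df["absolute_error"].quantile([0.25, 0.5, 0.75, 0.9, 1.0])
    else:
        percentiles = pd.Series(dtype=float)
    return QuantReport(per_junction=df, total_absolute_error=total,
                       percentiles=percentiles)


def pseudo_true_set(counts: pd.DataFrame) -> pd.Index:
    """Junctions whose median read count across methods is > 0."""
    return counts.index[counts.median(axis=1) > 0]


def pseudo_metrics(counts: pd.DataFrame) -> dict[str, DetectionReport]:
    """Score each method against the cross-method consensus.

    ``counts``: junction rows x method columns, integer read counts (0 =
    not detected by that method). Requires at least two methods; invariant
    to column order.
    """
    if counts.shape[1] < 2:
        raise ContractViolation("pseudo metrics require >= 2 methods")
    pseudo_true = set(pseudo_true_set(counts))
    reports = {}
    for method in counts.columns:
        called = set(counts.index[counts[method] > 0])
        tp = len(called & pseudo_true)
        fp = len(called - pseudo_true)
        fn = len(pseudo_true - called)
        reports[method] = _report(tp, fp, fn)
    return reports


def detection_report_frame(reports: Mapping[str, DetectionReport]) -> pd.DataFrame:
    rows = {
        name: {"tp": r.tp, "fp": r.fp, "fn": r.fn,
               "sensitivity": r.sensitivity, "ppv": r.ppv, "f1": r.f1}
        for name, r in reports.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")
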