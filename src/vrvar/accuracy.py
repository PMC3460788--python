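"""Accuracy of a called SNP set against a gold-standard difference set.

Both sets are keyed by (position, alt allele) over a coordinate-matched
region.  Rates: false positives over called SNPs, false negatives over true
SNPs, base-pair accuracy 1 - (fp + fn) / region_bp.  A call at a true-SNP
position with the wrong alt allele counts as one false positive and one
false negative.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AccuracyReport:
    region_bp: int
    n_true: int
    n_called: int
    n_tp: int
    n_fp: int
    n_fn: int
    fp_rate: float  # fraction of called SNPs that are spurious
    fn_rate: float  # fraction of true SNPs missed; NaN-flagged if no truth
    bp_accuracy: float
    fn_rate_defined: bool = True

    def __post_init__(self) -> None:
        assert self.n_tp + self.n_fp == self.n_called
        assert self.n_tp + self.n_fn == self.n_true


def score_calls(called, truth, region_bp: int) -> AccuracyReport:
    """Score called SNPs against a truth set over ``region_bp`` bases.

    ``called`` and ``truth`` are iterables of (position, alt) keys.
    """
    if region_bp <= 0:
        raise ValueError("region_bp must be positive")
    called_set, truth_set = set(called), set(truth)
    tp = called_set & truth_set
    fp = called_set - truth_set
    fn = truth_set - called_set
    fn_defined = bool(truth_set)
    return AccuracyReport(
        region_bp=region_bp,
        n_true=len(truth_set), n_called=len(called_set),
        n_tp=len(tp), n_fp=len(fp), n_fn=len(fn),
        fp_rate=len(fp) / len(called_set) if called_set else 0.0,
        fn_rate=len(fn) / len(truth_set) if fn_defined else float("nan"),
        bp_accuracy=1.0 - (len(fp) + len(fn)) / region_bp,
        fn_rate_defined=fn_defined,
    )


def diff_sequences(reference: str, other: str, offset: int = 0):
    """SNP keys from two coordinate-matched sequences (truth-set helper)."""
    if len(reference) != len(other):
        raise ValueError("sequences must be coordinate-matched (equal length)")
    return {(offset + i, b) for i, (a, b) in enumerate(zip(reference, other))
            if a != b}


def report_dict(report: AccuracyReport) -> dict:
    """JSON-ready form; rates as percentages, denominators stated."""
    return {
        "region_bp": report.region_bp,
        "n_true": report.n_true, "n_called": report.n_called,
        "n_tp": report.n_tp, "n_fp": report.n_fp, "n_fn": report.n_fn,
        "fp_rate_pct_of_called": round(100 * report.fp_rate, 2),
        "fn_rate_pct_of_true": (round(100 * report.fn_rate, 2)
                                if report.fn_rate_defined else None),
        "bp_accuracy_pct": round(100 * report.bp_accuracy, 2),
        "denominators": "fp/called, fn/true, accuracy/region_bp",
    }
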