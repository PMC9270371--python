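"""Experimentally validated FDR and post-score-cutoff correction.

With a grouped ground-truth library the real error rate of a search-engine
result is directly measurable:

    FDR_validated = (# target XLs across peptides not within one group)
                    / (# target XLs total)

where "across peptides not within one group" covers both cross-group links
and links involving sequences never synthesized.  On CSM level every
spectrum match counts; on unique-link level every residue pair counts once.

Because engine-internal target-decoy estimates are often optimistic, the
module also finds the least strict score cutoff whose retained set reaches a
target validated FDR — the post-score-cutoff correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .library import PeptideLibrary, classify_pair
from .results import CrosslinkRecord

logger = logging.getLogger(__name__)

FALSE_LABELS = ("cross_group_false", "non_library_false")


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Display a fraction as a percentage, rounded half-up (2/425 → '0.5 %')."""
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(repr(fraction)) * 100).quantize(q, rounding=ROUND_HALF_UP)
    return f"{pct} %"


@dataclass
class ValidationResult:
    """Counts and experimentally validated FDR, overall and per link class."""

    level: str
    n_total: int
    n_within_group: int
    n_cross_group: int
    n_non_library: int
    per_class: dict[str, dict[str, int]]
    annotated: list[tuple[CrosslinkRecord, str, str | None]]

    @property
    def n_false(self) -> int:
        return self.n_cross_group + self.n_non_library

    @property
    def fdr(self) -> float:
        return self.n_false / self.n_total if self.n_total else 0.0

    @property
    def fdr_display(self) -> str:
        return format_percent(self.fdr)

    def to_frame(self):
        """Annotated record list as a DataFrame (same/different-group report)."""
        import pandas as pd

        rows = []
        for r, label, cls in self.annotated:
            rows.append({
                "sequence_a": r.seq_a, "sequence_b": r.seq_b,
                "protein_a": r.protein_a, "protein_b": r.protein_b,
                "score": r.score, "n_csms": r.n_csms,
                "truth": label, "link_class": cls or "",
            })
        return pd.DataFrame(rows)


def validated_fdr(
    records: Sequence[CrosslinkRecord],
    library: PeptideLibrary,
    level: str = "unique_link",
) -> ValidationResult:
    """Label every record against the library and compute the validated FDR.

    *records* must already be target-filtered; on ``csm`` level each spectrum
    match counts toward the totals, on ``unique_link`` level each residue
    pair counts once (group CSMs first with
    :func:`xlfdr.results.group_to_unique_links`).
    """
    annotated: list[tuple[CrosslinkRecord, str, str | None]] = []
    counts = {"within_group_true": 0, "cross_group_false": 0, "non_library_false": 0}
    per_class: dict[str, dict[str, int]] = {}
    for r in records:
        label, cls = classify_pair(r.seq_a, r.seq_b, library)
        annotated.append((r, label, cls))
        counts[label] += 1
        slot = per_class.setdefault(cls or "unknown", {
            "within_group_true": 0, "cross_group_false": 0, "non_library_false": 0})
        slot[label] += 1
    if not records:
        logger.warning("validated_fdr called on an empty record set; FDR defined as 0")
    return ValidationResult(
        level=level,
        n_total=len(records),
        n_within_group=counts["within_group_true"],
        n_cross_group=counts["cross_group_false"],
        n_non_library=counts["non_library_false"],
        per_class=per_class,
        annotated=annotated,
    )


def fdr_score_curve(
    records: Sequence[CrosslinkRecord],
    library: PeptideLibrary,
) -> list[tuple[float, int, float]]:
    """Validated FDR as a function of score threshold.

    One point ``(threshold, n_retained, fdr)`` per distinct normalized score,
    thresholds descending (strictest first), retained set = records with
    score >= threshold, so ``n_retained`` is non-decreasing along the curve.
    """
    labels = [classify_pair(r.seq_a, r.seq_b, library)[0] for r in records]
    order = sorted(range(len(records)), key=lambda i: -records[i].score)
    curve: list[tuple[float, int, float]] = []
    n_ret = n_false = 0
    i = 0
    while i < len(order):
        t = records[order[i]].score
        while i < len(order) and records[order[i]].score == t:
            n_ret += 1
            if labels[order[i]] in FALSE_LABELS:
                n_false += 1
            i += 1
        curve.append((t, n_ret, n_false / n_ret))
    return curve


@dataclass
class CutoffResult:
    """Outcome of the post-score-cutoff FDR correction.

    ``threshold`` is on the normalized higher-better scale, ties retained
    (records with score >= threshold survive).  An infeasible target yields
    an empty retained set with ``threshold = +inf``.
    """

    threshold: float
    n_retained: int
    achieved_fdr: float
    target_fdr: float
    retained: list[CrosslinkRecord]
    curve: list[tuple[float, int, float]]

    @property
    def feasible(self) -> bool:
        return self.n_retained > 0


def apply_score_cutoff(
    records: Sequence[CrosslinkRecord],
    library: PeptideLibrary,
    target_fdr: float,
) -> CutoffResult:
    """Least strict score threshold whose retained set meets *target_fdr*.

    Scans the validated-FDR curve from the least strict threshold upward and
    returns the first (= lowest, maximizing ``n_retained``) threshold where
    the validated FDR of ``{score >= threshold}`` is <= *target_fdr*.
    """
    if not (0 < target_fdr <= 1):
        raise ValueError(f"target_fdr must be in (0, 1], got {target_fdr}")
    curve = fdr_score_curve(records, library)
    for t, n_ret, fdr in reversed(curve):  # least strict first
        if fdr <= target_fdr:
            return CutoffResult(
                threshold=t,
                n_retained=n_ret,
                achieved_fdr=fdr,
                target_fdr=target_fdr,
                retained=[r for r in records if r.score >= t],
                curve=curve,
            )
    return CutoffResult(
        threshold=math.inf, n_retained=0, achieved_fdr=0.0,
        target_fdr=target_fdr, retained=[], curve=curve,
    )


def plot_fdr_curves(
    curve: Sequence[tuple[float, int, float]],
    path_prefix: str,
    target_fdr: float | None = None,
) -> list[str]:
    """Score-vs-FDR and score-vs-count graphs; returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thresholds = [p[0] for p in curve]
    counts = [p[1] for p in curve]
    fdrs = [100 * p[2] for p in curve]
    written = []
    for ys, ylabel, suffix in [(fdrs, "validated FDR [%]", "fdr"),
                               (counts, "retained IDs", "count")]:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(thresholds, ys, drawstyle="steps-post")
        if suffix == "fdr" and target_fdr is not None:
            ax.axhline(100 * target_fdr, ls="--", color="red", lw=0.8)
        ax.set_xlabel("score threshold (normalized)")
        ax.set_ylabel(ylabel)
        ax.invert_xaxis()
        fig.tight_layout()
        out = f"{path_prefix}_score_vs_{suffix}.png"
        fig.savefig(out, dpi=150)
        plt.close(fig)
        written.append(out)
    return written
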