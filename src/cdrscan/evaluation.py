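"""Classify dip calls against a truth set and compute precision / recall.

A truth interval is *correct* when some overlapping call covers it to
within a boundary tolerance at both ends, *partial* when a call overlaps
it but leaves a larger boundary deficit (the call could be extended on
one or both sides), and *missed* when nothing overlaps it.  A call is
*erroneous* when it overlaps no truth interval.  One call may credit
several truth intervals (matching the caller's merge behaviour); a strict
one-to-one matching mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io import CdrCall, GenomicInterval

DEFAULT_BOUNDARY_TOL = 5000  # one default-sized bin


@dataclass(frozen=True)
class EvalResult:
    n_truth: int
    n_calls: int
    correct: int
    partial: int
    missed: int
    erroneous: int
    precision: float | None
    recall: float | None


def _as_interval(call) -> GenomicInterval:
    if isinstance(call, CdrCall):
        return call.interval
    return call


def classify_calls(calls: Sequence[CdrCall | GenomicInterval],
                   truth: Sequence[GenomicInterval],
                   boundary_tol: int = DEFAULT_BOUNDARY_TOL,
                   one_to_one: bool = False) -> EvalResult:
    """Score *calls* against *truth* with an overlap/tolerance rule.

    With ``one_to_one`` each call credits at most one truth interval (the
    one it overlaps most), approximating a bipartite matching.  Precision
    and recall are ``None`` when their denominators are zero.
    """
    if boundary_tol < 0:
        raise ValueError("boundary_tol must be >= 0")
    call_ivs = [_as_interval(c) for c in calls]

    claimed: dict[int, int] = {}
    if one_to_one:
        for ci, civ in enumerate(call_ivs):
            best, best_ov = None, 0
            for ti, tiv in enumerate(truth):
                ov = min(civ.end, tiv.end) - max(civ.start, tiv.start)
                if civ.chrom == tiv.chrom and ov > best_ov:
                    best, best_ov = ti, ov
            if best is not None:
                claimed[ci] = best

    correct = partial = missed = 0
    for ti, tiv in enumerate(truth):
        overlapping = [
            ci for ci, civ in enumerate(call_ivs)
            if civ.overlaps(tiv)
            and (not one_to_one or claimed.get(ci) == ti)]
        if not overlapping:
            missed += 1
        elif any(call_ivs[ci].start <= tiv.start + boundary_tol
                 and call_ivs[ci].end >= tiv.end - boundary_tol
                 for ci in overlapping):
            correct += 1
        else:
            partial += 1

    erroneous = sum(
        1 for civ in call_ivs
        if not any(civ.overlaps(tiv) for tiv in truth))

    n_calls = len(call_ivs)
    n_truth = len(truth)
    precision = (n_calls - erroneous) / n_calls if n_calls > 0 else None
    recall = (correct + partial) / n_truth if n_truth > 0 else None
    return EvalResult(n_truth=n_truth, n_calls=n_calls, correct=correct,
                      partial=partial, missed=missed, erroneous=erroneous,
                      precision=precision, recall=recall)


def format_eval_summary(result: EvalResult) -> str:
    """Render an :class:`EvalResult` as a two-line TSV summary."""
    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.4f}"

    header = ["n_truth", "n_calls", "correct", "partial", "missed",
              "erroneous", "precision", "recall"]
    row = [str(result.n_truth), str(result.n_calls), str(result.correct),
           str(result.partial), str(result.missed), str(result.erroneous),
           fmt(result.precision), fmt(result.recall)]
    return "\t".join(header) + "\n" + "\t".join(row) + "\n"


__all__ = ["EvalResult", "classify_calls", "format_eval_summary",
           "DEFAULT_BOUNDARY_TOL"]
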