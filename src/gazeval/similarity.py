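"""Histogram-based similarity between two gaze-error datasets.

Two error sequences (e.g. from different trackers or operating
conditions) are binned onto shared equal-width edges, normalized to
probability vectors, and compared with three standard measures:

* Pearson correlation of the probability vectors, in [−1, 1];
* histogram intersection Σ min(pᵢ, qᵢ), in [0, 1];
* Bhattacharyya distance in the bounded Hellinger-affine form
  √(1 − BC) with BC = Σ √(pᵢ qᵢ), in [0, 1] (0 for identical
  histograms, 1 for disjoint supports).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ValidationError

__all__ = ["Histogram", "SimilarityReport", "build_histogram", "build_histograms", "compare_histograms"]


@dataclass
class Histogram:
    """A normalized histogram: B+1 strictly increasing edges, B probabilities."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.probabilities = np.asarray(self.probabilities, float)
        if self.bin_edges.ndim != 1 or self.bin_edges.size != self.probabilities.size + 1:
            raise ValidationError("need B+1 edges for B probabilities")
        if not (np.diff(self.bin_edges) > 0).all():
            raise ValidationError("bin edges must be strictly increasing")
        if (self.probabilities < 0).any():
            raise ValidationError("probabilities must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValidationError("probabilities must sum to 1")


@dataclass
class SimilarityReport:
    correlation: float
    intersection: float
    bhattacharyya_dist: float
    bhattacharyya_coef: float


def build_histogram(values, bin_edges) -> Histogram:
    """Bin *values* onto the given edges and normalize to sum 1."""
    counts, _ = np.histogram(np.asarray(values, float), bins=bin_edges)
    total = counts.sum()
    if total == 0:
        raise ValidationError("no values fall inside the bin range")
    return Histogram(np.asarray(bin_edges, float), counts / total)


def build_histograms(a, b, bins: int = 32) -> tuple[Histogram, Histogram]:
    """Histograms of two datasets on shared equal-width edges.

    The shared range spans the pooled minimum to maximum.  A degenerate
    range (all values identical) is an error; widen the range upstream.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both datasets must be nonempty")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if not hi > lo:
        raise ValidationError("degenerate range: all pooled values identical")
    edges = np.linspace(lo, hi, bins + 1)
    return build_histogram(a, edges), build_histogram(b, edges)


def compare_histograms(p: Histogram, q: Histogram) -> SimilarityReport:
    """Correlation, intersection and Bhattacharyya distance of two histograms.

    Both must share bin edges.  If one probability vector has zero
    variance (perfectly flat), the Pearson correlation is defined as 1
    when the vectors are equal and 0 otherwise.
    """
    if p.bin_edges.size != q.bin_edges.size or not np.allclose(
        p.bin_edges, q.bin_edges, atol=1e-12, rtol=0
    ):
        raise ValidationError("histograms must share bin edges")
    pv, qv = p.probabilities, q.probabilities
    if pv.std() == 0 or qv.std() == 0:
        corr = 1.0 if np.array_equal(pv, qv) else 0.0
    else:
        corr = float(np.corrcoef(pv, qv)[0, 1])
    intersection = float(np.minimum(pv, qv).sum())
    # 1 - BC = (1/2) sum (sqrt(p) - sqrt(q))^2 algebraically; this form is
    # exactly 0 for identical histograms instead of accumulating rounding.
    dist_sq = 0.5 * float(((np.sqrt(pv) - np.sqrt(qv)) ** 2).sum())
    dist = float(np.sqrt(min(max(dist_sq, 0.0), 1.0)))
    bc = 1.0 - dist_sq
    return SimilarityReport(corr, intersection, dist, bc)
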