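"""Summary-statistic sweep classifiers.

Implements the haplotype-based statistics the CNNs are compared against:

* Garud's H1 -- sum of squared distinct-haplotype frequencies; approaches
  1 when a single haplotype dominates the sample (sweep signature).
* S -- the number of segregating sites in the window; a sweep reduces
  diversity and hence S.  Watterson's theta is S over the harmonic number
  of (n - 1).
* iHS -- the log-ratio of integrated extended haplotype homozygosity (EHH)
  for ancestral- versus derived-allele cores, standardized within
  derived-allele-count bins learned from neutral simulations; the
  region-level score is the maximum |standardized iHS|.

All statistics operate on raw (filtered but not width-standardized)
haplotype matrices.  A scalar statistic becomes a classifier by fitting
the accuracy-optimal decision threshold on the training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .demography import HaplotypeMatrix

__all__ = [
    "StatResult",
    "ThresholdClassifier",
    "IhsStandardizer",
    "garud_h1",
    "segregating_sites",
    "watterson_theta",
    "ehh_decay",
    "ihs_scores",
    "standardize_and_summarize_ihs",
    "max_abs_ihs",
    "fit_threshold",
    "fit_ihs_standardizer",
]

EHH_TRUNCATION = 0.05
IHS_CORE_MAF_FLOOR = 0.05
MIN_BIN_COUNT = 20


class InputError(ValueError):
    pass


class FittingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scalar statistics
# ---------------------------------------------------------------------------


def garud_h1(m: HaplotypeMatrix) -> float:
    """Sum of squared haplotype frequencies, in [1/n, 1]."""
    if m.n_haplotypes == 0:
        raise InputError("empty matrix")
    if m.n_sites == 0:
        return 1.0  # all haplotypes identical (empty strings)
    _, counts = np.unique(m.alleles, axis=0, return_counts=True)
    p = counts / m.n_haplotypes
    return float(np.sum(p * p))


def segregating_sites(m: HaplotypeMatrix) -> int:
    """Number of columns carrying both alleles."""
    if m.n_sites == 0:
        return 0
    return int(m.segregating_mask().sum())


def harmonic_number(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def watterson_theta(s: int, n: int) -> float:
    """Watterson's estimator S / H_{n-1} (per region)."""
    if n < 2:
        raise InputError("need at least two haplotypes")
    if s < 0:
        raise InputError("negative site count")
    return s / harmonic_number(n - 1)


# ---------------------------------------------------------------------------
# EHH / iHS
# ---------------------------------------------------------------------------


def _ehh_curve(core_rows: np.ndarray, direction: int, focal: int) -> tuple[np.ndarray, np.ndarray]:
    """EHH values walking outward from the focal column (inclusive start).

    Returns (site_offsets, ehh) where offsets index columns in walk order;
    the first entry is the focal column itself (EHH = 1 by construction for
    haplotypes sharing the core allele).
    """
    n, n_sites = core_rows.shape
    if n < 2:
        return np.array([0]), np.array([1.0])
    pair_total = n * (n - 1) / 2
    cols = range(focal, n_sites) if direction > 0 else range(focal, -1, -1)
    group = np.zeros(n, dtype=np.int64)
    ehh_vals = []
    offsets = []
    n_groups = 1
    for k, col in enumerate(cols):
        # refine grouping by the allele at this column
        key = group * 2 + core_rows[:, col]
        _, group = np.unique(key, return_inverse=True)
        n_groups = group.max() + 1
        counts = np.bincount(group)
        hom = np.sum(counts * (counts - 1) / 2) / pair_total
        offsets.append(k)
        ehh_vals.append(hom)
        if hom < EHH_TRUNCATION:
            break
    return np.asarray(offsets), np.asarray(ehh_vals)


def ehh_decay(m: HaplotypeMatrix, focal: int, allele: int) -> dict:
    """EHH decay curves (left and right) for one core allele at a focal site."""
    carriers = m.alleles[:, focal] == allele
    rows = m.alleles[carriers]
    out = {}
    for name, direction in (("right", +1), ("left", -1)):
        off, vals = _ehh_curve(rows, direction, focal)
        idx = focal + direction * off
        out[name] = (m.positions[idx], vals)
    return out


def _ihh(m: HaplotypeMatrix, focal: int, allele: int) -> float:
    """Integrated EHH (trapezoid over bp) for one core allele, truncating
    where EHH drops below the truncation level or at the region edge."""
    curves = ehh_decay(m, focal, allele)
    total = 0.0
    for name in ("left", "right"):
        pos, vals = curves[name]
        if len(pos) > 1:
            total += abs(np.trapezoid(vals, pos))
    return total


def ihs_scores(m: HaplotypeMatrix, positions: np.ndarray | None = None) -> np.ndarray:
    """Unstandardized iHS per site: ln(iHH_ancestral / iHH_derived).

    Requires ancestral/derived (not major/minor) coding.  Sites whose core
    minor-allele frequency is below the floor, or whose iHH integrals are
    degenerate, are returned as NaN.
    """
    if m.n_sites < 2:
        raise InputError("need at least two sites for iHS")
    n = m.n_haplotypes
    freq = m.alleles.mean(axis=0)
    out = np.full(m.n_sites, np.nan)
    for j in range(m.n_sites):
        maf = min(freq[j], 1 - freq[j])
        if maf < IHS_CORE_MAF_FLOOR or maf == 0:
            continue
        ihh_a = _ihh(m, j, 0)
        ihh_d = _ihh(m, j, 1)
        if ihh_a <= 0 or ihh_d <= 0:
            continue
        out[j] = np.log(ihh_a / ihh_d)
    return out


@dataclass
class IhsStandardizer:
    """Per-derived-allele-count moments of unstandardized iHS.

    Fitted from neutral simulations of the matching demography; sparse bins
    (fewer than ``MIN_BIN_COUNT`` observations) are pooled with the nearest
    populated bin.
    """

    n_haplotypes: int
    mean: np.ndarray = field(default_factory=lambda: np.array([]))
    std: np.ndarray = field(default_factory=lambda: np.array([]))
    counts: np.ndarray = field(default_factory=lambda: np.array([]))

    def standardize(self, scores: np.ndarray, derived_counts: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        derived_counts = np.asarray(derived_counts, dtype=int)
        z = np.full_like(scores, np.nan, dtype=float)
        ok = ~np.isnan(scores)
        dc = derived_counts[ok]
        z[ok] = (scores[ok] - self.mean[dc]) / self.std[dc]
        return z


def fit_ihs_standardizer(
    neutral_matrices: Sequence[HaplotypeMatrix], n_haplotypes: int | None = None
) -> IhsStandardizer:
    """Learn per-bin mean/sd of iHS from neutral simulations (bins are
    derived allele counts 0..n)."""
    if not neutral_matrices:
        raise FittingError("no neutral simulations supplied")
    n = n_haplotypes or neutral_matrices[0].n_haplotypes
    values: list[list[float]] = [[] for _ in range(n + 1)]
    for m in neutral_matrices:
        scores = ihs_scores(m)
        dac = m.alleles.sum(axis=0)
        for v, c in zip(scores, dac):
            if not np.isnan(v):
                values[int(c)].append(v)
    mean = np.zeros(n + 1)
    std = np.ones(n + 1)
    counts = np.array([len(v) for v in values])
    populated = np.flatnonzero(counts >= MIN_BIN_COUNT)
    if populated.size == 0:
        raise FittingError("all standardization bins are sparse; simulate more data")
    for c in range(n + 1):
        source = c
        if counts[c] < MIN_BIN_COUNT:
            source = populated[np.argmin(np.abs(populated - c))]  # pool with nearest
        vals = np.asarray(values[source])
        mean[c] = vals.mean()
        std[c] = vals.std(ddof=1) if vals.size > 1 else 1.0
        if std[c] == 0:
            std[c] = 1.0
    return IhsStandardizer(n_haplotypes=n, mean=mean, std=std, counts=counts)


def standardize_and_summarize_ihs(
    scores: np.ndarray, derived_counts: np.ndarray, std: IhsStandardizer
) -> float:
    """Region-level score: max |standardized iHS| over non-missing sites
    (NaN when every site is missing)."""
    z = std.standardize(scores, derived_counts)
    if np.isnan(z).all():
        return float("nan")
    return float(np.nanmax(np.abs(z)))


def max_abs_ihs(m: HaplotypeMatrix, std: IhsStandardizer) -> float:
    """Convenience wrapper: compute, standardize and summarize iHS for one
    ancestral/derived-coded matrix."""
    scores = ihs_scores(m)
    return standardize_and_summarize_ihs(scores, m.alleles.sum(axis=0), std)


# ---------------------------------------------------------------------------
# Threshold classifiers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdClassifier:
    threshold: float
    direction: Literal["greater_is_sweep", "lesser_is_sweep"]
    train_accuracy: float

    def predict(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.direction == "greater_is_sweep":
            return (values > self.threshold).astype(np.int64)
        return (values < self.threshold).astype(np.int64)


@dataclass
class StatResult:
    """Per-sample values of one scalar statistic plus its fitted threshold."""

    method: str
    values: np.ndarray
    classifier: ThresholdClassifier | None = None

    @property
    def threshold(self) -> float | None:
        return None if self.classifier is None else self.classifier.threshold

    @property
    def direction(self) -> str | None:
        return None if self.classifier is None else self.classifier.direction


def fit_threshold(values: np.ndarray, labels: np.ndarray) -> ThresholdClassifier:
    """Accuracy-maximizing decision threshold on training data.

    Candidate thresholds are midpoints between adjacent sorted unique
    values (plus sentinels beyond the range); both decision directions are
    searched and ties are broken toward the smaller threshold with
    ``greater_is_sweep`` preferred.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape:
        raise FittingError("values / labels length mismatch")
    if len(np.unique(labels)) < 2:
        raise FittingError("both classes must be present to fit a threshold")
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.array([])
    candidates = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    best = None
    n = len(labels)
    for direction in ("greater_is_sweep", "lesser_is_sweep"):
        for thr in candidates:
            pred = (values > thr) if direction == "greater_is_sweep" else (values < thr)
            acc = np.count_nonzero(pred.astype(int) == labels) / n
            key = (acc, -thr)  # prefer higher accuracy, then smaller threshold
            if best is None or key > best[0]:
                best = (key, thr, direction, acc)
    _, thr, direction, acc = best
    return ThresholdClassifier(threshold=float(thr), direction=direction, train_accuracy=float(acc))


def evaluate_statistic(
    method: str,
    values: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
) -> StatResult:
    """Fit a threshold on the training subset only and wrap the result."""
    clf = fit_threshold(np.asarray(values)[train_idx], np.asarray(labels)[train_idx])
    return StatResult(method=method, values=np.asarray(values, dtype=float), classifier=clf)
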