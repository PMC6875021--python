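"""Agreement statistics for validating automated annulus measurements.

The validation battery mirrors standard interobserver-agreement practice:
Dice overlap between segmentations, paired differences with the two-sided
Wilcoxon signed-rank test, Pearson correlation, Shapiro-Wilk normality
check of the measurement distributions, Bland-Altman bias and limits of
agreement, and the exact-match ratio between the prosthesis sizes two
sources select.

The Wilcoxon implementation uses Pratt's treatment of zero differences and
average ranks for ties, with the exact permutation null (dynamic-programming
convolution over sign flips) for n <= 25 and a tie-corrected normal
approximation above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import BinaryMask, ValidationError
from .sizing import OUT_OF_RANGE_HIGH, OUT_OF_RANGE_LOW, DeviceSelection

__all__ = [
    "PairedSeries",
    "AgreementReport",
    "BlandAltman",
    "SizeAgreement",
    "CohortCase",
    "CohortReport",
    "dice",
    "paired_difference",
    "wilcoxon_signed_rank",
    "bland_altman",
    "pearson",
    "shapiro_wilk",
    "size_agreement",
    "evaluate_cohort",
]

#: Limits-of-agreement multiplier (95% under normality).
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedSeries:
    """Two matched measurement sequences (same cases, two sources)."""

    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, dtype=np.float64)
        b = np.asarray(self.values_b, dtype=np.float64)
        if a.ndim != 1 or b.ndim != 1 or len(a) != len(b):
            raise ValidationError("paired series must be equal-length 1-D sequences")
        if len(a) < 3:
            raise ValidationError(f"paired series needs >= 3 pairs, got {len(a)}")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ValidationError("paired series values must be finite")
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)

    def differences(self) -> np.ndarray:
        return self.values_a - self.values_b


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) between two same-shape binary masks."""
    av = a.values if isinstance(a, BinaryMask) else np.asarray(a)
    bv = b.values if isinstance(b, BinaryMask) else np.asarray(b)
    if av.shape != bv.shape:
        raise ValidationError(f"mask shape mismatch: {av.shape} vs {bv.shape}")
    av = av.astype(bool)
    bv = bv.astype(bool)
    denom = int(av.sum()) + int(bv.sum())
    if denom == 0:
        raise ValidationError("Dice undefined: both masks are empty")
    return 2.0 * int((av & bv).sum()) / denom


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pratt ranking: rank |d| including zeros, then drop the zeros."""
    ranks = sps.rankdata(np.abs(d))  # average ranks for ties
    nonzero = d != 0
    return ranks[nonzero], d[nonzero]


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over the 2^m sign-flip null, via DP convolution.

    Average ranks can be half-integers, so everything is doubled to count
    on an integer lattice.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: counts.size - r]
    n_outcomes = 2.0 ** len(ranks)
    w2 = int(np.rint(2.0 * w_plus))
    cdf = counts[: w2 + 1].sum() / n_outcomes
    sf = counts[w2:].sum() / n_outcomes
    return min(1.0, 2.0 * min(cdf, sf))


def _normal_two_sided_p(d: np.ndarray, ranks: np.ndarray, w_plus: float) -> float:
    """Tie- and zero-corrected normal approximation (Pratt)."""
    n = len(d)
    n_zero = int(np.sum(d == 0))
    mu = (n * (n + 1) - n_zero * (n_zero + 1)) / 4.0
    var = (n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
    _, tie_counts = np.unique(np.abs(d[d != 0]), return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:
        return 1.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def wilcoxon_signed_rank(d: np.ndarray, exact_max_n: int = 25) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test on a difference vector.

    Returns ``(W_plus, p_value, degenerate)``; ``degenerate`` is set when
    every difference is zero (p fixed at 1).
    """
    d = np.asarray(d, dtype=np.float64)
    if np.all(d == 0):
        return 0.0, 1.0, True
    ranks, d_nz = _signed_ranks(d)
    w_plus = float(ranks[d_nz > 0].sum())
    if len(d) <= exact_max_n:
        p = _exact_two_sided_p(ranks, w_plus)
    else:
        p = _normal_two_sided_p(d, ranks, w_plus)
    return w_plus, p, False


def paired_difference(series: PairedSeries) -> tuple[float, float, float, bool]:
    """Mean, sample SD (n-1 denominator) and Wilcoxon p of paired differences.

    Returns ``(mean_diff, sd_diff, wilcoxon_p, degenerate)``.
    """
    d = series.differences()
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    _, p, degenerate = wilcoxon_signed_rank(d)
    return mean, sd, p, degenerate


# ---------------------------------------------------------------------------
# Bland-Altman, Pearson, Shapiro-Wilk
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltman:
    """Bias and limits of agreement, plus the plotted pairs."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray
    diffs: np.ndarray


def bland_altman(series: PairedSeries) -> BlandAltman:
    """Per-pair mean vs difference summary: bias and bias +/- 1.96 sd."""
    d = series.differences()
    m = (series.values_a + series.values_b) / 2.0
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        means=m,
        diffs=d,
    )


def pearson(series: PairedSeries) -> float:
    """Product-moment correlation of the two series."""
    a, b = series.values_a, series.values_b
    if np.all(a == a[0]) or np.all(b == b[0]):
        raise ValidationError("Pearson correlation undefined for a constant series")
    return float(sps.pearsonr(a, b).statistic)


def shapiro_wilk(values: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality test (Royston AS R94 as in scipy)."""
    v = np.asarray(values, dtype=np.float64)
    if v.ndim != 1 or not 3 <= len(v) <= 5000:
        raise ValidationError(f"Shapiro-Wilk needs 3 <= n <= 5000 1-D values, got {v.shape}")
    if np.all(v == v[0]):
        raise ValidationError("Shapiro-Wilk undefined for constant input")
    res = sps.shapiro(v)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Device-size agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeAgreement:
    """Exact-match ratio and confusion table between two selection sequences."""

    ratio: float
    table: pd.DataFrame  # rows: label_a, cols: label_b, counts
    n_under: int  # a chose a smaller size than b
    n_over: int  # a chose a larger size than b


def _label_order(labels: set[str]) -> list[str]:
    sizes = sorted((l for l in labels if l not in (OUT_OF_RANGE_LOW, OUT_OF_RANGE_HIGH)),
                   key=float)
    out = []
    if OUT_OF_RANGE_LOW in labels:
        out.append(OUT_OF_RANGE_LOW)
    out.extend(sizes)
    if OUT_OF_RANGE_HIGH in labels:
        out.append(OUT_OF_RANGE_HIGH)
    return out


def size_agreement(
    selections_a: list[DeviceSelection], selections_b: list[DeviceSelection]
) -> SizeAgreement:
    """Fraction of exactly equal size labels, with the full confusion table.

    Under/over-estimation counts follow the label ordering (sentinels sort
    below/above every numeric size).
    """
    if len(selections_a) != len(selections_b):
        raise ValidationError("selection sequences must have equal length")
    if len(selections_a) == 0:
        raise ValidationError("selection sequences are empty")
    fam = {s.device_family for s in selections_a} | {s.device_family for s in selections_b}
    if len(fam) != 1:
        raise ValidationError(f"device family mismatch: {sorted(fam)}")

    la = [s.size_label for s in selections_a]
    lb = [s.size_label for s in selections_b]
    order = _label_order(set(la) | set(lb))
    rank = {label: i for i, label in enumerate(order)}
    table = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for x, y in zip(la, lb):
        table.loc[x, y] += 1
    n_agree = sum(x == y for x, y in zip(la, lb))
    n_under = sum(rank[x] < rank[y] for x, y in zip(la, lb))
    n_over = sum(rank[x] > rank[y] for x, y in zip(la, lb))
    return SizeAgreement(
        ratio=n_agree / len(la), table=table, n_under=n_under, n_over=n_over
    )


# ---------------------------------------------------------------------------
# Cohort evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for one measurement (area or perimeter)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    wilcoxon_p: float
    shapiro_p: float  # NaN when the differences are degenerate (all equal)
    n: int
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pearson_r": self.pearson_r,
            "wilcoxon_p": self.wilcoxon_p,
            "shapiro_p": self.shapiro_p,
            "n": self.n,
            "degenerate": self.degenerate,
        }


def agreement_report(series: PairedSeries) -> AgreementReport:
    """Compose paired-difference, Bland-Altman, Pearson and normality stats."""
    mean, sd, p, degenerate = paired_difference(series)
    ba = bland_altman(series)
    r = pearson(series)
    d = series.differences()
    if np.all(d == d[0]):
        shapiro_p = float("nan")
    else:
        _, shapiro_p = shapiro_wilk(d)
    return AgreementReport(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        pearson_r=r,
        wilcoxon_p=p,
        shapiro_p=shapiro_p,
        n=len(d),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class CohortCase:
    """Per-case evaluation inputs: measurement plus optional mask."""

    area: float
    perimeter: float
    mask: BinaryMask | None = None


@dataclass(frozen=True)
class CohortReport:
    """Machine-readable evaluation of a detection run against a reference."""

    area: AgreementReport
    perimeter: AgreementReport
    dice_mean: float | None
    dice_values: dict[str, float] | None
    sapien: SizeAgreement
    evolut: SizeAgreement
    case_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_cases": len(self.case_ids),
            "area": self.area.to_dict(),
            "perimeter": self.perimeter.to_dict(),
            "dice_mean": self.dice_mean,
            "sapien_agreement_ratio": self.sapien.ratio,
            "evolut_agreement_ratio": self.evolut.ratio,
        }


def evaluate_cohort(
    detections: dict[str, CohortCase],
    truths: dict[str, CohortCase],
    charts: tuple,
    label_a: str = "model",
    label_b: str = "reference",
) -> CohortReport:
    """Evaluate matched detection/reference cases: agreement on area,
    perimeter, Dice (when both sides carry masks) and both device sizings.

    Raises listing the unmatched case ids if the keys differ.
    """
    from .sizing import select_size  # local import to avoid cycle at module load

    unmatched = sorted(set(detections) ^ set(truths))
    if unmatched:
        raise ValidationError(f"unmatched case ids: {unmatched}")
    ids = tuple(sorted(detections))
    if len(ids) < 3:
        raise ValidationError("cohort evaluation needs >= 3 matched cases")
    sapien_chart, evolut_chart = charts

    areas_a = np.array([detections[i].area for i in ids])
    areas_b = np.array([truths[i].area for i in ids])
    perims_a = np.array([detections[i].perimeter for i in ids])
    perims_b = np.array([truths[i].perimeter for i in ids])

    area_rep = agreement_report(PairedSeries(areas_a, areas_b, label_a, label_b))
    perim_rep = agreement_report(PairedSeries(perims_a, perims_b, label_a, label_b))

    dice_values = None
    dice_mean = None
    if all(detections[i].mask is not None and truths[i].mask is not None for i in ids):
        dice_values = {i: dice(detections[i].mask, truths[i].mask) for i in ids}
        dice_mean = float(np.mean(list(dice_values.values())))

    sap = size_agreement(
        [select_size(a, sapien_chart) for a in areas_a],
        [select_size(a, sapien_chart) for a in areas_b],
    )
    evo = size_agreement(
        [select_size(p, evolut_chart) for p in perims_a],
        [select_size(p, evolut_chart) for p in perims_b],
    )
    return CohortReport(
        area=area_rep,
        perimeter=perim_rep,
        dice_mean=dice_mean,
        dice_values=dice_values,
        sapien=sap,
        evolut=evo,
        case_ids=ids,
    )
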