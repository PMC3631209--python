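"""Dosage calling from fluorescent capillary-electrophoresis peak areas.

Pipeline: parse a GeneMapper-style peak table, take each sample's
test-amplicon / control-amplicon area ratio, normalize it by the same
ratio measured on a pooled reference DNA run in parallel (correcting
amplification-efficiency bias between the two products), then standardize
against a normal-control cohort.  If the control normalized ratios are
compatible with a Gaussian (D'Agostino-Pearson omnibus test), ordinary
Z scores are used; otherwise robust pseudo-Z scores based on the median
and the IQR-derived pseudo standard deviation (IQR / 1.349).  Diagnostic
performance is summarized by empirical ROC analysis with Youden-index
threshold selection, and predictive values carry continuity-corrected
Wilson 95% confidence intervals.

Expected normalized ratios: ~1 for normal dosage, ~0.5 for a hemizygous
deletion, ~1.5 for an autosomal duplication, ~2 for a duplicated
hemizygous X in males.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from scipy import stats

from .primer_design import CandidateAssay

#: Gaussian quantile span of the interquartile range; IQR / 1.349 estimates sigma.
IQR_TO_SD = 1.349

#: Minimum cohort size for the normality test to be meaningful.
NORMALITY_MIN_N = 20


@dataclass(frozen=True)
class PeakRecord:
    sample_id: str
    size: float        # fragment size, bp (fractional: capillary sizing)
    height: float      # fluorescence units
    area: float        # fluorescence x bp
    dye: Optional[str] = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"peak size must be positive, got {self.size}")
        if self.area < 0:
            raise ValueError(f"peak area must be >= 0, got {self.area}")


@dataclass(frozen=True)
class SampleRatio:
    sample_id: str
    test_area: float
    control_area: float

    def __post_init__(self) -> None:
        if self.control_area <= 0:
            raise ValueError(f"{self.sample_id}: control area must be positive")

    @property
    def ratio(self) -> float:
        return self.test_area / self.control_area


@dataclass(frozen=True)
class NormalizedRatio:
    sample_id: str
    nr: float

    def __post_init__(self) -> None:
        if self.nr <= 0:
            raise ValueError(f"{self.sample_id}: normalized ratio must be positive")


@dataclass(frozen=True)
class CohortStats:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    k2: Optional[float] = None       # D'Agostino-Pearson omnibus statistic
    p_normal: Optional[float] = None

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def pseudo_sd(self) -> float:
        return self.iqr / IQR_TO_SD


@dataclass(frozen=True)
class Score:
    sample_id: str
    value: float
    method: str  # "Z" | "PZ"


@dataclass(frozen=True)
class DosageCall:
    sample_id: str
    call: str            # deletion | normal | duplication
    threshold: float
    score: float


@dataclass
class ROCResult:
    auc: float
    threshold: float      # in score units; see `direction` for its sense
    sensitivity: float    # percent, at `threshold`
    specificity: float    # percent, at `threshold`
    direction: str        # deletion (positives score low) | duplication (high)
    table: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class ProportionCI:
    percent: float
    lo: float
    hi: float


@dataclass(frozen=True)
class DiagnosticCIs:
    ppv: Optional[ProportionCI]
    npv: Optional[ProportionCI]
    fpr: Optional[ProportionCI]  # complement of PPV: P(false positive | positive call)
    fnr: Optional[ProportionCI]  # complement of NPV


# --------------------------------------------------------------------------
# peak table parsing and ratio extraction
# --------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("sample", "size", "height", "area")


def parse_peak_table(source: Union[str, TextIO]) -> list[PeakRecord]:
    """Parse a TSV peak table with (case-insensitive) Sample, Size, Height,
    Area columns and an optional Dye column.  ``#`` lines are comments.

    Rows whose Size or Area fail to parse are rejected with a warning
    naming the row number.
    """
    text = source if isinstance(source, str) else source.read()
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    colmap = {c.lower().strip(): c for c in df.columns}
    for required in _REQUIRED_COLUMNS:
        if required not in colmap:
            raise ValueError(f"peak table is missing required column {required.capitalize()!r}")
    records: list[PeakRecord] = []
    bad_rows: list[int] = []
    dye_col = colmap.get("dye")
    for idx, row in df.iterrows():
        try:
            size = float(row[colmap["size"]])
            height = float(row[colmap["height"]])
            area = float(row[colmap["area"]])
        except (TypeError, ValueError):
            bad_rows.append(idx + 2)  # 1-based, counting the header row
            continue
        records.append(
            PeakRecord(
                sample_id=str(row[colmap["sample"]]),
                size=size,
                height=height,
                area=area,
                dye=str(row[dye_col]) if dye_col is not None else None,
            )
        )
    if bad_rows:
        warnings.warn(f"rejected unparseable peak-table rows: {bad_rows}", stacklevel=2)
    return records


def assign_peaks(
    peaks: Sequence[PeakRecord],
    assay: CandidateAssay,
    tol: float = 1.0,
) -> tuple[list[SampleRatio], list[tuple[str, str]]]:
    """Per sample, pick the largest-area peak strictly within ``tol`` bp of
    each expected (tailed) amplicon size and form the test/control area ratio.

    Returns (ratios, uncallable) where ``uncallable`` lists samples missing
    either peak with a reason; they are reported, never silently dropped.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    test_size = assay.test_amplicon.size_tailed
    control_size = assay.control_amplicon.size_tailed
    by_sample: dict[str, list[PeakRecord]] = {}
    for p in peaks:
        by_sample.setdefault(p.sample_id, []).append(p)

    ratios: list[SampleRatio] = []
    uncallable: list[tuple[str, str]] = []
    for sample_id, sample_peaks in by_sample.items():
        picked = {}
        failed = None
        for role, center in (("test", test_size), ("control", control_size)):
            window = [p for p in sample_peaks if abs(p.size - center) < tol]
            if not window:
                failed = f"no peak within {tol} bp of {role} size {center}"
                break
            window.sort(key=lambda p: (-p.area, abs(p.size - center)))
            if (
                len(window) > 1
                and window[0].area == window[1].area
                and abs(window[0].size - center) == abs(window[1].size - center)
            ):
                raise ValueError(
                    f"{sample_id}: two equidistant equal-area peaks in the {role} window"
                )
            picked[role] = window[0]
        if failed is not None:
            uncallable.append((sample_id, failed))
            continue
        ratios.append(
            SampleRatio(
                sample_id=sample_id,
                test_area=picked["test"].area,
                control_area=picked["control"].area,
            )
        )
    return ratios, uncallable


def normalize(r_sample: SampleRatio, r_reference: float) -> NormalizedRatio:
    """Divide a sample's test/control ratio by the reference pool's ratio."""
    if r_reference <= 0:
        raise ValueError("reference ratio must be positive")
    return NormalizedRatio(sample_id=r_sample.sample_id, nr=r_sample.ratio / r_reference)


def reference_ratio(ratios: Sequence[SampleRatio], reference_id: str) -> float:
    """Reference-pool ratio; replicates are averaged (arithmetic mean)."""
    reps = [r.ratio for r in ratios if r.sample_id == reference_id]
    if not reps:
        raise ValueError(f"reference sample {reference_id!r} not found")
    return float(np.mean(reps))


def normalize_cohort(
    ratios: Sequence[SampleRatio], reference_id: str
) -> list[NormalizedRatio]:
    """Normalize every non-reference sample by the reference-pool ratio."""
    ref = reference_ratio(ratios, reference_id)
    return [normalize(r, ref) for r in ratios if r.sample_id != reference_id]


# --------------------------------------------------------------------------
# cohort statistics and scoring
# --------------------------------------------------------------------------

def cohort_stats(values: Sequence[float], alpha: float = 0.05) -> CohortStats:
    """Summary statistics of a control cohort; the normality test is run
    only when n is large enough for it to be valid."""
    arr = np.asarray(values, dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 values")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
    k2 = p = None
    if n >= NORMALITY_MIN_N and np.std(arr) > 0:
        k2, p = dagostino_pearson(arr)
    return CohortStats(
        n=n, mean=float(np.mean(arr)), sd=float(np.std(arr, ddof=1)),
        median=float(med), q1=float(q1), q3=float(q3),
        k2=k2, p_normal=p,
    )


def dagostino_pearson(values: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test.

    K2 = Z(skewness)^2 + Z(kurtosis)^2, referred to chi-square with 2 df.
    Requires n >= 20 (validity floor of the kurtosis transform).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < NORMALITY_MIN_N:
        raise ValueError(f"normality test requires n >= {NORMALITY_MIN_N}, got {arr.size}")
    if np.ptp(arr) == 0:
        raise ValueError("normality test undefined for a constant vector")
    k2, p = stats.normaltest(arr)
    return float(k2), float(p)


def z_scores(cohort: Sequence[float], x: float) -> float:
    """Standard Z score of ``x`` against the cohort mean and sample SD."""
    arr = np.asarray(cohort, dtype=float)
    if arr.size < 2:
        raise ValueError("cohort must have n >= 2")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        raise ValueError("cohort standard deviation is zero")
    return (x - float(np.mean(arr))) / sd


def pseudo_z(cohort: Sequence[float], x: float) -> float:
    """Robust pseudo-Z score: (x - median) / (IQR / 1.349).

    Quartiles use linear interpolation.  Insensitive to outliers and to
    the skew that rejects the Gaussian gate.
    """
    arr = np.asarray(cohort, dtype=float)
    if arr.size < 4:
        raise ValueError("pseudo-Z requires a cohort of n >= 4")
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    if iqr == 0:
        raise ValueError("cohort IQR is zero")
    return float((x - med) / (iqr / IQR_TO_SD))


def score_cohort(
    controls: Sequence[NormalizedRatio],
    samples: Sequence[NormalizedRatio],
    alpha: float = 0.05,
) -> tuple[list[Score], CohortStats]:
    """Score samples against the control cohort, choosing Z or pseudo-Z once.

    Z scores are used when the control normalized ratios pass the
    D'Agostino-Pearson gate at ``alpha``; pseudo-Z otherwise, and always
    for cohorts too small for the normality test.
    """
    ids = [c.sample_id for c in controls] + [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample id(s) across controls/samples: {dupes}")
    values = [c.nr for c in controls]
    cs = cohort_stats(values, alpha=alpha)
    if cs.p_normal is not None and cs.p_normal >= alpha:
        method = "Z"
        scorer = lambda x: z_scores(values, x)  # noqa: E731
    else:
        method = "PZ"
        scorer = lambda x: pseudo_z(values, x)  # noqa: E731
    scores = [Score(s.sample_id, scorer(s.nr), method) for s in samples]
    return scores, cs


# --------------------------------------------------------------------------
# ROC, predictive values, dosage calls
# --------------------------------------------------------------------------

def roc(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = "deletion",
) -> ROCResult:
    """Empirical ROC over all distinct score thresholds.

    ``labels`` mark affected samples.  For ``direction='deletion'`` the
    positive class lies below the threshold; for 'duplication', above.
    AUC is the trapezoidal area; the operating threshold maximizes the
    Youden index J = sens + spec - 1, ties broken toward higher
    specificity.  The returned threshold is in score units with strict
    inequality semantics matching :func:`call_dosage`.
    """
    if direction not in ("deletion", "duplication"):
        raise ValueError("direction must be 'deletion' or 'duplication'")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    # orient so that affected samples have HIGH x
    x = -s if direction == "deletion" else s
    order = np.sort(np.unique(x))
    # candidate cuts: below all, between consecutive distinct values, above all
    mids = (order[:-1] + order[1:]) / 2 if order.size > 1 else np.array([])
    cuts = np.concatenate(([order[0] - 1.0], mids, [order[-1] + 1.0]))
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    sens = np.array([np.mean(x[y] > t) for t in cuts])
    spec = np.array([np.mean(x[~y] <= t) for t in cuts])
    # AUC by trapezoid over the empirical curve
    fpr = 1 - spec
    idx = np.lexsort((sens, fpr))  # ties in FPR ordered by ascending TPR
    auc = float(np.trapezoid(sens[idx], fpr[idx]))
    j = sens + spec - 1
    best = np.lexsort((-spec, -j))[0]  # max J, ties -> higher specificity
    t = float(cuts[best])
    threshold = -t if direction == "deletion" else t
    table = pd.DataFrame(
        {
            "threshold": -cuts if direction == "deletion" else cuts,
            "sensitivity_pct": sens * 100,
            "specificity_pct": spec * 100,
            "youden_j": j,
        }
    )
    return ROCResult(
        auc=auc,
        threshold=threshold,
        sensitivity=float(sens[best] * 100),
        specificity=float(spec[best] * 100),
        direction=direction,
        table=table,
    )


def wilson_cc(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Continuity-corrected Wilson score interval for a binomial proportion.

    Bounds are clipped to [0, 1]; the interval always contains x/n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    z = stats.norm.ppf(1 - (1 - conf) / 2)
    p = x / n
    denom = 2 * (n + z * z)
    if x == 0:
        lo = 0.0
    else:
        lo = (2 * n * p + z * z - 1 - z * math.sqrt(
            z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1)
        )) / denom
    if x == n:
        hi = 1.0
    else:
        hi = (2 * n * p + z * z + 1 + z * math.sqrt(
            z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1)
        )) / denom
    return max(0.0, lo), min(1.0, hi)


def _proportion_ci(x: int, n: int, conf: float) -> ProportionCI:
    lo, hi = wilson_cc(x, n, conf)
    return ProportionCI(percent=100 * x / n, lo=100 * lo, hi=100 * hi)


def diagnostic_cis(tp: int, fp: int, tn: int, fn: int, conf: float = 0.95) -> DiagnosticCIs:
    """Predictive values with continuity-corrected Wilson confidence intervals.

    PPV = tp / (tp + fp) and NPV = tn / (tn + fn); the false-positive and
    false-negative estimates are their complements.  A field whose
    denominator is zero is reported absent (None).
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    npos = tp + fp
    nneg = tn + fn
    ppv = _proportion_ci(tp, npos, conf) if npos >= 1 else None
    fpr = _proportion_ci(fp, npos, conf) if npos >= 1 else None
    npv = _proportion_ci(tn, nneg, conf) if nneg >= 1 else None
    fnr = _proportion_ci(fn, nneg, conf) if nneg >= 1 else None
    return DiagnosticCIs(ppv=ppv, npv=npv, fpr=fpr, fnr=fnr)


def call_dosage(
    scores: Sequence[Score], threshold: float, direction: str = "deletion"
) -> list[DosageCall]:
    """Classify each scored sample (strict inequality; at-threshold is normal).

    Deletion direction: deletion iff score < threshold.
    Duplication direction: duplication iff score > threshold.
    """
    if direction not in ("deletion", "duplication"):
        raise ValueError("direction must be 'deletion' or 'duplication'")
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    calls = []
    for s in scores:
        if direction == "deletion":
            call = "deletion" if s.value < threshold else "normal"
        else:
            call = "duplication" if s.value > threshold else "normal"
        calls.append(DosageCall(sample_id=s.sample_id, call=call, threshold=threshold, score=s.value))
    return calls


def calls_to_tsv(
    calls: Sequence[DosageCall],
    nrs: Optional[dict[str, float]] = None,
    method: str = "",
) -> str:
    lines = ["sample\tnr\tscore\tmethod\tcall\tthreshold"]
    for c in calls:
        nr = f"{nrs[c.sample_id]:.4f}" if nrs and c.sample_id in nrs else "NA"
        lines.append(
            f"{c.sample_id}\t{nr}\t{c.score:.4f}\t{method}\t{c.call}\t{c.threshold:g}"
        )
    return "\n".join(lines) + "\n"
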