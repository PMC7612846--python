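"""Statistical machinery for atlas QC, validation and group comparison.

Contents:

* movement/distortion QC score (z-normalised metrics -> per-subject RMS,
  1-SD rejection rule)
* repeated-measures correlation (ANCOVA with per-unit intercepts and a
  common slope; r is the correlation between residuals)
* Fisher z-transform and bootstrap confidence intervals for differences of
  z-transformed correlations: percentile bootstrap resampling whole units,
  and a moving-block bootstrap for spatially dependent slice series
* paired t-test on peak Dice scores
* Mann-Whitney U per tract with Bonferroni correction

The repeated-measures correlation removes between-unit variation: with
records (unit, x, y), x and y are centred within unit and

    r = sum(xc*yc) / sqrt(sum(xc^2) * sum(yc^2)),   df = N - k - 1

for N records and k units, which is exactly the ANCOVA estimator (the
common-slope sum of squares over effect-plus-error), signed by the slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DegenerateDataError",
    "CorrelationResult",
    "ZDiffResult",
    "QCRecord",
    "GroupComparisonResult",
    "qc_scores",
    "qc_table",
    "rm_corr",
    "fisher_z",
    "zdiff_ci_percentile",
    "zdiff_ci_moving_block",
    "paired_t_peak_dice",
    "mannwhitney_tracts",
    "DEFAULT_N_BOOT",
    "DEFAULT_ALPHA",
]

DEFAULT_N_BOOT = 2000
DEFAULT_ALPHA = 0.05


class DegenerateDataError(ValueError):
    """Raised when data carry no within-unit variance (or similar degeneracy)."""


# ---------------------------------------------------------------------------
# QC score
# ---------------------------------------------------------------------------

@dataclass
class QCRecord:
    subject: str
    metrics: np.ndarray
    score: float
    rejected: bool


def qc_scores(metrics: pd.DataFrame) -> list[QCRecord]:
    """Per-subject movement/distortion score with 1-SD rejection.

    Each metric column is z-normalised across subjects (zero-variance columns
    are set to 0), the score is the RMS of the normalised metrics, and a
    subject is rejected iff its score exceeds mean + 1 SD of all scores.

    ``metrics`` is indexed by subject (or carries a 'subject' column) with
    one numeric column per QC metric.
    """
    df = metrics.copy()
    if "subject" in df.columns:
        df = df.set_index("subject")
    if df.shape[0] < 3:
        raise ValueError("QC needs at least 3 subjects")
    if df.shape[1] < 1:
        raise ValueError("QC needs at least 1 metric")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or not np.all(np.isfinite(vals)):
        raise ValueError("QC metric table must be numeric and finite")
    sd = vals.std(axis=0, ddof=1)
    mean = vals.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[:, sd == 0.0] = 0.0
    scores = np.sqrt((z ** 2).mean(axis=1))
    cutoff = scores.mean() + scores.std(ddof=1)
    return [
        QCRecord(subject=str(s), metrics=vals[i], score=float(scores[i]),
                 rejected=bool(scores[i] > cutoff))
        for i, s in enumerate(df.index)
    ]


def qc_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """:func:`qc_scores` as a tidy frame (subject, score, rejected)."""
    recs = qc_scores(metrics)
    return pd.DataFrame(
        {"subject": [r.subject for r in recs],
         "score": [r.score for r in recs],
         "rejected": [r.rejected for r in recs]}
    )


# ---------------------------------------------------------------------------
# Repeated-measures correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    df: int
    p: float
    m: float  # pooled OLS slope over all records (as plotted)
    c: float  # pooled OLS intercept
    n_records: int
    n_units: int


def _validate_rm(subjects, x, y):
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (subjects.shape == x.shape == y.shape) or x.ndim != 1:
        raise ValueError("subjects, x, y must be 1-D and aligned")
    units, codes = np.unique(subjects, return_inverse=True)
    if units.size < 2:
        raise ValueError("repeated-measures correlation needs >= 2 units")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError("every unit needs >= 2 records")
    return codes, units.size, x, y


def _center_within(v: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    means = np.bincount(codes, weights=v, minlength=k) / np.bincount(codes, minlength=k)
    return v - means[codes]


def rm_corr(subjects, x, y) -> CorrelationResult:
    """Repeated-measures correlation of y on x with unit-specific intercepts.

    Returns r (signed by the common slope), df = N - k - 1, the two-sided p
    from the t distribution, and the pooled ordinary-least-squares line
    (m, c) fitted to all records.
    """
    codes, k, x, y = _validate_rm(subjects, x, y)
    xc = _center_within(x, codes, k)
    yc = _center_within(y, codes, k)
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx <= 0.0 or syy <= 0.0:
        raise DegenerateDataError("zero within-unit variance in x or y")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    n = x.size
    df = n - k - 1
    if df <= 0:
        raise ValueError("not enough records for the residual df")
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = abs(r) * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(t, df)
    m, c = np.polyfit(x, y, 1)
    return CorrelationResult(r=r, df=df, p=float(p), m=float(m), c=float(c),
                             n_records=n, n_units=k)


def fisher_z(r: float) -> float:
    """Variance-stabilising z-transform atanh(r); |r| must be < 1."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"fisher_z requires |r| < 1, got {r}")
    return math.atanh(r)


# ---------------------------------------------------------------------------
# Bootstrap comparison of two dependent correlations
# ---------------------------------------------------------------------------

@dataclass
class ZDiffResult:
    delta_z: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    method: str
    r1: float
    r2: float
    n_dropped: int = 0


def _as_rect(subjects, *cols):
    """Stack aligned per-unit record arrays into (n_units, n_records) matrices.

    Requires a balanced design (equal records per unit), which is how both
    the whole-tract analysis (subjects x tracts) and the slice-wise analysis
    (subjects x common slice range) arrive here. Records keep their input
    order within each unit.
    """
    subjects = np.asarray(subjects)
    units = pd.unique(subjects)
    rows = [np.nonzero(subjects == u)[0] for u in units]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires a balanced design (equal records per unit)")
    idx = np.stack(rows)
    return [np.asarray(c, dtype=float)[idx] for c in cols]


def _rect_r(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Repeated-measures r for stacked replicates.

    X, Y have shape (..., n_units, n_records); unit means are removed along
    the record axis and r is pooled over units. Degenerate replicates yield
    NaN rather than raising.
    """
    Xc = X - X.mean(axis=-1, keepdims=True)
    Yc = Y - Y.mean(axis=-1, keepdims=True)
    sxy = (Xc * Yc).sum(axis=(-2, -1))
    sxx = (Xc * Xc).sum(axis=(-2, -1))
    syy = (Yc * Yc).sum(axis=(-2, -1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = sxy / np.sqrt(sxx * syy)
    return np.where((sxx > 0) & (syy > 0), r, np.nan)


def _finish_boot(delta: np.ndarray, delta_hat: float, r1: float, r2: float,
                 n_boot: int, alpha: float, seed: int, method: str) -> ZDiffResult:
    valid = delta[np.isfinite(delta)]
    n_dropped = n_boot - valid.size
    if n_dropped > 0.1 * n_boot:
        raise DegenerateDataError(
            f"{n_dropped}/{n_boot} bootstrap replicates degenerate")
    lo, hi = np.percentile(valid, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return ZDiffResult(delta_z=delta_hat, ci_low=float(lo), ci_high=float(hi),
                       n_boot=n_boot, seed=seed, method=method,
                       r1=r1, r2=r2, n_dropped=int(n_dropped))


def zdiff_ci_percentile(subjects, x, y1, y2, n_boot: int = DEFAULT_N_BOOT,
                        alpha: float = DEFAULT_ALPHA, seed: int = 0) -> ZDiffResult:
    """Percentile-bootstrap CI for z(r1) - z(r2) of two dependent correlations.

    x holds the gold-standard measurements, y1 and y2 the two atlas
    measurements of the same records. Units (subjects) are resampled with
    replacement — records within a subject move together — and both
    repeated-measures correlations are recomputed per replicate. Replicates
    with degenerate data (or |r| = 1) are dropped; more than 10% dropped is
    an error.
    """
    res1 = rm_corr(subjects, x, y1)
    res2 = rm_corr(subjects, x, y2)
    delta_hat = fisher_z(res1.r) - fisher_z(res2.r)
    X, Y1, Y2 = _as_rect(subjects, x, y1, y2)
    U = X.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, U, size=(n_boot, U))
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.arctanh(_rect_r(X[idx], Y1[idx])) - np.arctanh(_rect_r(X[idx], Y2[idx]))
    return _finish_boot(delta, delta_hat, res1.r, res2.r, n_boot, alpha, seed,
                        "iid")


def zdiff_ci_moving_block(subjects, x, y1, y2, block_len: int | None = None,
                          n_boot: int = DEFAULT_N_BOOT, alpha: float = DEFAULT_ALPHA,
                          seed: int = 0) -> ZDiffResult:
    """Moving-block bootstrap CI for z(r1) - z(r2) on ordered slice series.

    Records within each unit must be ordered by slice index. Within every
    unit, overlapping blocks of ``block_len`` consecutive slices are drawn
    with replacement, concatenated and truncated to the series length; the
    same block draw is applied to x, y1 and y2 so their pairing is kept.
    Default block length is ceil(sqrt(L)) of the series length.
    """
    res1 = rm_corr(subjects, x, y1)
    res2 = rm_corr(subjects, x, y2)
    delta_hat = fisher_z(res1.r) - fisher_z(res2.r)
    X, Y1, Y2 = _as_rect(subjects, x, y1, y2)
    U, L = X.shape
    if block_len is None:
        block_len = int(math.ceil(math.sqrt(L)))
    if not 1 <= block_len <= L:
        raise ValueError(f"block_len must be in [1, {L}], got {block_len}")
    n_blocks = int(math.ceil(L / block_len))
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, L - block_len + 1, size=(n_boot, U, n_blocks))
    pos = (starts[..., None] + np.arange(block_len)).reshape(n_boot, U, -1)[..., :L]
    urow = np.arange(U)[None, :, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = (np.arctanh(_rect_r(X[urow, pos], Y1[urow, pos]))
                 - np.arctanh(_rect_r(X[urow, pos], Y2[urow, pos])))
    return _finish_boot(delta, delta_hat, res1.r, res2.r, n_boot, alpha, seed,
                        "moving_block")


# ---------------------------------------------------------------------------
# Peak-Dice paired test and tract-wise group comparison
# ---------------------------------------------------------------------------

def paired_t_peak_dice(peaks_a: pd.DataFrame, peaks_b: pd.DataFrame) -> pd.DataFrame:
    """Two-tailed paired t-test per tract comparing peak Dice scores.

    Inputs are subject-by-tract frames with matching index and columns (one
    row per subject, one column per tract). Returns a frame (tract, t, p).
    """
    if list(peaks_a.columns) != list(peaks_b.columns):
        raise ValueError("tract columns must match")
    b = peaks_b.loc[peaks_a.index]  # pair by subject
    rows = []
    for tract in peaks_a.columns:
        d = peaks_a[tract].to_numpy(dtype=float) - b[tract].to_numpy(dtype=float)
        if d.size < 2:
            raise ValueError("paired t-test needs >= 2 pairs")
        if np.allclose(d, d[0]) and np.isclose(d.std(ddof=1), 0.0):
            raise DegenerateDataError(f"zero-variance differences for {tract}")
        t, p = sps.ttest_rel(peaks_a[tract].to_numpy(dtype=float),
                             b[tract].to_numpy(dtype=float))
        rows.append({"tract": tract, "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class GroupComparisonResult:
    tract: str
    U: float
    p_raw: float
    p_corrected: float
    significant: bool


def _mw_two_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.all(a == a[0]) and np.all(b == a[0]):
        # no information at all: U at its mean, p = 1
        return float(len(a) * len(b) / 2.0), 1.0
    combined = np.concatenate([a, b])
    ties = np.unique(combined).size < combined.size
    method = "exact" if (min(len(a), len(b)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mannwhitney_tracts(case_fa: pd.DataFrame, control_fa: pd.DataFrame,
                       m_tests: int | None = None,
                       alpha: float = DEFAULT_ALPHA) -> list[GroupComparisonResult]:
    """Two-sided Mann-Whitney U per tract with Bonferroni correction.

    Inputs are subject-by-tract frames of whole-tract FA for cases and
    controls. The exact null distribution is used for small, tie-free groups
    (min group size <= 8); otherwise the tie-corrected normal approximation.
    Bonferroni m defaults to the number of tract tests actually run;
    significance is corrected p < ``alpha``.
    """
    if list(case_fa.columns) != list(control_fa.columns):
        raise ValueError("tract columns must match")
    tracts = list(case_fa.columns)
    m = m_tests if m_tests is not None else len(tracts)
    out = []
    for tract in tracts:
        a = case_fa[tract].dropna().to_numpy(dtype=float)
        b = control_fa[tract].dropna().to_numpy(dtype=float)
        if len(a) < 1 or len(b) < 1:
            raise ValueError(f"need >= 1 subject per group for {tract}")
        U, p = _mw_two_sided(a, b)
        p_corr = min(1.0, m * p)
        out.append(GroupComparisonResult(tract=tract, U=U, p_raw=p,
                                         p_corrected=p_corr,
                                         significant=p_corr < alpha))
    return out
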