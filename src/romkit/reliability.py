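"""Test-retest and inter-device reliability of ROM measurements.

The reliability index is the intraclass correlation coefficient from a
two-way mixed-effects ANOVA of subjects x repeated measurements, in its
consistency form (fixed offsets between measurements do not count against
reliability).  With MSR the between-subject mean square, MSE the residual
mean square, n subjects and k measurements:

    ICC(3,1)  = (MSR - MSE) / (MSR + (k - 1) MSE)     single measurement
    ICC(3,k)  = (MSR - MSE) / MSR                     average of k

Confidence intervals follow the F-based construction: with
F = MSR/MSE on (n - 1, (n - 1)(k - 1)) degrees of freedom,
FL = F / F_{1-a/2} and FU = F * F_{1-a/2} (swapped df), transformed to the
chosen ICC form.

From the ICC, two error quantities in the measurement's own units:

    SEM = sqrt(sigma_T^2 * (1 - ICC))      standard error of measurement
    MDC = z_95% * sqrt(2) * SEM            minimal detectable change

where sigma_T^2 is the total variance of the measurement matrix and
z_95% = 1.959964.  The MDC is the smallest change distinguishable from
measurement error at 95% confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: ICC interpretation bands (upper edges, half-open bins; the last bin is
#: closed at 1).  Negative ICCs fall in the lowest band.
ICC_BANDS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost_perfect"),
)

ICC_FORMS = ("average_k", "single")
INTER_PAIRINGS = ("device_mean", "trial_index")


class ReliabilityError(ValueError):
    pass


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    form: str
    n: int
    k: int
    msr: float
    msc: float
    mse: float
    degenerate: bool = False


@dataclass
class ReliabilityReport:
    """One Table-style reliability row: movement x mode."""

    movement: str
    mode: str                  # intra_pose33 | intra_mocap39 | inter_device
    icc: float
    ci95: tuple[float, float]
    sem: float
    mdc: float
    band: str
    n_subjects: int
    k_measurements: int
    n_dropped: int = 0


@dataclass
class RegressionResult:
    movement: str
    slope: float
    intercept: float
    r2: float
    n: int


# ---------------------------------------------------------------------------
# measurement matrices
# ---------------------------------------------------------------------------

def matrix_from_long(
    df: pd.DataFrame,
    rows: str = "subject",
    cols: str = "trial",
    values: str = "rom",
) -> tuple[np.ndarray, int]:
    """Pivot a long ROM table into a complete-case subjects x k matrix.

    Returns ``(matrix, n_dropped)`` where ``n_dropped`` counts subjects
    removed for having any missing cell.
    """
    wide = df.pivot_table(index=rows, columns=cols, values=values, aggfunc="mean")
    complete = wide.dropna()
    return complete.to_numpy(float), int(len(wide) - len(complete))


def _anova_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((m - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way_mixed(
    m: np.ndarray, form: str = "average_k", alpha: float = 0.05
) -> ICCResult:
    """Two-way mixed-effects consistency ICC with an F-based CI.

    ``m`` is a complete subjects x measurements matrix (n >= 2, k >= 2).
    ``form="average_k"`` rates the mean of the k measurements (ICC(3,k));
    ``"single"`` rates one measurement (ICC(3,1)).  Zero between-subject
    variance is degenerate: the ICC is reported as 0 with a flag.
    """
    m = np.asarray(m, float)
    if m.ndim != 2:
        raise ReliabilityError("measurement matrix must be 2-D")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ReliabilityError(f"need >= 2 subjects and >= 2 measurements, got {m.shape}")
    if np.isnan(m).any():
        raise ReliabilityError("matrix has missing cells; use matrix_from_long")
    if form not in ICC_FORMS:
        raise ReliabilityError(f"unknown ICC form {form!r}")
    msr, msc, mse = _anova_mean_squares(m)
    if msr <= 0 or np.isclose(msr, 0.0):
        logger.warning("zero between-subject variance; ICC degenerate")
        return ICCResult(0.0, (0.0, 0.0), form, n, k, msr, msc, mse, degenerate=True)
    if mse == 0:
        icc = 1.0
        return ICCResult(icc, (1.0, 1.0), form, n, k, msr, msc, mse)
    if form == "single":
        icc = (msr - mse) / (msr + (k - 1) * mse)
    else:
        icc = (msr - mse) / msr
    icc = min(icc, 1.0)  # guard against float drift when mse ~ 0
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f0 = msr / mse
    fl = f0 / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = f0 * stats.f.ppf(1 - alpha / 2, df2, df1)
    if form == "single":
        ci = ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))
    else:
        ci = (1 - 1 / fl, 1 - 1 / fu)
    return ICCResult(float(icc), (float(ci[0]), float(ci[1])), form, n, k, msr, msc, mse)


# ---------------------------------------------------------------------------
# SEM / MDC / interpretation
# ---------------------------------------------------------------------------

def sem_from_icc(icc: float, total_variance: float) -> float:
    """Standard error of measurement: sqrt(sigma_T^2 * (1 - ICC))."""
    if total_variance < 0:
        raise ReliabilityError("total variance must be non-negative")
    if icc > 1:
        raise ReliabilityError(f"ICC cannot exceed 1, got {icc}")
    return float(np.sqrt(total_variance * (1.0 - icc)))


#: two-sided 95% normal quantile, as used in the MDC formula
Z_95 = float(stats.norm.ppf(0.975))


def mdc_from_sem(sem: float, confidence: float = 0.95) -> float:
    """Minimal detectable change: z * sqrt(2) * SEM.

    With the default 95% confidence, MDC = 2.771808 * SEM.
    """
    if sem < 0:
        raise ReliabilityError("SEM must be non-negative")
    z = float(stats.norm.ppf(0.5 + confidence / 2.0))
    return z * np.sqrt(2.0) * sem


def interpret_icc(icc: float) -> str:
    """Map an ICC to its interpretation band.

    Half-open bins [0, 0.2), [0.2, 0.4), [0.4, 0.6), [0.6, 0.8), [0.8, 1];
    boundary values go to the upper band; negative values are 'slight'.
    """
    if icc < 0:
        return "slight"
    for upper, band in ICC_BANDS:
        if icc < upper:
            return band
    return "almost_perfect"


# ---------------------------------------------------------------------------
# regression between devices
# ---------------------------------------------------------------------------

def device_regression(
    x: np.ndarray, y: np.ndarray, movement: str = ""
) -> RegressionResult:
    """OLS of webcam-derived ROM (y) on mocap-derived ROM (x, predictor)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ReliabilityError("x and y must be paired 1-D series")
    if len(x) < 3:
        raise ReliabilityError("need at least 3 paired observations")
    if np.var(x) == 0:
        raise ReliabilityError("zero variance in predictor")
    if np.var(y) == 0:  # flat response: r is 0/0 in the closed form
        return RegressionResult(
            movement=movement, slope=0.0, intercept=float(y.mean()),
            r2=0.0, n=len(x),
        )
    fit = stats.linregress(x, y)
    return RegressionResult(
        movement=movement,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# the full report
# ---------------------------------------------------------------------------

def reliability_report(
    rom_table: pd.DataFrame,
    icc_form: str = "average_k",
    inter_pairing: str = "device_mean",
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-movement reliability rows from a long ROM table.

    ``rom_table`` needs columns subject, movement, device, trial, rom (a
    ``usable`` column, when present, restricts to usable rows).  For each
    movement: one intra-device row per device (subjects x trials) and, when
    two devices are present, one inter-device row.  ``inter_pairing``
    "device_mean" averages trials within device before pairing (k = 2);
    "trial_index" pairs trial-by-trial (k = 2 x n_trials).

    sigma_T^2 for the SEM is the population variance of all cells of the
    movement's measurement matrix.  Movements with fewer than 2 complete
    subjects are skipped with a log entry.
    """
    if icc_form not in ICC_FORMS:
        raise ReliabilityError(f"unknown ICC form {icc_form!r}")
    if inter_pairing not in INTER_PAIRINGS:
        raise ReliabilityError(f"unknown inter-device pairing {inter_pairing!r}")
    df = rom_table.copy()
    if "usable" in df.columns:
        df = df[df["usable"].astype(bool)]
    rows = []
    for movement, sub in df.groupby("movement", sort=True):
        devices = sorted(sub["device"].unique())
        for device in devices:
            m, dropped = matrix_from_long(sub[sub["device"] == device])
            rows.extend(
                _report_rows(movement, f"intra_{device}", m, dropped,
                             icc_form, confidence)
            )
        if len(devices) == 2:
            m, dropped = _inter_matrix(sub, devices, inter_pairing)
            rows.extend(
                _report_rows(movement, "inter_device", m, dropped,
                             icc_form, confidence)
            )
    out = pd.DataFrame(
        [r.__dict__ | {"ci_lo": r.ci95[0], "ci_hi": r.ci95[1]} for r in rows],
        columns=["movement", "mode", "icc", "ci95", "ci_lo", "ci_hi", "sem",
                 "mdc", "band", "n_subjects", "k_measurements", "n_dropped"],
    )
    return out.drop(columns=["ci95"])


def _inter_matrix(
    sub: pd.DataFrame, devices: list[str], pairing: str
) -> tuple[np.ndarray, int]:
    if pairing == "device_mean":
        return matrix_from_long(sub, rows="subject", cols="device")
    wide = sub.pivot_table(
        index="subject", columns=["device", "trial"], values="rom", aggfunc="mean"
    )
    complete = wide.dropna()
    return complete.to_numpy(float), int(len(wide) - len(complete))


def _report_rows(
    movement: str, mode: str, m: np.ndarray, dropped: int,
    icc_form: str, confidence: float,
) -> list[ReliabilityReport]:
    if m.size == 0 or m.shape[0] < 2 or m.shape[1] < 2:
        logger.warning("%s / %s: insufficient data, skipped", movement, mode)
        return []
    res = icc_two_way_mixed(m, form=icc_form)
    total_var = float(np.var(m))  # population variance of all cells
    sem = sem_from_icc(res.icc, total_var)
    mdc = mdc_from_sem(sem, confidence)
    return [
        ReliabilityReport(
            movement=movement, mode=mode, icc=res.icc, ci95=res.ci95,
            sem=sem, mdc=mdc, band=interpret_icc(res.icc),
            n_subjects=res.n, k_measurements=res.k, n_dropped=dropped,
        )
    ]


def regression_report(rom_table: pd.DataFrame) -> pd.DataFrame:
    """Per-movement OLS of webcam ROM on mocap ROM (subject device means)."""
    df = rom_table.copy()
    if "usable" in df.columns:
        df = df[df["usable"].astype(bool)]
    rows = []
    for movement, sub in df.groupby("movement", sort=True):
        devices = set(sub["device"].unique())
        if not {"pose33", "mocap39"} <= devices:
            continue
        wide = sub.pivot_table(
            index="subject", columns="device", values="rom", aggfunc="mean"
        ).dropna()
        if len(wide) < 3:
            logger.warning("%s: < 3 paired subjects, regression skipped", movement)
            continue
        try:
            fit = device_regression(
                wide["mocap39"].to_numpy(), wide["pose33"].to_numpy(), movement
            )
        except ReliabilityError as exc:
            logger.warning("%s: regression skipped: %s", movement, exc)
            continue
        rows.append(fit.__dict__)
    return pd.DataFrame(rows, columns=["movement", "slope", "intercept", "r2", "n"])
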