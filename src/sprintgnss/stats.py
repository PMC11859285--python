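"""Method-agreement statistics for paired per-step series.

For two paired series (test vs reference) the report carries RMSE, bias with
its 95% CI, SD of the differences, Bland-Altman 95% limits of agreement,
Pearson's R with a two-sided p-value, and ICC(2,1) — two-way random effects,
absolute agreement, single measurement (Shrout-Fleiss) — with an F-based 95%
CI. Interpretation labels follow the conventional bins: R >= 0.90 excellent,
0.70-0.89 strong, 0.50-0.69 moderate, 0.30-0.49 weak, < 0.30 negligible;
ICC < 0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good, > 0.90 excellent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .detection import Leg, Section, StepRecord

log = logging.getLogger("sprintgnss")


@dataclass
class AgreementReport:
    n: int
    bias: float
    bias_ci95: tuple[float, float]
    sd_diff: float            # sample SD of differences (ddof=1)
    rmse: float
    loa: tuple[float, float]  # Bland-Altman 95% limits of agreement
    pearson_r: float          # nan if either series is constant
    r_pvalue: float
    r_sig: str                # "**" if p < 0.01, "*" if p < 0.05, else ""
    icc: float
    icc_ci95: tuple[float, float]
    r_label: str
    icc_label: str

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, float) and not math.isfinite(v):
                return None
            return v
        return {
            "n": self.n,
            "bias": _clean(self.bias),
            "bias_ci95": [_clean(v) for v in self.bias_ci95],
            "sd_diff": _clean(self.sd_diff),
            "rmse": _clean(self.rmse),
            "loa": [_clean(v) for v in self.loa],
            "pearson_r": _clean(self.pearson_r),
            "r_pvalue": _clean(self.r_pvalue),
            "r_sig": self.r_sig,
            "icc": _clean(self.icc),
            "icc_ci95": [_clean(v) for v in self.icc_ci95],
            "r_label": self.r_label,
            "icc_label": self.icc_label,
        }


def icc_2_1(test, ref, alpha: float = 0.05,
            form: str = "icc2") -> tuple[float, tuple[float, float]]:
    """Single-measure intraclass correlation for an n-subjects x 2-raters table.

    ``form='icc2'`` is ICC(2,1), two-way random effects with absolute
    agreement; ``form='icc3'`` is the consistency variant ICC(3,1) offered
    for sensitivity analyses. Confidence limits use the exact F formulas.
    """
    x = np.column_stack([np.asarray(ref, float), np.asarray(test, float)])
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(np.sum((x - grand) ** 2))
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if form == "icc3":
        denom = msr + (k - 1) * mse
        icc = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0:
            return 1.0, (1.0, 1.0)
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sstats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * sstats.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
        return icc, (lo, hi)
    if form != "icc2":
        raise ValueError(f"unknown ICC form {form!r}")

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return 1.0, (1.0, 1.0)
    icc = min((msr - mse) / denom, 1.0)  # guard float fuzz on near-identity
    if mse == 0 and msc == 0:
        return icc, (icc, icc)
    # Shrout-Fleiss F-based interval with Satterthwaite degrees of freedom
    r0 = icc
    a = k * r0 / (n * (1 - r0)) if r0 < 1 else np.inf
    b = 1 + k * r0 * (n - 1) / (n * (1 - r0)) if r0 < 1 else np.inf
    if not np.isfinite(a):
        return icc, (icc, icc)
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
    f1 = sstats.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = sstats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    return icc, (min(lo, 1.0), min(hi, 1.0))


def agreement(test, ref, icc_form: str = "icc2") -> AgreementReport:
    """Full agreement report between a test and a reference series (paired)."""
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if test.shape != ref.shape or test.ndim != 1:
        raise ValueError("test and ref must be 1-D and the same length")
    n = len(test)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    d = test - ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    rmse = float(np.sqrt(np.mean(d**2)))
    tcrit = float(sstats.t.ppf(0.975, n - 1))
    half = tcrit * sd / np.sqrt(n)
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)

    if np.std(test) == 0 or np.std(ref) == 0:
        r, p = float("nan"), float("nan")
        log.warning("Pearson r undefined: at least one series is constant")
    else:
        r, p = sstats.pearsonr(test, ref)
        r, p = float(r), float(p)
    sig = "**" if p < 0.01 else ("*" if p < 0.05 else "")

    icc, icc_ci = icc_2_1(test, ref, form=icc_form)
    return AgreementReport(
        n=n, bias=bias, bias_ci95=(bias - half, bias + half), sd_diff=sd,
        rmse=rmse, loa=loa, pearson_r=r, r_pvalue=p, r_sig=sig,
        icc=float(icc), icc_ci95=(float(icc_ci[0]), float(icc_ci[1])),
        r_label=interpret_r(r) if np.isfinite(r) else "undefined",
        icc_label=interpret_icc(float(icc)))


def interpret_r(r: float) -> str:
    """Correlation-strength label on |r|."""
    a = abs(r)
    if a > 1:
        raise ValueError("|r| cannot exceed 1")
    if a >= 0.90:
        return "excellent"
    if a >= 0.70:
        return "strong"
    if a >= 0.50:
        return "moderate"
    if a >= 0.30:
        return "weak"
    return "negligible"


def interpret_icc(icc: float) -> str:
    """Reliability label for an ICC value."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    if icc > 0.90:
        return "excellent"
    if icc >= 0.75:
        return "good"
    if icc >= 0.50:
        return "moderate"
    return "poor"


def percent_match(derived: float, reference: float) -> float:
    """Agreement of a derived quantity with its reference, as a percentage.

    100 * (1 - |derived - reference| / reference), reported to 2 decimals.
    """
    if reference <= 0:
        raise ValueError("reference must be positive")
    return round(100.0 * (1.0 - abs(derived - reference) / reference), 2)


# ---------------------------------------------------------------------------
# stratified comparison of two per-step series (Table 1/2/3 style)

_STRATA = ("overall", "left", "right", "curve", "straight")


def _in_stratum(rec: StepRecord, stratum: str) -> bool:
    if stratum == "overall":
        return True
    if stratum in ("left", "right"):
        return rec.leg is Leg[stratum.upper()]
    return rec.section is Section[stratum.upper()]


def compare_step_series(pairs: list[tuple[StepRecord, StepRecord]],
                        min_pairs: int = 3,
                        icc_form: str = "icc2") -> dict:
    """Agreement reports per parameter (sf, sl, velocity) and per stratum.

    ``pairs`` holds (test_record, ref_record) tuples; strata (leg, section)
    are taken from the reference record. Strata with fewer than ``min_pairs``
    pairs are skipped with a warning.
    """
    out: dict[str, dict[str, dict]] = {}
    for param in ("sf", "sl", "velocity"):
        out[param] = {}
        for stratum in _STRATA:
            sel = [(getattr(t, param), getattr(r, param))
                   for t, r in pairs if _in_stratum(r, stratum)]
            if len(sel) < min_pairs:
                log.warning("stratum %s/%s skipped: %d pairs < %d",
                            param, stratum, len(sel), min_pairs)
                continue
            test_v, ref_v = zip(*sel)
            out[param][stratum] = agreement(test_v, ref_v, icc_form=icc_form).to_dict()
    return out
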