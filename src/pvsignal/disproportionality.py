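"""Disproportionality statistics on 2×2 report tables.

Four detectors standard in pharmacovigilance signal mining, with T = a+b+c+d
and the shared standard-error term s = sqrt(1/a + 1/b + 1/c + 1/d):

ROR (reporting odds ratio)
    ROR = ad/bc, 95% CI = exp(ln ROR ± 1.96 s).
PRR (proportional reporting ratio)
    PRR = a(c+d) / (c(a+b)), 95% CI = exp(ln PRR ± 1.96 s), with the
    accompanying chi-squared statistic
    χ² = (ad − bc)² T / ((a+b)(c+d)(a+c)(b+d))  (no Yates correction).
BCPNN information component
    IC = log2( aT / ((a+c)(a+b)) ), the observed/expected log-ratio of the
    Bayesian confidence propagation neural network;
    IC025 = exp(ln IC − 1.96 s), a multiplicative interval applied to the IC
    point value itself.  This lower bound is therefore defined only when
    IC > 0, and is then automatically positive — see docs/methods.md for the
    consequences and for the conventional additive interval available via
    ``bcpnn_additive_interval=True``.
EBGM (empirical Bayes geometric mean, MGPS point value)
    EBGM = aT / ((a+c)(a+b)), i.e. the observed-to-expected reporting ratio,
    with EBGM05 = exp(ln EBGM − 1.64 s).  The identity EBGM = 2^IC holds
    exactly.  No gamma-Poisson shrinkage is applied (deliberately out of
    scope; see docs/methods.md).

Zero cells leave a statistic undefined (flagged, never an exception) unless
the optional Haldane–Anscombe continuity correction (+0.5 to every cell) is
requested.  Undefined statistics are never significant.

Significance gates (all additionally require n = a ≥ 3):
    ROR:   lower 95% bound > 1
    PRR:   lower 95% bound > 1, PRR ≥ 2, χ² ≥ 4
    BCPNN: IC > 0 and IC025 > 0
    MGPS:  EBGM05 > 2
A pair is a *combined* signal only when all four gates pass.

Signal-intensity bands (open below, closed above):
    ROR / PRR (on the point value): (2,10] weak, (10,50] medium, >50 strong
    BCPNN (on IC025):               (0,1.5] weak, (1.5,3] medium, >3 strong
    MGPS (on EBGM05):               (2,10] weak, (10,30] medium, >30 strong
Nonsignificant pairs grade ``none`` regardless of magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .contingency import ContingencyTable

METHODS = ("ror", "prr", "bcpnn", "mgps")
INTENSITY_LEVELS = ("none", "weak", "medium", "strong")
INTENSITY_MARKS = {"none": "", "weak": "+", "medium": "++", "strong": "+++"}

_BANDS = {
    "ror": (2.0, 10.0, 50.0),
    "prr": (2.0, 10.0, 50.0),
    "bcpnn": (0.0, 1.5, 3.0),
    "mgps": (2.0, 10.0, 30.0),
}

Z95 = 1.96
Z90 = 1.64  # one-sided 5% bound used for EBGM05
MIN_REPORTS = 3


@dataclass(frozen=True)
class SignalStatistics:
    """Point estimates and interval bounds for one drug–event table.

    ``n`` is the raw ``a`` cell (report count), untouched by any continuity
    correction.  Undefined quantities are NaN with the corresponding entry of
    ``defined`` false.
    """

    n: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    prr_low: float
    prr_high: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    shared_se: float
    defined: dict[str, bool] = field(default_factory=dict)


@dataclass(frozen=True)
class SignalDecision:
    significant: dict[str, bool]
    combined: bool
    intensity: dict[str, str]


class RorResult(NamedTuple):
    ror: float
    ror_low: float
    ror_high: float


class PrrResult(NamedTuple):
    prr: float
    prr_low: float
    prr_high: float
    chi2: float


class BcpnnResult(NamedTuple):
    ic: float
    ic025: float


class MgpsResult(NamedTuple):
    ebgm: float
    ebgm05: float


# ---------------------------------------------------------------------------
# vectorised core — the single implementation behind scalar and frame APIs

def _compute_arrays(a, b, c, d, continuity_correction=False,
                    bcpnn_additive_interval=False) -> dict[str, np.ndarray]:
    a0 = np.asarray(a, dtype=float)
    a = a0.copy()
    b = np.asarray(b, dtype=float).copy()
    c = np.asarray(c, dtype=float).copy()
    d = np.asarray(d, dtype=float).copy()
    if continuity_correction:
        a += 0.5
        b += 0.5
        c += 0.5
        d += 0.5
    T = a + b + c + d

    all_pos = (a > 0) & (b > 0) & (c > 0) & (d > 0)
    margins_pos = ((a + b) > 0) & ((c + d) > 0) & ((a + c) > 0) & ((b + d) > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(all_pos, np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d), np.nan)

        ror = np.where(all_pos, a * d / (b * c), np.nan)
        ror_low = ror * np.exp(-Z95 * s)
        ror_high = ror * np.exp(Z95 * s)

        prr = np.where(all_pos, a * (c + d) / (c * (a + b)), np.nan)
        prr_low = prr * np.exp(-Z95 * s)
        prr_high = prr * np.exp(Z95 * s)

        chi2 = np.where(
            margins_pos,
            (a * d - b * c) ** 2 * T / ((a + b) * (c + d) * (a + c) * (b + d)),
            np.nan,
        )

        ratio = np.where((a > 0) & margins_pos, a * T / ((a + c) * (a + b)), np.nan)
        ic = np.log2(ratio)
        ebgm = ratio
        if bcpnn_additive_interval:
            # conventional normal-approximation interval on the log2 scale
            ic025 = ic - Z95 * s / math.log(2.0)
        else:
            # interval as printed: multiplicative factor applied to IC itself,
            # hence only defined for IC > 0
            ic025 = np.where(ic > 0, ic * np.exp(-Z95 * s), np.nan)
        ebgm05 = ebgm * np.exp(-Z90 * s)

    return {
        "n": a0,
        "shared_se": s,
        "ror": ror, "ror_low": ror_low, "ror_high": ror_high,
        "prr": prr, "prr_low": prr_low, "prr_high": prr_high,
        "chi2": chi2,
        "ic": ic, "ic025": ic025,
        "ebgm": ebgm, "ebgm05": ebgm05,
    }


def _significance_arrays(v: dict[str, np.ndarray], min_reports: int = MIN_REPORTS
                         ) -> dict[str, np.ndarray]:
    n_ok = v["n"] >= min_reports

    def fin(x):
        return np.isfinite(x)

    sig_ror = n_ok & fin(v["ror_low"]) & (v["ror_low"] > 1.0)
    sig_prr = (
        n_ok & fin(v["prr_low"]) & (v["prr_low"] > 1.0)
        & fin(v["prr"]) & (v["prr"] >= 2.0)
        & fin(v["chi2"]) & (v["chi2"] >= 4.0)
    )
    sig_bcpnn = n_ok & fin(v["ic"]) & (v["ic"] > 0.0) & fin(v["ic025"]) & (v["ic025"] > 0.0)
    sig_mgps = n_ok & fin(v["ebgm05"]) & (v["ebgm05"] > 2.0)
    return {
        "sig_ror": sig_ror,
        "sig_prr": sig_prr,
        "sig_bcpnn": sig_bcpnn,
        "sig_mgps": sig_mgps,
        "sig_combined": sig_ror & sig_prr & sig_bcpnn & sig_mgps,
    }


def _band_label(value: float, edges: tuple[float, float, float]) -> str:
    lo, mid, hi = edges
    if not math.isfinite(value) or value <= lo:
        return "none"
    if value <= mid:
        return "weak"
    if value <= hi:
        return "medium"
    return "strong"


_GRADED_ON = {"ror": "ror", "prr": "prr", "bcpnn": "ic025", "mgps": "ebgm05"}


def statistics_frame(tables, continuity_correction: bool = False,
                     bcpnn_additive_interval: bool = False,
                     min_reports: int = MIN_REPORTS) -> pd.DataFrame:
    """All statistics, significance flags and intensity grades for many tables.

    ``tables`` is an iterable of :class:`ContingencyTable` or a DataFrame with
    columns ``a, b, c, d`` (optionally ``drug, pt``).
    """
    if isinstance(tables, pd.DataFrame):
        frame = tables.reset_index(drop=True)
    else:
        from .contingency import tables_to_frame
        frame = tables_to_frame(tables)
    v = _compute_arrays(frame["a"], frame["b"], frame["c"], frame["d"],
                        continuity_correction=continuity_correction,
                        bcpnn_additive_interval=bcpnn_additive_interval)
    sig = _significance_arrays(v, min_reports=min_reports)
    out = frame.copy()
    out["n"] = frame["a"].astype(int)
    for key in ("ror", "ror_low", "ror_high", "prr", "prr_low", "prr_high",
                "chi2", "ic", "ic025", "ebgm", "ebgm05", "shared_se"):
        out[key] = v[key]
    for key, val in sig.items():
        out[key] = val
    for method in METHODS:
        graded = v[_GRADED_ON[method]]
        out[f"intensity_{method}"] = [
            _band_label(x, _BANDS[method]) if s else "none"
            for x, s in zip(np.atleast_1d(graded), np.atleast_1d(sig[f"sig_{method}"]))
        ]
    return out


# ---------------------------------------------------------------------------
# scalar API

def _scalar(table: ContingencyTable, continuity_correction=False,
            bcpnn_additive_interval=False) -> dict[str, float]:
    v = _compute_arrays(
        np.array([table.a]), np.array([table.b]),
        np.array([table.c]), np.array([table.d]),
        continuity_correction=continuity_correction,
        bcpnn_additive_interval=bcpnn_additive_interval,
    )
    return {k: float(arr[0]) for k, arr in v.items()}


def ror_statistic(table: ContingencyTable,
                  continuity_correction: bool = False) -> RorResult:
    v = _scalar(table, continuity_correction)
    return RorResult(v["ror"], v["ror_low"], v["ror_high"])


def prr_statistic(table: ContingencyTable,
                  continuity_correction: bool = False) -> PrrResult:
    v = _scalar(table, continuity_correction)
    return PrrResult(v["prr"], v["prr_low"], v["prr_high"], v["chi2"])


def bcpnn_statistic(table: ContingencyTable, continuity_correction: bool = False,
                    additive_interval: bool = False) -> BcpnnResult:
    v = _scalar(table, continuity_correction, additive_interval)
    return BcpnnResult(v["ic"], v["ic025"])


def mgps_statistic(table: ContingencyTable,
                   continuity_correction: bool = False) -> MgpsResult:
    v = _scalar(table, continuity_correction)
    return MgpsResult(v["ebgm"], v["ebgm05"])


def compute_statistics(table: ContingencyTable, continuity_correction: bool = False,
                       bcpnn_additive_interval: bool = False) -> SignalStatistics:
    """All four detectors for one table, with per-statistic defined flags."""
    v = _scalar(table, continuity_correction, bcpnn_additive_interval)
    defined = {
        "ror": math.isfinite(v["ror"]),
        "prr": math.isfinite(v["prr"]),
        "chi2": math.isfinite(v["chi2"]),
        "ic": math.isfinite(v["ic"]),
        "ic025": math.isfinite(v["ic025"]),
        "ebgm": math.isfinite(v["ebgm"]),
        "ebgm05": math.isfinite(v["ebgm05"]),
    }
    return SignalStatistics(
        n=table.a,
        ror=v["ror"], ror_low=v["ror_low"], ror_high=v["ror_high"],
        prr=v["prr"], prr_low=v["prr_low"], prr_high=v["prr_high"],
        chi2=v["chi2"],
        ic=v["ic"], ic025=v["ic025"],
        ebgm=v["ebgm"], ebgm05=v["ebgm05"],
        shared_se=v["shared_se"],
        defined=defined,
    )


def evaluate_significance(stats: SignalStatistics,
                          min_reports: int = MIN_REPORTS) -> SignalDecision:
    """Apply the four positivity gates; combined requires all four."""
    v = {
        "n": np.array([float(stats.n)]),
        "ror_low": np.array([stats.ror_low]),
        "prr": np.array([stats.prr]),
        "prr_low": np.array([stats.prr_low]),
        "chi2": np.array([stats.chi2]),
        "ic": np.array([stats.ic]),
        "ic025": np.array([stats.ic025]),
        "ebgm05": np.array([stats.ebgm05]),
    }
    sig = _significance_arrays(v, min_reports=min_reports)
    significant = {m: bool(sig[f"sig_{m}"][0]) for m in METHODS}
    decision = SignalDecision(
        significant=significant,
        combined=bool(sig["sig_combined"][0]),
        intensity={m: "none" for m in METHODS},
    )
    return SignalDecision(decision.significant, decision.combined,
                          grade_intensity(stats, decision))


def grade_intensity(stats: SignalStatistics, decision: SignalDecision) -> dict[str, str]:
    """Band membership per method; nonsignificant methods grade ``none``."""
    graded_value = {
        "ror": stats.ror,
        "prr": stats.prr,
        "bcpnn": stats.ic025,
        "mgps": stats.ebgm05,
    }
    return {
        m: _band_label(graded_value[m], _BANDS[m]) if decision.significant[m] else "none"
        for m in METHODS
    }


# ---------------------------------------------------------------------------
# presentation

def format_statistics_table(frame: pd.DataFrame, ndigits: int = 2) -> pd.DataFrame:
    """Render a statistics frame in the conventional published layout.

    Columns: PT, N, ROR (95% CI), PRR (χ²), IC (IC025), EBGM (EBGM05), and an
    intensity marker from the BCPNN grade; a ``§`` suffix marks novel PTs when
    a ``novel`` column is present.  Values are rounded half-up at ``ndigits``
    for presentation only.
    """
    from ._util import round_half_up

    def r(x):
        return "NA" if not np.isfinite(x) else f"{round_half_up(float(x), ndigits):.{ndigits}f}"

    rows = []
    for _, row in frame.iterrows():
        pt = str(row.get("pt", ""))
        if bool(row.get("novel", False)):
            pt += " §"
        rows.append({
            "PT": pt,
            "N": int(row["n"]),
            "ROR (95% CI)": f"{r(row['ror'])} ({r(row['ror_low'])}-{r(row['ror_high'])})",
            "PRR (chi2)": f"{r(row['prr'])} ({r(row['chi2'])})",
            "IC (IC025)": f"{r(row['ic'])} ({r(row['ic025'])})",
            "EBGM (EBGM05)": f"{r(row['ebgm'])} ({r(row['ebgm05'])})",
            "intensity": INTENSITY_MARKS[str(row.get("intensity_bcpnn", "none"))],
        })
    return pd.DataFrame(
        rows, columns=["PT", "N", "ROR (95% CI)", "PRR (chi2)", "IC (IC025)",
                       "EBGM (EBGM05)", "intensity"]
    )
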