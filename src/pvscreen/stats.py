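"""Disproportionality statistics for 2x2 reporting tables.

Five classical signal-detection methods are implemented over the a/b/c/d
table:

ROR     reporting odds ratio ad/(bc), lognormal 95% CI with
        SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d).
PRR     proportional reporting ratio [a/(a+b)] / [c/(c+d)], lognormal CI
        with SE(ln PRR) = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)), paired with
        the (uncorrected) Pearson chi-square
        (ad - bc)^2 N / [(a+b)(a+c)(c+d)(b+d)].
MHRA    the criterion PRR >= 2 and chi-square >= 4 and a >= 3.
BCPNN   the one-layer Bayesian confidence propagation neural network
        information component IC = log2[a N / ((a+b)(a+c))] with the
        Dirichlet-prior posterior moments E(IC), V(IC) and the credibility
        bound IC - 2SD = E(IC) - 2 sqrt(V(IC)); signal when it exceeds 0.
EBGM    the crude empirical-Bayes-style geometric mean of the relative
        reporting ratio a N / ((a+b)(a+c)) — numerically log2-identical to
        IC — with a lognormal interval sharing the ROR's standard error;
        signal when its lower bound (EBGM05) exceeds 2.  (No gamma-Poisson
        mixture fit is performed; the interval is lognormal.)

All computations work element-wise on numpy arrays; the scalar API wraps
them into a :class:`SignalMetrics` record.  Zero cells make ROR/PRR
undefined: by default the affected statistics come back NaN with a reason
code, or a Haldane-Anscombe +0.5 continuity correction can be enabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .contingency import ContingencyTable
from .errors import ConfigError

LN2 = np.log(2.0)


@dataclass(frozen=True, slots=True)
class BCPNNPriors:
    """Dirichlet hyper-parameters of the one-layer BCPNN.

    The defaults (gamma11 = alpha1 = beta1 = 1, alpha = beta = 2) are the
    canonical literature values: a uniform prior on each marginal reporting
    probability and a joint prior centred on independence.
    """

    gamma11: float = 1.0
    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0

    def __post_init__(self):
        for name in ("gamma11", "alpha1", "beta1", "alpha", "beta"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"BCPNN prior {name} must be > 0")


@dataclass(frozen=True, slots=True)
class ThresholdConfig:
    """Signal thresholds, one rule per method.

    ror:    a >= min_a and ROR 95% CI lower limit > 1
    prr:    a >= min_a and PRR 95% CI lower limit > 1
    mhra:   PRR >= prr_min and chi2 >= chi2_min and a >= mhra_min_a
    bcpnn:  IC - 2SD > 0
    ebgm:   EBGM05 > ebgm_min
    """

    min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    mhra_min_a: int = 3
    ebgm_min: float = 2.0

    def __post_init__(self):
        if self.min_a < 1:
            raise ConfigError("min_a must be >= 1")
        if self.prr_min <= 0 or self.chi2_min <= 0:
            raise ConfigError("prr_min and chi2_min must be > 0")


METHODS = ("ror", "prr", "mhra", "bcpnn", "ebgm")


@dataclass(slots=True)
class SignalMetrics:
    """All statistics, bounds and per-method flags for one table."""

    a: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    e_ic: float
    v_ic: float
    ic_minus_2sd: float
    ebgm: float
    ebgm_lo: float
    ebgm_hi: float
    flags: dict[str, bool] = field(default_factory=dict)
    reasons: tuple[str, ...] = ()


# ---- vectorized cores ----------------------------------------------------


def _asfloat(*cells):
    return [np.asarray(x, dtype=float) for x in cells]


def ror_arrays(a, b, c, d, z: float = 1.96):
    """(ror, lo, hi) element-wise; NaN where b*c or a*d is zero."""
    a, b, c, d = _asfloat(a, b, c, d)
    with np.errstate(divide="ignore", invalid="ignore"):
        ror = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        valid = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        ror = np.where(valid, ror, np.nan)
        lo = np.exp(np.log(ror) - z * se)
        hi = np.exp(np.log(ror) + z * se)
    return ror, lo, hi


def prr_arrays(a, b, c, d, z: float = 1.96):
    """(prr, lo, hi, chi2) element-wise; PRR NaN where a or c is zero."""
    a, b, c, d = _asfloat(a, b, c, d)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        prr = (a / (a + b)) / (c / (c + d))
        se = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        valid = (a > 0) & (c > 0) & (a + b > 0) & (c + d > 0)
        prr = np.where(valid, prr, np.nan)
        lo = np.exp(np.log(prr) - z * se)
        hi = np.exp(np.log(prr) + z * se)
        chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (a + c) * (c + d) * (b + d))
        chi2 = np.where((a + b > 0) & (a + c > 0) & (c + d > 0) & (b + d > 0), chi2, np.nan)
    return prr, lo, hi, chi2


def bcpnn_arrays(a, b, c, d, priors: BCPNNPriors = BCPNNPriors()):
    """(ic, e_ic, v_ic, ic_minus_2sd) element-wise.

    IC is the raw log2 relative reporting ratio; E(IC) and V(IC) are the
    posterior moments under the Dirichlet priors, with the joint prior
    parameter gamma tied to the margins so that the prior IC expectation is
    zero:  gamma = gamma11 (N+alpha)(N+beta) / [(a+b+alpha1)(a+c+beta1)].
    """
    a, b, c, d = _asfloat(a, b, c, d)
    n = a + b + c + d
    p = priors
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = np.log2(a * n / ((a + b) * (a + c)))
        ic = np.where(a > 0, ic, np.nan)
        gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / ((a + b + p.alpha1) * (a + c + p.beta1))
        e_ic = np.log2(
            (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
            / ((n + gamma) * (a + b + p.alpha1) * (a + c + p.beta1))
        )
        v_ic = (
            (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
            + (n - (a + b) + p.alpha - p.alpha1) / ((a + b + p.alpha1) * (1 + n + p.alpha))
            + (n - (a + c) + p.beta - p.beta1) / ((a + c + p.beta1) * (1 + n + p.beta))
        ) / LN2**2
        ic_minus_2sd = e_ic - 2.0 * np.sqrt(v_ic)
    return ic, e_ic, v_ic, ic_minus_2sd


def ebgm_arrays(a, b, c, d, z: float = 1.96):
    """(ebgm, lo, hi): crude relative reporting ratio, lognormal interval."""
    a, b, c, d = _asfloat(a, b, c, d)
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        ebgm = a * n / ((a + c) * (a + b))
        ebgm = np.where(a > 0, ebgm, np.nan)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = np.exp(np.log(ebgm) - z * se)
        hi = np.exp(np.log(ebgm) + z * se)
    return ebgm, lo, hi


def flags_arrays(a, ror_lo, prr, prr_lo, chi2, ic_minus_2sd, ebgm_lo,
                 cfg: ThresholdConfig = ThresholdConfig()):
    """Per-method boolean signal flags; NaN statistics never flag."""
    a = np.asarray(a, dtype=float)

    def safe_gt(x, thr):
        x = np.asarray(x, dtype=float)
        return np.where(np.isnan(x), False, x > thr)

    def safe_ge(x, thr):
        x = np.asarray(x, dtype=float)
        return np.where(np.isnan(x), False, x >= thr)

    return {
        "ror": (a >= cfg.min_a) & safe_gt(ror_lo, 1.0),
        "prr": (a >= cfg.min_a) & safe_gt(prr_lo, 1.0),
        "mhra": (a >= cfg.mhra_min_a) & safe_ge(prr, cfg.prr_min) & safe_ge(chi2, cfg.chi2_min),
        "bcpnn": safe_gt(ic_minus_2sd, 0.0),
        "ebgm": safe_gt(ebgm_lo, cfg.ebgm_min),
    }


# ---- scalar API ----------------------------------------------------------


def _cells(t: ContingencyTable, continuity_correction: bool):
    a, b, c, d = t.cells()
    reasons = []
    if min(a, b, c, d) == 0:
        if continuity_correction:
            return a + 0.5, b + 0.5, c + 0.5, d + 0.5, ("continuity_correction",)
        for cell, v in zip("abcd", (a, b, c, d)):
            if v == 0:
                reasons.append(f"zero_cell_{cell}")
    return a, b, c, d, tuple(reasons)


def compute_ror(t: ContingencyTable, z: float = 1.96, continuity_correction: bool = False):
    """Reporting odds ratio and its lognormal CI as (ror, lo, hi)."""
    a, b, c, d, _ = _cells(t, continuity_correction)
    ror, lo, hi = ror_arrays(a, b, c, d, z)
    return float(ror), float(lo), float(hi)


def compute_prr(t: ContingencyTable, z: float = 1.96, continuity_correction: bool = False):
    """PRR, its lognormal CI and the chi-square as (prr, lo, hi, chi2)."""
    a, b, c, d, _ = _cells(t, continuity_correction)
    prr, lo, hi, chi2 = prr_arrays(a, b, c, d, z)
    return float(prr), float(lo), float(hi), float(chi2)


def compute_bcpnn(t: ContingencyTable, priors: BCPNNPriors = BCPNNPriors()):
    """(ic, e_ic, v_ic, ic_minus_2sd) for one table."""
    ic, e_ic, v_ic, lo = bcpnn_arrays(t.a, t.b, t.c, t.d, priors)
    return float(ic), float(e_ic), float(v_ic), float(lo)


def compute_ebgm(t: ContingencyTable, z: float = 1.96):
    """(ebgm, ebgm05, ebgm95) for one table."""
    ebgm, lo, hi = ebgm_arrays(t.a, t.b, t.c, t.d, z)
    return float(ebgm), float(lo), float(hi)


def compute_metrics(
    t: ContingencyTable,
    priors: BCPNNPriors = BCPNNPriors(),
    thresholds: ThresholdConfig = ThresholdConfig(),
    z: float = 1.96,
    continuity_correction: bool = False,
) -> SignalMetrics:
    """All five methods plus flags for one table."""
    a0 = t.a
    a, b, c, d, reasons = _cells(t, continuity_correction)
    ror, ror_lo, ror_hi = ror_arrays(a, b, c, d, z)
    prr, prr_lo, prr_hi, chi2 = prr_arrays(a, b, c, d, z)
    ic, e_ic, v_ic, ic2sd = bcpnn_arrays(a, b, c, d, priors)
    ebgm, ebgm_lo, ebgm_hi = ebgm_arrays(a, b, c, d, z)
    flags = flags_arrays(a0, ror_lo, prr, prr_lo, chi2, ic2sd, ebgm_lo, thresholds)
    return SignalMetrics(
        a=a0,
        ror=float(ror), ror_lo=float(ror_lo), ror_hi=float(ror_hi),
        prr=float(prr), prr_lo=float(prr_lo), prr_hi=float(prr_hi),
        chi2=float(chi2),
        ic=float(ic), e_ic=float(e_ic), v_ic=float(v_ic), ic_minus_2sd=float(ic2sd),
        ebgm=float(ebgm), ebgm_lo=float(ebgm_lo), ebgm_hi=float(ebgm_hi),
        flags={k: bool(v) for k, v in flags.items()},
        reasons=reasons,
    )


def evaluate_flags(
    m: SignalMetrics, a: Optional[int] = None, cfg: ThresholdConfig = ThresholdConfig()
) -> dict[str, bool]:
    """Re-evaluate per-method flags for a metrics record (a defaults to m.a)."""
    a = m.a if a is None else a
    flags = flags_arrays(
        a, m.ror_lo, m.prr, m.prr_lo, m.chi2, m.ic_minus_2sd, m.ebgm_lo, cfg
    )
    return {k: bool(v) for k, v in flags.items()}


# ---- published-row reconstruction ---------------------------------------


def reconstruct_table_from_stats(
    a: int, b: int, ror: float, chi2: float,
    c_bracket: tuple[float, float] = (1.0, 1e12),
) -> ContingencyTable:
    """Recover (a, b, c, d) from a published table row.

    Published PT rows report a (case records), the exposure's total event
    records (fixing b), the ROR point estimate and the chi-square.  The ROR
    fixes the ratio d/c = ROR*b/a; the chi-square is strictly monotone in
    the remaining scale c, so a scalar root solve recovers the comparator
    margin.  Cells are rounded to the nearest integers.
    """
    if a <= 0 or b < 0 or ror <= 0 or chi2 <= 0:
        raise ConfigError("need a > 0, b >= 0, ror > 0, chi2 > 0")
    k = ror * b / a

    def chi2_of(c: float) -> float:
        d = k * c
        n = a + b + c + d
        return (a * d - b * c) ** 2 * n / ((a + b) * (a + c) * (c + d) * (b + d))

    lo, hi = c_bracket
    f_lo, f_hi = chi2_of(lo) - chi2, chi2_of(hi) - chi2
    if f_lo * f_hi > 0:
        raise ConfigError("chi2 target not bracketed; widen c_bracket")
    c = brentq(lambda x: chi2_of(x) - chi2, lo, hi, xtol=1e-6, rtol=1e-14)
    d = k * c
    return ContingencyTable(int(a), int(b), int(round(c)), int(round(d)))
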