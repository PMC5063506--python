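"""Reporter and cytokine summary statistics.

Dose-response curves are response (OD or Vmax) versus log10 molar
concentration.  Two AUC readings are provided: integration of a natural
cubic spline through the points, and the composite trapezoidal rule.
Potency is summarized as pEC50 = -log10(EC50 in molar) from a
four-parameter logistic (4PL) fit.

Group comparisons report the mean percent difference of a compound from a
reference stimulus, 100*(mean_cmp - mean_ref)/mean_ref, with a two-sided
confidence interval (90% by default) on that ratio-derived quantity —
Fieller's theorem by default, a seeded percentile bootstrap as the
robustness alternative.  A compound is called significantly higher than the
reference when the lower CI bound exceeds 0%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import CubicSpline

from .errors import ComputationError, InputError


@dataclass(frozen=True)
class DoseResponseCurve:
    """Concentration-response vectors; concentrations in molar units."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray | None = None   # replicate labels, optional

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise InputError("concentrations and responses must be equal-length 1-D")
        if np.any(conc <= 0) or not np.all(np.isfinite(conc)):
            raise InputError("concentrations must be strictly positive and finite")
        if not np.all(np.isfinite(resp)):
            raise InputError("responses must be finite")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)
        if self.replicates is not None:
            reps = np.asarray(self.replicates)
            if reps.shape != conc.shape:
                raise InputError("replicate labels must match data length")
            object.__setattr__(self, "replicates", reps)

    @property
    def log10_concentrations(self) -> np.ndarray:
        return np.log10(self.concentrations)

    def per_replicate(self):
        """Yield (label, sorted log10 conc, responses) per replicate subset."""
        if self.replicates is None:
            groups = [("all", np.arange(len(self.concentrations)))]
        else:
            labels = pd.unique(self.replicates)
            groups = [(lab, np.flatnonzero(self.replicates == lab)) for lab in labels]
        for label, idx in groups:
            x = self.log10_concentrations[idx]
            y = self.responses[idx]
            order = np.argsort(x, kind="stable")
            yield label, x[order], y[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, concentration: str = "concentration",
                       response: str = "response", replicate: str | None = "replicate"):
        reps = df[replicate].to_numpy() if replicate and replicate in df.columns else None
        return cls(df[concentration].to_numpy(dtype=float),
                   df[response].to_numpy(dtype=float), reps)


def _check_distinct(x: np.ndarray, minimum: int, what: str) -> None:
    if len(np.unique(x)) < minimum:
        raise InputError(f"{what} requires >= {minimum} distinct concentrations")
    if len(np.unique(x)) != len(x):
        raise InputError(f"{what}: duplicate concentrations within a replicate")


def spline_auc(curve: DoseResponseCurve, bc_type: str = "natural",
               mode: str = "per-replicate") -> float:
    """Integral of the cubic spline through (log10 conc, response).

    ``mode="per-replicate"`` (default) integrates each replicate's spline and
    averages; ``mode="means"`` splines the per-concentration replicate means.
    The boundary condition defaults to natural (zero second derivative).
    """
    if mode not in ("per-replicate", "means"):
        raise InputError(f"unknown mode {mode!r}")
    if mode == "means" and curve.replicates is not None:
        x_all = curve.log10_concentrations
        df = pd.DataFrame({"x": x_all, "y": curve.responses})
        g = df.groupby("x", sort=True)["y"].mean()
        subsets = [("means", g.index.to_numpy(), g.to_numpy())]
    else:
        subsets = list(curve.per_replicate())
    aucs = []
    for _, x, y in subsets:
        _check_distinct(x, 3, "spline AUC")
        cs = CubicSpline(x, y, bc_type=bc_type)
        aucs.append(float(cs.integrate(x[0], x[-1])))
    return float(np.mean(aucs))


def trapezoid_auc(curve: DoseResponseCurve) -> float:
    """Composite trapezoid AUC over (log10 molar, response), replicate-averaged."""
    aucs = []
    for _, x, y in curve.per_replicate():
        _check_distinct(x, 2, "trapezoid AUC")
        aucs.append(float(np.trapezoid(y, x)))
    return float(np.mean(aucs))


# ---------------------------------------------------------------------------
# 4PL potency fit
# ---------------------------------------------------------------------------

def four_pl(x: np.ndarray, floor: float, span: float, log_ec50: float,
            hill: float) -> np.ndarray:
    """4PL in log10 molar units; ceiling = floor + span, span >= 0."""
    return floor + span / (1.0 + 10.0 ** ((log_ec50 - x) * hill))


@dataclass(frozen=True)
class PEC50Fit:
    pec50: float
    ec50: float
    hill: float
    floor: float
    ceiling: float
    converged: bool
    message: str
    residual_sd: float
    brackets_inflection: bool


def fit_pec50(curve: DoseResponseCurve) -> PEC50Fit:
    """Least-squares 4PL fit; pEC50 = -log10(EC50 in molar).

    Initialization from data quantiles; bounds keep ceiling >= floor (span
    parameterization) and the Hill slope positive.  Non-convergence is
    flagged in the result, never silently replaced.
    """
    x = curve.log10_concentrations
    y = curve.responses
    if len(np.unique(x)) < 4:
        raise InputError("4PL fit requires >= 4 distinct concentrations")
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]

    lo, hi = float(np.min(y)), float(np.max(y))
    span0 = max(hi - lo, 1e-12)
    mid = lo + span0 / 2.0
    log_ec50_0 = float(x[np.argmin(np.abs(y - mid))])
    p0 = [lo, span0, log_ec50_0, 1.0]
    bounds = ([-np.inf, 0.0, x.min() - 6.0, 1e-3],
              [np.inf, np.inf, x.max() + 6.0, 100.0])
    try:
        popt, _ = optimize.curve_fit(four_pl, x, y, p0=p0, bounds=bounds, maxfev=20000)
        converged, message = True, "converged"
    except RuntimeError as exc:
        popt, converged, message = np.asarray(p0), False, str(exc)
    floor, span, log_ec50, hill = (float(v) for v in popt)
    resid = y - four_pl(x, *popt)
    # diagnostic: does the data bracket the fitted inflection?
    brackets = bool(x.min() <= log_ec50 <= x.max())
    return PEC50Fit(
        pec50=-log_ec50, ec50=10.0 ** log_ec50, hill=hill,
        floor=floor, ceiling=floor + span,
        converged=converged, message=message,
        residual_sd=float(np.sqrt(np.mean(resid ** 2))),
        brackets_inflection=brackets,
    )


# ---------------------------------------------------------------------------
# percent difference from reference with CI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupAssayTable:
    """Replicate measurements for a reference stimulus and a comparison compound."""

    reference: np.ndarray
    comparison: np.ndarray
    species: str = ""
    cytokine: str = ""

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        cmp_ = np.asarray(self.comparison, dtype=float)
        if len(ref) < 2 or len(cmp_) < 2:
            raise InputError("need >= 2 replicates per group")
        if ref.mean() <= 0:
            raise InputError("reference group mean must be positive")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "comparison", cmp_)


@dataclass(frozen=True)
class PercentDiffResult:
    estimate: float
    lower: float
    upper: float
    level: float
    significant: bool     # lower bound of the CI above 0%
    method: str
    unbounded: bool = False   # Fieller denominator CI spanned zero


def _fieller_ratio_ci(m1, v1, m0, v0, df, level):
    """CI for m1/m0 by Fieller's theorem; v are variances of the means.

    Solves (m1 - rho*m0)^2 <= t^2 (v1 + rho^2 v0) for rho.  Returns
    (lo, hi, unbounded): when the denominator is not significantly away from
    zero the solution set is unbounded and infinite limits are returned.
    """
    t = stats.t.ppf(0.5 + level / 2.0, df)
    a = m0 ** 2 - t ** 2 * v0
    b = -2.0 * m1 * m0
    c = m1 ** 2 - t ** 2 * v1
    disc = b ** 2 - 4 * a * c
    if a <= 0:
        return -np.inf, np.inf, True
    if disc < 0:
        # numerically possible only at disc ~ 0; collapse to the point estimate
        rho = m1 / m0
        return rho, rho, False
    r1 = (-b - np.sqrt(disc)) / (2 * a)
    r2 = (-b + np.sqrt(disc)) / (2 * a)
    return min(r1, r2), max(r1, r2), False


def percent_diff_ci(table: GroupAssayTable, level: float = 0.90,
                    method: str = "fieller", n_boot: int = 10000,
                    seed: int | None = None) -> PercentDiffResult:
    """Percent difference of comparison from reference with a two-sided CI.

    estimate = 100*(mean_cmp - mean_ref)/mean_ref.  ``method="fieller"``
    (default) applies Fieller's theorem for a ratio of independent means with
    Welch-Satterthwaite degrees of freedom; ``method="bootstrap"`` uses a
    seeded percentile bootstrap of the ratio.  Significance = CI lower bound
    above 0%.
    """
    if not 0 < level < 1:
        raise InputError("level must be in (0, 1)")
    ref, cmp_ = table.reference, table.comparison
    m0, m1 = float(ref.mean()), float(cmp_.mean())
    estimate = 100.0 * (m1 - m0) / m0

    if method == "fieller":
        v0 = float(ref.var(ddof=1)) / len(ref)
        v1 = float(cmp_.var(ddof=1)) / len(cmp_)
        if v0 == 0.0 and v1 == 0.0:
            return PercentDiffResult(estimate, estimate, estimate, level,
                                     estimate > 0, method)
        num = (v1 + v0) ** 2
        den = (v1 ** 2 / max(len(cmp_) - 1, 1)) + (v0 ** 2 / max(len(ref) - 1, 1))
        df = num / den if den > 0 else len(ref) + len(cmp_) - 2
        lo, hi, unbounded = _fieller_ratio_ci(m1, v1, m0, v0, df, level)
        lower, upper = 100.0 * (lo - 1.0), 100.0 * (hi - 1.0)
        return PercentDiffResult(estimate, lower, upper, level,
                                 bool(lower > 0), method, unbounded)

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        idx0 = rng.integers(0, len(ref), size=(n_boot, len(ref)))
        idx1 = rng.integers(0, len(cmp_), size=(n_boot, len(cmp_)))
        bm0 = ref[idx0].mean(axis=1)
        bm1 = cmp_[idx1].mean(axis=1)
        ok = bm0 != 0
        if not np.all(ok):
            bm0, bm1 = bm0[ok], bm1[ok]
        pct = 100.0 * (bm1 - bm0) / bm0
        alpha = (1.0 - level) / 2.0
        lower, upper = (float(np.quantile(pct, q)) for q in (alpha, 1 - alpha))
        return PercentDiffResult(estimate, lower, upper, level,
                                 bool(lower > 0), method)

    raise InputError(f"unknown CI method {method!r}")


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

def read_plate_table(path) -> pd.DataFrame:
    """CSV/TSV with columns condition, concentration, [unit], [replicate], response."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"condition", "concentration", "response"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"plate table missing columns {sorted(missing)}")
    return df


def curve_for_condition(df: pd.DataFrame, condition: str) -> DoseResponseCurve:
    sub = df[df["condition"] == condition]
    if sub.empty:
        raise InputError(f"condition {condition!r} not in table")
    return DoseResponseCurve.from_dataframe(sub)
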