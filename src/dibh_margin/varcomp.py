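"""Nested random-effect variance components by restricted maximum likelihood.

The positional errors are modelled as

    y[p,f,k] = M + a[p] + b[p,f] + e[p,f,k]

with independent Gaussian effects: ``a`` per patient (variance Σpt²),
``b`` per fraction nested within patient (σfr²), and frame residuals ``e``
(σintra²).  Fraction labels are only meaningful within a patient; field
labels are carried by the data but are not a variance level.  The fit
maximises the restricted log-likelihood over the three variances with the
overall mean profiled out by GLS, on arbitrary unbalanced designs.

The restricted likelihood is evaluated in closed form from per-fraction
sufficient statistics (count, mean, within-fraction sum of squares), so a
cohort of several hundred thousand frames reduces to a few hundred cells
and the fit runs in milliseconds.  Writing lam_j = σintra² + n_j σfr² for
fraction cell j and s_p = Σ_j n_j/lam_j within patient p, Sherman–Morrison
on the patient-level compound symmetry gives

    log|V|      = Σ_j (n_j−1) log σintra² + Σ_j log lam_j + Σ_p log(1 + Σpt² s_p)
    1'V⁻¹1      = Σ_p s_p / (1 + Σpt² s_p)
    r'V⁻¹r      = Σ_j SSW_j/σintra² + Σ_j n_j r̄_j²/lam_j
                  − Σ_p Σpt² (Σ_j n_j r̄_j/lam_j)² / (1 + Σpt² s_p)

and −2·l_R = (N−1)log 2π + log|V| + log(1'V⁻¹1) + r'V⁻¹r at the GLS mean.

Confidence intervals for the three SDs come from the profile restricted
likelihood (inverted chi-square(1) deviance); the overall mean gets a Wald
interval from its GLS variance.  A parametric bootstrap is available as an
alternative interval method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2, norm

__all__ = [
    "IdentifiabilityError",
    "VarianceComponents",
    "fit_reml",
    "confidence_intervals",
    "overall_mean_test",
]

_LOG2PI = np.log(2.0 * np.pi)


class IdentifiabilityError(ValueError):
    """The design cannot separate the requested variance components."""


# ---------------------------------------------------------------------------
# Sufficient statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _NestedStats:
    """Per-fraction-cell sufficient statistics of a nested data set."""

    n: np.ndarray        # observations per cell
    ybar: np.ndarray     # cell means
    ssw: np.ndarray      # within-cell sums of squares
    pidx: np.ndarray     # 0-based patient code per cell
    n_patients: int

    @property
    def n_obs(self) -> int:
        return int(self.n.sum())

    @property
    def n_cells(self) -> int:
        return self.n.size


def _nested_stats(observations: pd.DataFrame) -> _NestedStats:
    required = {"patient_id", "fraction", "error_mm"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations lack required columns: {sorted(missing)}")
    y = observations["error_mm"].to_numpy(dtype=float)
    if y.size == 0:
        raise ValueError("observations are empty")
    if not np.all(np.isfinite(y)):
        raise ValueError("error_mm contains non-finite values")

    pat = observations["patient_id"].to_numpy()
    frac = observations["fraction"].to_numpy()
    _, p_codes = np.unique(pat, return_inverse=True)
    # Cell key: fraction nested within patient.
    cell_keys = np.stack([p_codes, pd.factorize(frac)[0]], axis=1)
    _, cell_codes = np.unique(cell_keys, axis=0, return_inverse=True)

    n_cells = cell_codes.max() + 1
    n = np.bincount(cell_codes, minlength=n_cells).astype(float)
    tot = np.bincount(cell_codes, weights=y, minlength=n_cells)
    ybar = tot / n
    ssw = np.bincount(cell_codes, weights=y * y, minlength=n_cells) - n * ybar**2
    ssw = np.maximum(ssw, 0.0)
    pidx = np.zeros(n_cells, dtype=np.int64)
    pidx[cell_codes] = p_codes
    return _NestedStats(n=n, ybar=ybar, ssw=ssw, pidx=pidx,
                        n_patients=int(p_codes.max()) + 1)


def _validate_design(stats: _NestedStats) -> None:
    if stats.n_patients < 2:
        raise IdentifiabilityError(
            "at least 2 patients are required to identify the inter-patient SD "
            f"(got {stats.n_patients}); fit cannot proceed")
    cells_per_patient = np.bincount(stats.pidx, minlength=stats.n_patients)
    if cells_per_patient.max() < 2:
        raise IdentifiabilityError(
            "every patient has a single fraction: the inter-fraction SD is "
            "confounded with the inter-patient SD")
    if stats.n.max() < 2:
        raise IdentifiabilityError(
            "every fraction has a single observation: the intra-fraction SD is "
            "confounded with the inter-fraction SD")


# ---------------------------------------------------------------------------
# Restricted likelihood
# ---------------------------------------------------------------------------

def _neg2_restricted_loglik(va: float, vb: float, ve: float,
                            stats: _NestedStats) -> float:
    """−2 × restricted log-likelihood at variances (Σpt², σfr², σintra²)."""
    n, ybar, ssw, pidx = stats.n, stats.ybar, stats.ssw, stats.pidx
    if ve <= 0 or va < 0 or vb < 0:
        return np.inf
    lam = ve + n * vb
    npat = stats.n_patients

    s_p = np.bincount(pidx, weights=n / lam, minlength=npat)
    t_p = np.bincount(pidx, weights=n * ybar / lam, minlength=npat)
    shrink = 1.0 + va * s_p
    den = float(np.sum(s_p / shrink))
    mu = float(np.sum(t_p / shrink)) / den

    r = ybar - mu
    q = np.bincount(pidx, weights=n * r * r / lam, minlength=npat)
    u = np.bincount(pidx, weights=n * r / lam, minlength=npat)
    quad = float(np.sum(ssw) / ve + np.sum(q - va * u * u / shrink))

    logdet = float(np.sum((n - 1.0)) * np.log(ve) + np.sum(np.log(lam))
                   + np.sum(np.log(shrink)))
    return (stats.n_obs - 1) * _LOG2PI + logdet + np.log(den) + quad


def _gls_mean_and_var(va: float, vb: float, ve: float,
                      stats: _NestedStats) -> tuple[float, float]:
    lam = ve + stats.n * vb
    s_p = np.bincount(stats.pidx, weights=stats.n / lam, minlength=stats.n_patients)
    t_p = np.bincount(stats.pidx, weights=stats.n * stats.ybar / lam,
                      minlength=stats.n_patients)
    shrink = 1.0 + va * s_p
    den = float(np.sum(s_p / shrink))
    mu = float(np.sum(t_p / shrink)) / den
    return mu, 1.0 / den


def _moment_start(stats: _NestedStats) -> np.ndarray:
    """Method-of-moments starting variances, floored at small positives."""
    dfw = np.sum(stats.n - 1.0)
    var_tot = max(float(np.var(np.repeat(stats.ybar, stats.n.astype(int)))), 1e-8)
    ve0 = float(np.sum(stats.ssw) / dfw) if dfw > 0 else var_tot / 3.0
    nbar = float(stats.n.mean())

    pat_of = stats.pidx
    npat = stats.n_patients
    cells_per = np.bincount(pat_of, minlength=npat).astype(float)
    pat_mean = np.bincount(pat_of, weights=stats.ybar, minlength=npat) / cells_per
    within = stats.ybar - pat_mean[pat_of]
    df_b = float(np.sum(cells_per - 1.0))
    vb0 = float(np.sum(within**2) / df_b - ve0 / nbar) if df_b > 0 else var_tot / 3.0
    fbar = float(cells_per.mean())
    va0 = float(np.var(pat_mean, ddof=1) - (max(vb0, 0.0) + ve0 / nbar) / fbar)

    floor = 1e-3 * var_tot
    return np.array([max(va0, floor), max(vb0, floor), max(ve0, floor)])


# ---------------------------------------------------------------------------
# Fit result container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceComponents:
    """REML estimates of the nested model, all on the mm scale.

    ``sigma_pt``/``sigma_fr``/``sigma_intra`` are the inter-patient,
    inter-fraction and intra-fraction SDs; ``mean_mm`` is the overall mean
    M.  Interval endpoints for the SDs are bounded below by 0; a component
    estimated on the zero boundary is flagged in ``boundary`` and carries a
    one-sided interval.
    """

    mean_mm: float
    mean_ci: tuple[float, float]
    sigma_pt: float
    sigma_pt_ci: tuple[float, float]
    sigma_fr: float
    sigma_fr_ci: tuple[float, float]
    sigma_intra: float
    sigma_intra_ci: tuple[float, float]
    ci_level: float
    ci_method: str
    boundary: dict = field(default_factory=dict)
    fit_report: dict = field(default_factory=dict)
    _stats: _NestedStats | None = field(default=None, repr=False, compare=False)

    @property
    def variances(self) -> tuple[float, float, float]:
        return (self.sigma_pt**2, self.sigma_fr**2, self.sigma_intra**2)

    def to_dict(self) -> dict:
        return {
            "overall_mean_mm": {"estimate": self.mean_mm, "ci": list(self.mean_ci)},
            "sigma_pt_mm": {"estimate": self.sigma_pt, "ci": list(self.sigma_pt_ci)},
            "sigma_fr_mm": {"estimate": self.sigma_fr, "ci": list(self.sigma_fr_ci)},
            "sigma_intra_mm": {"estimate": self.sigma_intra, "ci": list(self.sigma_intra_ci)},
            "ci_level": self.ci_level,
            "ci_method": self.ci_method,
            "boundary": dict(self.boundary),
            "fit_report": {k: v for k, v in self.fit_report.items()},
        }

    def summary(self) -> str:
        lvl = int(round(100 * self.ci_level))
        rows = [
            ("Inter-patient SD (Sigma_pt)", self.sigma_pt, self.sigma_pt_ci),
            ("Inter-fraction SD (sigma_fr)", self.sigma_fr, self.sigma_fr_ci),
            ("Intra-fraction SD (sigma_intra)", self.sigma_intra, self.sigma_intra_ci),
            ("Overall mean (M)", self.mean_mm, self.mean_ci),
        ]
        lines = [f"{'Component':<34}{'mm':>8}  {lvl}% CI (mm)"]
        for name, est, (lo, hi) in rows:
            lines.append(f"{name:<34}{est:>8.2f}  {lo:.2f} to {hi:.2f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_VAR_FLOOR_REL = 1e-10  # relative variance floor used as the optimiser's 0


def _fit_variances(stats: _NestedStats,
                   fixed: dict[int, float] | None = None,
                   start: np.ndarray | None = None) -> tuple[np.ndarray, float, dict]:
    """Minimise −2 l_R over log-variances, optionally pinning components.

    ``fixed`` maps component index (0=Σpt², 1=σfr², 2=σintra²) to a fixed
    variance value.  Returns (variances, objective minimum, report).
    """
    fixed = fixed or {}
    scale = max(float(np.var(np.repeat(stats.ybar, stats.n.astype(int)))), 1e-12)
    floor = _VAR_FLOOR_REL * scale
    free = [i for i in range(3) if i not in fixed]

    v0 = _moment_start(stats) if start is None else np.asarray(start, dtype=float)
    v0 = np.maximum(v0, floor)

    def unpack(theta: np.ndarray) -> np.ndarray:
        v = np.empty(3)
        for i, val in fixed.items():
            v[i] = val
        v[free] = np.exp(theta)
        return v

    def objective(theta: np.ndarray) -> float:
        va, vb, ve = unpack(theta)
        return _neg2_restricted_loglik(va, vb, ve, stats)

    if not free:
        v = unpack(np.empty(0))
        return v, objective(np.empty(0)), {"converged": True, "grad_norm": 0.0,
                                           "message": "all components fixed"}

    theta0 = np.log(v0[free])
    bounds = [(np.log(floor), np.log(1e6 * scale))] * len(free)
    res = optimize.minimize(objective, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9})
    grad_norm = float(np.max(np.abs(res.jac))) if res.jac is not None else np.nan
    converged = bool(res.success) or grad_norm < 1e-3
    if not converged:
        # Line-search failures near flat optima: polish with Nelder-Mead.
        polish = optimize.minimize(objective, res.x, method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-12,
                                            "maxiter": 2000})
        if polish.fun <= res.fun:
            res = polish
        converged = bool(res.success) or abs(polish.fun - res.fun) < 1e-6
    theta = np.clip(res.x, np.log(floor), None)
    v = unpack(theta)
    # A component driven to the floor is a zero-boundary solution.
    at_floor = {free[j] for j in range(len(free)) if theta[j] <= np.log(floor) + 1e-6}
    for i in at_floor:
        v[i] = 0.0
    report = {
        "converged": converged,
        "grad_norm": grad_norm,
        "message": str(res.message),
        "n_iter": int(res.nit),
        "at_zero_boundary": sorted(at_floor),
    }
    obj = _neg2_restricted_loglik(max(v[0], 0.0), max(v[1], 0.0), max(v[2], floor), stats)
    return v, obj, report


_COMPONENT_NAMES = ("sigma_pt", "sigma_fr", "sigma_intra")


def _profile_ci_variance(stats: _NestedStats, vhat: np.ndarray, obj_min: float,
                         comp: int, level: float) -> tuple[float, float, bool]:
    """Profile-likelihood interval for one variance component.

    Returns (lo, hi) on the variance scale and a flag marking a one-sided
    interval (component at the zero boundary).
    """
    if level <= 0:
        return float(vhat[comp]), float(vhat[comp]), False
    target = obj_min + chi2.ppf(level, 1)
    scale = max(float(np.var(np.repeat(stats.ybar, stats.n.astype(int)))), 1e-12)
    floor = _VAR_FLOOR_REL * scale

    def profiled(v: float) -> float:
        _, obj, _ = _fit_variances(stats, fixed={comp: v},
                                   start=np.maximum(vhat, floor))
        return obj

    def h(v: float) -> float:
        return profiled(v) - target

    vh = max(float(vhat[comp]), 0.0)
    one_sided = False

    # Upper endpoint: expand geometrically until the deviance crosses.
    up = max(vh, floor) * 2.0
    lo_bracket = max(vh, floor)
    for _ in range(60):
        if h(up) > 0:
            break
        lo_bracket, up = up, up * 2.0
    hi = float(optimize.brentq(h, lo_bracket, up, xtol=1e-12, rtol=1e-9))

    # Lower endpoint: shrink toward 0; if the deviance never crosses, the
    # interval is one-sided at the boundary.
    if vh <= floor or h(floor) < 0:
        lo = 0.0
        one_sided = True
    else:
        down = vh / 2.0
        hi_bracket = vh
        crossed = False
        for _ in range(80):
            if h(down) > 0:
                crossed = True
                break
            hi_bracket, down = down, down / 2.0
            if down < floor:
                break
        if crossed:
            lo = float(optimize.brentq(h, down, hi_bracket, xtol=1e-14, rtol=1e-9))
        else:
            lo, one_sided = 0.0, True
    return lo, hi, one_sided


def _bootstrap_cis(stats: _NestedStats, vhat: np.ndarray, mu: float,
                   level: float, n_boot: int, seed: int) -> dict[str, tuple[float, float]]:
    """Percentile parametric bootstrap on the sufficient statistics."""
    rng = np.random.default_rng(seed)
    va, vb, ve = np.maximum(vhat, 0.0)
    draws = {name: [] for name in (*_COMPONENT_NAMES, "mean")}
    dfw = (stats.n - 1.0).astype(float)
    for _ in range(n_boot):
        a = rng.normal(0.0, np.sqrt(va), size=stats.n_patients)[stats.pidx]
        b = rng.normal(0.0, np.sqrt(vb), size=stats.n_cells)
        ybar = mu + a + b + rng.normal(0.0, np.sqrt(ve / stats.n))
        ssw = ve * rng.chisquare(np.maximum(dfw, 1e-12)) * (dfw > 0)
        bstats = _NestedStats(n=stats.n, ybar=ybar, ssw=ssw, pidx=stats.pidx,
                              n_patients=stats.n_patients)
        v, _, _ = _fit_variances(bstats)
        m, _ = _gls_mean_and_var(*np.maximum(v, 0.0), bstats)
        for name, val in zip(_COMPONENT_NAMES, np.sqrt(np.maximum(v, 0.0))):
            draws[name].append(val)
        draws["mean"].append(m)
    lo_q, hi_q = (1 - level) / 2.0, 1 - (1 - level) / 2.0
    return {name: (float(np.quantile(vals, lo_q)), float(np.quantile(vals, hi_q)))
            for name, vals in draws.items()}


def fit_reml(
    observations: pd.DataFrame,
    ci_level: float = 0.95,
    ci_method: str = "profile",
    n_boot: int = 200,
    boot_seed: int = 0,
) -> VarianceComponents:
    """Fit the nested model by REML and return components with intervals.

    ``observations`` is a tidy frame with at least ``patient_id``,
    ``fraction`` and ``error_mm`` columns (``field``/``frame`` are carried
    by the schema but not modelled).  Raises
    :class:`IdentifiabilityError` on degenerate designs and
    :class:`RuntimeError` on optimiser failure.
    """
    if ci_method not in ("profile", "bootstrap"):
        raise ValueError(f"ci_method must be 'profile' or 'bootstrap', got {ci_method!r}")
    if not (0.0 <= ci_level < 1.0):
        raise ValueError(f"ci_level must be in [0, 1), got {ci_level}")
    stats = _nested_stats(observations)
    _validate_design(stats)

    # Zero-variance data: every component is exactly 0 and the restricted
    # likelihood is unbounded, so report the degenerate solution directly.
    y = observations["error_mm"].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        c = float(y[0])
        zero_ci = (0.0, 0.0)
        return VarianceComponents(
            mean_mm=c, mean_ci=(c, c),
            sigma_pt=0.0, sigma_pt_ci=zero_ci,
            sigma_fr=0.0, sigma_fr_ci=zero_ci,
            sigma_intra=0.0, sigma_intra_ci=zero_ci,
            ci_level=ci_level, ci_method=ci_method,
            boundary={name: True for name in _COMPONENT_NAMES},
            fit_report={"converged": True, "grad_norm": 0.0,
                        "message": "degenerate zero-variance data",
                        "neg2_restricted_loglik": float("-inf"),
                        "restricted_loglik": float("inf"),
                        "n_obs": stats.n_obs, "n_patients": stats.n_patients,
                        "n_fraction_cells": stats.n_cells},
            _stats=stats,
        )

    vhat, obj_min, report = _fit_variances(stats)
    if not report["converged"]:
        raise RuntimeError(f"REML optimisation did not converge: {report['message']}; "
                           f"trace: {report}")
    mu, mu_var = _gls_mean_and_var(*np.maximum(vhat, 0.0), stats)

    z = norm.ppf(0.5 + ci_level / 2.0) if ci_level > 0 else 0.0
    mean_ci = (mu - z * np.sqrt(mu_var), mu + z * np.sqrt(mu_var))

    boundary: dict[str, bool] = {}
    cis: dict[str, tuple[float, float]] = {}
    if ci_method == "profile":
        for i, name in enumerate(_COMPONENT_NAMES):
            lo_v, hi_v, one_sided = _profile_ci_variance(stats, vhat, obj_min, i, ci_level)
            cis[name] = (float(np.sqrt(lo_v)), float(np.sqrt(hi_v)))
            if one_sided or vhat[i] == 0.0:
                boundary[name] = True
    else:
        boot = _bootstrap_cis(stats, vhat, mu, ci_level, n_boot, boot_seed)
        for name in _COMPONENT_NAMES:
            cis[name] = boot[name]
        mean_ci = boot["mean"]
        for i, name in enumerate(_COMPONENT_NAMES):
            if vhat[i] == 0.0:
                boundary[name] = True

    sds = np.sqrt(np.maximum(vhat, 0.0))
    cells_per_patient = np.bincount(stats.pidx, minlength=stats.n_patients)
    fit_report = {
        **report,
        "neg2_restricted_loglik": float(obj_min),
        "restricted_loglik": float(-0.5 * obj_min),
        "n_obs": stats.n_obs,
        "n_patients": stats.n_patients,
        "n_fraction_cells": stats.n_cells,
        "min_fractions_per_patient": int(cells_per_patient.min()),
        "max_fractions_per_patient": int(cells_per_patient.max()),
    }
    return VarianceComponents(
        mean_mm=mu, mean_ci=(float(mean_ci[0]), float(mean_ci[1])),
        sigma_pt=float(sds[0]), sigma_pt_ci=cis["sigma_pt"],
        sigma_fr=float(sds[1]), sigma_fr_ci=cis["sigma_fr"],
        sigma_intra=float(sds[2]), sigma_intra_ci=cis["sigma_intra"],
        ci_level=ci_level, ci_method=ci_method, boundary=boundary,
        fit_report=fit_report, _stats=stats,
    )


def confidence_intervals(components: VarianceComponents, level: float = 0.95,
                         ci_method: str = "profile") -> dict[str, tuple[float, float]]:
    """Recompute intervals for a converged fit at another level.

    Returns a mapping with keys ``mean``, ``sigma_pt``, ``sigma_fr``,
    ``sigma_intra``; SD intervals are bounded below by 0 and collapse to
    the point estimate at ``level=0``.
    """
    if components._stats is None:
        raise ValueError("fit does not carry its sufficient statistics")
    stats = components._stats
    vhat = np.array(components.variances)
    obj_min = components.fit_report["neg2_restricted_loglik"]
    mu, mu_var = _gls_mean_and_var(*vhat, stats)
    out: dict[str, tuple[float, float]] = {}
    if ci_method == "profile":
        for i, name in enumerate(_COMPONENT_NAMES):
            lo_v, hi_v, _ = _profile_ci_variance(stats, vhat, obj_min, i, level)
            out[name] = (float(np.sqrt(lo_v)), float(np.sqrt(hi_v)))
    elif ci_method == "bootstrap":
        boot = _bootstrap_cis(stats, vhat, mu, level, 200, 0)
        out = {name: boot[name] for name in _COMPONENT_NAMES}
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z = norm.ppf(0.5 + level / 2.0) if level > 0 else 0.0
    out["mean"] = (mu - z * np.sqrt(mu_var), mu + z * np.sqrt(mu_var))
    return out


def overall_mean_test(components: VarianceComponents) -> bool:
    """True iff the CI for the overall mean excludes 0 (inclusive bounds)."""
    lo, hi = components.mean_ci
    return not (lo <= 0.0 <= hi)
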