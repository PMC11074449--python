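"""Likelihood-ratio computation and experiment drivers.

The LR is P(E | Hp) / P(E | Hd) with the nuisance parameters (mu, omega,
epsilon and, for K > 2, the subclone weight split) maximized separately
under each hypothesis; the a-priori parameters M_xn (normal-cell fraction,
from pathology) and phi (variant incidence) are fixed, not searched.

Drivers reproduce the study designs: a 21 x 21 grid of LRs over
[M_xn +/- 0.10] x the colorectal phi range, per-locus-phi interval LRs over
the M_xn confidence interval, a non-contributor (Hd-true) specificity test
with randomly generated persons of interest, kinship alternatives
(parent-offspring, full sibling) under Hd, and a gamma Q-Q diagnostic of
locus total peak heights.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.stats import qmc

from .str_io import DEFAULT_AT, FrequencyTable, KitMap, STRProfile, ValidationError
from .genotype_priors import (HD_FS, HD_PO, HD_UNRELATED, HP, HypothesisSpec,
                              VariantIncidence, estimate_min_contributors)
from .peak_model import DegradationFit, GammaParams, LikelihoodTables, fit_degradation

logger = logging.getLogger("tumorlr")

LN10 = math.log(10.0)

OMEGA_BOUNDS = (0.05, 1.5)
EPSILON_BOUNDS = (0.1, 1.0)


class OptimizationError(RuntimeError):
    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class FitResult:
    params: GammaParams
    log_likelihood: float
    per_locus: dict[str, float]
    n_evaluations: int = 0
    converged: bool = True


@dataclass
class LRResult:
    log10_lr: float
    hp_fit: FitResult
    hd_fit: FitResult
    per_locus_log10_lr: dict[str, float]
    noc: int
    hd_kind: str

    @property
    def lr(self) -> float:
        return 10.0 ** self.log10_lr


# ---------------------------------------------------------------------------
# nuisance-parameter maximization
# ---------------------------------------------------------------------------

def _smart_start(evidence: STRProfile, deg: DegradationFit, include_eps: bool,
                 K: int) -> list[float]:
    totals = [sum(p.height for p in obs.peaks if p.height is not None)
              for obs in evidence.loci.values()]
    totals = [t for t in totals if t > 0]
    mu0 = (np.median(totals) / 2.0) if totals else 1000.0
    x = [math.log(max(mu0, 50.0)), 0.25]
    if include_eps:
        x.append(min(max(deg.epsilon, EPSILON_BOUNDS[0] + 1e-6), 1.0))
    x += [0.5] * (K - 2)  # stick-breaking split of the subclone mass
    return x


def _unpack(x, mxn: float, include_eps: bool, K: int):
    mu = math.exp(x[0])
    omega = x[1]
    eps = x[2] if include_eps else 1.0
    split = np.empty(K - 1)
    rest = 1.0
    pos = 2 + int(include_eps)
    for i in range(K - 2):
        split[i] = rest * x[pos + i]
        rest -= split[i]
    split[K - 2] = rest
    w = np.empty(K)
    w[0] = mxn
    w[1:] = (1.0 - mxn) * split
    return mu, omega, eps, w


def maximize_likelihood(evidence: STRProfile, hyp: HypothesisSpec,
                        freqs: FrequencyTable, kit: KitMap,
                        at: float = DEFAULT_AT, seed: int = 0,
                        n_starts: int = 5,
                        degradation: DegradationFit | None = None,
                        tables: LikelihoodTables | None = None,
                        xtol: float = 1e-6, ftol: float = 1e-8) -> FitResult:
    """Maximize the profile likelihood over (mu, omega[, epsilon, split])
    with bounded Powell search from deterministic multi-starts (a data-driven
    start plus seeded Sobol points)."""
    if tables is None:
        tables = LikelihoodTables(evidence, hyp, freqs, kit, at=at)
    if degradation is None:
        try:
            degradation = fit_degradation(evidence)
        except ValidationError:
            degradation = DegradationFit(1.0, 0.0, include_degradation=False)
    include_eps = degradation.include_degradation
    K = hyp.K

    if tables.infeasible_loci:
        # some locus cannot be explained under this hypothesis at any
        # parameter values: the likelihood is identically zero
        logger.info("%s structurally excluded (loci %s)", hyp.kind,
                    ",".join(tables.infeasible_loci))
        start = _smart_start(evidence, degradation, include_eps, K)
        mu, omega, eps, w = _unpack(start, hyp.mxn, include_eps, K)
        _, per_locus = tables.log_likelihood(mu, omega, eps, w)
        return FitResult(params=GammaParams(mu=mu, omega=omega, epsilon=eps, weights=w),
                         log_likelihood=-np.inf,
                         per_locus=dict(zip(tables.loci, per_locus)),
                         n_evaluations=1, converged=True)

    bounds = [(math.log(max(at / 10.0, 1.0)), math.log(1e5)), OMEGA_BOUNDS]
    if include_eps:
        bounds.append(EPSILON_BOUNDS)
    bounds += [(1e-6, 1.0 - 1e-6)] * (K - 2)

    evals = 0

    def objective(x):
        nonlocal evals
        evals += 1
        mu, omega, eps, w = _unpack(x, hyp.mxn, include_eps, K)
        total, _ = tables.log_likelihood(mu, omega, eps, w)
        return 1e12 if not np.isfinite(total) else -total

    starts = [_smart_start(evidence, degradation, include_eps, K)]
    if n_starts > 1:
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        sob = qmc.Sobol(d=len(bounds), scramble=True, seed=seed)
        starts += list(lo + sob.random(n_starts - 1) * (hi - lo))

    best = None
    for x0 in starts:
        res = optimize.minimize(objective, np.asarray(x0, dtype=float),
                                method="Powell", bounds=bounds,
                                options={"xtol": xtol, "ftol": ftol,
                                         "maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise OptimizationError(
            f"likelihood maximization failed under {hyp.kind}", best=best)

    mu, omega, eps, w = _unpack(best.x, hyp.mxn, include_eps, K)
    total, per_locus = tables.log_likelihood(mu, omega, eps, w)
    params = GammaParams(mu=mu, omega=omega, epsilon=eps, weights=w)
    return FitResult(params=params, log_likelihood=total,
                     per_locus=dict(zip(tables.loci, per_locus)),
                     n_evaluations=evals, converged=bool(best.success))


# ---------------------------------------------------------------------------
# LR
# ---------------------------------------------------------------------------

def compute_lr(evidence: STRProfile, poi: STRProfile, mxn: float,
               phi: VariantIncidence, freqs: FrequencyTable, kit: KitMap,
               hd_kind: str = HD_UNRELATED, at: float = DEFAULT_AT,
               K: int | None = None, seed: int = 0, n_starts: int = 5,
               degradation: DegradationFit | None = None,
               hd_fit: FitResult | None = None,
               xtol: float = 1e-6, ftol: float = 1e-8) -> LRResult:
    """log10 LR of Hp (evidence from *poi*) against an Hd kind, with per-locus
    decomposition. Numerator and denominator are maximized independently; a
    precomputed *hd_fit* (e.g. cached across non-contributors) is reused."""
    if K is None:
        K = estimate_min_contributors(evidence)
    if degradation is None:
        try:
            degradation = fit_degradation(evidence)
        except ValidationError:
            degradation = DegradationFit(1.0, 0.0, include_degradation=False)
    hyp_p = HypothesisSpec(kind=HP, K=K, poi=poi, mxn=mxn, phi=phi)
    hp_fit = maximize_likelihood(evidence, hyp_p, freqs, kit, at=at, seed=seed,
                                 n_starts=n_starts, degradation=degradation,
                                 xtol=xtol, ftol=ftol)
    if hd_fit is None:
        hyp_d = HypothesisSpec(kind=hd_kind, K=K,
                               poi=None if hd_kind == HD_UNRELATED else poi,
                               mxn=mxn, phi=phi)
        hd_fit = maximize_likelihood(evidence, hyp_d, freqs, kit, at=at,
                                     seed=seed, n_starts=n_starts,
                                     degradation=degradation)
    per_locus = {
        locus: (hp_fit.per_locus[locus] - hd_fit.per_locus[locus]) / LN10
        for locus in hp_fit.per_locus
    }
    return LRResult(
        log10_lr=(hp_fit.log_likelihood - hd_fit.log_likelihood) / LN10,
        hp_fit=hp_fit, hd_fit=hd_fit, per_locus_log10_lr=per_locus,
        noc=K, hd_kind=hd_kind)


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def mxn_interval(center: float, half_width: float = 0.10, n: int = 21
                 ) -> np.ndarray:
    """Evenly spaced M_xn values on [center - hw, center + hw], clipped to
    [0.01, 0.99] (the +/-10% confidence interval is read as absolute)."""
    lo = max(0.01, center - half_width)
    hi = min(0.99, center + half_width)
    return np.linspace(lo, hi, n)


@dataclass
class AxisFit:
    fixed_value: float
    slope: float
    intercept: float
    pearson_r: float


@dataclass
class GridResult:
    mxn_grid: np.ndarray
    phi_grid: np.ndarray
    log10_lr: np.ndarray  # (n_mxn, n_phi)
    mxn_fits: list[AxisFit] = field(default_factory=list)  # vs mxn at fixed phi
    phi_fits: list[AxisFit] = field(default_factory=list)  # vs phi at fixed mxn


def grid_experiment(evidence: STRProfile, poi: STRProfile, mxn_center: float,
                    freqs: FrequencyTable, kit: KitMap,
                    phi_range: tuple[float, float] = (0.0775, 0.4341),
                    n: int = 21, loss_fraction: float = 0.5,
                    at: float = DEFAULT_AT, K: int | None = None,
                    seed: int = 0, n_starts: int = 5) -> GridResult:
    """LRs over an n x n grid of (M_xn, phi) a-priori parameters, with
    least-squares fits of log10 LR against each axis."""
    mxns = mxn_interval(mxn_center, n=n)
    phis = np.linspace(phi_range[0], phi_range[1], n)
    mat = np.full((n, n), np.nan)
    deg = fit_degradation(evidence)
    for i, mxn in enumerate(mxns):
        for j, phi in enumerate(phis):
            try:
                res = compute_lr(evidence, poi, float(mxn),
                                 VariantIncidence.scalar(float(phi), loss_fraction),
                                 freqs, kit, at=at, K=K, seed=seed,
                                 n_starts=n_starts, degradation=deg)
                mat[i, j] = res.log10_lr
            except (OptimizationError, ValidationError) as exc:
                logger.warning("grid cell (%.3f, %.3f) failed: %s", mxn, phi, exc)
    mxn_fits = [_axis_fit(mxns, mat[:, j], float(phis[j])) for j in range(n)]
    phi_fits = [_axis_fit(phis, mat[i, :], float(mxns[i])) for i in range(n)]
    return GridResult(mxn_grid=mxns, phi_grid=phis, log10_lr=mat,
                      mxn_fits=[f for f in mxn_fits if f is not None],
                      phi_fits=[f for f in phi_fits if f is not None])


def _axis_fit(x, y, fixed) -> AxisFit | None:
    m = np.isfinite(y)
    if m.sum() < 3:
        return None
    res = stats.linregress(np.asarray(x)[m], np.asarray(y)[m])
    return AxisFit(fixed_value=fixed, slope=float(res.slope),
                   intercept=float(res.intercept), pearson_r=float(res.rvalue))


@dataclass
class IntervalResult:
    mxn_values: np.ndarray
    log10_lr: np.ndarray

    @property
    def summary(self) -> dict[str, float]:
        v = self.log10_lr[np.isfinite(self.log10_lr)]
        return {"min": float(v.min()), "mean": float(v.mean()),
                "max": float(v.max())}


def interval_lr(evidence: STRProfile, poi: STRProfile, mxn_center: float,
                phi: VariantIncidence, freqs: FrequencyTable, kit: KitMap,
                n: int = 21, at: float = DEFAULT_AT, K: int | None = None,
                seed: int = 0, n_starts: int = 5) -> IntervalResult:
    """LR interval over [M_xn +/- 0.10] at per-locus phi (mean-substituted for
    missing loci): the conservative report accompanying a point estimate."""
    mxns = mxn_interval(mxn_center, n=n)
    deg = fit_degradation(evidence)
    vals = np.full(n, np.nan)
    for i, mxn in enumerate(mxns):
        res = compute_lr(evidence, poi, float(mxn), phi, freqs, kit, at=at,
                         K=K, seed=seed, n_starts=n_starts, degradation=deg)
        vals[i] = res.log10_lr
    return IntervalResult(mxn_values=mxns, log10_lr=vals)


@dataclass
class NonContributorResult:
    group_mxn: np.ndarray
    log10_lr: dict[float, np.ndarray]  # group mxn -> per-POI values

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate(list(self.log10_lr.values()))

    @property
    def fraction_below_zero(self) -> float:
        pooled = self.pooled
        return float(np.mean(pooled < 0.0))

    def boxplot_stats(self) -> dict[float, dict[str, float]]:
        out = {}
        for mxn, vals in self.log10_lr.items():
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            out[mxn] = {"min": float(vals.min()), "q1": float(q1),
                        "median": float(med), "q3": float(q3),
                        "max": float(vals.max()), "mean": float(vals.mean())}
        return out


def non_contributor_test(evidence: STRProfile, freqs: FrequencyTable,
                         kit: KitMap, mxn_values, phi: VariantIncidence,
                         n_individuals: int = 1000, groups: int = 5,
                         per_group: int = 200, at: float = DEFAULT_AT,
                         K: int | None = None, seed: int = 0,
                         n_starts_hp: int = 1) -> NonContributorResult:
    """Hd-true specificity test: random persons of interest scored against
    the evidence at the five M_xn group values (min, quartiles, max of the
    interval). The Hd-unrelated denominator is independent of the POI and is
    optimized once per group; the per-POI numerator uses a reduced
    multi-start count (under-maximizing it can only push non-contributor LRs
    further below zero)."""
    from .simulate import sample_reference_profile  # cycle-free at call time

    mxn_values = np.asarray(mxn_values, dtype=float)
    group_mxn = np.percentile(mxn_values, np.linspace(0, 100, groups))
    if K is None:
        K = estimate_min_contributors(evidence)
    deg = fit_degradation(evidence)
    per_group = min(per_group, max(1, n_individuals // groups))
    rng = np.random.default_rng(seed)

    results: dict[float, np.ndarray] = {}
    for gi, mxn in enumerate(group_mxn):
        hyp_d = HypothesisSpec(kind=HD_UNRELATED, K=K, poi=None,
                               mxn=float(mxn), phi=phi)
        hd_fit = maximize_likelihood(evidence, hyp_d, freqs, kit, at=at,
                                     seed=seed, n_starts=5, degradation=deg)
        vals = np.empty(per_group)
        for i in range(per_group):
            poi = sample_reference_profile(
                freqs, seed=int(rng.integers(2 ** 31)),
                sample_id=f"NC{gi}_{i}", loci=list(evidence.loci), kit=kit)
            res = compute_lr(evidence, poi, float(mxn), phi, freqs, kit,
                             at=at, K=K, seed=seed, n_starts=n_starts_hp,
                             degradation=deg, hd_fit=hd_fit,
                             xtol=1e-4, ftol=1e-7)
            vals[i] = res.log10_lr
        results[float(mxn)] = vals
    return NonContributorResult(group_mxn=group_mxn, log10_lr=results)


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass
class QQDiagnostic:
    shape: float
    scale: float
    theoretical: np.ndarray
    empirical: np.ndarray


def gamma_qq_diagnostic(evidence: STRProfile, min_loci: int = 10) -> QQDiagnostic:
    """Maximum-likelihood gamma fit to per-locus total peak heights with
    theoretical-vs-empirical quantile pairs for a Q-Q plot."""
    totals = np.array([
        sum(p.height for p in obs.peaks if p.height is not None)
        for obs in evidence.loci.values()
    ])
    totals = totals[totals > 0]
    if totals.size < min_loci:
        raise ValidationError(f"Q-Q diagnostic needs >= {min_loci} loci")
    if np.ptp(totals) == 0:
        raise ValidationError("degenerate data: all locus totals equal")
    shape, _, scale = stats.gamma.fit(totals, floc=0)
    emp = np.sort(totals)
    probs = (np.arange(1, emp.size + 1) - 0.5) / emp.size
    theo = stats.gamma.ppf(probs, a=shape, scale=scale)
    return QQDiagnostic(shape=float(shape), scale=float(scale),
                        theoretical=theo, empirical=emp)
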