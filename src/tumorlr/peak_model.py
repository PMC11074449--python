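"""Gamma peak-height likelihood for STR mixtures.

Peak heights follow Y ~ gamma(1/omega^2, mu*omega^2): mu is the expected
height of one allele copy at full mixture weight (undegraded) and omega the
coefficient of variation. Height contributions of the cell populations are
independent, so with a shared scale theta = mu*omega^2 the per-allele shapes
add:

    shape(a) = (1/omega^2) * sum_pop w_pop * n(a, pop) * D(size(a)),

with n(a, pop) in {0, 1, 2} the copy number of allele a in population pop
and D the degradation factor epsilon ** ((size - 90) / 100) — the standard
log-linear "ski-slope" decay of FFPE material, epsilon being the survival
probability of a 100 bp stretch.

Dropout of an expected allele is the gamma probability mass below the
analytical threshold (CDF at AT); an observed allele no population carries
makes the genotype combination impossible (drop-in is not modeled).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .str_io import LOSS, Q, DEFAULT_AT, FrequencyTable, KitMap, LocusObservation, \
    STRProfile, ValidationError
from .genotype_priors import GenotypeCombination, HypothesisSpec, enumerate_combinations

logger = logging.getLogger("tumorlr")

_LOG0 = -np.inf


@dataclass
class GammaParams:
    """Nuisance parameters of the peak-height model.

    weights[0] is the normal-cell fraction M_xn; weights[1:] are the K-1
    subclone fractions, summing to 1 - M_xn.
    """

    mu: float
    omega: float
    epsilon: float = 1.0
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.mu <= 0 or self.omega <= 0:
            raise ValidationError("mu and omega must be positive")
        if not 0 < self.epsilon <= 1:
            raise ValidationError(f"epsilon outside (0,1]: {self.epsilon}")
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValidationError("negative mixture weight")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValidationError("mixture weights must sum to 1")

    @property
    def scale(self) -> float:
        return self.mu * self.omega ** 2


@dataclass
class DegradationFit:
    """Log-linear degradation fit: per_base_slope = P(no breakage between a
    given base pair); p_deg = 1 - per_base_slope; epsilon = slope^100."""

    per_base_slope: float
    intercept: float
    include_degradation: bool

    @property
    def p_deg(self) -> float:
        return 1.0 - self.per_base_slope

    @property
    def epsilon(self) -> float:
        return min(1.0, self.per_base_slope ** 100)


def degradation_factor(size: float, epsilon: float) -> float:
    """epsilon ** ((size - 90) / 100); epsilon = 1 disables degradation."""
    if epsilon <= 0 or epsilon > 1:
        raise ValidationError(f"epsilon outside (0,1]: {epsilon}")
    if size <= 0:
        raise ValidationError(f"non-positive fragment size: {size}")
    return epsilon ** ((size - 90.0) / 100.0)


def fit_degradation(profile: STRProfile, kit: KitMap | None = None,
                    include_threshold: float = 1e-4) -> DegradationFit:
    """Least-squares fit of log mean locus peak height on mean locus fragment
    size. Degradation is included downstream when p_deg exceeds
    *include_threshold*."""
    xs, ys = [], []
    for obs in profile.loci.values():
        heights = [p.height for p in obs.peaks if p.height is not None]
        size = obs.mean_size()
        if heights and size is not None:
            xs.append(size)
            ys.append(math.log(float(np.mean(heights))))
    if len(xs) < 3:
        raise ValidationError(f"degradation fit needs >= 3 usable loci, got {len(xs)}")
    res = stats.linregress(xs, ys)
    slope_pb = float(np.exp(min(res.slope, 0.0)))  # heights cannot grow with size
    return DegradationFit(per_base_slope=slope_pb, intercept=float(res.intercept),
                          include_degradation=(1.0 - slope_pb) > include_threshold)


def allele_shapes(combo: GenotypeCombination, params: GammaParams, kit: KitMap,
                  locus: str, sizes: dict[str, float] | None = None
                  ) -> dict[str, float]:
    """Gamma shape per allele for one genotype combination (LOSS carries no
    copies). *sizes* overrides kit sizes, e.g. with observed fragment sizes."""
    shapes: dict[str, float] = {}
    inv_o2 = 1.0 / params.omega ** 2
    for w, geno in zip(params.weights, combo.populations):
        for allele in geno:
            if allele == LOSS:
                continue
            if allele not in shapes:
                shapes[allele] = 0.0
            size = (sizes or {}).get(allele)
            if size is None:
                size = kit.mean_size(locus) if allele == Q else kit.size(locus, allele)
            shapes[allele] += inv_o2 * w * degradation_factor(size, params.epsilon)
    return shapes


# ---------------------------------------------------------------------------
# vectorized likelihood tables
# ---------------------------------------------------------------------------

class LikelihoodTables:
    """Precomputed per-hypothesis arrays for fast likelihood evaluation.

    Genotype priors do not depend on the optimised nuisance parameters
    (mu, omega, epsilon, subclone split), so enumeration happens once per
    (evidence, hypothesis) and each evaluation only recomputes the gamma
    terms, vectorised over a flattened (combination x allele) table across
    all loci.
    """

    def __init__(self, evidence: STRProfile, hyp: HypothesisSpec,
                 freqs: FrequencyTable, kit: KitMap, at: float = DEFAULT_AT):
        self.hyp = hyp
        self.at = float(at)
        self.loci: list[str] = list(evidence.loci)
        self.combos: list[list[GenotypeCombination]] = []

        K = hyp.K
        per_locus = []
        for locus in self.loci:
            obs = evidence.loci[locus]
            combos = enumerate_combinations(obs, hyp, freqs)
            self.combos.append([c for c, _ in combos])
            # observed alleles are always on the axis so that a combination
            # failing to explain one is scored impossible, not skipped
            universe: list[str] = list(obs.alleles)
            for c, _ in combos:
                for geno in c.populations:
                    for a in geno:
                        if a != LOSS and a not in universe:
                            universe.append(a)
            A = len(universe)
            index = {a: i for i, a in enumerate(universe)}
            heights = np.full(A, np.nan)
            sizes = np.empty(A)
            for a, i in index.items():
                h = obs.height(a)
                heights[i] = np.nan if h is None else h
                pk = next((p for p in obs.peaks if p.allele == a), None)
                if pk is not None and pk.size is not None:
                    sizes[i] = pk.size
                elif a == Q:
                    ms = obs.mean_size()
                    sizes[i] = ms if ms is not None else kit.mean_size(locus)
                else:
                    sizes[i] = kit.size(locus, a)
            ncopy = np.zeros((len(combos), K, A))
            logprior = np.empty(len(combos))
            for ci, (c, p) in enumerate(combos):
                logprior[ci] = math.log(p)
                for ki, geno in enumerate(c.populations):
                    for a in geno:
                        if a != LOSS:
                            ncopy[ci, ki, index[a]] += 1.0
            per_locus.append((logprior, ncopy, heights, sizes))

        # flatten across loci, padding the allele axis
        Amax = max((t[3].size for t in per_locus), default=1)
        Ctot = sum(t[0].size for t in per_locus)
        self.logprior = np.empty(Ctot)
        self.ncopy = np.zeros((Ctot, K, Amax))
        self.heights = np.full((Ctot, Amax), np.nan)
        self.size_expo = np.zeros((Ctot, Amax))  # (size - 90) / 100
        self.valid = np.zeros((Ctot, Amax), dtype=bool)
        self.starts = np.zeros(len(per_locus), dtype=int)
        pos = 0
        for li, (logprior, ncopy, heights, sizes) in enumerate(per_locus):
            C, _, A = ncopy.shape
            self.starts[li] = pos
            sl = slice(pos, pos + C)
            self.logprior[sl] = logprior
            self.ncopy[sl, :, :A] = ncopy
            self.heights[sl, :A] = heights[None, :]
            self.size_expo[sl, :A] = (sizes[None, :] - 90.0) / 100.0
            self.valid[sl, :A] = True
            pos += C
        self.obs = self.valid & ~np.isnan(self.heights)
        self.log_h = np.where(self.obs, np.log(np.where(self.obs, self.heights, 1.0)), 0.0)
        self.n_combos = Ctot
        # a locus is infeasible when every combination leaves some observed
        # allele without a carrier: its likelihood is 0 at any parameters
        covered = (self.ncopy.sum(axis=1) > 0) | ~self.obs
        combo_ok = covered.all(axis=1)
        locus_ids = np.repeat(np.arange(len(self.loci)),
                              np.diff(np.append(self.starts, Ctot)))
        self.infeasible_loci = [
            self.loci[i] for i in range(len(self.loci))
            if not combo_ok[locus_ids == i].any()
        ]

    def weights(self, mxn: float, split: np.ndarray | None = None) -> np.ndarray:
        """Full weight vector [mxn, subclone weights] from a split of 1-mxn."""
        K = self.hyp.K
        if split is None:
            split = np.full(K - 1, 1.0 / (K - 1))
        w = np.empty(K)
        w[0] = mxn
        w[1:] = (1.0 - mxn) * np.asarray(split)
        return w

    def log_likelihood(self, mu: float, omega: float, epsilon: float,
                       weights: np.ndarray) -> tuple[float, np.ndarray]:
        """Profile log-likelihood and per-locus vector at fixed parameters."""
        inv_o2 = 1.0 / omega ** 2
        theta = mu * omega ** 2
        eff = np.einsum("k,cka->ca", weights, self.ncopy)
        if epsilon < 1.0:
            eff = eff * np.exp(math.log(epsilon) * self.size_expo)
        shape = inv_o2 * eff
        pos = shape > 0.0

        terms = np.zeros_like(shape)
        # observed peaks: gamma log-density
        m = self.obs & pos
        if np.any(m):
            s = shape[m]
            terms[m] = ((s - 1.0) * self.log_h[m] - self.heights[m] / theta
                        - special.gammaln(s) - s * math.log(theta))
        # observed peak that no population explains: impossible (no drop-in)
        terms[self.obs & ~pos] = _LOG0
        # expected but unobserved: dropout mass below AT
        m = self.valid & ~self.obs & pos
        if np.any(m):
            with np.errstate(divide="ignore"):
                terms[m] = np.log(special.gammainc(shape[m], self.at / theta))

        combo_ll = self.logprior + terms.sum(axis=1)
        per_locus = _segment_logsumexp(combo_ll, self.starts)
        return float(per_locus.sum()), per_locus


def _segment_logsumexp(x: np.ndarray, starts: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.maximum.reduceat(x, starts)
        safe_mx = np.where(np.isfinite(mx), mx, 0.0)
        seg = np.repeat(np.arange(starts.size), np.diff(np.append(starts, x.size)))
        sums = np.add.reduceat(np.exp(x - safe_mx[seg]), starts)
        out = np.where(np.isfinite(mx), safe_mx + np.log(sums), mx)
    return out


# ---------------------------------------------------------------------------
# public likelihood operations
# ---------------------------------------------------------------------------

def locus_likelihood(obs: LocusObservation, combo: GenotypeCombination,
                     params: GammaParams, at: float = DEFAULT_AT,
                     kit: KitMap | None = None) -> float:
    """Likelihood density of one locus's peaks given a genotype combination."""
    sizes = {p.allele: p.size for p in obs.peaks if p.size is not None}
    if obs.mean_size() is not None:
        sizes[Q] = obs.mean_size()
    shapes = allele_shapes(combo, params, kit, obs.locus, sizes=sizes)
    theta = params.scale
    density = 1.0
    for peak in obs.peaks:
        s = shapes.get(peak.allele, 0.0)
        if s <= 0.0:
            return 0.0  # drop-in not modeled
        density *= stats.gamma.pdf(peak.height, a=s, scale=theta)
    observed = set(obs.alleles)
    for allele, s in shapes.items():
        if s > 0.0 and allele not in observed:
            density *= stats.gamma.cdf(at, a=s, scale=theta)
    return float(density)


def profile_log_likelihood(evidence: STRProfile, hyp: HypothesisSpec,
                           params: GammaParams, freqs: FrequencyTable,
                           kit: KitMap, at: float = DEFAULT_AT
                           ) -> tuple[float, dict[str, float]]:
    """Sum over loci of log sum over genotype combinations of
    prior * peak-height density. Returns (total, per-locus mapping); loci
    whose enumeration carries zero likelihood contribute -inf and are
    flagged."""
    tables = LikelihoodTables(evidence, hyp, freqs, kit, at=at)
    total, per_locus = tables.log_likelihood(params.mu, params.omega,
                                             params.epsilon, params.weights)
    out = dict(zip(tables.loci, per_locus))
    for locus, v in out.items():
        if not np.isfinite(v):
            logger.warning("locus %s has zero likelihood under %s", locus, hyp.kind)
    return total, out
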