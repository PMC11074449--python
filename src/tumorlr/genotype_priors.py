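"""Genotype enumeration and prior probabilities for tumor-tissue mixtures.

Tumor tissue is modeled as a mixture of one normal cell population and K-1
tumor subclones. At each locus the prior probability of a genotype
combination g = (g_n, g_t,1..K-1) factorizes as

    P(g | H, phi) = P(g_n | H) * prod_k P(g_t,k | g_n, phi),

where P(g_n | H) is 1 for the person of interest under Hp, a Hardy-Weinberg
prior under the unrelated-defense hypothesis, and an IBD-conditioned kinship
prior when the defense names a parent-offspring (PO) or full-sibling (FS)
relative.

Each tumor subclone genotype descends from the normal genotype slot by slot:
an allele copy is retained with probability 1-phi, lost with probability
phi*lambda, or replaced by allele a with probability phi*(1-lambda)*f(a),
f being the population frequency (replacement may regenerate the source
allele). phi is the per-locus incidence of somatic STR variants; lambda
splits a variant event between loss (LOH-type) and replacement (Aadd/Anew-
type) outcomes. This descent model gives nonzero prior to all observed
variant classes and normalizes exactly over the tumor genotype states.

Unobserved alleles are aggregated into the single symbol Q carrying the
residual frequency mass, which keeps enumeration finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement, product

from .str_io import LOSS, Q, FrequencyTable, LocusObservation, STRProfile, ValidationError

HP = "HP"
HD_UNRELATED = "HD_UNRELATED"
HD_PO = "HD_PO"
HD_FS = "HD_FS"

#: IBD coefficients (k0, k1, k2) per relationship
IBD_COEFFS = {"PO": (0.0, 1.0, 0.0), "FS": (0.25, 0.5, 0.25)}

#: published per-locus incidence range of somatic STR variants in colorectal
#: carcinoma (19 loci)
COLORECTAL_PHI_RANGE = (0.0775, 0.4341)


@dataclass(frozen=True)
class Genotype:
    """An unordered pair of allele designations."""

    alleles: tuple[str, str]

    def __init__(self, a, b: str | None = None):
        if b is None:
            if isinstance(a, str):
                raise ValidationError("Genotype needs two allele designations")
            a, b = a  # unpack a pair
        object.__setattr__(self, "alleles", tuple(sorted((str(a), str(b)))))

    def __iter__(self):
        return iter(self.alleles)

    def __contains__(self, allele):
        return allele in self.alleles

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    def count(self, allele: str) -> int:
        return self.alleles.count(allele)

    def __repr__(self):
        return f"Genotype({self.alleles[0]},{self.alleles[1]})"


@dataclass
class GenotypeCombination:
    normal: Genotype
    subclones: tuple[Genotype, ...]

    def __post_init__(self):
        if len(self.subclones) < 1:
            raise ValidationError("at least one tumor subclone required (K >= 2)")
        self.subclones = tuple(self.subclones)

    @property
    def populations(self) -> tuple[Genotype, ...]:
        return (self.normal, *self.subclones)


@dataclass
class VariantIncidence:
    """Per-locus incidence phi of somatic STR variants.

    Loci absent from the mapping fall back to the arithmetic mean of the
    provided values. ``loss_fraction`` (lambda) is the share of a variant
    event realised as allele loss rather than replacement.
    """

    phi: dict[str, float] = field(default_factory=dict)
    default: float | None = None
    loss_fraction: float = 0.5

    def __post_init__(self):
        for locus, p in self.phi.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"phi for {locus} outside [0,1]: {p}")
        if not 0.0 <= self.loss_fraction <= 1.0:
            raise ValidationError(f"loss_fraction outside [0,1]: {self.loss_fraction}")
        if self.default is None and self.phi:
            self.default = sum(self.phi.values()) / len(self.phi)

    @classmethod
    def scalar(cls, phi: float, loss_fraction: float = 0.5) -> "VariantIncidence":
        if not 0.0 <= phi <= 1.0:
            raise ValidationError(f"phi outside [0,1]: {phi}")
        return cls(phi={}, default=phi, loss_fraction=loss_fraction)

    def at(self, locus: str) -> float:
        p = self.phi.get(locus, self.default)
        if p is None:
            raise ValidationError(f"no phi value for locus {locus} and no default")
        return p


@dataclass
class HypothesisSpec:
    """One side of the LR: who contributed the normal cells, and the mixture
    structure (K populations, normal fraction mxn, variant incidence phi)."""

    kind: str
    K: int
    poi: STRProfile | None
    mxn: float
    phi: VariantIncidence

    def __post_init__(self):
        if self.kind not in (HP, HD_UNRELATED, HD_PO, HD_FS):
            raise ValidationError(f"unknown hypothesis kind {self.kind!r}")
        if self.K < 2:
            raise ValidationError(f"K must be >= 2, got {self.K}")
        if not 0.0 <= self.mxn <= 1.0:
            raise ValidationError(f"mxn outside [0,1]: {self.mxn}")
        if self.kind in (HP, HD_PO, HD_FS) and self.poi is None:
            raise ValidationError(f"{self.kind} requires a person-of-interest profile")


# ---------------------------------------------------------------------------
# number of contributors
# ---------------------------------------------------------------------------

def estimate_min_contributors(profile: STRProfile) -> int:
    """Minimum number of cell populations by the maximum allele count (MAC):
    2 when Lmax < 3, else ceiling(Lmax / 2)."""
    counts = [len(obs.peaks) for obs in profile.loci.values()]
    lmax = max(counts, default=0)
    if lmax == 0:
        raise ValidationError("profile has no observed alleles at any locus")
    if lmax < 3:
        return 2
    return math.ceil(lmax / 2)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def hw_prior(g: Genotype, freqs: FrequencyTable, locus: str,
             q_candidates=None) -> float:
    """Hardy-Weinberg genotype prior: f_a^2 or 2 f_a f_b.

    The Q allele takes the residual frequency mass relative to the explicit
    candidate allele set *q_candidates* (required when g contains Q).
    """
    if LOSS in g:
        raise ValidationError("normal genotypes cannot contain LOSS")

    def f(a):
        if a == Q:
            if q_candidates is None:
                raise ValidationError("Q frequency needs the candidate allele set")
            return freqs.residual(locus, q_candidates)
        return freqs.freq(locus, a)

    a, b = g.alleles
    return f(a) ** 2 if a == b else 2.0 * f(a) * f(b)


def descent_distribution(source: str, phi: float, loss_fraction: float,
                         replacement_freqs: dict[str, float]) -> dict[str, float]:
    """Distribution of one tumor allele slot descended from *source*:
    retain with 1-phi, loss with phi*lambda, replace by a with
    phi*(1-lambda)*f(a) over *replacement_freqs* (which sums to 1)."""
    if not 0.0 <= phi <= 1.0:
        raise ValidationError(f"phi outside [0,1]: {phi}")
    d: dict[str, float] = {}
    d[source] = 1.0 - phi
    d[LOSS] = d.get(LOSS, 0.0) + phi * loss_fraction
    rep = phi * (1.0 - loss_fraction)
    if rep > 0.0:
        for a, f in replacement_freqs.items():
            d[a] = d.get(a, 0.0) + rep * f
    return d


def replacement_frequencies(freqs: FrequencyTable, locus: str,
                            targets) -> dict[str, float]:
    """Normalized replacement-target distribution over explicit alleles plus
    the aggregate Q state (residual mass)."""
    out = {a: freqs.freq(locus, a) for a in targets if a not in (Q, LOSS)}
    out[Q] = freqs.residual(locus, [a for a in targets if a not in (Q, LOSS)])
    total = sum(out.values())
    return {a: f / total for a, f in out.items()}


def tumor_genotype_prior(g_t: Genotype, g_n: Genotype, phi: float,
                         loss_fraction: float,
                         replacement_freqs: dict[str, float]) -> float:
    """P(g_t | g_n, phi): probability that tumor genotype g_t descends from
    normal genotype g_n under the slot-wise variant model. Proper over
    unordered tumor states."""
    if LOSS in g_n:
        raise ValidationError("normal genotypes cannot contain LOSS")
    d1 = descent_distribution(g_n.alleles[0], phi, loss_fraction, replacement_freqs)
    d2 = descent_distribution(g_n.alleles[1], phi, loss_fraction, replacement_freqs)
    x, y = g_t.alleles
    if x == y:
        return d1.get(x, 0.0) * d2.get(x, 0.0)
    return d1.get(x, 0.0) * d2.get(y, 0.0) + d1.get(y, 0.0) * d2.get(x, 0.0)


def kinship_prior(g_u: Genotype, g_poi: Genotype, relationship: str,
                  freq) -> float:
    """P(g_u | g_poi, relationship) via IBD coefficients.

    PO: (k0,k1,k2) = (0,1,0); FS: (1/4,1/2,1/4). *freq* is a callable
    allele -> population frequency over the enumeration universe (Q residual
    included by the caller). Normalizes to 1 over all unordered g_u drawn
    from a universe whose frequencies sum to 1 and contains g_poi's alleles.
    """
    if relationship not in IBD_COEFFS:
        raise ValidationError(f"unsupported relationship {relationship!r}")
    if LOSS in g_u or LOSS in g_poi:
        raise ValidationError("kinship priors apply to normal genotypes only")
    k0, k1, k2 = IBD_COEFFS[relationship]
    a, b = g_poi.alleles
    x, y = g_u.alleles
    # 0 IBD: plain HW
    hw = freq(x) ** 2 if x == y else 2.0 * freq(x) * freq(y)
    # 1 IBD: one allele copied from a uniformly chosen poi allele, the other
    # drawn from the population
    p1 = 0.0
    for shared, other in ((x, y), (y, x)):
        share_prob = (int(shared == a) + int(shared == b)) / 2.0
        if share_prob:
            p1 += share_prob * freq(other)
    if x == y:
        p1 /= 2.0  # the two orderings coincide for homozygotes
    # 2 IBD: identical genotypes
    p2 = 1.0 if g_u == g_poi else 0.0
    return k0 * hw + k1 * p1 + k2 * p2


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def candidate_normal_alleles(locus_obs: LocusObservation,
                             hyp: HypothesisSpec) -> list[str]:
    """Candidate alleles for the normal genotype: observed + POI alleles
    under Hp; observed + Q under unrelated Hd; observed + POI alleles + Q
    under kinship Hd (POI alleles must be explicit for IBD conditioning)."""
    observed = list(locus_obs.alleles)
    if hyp.kind == HP:
        extra = [a for a in hyp.poi.genotype(locus_obs.locus) if a not in observed]
        return observed + extra
    if hyp.kind == HD_UNRELATED:
        return observed + [Q]
    extra = [a for a in hyp.poi.genotype(locus_obs.locus) if a not in observed]
    return observed + extra + [Q]


def candidate_tumor_alleles(normal_candidates, locus_obs: LocusObservation
                            ) -> list[str]:
    """Tumor allele states: every normal candidate plus the aggregate
    unobserved state Q and LOSS."""
    alleles = [a for a in normal_candidates if a != Q]
    for a in locus_obs.alleles:
        if a not in alleles:
            alleles.append(a)
    return alleles + [Q, LOSS]


def enumerate_combinations(locus_obs: LocusObservation, hyp: HypothesisSpec,
                           freqs: FrequencyTable
                           ) -> list[tuple[GenotypeCombination, float]]:
    """All genotype combinations at one locus with their prior probability
    under *hyp*; zero-prior combinations are pruned."""
    locus = locus_obs.locus
    normal_cands = candidate_normal_alleles(locus_obs, hyp)
    explicit = [a for a in normal_cands if a != Q]
    if not normal_cands:
        raise ValidationError(f"empty candidate allele set at {locus}")

    phi = hyp.phi.at(locus)
    lam = hyp.phi.loss_fraction
    rep_freqs = replacement_frequencies(freqs, locus, explicit)

    # normal genotypes with P(g_n | hyp)
    if hyp.kind == HP:
        normals = [(Genotype(*hyp.poi.genotype(locus)), 1.0)]
    elif hyp.kind == HD_UNRELATED:
        normals = [
            (g, hw_prior(g, freqs, locus, q_candidates=explicit))
            for g in (Genotype(a, b)
                      for a, b in combinations_with_replacement(sorted(normal_cands), 2))
        ]
    else:  # HD_PO / HD_FS
        rel = "PO" if hyp.kind == HD_PO else "FS"
        g_poi = Genotype(*hyp.poi.genotype(locus))
        q_mass = freqs.residual(locus, explicit)

        def f(a):
            return q_mass if a == Q else freqs.freq(locus, a)

        normals = [
            (g, kinship_prior(g, g_poi, rel, f))
            for g in (Genotype(a, b)
                      for a, b in combinations_with_replacement(sorted(normal_cands), 2))
        ]

    tumor_universe = candidate_tumor_alleles(normal_cands, locus_obs)
    tumor_states = [Genotype(a, b)
                    for a, b in combinations_with_replacement(sorted(tumor_universe), 2)]

    out: list[tuple[GenotypeCombination, float]] = []
    n_sub = hyp.K - 1
    for g_n, p_n in normals:
        if p_n <= 0.0:
            continue
        tumor_priors = [
            (g_t, tumor_genotype_prior(g_t, g_n, phi, lam, rep_freqs))
            for g_t in tumor_states
        ]
        tumor_priors = [(g, p) for g, p in tumor_priors if p > 0.0]
        for subs in product(tumor_priors, repeat=n_sub):
            prior = p_n
            for _, p in subs:
                prior *= p
            if prior > 0.0:
                out.append((GenotypeCombination(
                    normal=g_n, subclones=tuple(g for g, _ in subs)), prior))
    if not out:
        raise ValidationError(f"no genotype combination has positive prior at {locus}")
    return out
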