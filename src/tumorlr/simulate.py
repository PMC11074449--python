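"""Synthetic STR data emulating tumor/reference sample pairs.

Generates allele-frequency tables, Hardy-Weinberg reference genotypes,
tumor evidence profiles built from K-1 subclone genotypes carrying somatic
STR variants (additional alleles Aadd, replacement alleles Anew, partial and
complete loss of heterozygosity pLOH/LOH) at per-locus incidence phi, gamma
peak heights with log-linear degradation, and Mendelian relatives
(parent-offspring, full siblings).

The tumor-genotype sampler is the generative twin of the analytic descent
prior in :mod:`tumorlr.genotype_priors`: each subclone allele slot retains
its somatic source with probability 1 - phi, is lost with probability
phi * lambda, and is replaced by a population-frequency draw with
probability phi * (1 - lambda).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .str_io import (DEFAULT_AT, FrequencyTable, KitMap, LocusObservation,
                     Peak, STRProfile)
from .genotype_priors import COLORECTAL_PHI_RANGE

#: the 21 autosomal loci of the GlobalFiler kit
GLOBALFILER_AUTOSOMAL = [
    "D3S1358", "vWA", "D16S539", "CSF1PO", "TPOX", "D8S1179", "D21S11",
    "D18S51", "D2S441", "D19S433", "TH01", "FGA", "D22S1045", "D5S818",
    "D13S317", "D7S820", "SE33", "D10S1248", "D1S1656", "D12S391", "D2S1338",
]


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic cohort.

    mu = 1500 RFU and omega = 0.2 keep total locus heights far above the
    analytical threshold at M_xn >= 0.1, matching 1 ng template input;
    per_base_slope = 0.996 sits inside the observed FFPE degradation range
    (p_deg about 0.0015-0.0057 per bp). The default generative phi of 0.05
    per allele slot reproduces the realized alteration incidence of typical
    colorectal FFPE cohorts (about 0.09 altered loci per locus typed, i.e.
    most samples show 0-3 altered loci of 21); the larger published
    survey incidences remain the *analysis* prior.
    """

    n_loci: int = 21
    alleles_per_locus: tuple[int, int] = (5, 10)
    mu: float = 1500.0
    omega: float = 0.2
    per_base_slope: float = 0.996
    mxn: float = 0.4
    K: int = 2
    phi: float | dict[str, float] = 0.05
    loss_fraction: float = 0.5
    at: float = DEFAULT_AT
    seed: int = 0
    noiseless: bool = False
    microvariant_prob: float = 0.15

    def __post_init__(self):
        for name in ("mxn", "loss_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0,1]: {v}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")

    def phi_at(self, locus: str) -> float:
        if isinstance(self.phi, dict):
            if locus in self.phi:
                return self.phi[locus]
            return float(np.mean(list(self.phi.values())))
        return float(self.phi)


def default_kit(loci=None) -> KitMap:
    """A synthetic size map: tetranucleotide motifs with offsets staggered so
    locus mean sizes span roughly 90-450 bp (a realistic multiplex layout,
    giving the degradation model leverage)."""
    loci = list(loci) if loci is not None else GLOBALFILER_AUTOSOMAL
    dyes = ["6-FAM", "VIC", "NED", "TAZ", "SID"]
    return KitMap(loci={
        locus: {"offset": 55.0 + 15.0 * i, "motif": 4.0, "dye": dyes[i % 5]}
        for i, locus in enumerate(loci)
    })


def simulate_frequency_table(cfg: SimConfig, loci=None) -> FrequencyTable:
    """Per-locus allele frequencies from a symmetric Dirichlet(1.5) over a
    random number of consecutive integer designations, with occasional ".3"
    microvariants."""
    rng = np.random.default_rng(cfg.seed)
    loci = list(loci) if loci is not None else GLOBALFILER_AUTOSOMAL[:cfg.n_loci]
    freqs: dict[str, dict[str, float]] = {}
    lo, hi = cfg.alleles_per_locus
    for locus in loci:
        n = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(6, 14))
        labels = [str(start + i) for i in range(n)]
        if rng.random() < cfg.microvariant_prob:
            k = int(rng.integers(0, n))
            labels[k] = labels[k] + ".3"
        probs = rng.dirichlet(np.full(n, 1.5))
        freqs[locus] = dict(zip(labels, probs.tolist()))
    return FrequencyTable(freqs=freqs)


def sample_reference_profile(freqs: FrequencyTable, seed: int,
                             sample_id: str = "REF", loci=None,
                             kit: KitMap | None = None) -> STRProfile:
    """Two alleles per locus drawn independently by population frequency."""
    rng = np.random.default_rng(seed)
    loci = list(loci) if loci is not None else list(freqs.freqs)
    prof = STRProfile(sample_id=sample_id, kind="reference")
    for locus in loci:
        alleles = freqs.alleles(locus)
        p = np.array([freqs.freqs[locus][a] for a in alleles])
        p = p / p.sum()
        pair = sorted({str(a) for a in rng.choice(alleles, size=2, p=p)})
        peaks = [Peak(allele=a, height=None,
                      size=kit.size(locus, a) if kit else None) for a in pair]
        prof.loci[locus] = LocusObservation(locus=locus, peaks=peaks)
    return prof


def _descend_slot(source: str, phi: float, lam: float, alleles, probs, rng):
    """Sample one tumor allele slot: (state, event) with event in
    retain | loss | replace."""
    u = rng.random()
    if u < 1.0 - phi:
        return source, "retain"
    if u < 1.0 - phi + phi * lam:
        return "LOSS", "loss"
    return str(rng.choice(alleles, p=probs)), "replace"


def _classify_locus(g_n: tuple[str, str], subclone: list[str]) -> list[str]:
    """Variant classes realised at one locus for one subclone genotype."""
    events = []
    present = [a for a in subclone if a != "LOSS"]
    lost = [a for a in g_n if a not in present]
    gained = [a for a in present if a not in g_n]
    n_loss = subclone.count("LOSS")
    if n_loss == 2:
        events.append("LOH")
    elif n_loss == 1:
        events.append("pLOH" if g_n[0] != g_n[1] else "LOH")
    for a in gained:
        # a replacement allele alongside the full somatic genotype adds a
        # peak (Aadd); one displacing a somatic allele is a new allele (Anew)
        events.append("Aadd" if not lost else "Anew")
    return events


def simulate_tumor_profile(reference: STRProfile, cfg: SimConfig,
                           freqs: FrequencyTable, kit: KitMap,
                           sample_id: str | None = None) -> STRProfile:
    """Evidence profile from a reference: subclone genotypes via the descent
    model, gamma peak heights with degradation, analytical thresholding.

    Applied variants are recorded in ``metadata["variants"]`` (per locus) and
    ``metadata["variant_counts"]`` for test assertions.
    """
    rng = np.random.default_rng(cfg.seed)
    sample_id = sample_id or f"T_{reference.sample_id}"
    eps = cfg.per_base_slope ** 100
    weights = np.concatenate([[cfg.mxn],
                              np.full(cfg.K - 1, (1.0 - cfg.mxn) / (cfg.K - 1))])
    prof = STRProfile(sample_id=sample_id, kind="evidence")
    variants: dict[str, list[str]] = {}
    counts = {"Aadd": 0, "Anew": 0, "pLOH": 0, "LOH": 0}
    genotypes_meta: dict[str, list] = {}

    for locus in reference.loci:
        g_n = reference.genotype(locus)
        phi = cfg.phi_at(locus)
        alleles = freqs.alleles(locus)
        probs = np.array([freqs.freqs[locus][a] for a in alleles])
        probs = probs / probs.sum()

        populations = [list(g_n)]
        locus_events: list[str] = []
        for _ in range(cfg.K - 1):
            sub = []
            for source in g_n:
                state, _event = _descend_slot(source, phi, cfg.loss_fraction,
                                              alleles, probs, rng)
                sub.append(state)
            populations.append(sub)
            locus_events.extend(_classify_locus(g_n, sub))
        variants[locus] = locus_events
        for e in locus_events:
            counts[e] += 1
        genotypes_meta[locus] = populations

        # expected copies per allele, degradation-scaled
        union: dict[str, float] = {}
        for w, geno in zip(weights, populations):
            for a in geno:
                if a == "LOSS":
                    continue
                union[a] = union.get(a, 0.0) + w
        peaks = []
        for a, dose in sorted(union.items()):
            size = kit.size(locus, a)
            d = eps ** ((size - 90.0) / 100.0)
            shape = dose * d / cfg.omega ** 2
            if cfg.noiseless:
                height = shape * cfg.mu * cfg.omega ** 2
            else:
                height = rng.gamma(shape, cfg.mu * cfg.omega ** 2)
            if height >= cfg.at:
                peaks.append(Peak(allele=a, height=float(height), size=size))
        prof.loci[locus] = LocusObservation(locus=locus, peaks=peaks)

    prof.metadata = {"variants": variants, "variant_counts": counts,
                     "true_genotypes": genotypes_meta,
                     "config": {"mu": cfg.mu, "omega": cfg.omega,
                                "per_base_slope": cfg.per_base_slope,
                                "mxn": cfg.mxn, "K": cfg.K,
                                "loss_fraction": cfg.loss_fraction,
                                "seed": cfg.seed}}
    return prof


def simulate_relative(reference: STRProfile, relationship: str,
                      freqs: FrequencyTable, seed: int,
                      sample_id: str | None = None,
                      kit: KitMap | None = None) -> STRProfile:
    """Mendelian relative of *reference*: PO transmits one uniformly chosen
    allele per locus; FS draws both siblings' alleles through two simulated
    parents consistent with the reference."""
    if relationship not in ("PO", "FS"):
        raise ValueError(f"unsupported relationship {relationship!r}")
    rng = np.random.default_rng(seed)
    sample_id = sample_id or f"{relationship}_{reference.sample_id}"
    prof = STRProfile(sample_id=sample_id, kind="reference")
    for locus in reference.loci:
        g = reference.genotype(locus)
        alleles = freqs.alleles(locus)
        probs = np.array([freqs.freqs[locus][a] for a in alleles])
        probs = probs / probs.sum()
        if relationship == "PO":
            transmitted = g[int(rng.integers(2))]
            other = str(rng.choice(alleles, p=probs))
            pair = (transmitted, other)
        else:
            # parents: each contributed one reference allele, plus a free one
            p1 = (g[0], str(rng.choice(alleles, p=probs)))
            p2 = (g[1], str(rng.choice(alleles, p=probs)))
            pair = (p1[int(rng.integers(2))], p2[int(rng.integers(2))])
        pair = sorted({str(a) for a in pair})
        prof.loci[locus] = LocusObservation(locus=locus, peaks=[
            Peak(allele=a, height=None,
                 size=kit.size(locus, a) if kit else None) for a in pair])
    return prof


@dataclass
class Case:
    evidence: STRProfile
    reference: STRProfile
    truth: dict = field(default_factory=dict)


def make_case_suite(n_cases: int = 17, cfg: SimConfig | None = None,
                    freqs: FrequencyTable | None = None,
                    kit: KitMap | None = None) -> list[Case]:
    """A cohort of synthetic tumor/reference pairs whose normal-cell
    fractions span M_xn in {0.1 .. 0.7} (tumor purity 30-90%), with truth
    metadata recording every applied variant."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    if freqs is None:
        freqs = simulate_frequency_table(cfg)
    if kit is None:
        kit = default_kit(list(freqs.freqs))
    mxn_levels = np.round(np.arange(0.1, 0.75, 0.1), 2)
    cases = []
    for i in range(n_cases):
        mxn = float(mxn_levels[i % len(mxn_levels)])
        ref_seed = int(rng.integers(2 ** 31))
        tum_seed = int(rng.integers(2 ** 31))
        if isinstance(cfg.phi, dict):
            phi = cfg.phi
        elif cfg.phi is None:
            lo, hi = COLORECTAL_PHI_RANGE
            phi = {locus: float(rng.uniform(lo, hi)) for locus in freqs.freqs}
        else:
            phi = cfg.phi
        case_cfg = SimConfig(**{**cfg.__dict__, "mxn": mxn, "seed": tum_seed,
                                "phi": phi})
        ref = sample_reference_profile(freqs, seed=ref_seed,
                                       sample_id=f"HBD{i:04d}", kit=kit)
        ev = simulate_tumor_profile(ref, case_cfg, freqs, kit,
                                    sample_id=f"HTFD{i:04d}")
        cases.append(Case(evidence=ev, reference=ref,
                          truth={"mxn": mxn, "phi": phi,
                                 "variant_counts": ev.metadata["variant_counts"],
                                 "seed": tum_seed}))
    return cases
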