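"""LR engine: brute-force oracle equivalence, the random-match-probability
limit, optimizer determinism and recovery, experiment drivers, diagnostics."""

import math
from itertools import product

import numpy as np
import pytest
from scipy import stats

from tumorlr.str_io import LOSS, Q, FrequencyTable, LocusObservation, Peak, STRProfile
from tumorlr.genotype_priors import (HD_FS, HD_PO, HD_UNRELATED, HP,
                                     HypothesisSpec, VariantIncidence)
from tumorlr.peak_model import DegradationFit, GammaParams, LikelihoodTables
from tumorlr.lr_engine import (compute_lr, gamma_qq_diagnostic, grid_experiment,
                               interval_lr, maximize_likelihood, mxn_interval,
                               non_contributor_test)
from tumorlr.simulate import (SimConfig, default_kit, sample_reference_profile,
                              simulate_frequency_table, simulate_tumor_profile)
from tumorlr.str_io import apply_analytical_threshold

from helpers import make_evidence, make_reference


# ---------------------------------------------------------------------------
# independent oracle: ordered enumeration of genotypes and descent events,
# never forming unordered tumor states or flattened tables
# ---------------------------------------------------------------------------

def oracle_locus_likelihood(obs, hyp, freqs, kit, params, at):
    locus = obs.locus
    observed = {p.allele: p for p in obs.peaks}
    if hyp.kind == HP:
        g = hyp.poi.genotype(locus)
        explicit = list(observed) + [a for a in g if a not in observed]
        normals = [((g[0], g[1]), 1.0)]
    else:
        explicit = list(observed)
        f_q = freqs.residual(locus, explicit)

        def f(a):
            return f_q if a == Q else freqs.freq(locus, a)

        cands = explicit + [Q]
        normals = []
        for n1, n2 in product(cands, repeat=2):
            normals.append(((n1, n2), f(n1) * f(n2)))  # ordered HW

    # replacement target distribution over explicit + Q, normalized
    rep = {a: freqs.freq(locus, a) for a in explicit}
    rep[Q] = freqs.residual(locus, explicit)
    z = sum(rep.values())
    rep = {a: v / z for a, v in rep.items()}
    phi = hyp.phi.at(locus)
    lam = hyp.phi.loss_fraction
    events = [("retain", None, 1 - phi), ("loss", None, phi * lam)] + [
        ("replace", a, phi * (1 - lam) * p) for a, p in rep.items()]

    def size_of(a):
        if a in observed and observed[a].size is not None:
            return observed[a].size
        if a == Q:
            sizes = [p.size for p in obs.peaks if p.size is not None]
            return float(np.mean(sizes)) if sizes else kit.mean_size(locus)
        return kit.size(locus, a)

    w = params.weights
    theta = params.scale
    total = 0.0
    for (n1, n2), p_n in normals:
        if p_n == 0.0:
            continue
        # all ordered descent event tuples for the K-1 subclones
        for ev_tuple in product(product(events, repeat=2), repeat=hyp.K - 1):
            p = p_n
            copies = {}
            for slot in (n1, n2):
                copies[slot] = copies.get(slot, 0.0) + w[0]
            for k, slots in enumerate(ev_tuple):
                for source, (kind, target, pe) in zip((n1, n2), slots):
                    p *= pe
                    out = source if kind == "retain" else (
                        None if kind == "loss" else target)
                    if out is not None:
                        copies[out] = copies.get(out, 0.0) + w[1 + k]
            if p == 0.0:
                continue
            dens = 1.0
            for a, dose in copies.items():
                shape = dose * params.epsilon ** ((size_of(a) - 90) / 100) / params.omega ** 2
                if a in observed:
                    if shape <= 0:
                        dens = 0.0
                        break
                    dens *= stats.gamma.pdf(observed[a].height, a=shape, scale=theta)
                elif shape > 0:
                    dens *= stats.gamma.cdf(at, a=shape, scale=theta)
            for a in observed:
                if a not in copies:
                    dens = 0.0
            total += p * dens
    return total


class TestOracleEquivalence:
    freqs = FrequencyTable(freqs={
        "L1": {"10": 0.3, "12": 0.45, "13": 0.15},
        "L2": {"8": 0.55, "9": 0.3},
    }, floor=1e-3)
    kit = default_kit(["L1", "L2"])

    def evidence(self):
        return make_evidence({"L1": ["10", "12", "13"], "L2": ["8"]})

    @pytest.mark.parametrize("kind,K", [(HP, 2), (HD_UNRELATED, 2), (HP, 3)])
    def test_full_likelihood_matches_ordered_enumeration(self, kind, K):
        ev = self.evidence()
        poi = make_reference({"L1": ["10", "12"], "L2": ["8", "9"]})
        hyp = HypothesisSpec(kind=kind, K=K,
                             poi=None if kind == HD_UNRELATED else poi,
                             mxn=0.45, phi=VariantIncidence.scalar(0.12))
        weights = [0.45] + [0.55 / (K - 1)] * (K - 1)
        params = GammaParams(mu=900, omega=0.25, epsilon=0.8, weights=weights)
        tables = LikelihoodTables(ev, hyp, self.freqs, self.kit, at=175)
        got, per_locus = tables.log_likelihood(params.mu, params.omega,
                                               params.epsilon, params.weights)
        expected = sum(
            math.log(oracle_locus_likelihood(ev.loci[m], hyp, self.freqs,
                                             self.kit, params, at=175))
            for m in ev.loci)
        assert got == pytest.approx(expected, rel=1e-6)
        assert sum(per_locus) == pytest.approx(got, abs=1e-9)

    def test_phi_zero_collapses_to_single_source(self):
        """With phi = 0 and both populations forced identical, the K = 2
        likelihood equals a directly computed single-source likelihood."""
        ev = make_evidence({"L1": ["10", "12"]})
        poi = make_reference({"L1": ["10", "12"]})
        hyp = HypothesisSpec(kind=HP, K=2, poi=poi, mxn=0.3,
                             phi=VariantIncidence.scalar(0.0))
        params = GammaParams(mu=900, omega=0.25, epsilon=1.0, weights=[0.3, 0.7])
        tables = LikelihoodTables(ev, hyp, self.freqs, self.kit, at=175)
        got, _ = tables.log_likelihood(params.mu, params.omega,
                                       params.epsilon, params.weights)
        shape, scale = 1 / 0.25 ** 2, 900 * 0.25 ** 2
        expected = (stats.gamma.logpdf(1000.0, a=shape, scale=scale)
                    + stats.gamma.logpdf(1000.0, a=shape, scale=scale))
        assert got == pytest.approx(expected, abs=1e-10)


class TestMaximizeLikelihood:
    def make_single_source_case(self, mu=1000.0, omega=0.15, seed=21):
        cfg = SimConfig(seed=seed, mu=mu, omega=omega, phi=0.0, mxn=0.5)
        freqs = simulate_frequency_table(cfg)
        kit = default_kit(list(freqs.freqs))
        ref = sample_reference_profile(freqs, seed=seed + 1, kit=kit)
        ev = apply_analytical_threshold(
            simulate_tumor_profile(ref, cfg, freqs, kit), cfg.at)
        return cfg, freqs, kit, ref, ev

    def test_parameter_recovery(self):
        cfg, freqs, kit, ref, ev = self.make_single_source_case()
        hyp = HypothesisSpec(kind=HP, K=2, poi=ref, mxn=0.5,
                             phi=VariantIncidence.scalar(0.0))
        fit = maximize_likelihood(ev, hyp, freqs, kit, seed=3)
        assert fit.params.mu == pytest.approx(1000.0, rel=0.05)
        assert fit.params.omega == pytest.approx(0.15, rel=0.20)

    def test_determinism(self):
        cfg, freqs, kit, ref, ev = self.make_single_source_case(seed=22)
        hyp = HypothesisSpec(kind=HP, K=2, poi=ref, mxn=0.5,
                             phi=VariantIncidence.scalar(0.05))
        a = maximize_likelihood(ev, hyp, freqs, kit, seed=9)
        b = maximize_likelihood(ev, hyp, freqs, kit, seed=9)
        assert a.log_likelihood == b.log_likelihood
        assert a.params.mu == b.params.mu


class TestComputeLR:
    def test_rmp_limit(self):
        """Noiseless single-source evidence at M_xn = 1, phi = 0, no
        degradation and no dropout: LR per locus reduces to the random match
        probability 1 / P_HW(poi)."""
        cfg = SimConfig(seed=31, phi=0.0, mxn=1.0, per_base_slope=1.0,
                        noiseless=True)
        freqs = simulate_frequency_table(cfg)
        kit = default_kit(list(freqs.freqs))
        ref = sample_reference_profile(freqs, seed=32, kit=kit)
        ev = apply_analytical_threshold(
            simulate_tumor_profile(ref, cfg, freqs, kit), cfg.at)
        res = compute_lr(ev, ref, 1.0, VariantIncidence.scalar(0.0), freqs, kit)
        from tumorlr.genotype_priors import Genotype, hw_prior
        expected = 0.0
        for locus in ev.loci:
            g = Genotype(*ref.genotype(locus))
            observed = ev.loci[locus].alleles
            expected -= math.log10(
                hw_prior(g, freqs, locus, q_candidates=observed))
        # numerator and denominator share one surface up to the HW constant;
        # residual slack is optimizer termination on the noiseless peak
        assert res.log10_lr == pytest.approx(expected, abs=0.01)

    def test_per_locus_decomposition_sums_to_total(self, sim_setup):
        s = sim_setup
        res = compute_lr(s["ev"], s["ref"], 0.4, VariantIncidence.scalar(0.1),
                         s["freqs"], s["kit"])
        assert sum(res.per_locus_log10_lr.values()) == pytest.approx(
            res.log10_lr, abs=1e-6)

    def test_unrelated_poi_gives_negative_lr(self, sim_setup):
        s = sim_setup
        stranger = sample_reference_profile(s["freqs"], seed=777, kit=s["kit"])
        res = compute_lr(s["ev"], stranger, 0.4, VariantIncidence.scalar(0.1),
                         s["freqs"], s["kit"])
        assert res.log10_lr < 0

    def test_kinship_ordering(self, sim_setup):
        s = sim_setup
        phi = VariantIncidence.scalar(0.1)
        args = (s["freqs"], s["kit"])
        lr_true = compute_lr(s["ev"], s["ref"], 0.4, phi, *args).log10_lr
        lr_po = compute_lr(s["ev"], s["ref"], 0.4, phi, *args,
                           hd_kind=HD_PO).log10_lr
        lr_fs = compute_lr(s["ev"], s["ref"], 0.4, phi, *args,
                           hd_kind=HD_FS).log10_lr
        assert lr_true >= lr_po >= lr_fs
        assert lr_fs > 0  # a relative is still excluded as the source


class TestExperimentDrivers:
    def test_interval_lr_summary_and_trend(self, sim_setup):
        s = sim_setup
        res = interval_lr(s["ev"], s["ref"], 0.4, VariantIncidence.scalar(0.15),
                          s["freqs"], s["kit"], n=5)
        assert res.mxn_values[0] == pytest.approx(0.3)
        assert res.mxn_values[-1] == pytest.approx(0.5)
        assert res.summary["mean"] == pytest.approx(res.log10_lr.mean())
        assert (res.log10_lr > 0).all()

    def test_grid_axes_and_trends(self, sim_setup):
        s = sim_setup
        res = grid_experiment(s["ev"], s["ref"], 0.4, s["freqs"], s["kit"], n=4)
        assert res.log10_lr.shape == (4, 4)
        assert np.isfinite(res.log10_lr).all()
        # LR falls with phi and rises with mxn (trend over the grid lines)
        assert all(f.slope < 0 for f in res.phi_fits)
        assert np.mean([f.slope for f in res.mxn_fits]) > 0

    def test_non_contributor_determinism_and_rank(self, sim_setup):
        s = sim_setup
        phi = VariantIncidence.scalar(0.15)
        kw = dict(per_group=8, seed=99, K=2)
        a = non_contributor_test(s["ev"], s["freqs"], s["kit"],
                                 mxn_interval(0.4), phi, **kw)
        b = non_contributor_test(s["ev"], s["freqs"], s["kit"],
                                 mxn_interval(0.4), phi, **kw)
        assert all(np.array_equal(a.log10_lr[m], b.log10_lr[m])
                   for m in a.log10_lr)
        assert a.fraction_below_zero >= 0.95
        # the true contributor outranks every non-contributor
        lr_true = compute_lr(s["ev"], s["ref"], 0.4, phi, s["freqs"],
                             s["kit"]).log10_lr
        assert lr_true > np.nanmax(a.pooled)


class TestQQDiagnostic:
    def make_profile_from_totals(self, totals):
        prof = STRProfile(sample_id="QQ", kind="evidence")
        for i, t in enumerate(totals):
            prof.loci[f"L{i}"] = LocusObservation(
                locus=f"L{i}", peaks=[Peak("10", float(t), 100.0 + i)])
        return prof

    def test_mle_recovery(self, rng):
        totals = rng.gamma(4.0, 500.0, size=200)
        res = gamma_qq_diagnostic(self.make_profile_from_totals(totals))
        assert res.shape == pytest.approx(4.0, rel=0.15)
        assert len(res.theoretical) == 200 == len(res.empirical)

    def test_scale_equivariance(self, rng):
        totals = rng.gamma(3.0, 400.0, size=60)
        a = gamma_qq_diagnostic(self.make_profile_from_totals(totals))
        b = gamma_qq_diagnostic(self.make_profile_from_totals(totals * 2.5))
        assert b.shape == pytest.approx(a.shape, abs=1e-6)
        assert b.scale == pytest.approx(a.scale * 2.5, rel=1e-6)

    def test_needs_enough_loci(self):
        with pytest.raises(Exception):
            gamma_qq_diagnostic(self.make_profile_from_totals([100.0] * 5))
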