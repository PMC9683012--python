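"""Pruning likelihood oracles, priors, MCMC mechanics, trace summaries,
presence-based minimum ages."""
import math

import numpy as np
import pytest

from paleoeve import clockdate as cd
from paleoeve import synthsim as ss
from paleoeve.alnkit import MultipleAlignment
from paleoeve.models import GTRModel


class TestPruningLikelihood:
    def test_two_taxon_jc_closed_form(self):
        """One site, matching and mismatching states, against the analytic
        Jukes-Cantor transition probabilities."""
        model = GTRModel()  # equal rates/frequencies, no gamma
        t = 0.2
        d = 2 * t
        same = cd.pruning_loglik(f"(A:{t},B:{t});",
                                 MultipleAlignment(["A", "B"], ["C", "C"]),
                                 model, clock_rate=1.0)
        diff = cd.pruning_loglik(f"(A:{t},B:{t});",
                                 MultipleAlignment(["A", "B"], ["C", "G"]),
                                 model, clock_rate=1.0)
        p_same = 0.25 * (0.25 + 0.75 * math.exp(-4 * d / 3))
        p_diff = 0.25 * (0.25 - 0.25 * math.exp(-4 * d / 3))
        assert same == pytest.approx(math.log(p_same), abs=1e-10)
        assert diff == pytest.approx(math.log(p_diff), abs=1e-10)

    def _enumeration_oracle(self, tree, rows, model, rate):
        topo = cd.IndexedTopology(tree)
        cats = model.category_rates
        pi = np.asarray(model.base_freqs)
        code = {c: i for i, c in enumerate("ACGT")}
        tips = [i for i in range(topo.n) if topo.is_tip[i]]
        internals = [i for i in range(topo.n) if not topo.is_tip[i]]
        L = len(next(iter(rows.values())))
        total = 0.0
        for site in range(L):
            site_like = 0.0
            for c, r in enumerate(cats):
                P = {}
                for i in range(topo.n):
                    if i == topo.root:
                        continue
                    dur = topo.ages0[topo.parent[i]] - topo.ages0[i]
                    P[i] = model.transition_matrices([dur * rate * r])[0]
                acc = 0.0
                from itertools import product

                for states in product(range(4), repeat=len(internals)):
                    assign = dict(zip(internals, states))
                    for i in tips:
                        assign[i] = code[rows[topo.tip_label[i]][site]]
                    pr = pi[assign[topo.root]]
                    for i in range(topo.n):
                        if i != topo.root:
                            pr *= P[i][assign[topo.parent[i]], assign[i]]
                    acc += pr
                site_like += acc / len(cats)
            total += math.log(site_like)
        return total

    @pytest.mark.parametrize("newick,labels", [
        ("((A:10,B:10):20,(C:25,D:25):5);", "ABCD"),
        ("(((A:8,B:8):10,C:18):12,(D:20,E:20):10);", "ABCDE"),
    ])
    def test_matches_enumeration_oracle(self, newick, labels, rng):
        model = GTRModel((1.3, 2.4, 0.7, 1.1, 3.3, 1.0),
                         (0.31, 0.19, 0.27, 0.23), gamma_shape=0.6)
        rows = {lab: "".join(rng.choice(list("ACGT"), 10)) for lab in labels}
        tree = ss.build_host_tree(newick)
        rate = 0.012
        ll = cd.pruning_loglik(tree, MultipleAlignment(list(labels),
                                                       [rows[l] for l in labels]),
                               model, rate)
        oracle = self._enumeration_oracle(tree, rows, model, rate)
        assert abs(ll - oracle) < 1e-8

    def test_duplicated_columns_double_loglik(self, rng):
        model = GTRModel(gamma_shape=0.8)
        rows = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(4)]
        tree = "((A:10,B:10):20,(C:25,D:25):5);"
        single = cd.pruning_loglik(tree, MultipleAlignment(list("ABCD"), rows),
                                   model, 0.01)
        double = cd.pruning_loglik(tree, MultipleAlignment(list("ABCD"),
                                                           [r * 2 for r in rows]),
                                   model, 0.01)
        assert double == pytest.approx(2 * single, rel=1e-12)

    def test_gap_and_n_treated_as_missing(self):
        model = GTRModel()
        tree = "(A:10,B:10);"
        full = cd.pruning_loglik(tree, MultipleAlignment(["A", "B"], ["A", "-"]),
                                 model, 0.01)
        # a fully missing partner reduces to the stationary probability
        assert full == pytest.approx(math.log(0.25))


class TestPriors:
    def test_calibration_at_mean_contributes_normal_mode(self, host_tree):
        topo = cd.IndexedTopology(host_tree)
        ages = topo.ages0.copy()
        root_cal = cd.CalibrationPrior(tuple(host_tree.taxa), 187.0, 5.0)
        cal = cd.CalibrationPrior(ss.DEFAULT_PLACENTALS, 102.0, 3.0)
        lp = cd.prior_logdensity(host_tree, ages, 0.003, [root_cal, cal])
        cal_off = cd.CalibrationPrior(ss.DEFAULT_PLACENTALS, 110.0, 3.0)
        lp_off = cd.prior_logdensity(host_tree, ages, 0.003, [root_cal, cal_off])
        assert lp - lp_off == pytest.approx(0.5 * ((110 - 102) / 3) ** 2)

    def test_child_older_than_parent_is_impossible(self, host_tree):
        topo = cd.IndexedTopology(host_tree)
        ages = topo.ages0.copy()
        crown = topo.mrca_index(ss.DEFAULT_PLACENTALS)
        ages[crown] = 1000.0
        assert cd.prior_logdensity(host_tree, ages, 0.003, []) == -math.inf

    def test_no_calibrations_leaves_rate_term_only(self, host_tree):
        topo = cd.IndexedTopology(host_tree)
        lp1 = cd.prior_logdensity(host_tree, topo.ages0, 0.003, [])
        lp2 = cd.prior_logdensity(host_tree, topo.ages0, 0.03, [])
        assert lp1 != lp2  # only the rate prior differs
        assert np.isfinite(lp1)


class TestMCMC:
    def test_same_seed_identical_trace(self, rng):
        tree = "((A:10,B:10):20,(C:25,D:25):5);"
        rows = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(4)]
        aln = MultipleAlignment(list("ABCD"), rows)
        cals = [cd.CalibrationPrior(("A", "B"), 10.0, 1.0)]
        cfg = cd.MCMCConfig(chain_length=2000, sample_every=50, seed=42)
        t1 = cd.mcmc_run(aln, tree, cals, cd.ClockModel(), GTRModel(gamma_shape=1.0), cfg)
        t2 = cd.mcmc_run(aln, tree, cals, cd.ClockModel(), GTRModel(gamma_shape=1.0), cfg)
        for name in t1.columns:
            assert np.array_equal(t1.columns[name], t2.columns[name])

    def test_prior_only_recovers_calibration_density(self):
        """Data-free chains sample each calibration normal (all internal
        nodes calibrated, so no uniform-polytope distortion)."""
        tree = "(((A:20,B:20):40,C:60):40,(D:70,E:70):30);"
        cals = [cd.CalibrationPrior(("A", "B"), 20.0, 2.0),
                cd.CalibrationPrior(("A", "B", "C"), 60.0, 3.0),
                cd.CalibrationPrior(("D", "E"), 70.0, 3.0),
                cd.CalibrationPrior(("A", "B", "C", "D", "E"), 100.0, 4.0)]
        cfg = cd.MCMCConfig(chain_length=120_000, sample_every=40, seed=3,
                            likelihood_on=False)
        trace = cd.mcmc_run(None, tree, cals, cd.ClockModel(), None, cfg)
        summ = cd.summarize_trace(trace)
        for cal in cals:
            target = frozenset(cal.taxa)
            key = [n for n, s in summ.items() if s.clade == target][0]
            s = summ[key]
            x = trace.columns[key][int(len(trace) * 0.25):]
            mcse = x.std(ddof=1) / math.sqrt(max(s.ess, 1.0))
            assert abs(s.mean - cal.mean) < 3 * mcse + 0.05 * cal.stdev
            assert abs(x.std(ddof=1) - cal.stdev) < 0.15 * cal.stdev

    def test_strict_clock_rate_recovery(self, host_tree):
        """Posterior mean rate lands near the simulating rate."""
        rate = 0.0027
        cfg = ss.SimulationConfig(seed=5, gamma_shape=None)
        aln = ss.simulate_neighborhood(host_tree, cfg, 800, seed=8)
        cals = [cd.CalibrationPrior(tuple(ss.DEFAULT_PLACENTALS), 102.0, 3.0),
                cd.CalibrationPrior(("Homo", "Pan"), 8.0, 1.0),
                cd.CalibrationPrior(("Homo", "Didelphis"), 172.0, 4.0),
                cd.CalibrationPrior(("Mus", "Rattus"), 70.0, 2.0),
                cd.CalibrationPrior(("Canis", "Felis"), 78.0, 2.5)]
        mcfg = cd.MCMCConfig(chain_length=8000, sample_every=20, seed=9)
        trace = cd.mcmc_run(aln, host_tree, cals,
                            cd.ClockModel(kind="strict", rate=0.003),
                            GTRModel(), mcfg)
        summ = cd.summarize_trace(trace)
        assert abs(summ["clock_rate"].mean - rate) / rate < 0.2


class TestTraceSummaries:
    def test_iid_normal_hpd_and_ess(self):
        x = np.random.default_rng(1).normal(size=10_000)
        lo, hi = cd.hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)
        ess = cd.effective_sample_size(x)
        assert abs(ess - len(x)) / len(x) < 0.1

    def test_hpd_contains_mass_by_construction(self):
        x = np.random.default_rng(2).exponential(size=5000)
        lo, hi = cd.hpd_interval(x, 0.95)
        assert ((x >= lo) & (x <= hi)).mean() >= 0.95

    def test_constant_trace(self):
        x = np.full(100, 3.14)
        lo, hi = cd.hpd_interval(x, 0.95)
        assert lo == hi == pytest.approx(3.14)
        assert cd.effective_sample_size(x) == 100

    def test_alternating_trace_has_tiny_ess(self):
        x = np.tile([0.0, 1.0], 500)
        assert cd.effective_sample_size(x) < 50

    def test_autocorrelated_trace_has_reduced_ess(self):
        rng = np.random.default_rng(3)
        x = np.zeros(5000)
        for i in range(1, 5000):
            x[i] = 0.9 * x[i - 1] + rng.normal()
        ess = cd.effective_sample_size(x)
        assert ess < 1500  # AR(1) with rho=.9 has ESS ~ n/19


class TestMinAgeFromPresence:
    def test_all_placentals_gives_crown_age(self, host_tree):
        presence = {t: "present" for t in ss.DEFAULT_PLACENTALS}
        presence.update({"Didelphis": "absent", "Ornithorhynchus": "ambiguous"})
        res = cd.min_age_from_presence(host_tree, presence)
        assert res.min_age == pytest.approx(102.0)
        assert res.carrier_mrca == frozenset(ss.DEFAULT_PLACENTALS)

    def test_two_sisters(self, host_tree):
        res = cd.min_age_from_presence(host_tree, {"Homo": True, "Pan": True,
                                                   "Mus": False})
        assert res.min_age == pytest.approx(8.0)

    def test_single_carrier_is_undefined(self, host_tree):
        with pytest.raises(cd.InsufficientCarriersError):
            cd.min_age_from_presence(host_tree, {"Homo": True, "Pan": False})

    def test_ambiguous_taxa_excluded(self, host_tree):
        presence = {"Homo": "present", "Pan": "ambiguous", "Macaca": "present"}
        res = cd.min_age_from_presence(host_tree, presence)
        assert res.min_age == pytest.approx(74.0)


class TestParalogueJoin:
    def test_two_clades_share_root(self, host_tree):
        carriers = ss.DEFAULT_PLACENTALS
        tree = cd.paralogue_join(host_tree, carriers, carriers, 200.0)
        assert tree.root_age == pytest.approx(200.0)
        assert len(tree.taxa) == 24
        assert tree.mrca_age([f"{t}__A" for t in carriers]) == pytest.approx(102.0)

    def test_root_age_must_exceed_crowns(self, host_tree):
        with pytest.raises(ValueError):
            cd.paralogue_join(host_tree, ss.DEFAULT_PLACENTALS,
                              ss.DEFAULT_PLACENTALS, 50.0)
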