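"""Node-calibrated Bayesian molecular dating on a fixed topology.

The model is standard: a rooted, ultrametric tree over the carrier taxa with
node ages in My, a (strict or uncorrelated-lognormal) molecular clock in
substitutions/site/My, a GTR+Gamma substitution process, normal calibration
priors on named most-recent-common-ancestor (MRCA) nodes, and a
Metropolis-Hastings sampler over node ages, clock rate, and (optionally)
substitution-model parameters.  The likelihood is Felsenstein pruning over
compressed site patterns, with partial-likelihood caching so that single
node-age proposals only recompute the path to the root.

Also provides the orthology-based minimum-age bound: the age of the MRCA of
all taxa carrying an orthologous insertion.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alnkit import MultipleAlignment
from .models import GTRModel, discrete_gamma_rates
from .synthsim import HostTree, TreeNode


@dataclass(frozen=True)
class CalibrationPrior:
    """Normal prior (mean, stdev in My) on the age of the MRCA of ``taxa``."""

    taxa: tuple[str, ...]
    mean: float
    stdev: float

    def __post_init__(self):
        if self.stdev <= 0:
            raise ValueError("calibration stdev must be positive")


@dataclass
class ClockModel:
    kind: str = "strict"                 # "strict" | "uncorrelated-lognormal"
    rate: float = 0.003                  # substitutions/site/My (initial value)
    sigma: float = 0.1                   # lognormal stdev of branch multipliers
    rate_prior_logmedian: float = math.log(0.003)
    rate_prior_sigma: float = 1.5

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("clock rate must be positive")
        if self.kind not in ("strict", "uncorrelated-lognormal"):
            raise ValueError(f"unknown clock kind {self.kind!r}")


@dataclass
class MCMCConfig:
    chain_length: int = 300_000
    sample_every: int = 100
    burnin_fraction: float = 0.25
    seed: int = 0
    estimate_model: bool = False
    tune: bool = True
    root_max: float = 500.0
    likelihood_on: bool = True           # False samples from the prior

    def __post_init__(self):
        if self.chain_length < self.sample_every:
            raise ValueError("chain length must be at least the sampling interval")
        if not 0.0 <= self.burnin_fraction < 1.0:
            raise ValueError("burn-in fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# Topology indexing and pruning likelihood
# ---------------------------------------------------------------------------

class IndexedTopology:
    """Postorder-indexed rooted topology with mutable node ages."""

    def __init__(self, tree: HostTree):
        self.nodes: list[TreeNode] = list(tree.root.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.n = len(self.nodes)
        self.root = self.index[id(tree.root)]
        self.parent = np.full(self.n, -1)
        self.children: list[list[int]] = [[] for _ in range(self.n)]
        for i, node in enumerate(self.nodes):
            for c in node.children:
                ci = self.index[id(c)]
                self.parent[ci] = i
                self.children[i].append(ci)
        self.is_tip = np.array([n.is_leaf for n in self.nodes])
        self.tip_label = {i: n.label for i, n in enumerate(self.nodes) if n.is_leaf}
        self.ages0 = np.array([n.age for n in self.nodes])
        self.internal = [i for i in range(self.n) if not self.is_tip[i]]
        self._clades: dict[int, frozenset[str]] = {
            i: frozenset(n.tip_labels()) for i, n in enumerate(self.nodes)}

    def clade(self, i: int) -> frozenset[str]:
        return self._clades[i]

    def mrca_index(self, taxa) -> int:
        wanted = frozenset(taxa)
        best, best_size = None, None
        for i, clade in self._clades.items():
            if wanted <= clade and (best_size is None or len(clade) < best_size):
                best, best_size = i, len(clade)
        if best is None:
            raise KeyError(f"taxa not resolvable on topology: {sorted(wanted)}")
        return best

    def ancestors_to_root(self, i: int) -> list[int]:
        out = []
        while i != -1:
            out.append(i)
            i = self.parent[i]
        return out


class PruningEngine:
    """Felsenstein pruning over compressed site patterns with caching."""

    def __init__(self, topo: IndexedTopology, alignment: MultipleAlignment,
                 model: GTRModel):
        self.topo = topo
        self.set_model(model)
        labels = set(topo.tip_label.values())
        if set(alignment.ids) != labels:
            missing = labels ^ set(alignment.ids)
            raise ValueError(f"alignment ids do not match topology tips: {sorted(missing)}")
        arr = alignment.to_array()
        arr = np.where((arr >= ord("a")) & (arr <= ord("z")), arr - 32, arr)
        lut = np.full(256, -1, np.int8)
        for k, b in enumerate(b"ACGT"):
            lut[b] = k
        codes = lut[arr]                                  # (ntaxa, L); -1 ambiguous
        order = [alignment.ids.index(topo.tip_label[i])
                 for i in range(topo.n) if topo.is_tip[i]]
        codes = codes[order]
        self.patterns, self.weights = np.unique(codes, axis=1, return_counts=True)
        self.n_patterns = self.patterns.shape[1]
        self.n_sites = int(self.weights.sum())

        ncat = len(self.cat_rates)
        tip_rows = [i for i in range(topo.n) if topo.is_tip[i]]
        self.partials = [None] * topo.n   # each (ncat, n_patterns, 4)
        for row, i in enumerate(tip_rows):
            p = np.ones((1, self.n_patterns, 4))
            obs = self.patterns[row]
            known = obs >= 0
            p[0, known] = 0.0
            p[0, np.nonzero(known)[0], obs[known]] = 1.0
            self.partials[i] = np.broadcast_to(p, (ncat, self.n_patterns, 4)).copy()
        self.pmats: list[np.ndarray | None] = [None] * topo.n

    def set_model(self, model: GTRModel) -> None:
        self.model = model
        self.cat_rates = model.category_rates
        self.freqs = np.asarray(model.base_freqs)

    def branch_lengths(self, ages: np.ndarray, rate: float,
                       multipliers: np.ndarray | None) -> np.ndarray:
        t = self.topo
        durations = ages[t.parent] - ages
        durations[t.root] = 0.0
        if np.any(durations[np.arange(t.n) != t.root] < 0):
            raise ValueError("negative branch duration: child older than parent")
        mult = multipliers if multipliers is not None else 1.0
        return durations * rate * mult

    def _compute_pmats(self, bl: np.ndarray, nodes) -> None:
        ncat = len(self.cat_rates)
        for i in nodes:
            if i == self.topo.root:
                continue
            dists = bl[i] * self.cat_rates
            self.pmats[i] = self.model.transition_matrices(dists)  # (ncat,4,4)

    def _compute_partial(self, i: int) -> None:
        acc = None
        for c in self.topo.children[i]:
            # (ncat,p,4) @ (ncat,4,4)^T -> (ncat,p,4), batched over categories
            contrib = np.matmul(self.partials[c], self.pmats[c].transpose(0, 2, 1))
            acc = contrib if acc is None else acc * contrib
        self.partials[i] = acc

    def full_loglik(self, ages, rate, multipliers=None) -> float:
        bl = self.branch_lengths(ages, rate, multipliers)
        self._compute_pmats(bl, range(self.topo.n))
        for i in self.topo.internal:
            self._compute_partial(i)
        return self._root_loglik()

    def update_loglik(self, ages, rate, multipliers, changed_nodes) -> float:
        """Recompute only transition matrices of edges whose length changed
        and partials on the paths from those nodes to the root."""
        bl = self.branch_lengths(ages, rate, multipliers)
        dirty_edges: set[int] = set()
        dirty_nodes: set[int] = set()
        for v in changed_nodes:
            dirty_edges.add(v)
            dirty_edges.update(self.topo.children[v])
            dirty_nodes.update(self.topo.ancestors_to_root(v))
        self._compute_pmats(bl, dirty_edges)
        for i in self.topo.internal:
            if i in dirty_nodes:
                self._compute_partial(i)
        return self._root_loglik()

    def snapshot(self, changed_nodes):
        nodes = set()
        for v in changed_nodes:
            nodes.update(self.topo.ancestors_to_root(v))
        edges = set()
        for v in changed_nodes:
            edges.add(v)
            edges.update(self.topo.children[v])
        return ([(i, self.partials[i]) for i in nodes if not self.topo.is_tip[i]],
                [(i, self.pmats[i]) for i in edges])

    def restore(self, snap) -> None:
        parts, mats = snap
        for i, p in parts:
            self.partials[i] = p
        for i, m in mats:
            self.pmats[i] = m

    def _root_loglik(self) -> float:
        root = self.partials[self.topo.root]
        site = (root @ self.freqs).mean(axis=0)
        if np.any(site <= 0) or not np.all(np.isfinite(site)):
            bad = int(np.argmin(site))
            raise FloatingPointError(
                f"non-finite site likelihood at pattern {bad} "
                f"(first site of weight {self.weights[bad]})")
        return float(np.dot(self.weights, np.log(site)))


def pruning_loglik(tree: HostTree | str, alignment: MultipleAlignment,
                   model: GTRModel, clock_rate: float = 1.0,
                   multipliers=None) -> float:
    """Log-likelihood of an alignment on a dated tree.

    ``tree`` carries node ages in My; each branch length is its duration
    times ``clock_rate`` (times an optional per-node multiplier array indexed
    in postorder).
    """
    if isinstance(tree, str):
        tree = HostTree.from_newick(tree)
    topo = IndexedTopology(tree)
    engine = PruningEngine(topo, alignment, model)
    return engine.full_loglik(topo.ages0.copy(), clock_rate, multipliers)


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def _lognormal_logpdf(x: float, mu: float, sigma: float) -> float:
    if x <= 0:
        return -math.inf
    z = (math.log(x) - mu) / sigma
    return -math.log(x * sigma * math.sqrt(2 * math.pi)) - 0.5 * z * z


class PriorModel:
    """Calibration normals + clock-rate, root-age and multiplier priors."""

    def __init__(self, topo: IndexedTopology, calibrations, clock: ClockModel,
                 root_max: float = 500.0, alpha_prior=(0.0, 1.5)):
        self.topo = topo
        self.clock = clock
        self.cal_nodes = [topo.mrca_index(c.taxa) for c in calibrations]
        self.cal_means = np.array([c.mean for c in calibrations])
        self.cal_sds = np.array([c.stdev for c in calibrations])
        self.root_calibrated = topo.root in self.cal_nodes
        self.root_min = float(self.cal_means.max()) if len(self.cal_means) else 0.0
        self.root_max = root_max
        self.alpha_prior = alpha_prior

    def log_density(self, ages: np.ndarray, rate: float,
                    multipliers: np.ndarray | None = None,
                    alpha: float | None = None) -> float:
        t = self.topo
        parents = t.parent
        ok = np.arange(t.n) == t.root
        if np.any(ages[~ok] >= ages[parents[~ok]]):
            return -math.inf
        lp = 0.0
        if len(self.cal_nodes):
            x = ages[self.cal_nodes]
            z = (x - self.cal_means) / self.cal_sds
            lp += float(np.sum(-np.log(self.cal_sds * math.sqrt(2 * math.pi)) - 0.5 * z * z))
        if not self.root_calibrated:
            root_age = ages[t.root]
            if not (self.root_min <= root_age <= self.root_max):
                return -math.inf
            lp += -math.log(self.root_max - self.root_min)
        lp += _lognormal_logpdf(rate, self.clock.rate_prior_logmedian,
                                self.clock.rate_prior_sigma)
        if multipliers is not None and self.clock.kind == "uncorrelated-lognormal":
            s = self.clock.sigma
            for i in range(t.n):
                if i != t.root:
                    lp += _lognormal_logpdf(float(multipliers[i]), -0.5 * s * s, s)
        if alpha is not None:
            lp += _lognormal_logpdf(alpha, *self.alpha_prior)
        return lp


def prior_logdensity(tree: HostTree, ages: np.ndarray, rate: float,
                     calibrations, clock: ClockModel | None = None,
                     root_max: float = 500.0) -> float:
    """Log prior density of a dated-tree state (ages in postorder)."""
    topo = IndexedTopology(tree)
    prior = PriorModel(topo, calibrations, clock or ClockModel(), root_max)
    return prior.log_density(np.asarray(ages, dtype=float), rate)


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------

@dataclass
class PosteriorTrace:
    columns: dict[str, np.ndarray]
    node_clades: dict[str, frozenset[str]]
    acceptance: dict[str, float]
    config: MCMCConfig

    def __len__(self) -> int:
        first = next(iter(self.columns.values()))
        return len(first)

    def to_tsv(self, handle) -> None:
        import pandas as pd

        pd.DataFrame(self.columns).to_csv(handle, sep="\t", index=False)


class _Move:
    def __init__(self, name, weight, step):
        self.name, self.weight, self.step = name, weight, step
        self.tried = 0
        self.accepted = 0


def mcmc_run(
    alignment: MultipleAlignment | None,
    topology: HostTree | str,
    calibrations: list[CalibrationPrior],
    clock: ClockModel | None = None,
    model: GTRModel | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorTrace:
    """Metropolis-Hastings sampler over node ages and clock rate.

    The topology is fixed; the starting state takes node ages from the input
    tree.  With ``config.likelihood_on=False`` (or ``alignment=None``) the
    chain samples from the prior, which is the standard check that
    calibration densities are recovered.
    """
    clock = clock or ClockModel()
    model = model or GTRModel(gamma_shape=0.5)
    config = config or MCMCConfig()
    if isinstance(topology, str):
        topology = HostTree.from_newick(topology)
    topo = IndexedTopology(topology)
    rng = np.random.default_rng(config.seed)

    use_like = config.likelihood_on and alignment is not None
    engine = PruningEngine(topo, alignment, model) if use_like else None
    prior = PriorModel(topo, calibrations, clock, config.root_max)

    ages = topo.ages0.copy()
    rate = clock.rate
    relaxed = clock.kind == "uncorrelated-lognormal"
    mult = np.ones(topo.n) if relaxed else None
    alpha = model.gamma_shape

    lp = prior.log_density(ages, rate, mult, alpha if config.estimate_model else None)
    if not np.isfinite(lp):
        raise ValueError("starting state has zero prior probability; "
                         "check input tree ages against calibrations")
    ll = engine.full_loglik(ages, rate, mult) if use_like else 0.0

    internal_nonroot = [i for i in topo.internal if i != topo.root]
    # two age kernels: bold uniform slides within the node's bounds for
    # traversal, and tunable local perturbations for tightly constrained
    # (calibrated) nodes where the slide almost never hits the posterior
    moves = [_Move("node_age", 3.0 * max(len(internal_nonroot), 1), 1.0),
             _Move("node_age_local", 4.0 * max(len(internal_nonroot), 1), 2.0),
             _Move("root_age", 1.0, 0.1),
             _Move("rate", 1.5, 0.2)]
    if relaxed:
        moves.append(_Move("multiplier", 2.0 * max(len(internal_nonroot), 1), 0.3))
    if config.estimate_model and model.gamma_shape is not None:
        moves.append(_Move("alpha", 1.0, 0.3))
    if config.estimate_model:
        moves.append(_Move("freqs", 1.0, 0.05))
        moves.append(_Move("exch", 1.0, 0.15))
    weights = np.array([mv.weight for mv in moves])
    weights = weights / weights.sum()

    n_samples = config.chain_length // config.sample_every + 1
    names = ["generation", "log_posterior", "log_likelihood", "clock_rate", "root_age"]
    node_cols = {f"age_{i}": i for i in internal_nonroot}
    clades = {f"age_{i}": topo.clade(i) for i in internal_nonroot}
    clades["root_age"] = topo.clade(topo.root)
    if config.estimate_model and model.gamma_shape is not None:
        names.append("gamma_shape")
    store = {name: np.empty(n_samples) for name in list(names) + list(node_cols)}
    sample_row = 0
    burn_end = int(config.chain_length * config.burnin_fraction)
    tune_interval = 200
    freqs = np.asarray(model.base_freqs, dtype=float)
    exch = np.asarray(model.exchangeabilities, dtype=float)

    def record(gen):
        nonlocal sample_row
        store["generation"][sample_row] = gen
        store["log_posterior"][sample_row] = lp + ll
        store["log_likelihood"][sample_row] = ll
        store["clock_rate"][sample_row] = rate
        store["root_age"][sample_row] = ages[topo.root]
        if "gamma_shape" in store:
            store["gamma_shape"][sample_row] = alpha
        for cname, i in node_cols.items():
            store[cname][sample_row] = ages[i]
        sample_row += 1

    record(0)
    for gen in range(1, config.chain_length + 1):
        mv = moves[int(rng.choice(len(moves), p=weights))]
        mv.tried += 1
        log_hastings = 0.0
        changed: list[int] = []
        new_ages, new_rate, new_mult = ages, rate, mult
        new_alpha, new_freqs, new_exch = alpha, freqs, exch
        model_changed = False

        if mv.name == "node_age" and internal_nonroot:
            v = internal_nonroot[int(rng.integers(len(internal_nonroot)))]
            lo = max(ages[c] for c in topo.children[v])
            hi = ages[topo.parent[v]]
            new_ages = ages.copy()
            new_ages[v] = rng.uniform(lo, hi)
            changed = [v]
        elif mv.name == "node_age_local" and internal_nonroot:
            v = internal_nonroot[int(rng.integers(len(internal_nonroot)))]
            lo = max(ages[c] for c in topo.children[v])
            hi = ages[topo.parent[v]]
            prop = ages[v] + (rng.random() - 0.5) * 2.0 * mv.step
            if not lo < prop < hi:
                if gen % config.sample_every == 0:
                    record(gen)
                continue
            new_ages = ages.copy()
            new_ages[v] = prop
            changed = [v]
        elif mv.name == "root_age":
            v = topo.root
            factor = math.exp(mv.step * (rng.random() - 0.5) * 2.0)
            new_ages = ages.copy()
            new_ages[v] = ages[v] * factor
            log_hastings = math.log(factor)
            changed = [v]
        elif mv.name == "rate":
            factor = math.exp(mv.step * (rng.random() - 0.5) * 2.0)
            new_rate = rate * factor
            log_hastings = math.log(factor)
        elif mv.name == "multiplier":
            v = int(rng.integers(topo.n - 1))
            v = v if v != topo.root else topo.n - 1
            factor = math.exp(mv.step * (rng.random() - 0.5) * 2.0)
            new_mult = mult.copy()
            new_mult[v] = mult[v] * factor
            log_hastings = math.log(factor)
            changed = [v]
        elif mv.name == "alpha":
            factor = math.exp(mv.step * (rng.random() - 0.5) * 2.0)
            new_alpha = alpha * factor
            log_hastings = math.log(factor)
            model_changed = True
        elif mv.name == "freqs":
            i, j = rng.choice(4, size=2, replace=False)
            eps = mv.step * (rng.random() - 0.5) * 2.0
            new_freqs = freqs.copy()
            new_freqs[i] += eps
            new_freqs[j] -= eps
            if np.any(new_freqs <= 1e-4):
                if gen % config.sample_every == 0:
                    record(gen)
                continue
            model_changed = True
        else:  # exch
            i, j = rng.choice(6, size=2, replace=False)
            eps = mv.step * (rng.random() - 0.5) * 2.0
            new_exch = exch.copy()
            new_exch[i] += eps
            new_exch[j] -= eps
            if np.any(new_exch <= 1e-4):
                if gen % config.sample_every == 0:
                    record(gen)
                continue
            model_changed = True

        new_lp = prior.log_density(new_ages, new_rate, new_mult,
                                   new_alpha if config.estimate_model else None)
        if not np.isfinite(new_lp):
            if gen % config.sample_every == 0:
                record(gen)
            continue
        if use_like:
            if model_changed:
                new_model = GTRModel(tuple(new_exch), tuple(new_freqs),
                                     new_alpha, model.n_categories)
                old_model = engine.model
                engine.set_model(new_model)
                new_ll = engine.full_loglik(new_ages, new_rate, new_mult)
            elif changed:
                snap = engine.snapshot(changed)
                new_ll = engine.update_loglik(new_ages, new_rate, new_mult, changed)
            else:
                snap = None
                new_ll = engine.full_loglik(new_ages, new_rate, new_mult)
        else:
            new_ll = 0.0

        accept = math.log(rng.random() + 1e-300) < (new_lp + new_ll) - (lp + ll) + log_hastings
        if accept:
            mv.accepted += 1
            ages, rate, mult, alpha = new_ages, new_rate, new_mult, new_alpha
            freqs, exch = new_freqs, new_exch
            lp, ll = new_lp, new_ll
            if model_changed:
                model = engine.model if use_like else GTRModel(
                    tuple(exch), tuple(freqs), alpha, model.n_categories)
        else:
            if use_like:
                if model_changed:
                    engine.set_model(old_model)
                    engine.full_loglik(ages, rate, mult)
                elif changed and snap is not None:
                    engine.restore(snap)
                else:
                    engine.full_loglik(ages, rate, mult)

        if config.tune and gen <= burn_end and gen % tune_interval == 0:
            for m in moves:
                if m.name == "node_age" or m.tried < 20:
                    continue
                acc = m.accepted / m.tried
                if acc < 0.2:
                    m.step = max(m.step * 0.8, 1e-3)
                elif acc > 0.4:
                    m.step = min(m.step * 1.25, 5.0)

        if gen % config.sample_every == 0:
            record(gen)

    acceptance = {m.name: (m.accepted / m.tried if m.tried else 0.0) for m in moves}
    for name, acc in acceptance.items():
        if acc == 0.0 and moves[0].tried:
            import warnings

            warnings.warn(f"move {name!r} accepted nothing after tuning", RuntimeWarning)
    columns = {k: v[:sample_row] for k, v in store.items()}
    return PosteriorTrace(columns, clades, acceptance, config)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

@dataclass
class NodeAgeSummary:
    name: str
    mean: float
    median: float
    hpd_low: float
    hpd_high: float
    ess: float
    clade: frozenset[str] | None = None


def hpd_interval(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing at least ``mass`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    w = int(math.ceil(mass * n))
    if w < 1 or n < 2:
        raise ValueError("too few samples for an HPD interval")
    if w >= n:
        return float(x[0]), float(x[-1])
    widths = x[w - 1:] - x[: n - w + 1]
    k = int(np.argmin(widths))
    return float(x[k]), float(x[k + w - 1])


def effective_sample_size(samples: np.ndarray, cutoff: float = 0.05) -> float:
    """ESS = n / (1 + 2 * sum of autocorrelation magnitudes).

    Autocorrelations are summed (in absolute value, which is conservative for
    antithetic chains) until they fall below ``cutoff``.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 3:
        return float(n)
    if np.all(x == x[0]):
        return float(n)
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acf = np.fft.irfft(f * np.conj(f), m)[:n]
    acf /= acf[0]
    s = 0.0
    for k in range(1, n // 2):
        if abs(acf[k]) < cutoff:
            break
        s += abs(acf[k])
    return float(min(n, max(1.0, n / (1.0 + 2.0 * s))))


def summarize_trace(trace: PosteriorTrace, burnin_fraction: float | None = None,
                    mass: float = 0.95) -> dict[str, NodeAgeSummary]:
    """Posterior mean/median/HPD/ESS per parameter after burn-in."""
    frac = trace.config.burnin_fraction if burnin_fraction is None else burnin_fraction
    out: dict[str, NodeAgeSummary] = {}
    n = len(trace)
    start = int(n * frac)
    if n - start < 2:
        raise ValueError("need at least 2 post-burn-in samples")
    for name, col in trace.columns.items():
        if name == "generation":
            continue
        x = col[start:]
        lo, hi = hpd_interval(x, mass)
        out[name] = NodeAgeSummary(
            name=name, mean=float(x.mean()), median=float(np.median(x)),
            hpd_low=lo, hpd_high=hi, ess=effective_sample_size(x),
            clade=trace.node_clades.get(name),
        )
    return out


# ---------------------------------------------------------------------------
# Presence-based minimum age
# ---------------------------------------------------------------------------

class InsufficientCarriersError(ValueError):
    """Fewer than two carrier taxa: the insertion cannot be dated by orthology."""


@dataclass
class MinAgeResult:
    min_age: float
    carrier_mrca: frozenset[str]
    carriers: tuple[str, ...]


def min_age_from_presence(host_tree: HostTree, presence: dict[str, str] | dict[str, bool],
                          locus: str | None = None) -> MinAgeResult:
    """Minimum insertion age: the age of the MRCA of all carrier taxa.

    ``presence`` maps taxon to a presence state ('present'/'absent'/
    'ambiguous', or a boolean); ambiguous taxa are excluded.  At least two
    carriers are required.
    """
    carriers = tuple(sorted(
        t for t, state in presence.items()
        if state is True or state == "present"))
    if len(carriers) < 2:
        raise InsufficientCarriersError(
            f"{len(carriers)} carrier(s) for locus {locus or '?'}; need >= 2")
    node = host_tree.mrca(carriers)
    return MinAgeResult(min_age=node.age,
                        carrier_mrca=frozenset(node.tip_labels()),
                        carriers=carriers)


# ---------------------------------------------------------------------------
# Two-locus (paralogue) topology construction
# ---------------------------------------------------------------------------

def paralogue_join(host_tree: HostTree, carriers_a, carriers_b,
                   root_age: float, labels: tuple[str, str] = ("A", "B")) -> HostTree:
    """Join two orthologue clades at a paralogue root.

    Each clade mirrors the host topology restricted to its carriers (tips are
    renamed ``taxon__label``); the clades attach to a root at ``root_age``
    My, the divergence of the two insertions' viral ancestors.
    """

    def sub(carriers, label) -> TreeNode:
        clone = HostTree.from_newick(host_tree.restricted_newick(carriers))

        def rename(node: TreeNode):
            if node.is_leaf:
                node.label = f"{node.label}__{label}"
            for c in node.children:
                rename(c)

        rename(clone.root)
        return clone.root

    ra, rb = sub(carriers_a, labels[0]), sub(carriers_b, labels[1])
    if root_age <= max(ra.age, rb.age):
        raise ValueError("paralogue root age must exceed both clade crown ages")
    root = TreeNode(None, root_age, [ra, rb])
    return HostTree(root)
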