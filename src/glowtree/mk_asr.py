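"""Two-state continuous-time Markov (Mk) trait model on time trees.

Provides the closed-form transition matrix, Felsenstein pruning likelihood,
marginal ancestral-state reconstruction, and a Metropolis-Hastings sampler
over the two rates that integrates over a posterior sample of trees by drawing
one tree uniformly per iteration (the BayesTraits-style treatment of
phylogenetic uncertainty).

States are 0 (absent) and 1 (present); rates are the gain rate ``q01`` and the
loss rate ``q10`` in events/Ma.  Missing tip states enter the pruning as the
ambiguous partial (1, 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from ._flat import FlatTree
from .treeio import TimeTree, TraitTable, TreeSample

log = logging.getLogger(__name__)

_SCALE_FLOOR = 1e-240


@dataclass(frozen=True)
class MkParams:
    """Gain (q01) and loss (q10) rates of the binary Mk model, events/Ma."""

    q01: float
    q10: float

    def __post_init__(self):
        if not (math.isfinite(self.q01) and math.isfinite(self.q10)):
            raise ValueError("rates must be finite")
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("rates must be >= 0")

    @property
    def total(self) -> float:
        return self.q01 + self.q10


@dataclass(frozen=True)
class RootPrior:
    """Prior on the root state: (P(state 0), P(state 1))."""

    p0: float
    p1: float
    mode: str = "fixed"

    def __post_init__(self):
        if self.p0 < 0 or self.p1 < 0 or abs(self.p0 + self.p1 - 1.0) > 1e-12:
            raise ValueError("root prior must be a probability vector")

    @classmethod
    def uniform(cls) -> "RootPrior":
        return cls(0.5, 0.5, mode="uniform")

    @classmethod
    def stationary(cls, params: MkParams) -> "RootPrior":
        q = params.total
        if q == 0:
            return cls(0.5, 0.5, mode="stationary")
        return cls(params.q10 / q, params.q01 / q, mode="stationary")


def resolve_root_prior(root: "RootPrior | str", params: MkParams) -> RootPrior:
    if isinstance(root, RootPrior):
        return root
    if root == "uniform":
        return RootPrior.uniform()
    if root == "stationary":
        return RootPrior.stationary(params)
    raise ValueError(f"unknown root prior {root!r}")


def transition_matrix(params: MkParams, t: float) -> np.ndarray:
    """P(t) of the two-state chain in closed form; rows sum to 1.

    P00 = (q10 + q01 e^{-(q01+q10) t}) / (q01 + q10), and symmetrically for
    the other entries; the identity when both rates are zero.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    q = params.total
    if q == 0:
        return np.eye(2)
    e = math.exp(-q * t)
    p00 = (params.q10 + params.q01 * e) / q
    p11 = (params.q01 + params.q10 * e) / q
    return np.array([[p00, 1.0 - p00], [1.0 - p11, p11]])


# ---------------------------------------------------------------- tip partials
def tip_partials(flat: FlatTree, traits: TraitTable) -> np.ndarray:
    """(n_tips, 2) conditional likelihoods; missing state -> (1, 1)."""
    traits.check_covers(flat.labels)
    out = np.ones((flat.n_tips, 2))
    for i, lab in enumerate(flat.labels):
        st = traits.states[lab]
        if st == 0:
            out[i, 1] = 0.0
        elif st == 1:
            out[i, 0] = 0.0
    return out


def _edge_probs(flat: FlatTree, params: MkParams) -> Tuple[list, list, list, list]:
    q = params.total
    bl = flat.blen
    if q == 0.0:
        n = flat.n_nodes
        one = [1.0] * n
        zero = [0.0] * n
        return one, zero, zero, one
    e = np.exp(-q * bl)
    p00 = (params.q10 + params.q01 * e) / q
    p11 = (params.q01 + params.q10 * e) / q
    p01 = 1.0 - p00
    p10 = 1.0 - p11
    return p00.tolist(), p01.tolist(), p10.tolist(), p11.tolist()


def _prune(
    flat: FlatTree, tipcond: np.ndarray, params: MkParams
) -> Tuple[list, list, float]:
    """Postorder partial likelihoods with underflow rescaling.

    Returns (partial0, partial1, log_scaler).
    """
    P00, P01, P10, P11 = _edge_probs(flat, params)
    n = flat.n_nodes
    part0 = [0.0] * n
    part1 = [0.0] * n
    tc = tipcond
    for i in range(flat.n_tips):
        part0[i] = tc[i, 0]
        part1[i] = tc[i, 1]
    logscale = 0.0
    children = flat.children
    for v in flat.internal_postorder:
        a = 1.0
        b = 1.0
        for c in children[v]:
            c0 = part0[c]
            c1 = part1[c]
            a *= P00[c] * c0 + P01[c] * c1
            b *= P10[c] * c0 + P11[c] * c1
        s = a + b
        if s < _SCALE_FLOOR:
            if s <= 0.0:
                part0[v] = 0.0
                part1[v] = 0.0
                continue
            a /= s
            b /= s
            logscale += math.log(s)
        part0[v] = a
        part1[v] = b
    return part0, part1, logscale


def tree_loglik(
    tree: "TimeTree | FlatTree",
    traits: TraitTable,
    params: MkParams,
    root: "RootPrior | str" = "uniform",
    tipcond: Optional[np.ndarray] = None,
) -> float:
    """Felsenstein pruning log-likelihood of the tip states."""
    flat = tree.flat if isinstance(tree, TimeTree) else tree
    if tipcond is None:
        tipcond = tip_partials(flat, traits)
    prior = resolve_root_prior(root, params)
    part0, part1, logscale = _prune(flat, tipcond, params)
    r = flat.root
    lik = prior.p0 * part0[r] + prior.p1 * part1[r]
    if lik <= 0.0:
        return -math.inf
    return math.log(lik) + logscale


def marginal_asr(
    tree: "TimeTree | FlatTree",
    traits: TraitTable,
    params: MkParams,
    root: "RootPrior | str" = "uniform",
    tipcond: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Marginal posterior P(state = 1) for every node (tips included).

    Combines downward (inside) partials with upward (outside) partials; each
    node's two state probabilities sum to one exactly.
    """
    flat = tree.flat if isinstance(tree, TimeTree) else tree
    if tipcond is None:
        tipcond = tip_partials(flat, traits)
    prior = resolve_root_prior(root, params)
    part0, part1, _ = _prune(flat, tipcond, params)
    P00, P01, P10, P11 = _edge_probs(flat, params)

    n = flat.n_nodes
    out0 = [0.0] * n
    out1 = [0.0] * n
    r = flat.root
    out0[r] = prior.p0
    out1[r] = prior.p1
    children = flat.children
    for v in reversed(flat.internal_postorder):
        ch = children[v]
        # downward message of each child = P_child^T @ (outside(v) * sibling products)
        for c in ch:
            s0 = out0[v]
            s1 = out1[v]
            for s in ch:
                if s == c:
                    continue
                s0 *= P00[s] * part0[s] + P01[s] * part1[s]
                s1 *= P10[s] * part0[s] + P11[s] * part1[s]
            d0 = s0 * P00[c] + s1 * P10[c]
            d1 = s0 * P01[c] + s1 * P11[c]
            z = d0 + d1
            if z > 0:
                d0 /= z
                d1 /= z
            out0[c] = d0
            out1[c] = d1

    marg = np.empty(n)
    for v in range(n):
        a = out0[v] * part0[v]
        b = out1[v] * part1[v]
        z = a + b
        marg[v] = 0.5 if z == 0 else b / z
    return marg


# ------------------------------------------------------------------- priors
@dataclass(frozen=True)
class RatePriors:
    """Independent priors on (q01, q10).

    ``exponential``: mean defaults to 1/tree-height per rate, i.e. about one
    event per root-to-tip path a priori.  ``uniform``: (0, 100/tree-height).
    """

    kind: str = "exponential"
    mean: Optional[float] = None  # exponential mean
    upper: Optional[float] = None  # uniform upper bound

    def resolved(self, tree_height: float) -> "RatePriors":
        if self.kind == "exponential":
            m = self.mean if self.mean is not None else 1.0 / tree_height
            return RatePriors("exponential", mean=m)
        if self.kind == "uniform":
            u = self.upper if self.upper is not None else 100.0 / tree_height
            return RatePriors("uniform", upper=u)
        raise ValueError(f"unknown prior kind {self.kind!r}")

    def logpdf(self, q: float) -> float:
        if q < 0:
            return -math.inf
        if self.kind == "exponential":
            return -q / self.mean - math.log(self.mean)
        if q > self.upper:
            return -math.inf
        return -math.log(self.upper)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "exponential":
            return float(rng.exponential(self.mean))
        return float(rng.uniform(0.0, self.upper))


@dataclass
class ChainSettings:
    iterations: int = 1_010_000
    burnin_frac: float = 0.1
    thin: int = 1_000
    proposal_halfwidth: float = 1.0  # log-multiplier window half-width

    def __post_init__(self):
        burn = int(self.iterations * self.burnin_frac)
        if self.iterations <= burn:
            raise ValueError("iterations must exceed burn-in")


def _ess(x: np.ndarray) -> float:
    """Effective sample size by the initial-positive-sequence autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, n // 2):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1.0 + 2.0 * s))


@dataclass
class ASRResult:
    """Per-tree mean marginal P(state 1) plus the thinned rate chain."""

    sample: TreeSample
    node_prob1: List[np.ndarray]  # per tree, length n_nodes of that tree
    draws_per_tree: np.ndarray
    trace: pd.DataFrame  # iteration, q01, q10, loglik, tree_index
    rate_summary: Dict[str, Dict[str, float]]
    acceptance_rate: float
    settings: ChainSettings = field(default=None)  # type: ignore[assignment]

    def node_table(self) -> pd.DataFrame:
        rows = []
        for ti, probs in enumerate(self.node_prob1):
            flat = self.sample[ti].flat
            keys = flat.node_keys()
            for v in flat.internal_postorder:
                rows.append(
                    {"tree": ti, "node": keys[v], "p_state1": float(probs[v])}
                )
        return pd.DataFrame(rows)


def _summarise_rates(trace: pd.DataFrame) -> Dict[str, Dict[str, float]]:
    out = {}
    for name in ("q01", "q10"):
        x = trace[name].to_numpy()
        lo, hi = np.quantile(x, [0.025, 0.975])
        out[name] = {
            "mean": float(np.mean(x)),
            "lower95": float(lo),
            "upper95": float(hi),
            "ess": _ess(x),
        }
    return out


def mcmc_asr(
    sample: TreeSample,
    traits: TraitTable,
    priors: RatePriors = RatePriors(),
    chain: ChainSettings = ChainSettings(),
    seed: int = 0,
    root: "RootPrior | str" = "uniform",
) -> ASRResult:
    """Metropolis-Hastings over (q01, q10) with uniform tree redraws.

    Every iteration proposes a fresh tree (uniformly from the sample) jointly
    with a log-multiplier update of one rate; retained iterations contribute a
    marginal reconstruction of the drawn tree, so node probabilities average
    over both rate and tree uncertainty.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    ntree = len(sample)
    flats = [t.flat for t in sample]
    tipconds = [tip_partials(f, traits) for f in flats]
    height = float(np.mean([f.height() for f in flats]))
    pri = priors.resolved(height)

    q01 = pri.sample(rng)
    q10 = pri.sample(rng)
    # a cold start at 0 would freeze the multiplier proposal
    q01 = max(q01, 1e-8)
    q10 = max(q10, 1e-8)
    cur_tree = int(rng.integers(ntree))

    def _ll(ti: int, p: MkParams) -> float:
        return tree_loglik(flats[ti], traits, p, root=root, tipcond=tipconds[ti])

    cur_params = MkParams(q01, q10)
    cur_ll = _ll(cur_tree, cur_params)
    cur_lp = pri.logpdf(q01) + pri.logpdf(q10)

    burn = int(chain.iterations * chain.burnin_frac)
    accepted = 0
    retained_rows = []
    sums = [np.zeros(f.n_nodes) for f in flats]
    draws = np.zeros(ntree, dtype=np.int64)
    w = chain.proposal_halfwidth

    for it in range(chain.iterations):
        prop_tree = int(rng.integers(ntree))
        which = int(rng.integers(2))
        factor = math.exp(w * (2.0 * rng.random() - 1.0))
        nq01, nq10 = (q01 * factor, q10) if which == 0 else (q01, q10 * factor)
        prop_params = MkParams(nq01, nq10)
        prop_ll = _ll(prop_tree, prop_params)
        prop_lp = pri.logpdf(nq01) + pri.logpdf(nq10)
        # Hastings term of the multiplier proposal is +log(factor)
        logalpha = (prop_ll + prop_lp) - (cur_ll + cur_lp) + math.log(factor)
        if logalpha >= 0 or rng.random() < math.exp(logalpha):
            q01, q10 = nq01, nq10
            cur_params = prop_params
            cur_tree = prop_tree
            cur_ll = prop_ll
            cur_lp = prop_lp
            accepted += 1
        if it >= burn and (it - burn) % chain.thin == 0:
            retained_rows.append((it, q01, q10, cur_ll, cur_tree))
            sums[cur_tree] += marginal_asr(
                flats[cur_tree], traits, cur_params, root=root,
                tipcond=tipconds[cur_tree],
            )
            draws[cur_tree] += 1

    acc_rate = accepted / chain.iterations
    if accepted == 0:
        log.warning(
            "MCMC accepted no proposals; the prior scale or proposal width "
            "likely mismatches the data"
        )
    trace = pd.DataFrame(
        retained_rows, columns=["iteration", "q01", "q10", "loglik", "tree_index"]
    )
    post_mean = MkParams(float(trace["q01"].mean()), float(trace["q10"].mean()))
    node_prob1 = []
    for ti in range(ntree):
        if draws[ti] > 0:
            node_prob1.append(sums[ti] / draws[ti])
        else:
            # trees never drawn after burn-in: reconstruct at the posterior mean
            node_prob1.append(
                marginal_asr(flats[ti], traits, post_mean, root=root,
                             tipcond=tipconds[ti])
            )
    return ASRResult(
        sample=sample,
        node_prob1=node_prob1,
        draws_per_tree=draws,
        trace=trace,
        rate_summary=_summarise_rates(trace),
        acceptance_rate=acc_rate,
        settings=chain,
    )
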