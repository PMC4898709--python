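"""Birth-death clade-richness envelopes and stepwise rate-shift search.

Two coupled analyses:

* Crown clade-size distribution under a constant-rate birth-death process
  with net diversification ``r = lambda - mu`` and relative extinction
  ``eps = mu / lambda``, conditioned on survival of both crown lineages:
  with ``beta = (e^{rt} - 1) / (e^{rt} - eps)``,
  ``P(N = n) = (n - 1) (1 - beta)^2 beta^{n - 2}`` for ``n >= 2``.
  Equal-tail quantiles of this distribution give expected-richness envelopes;
  an observed described-species count strictly above the upper bound flags a
  clade as exceptionally species-rich.

* A stepwise AICc search for diversification-rate shifts on a time tree whose
  tips carry taxonomic richness (each terminal may stand for an unresolved
  clade of ``m`` described species).  The likelihood is edge-additive: internal
  edges contribute the no-observed-split probability of the reconstructed
  process, internal nodes an observed-split factor, and terminals the stem-age
  taxonomic (geometric) likelihood ``(1 - beta_s) beta_s^{m - 1}``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from ._flat import FlatTree
from .treeio import RichnessTable, TimeTree

log = logging.getLogger(__name__)

EPS_MAX = 0.99


@dataclass(frozen=True)
class BDParams:
    """Net diversification r (1/Ma) and relative extinction eps = mu/lambda."""

    r: float
    eps: float = 0.0

    def __post_init__(self):
        if not (math.isfinite(self.r) and math.isfinite(self.eps)):
            raise ValueError("rates must be finite")
        if self.eps < 0 or self.eps >= 1:
            raise ValueError("relative extinction must lie in [0, 1)")

    @property
    def lam(self) -> float:
        return self.r / (1.0 - self.eps)

    @property
    def mu(self) -> float:
        return self.lam * self.eps

    @classmethod
    def from_lambda_mu(cls, lam: float, mu: float) -> "BDParams":
        if lam <= 0:
            raise ValueError("lambda must be > 0")
        if mu < 0 or mu >= lam:
            raise ValueError("mu must lie in [0, lambda)")
        return cls(lam - mu, mu / lam)


def _beta(bd: BDParams, t: float) -> float:
    ert = math.exp(bd.r * t)
    return (ert - 1.0) / (ert - bd.eps)


def crown_size_pmf(
    bd: BDParams, t: float, tail: float = 1e-9
) -> Tuple[np.ndarray, np.ndarray]:
    """PMF of crown clade size at age ``t`` given both crown lineages survive.

    Returns ``(n_values, probs)`` truncated adaptively so the retained mass is
    at least ``1 - tail``.
    """
    if bd.r <= 0:
        raise ValueError("net diversification must be > 0")
    if t <= 0:
        raise ValueError("crown age must be > 0")
    b = _beta(bd, t)
    # N - 2 is negative binomial(2, 1-b); invert its survival function for the cut
    if b == 0:
        return np.array([2]), np.array([1.0])
    nmax = 2 + int(
        math.ceil(
            (math.log(tail) - math.log(2.0 / (1 - b))) / math.log(b)
        )
    )
    nmax = max(nmax, 10)
    n = np.arange(2, nmax + 1)
    logp = (
        np.log(n - 1.0) + 2.0 * math.log1p(-b) + (n - 2.0) * math.log(b)
    )
    p = np.exp(logp)
    while p.sum() < 1.0 - tail:
        extra = np.arange(nmax + 1, 2 * nmax + 1)
        p_extra = np.exp(
            np.log(extra - 1.0) + 2.0 * math.log1p(-b) + (extra - 2.0) * math.log(b)
        )
        n = np.concatenate([n, extra])
        p = np.concatenate([p, p_extra])
        nmax *= 2
    return n, p


def richness_interval(
    bd: BDParams, t: float, coverage: float = 0.95
) -> Tuple[int, int]:
    """Equal-tail quantile bounds of the crown-size pmf at the given coverage."""
    if not (0.0 < coverage < 1.0):
        raise ValueError("coverage must lie in (0, 1)")
    n, p = crown_size_pmf(bd, t)
    cdf = np.cumsum(p)
    alpha = (1.0 - coverage) / 2.0
    lower = int(n[np.searchsorted(cdf, alpha)])
    upper = int(n[np.searchsorted(cdf, 1.0 - alpha)])
    return lower, upper


@dataclass
class RichnessEnvelope:
    clade: str
    crown_age_ma: float
    r: float
    eps: float
    expected: float
    lower: int
    upper: int
    observed: Optional[int] = None
    exceptional: Optional[bool] = None
    depauperate: Optional[bool] = None


def expected_crown_size(bd: BDParams, t: float) -> float:
    """Mean of the surviving-crown clade-size distribution, 2/(1-beta)."""
    return 2.0 / (1.0 - _beta(bd, t))


def flag_exceptional(observed: int, lower: int, upper: int) -> Tuple[bool, bool]:
    """(exceptional, depauperate): strictly above the upper bound / strictly below
    the lower bound.  A clade sitting exactly on a bound is neither."""
    if observed < 2:
        raise ValueError("observed richness must be >= 2")
    return observed > upper, observed < lower


def richness_envelopes(
    tree: "TimeTree | FlatTree",
    richness: RichnessTable,
    bd: BDParams,
    coverage: float = 0.95,
) -> pd.DataFrame:
    """Envelope report for every clade in the richness table (Fig-4-style tabular).

    Crown ages come from the tree's node heights unless the table supplies one.
    """
    flat = tree.flat if isinstance(tree, TimeTree) else tree
    rows = []
    for cl in richness:
        defined = cl.tips & frozenset(flat.labels)
        if cl.crown_age_ma is not None:
            age = cl.crown_age_ma
        else:
            if len(defined) < 2:
                log.warning("clade %s: <2 sampled tips and no crown age; skipped", cl.name)
                continue
            age = float(flat.ages[flat.mrca(defined)])
        lower, upper = richness_interval(bd, age, coverage)
        exc, dep = flag_exceptional(cl.species, lower, upper)
        rows.append(
            {
                "clade": cl.name,
                "crown_age_ma": age,
                "r": bd.r,
                "eps": bd.eps,
                "expected": expected_crown_size(bd, age),
                "lower": lower,
                "upper": upper,
                "observed": cl.species,
                "exceptional": exc,
                "depauperate": dep,
            }
        )
    return pd.DataFrame(rows)


# ======================================================= piecewise likelihood
def _edge_arrays(flat: FlatTree, tip_richness: np.ndarray):
    """Per-edge quantities used by the piecewise likelihood."""
    child = np.arange(flat.n_nodes - 1)
    parent = flat.parent[child]
    s = flat.ages[parent]  # older end
    u = flat.ages[child]  # younger end
    is_tip = child < flat.n_tips
    m = np.where(is_tip, tip_richness[np.minimum(child, flat.n_tips - 1)], 1)
    return s, u, is_tip, m.astype(float)


def _piece_loglik(
    r: float, eps: float, s: np.ndarray, u: np.ndarray, is_tip: np.ndarray, m: np.ndarray
) -> float:
    """Log-likelihood contribution of one set of edges under (r, eps).

    Internal edge: -[r (s-u) + ln((lam - mu e^{-r s})/(lam - mu e^{-r u}))]
                   + ln(lam (1 - p0(u)))  for the observed split at the child.
    Terminal edge: ln[(1 - beta(s)) beta(s)^{m-1}] with stem age s.
    """
    if r <= 0 or eps < 0 or eps >= 1:
        return -math.inf
    lam = r / (1.0 - eps)
    mu = lam * eps
    ll = 0.0
    # internal edges
    ii = ~is_tip
    if np.any(ii):
        si, ui = s[ii], u[ii]
        fs = lam - mu * np.exp(-r * si)
        fu = lam - mu * np.exp(-r * ui)
        # 1 - p0(t) = r / (lam - mu e^{-rt})
        ll += float(
            np.sum(-(r * (si - ui)) - np.log(fs) + np.log(fu))
            + np.sum(np.log(lam * r / fu))
        )
    it = is_tip
    if np.any(it):
        st, mt = s[it], m[it]
        x = np.maximum(r * st, 1e-12)
        emx = np.exp(-x)
        # log(beta) and log(1 - beta) without forming e^{r s}
        log_denom = np.log1p(-eps * emx)
        log_beta = np.log(-np.expm1(-x)) - log_denom
        log_1mb = math.log1p(-eps) - x - log_denom
        ll += float(np.sum(log_1mb + (mt - 1.0) * log_beta))
    return ll


@dataclass
class Piece:
    """A contiguous set of edges sharing one BDParams; identified by the child
    node of its stem edge (None for the background piece rooted at the root)."""

    shift_node: Optional[int]
    edges: np.ndarray  # child-node indices
    params: Optional[BDParams] = None
    loglik: float = math.nan


@dataclass
class ShiftConfig:
    pieces: List[Piece]
    aicc: float
    loglik: float
    n_obs: int
    trace: List[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return 2 * len(self.pieces) + (len(self.pieces) - 1)

    def table(self, flat: FlatTree) -> pd.DataFrame:
        keys = flat.node_keys()
        rows = []
        for pc in self.pieces:
            rows.append(
                {
                    "piece": "background" if pc.shift_node is None else keys[pc.shift_node],
                    "n_edges": len(pc.edges),
                    "r": pc.params.r,
                    "eps": pc.params.eps,
                    "lambda": pc.params.lam,
                    "mu": pc.params.mu,
                    "loglik": pc.loglik,
                }
            )
        return pd.DataFrame(rows)


def aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return math.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def bd_loglik(
    tree: "TimeTree | FlatTree",
    tip_richness: "np.ndarray | Dict[str, int]",
    pieces: Sequence[Tuple[Sequence[int], BDParams]],
) -> float:
    """Total piecewise birth-death + taxonomic log-likelihood.

    ``pieces`` is a sequence of (edge child-index list, BDParams) that must
    partition the tree's edges; tip richness must be >= 1 everywhere.
    """
    flat = tree.flat if isinstance(tree, TimeTree) else tree
    rich = _as_richness_array(flat, tip_richness)
    s, u, is_tip, m = _edge_arrays(flat, rich)
    seen = np.zeros(flat.n_nodes - 1, dtype=bool)
    total = 0.0
    for edges, bd in pieces:
        idx = np.asarray(list(edges), dtype=np.int64)
        if np.any(seen[idx]):
            raise ValueError("pieces overlap")
        seen[idx] = True
        total += _piece_loglik(bd.r, bd.eps, s[idx], u[idx], is_tip[idx], m[idx])
    if not np.all(seen):
        raise ValueError("pieces do not cover all edges")
    return total


def _as_richness_array(flat: FlatTree, tip_richness) -> np.ndarray:
    if isinstance(tip_richness, dict):
        arr = np.array([tip_richness.get(lab, 1) for lab in flat.labels], dtype=np.int64)
    else:
        arr = np.asarray(tip_richness, dtype=np.int64)
        if len(arr) != flat.n_tips:
            raise ValueError("need one richness per tip")
    if np.any(arr < 1):
        raise ValueError("tip richness must be >= 1")
    return arr


def _fit_piece(
    s, u, is_tip, m, starts: Sequence[Tuple[float, float]] = None
) -> Tuple[BDParams, float]:
    """Maximum-likelihood (r, eps) for one edge set; multi-start L-BFGS-B on
    (log r, eps)."""
    span = max(float(np.max(s)), 1e-6)
    total_m = float(np.sum(m[is_tip])) if np.any(is_tip) else 2.0
    r0 = max(math.log(max(total_m, 3.0)) / span, 1e-4)
    if starts is None:
        starts = [(r0, 0.0), (r0, 0.5), (r0, 0.9)]

    def nll(x):
        return -_piece_loglik(math.exp(x[0]), x[1], s, u, is_tip, m)

    best = None
    for r_init, e_init in starts:
        try:
            res = optimize.minimize(
                nll,
                x0=[math.log(r_init), e_init],
                method="L-BFGS-B",
                bounds=[(math.log(1e-8), math.log(1e3)), (0.0, EPS_MAX)],
            )
        except Exception as exc:  # pragma: no cover - optimizer hiccup
            log.warning("piece fit failed from start %s: %s", (r_init, e_init), exc)
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("piece likelihood optimisation failed from all starts")
    r_hat = math.exp(best.x[0])
    return BDParams(r_hat, float(best.x[1])), -float(best.fun)


def fit_bd(
    tree: "TimeTree | FlatTree", tip_richness="ones"
) -> Tuple[BDParams, float]:
    """Single-piece maximum-likelihood fit over the whole tree."""
    flat = tree.flat if isinstance(tree, TimeTree) else tree
    if isinstance(tip_richness, str) and tip_richness == "ones":
        rich = np.ones(flat.n_tips, dtype=np.int64)
    else:
        rich = _as_richness_array(flat, tip_richness)
    s, u, is_tip, m = _edge_arrays(flat, rich)
    return _fit_piece(s, u, is_tip, m)


def medusa_search(
    tree: "TimeTree | FlatTree",
    tip_richness="ones",
    threshold: float = 4.0,
    max_shifts: int = 10,
) -> ShiftConfig:
    """Stepwise AICc search for diversification-rate shifts.

    Fits a single birth-death model, then repeatedly tries a shift on every
    eligible stem edge (edges subtending an internal node), refitting the
    carved subtree piece and its donor; the best candidate is accepted iff it
    lowers AICc by at least ``threshold``.  Deterministic given the tree.
    """
    flat = tree.flat if isinstance(tree, TimeTree) else tree
    if flat.n_tips < 3:
        raise ValueError("need at least 3 tips")
    if isinstance(tip_richness, str) and tip_richness == "ones":
        rich = np.ones(flat.n_tips, dtype=np.int64)
    else:
        rich = _as_richness_array(flat, tip_richness)
    s, u, is_tip, m = _edge_arrays(flat, rich)
    n_edges = flat.n_nodes - 1
    n_obs = n_edges

    def fit_edges(idx: np.ndarray, warm: Optional[BDParams] = None):
        starts = None
        if warm is not None:
            starts = [(warm.r, warm.eps), (warm.r, 0.5), (warm.r, 0.0)]
        return _fit_piece(s[idx], u[idx], is_tip[idx], m[idx], starts=starts)

    all_edges = np.arange(n_edges)
    params0, ll0 = fit_edges(all_edges)
    pieces = [Piece(None, all_edges, params0, ll0)]
    total_ll = ll0
    cfg_aicc = aicc(total_ll, 2 * 1 + 0, n_obs)
    trace = [f"single-rate fit: r={params0.r:.5f} eps={params0.eps:.3f} AICc={cfg_aicc:.2f}"]

    # subtree edge lists, computed once
    subtree_edges: Dict[int, np.ndarray] = {}
    for v in range(flat.n_nodes - 1):
        if v >= flat.n_tips:
            nodes = flat.subtree_nodes(v)
            subtree_edges[v] = np.asarray(sorted(nodes), dtype=np.int64)

    piece_of = np.zeros(n_edges, dtype=np.int64)
    shift_nodes: List[Optional[int]] = [None]

    while len(pieces) - 1 < max_shifts:
        k_new = 2 * (len(pieces) + 1) + len(pieces)
        best = None  # (aicc, shift_node, donor_idx, new piece fits...)
        for v, sub in subtree_edges.items():
            if v in shift_nodes:
                continue
            donor_idx = int(piece_of[v])
            take = sub[piece_of[sub] == donor_idx]
            donor_edges = pieces[donor_idx].edges
            remain = donor_edges[~np.isin(donor_edges, take)]
            if len(take) < 3 or len(remain) < 3:
                continue
            try:
                p_new, ll_new = fit_edges(take, warm=pieces[donor_idx].params)
                p_rem, ll_rem = fit_edges(remain, warm=pieces[donor_idx].params)
            except RuntimeError as exc:
                log.warning("candidate shift at node %d skipped: %s", v, exc)
                continue
            ll_total = total_ll - pieces[donor_idx].loglik + ll_new + ll_rem
            cand_aicc = aicc(ll_total, k_new, n_obs)
            if best is None or cand_aicc < best[0] - 1e-12:
                best = (cand_aicc, v, donor_idx, take, remain, p_new, ll_new, p_rem, ll_rem)
        if best is None or best[0] > cfg_aicc - threshold:
            break
        cand_aicc, v, donor_idx, take, remain, p_new, ll_new, p_rem, ll_rem = best
        pieces[donor_idx] = Piece(pieces[donor_idx].shift_node, remain, p_rem, ll_rem)
        pieces.append(Piece(v, take, p_new, ll_new))
        piece_of[take] = len(pieces) - 1
        shift_nodes.append(v)
        total_ll = sum(pc.loglik for pc in pieces)
        trace.append(
            f"accepted shift at node {v}: r={p_new.r:.5f} eps={p_new.eps:.3f} "
            f"dAICc={cfg_aicc - cand_aicc:.2f}"
        )
        cfg_aicc = cand_aicc

    return ShiftConfig(pieces=pieces, aicc=cfg_aicc, loglik=total_ll, n_obs=n_obs, trace=trace)
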