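"""From reconstructions to counts of independent trait origins.

A gain is an edge whose parent is reconstructed absent (0) and child present
(1); every gain is counted as one independent origin.  Losses (1 -> 0) are
tallied alongside but never folded into the origin count.  Each gain is
classified by the mechanism annotations of its state-1 descendant tips, and
the cross-tree distribution of per-tree gain counts is summarised with the
minimum always reported (the headline "at least N" reading).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._flat import FlatTree
from .mk_asr import ASRResult, MkParams, RootPrior, marginal_asr, resolve_root_prior, tip_partials, transition_matrix, _prune, _edge_probs
from .treeio import RichnessTable, TimeTree, TraitTable

log = logging.getLogger(__name__)


@dataclass
class OriginEvent:
    tree_index: int
    parent: int
    child: int
    direction: str  # "gain" | "loss"
    mechanism: Optional[str] = None  # gains only

    def __post_init__(self):
        if self.direction not in ("gain", "loss"):
            raise ValueError("direction must be 'gain' or 'loss'")
        if self.direction == "loss" and self.mechanism is not None:
            raise ValueError("mechanism applies to gains only")


def binarize(prob1, threshold: float = 0.5) -> np.ndarray:
    """State 1 iff P(1) > threshold; a tie resolves to 0 (absence-conservative)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    p = np.asarray(prob1, dtype=float)
    return (p > threshold).astype(np.int8)


def count_transitions(
    flat: "FlatTree | TimeTree", states: Sequence[int], tree_index: int = 0
) -> List[OriginEvent]:
    """One event per edge whose endpoints disagree; tips count as children."""
    if isinstance(flat, TimeTree):
        flat = flat.flat
    st = np.asarray(states)
    if len(st) != flat.n_nodes:
        raise ValueError("need one binary state per node (tips and internals)")
    events: List[OriginEvent] = []
    parent = flat.parent
    for c in range(flat.n_nodes - 1):
        p = int(parent[c])
        if st[p] == st[c]:
            continue
        direction = "gain" if (st[p] == 0 and st[c] == 1) else "loss"
        events.append(OriginEvent(tree_index, p, int(c), direction))
    return events


def classify_mechanism(
    event: OriginEvent, flat: "FlatTree | TimeTree", traits: TraitTable
) -> str:
    """Mechanism of a gain = the unique annotation among its state-1 descendant
    tips; 'mixed' if several annotations, 'unknown' if none are informative."""
    if event.direction != "gain":
        raise ValueError("mechanism classification applies to gains")
    if isinstance(flat, TimeTree):
        flat = flat.flat
    mechs = set()
    for v in flat.subtree_nodes(event.child):
        if v < flat.n_tips:
            lab = flat.labels[v]
            if traits.states.get(lab) == 1:
                mechs.add(traits.mechanisms.get(lab, "unknown"))
    if not mechs:
        log.warning(
            "gain on edge to node %d has no state-1 descendant tips; "
            "classified 'unknown'", event.child,
        )
        return "unknown"
    informative = mechs - {"unknown"}
    if len(informative) > 1:
        return "mixed"
    if len(informative) == 1:
        return next(iter(informative))
    return "unknown"


def events_from_asr(
    asr: ASRResult, traits: TraitTable, threshold: float = 0.5
) -> List[List[OriginEvent]]:
    """Binarize every tree's reconstruction and scan its edges for events.

    Observed tip states override reconstructed tip marginals; missing tips use
    their reconstructed marginal.
    """
    per_tree: List[List[OriginEvent]] = []
    for ti, probs in enumerate(asr.node_prob1):
        flat = asr.sample[ti].flat
        states = binarize(probs, threshold)
        for i, lab in enumerate(flat.labels):
            st = traits.states[lab]
            if st is not None:
                states[i] = st
        events = count_transitions(flat, states, tree_index=ti)
        for ev in events:
            if ev.direction == "gain":
                ev.mechanism = classify_mechanism(ev, flat, traits)
        per_tree.append(events)
    return per_tree


# ------------------------------------------------------------------ summary
@dataclass
class OriginSummary:
    per_tree_gains: List[int]
    per_tree_losses: List[int]
    minimum: int
    mode: int
    median: float
    interval95: Tuple[int, int]
    mechanism_tallies: Dict[str, int]
    species_by_mechanism: Dict[str, int]
    species_tally_complete: bool
    reference_tree: int
    events_table: pd.DataFrame = field(repr=False, default=None)  # type: ignore

    def to_text(self) -> str:
        lines = [
            "Origin summary",
            "==============",
            f"trees analysed          : {len(self.per_tree_gains)}",
            f"gains (minimum)         : {self.minimum}",
            f"gains (mode)            : {self.mode}",
            f"gains (median)          : {self.median:g}",
            f"gains (95% interval)    : {self.interval95[0]}-{self.interval95[1]}",
            f"losses (median)         : {np.median(self.per_tree_losses):g}",
            f"reference tree index    : {self.reference_tree}",
            "gains by mechanism      : "
            + ", ".join(f"{k}={v}" for k, v in sorted(self.mechanism_tallies.items())),
            "species by mechanism    : "
            + ", ".join(
                f"{k}={v}" for k, v in sorted(self.species_by_mechanism.items())
            )
            + ("" if self.species_tally_complete else "  [incomplete]"),
        ]
        return "\n".join(lines)


def _smallest_containing_clade(
    flat: FlatTree, richness: RichnessTable, gain_tips: frozenset
) -> Optional[object]:
    best = None
    best_span = None
    clades = flat.clades()
    for cl in richness:
        defined = cl.tips & frozenset(flat.labels)
        if len(defined) < 2:
            continue
        span = clades[flat.mrca(defined)]
        if gain_tips <= span:
            if best is None or len(span) < best_span:
                best, best_span = cl, len(span)
    return best


def summarize(
    per_tree_events: List[List[OriginEvent]],
    sample,
    traits: TraitTable,
    richness: Optional[RichnessTable] = None,
) -> OriginSummary:
    """Cross-tree distribution of gain counts plus mechanism/species tallies.

    Mechanism and species tallies are computed on the reference tree: the
    lowest-index tree whose gain count equals the cross-tree mode.
    """
    if not per_tree_events:
        raise ValueError("no events to summarise")
    gains = [sum(e.direction == "gain" for e in evs) for evs in per_tree_events]
    losses = [sum(e.direction == "loss" for e in evs) for evs in per_tree_events]
    counts = Counter(gains)
    top = max(counts.values())
    mode = min(k for k, v in counts.items() if v == top)
    lo, hi = np.quantile(gains, [0.025, 0.975])
    ref = gains.index(mode)

    ref_events = per_tree_events[ref]
    flat = sample[ref].flat
    clades = flat.clades()
    tallies: Dict[str, int] = {}
    species: Dict[str, int] = {}
    seen_clades: Dict[str, set] = {}
    complete = True
    rows = []
    for evs, ti in [(per_tree_events[i], i) for i in range(len(per_tree_events))]:
        fl = sample[ti].flat
        keys = fl.node_keys()
        for ev in evs:
            rows.append(
                {
                    "tree": ti,
                    "edge": f"{keys[ev.parent]}->{keys[ev.child]}",
                    "direction": ev.direction,
                    "mechanism": ev.mechanism or "",
                    "clade": "",
                }
            )
    events_table = pd.DataFrame(
        rows, columns=["tree", "edge", "direction", "mechanism", "clade"]
    )

    for ev in ref_events:
        if ev.direction != "gain":
            continue
        mech = ev.mechanism or "unknown"
        tallies[mech] = tallies.get(mech, 0) + 1
        if richness is not None:
            cl = _smallest_containing_clade(flat, richness, clades[ev.child])
            if cl is None:
                complete = False
                continue
            seen_clades.setdefault(mech, set())
            if cl.name not in seen_clades[mech]:
                seen_clades[mech].add(cl.name)
                species[mech] = species.get(mech, 0) + cl.species
            mask = (events_table["tree"] == ref) & (
                events_table["edge"]
                == f"{flat.node_keys()[ev.parent]}->{flat.node_keys()[ev.child]}"
            )
            events_table.loc[mask, "clade"] = cl.name
    if richness is None:
        complete = False

    return OriginSummary(
        per_tree_gains=gains,
        per_tree_losses=losses,
        minimum=min(gains),
        mode=mode,
        median=float(np.median(gains)),
        interval95=(int(lo), int(hi)),
        mechanism_tallies=tallies,
        species_by_mechanism=species,
        species_tally_complete=complete,
        reference_tree=ref,
        events_table=events_table,
    )


def threshold_sweep(
    asr: ASRResult, traits: TraitTable, thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 0.95)
) -> pd.DataFrame:
    """Sensitivity of the modal/min gain count to the binarization cutoff."""
    rows = []
    for th in thresholds:
        per_tree = events_from_asr(asr, traits, threshold=th)
        gains = [sum(e.direction == "gain" for e in evs) for evs in per_tree]
        counts = Counter(gains)
        top = max(counts.values())
        rows.append(
            {
                "threshold": th,
                "min_gains": min(gains),
                "modal_gains": min(k for k, v in counts.items() if v == top),
                "median_gains": float(np.median(gains)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------- stochastic-mapping cross-check
def expected_gains_stochastic_map(
    tree: "TimeTree | FlatTree",
    traits: TraitTable,
    params: MkParams,
    root: "RootPrior | str" = "uniform",
    n_maps: int = 100,
    seed: int = 0,
) -> float:
    """Expected number of gains from sampled full character histories.

    Samples joint node states from the conditional distribution (backward
    pass over the pruning partials), then draws the within-branch history by
    endpoint-conditioned CTMC simulation (uniformization) and counts 0->1
    jumps.  Off by default in the pipeline; a cross-check on edge-based counts.
    """
    flat = tree.flat if isinstance(tree, TimeTree) else tree
    rng = np.random.default_rng(seed)
    tipcond = tip_partials(flat, traits)
    prior = resolve_root_prior(root, params)
    part0, part1, _ = _prune(flat, tipcond, params)
    P00, P01, P10, P11 = _edge_probs(flat, params)
    P = [[P00, P01], [P10, P11]]
    q = [[-params.q01, params.q01], [params.q10, -params.q10]]
    qmax = max(params.q01, params.q10)
    if qmax == 0:
        return 0.0
    # uniformized transition kernel
    R = np.array(
        [
            [1.0 - params.q01 / qmax, params.q01 / qmax],
            [params.q10 / qmax, 1.0 - params.q10 / qmax],
        ]
    )
    part = [(part0[v], part1[v]) for v in range(flat.n_nodes)]
    total_gains = 0
    for _ in range(n_maps):
        states = np.zeros(flat.n_nodes, dtype=np.int8)
        r = flat.root
        w1 = prior.p1 * part[r][1]
        w = prior.p0 * part[r][0] + w1
        states[r] = 1 if rng.random() < (w1 / w if w > 0 else 0.5) else 0
        for v in reversed(range(flat.n_nodes - 1)):
            ps = states[flat.parent[v]]
            w1 = P[ps][1][v] * part[v][1]
            w = P[ps][0][v] * part[v][0] + w1
            states[v] = 1 if rng.random() < (w1 / w if w > 0 else 0.5) else 0
        # endpoint-conditioned jumps per branch via uniformization
        for v in range(flat.n_nodes - 1):
            a = int(states[flat.parent[v]])
            b = int(states[v])
            t = flat.blen[v]
            pab = P[a][b][v]
            if pab <= 0:
                continue
            # sample number of uniformized events N | endpoints
            u = rng.random() * pab
            acc = 0.0
            n = 0
            Rn = np.eye(2)
            pois = math.exp(-qmax * t)
            while True:
                acc += pois * Rn[a, b]
                if acc >= u or n > 10_000:
                    break
                n += 1
                pois *= qmax * t / n
                Rn = Rn @ R
            # sample the uniformized path of length n conditioned on endpoints
            cur = a
            for k in range(n, 0, -1):
                # P(next = s | reach b in k-1 more steps)
                Rk1 = np.linalg.matrix_power(R, k - 1)
                w1 = R[cur, 1] * Rk1[1, b]
                w = R[cur, 0] * Rk1[0, b] + w1
                nxt = 1 if rng.random() < (w1 / w if w > 0 else 0.5) else 0
                if cur == 0 and nxt == 1:
                    total_gains += 1
                cur = nxt
    return total_gains / n_maps
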