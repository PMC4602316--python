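"""Log pseudo-likelihood of a network given aggregated triple weights.

The pseudo-likelihood treats the three binary triples of every 3-subset of
taxa as an independent multinomial sample: up to an additive constant that
does not depend on the network or its parameters (the multinomial
coefficient, which is dropped), the log pseudo-likelihood is

    sum over 3-subsets {X,Y,Z}  sum_{i=1..3}  ρ(t_i, G) · ln P(t_i | Ψ, γ),

with ρ the aggregated triple weights and P the exact coalescent triple
probabilities.  Because the constant is dropped, reported values are
comparable only within a fixed gene-tree data set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .coalescent import TripleEngine
from .network import PhyloNetwork
from .triples import TripleTable

__all__ = [
    "PseudoLikelihoodScore",
    "log_pseudo_likelihood",
    "optimize_parameters",
    "OptimizedParameters",
]

LENGTH_BOUNDS = (1e-6, 30.0)
GAMMA_BOUNDS = (1e-6, 1.0 - 1e-6)


@dataclass
class PseudoLikelihoodScore:
    """Total log pseudo-likelihood (natural log, multinomial coefficient
    dropped) and the additive per-3-subset contributions."""

    log_value: float
    contributions: dict = field(repr=False)

    def __float__(self) -> float:
        return self.log_value


def log_pseudo_likelihood(net: PhyloNetwork, table: TripleTable,
                          engine: TripleEngine | None = None) -> PseudoLikelihoodScore:
    """Score a network (with its current branch lengths and inheritance
    probabilities) against a triple table."""
    if not set(table.taxa) <= set(net.taxa):
        missing = sorted(set(table.taxa) - set(net.taxa))
        raise ValueError(f"table taxa {missing} absent from the network")
    if engine is None:
        engine = TripleEngine(net, taxa=table.taxa)
    # read parameters from the network being scored, not from the (possibly
    # shared) engine's reference network: an engine may be reused across
    # parameter variants of one topology with identical edge identifiers
    lengths, gammas = {}, {}
    for u, v, k, data in net.graph.edges(keys=True, data=True):
        lengths[(u, v, k)] = data["length"]
        gammas[(u, v, k)] = data["gamma"]
    return _score(engine, table, lengths, gammas)


def _score(engine: TripleEngine, table: TripleTable, lengths, gammas
           ) -> PseudoLikelihoodScore:
    contributions = {}
    total = 0.0
    for subset in engine.subsets:
        w = table.subset_weights(subset)
        p = engine._run(subset, lengths, gammas)
        c = 0.0
        for wi, pi in zip(w, p):
            if wi == 0.0:
                continue
            if pi <= 0.0:
                c = -math.inf
                break
            c += wi * math.log(pi)
        contributions[subset] = c
        total += c
    return PseudoLikelihoodScore(total, contributions)


@dataclass
class OptimizedParameters:
    """Result of maximizing the pseudo-likelihood over a fixed topology."""

    network: PhyloNetwork
    lengths: dict
    gammas: dict
    score: PseudoLikelihoodScore
    unidentifiable_gammas: list
    n_evaluations: int


def optimize_parameters(topology: PhyloNetwork, table: TripleTable,
                        n_starts: int = 5, seed: int = 0,
                        tol: float = 1e-8, max_evaluations: int = 2000,
                        ) -> OptimizedParameters:
    """Maximize the log pseudo-likelihood over the internal branch lengths
    (log scale, bounded to [1e-6, 30] coalescent units) and inheritance
    probabilities (logit scale, bounded to [1e-6, 1-1e-6]) of a fixed
    topology, by bounded quasi-Newton (L-BFGS-B) with multi-start.

    Pendant branch lengths cannot affect triple probabilities and are left
    untouched.  The returned score is never below the score at the input
    parameters.  Inheritance probabilities whose value has no detectable
    effect on the score are reported in ``unidentifiable_gammas`` (their
    fitted values are arbitrary).
    """
    rng = np.random.default_rng(seed)
    net = topology.copy()
    engine = TripleEngine(net, taxa=table.taxa)
    base_lengths, base_gammas = engine.current_params()
    free_lengths = [e for e in net.internal_edges()]
    free_gammas = [net.reticulation_edges(h)[0] for h in _sorted_nodes(net.reticulations)]
    partner = {}
    for e in free_gammas:
        e1, e2 = net.reticulation_edges(e[1])
        partner[e] = e2 if e == e1 else e1
    nl = len(free_lengths)
    lo_l, hi_l = math.log(LENGTH_BOUNDS[0]), math.log(LENGTH_BOUNDS[1])
    lo_g = math.log(GAMMA_BOUNDS[0] / (1 - GAMMA_BOUNDS[0]))
    hi_g = -lo_g
    bounds = [(lo_l, hi_l)] * nl + [(lo_g, hi_g)] * len(free_gammas)
    n_eval = [0]

    def unpack(x):
        lengths = dict(base_lengths)
        gammas = dict(base_gammas)
        for e, xi in zip(free_lengths, x[:nl]):
            lengths[e] = math.exp(xi)
        for e, xi in zip(free_gammas, x[nl:]):
            gam = 1.0 / (1.0 + math.exp(-xi))
            gammas[e] = gam
            gammas[partner[e]] = 1.0 - gam
        return lengths, gammas

    def negscore(x):
        n_eval[0] += 1
        lengths, gammas = unpack(x)
        s = _score(engine, table, lengths, gammas).log_value
        return 1e12 if s == -math.inf else -s

    def clip(v, lo, hi):
        return min(max(v, lo + 1e-9), hi - 1e-9)

    x0 = np.array(
        [clip(math.log(max(base_lengths[e], LENGTH_BOUNDS[0])), lo_l, hi_l)
         for e in free_lengths] +
        [clip(math.log(base_gammas[e] / max(1 - base_gammas[e], 1e-12))
              if 0 < base_gammas[e] < 1 else 0.0, lo_g, hi_g)
         for e in free_gammas])
    starts = [x0]
    for _ in range(n_starts - 1):
        starts.append(np.concatenate([
            np.clip(rng.normal(0.0, 1.0, size=nl), lo_l + 1e-6, hi_l - 1e-6),
            np.clip(rng.normal(0.0, 1.5, size=len(free_gammas)),
                    lo_g + 1e-6, hi_g - 1e-6)]))

    best_x, best_val = x0, negscore(x0)
    start_val = best_val
    for s in starts:
        res = minimize(negscore, s, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "maxfun": max_evaluations})
        if res.fun < best_val:
            best_x, best_val = res.x, float(res.fun)

    if best_val > start_val:      # non-improvement returns the input
        best_x, best_val = x0, start_val
    lengths, gammas = unpack(best_x)
    for e in free_lengths:
        net.set_length(e, lengths[e])
    for e in free_gammas:
        net.set_gamma(e, gammas[e])

    # flat-likelihood detection for inheritance probabilities
    unident = []
    for i, e in enumerate(free_gammas):
        probe = np.array(best_x, copy=True)
        span = []
        for v in (-1.0, 1.0):
            probe[nl + i] = best_x[nl + i] + v
            span.append(negscore(probe))
        if max(abs(s - best_val) for s in span) < 1e-9:
            unident.append(e)

    score = _score(engine, table, lengths, gammas)
    return OptimizedParameters(
        network=net,
        lengths={e: lengths[e] for e in free_lengths},
        gammas={e: gammas[e] for e in free_gammas},
        score=score,
        unidentifiable_gammas=unident,
        n_evaluations=n_eval[0])


def _sorted_nodes(nodes):
    return sorted(nodes, key=lambda v: (str(type(v)), str(v)))
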