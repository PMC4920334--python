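"""Maximum-likelihood Mk ancestral-state reconstruction on a chronogram.

The Mk model is a continuous-time Markov chain over k unordered states with
a single rate ``q`` of change to EACH alternative state (total leaving rate
``(k-1) q``), giving the closed-form transition probabilities

    P_same(t) = 1/k + (k-1)/k * exp(-k q t)
    P_diff(t) = 1/k -     1/k * exp(-k q t)

Likelihoods are computed by post-order conditional-likelihood propagation
(the pruning algorithm) with per-node rescaling, the rate is fitted by a
bounded one-dimensional search on log10(q), and per-node scaled marginal
likelihoods are obtained by the outside-inside (re-rooting) recursion. The
root prior is uniform (the Mk stationary distribution). Fossil tips
participate exactly like extant tips: they are simply attached at their
occurrence ages by the chronogram, which is what lets deep fossils inform
ancestral habitat at the root.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import ValidationError
from .phylo_io import HabitatMatrix
from .timescale import Chronogram

logger = logging.getLogger(__name__)

LOG10_Q_BOUNDS = (-8.0, 2.0)


@dataclass(frozen=True)
class MkModel:
    """Symmetric k-state Mk model with per-alternative-state rate ``q``
    (per Myr on a chronogram) and a uniform root prior."""

    k: int
    q: float

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("Mk model needs k >= 2 states")
        if self.q < 0:
            raise ValidationError("rate q must be non-negative")

    @property
    def root_prior(self) -> np.ndarray:
        return np.full(self.k, 1.0 / self.k)


def mk_transition(q: float, t: float, k: int = 3) -> np.ndarray:
    """k x k transition-probability matrix of the Mk chain over duration t."""
    if q < 0 or t < 0:
        raise ValidationError("q and t must be non-negative")
    e = np.exp(-k * q * t)
    same = 1.0 / k + (k - 1) / k * e
    diff = 1.0 / k - 1.0 / k * e
    P = np.full((k, k), diff)
    np.fill_diagonal(P, same)
    return P


@dataclass
class MarginalStates:
    """Per-node scaled marginal likelihoods (each vector sums to 1)."""

    states: tuple[str, ...]
    marginals: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, node_label: str) -> np.ndarray:
        return self.marginals[node_label]

    def __iter__(self):
        return iter(self.marginals)


def _tip_partials(chronogram: Chronogram, tip_states: HabitatMatrix,
                  states: Sequence[str]) -> dict[dendropy.Node, np.ndarray]:
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    partials = {}
    for lf in chronogram.dtree.leaf_node_iter():
        name = lf.taxon.label
        if name not in tip_states.states:
            raise ValidationError(f"tip {name!r} missing from the state matrix")
        state = tip_states.states[name]
        if state == "?":  # ambiguous: uninformative partial
            vec = np.ones(k)
        else:
            vec = np.zeros(k)
            vec[index[state]] = 1.0
        partials[lf] = vec
    return partials


def _downpass(chronogram: Chronogram, tip_partials, q: float, k: int):
    """Post-order conditional likelihoods with per-node rescaling.

    Returns (down-partials per node, total log scaling factor).
    """
    down: dict[dendropy.Node, np.ndarray] = {}
    log_scale = 0.0
    for node in chronogram.dtree.postorder_node_iter():
        if node.is_leaf():
            down[node] = tip_partials[node]
            continue
        vec = np.ones(k)
        for child in node.child_nodes():
            P = mk_transition(q, child.edge.length or 0.0, k)
            vec = vec * (P @ down[child])
        s = vec.max()
        if s <= 0:
            # impossible data under q == 0; keep a floor so logs stay finite
            down[node] = vec
            continue
        down[node] = vec / s
        log_scale += np.log(s)
    return down, log_scale


def mk_loglik(chronogram: Chronogram, tip_states: HabitatMatrix, q: float,
              states: Sequence[str] | None = None) -> float:
    """Log-likelihood of the tip states under Mk(q), by pruning.

    For ``q == 0`` this is ``log(1/k)`` when all tips share one state and
    ``-inf`` otherwise.
    """
    states = tuple(states or tip_states.alphabet)
    k = len(states)
    tips = _tip_partials(chronogram, tip_states, states)
    down, log_scale = _downpass(chronogram, tips, q, k)
    root = chronogram.dtree.seed_node
    lik = float(np.mean(down[root]))  # uniform prior: (1/k) * sum
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + log_scale)


def fit_mk(chronogram: Chronogram, tip_states: HabitatMatrix,
           states: Sequence[str] | None = None,
           log10_bounds: tuple[float, float] = LOG10_Q_BOUNDS,
           rel_tol: float = 1e-8) -> tuple[float, float]:
    """Maximum-likelihood rate ``(q_hat, lnL)`` by bounded search on log10(q).

    The 1-D Mk likelihood in q is unimodal in practice; no restarts are
    needed. When every tip shares one state the likelihood is maximized at
    the boundary q = 0, which is returned with a warning.
    """
    states = tuple(states or tip_states.alphabet)
    observed = {tip_states.states[t] for t in tip_states.states}
    if len(observed) < 2:
        warnings.warn("all tips share one state; q_hat = 0", stacklevel=2)
        return 0.0, mk_loglik(chronogram, tip_states, 0.0, states)

    def neg(x: float) -> float:
        return -mk_loglik(chronogram, tip_states, 10.0 ** x, states)

    res = minimize_scalar(neg, bounds=log10_bounds, method="bounded",
                          options={"xatol": rel_tol})
    q_hat = float(10.0 ** res.x)
    lnl = -float(res.fun)
    logger.info("fit_mk: q_hat = %.6g /Myr, lnL = %.6f", q_hat, lnl)
    return q_hat, lnl


def marginal_states(chronogram: Chronogram, tip_states: HabitatMatrix,
                    q: float,
                    states: Sequence[str] | None = None) -> MarginalStates:
    """Scaled marginal likelihoods of every node (re-rooting recursion).

    For each node v and state i the unscaled marginal is the likelihood of
    the full data with v fixed in state i; scaling normalizes each node's
    vector to sum to 1. At the root this equals the prior-weighted root
    conditional likelihoods. Because the Mk transition matrix is symmetric,
    the outside (above-node) partials propagate with the same matrices as
    the inside ones.
    """
    states = tuple(states or tip_states.alphabet)
    k = len(states)
    tips = _tip_partials(chronogram, tip_states, states)
    down, _ = _downpass(chronogram, tips, q, k)

    up: dict[dendropy.Node, np.ndarray] = {}
    root = chronogram.dtree.seed_node
    up[root] = np.full(k, 1.0 / k)  # the uniform root prior
    out = MarginalStates(states)
    for node in chronogram.dtree.preorder_node_iter():
        if node is not root:
            parent = node.parent_node
            sib_prod = up[parent].copy()
            for sib in parent.child_nodes():
                if sib is node:
                    continue
                Ps = mk_transition(q, sib.edge.length or 0.0, k)
                sib_prod = sib_prod * (Ps @ down[sib])
            P = mk_transition(q, node.edge.length or 0.0, k)
            vec = P.T @ sib_prod
            s = vec.max()
            up[node] = vec / s if s > 0 else vec
        m = up[node] * down[node]
        total = m.sum()
        if total <= 0:
            raise ValidationError(
                "zero marginal likelihood at a node (impossible data, q = 0?)"
            )
        out.marginals[chronogram.node_label(node)] = m / total
    return out


def root_state_report(marginals: MarginalStates,
                      root_label: str = "n1") -> pd.DataFrame:
    """Root-state probabilities sorted descending (columns state, probability)."""
    vec = np.asarray(marginals[root_label], dtype=float)
    vec = vec / vec.sum()
    df = pd.DataFrame({"state": marginals.states, "probability": vec})
    return df.sort_values("probability", ascending=False,
                          kind="stable").reset_index(drop=True)
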