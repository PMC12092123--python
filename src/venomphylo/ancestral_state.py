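"""Maximum-likelihood ancestral states for a binary trait (Mk model).

Implements the continuous-time Markov model of discrete character
evolution on a calibrated tree: likelihood by Felsenstein's pruning
algorithm, rate estimation by bounded numerical optimization, and marginal
ancestral-state probabilities by the up-down (re-rooting-equivalent)
algorithm.  Supports equal rates (ER, one rate q with
P01(t) = (1 - exp(-2qt))/2) and all-rates-different (ARD, separate 0->1
and 1->0 rates).  Rates are in transitions per Myr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .data_io import CalibratedPhylogeny, normalize_label
from .errors import ConvergenceError, DomainError, VenomPhyloError


class MissingTipStateError(VenomPhyloError):
    def __init__(self, tips):
        self.tips = sorted(tips)
        super().__init__("missing tip states for: " + ", ".join(self.tips))


def transition_matrix(rates, t: float, model: str = "ER") -> np.ndarray:
    """2x2 transition probability matrix over a branch of length t.

    ER takes a single rate q (matrix exponential has the closed form
    P01 = P10 = (1 - exp(-2qt))/2); ARD takes (q01, q10) with stationary
    frequencies (q10, q01)/(q01 + q10).
    """
    if t < 0:
        raise DomainError("branch length must be >= 0")
    if model == "ER":
        q = float(np.atleast_1d(rates)[0])
        if q < 0:
            raise DomainError("rate must be >= 0")
        p01 = 0.5 * (1.0 - np.exp(-2.0 * q * t))
        return np.array([[1.0 - p01, p01], [p01, 1.0 - p01]])
    if model == "ARD":
        q01, q10 = (float(v) for v in rates)
        if q01 < 0 or q10 < 0:
            raise DomainError("rates must be >= 0")
        r = q01 + q10
        if r == 0:
            return np.eye(2)
        pi1 = q01 / r
        pi0 = q10 / r
        decay = np.exp(-r * t)
        return np.array([
            [pi0 + pi1 * decay, pi1 * (1.0 - decay)],
            [pi0 * (1.0 - decay), pi1 + pi0 * decay],
        ])
    raise ValueError(f"unknown model {model!r}")


def equilibrium_frequencies(rates, model: str = "ER") -> np.ndarray:
    if model == "ER":
        return np.array([0.5, 0.5])
    q01, q10 = (float(v) for v in rates)
    r = q01 + q10
    if r == 0:
        return np.array([0.5, 0.5])
    return np.array([q10 / r, q01 / r])


def _normalized_states(tree: CalibratedPhylogeny, tip_states: dict):
    states = {normalize_label(k): int(v) for k, v in tip_states.items()}
    missing = []
    for lab in tree.tip_labels:
        if normalize_label(lab) not in states:
            missing.append(lab)
    if missing:
        raise MissingTipStateError(missing)
    for v in states.values():
        if v not in (0, 1):
            raise DomainError(f"tip states must be 0/1, got {v}")
    return states


def _down_pass(tree, states, rates, model):
    """Partial likelihoods of the data below each node, with log scaling."""
    down = {}
    logscale = 0.0
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            vec = np.zeros(2)
            vec[states[normalize_label(node.taxon.label)]] = 1.0
        else:
            vec = np.ones(2)
            for child in node.child_nodes():
                p = transition_matrix(
                    rates, child.edge.length or 0.0, model
                )
                vec = vec * (p @ down[child])
            peak = vec.max()
            if peak > 0 and peak < 1e-200:
                vec = vec / peak
                logscale += np.log(peak)
        down[node] = vec
    return down, logscale


def mk_loglik(
    tree: CalibratedPhylogeny,
    tip_states: dict,
    rates,
    model: str = "ER",
    root_prior: str = "equilibrium",
) -> float:
    """Log-likelihood of binary tip states under the Mk model.

    Computed by post-order pruning; the root is weighted by equilibrium
    frequencies (or the observed tip-state frequencies when
    ``root_prior="observed"``).
    """
    states = _normalized_states(tree, tip_states)
    down, logscale = _down_pass(tree, states, rates, model)
    pi = _root_prior(states, rates, model, root_prior)
    like = float(pi @ down[tree.tree.seed_node])
    if like <= 0:
        return -np.inf
    return float(np.log(like) + logscale)


def _root_prior(states, rates, model, root_prior):
    if root_prior == "equilibrium":
        return equilibrium_frequencies(rates, model)
    if root_prior == "observed":
        vals = np.array(list(states.values()))
        p1 = vals.mean()
        return np.array([1.0 - p1, p1])
    raise ValueError(f"unknown root prior {root_prior!r}")


@dataclass(frozen=True)
class AncestralEstimate:
    """Fitted rate(s), log-likelihood and per-node marginal probabilities.

    ``node_marginals`` is keyed by internal node id (the node's label when
    present, else ``node<k>`` in preorder); each value is (P(state 0),
    P(state 1)) and sums to one.
    """

    model: str
    rates: tuple[float, ...]
    log_likelihood: float
    node_marginals: dict[str, tuple[float, float]]
    root_id: str


def marginal_probabilities(
    tree: CalibratedPhylogeny,
    tip_states: dict,
    rates,
    model: str = "ER",
    root_prior: str = "equilibrium",
) -> dict[str, tuple[float, float]]:
    """Marginal state probabilities at every internal node.

    Up-down algorithm: combine the partial likelihood of the data below a
    node with the likelihood of everything outside its subtree (equivalent
    to re-rooting at each node in turn).
    """
    states = _normalized_states(tree, tip_states)
    down, _ = _down_pass(tree, states, rates, model)
    pi = _root_prior(states, rates, model, root_prior)

    root = tree.tree.seed_node
    up = {root: pi.copy()}
    marginals = {}
    ids = _node_ids(tree)

    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        # marginal at this node
        m = up[node] * down[node]
        total = m.sum()
        if total <= 0:
            raise DomainError("zero likelihood at a node; check inputs")
        marginals[ids[node]] = (m[0] / total, m[1] / total)
        # propagate outside-likelihoods to children
        children = node.child_nodes()
        child_msgs = []
        for child in children:
            p = transition_matrix(rates, child.edge.length or 0.0, model)
            child_msgs.append(p @ down[child])
        for k, child in enumerate(children):
            outside = up[node].copy()
            for j, msg in enumerate(child_msgs):
                if j != k:
                    outside = outside * msg
            p = transition_matrix(rates, child.edge.length or 0.0, model)
            vec = outside @ p
            peak = vec.max()
            if peak > 0:
                vec = vec / peak  # only ratios matter for marginals
            up[child] = vec
    return marginals


def _node_ids(tree: CalibratedPhylogeny) -> dict:
    ids = {}
    k = 0
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = node.label if node.label else f"node{k}"
        k += 1
    return ids


_RATE_LOWER = 1e-9


def estimate_asr(
    tree: CalibratedPhylogeny,
    tip_states: dict,
    model: str = "ER",
    root_prior: str = "equilibrium",
    rate_upper: float | None = None,
) -> AncestralEstimate:
    """Fit Mk rate(s) by maximum likelihood and reconstruct node states.

    ER uses bounded 1-D optimization of the rate; ARD optimizes both rates
    on log scale from the ER solution.  When all tips share one state the
    rate estimate sits at the lower boundary and every node is
    reconstructed in that state with probability ~1.
    """
    states = _normalized_states(tree, tip_states)
    depth = tree.depth
    upper = rate_upper if rate_upper is not None else 100.0 / max(depth, 1e-9)

    # Optimize on log scale: the likelihood is flat in the rate for large
    # rates, which traps bounded minimizers on the linear scale.
    def neg_er(log_q):
        return -mk_loglik(tree, states, [10.0 ** log_q], "ER", root_prior)

    res = minimize_scalar(
        neg_er, bounds=(np.log10(_RATE_LOWER), np.log10(upper)),
        method="bounded", options={"xatol": 1e-10},
    )
    if not res.success:
        raise ConvergenceError("ER rate optimization failed", best=res)
    er_rate = float(10.0 ** res.x)

    if model == "ER":
        rates = (er_rate,)
        loglik = -float(res.fun)
    elif model == "ARD":
        x0 = np.log([max(er_rate, 1e-6)] * 2)

        def neg_ard(logq):
            return -mk_loglik(tree, states, np.exp(logq), "ARD", root_prior)

        opt = minimize(neg_ard, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10,
                                "maxiter": 2000})
        if not opt.success:
            raise ConvergenceError("ARD rate optimization failed", best=opt)
        rates = tuple(float(v) for v in np.exp(opt.x))
        loglik = -float(opt.fun)
    else:
        raise ValueError(f"unknown model {model!r}")

    marg = marginal_probabilities(tree, states, rates, model, root_prior)
    ids = _node_ids(tree)
    root_id = ids[tree.tree.seed_node]
    return AncestralEstimate(
        model=model,
        rates=rates,
        log_likelihood=loglik,
        node_marginals=marg,
        root_id=root_id,
    )
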