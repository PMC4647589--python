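"""Symmetric two-state Mk model: likelihood, rate estimation, marginal ancestral states.

The model is a continuous-time Markov chain on {0 = absent, 1 = present}
with a single rate ``q`` for both gains and losses (rate matrix
``[[-q, q], [q, -q]]``).  Over a branch of length ``t`` the transition
probabilities have the closed form

    P(stay)   = (1 + exp(-2 q t)) / 2
    P(switch) = (1 - exp(-2 q t)) / 2.

Tree likelihoods use the pruning algorithm (post-order conditional
likelihoods with per-node rescaling, so 200+ tip trees at high rates do not
underflow), the root carries a flat (1/2, 1/2) prior — which for this
symmetric chain is also the stationary distribution — and multifurcations
are handled natively by taking the product over all children.

Marginal ("proportional likelihood") ancestral states at a node are the
full-data likelihoods with that node clamped to each state, normalized to
sum to one, evaluated at the character's global maximum-likelihood rate
without re-optimizing per clamping.  They are computed in one outside-inside
(up-down) pass; this is the quantity classically reported as node pies in
percentage form, and is distinct from joint (max-product) reconstruction.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .tree import CladeDefinition, PhyloTree, TreeError, mrca

__all__ = [
    "MISSING",
    "transition_matrix",
    "MkAncestralReconstruction",
    "MkAncestralResults",
    "AncestralStateTable",
    "CladeReport",
    "tree_log_likelihood",
    "estimate_rate",
    "marginal_node_proportions",
    "paint_branches",
    "clade_report",
    "pooled_rate_mle",
]

MISSING = "?"

DEFAULT_Q_BOUNDS = (1e-8, 1e3)


def transition_matrix(q: float, t: float) -> np.ndarray:
    """2x2 transition probability matrix of the symmetric chain over time t.

    Rows index the starting state, columns the ending state; rows sum to 1
    and the matrix is symmetric.  q = 0 gives the identity; q*t -> infinity
    gives the (1/2, 1/2) stationary matrix.
    """
    if q < 0 or t < 0:
        raise ValueError(f"q and t must be nonnegative (got q={q}, t={t})")
    e = math.exp(-2.0 * q * t)
    stay = 0.5 * (1.0 + e)
    switch = 0.5 * (1.0 - e)
    return np.array([[stay, switch], [switch, stay]])


# -- internal tree indexing ---------------------------------------------------


class _TreeArrays:
    """Flat postorder view of a tree for vectorized pruning."""

    def __init__(self, tree: PhyloTree):
        self.tree = tree
        post = tree.postorder()
        self.post_ids = [n.id for n in post]
        self.nodes = {n.id: n for n in tree.nodes}
        self.children = {n.id: [c.id for c in n.children] for n in tree.nodes}
        self.lengths = {}
        for n in tree.nodes:
            if not n.is_root:
                if n.length is None:
                    raise TreeError(
                        f"node {n.id} has no branch length; call "
                        "set_unit_branch_lengths first"
                    )
                self.lengths[n.id] = float(n.length)
        self.tip_ids = [n.id for n in post if n.is_tip]
        self.tip_label_to_id = {n.label: n.id for n in tree.tips()}
        self.root_id = tree.root.id


def _encode_states(
    arrays: _TreeArrays, tip_states: Mapping[str, object]
) -> np.ndarray:
    """Tip states as an int8 vector indexed like tip order (-1 = missing)."""
    enc = np.empty(len(arrays.tip_ids), dtype=np.int8)
    for j, tid in enumerate(arrays.tip_ids):
        label = arrays.nodes[tid].label
        if label not in tip_states:
            raise TreeError(f"tip {label!r} has no character state")
        s = tip_states[label]
        if s in (0, 1):
            enc[j] = int(s)
        elif s in ("0", "1"):
            enc[j] = int(s)
        elif s == MISSING or s is None:
            enc[j] = -1
        else:
            raise TreeError(f"state for tip {label!r} must be 0, 1 or '?'; got {s!r}")
    return enc


def _down_pass(
    arrays: _TreeArrays, states: np.ndarray, q: float
) -> tuple[dict, dict, np.ndarray]:
    """Post-order conditional likelihoods with per-node rescaling.

    ``states`` has shape (n_chars, n_tips), entries in {-1, 0, 1}.
    Returns (D, M, logscale): D[node_id] is the rescaled conditional
    likelihood array (n_chars, 2); M[node_id] the message that node sends to
    its parent (transition matrix applied, shape (n_chars, 2)); logscale the
    accumulated per-character log of the rescaling factors (-inf where the
    data have probability zero).
    """
    n_chars = states.shape[0]
    tip_col = {tid: j for j, tid in enumerate(arrays.tip_ids)}
    D: dict[int, np.ndarray] = {}
    M: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_chars)
    for nid in arrays.post_ids:
        kids = arrays.children[nid]
        if not kids:
            s = states[:, tip_col[nid]]
            cond = np.ones((n_chars, 2))
            cond[s == 0, 1] = 0.0
            cond[s == 1, 0] = 0.0
        else:
            cond = np.ones((n_chars, 2))
            for c in kids:
                cond = cond * M[c]
            scale = cond.sum(axis=1)
            dead = scale == 0.0
            with np.errstate(divide="ignore", invalid="ignore"):
                cond = np.where(dead[:, None], 0.0, cond / np.where(dead, 1.0, scale)[:, None])
            with np.errstate(divide="ignore"):
                logscale = logscale + np.where(dead, -np.inf, np.log(np.where(dead, 1.0, scale)))
        D[nid] = cond
        if nid != arrays.root_id:
            P = transition_matrix(q, arrays.lengths[nid])
            M[nid] = cond @ P  # symmetric P: message to parent
    return D, M, logscale


def _loglik_from_down(
    D: dict, logscale: np.ndarray, root_id: int, root_prior: np.ndarray
) -> np.ndarray:
    rootmass = D[root_id] @ root_prior
    with np.errstate(divide="ignore"):
        return np.log(rootmass) + logscale


def _up_pass(
    arrays: _TreeArrays, D: dict, M: dict, q: float, root_prior: np.ndarray
) -> dict:
    """Pre-order outside likelihoods U[node_id] (n_chars, 2), renormalized.

    U[v](s) is proportional to the likelihood of all data outside v's
    subtree given state s at v; U at the root is the prior.
    """
    U: dict[int, np.ndarray] = {}
    n_chars = next(iter(D.values())).shape[0]
    U[arrays.root_id] = np.tile(root_prior, (n_chars, 1))
    for nid in reversed(arrays.post_ids):  # preorder
        kids = arrays.children[nid]
        if not kids:
            continue
        for c in kids:
            sib = np.ones((n_chars, 2))
            for b in kids:
                if b != c:
                    sib = sib * M[b]
            parent_part = U[nid] * sib
            P = transition_matrix(q, arrays.lengths[c])
            u = parent_part @ P
            norm = u.sum(axis=1, keepdims=True)
            norm[norm == 0.0] = 1.0
            U[c] = u / norm
    return U


# -- the model / results pair -------------------------------------------------


class MkAncestralReconstruction:
    """Maximum-likelihood model of one binary character on a fixed rooted tree.

    Parameters
    ----------
    tree : PhyloTree
        Rooted tree with branch lengths set (typically all 1).
    tip_states : mapping
        Tip label -> state in {0, 1, '?'}; '?' contributes the uninformative
        conditional likelihood (1, 1).
    root_prior : pair of floats
        Prior over (absent, present) at the root; flat by default, which for
        the symmetric model equals the stationary distribution.
    q_bounds : pair of floats
        Search interval for the transition rate.
    """

    def __init__(
        self,
        tree: PhyloTree,
        tip_states: Mapping[str, object],
        *,
        root_prior: Sequence[float] = (0.5, 0.5),
        q_bounds: tuple[float, float] = DEFAULT_Q_BOUNDS,
    ):
        self.tree = tree
        self._arrays = _TreeArrays(tree)
        self._states = _encode_states(self._arrays, tip_states)[None, :]
        prior = np.asarray(root_prior, dtype=float)
        if prior.shape != (2,) or prior.min() < 0 or not math.isclose(prior.sum(), 1.0):
            raise ValueError("root_prior must be two nonnegative numbers summing to 1")
        self.root_prior = prior
        if not (0 < q_bounds[0] < q_bounds[1]):
            raise ValueError("q_bounds must satisfy 0 < q_min < q_max")
        self.q_bounds = (float(q_bounds[0]), float(q_bounds[1]))
        self.tip_states = dict(tip_states)

    def loglike(self, q: float) -> float:
        """Log-likelihood of the tip data at rate q (−inf if probability 0)."""
        if q < 0:
            raise ValueError("q must be nonnegative")
        D, _, logscale = _down_pass(self._arrays, self._states, q)
        ll = _loglik_from_down(D, logscale, self._arrays.root_id, self.root_prior)
        return float(ll[0])

    def fit(self, *, xatol: float = 1e-9) -> "MkAncestralResults":
        """Maximize the likelihood over q by bounded search on log q."""
        lo, hi = math.log(self.q_bounds[0]), math.log(self.q_bounds[1])
        res = minimize_scalar(
            lambda x: -self.loglike(math.exp(x)),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": xatol},
        )
        if not res.success:
            raise RuntimeError(
                f"rate optimization did not converge (last iterate q="
                f"{math.exp(res.x):.6g}, message: {res.message})"
            )
        q_hat = math.exp(res.x)
        at_bound = None
        if res.x - lo < 1e-6:
            at_bound = "lower"
        elif hi - res.x < 1e-6:
            at_bound = "upper"
        return MkAncestralResults(
            model=self,
            q=q_hat,
            llf=-res.fun,
            converged=bool(res.success),
            at_bound=at_bound,
            nit=int(res.nfev),
        )

    def marginals_at(self, q: float) -> "AncestralStateTable":
        """Marginal (clamp-and-renormalize) state proportions at a fixed q."""
        D, M, logscale = _down_pass(self._arrays, self._states, q)
        U = _up_pass(self._arrays, D, M, q, self.root_prior)
        ll = float(_loglik_from_down(D, logscale, self._arrays.root_id, self.root_prior)[0])
        props: dict[int, tuple[float, float]] = {}
        for nid in self._arrays.post_ids:
            joint = D[nid][0] * U[nid][0]
            total = joint.sum()
            if total == 0.0:
                raise ZeroDivisionError(
                    f"data have zero probability at q={q}; marginals undefined"
                )
            p = joint / total
            props[nid] = (float(p[0]), float(p[1]))
        internal = {n.id for n in self.tree.nodes if not n.is_tip}
        return AncestralStateTable(
            proportions=props, internal_ids=internal, q=q, log_likelihood=ll
        )


@dataclass
class MkAncestralResults:
    """Fit results: the ML rate, its log-likelihood and reconstructions."""

    model: MkAncestralReconstruction
    q: float
    llf: float
    converged: bool
    at_bound: Optional[str]
    nit: int
    _marginals: Optional["AncestralStateTable"] = field(default=None, repr=False)

    @property
    def params(self) -> dict:
        return {"q": self.q}

    def marginal_proportions(self) -> "AncestralStateTable":
        """Node proportions at the fitted rate (cached)."""
        if self._marginals is None:
            self._marginals = self.model.marginals_at(self.q)
        return self._marginals

    def paint_branches(self, threshold: float = 0.50) -> set[int]:
        return paint_branches(self.marginal_proportions(), threshold)

    def summary(self) -> str:
        lines = [
            "Mk (2-state, 1-rate) ancestral state reconstruction",
            "=" * 51,
            f"tips: {self.model.tree.n_tips}    "
            f"log-likelihood: {self.llf:.6f}",
            f"q (gain = loss rate): {self.q:.6g}"
            + (f"   [at {self.at_bound} bound]" if self.at_bound else ""),
            f"converged: {self.converged}  (function evals: {self.nit})",
            "",
            "node   P(absent)  P(present)",
        ]
        table = self.marginal_proportions()
        for nid in sorted(table.internal_ids):
            p0, p1 = table.proportions[nid]
            lines.append(f"{nid:>4}   {p0:9.4f}  {p1:10.4f}")
        return "\n".join(lines)


@dataclass
class AncestralStateTable:
    """Per-node proportional likelihoods of (absent, present).

    ``proportions`` covers every node (tips are degenerate at their observed
    state); ``internal_ids`` identifies the ancestral nodes the report is
    about.  Each pair sums to 1 within 1e-9.
    """

    proportions: dict[int, tuple[float, float]]
    internal_ids: set[int]
    q: float
    log_likelihood: float

    def __post_init__(self) -> None:
        for nid, (p0, p1) in self.proportions.items():
            if not (-1e-9 <= p0 <= 1 + 1e-9 and -1e-9 <= p1 <= 1 + 1e-9):
                raise ValueError(f"proportions out of [0,1] at node {nid}")
            if abs(p0 + p1 - 1.0) > 1e-9:
                raise ValueError(f"proportions at node {nid} do not sum to 1")

    def present(self, node_id: int) -> float:
        return self.proportions[node_id][1]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"node": nid, "p_absent": p0, "p_present": p1,
             "internal": nid in self.internal_ids}
            for nid, (p0, p1) in sorted(self.proportions.items())
        ]
        return pd.DataFrame(rows).set_index("node")

    def to_json(self, **kwargs) -> str:
        payload = {
            "q": self.q,
            "log_likelihood": self.log_likelihood,
            "nodes": {
                str(nid): {"p_absent": p0, "p_present": p1,
                           "internal": nid in self.internal_ids}
                for nid, (p0, p1) in sorted(self.proportions.items())
            },
        }
        return json.dumps(payload, **kwargs)


# -- functional wrappers ------------------------------------------------------


def tree_log_likelihood(
    tree: PhyloTree,
    tip_states: Mapping[str, object],
    q: float,
    *,
    root_prior: Sequence[float] = (0.5, 0.5),
) -> float:
    """Pruning log-likelihood of one binary character at rate q."""
    return MkAncestralReconstruction(
        tree, tip_states, root_prior=root_prior
    ).loglike(q)


def estimate_rate(
    tree: PhyloTree,
    tip_states: Mapping[str, object],
    *,
    q_bounds: tuple[float, float] = DEFAULT_Q_BOUNDS,
    root_prior: Sequence[float] = (0.5, 0.5),
) -> MkAncestralResults:
    """ML estimate of the single transition rate for one character."""
    return MkAncestralReconstruction(
        tree, tip_states, root_prior=root_prior, q_bounds=q_bounds
    ).fit()


def marginal_node_proportions(
    tree: PhyloTree,
    tip_states: Mapping[str, object],
    q: float,
    *,
    root_prior: Sequence[float] = (0.5, 0.5),
) -> AncestralStateTable:
    """Marginal proportions at a fixed (already fitted) rate."""
    return MkAncestralReconstruction(
        tree, tip_states, root_prior=root_prior
    ).marginals_at(q)


def paint_branches(table: AncestralStateTable, threshold: float = 0.50) -> set[int]:
    """Branches (child-node ids) whose 'present' proportion strictly exceeds
    the threshold; a node at exactly the threshold is not painted.  Tip
    branches follow the observed state (their proportions are degenerate)."""
    painted = set()
    for nid, (_, p1) in table.proportions.items():
        if p1 > threshold:
            painted.add(nid)
    return painted


def pooled_rate_mle(
    tree: PhyloTree,
    characters: Sequence[Mapping[str, object]],
    *,
    q_bounds: tuple[float, float] = DEFAULT_Q_BOUNDS,
    root_prior: Sequence[float] = (0.5, 0.5),
) -> float:
    """ML rate shared across many characters on one tree (sum of log-likelihoods).

    Used for parameter-recovery checks, where the pooled estimate is far less
    variable than any single character's.
    """
    arrays = _TreeArrays(tree)
    states = np.stack([_encode_states(arrays, ts) for ts in characters])
    prior = np.asarray(root_prior, dtype=float)

    def neg(x: float) -> float:
        D, _, logscale = _down_pass(arrays, states, math.exp(x))
        ll = _loglik_from_down(D, logscale, arrays.root_id, prior)
        return -float(ll.sum())

    lo, hi = math.log(q_bounds[0]), math.log(q_bounds[1])
    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-9})
    if not res.success:
        raise RuntimeError("pooled rate optimization did not converge")
    return math.exp(res.x)


# -- clade report -------------------------------------------------------------


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0." + "0" * ndigits),
                                           rounding=ROUND_HALF_UP))


class CladeReport:
    """Percent likelihood of 'present' at each named clade's MRCA.

    Rows are compound classes (characters), columns are clades ordered from
    most to least inclusive; a cell is flagged when it strictly exceeds the
    threshold (exact ties are ambiguous, not flagged).
    """

    def __init__(
        self,
        percent: pd.DataFrame,
        threshold: float = 0.50,
        per_character: Optional[dict] = None,
        clade_sizes: Optional[dict] = None,
    ):
        if ((percent.values < -1e-9) | (percent.values > 100 + 1e-9)).any():
            raise ValueError("report cells must be percentages in [0, 100]")
        self.percent = percent
        self.threshold = threshold
        self.per_character = per_character or {}
        self.clade_sizes = clade_sizes or {}

    @property
    def flags(self) -> pd.DataFrame:
        return self.percent > self.threshold * 100.0

    def rounded(self) -> pd.DataFrame:
        return self.percent.map(_round_half_up)

    def to_tsv(self, path_or_buf=None):
        out = self.rounded().copy()
        for col in list(out.columns):
            out[col + "_likely"] = self.flags[col]
        return out.to_csv(path_or_buf, sep="\t")

    @classmethod
    def from_percent_table(cls, percent: pd.DataFrame, threshold: float = 0.50,
                          clade_sizes: Optional[dict] = None) -> "CladeReport":
        return cls(percent, threshold=threshold, clade_sizes=clade_sizes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CladeReport {self.percent.shape[0]} classes x {self.percent.shape[1]} clades>"


def clade_report(
    tree: PhyloTree,
    matrix,
    clades: Sequence[CladeDefinition],
    *,
    threshold: float = 0.50,
    q_bounds: tuple[float, float] = DEFAULT_Q_BOUNDS,
    root_prior: Sequence[float] = (0.5, 0.5),
) -> CladeReport:
    """Fit each character, reconstruct marginals, and report clade MRCAs.

    ``matrix`` is a BinaryCharacterMatrix (species x class).  Species must
    match the tree's tips exactly; any mismatch is reported in full.
    """
    tree_tips = set(tree.tip_labels)
    mat_species = set(matrix.species)
    if tree_tips != mat_species:
        missing = sorted(tree_tips - mat_species)
        extra = sorted(mat_species - tree_tips)
        raise TreeError(
            "species/tip mismatch: "
            f"tips without matrix rows: {missing}; rows without tips: {extra}"
        )
    names = [c.name for c in clades]
    if len(set(names)) != len(names):
        raise ValueError("clade names must be unique within a report")
    for c in clades:
        unknown = c.tip_labels - tree_tips
        if unknown:
            raise TreeError(f"clade {c.name!r} references unknown tips: {sorted(unknown)}")
    order = sorted(clades, key=lambda c: -len(c.tip_labels))
    clade_nodes = {c.name: mrca(tree, c.tip_labels).id for c in order}

    percent = pd.DataFrame(index=list(matrix.characters),
                           columns=[c.name for c in order], dtype=float)
    per_character: dict[str, MkAncestralResults] = {}
    for char in matrix.characters:
        states = matrix.column(char)
        res = estimate_rate(tree, states, q_bounds=q_bounds, root_prior=root_prior)
        per_character[char] = res
        table = res.marginal_proportions()
        for cname, nid in clade_nodes.items():
            percent.loc[char, cname] = 100.0 * table.present(nid)
    return CladeReport(
        percent,
        threshold=threshold,
        per_character=per_character,
        clade_sizes={c.name: len(c.tip_labels) for c in order},
    )
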