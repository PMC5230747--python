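"""Structure discovery on the transistor wiring graph.

The circuit "connectome" is expressed as six binary relations over
transistors, one per ordered terminal pair (gate, c1, c2): transistor i is
related to transistor j under relation A->B when terminal A of i and
terminal B of j attach to the same wire.  Power and ground rails are
excluded from relation construction — they touch nearly every device and
would swamp the signal topology.

A simplified stochastic block model is fit jointly to the six relations: one
shared cluster assignment over transistors, a fixed number of clusters K,
independent Bernoulli edge probabilities per (relation, block pair) with
Beta(1, 1) priors, and a symmetric Dirichlet(1) prior on cluster sizes.
Inference is collapsed Gibbs sampling over node labels; the best-posterior
sample visited is returned, so the reported log posterior never falls below
the initialization's.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import betaln, gammaln

from .netlist import Netlist

__all__ = [
    "RelationGraphs",
    "BlockAssignment",
    "RELATION_NAMES",
    "build_relations",
    "sbm_fit",
    "log_posterior",
]

RELATION_NAMES = ("g_c1", "g_c2", "c1_c2", "c2_c1", "c1_g", "c2_g")
_TERMINAL_PAIRS = (
    ("gate", "c1"),
    ("gate", "c2"),
    ("c1", "c2"),
    ("c2", "c1"),
    ("c1", "gate"),
    ("c2", "gate"),
)


@dataclass
class RelationGraphs:
    """Six binary adjacency matrices over transistors, shared node order."""

    matrices: dict[str, np.ndarray]
    node_ids: tuple[int, ...]
    distances: np.ndarray | None = None  # pairwise layout distances (um)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def stacked(self) -> np.ndarray:
        return np.stack([self.matrices[name] for name in RELATION_NAMES])

    def to_triplet_frame(self):
        import pandas as pd

        rows = []
        for name in RELATION_NAMES:
            r, c = np.nonzero(self.matrices[name])
            for i, j in zip(r, c):
                rows.append({"relation": name,
                             "source": self.node_ids[i],
                             "target": self.node_ids[j]})
        return pd.DataFrame(rows, columns=["relation", "source", "target"])


def build_relations(netlist: Netlist) -> RelationGraphs:
    """Wire-sharing relations between transistor terminals.

    Edge (i, j) exists in relation A->B iff terminal A of transistor i and
    terminal B of transistor j share a wire that is neither the power nor the
    ground rail.  Self-pairs are excluded.
    """
    netlist.validate()
    rails = {netlist.power_id, netlist.ground_id}
    trans = netlist.transistors
    n = len(trans)
    ids = tuple(t.id for t in trans)
    terminal = {
        "gate": np.array([t.gate for t in trans]),
        "c1": np.array([t.c1 for t in trans]),
        "c2": np.array([t.c2 for t in trans]),
    }
    matrices = {}
    for name, (a, b) in zip(RELATION_NAMES, _TERMINAL_PAIRS):
        wa = terminal[a]
        wb = terminal[b]
        mat = (wa[:, None] == wb[None, :])
        mat &= ~np.isin(wa, list(rails))[:, None]
        np.fill_diagonal(mat, False)
        matrices[name] = mat.astype(np.uint8)
    pos = netlist.positions()
    if len(pos):
        diff = pos[:, None, :] - pos[None, :, :]
        distances = np.sqrt((diff ** 2).sum(axis=2))
    else:
        distances = None
    return RelationGraphs(matrices=matrices, node_ids=ids, distances=distances)


@dataclass
class BlockAssignment:
    """Shared node-to-cluster labels plus per-relation block probabilities."""

    labels: np.ndarray  # (n,) ints in [0, K)
    K: int
    edge_probabilities: dict[str, np.ndarray]  # relation -> (K, K) means
    log_posterior: float
    log_posterior_trace: list[float] = field(default_factory=list)
    node_ids: tuple[int, ...] | None = None

    def to_frame(self):
        import pandas as pd

        ids = self.node_ids or tuple(range(len(self.labels)))
        return pd.DataFrame({"node": ids, "cluster": self.labels})


def _block_counts(stack: np.ndarray, labels: np.ndarray, K: int):
    """Edge and dyad counts per (relation, block, block)."""
    n = labels.shape[0]
    onehot = np.eye(K)[labels]  # (n, K)
    sizes = onehot.sum(axis=0)
    # possible ordered dyads between blocks (self-pairs excluded on diagonal)
    dyads = np.outer(sizes, sizes) - np.diag(sizes)
    edges = np.einsum("rij,ia,jb->rab", stack, onehot, onehot)
    return edges, dyads


def log_posterior(stack: np.ndarray, labels: np.ndarray, K: int) -> float:
    """Collapsed log posterior (up to a constant) of a shared assignment.

    Beta(1,1)-Bernoulli marginal likelihood per (relation, block pair) plus a
    symmetric Dirichlet(1) label prior.
    """
    edges, dyads = _block_counts(stack, labels, K)
    ll = betaln(edges + 1.0, dyads[None] - edges + 1.0).sum()
    ll -= stack.shape[0] * K * K * betaln(1.0, 1.0)
    sizes = np.bincount(labels, minlength=K)
    prior = gammaln(K * 1.0) - gammaln(labels.shape[0] + K * 1.0) + gammaln(sizes + 1.0).sum() - K * gammaln(1.0)
    return float(ll + prior)


def sbm_fit(relations: RelationGraphs, K: int, seed: int = 0,
            sweeps: int = 20, n_restarts: int = 8,
            init_labels: Sequence[int] | None = None) -> BlockAssignment:
    """Collapsed Gibbs sampling for the shared-assignment Bernoulli SBM.

    Runs ``n_restarts`` independent chains of ``sweeps`` full sweeps each
    (single-site Gibbs can lock into merged/split block configurations when
    the posterior is sharply peaked) and returns the best-posterior
    labelling visited across chains, including each chain's initialization —
    so the returned posterior never falls below the initial one.
    Deterministic for a given seed.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n = relations.n_nodes
    if K > n:
        raise ValueError(f"K={K} exceeds the number of nodes ({n})")
    if n_restarts > 1 and init_labels is None:
        best = None
        for sub in np.random.SeedSequence(seed).spawn(n_restarts):
            cand = sbm_fit(relations, K, seed=int(sub.generate_state(1)[0] % (2**31)),
                           sweeps=sweeps, n_restarts=1)
            if best is None or cand.log_posterior > best.log_posterior:
                best = cand
        return best
    stack = relations.stacked().astype(float)
    rng = np.random.default_rng(seed)
    if init_labels is not None:
        labels = np.asarray(init_labels, dtype=int).copy()
        if labels.shape != (n,) or labels.min() < 0 or labels.max() >= K:
            raise ValueError("invalid initial labels")
    else:
        labels = rng.integers(0, K, size=n)
    best_labels = labels.copy()
    best_lp = log_posterior(stack, labels, K)
    trace = [best_lp]
    # incremental sufficient statistics: per-relation block edge counts and
    # block sizes; a node's move only touches one row and one column
    onehot = np.eye(K)[labels]
    edges = np.einsum("rij,ia,jb->rab", stack, onehot, onehot)
    sizes = np.bincount(labels, minlength=K).astype(float)
    lgamma_prior = gammaln(K * 1.0) - gammaln(n + K * 1.0)

    def full_lp(e, s):
        dyads = np.outer(s, s) - np.diag(s)
        ll = betaln(e + 1.0, dyads[None] - e + 1.0).sum()
        return ll + lgamma_prior + gammaln(s + 1.0).sum()

    for _ in range(sweeps):
        order = rng.permutation(n)
        for i in order:
            k_old = int(labels[i])
            douts = stack[:, i, :] @ onehot  # (R, K): i -> block b edges
            dins = np.einsum("rn,nk->rk", stack[:, :, i], onehot)
            # remove node i from its block
            edges[:, k_old, :] -= douts
            edges[:, :, k_old] -= dins
            sizes[k_old] -= 1
            onehot[i] = 0.0
            scores = np.empty(K)
            for k in range(K):
                e = edges.copy()
                e[:, k, :] += douts
                e[:, :, k] += dins
                s = sizes.copy()
                s[k] += 1
                scores[k] = full_lp(e, s)
            probs = np.exp(scores - scores.max())
            probs /= probs.sum()
            k_new = int(rng.choice(K, p=probs))
            labels[i] = k_new
            edges[:, k_new, :] += douts
            edges[:, :, k_new] += dins
            sizes[k_new] += 1
            onehot[i, k_new] = 1.0
            if scores[k_new] > best_lp:
                best_lp = scores[k_new]
                best_labels = labels.copy()
        trace.append(log_posterior(stack, labels, K))
    edges, dyads = _block_counts(relations.stacked().astype(float), best_labels, K)
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = {
            name: np.where(dyads > 0, edges[r] / np.maximum(dyads, 1), 0.0)
            for r, name in enumerate(RELATION_NAMES)
        }
    return BlockAssignment(
        labels=best_labels,
        K=K,
        edge_probabilities=probs,
        log_posterior=best_lp,
        log_posterior_trace=trace,
        node_ids=relations.node_ids,
    )
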