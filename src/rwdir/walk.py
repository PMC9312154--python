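"""Random walk with dynamic incentive restart (RW-DIR) and its baselines.

The walk is a restart random walk, Pt+1 = alpha * W^T Pt + (1 - alpha) * P0,
over the heterogeneous network, modified each iteration by label-dependent
updates:

* a newly reached *related* vertex is added to the restart vector P0 with
  value 0.1 (then P0 is renormalized) — an incentive that spreads the
  restart mass over the growing set of confirmed disease vertices;
* every reached *irrelevant* vertex has its Pt entry divided by its degree
  each iteration — a penalty that drains probability from vertices known to
  belong elsewhere;
* *unlabeled* vertices are resolved by entropy-guided belief propagation:
  once the walk has covered the graph, each vertex carries a two-label
  belief (m1 = related, m2 = irrelevant), the transition matrix is rebuilt
  every iteration so a walker preferentially moves to high-entropy
  (uncertain) vertices, and beliefs propagate along it with labeled
  vertices clamped.  The final m1 of the unlabeled vertices is the ranking
  score.

`run_trwr` is the traditional restart walk (fixed degree-normalized W, no
label updates); `run_rwdir_no_entropy` keeps incentives and penalties but
never allocates beliefs, ranking by the stationary Pt instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .hetnet import (
    BlockAdjacency,
    HeteroNetwork,
    Label,
    LabelAssignment,
    build_adjacency,
)
from .transition import TransitionMatrix, block_transition_matrix, transfer_parameters

logger = logging.getLogger(__name__)

__all__ = [
    "WalkConfig",
    "WalkState",
    "BeliefState",
    "RankedResult",
    "TRWRResult",
    "StartError",
    "rwr_step",
    "run_trwr",
    "init_walk",
    "detect_newly_visited",
    "apply_incentive",
    "apply_penalty",
    "init_beliefs",
    "entropy",
    "entropy_transition_update",
    "propagate_beliefs",
    "run_rwdir",
    "run_rwdir_no_entropy",
    "run_trwr_on_network",
]

#: restart weight given to each related vertex in the traditional walk's P0
TRWR_RESTART_VALUE = 0.1
#: incentive weight a newly reached related vertex receives in P0
INCENTIVE_VALUE = 0.1


class StartError(ValueError):
    """The walk cannot start (no related vertex to seed from)."""


@dataclass(frozen=True)
class WalkConfig:
    """Run configuration.

    alpha is the probability of following W rather than restarting (the
    conventional restart-walk value 0.85 by default); tol is the L1
    convergence threshold on Pt; visit_eps is the minimum Pt change that
    counts as "walked to" (guards float noise only); stagnation_window is
    the number of consecutive iterations without a new visit after which
    coverage is declared for graphs the walk cannot fully reach.
    """

    alpha: float = 0.85
    tol: float = 1e-6
    max_iter: int = 1000
    visit_eps: float = 1e-12
    seed: int = 0
    stagnation_window: int = 5
    check_invariants: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass
class WalkState:
    """Mutable walk state: restart vector, current distribution, visit set."""

    P0: np.ndarray
    Pt: np.ndarray
    visited: set[int]
    t: int = 0
    alpha: float = 0.85
    global_coverage_reached: bool = False


@dataclass
class BeliefState:
    """Per-vertex two-label beliefs; m1 + m2 = 1 elementwise."""

    m1: np.ndarray
    m2: np.ndarray


class TRWRResult(NamedTuple):
    pt: np.ndarray
    iterations: int
    converged: bool


@dataclass(frozen=True)
class RankedResult:
    """Final ranking over the unlabeled vertices.

    ``scores`` maps unlabeled vertex id to its ranking score (final m1 for
    RW-DIR, stationary Pt for the baselines); ``ranking`` is score-descending
    with deterministic tie-breaks (final Pt descending, then canonical
    index).
    """

    scores: dict[str, float]
    ranking: tuple[str, ...]
    iterations_run: int
    converged: bool
    params_used: dict
    algorithm: str
    final_pt: dict[str, float]
    final_m1: dict[str, float] | None = None
    final_p0: dict[str, float] | None = None
    log: tuple[dict, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def rwr_step(
    W: TransitionMatrix | np.ndarray,
    Pt: np.ndarray,
    P0: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """One restart-walk update alpha * W^T Pt + (1 - alpha) * P0.

    W is row-stochastic with rows as sources, so the transpose action moves
    mass from source to destination.
    """
    M = W.W if isinstance(W, TransitionMatrix) else W
    if M.shape[0] != Pt.shape[0] or Pt.shape != P0.shape:
        raise ValueError("dimension mismatch between W, Pt and P0")
    return alpha * (M.T @ Pt) + (1.0 - alpha) * P0


def run_trwr(
    W: TransitionMatrix | np.ndarray,
    P0: np.ndarray,
    alpha: float,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> TRWRResult:
    """Iterate the restart walk from P0 until the L1 change drops below tol.

    The fixed point is (1 - alpha) (I - alpha W^T)^-1 P0; non-convergence
    within ``max_iter`` is flagged and the best iterate returned.
    """
    Pt = P0.copy()
    for t in range(1, max_iter + 1):
        nxt = rwr_step(W, Pt, P0, alpha)
        delta = float(np.abs(nxt - Pt).sum())
        Pt = nxt
        if delta < tol:
            return TRWRResult(Pt, t, True)
    warnings.warn(f"restart walk did not converge in {max_iter} iterations", stacklevel=2)
    return TRWRResult(Pt, max_iter, False)


def init_walk(
    net: HeteroNetwork,
    labels: Sequence[Label],
    alpha: float,
) -> WalkState:
    """Seed the walk at the maximum-degree related vertex.

    Ties on degree break toward the lowest canonical index.  The seed is the
    sole support of both P0 and Pt.
    """
    h = net.h
    adj = build_adjacency(net)
    deg = adj.degrees()
    related = [i for i, lab in enumerate(labels) if lab is Label.RELATED]
    if not related:
        raise StartError("no related vertex to seed the walk from")
    seed = max(related, key=lambda i: (deg[i], -i))
    P0 = np.zeros(h)
    P0[seed] = 1.0
    return WalkState(P0=P0, Pt=P0.copy(), visited={seed}, t=0, alpha=alpha)


def detect_newly_visited(
    Pt: np.ndarray,
    Pt_prev: np.ndarray,
    visited: set[int],
    visit_eps: float,
) -> set[int]:
    """Indices not yet visited whose Pt entry moved by more than visit_eps."""
    changed = np.nonzero(np.abs(Pt - Pt_prev) > visit_eps)[0]
    return {int(i) for i in changed} - visited


def apply_incentive(state: WalkState, v: int, labels: Sequence[Label]) -> WalkState:
    """Add a newly reached related vertex to P0 with weight 0.1, renormalize.

    Idempotent: a vertex already in P0's support (including the seed) is
    left untouched.
    """
    if labels[v] is not Label.RELATED:
        raise ValueError(f"incentive applied to non-related vertex index {v}")
    if state.P0[v] > 0:
        return state
    state.P0[v] = INCENTIVE_VALUE
    state.P0 /= state.P0.sum()
    return state


def apply_penalty(state: WalkState, v: int, deg: int) -> WalkState:
    """Divide Pt(v) by the vertex degree, then renormalize Pt.

    Applied each iteration to every visited irrelevant vertex; a degree-0
    vertex is skipped with a warning (nothing to divide by).
    """
    if deg == 0:
        warnings.warn(f"penalty skipped for zero-degree vertex index {v}", stacklevel=2)
        return state
    state.Pt[v] /= deg
    state.Pt /= state.Pt.sum()
    return state


def init_beliefs(Pt: np.ndarray, labels: Sequence[Label], h: int) -> BeliefState:
    """Initial beliefs from the Pt visit ranking.

    Unlabeled vertex with rank r (rank 1 = largest Pt, ordinal ties broken
    by canonical index) gets m1 = (h - r) / h; related vertices are clamped
    to (1, 0) and irrelevant ones to (0, 1).
    """
    order = np.lexsort((np.arange(h), -Pt))  # Pt descending, index ascending
    rank = np.empty(h, dtype=float)
    rank[order] = np.arange(1, h + 1)
    m1 = (h - rank) / h
    for i, lab in enumerate(labels):
        if lab is Label.RELATED:
            m1[i] = 1.0
        elif lab is Label.IRRELEVANT:
            m1[i] = 0.0
    return BeliefState(m1=m1, m2=1.0 - m1)


def entropy(beliefs: BeliefState) -> np.ndarray:
    """Two-label Shannon entropy per vertex, in bits; 0*log2(0) := 0."""
    E = np.zeros_like(beliefs.m1)
    for m in (beliefs.m1, beliefs.m2):
        pos = m > 0
        E[pos] -= m[pos] * np.log2(m[pos])
    return E


def entropy_transition_update(adj: BlockAdjacency, E: np.ndarray) -> TransitionMatrix:
    """Transition matrix proportional to destination entropy over N+(v).

    Row v distributes its mass over the closed neighborhood N+(v) =
    neighbors(v) plus v itself, each destination weighted by its entropy;
    if all entropies in N+(v) are zero the row falls back to uniform over
    N+(v).
    """
    Nplus = adj.H.astype(float) + np.eye(adj.h)
    W = Nplus * E[None, :]
    sums = W.sum(axis=1)
    zero = sums == 0
    if np.any(zero):
        W[zero] = Nplus[zero]
        sums[zero] = Nplus[zero].sum(axis=1)
    W = W / sums[:, None]
    return TransitionMatrix(W=W, provenance="entropy")


def propagate_beliefs(
    beliefs: BeliefState,
    W: TransitionMatrix | np.ndarray,
    labels: Sequence[Label],
) -> BeliefState:
    """One round of label-message passing along W.

    Vertex i aggregates messages m_k(j) * W(j, i) from its in-neighbors,
    normalizes over the two labels, and labeled vertices are re-clamped.  A
    vertex receiving no mass keeps its beliefs.
    """
    M = W.W if isinstance(W, TransitionMatrix) else W
    s1 = M.T @ beliefs.m1
    s2 = M.T @ beliefs.m2
    total = s1 + s2
    m1 = beliefs.m1.copy()
    pos = total > 0
    m1[pos] = s1[pos] / total[pos]
    for i, lab in enumerate(labels):
        if lab is Label.RELATED:
            m1[i] = 1.0
        elif lab is Label.IRRELEVANT:
            m1[i] = 0.0
    return BeliefState(m1=m1, m2=1.0 - m1)


# ---------------------------------------------------------------------------
# Full algorithms
# ---------------------------------------------------------------------------


def _reachable_from(adj: BlockAdjacency, seed: int) -> set[int]:
    n_comp, comp = connected_components(csr_matrix(adj.H), directed=False)
    return {int(i) for i in np.nonzero(comp == comp[seed])[0]}


def _rank_unlabeled(
    net: HeteroNetwork,
    labels: Sequence[Label],
    scores: np.ndarray,
    pt: np.ndarray,
) -> tuple[dict[str, float], tuple[str, ...]]:
    ids = net.ids
    unlabeled = [i for i, lab in enumerate(labels) if lab is Label.UNLABELED]
    score_map = {ids[i]: float(scores[i]) for i in unlabeled}
    order = sorted(unlabeled, key=lambda i: (-scores[i], -pt[i], i))
    return score_map, tuple(ids[i] for i in order)


def _assert_invariants(
    state: WalkState,
    beliefs: BeliefState | None,
    labels: Sequence[Label],
) -> None:
    """Conservation checks run after each iteration when configured."""
    assert np.all(state.P0 >= 0) and abs(state.P0.sum() - 1.0) < 1e-9, "P0 not normalized"
    assert np.all(state.Pt >= 0) and abs(state.Pt.sum() - 1.0) < 1e-9, "Pt not normalized"
    if beliefs is not None:
        assert np.allclose(beliefs.m1 + beliefs.m2, 1.0, atol=1e-12), "m1 + m2 != 1"
        E = entropy(beliefs)
        assert np.all(E >= 0.0) and np.all(E <= 1.0 + 1e-12), "entropy outside [0, 1]"
        for i, lab in enumerate(labels):
            if lab is Label.RELATED:
                assert beliefs.m1[i] == 1.0, "related belief unclamped"
            elif lab is Label.IRRELEVANT:
                assert beliefs.m1[i] == 0.0, "irrelevant belief unclamped"


def _run_incentive_walk(
    net: HeteroNetwork,
    labels: LabelAssignment | Sequence[Label],
    config: WalkConfig,
    use_entropy: bool,
) -> RankedResult:
    """Shared driver for RW-DIR and its no-entropy ablation."""
    if isinstance(labels, LabelAssignment):
        resolved = labels.resolve(net)
    else:
        resolved = list(labels)
    h = net.h
    adj = build_adjacency(net)
    deg = adj.degrees()
    params = transfer_parameters(adj)
    W: TransitionMatrix = block_transition_matrix(adj, params)

    state = init_walk(net, resolved, config.alpha)
    seed = next(iter(state.visited))
    reachable = _reachable_from(adj, seed)

    related = [i for i, lab in enumerate(resolved) if lab is Label.RELATED]
    irrelevant = [i for i, lab in enumerate(resolved) if lab is Label.IRRELEVANT]
    has_unlabeled = any(lab is Label.UNLABELED for lab in resolved)
    entropy_active = use_entropy and has_unlabeled

    beliefs: BeliefState | None = None
    stagnant = 0
    converged = False
    log: list[dict] = []

    for t in range(1, config.max_iter + 1):
        state.t = t
        Pt_prev = state.Pt
        state.Pt = rwr_step(W, Pt_prev, state.P0, config.alpha)

        new = detect_newly_visited(state.Pt, Pt_prev, state.visited, config.visit_eps)
        if new:
            state.visited |= new
            stagnant = 0
        else:
            stagnant += 1

        incentives = 0
        for v in sorted(new):
            if resolved[v] is Label.RELATED:
                apply_incentive(state, v, resolved)
                incentives += 1
        for v in irrelevant:
            if v in state.visited and deg[v] > 0:
                apply_penalty(state, v, int(deg[v]))

        if not state.global_coverage_reached and (
            reachable <= state.visited or stagnant >= config.stagnation_window
        ):
            state.global_coverage_reached = True

        if entropy_active and state.global_coverage_reached:
            if beliefs is None:
                beliefs = init_beliefs(state.Pt, resolved, h)
            E = entropy(beliefs)
            W = entropy_transition_update(adj, E)
            beliefs = propagate_beliefs(beliefs, W, resolved)

        if config.check_invariants:
            _assert_invariants(state, beliefs, resolved)

        delta = float(np.abs(state.Pt - Pt_prev).sum())
        log.append(
            {
                "t": t,
                "newly_visited": len(new),
                "incentives": incentives,
                "coverage": state.global_coverage_reached,
                "l1_delta": delta,
            }
        )
        if delta < config.tol and (not entropy_active or beliefs is not None):
            converged = True
            break

    if not converged:
        warnings.warn(
            f"walk did not converge in {config.max_iter} iterations "
            f"(last L1 delta {log[-1]['l1_delta']:.3g})",
            stacklevel=3,
        )
    if entropy_active and beliefs is None:  # pragma: no cover - max_iter pathologies
        beliefs = init_beliefs(state.Pt, resolved, h)

    ids = net.ids
    final_pt = {ids[i]: float(state.Pt[i]) for i in range(h)}
    if use_entropy and beliefs is not None:
        scores, ranking = _rank_unlabeled(net, resolved, beliefs.m1, state.Pt)
        final_m1 = {ids[i]: float(beliefs.m1[i]) for i in range(h)}
    else:
        scores, ranking = _rank_unlabeled(net, resolved, state.Pt, state.Pt)
        final_m1 = None
    return RankedResult(
        scores=scores,
        ranking=ranking,
        iterations_run=state.t,
        converged=converged,
        params_used=asdict(config),
        algorithm="rwdir" if use_entropy else "rwdir-no-entropy",
        final_pt=final_pt,
        final_m1=final_m1,
        final_p0={ids[i]: float(state.P0[i]) for i in range(h)},
        log=tuple(log),
    )


def run_rwdir(
    net: HeteroNetwork,
    labels: LabelAssignment | Sequence[Label],
    config: WalkConfig | None = None,
) -> RankedResult:
    """Full RW-DIR: incentives, penalties and entropy-guided beliefs.

    Unlabeled vertices are ranked by their final m1 (probability of the
    related label).  With no unlabeled vertex the belief machinery is
    vacuous and skipped, so the Pt trajectory coincides with the
    no-entropy variant.
    """
    return _run_incentive_walk(net, labels, config or WalkConfig(), use_entropy=True)


def run_rwdir_no_entropy(
    net: HeteroNetwork,
    labels: LabelAssignment | Sequence[Label],
    config: WalkConfig | None = None,
) -> RankedResult:
    """Ablation: incentives and penalties only; ranking by stationary Pt."""
    return _run_incentive_walk(net, labels, config or WalkConfig(), use_entropy=False)


def run_trwr_on_network(
    net: HeteroNetwork,
    labels: LabelAssignment | Sequence[Label],
    config: WalkConfig | None = None,
) -> RankedResult:
    """Traditional restart walk baseline on the heterogeneous network.

    Every related vertex receives restart weight 0.1 (P0 then normalized,
    i.e. uniform over the related set), W is the plain degree-normalized
    adjacency, and unlabeled vertices are ranked by the stationary Pt.
    """
    from .transition import degree_transition_matrix

    config = config or WalkConfig()
    if isinstance(labels, LabelAssignment):
        resolved = labels.resolve(net)
    else:
        resolved = list(labels)
    adj = build_adjacency(net)
    W = degree_transition_matrix(adj)
    P0 = np.zeros(net.h)
    related = [i for i, lab in enumerate(resolved) if lab is Label.RELATED]
    if not related:
        raise StartError("no related vertex to seed the walk from")
    P0[related] = TRWR_RESTART_VALUE
    P0 /= P0.sum()
    pt, iters, converged = run_trwr(W, P0, config.alpha, config.tol, config.max_iter)
    scores, ranking = _rank_unlabeled(net, resolved, pt, pt)
    ids = net.ids
    return RankedResult(
        scores=scores,
        ranking=ranking,
        iterations_run=iters,
        converged=converged,
        params_used=asdict(config),
        algorithm="trwr",
        final_pt={ids[i]: float(pt[i]) for i in range(net.h)},
        final_m1=None,
    )
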