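"""Transfer parameters and transition matrices for the heterogeneous walk.

Three transfer parameters steer how much transition mass a walker sends
across vertex classes:

    lambda = |mRNA-miRNA|  / (|mRNA-mRNA|  + |miRNA-miRNA|)
    delta  = |mRNA-lncRNA| / (|mRNA-mRNA|  + |lncRNA-lncRNA|)
    theta  = |miRNA-lncRNA|/ (|miRNA-miRNA|+ |lncRNA-lncRNA|)

where |X-Y| is the number of edges between classes X and Y.  The block
transition matrix assembles nine sub-matrices: each cross block is the
row-normalized adjacency block scaled by its transfer parameter, and each
diagonal block is scaled by the remainder (1 minus the row class's two
cross parameters).  The degree-normalized matrix (W = H / deg, ignoring
types) is the baseline used by the traditional restart walk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .hetnet import TYPE_ORDER, BlockAdjacency, RNAType

__all__ = [
    "ParameterError",
    "TransferParams",
    "TransitionMatrix",
    "transfer_parameters",
    "block_transition_matrix",
    "degree_transition_matrix",
    "write_triplets",
]


class ParameterError(ValueError):
    """A transfer-parameter row budget is violated (diagonal weight < 0)."""


# unordered class pair -> attribute name
_CROSS = {
    frozenset((RNAType.MRNA, RNAType.MIRNA)): "lambda_",
    frozenset((RNAType.MRNA, RNAType.LNCRNA)): "delta",
    frozenset((RNAType.MIRNA, RNAType.LNCRNA)): "theta",
}


@dataclass(frozen=True)
class TransferParams:
    """Cross-class transfer fractions (lambda_, delta, theta), each in [0, 1].

    For every class the two cross parameters it participates in must sum to
    at most 1, otherwise its diagonal block weight would go negative.
    """

    lambda_: float
    delta: float
    theta: float

    def __post_init__(self) -> None:
        for name, value in (("lambda", self.lambda_), ("delta", self.delta), ("theta", self.theta)):
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} = {value} outside [0, 1]")
        budgets = {
            "mRNA": self.lambda_ + self.delta,
            "miRNA": self.lambda_ + self.theta,
            "lncRNA": self.delta + self.theta,
        }
        for cls, total in budgets.items():
            if total > 1.0:
                raise ParameterError(
                    f"cross parameters of {cls} sum to {total} > 1; "
                    "diagonal block weight would be negative"
                )

    def cross(self, a: RNAType, b: RNAType) -> float:
        """Transfer parameter for the unordered class pair (a, b), a != b."""
        return getattr(self, _CROSS[frozenset((a, b))])

    def diagonal(self, t: RNAType) -> float:
        """Within-class weight: 1 minus the class's two cross parameters."""
        others = [u for u in TYPE_ORDER if u is not t]
        return 1.0 - self.cross(t, others[0]) - self.cross(t, others[1])

    @classmethod
    def from_block_counts(
        cls, ss: int, mm: int, nn: int, sm: int, sn: int, mn: int
    ) -> "TransferParams":
        """Parameters from the six block edge counts.

        Arguments are the edge counts within mRNA (ss), miRNA (mm), lncRNA
        (nn) and across mRNA-miRNA (sm), mRNA-lncRNA (sn), miRNA-lncRNA (mn).
        A zero denominator yields 0 with a warning: with no within-class
        edges on either side no cross-class preference is inferable.
        """

        def ratio(num: int, den: int, name: str) -> float:
            if den == 0:
                if num:
                    warnings.warn(
                        f"{name}: zero within-class edges on both sides; set to 0",
                        stacklevel=3,
                    )
                return 0.0
            return num / den

        return cls(
            lambda_=ratio(sm, ss + mm, "lambda"),
            delta=ratio(sn, ss + nn, "delta"),
            theta=ratio(mn, mm + nn, "theta"),
        )


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix W in canonical vertex order.

    ``provenance`` records how W was built: block-normalized heterogeneous
    ("block"), plain degree-normalized ("degree") or entropy-derived
    ("entropy").  Rows of zero-degree vertices are all-zero.
    """

    W: np.ndarray
    provenance: str

    @property
    def h(self) -> int:
        return self.W.shape[0]


def transfer_parameters(adj: BlockAdjacency) -> TransferParams:
    """Lambda, delta, theta from the adjacency's block edge counts."""
    c = adj.count
    return TransferParams.from_block_counts(
        ss=c(RNAType.MRNA, RNAType.MRNA),
        mm=c(RNAType.MIRNA, RNAType.MIRNA),
        nn=c(RNAType.LNCRNA, RNAType.LNCRNA),
        sm=c(RNAType.MRNA, RNAType.MIRNA),
        sn=c(RNAType.MRNA, RNAType.LNCRNA),
        mn=c(RNAType.MIRNA, RNAType.LNCRNA),
    )


def block_transition_matrix(adj: BlockAdjacency, params: TransferParams) -> TransitionMatrix:
    """Block-normalized heterogeneous transition matrix.

    For row vertex i of class T and column block U the entry is
    ``X * H(i, j) / sum_k-in-U H(i, k)`` with X the cross parameter for
    (T, U) when T != U and the diagonal remainder when T == U.  A row with
    no edge into some positively-weighted block would otherwise be
    sub-stochastic; that block's mass is redistributed proportionally over
    the row's non-empty blocks by a final row renormalization.  Zero-degree
    rows stay all-zero.
    """
    H = adj.H.astype(float)
    h = adj.h
    W = np.zeros((h, h), dtype=float)
    for t in TYPE_ORDER:
        rows = adj.type_slices[t]
        if rows.stop == rows.start:
            continue
        for u in TYPE_ORDER:
            cols = adj.type_slices[u]
            if cols.stop == cols.start:
                continue
            x = params.diagonal(t) if t is u else params.cross(t, u)
            block = H[rows, cols]
            deg = block.sum(axis=1)
            nz = deg > 0
            out = np.zeros_like(block)
            out[nz] = x * block[nz] / deg[nz, None]
            W[rows, cols] = out
    row_sums = W.sum(axis=1)
    nz = row_sums > 0
    W[nz] = W[nz] / row_sums[nz, None]
    return TransitionMatrix(W=W, provenance="block")


def degree_transition_matrix(adj: BlockAdjacency) -> TransitionMatrix:
    """Plain degree normalization W(i, j) = H(i, j) / deg(i), ignoring classes."""
    H = adj.H.astype(float)
    deg = H.sum(axis=1)
    W = np.zeros_like(H)
    nz = deg > 0
    W[nz] = H[nz] / deg[nz, None]
    return TransitionMatrix(W=W, provenance="degree")


def write_triplets(tm: TransitionMatrix, ids, path) -> None:
    """Plain-text sparse triplet export: row id, column id, value."""
    ids = list(ids)
    with open(path, "w", encoding="utf-8") as fh:
        rows, cols = np.nonzero(tm.W)
        for i, j in zip(rows, cols):
            fh.write(f"{ids[i]}\t{ids[j]}\t{tm.W[i, j]:.12g}\n")
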