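"""Laplacian-regularized label diffusion and confidence z-scores.

For one candidate function, every node carries an initial label
y_i in {+1, -1, 0}: +1 if the node is known to have the function, -1 if it
is known to have some other function (and negatives are enabled), 0 if
there is no evidence either way. The diffused labels f minimize the
quadratic cost

    sum_i (f_i - y_i)^2  +  alpha * sum_{i<j} w_ij (f_i - f_j)^2,

which trades fidelity to the initial labels against smoothness along
strong network edges; its unique minimizer solves the sparse SPD linear
system (I + alpha * L) f = y with combinatorial Laplacian L = D - W.

Because candidate functions differ wildly in label frequency, raw f values
are not comparable across functions. They are therefore normalized to a
z-score over all unlabeled nodes: z_i = (f_i - mean(f)) / sd(f), mean and
population SD taken over the unlabeled (y = 0) nodes only. z measures the
positive deviation from the expected random mean in SD units and lets
functions of different prevalence compete on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .labels import LabelTable
from .match_graph import SimilarityNetwork

__all__ = [
    "LabelVector",
    "DiffusionSolution",
    "ZScoreVector",
    "build_label_vector",
    "laplacian_matrix",
    "diffusion_operator",
    "solve_diffusion",
    "prediction_zscores",
]

ZERO_VARIANCE_TOL = 1e-12


@dataclass
class LabelVector:
    """Initial labels for one function over the network's node order."""

    y: np.ndarray  # entries in {+1, -1, 0}
    function: str
    nodes: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.isin(self.y, (-1.0, 0.0, 1.0)).all():
            raise ValueError("label vector entries must be in {+1, -1, 0}")
        if len(self.y) != len(self.nodes):
            raise ValueError("label vector length != node count")

    @property
    def p(self) -> int:
        """Number of labeled nodes (y != 0)."""
        return int(np.count_nonzero(self.y))

    @property
    def q(self) -> int:
        """Number of unlabeled nodes."""
        return len(self.y) - self.p

    @property
    def unlabeled_mask(self) -> np.ndarray:
        return self.y == 0


@dataclass
class DiffusionSolution:
    """Solved diffusion: f in [-1, 1]^n plus the achieved residual."""

    f: np.ndarray
    alpha: float
    residual: float


@dataclass
class ZScoreVector:
    """Per-unlabeled-node z-scores for one function."""

    z: dict[str, float]
    mu_f: float
    sigma_f: float


def build_label_vector(
    labels: LabelTable,
    function: str,
    network: SimilarityNetwork,
    use_negatives: bool = True,
    withheld: set[str] | frozenset[str] = frozenset(),
) -> LabelVector:
    """Encode one function's evidence as y in {+1, -1, 0}^n.

    The evaluation level is the component count of ``function`` (e.g.
    ``"3.1.1"`` -> level 3). A node is +1 if any of its ECs truncates to
    ``function``; -1 if negatives are enabled and it carries at least one
    complete-at-level EC, none equal to ``function``; 0 otherwise. Partial
    codes at the level are never negative evidence. ``withheld`` nodes
    (test queries) are forced to 0.
    """
    from .ec import ECNumber

    ec = ECNumber.parse(function)  # raises MalformedECError on junk
    level = len(ec.components)
    if not ec.complete_at(level):
        raise ValueError(f"function {function!r} is not complete at level {level}")

    y = np.zeros(network.n_nodes)
    for i, node in enumerate(network.nodes):
        if node in withheld:
            continue
        funcs = labels.node_functions(node, level)
        if function in funcs:
            y[i] = 1.0
        elif funcs and use_negatives:
            y[i] = -1.0
    return LabelVector(y=y, function=function, nodes=list(network.nodes))


def laplacian_matrix(W: sp.csr_array, kind: str = "combinatorial") -> sp.csr_array:
    """Graph Laplacian of a symmetric nonnegative weight matrix.

    ``combinatorial``: L = D - W with D = diag(row sums).
    ``normalized``: L = I - D^{-1/2} W D^{-1/2}, isolated nodes get a zero row.
    """
    degrees = np.asarray(W.sum(axis=1)).ravel()
    if kind == "combinatorial":
        return (sp.diags_array(degrees) - W).tocsr()
    if kind == "normalized":
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(degrees > 0, 1.0 / np.sqrt(np.maximum(degrees, 1e-300)), 0.0)
        Dhalf = sp.diags_array(inv_sqrt)
        eye = sp.diags_array(np.where(degrees > 0, 1.0, 0.0))
        return (eye - Dhalf @ W @ Dhalf).tocsr()
    raise ValueError(f"unknown laplacian kind {kind!r}")


def diffusion_operator(
    network: SimilarityNetwork, alpha: float, laplacian: str = "combinatorial"
):
    """Prefactorized solver for (I + alpha*L) x = b.

    The system matrix does not depend on the label vector, so one
    factorization serves every candidate function on a network.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    W = network.adjacency()
    if W.nnz and not np.isfinite(W.data).all():
        raise ValueError("non-finite edge weights")
    n = network.n_nodes
    A = (sp.eye_array(n) + alpha * laplacian_matrix(W, laplacian)).tocsc()
    if alpha == 0 or n == 0:
        return lambda b: np.asarray(b, dtype=float).copy(), A
    solve = spla.factorized(A)
    return solve, A


def solve_diffusion(
    network: SimilarityNetwork,
    y: LabelVector,
    alpha: float = 1.0,
    laplacian: str = "combinatorial",
    tol: float = 1e-8,
) -> DiffusionSolution:
    """Solve (I + alpha*L) f = y to relative residual <= ``tol``.

    The system matrix is symmetric positive definite for alpha > 0, so the
    direct sparse factorization cannot fail; alpha = 0 returns f = y
    exactly. The achieved residual is verified and reported.
    """
    if list(y.nodes) != list(network.nodes):
        raise ValueError("label vector node order does not match network")
    solve, A = diffusion_operator(network, alpha, laplacian)
    f = solve(y.y)
    ynorm = float(np.linalg.norm(y.y))
    residual = float(np.linalg.norm(A @ f - y.y)) / (ynorm if ynorm > 0 else 1.0)
    if residual > tol:
        raise ArithmeticError(
            f"diffusion solve residual {residual:.3e} exceeds tolerance {tol:.1e}"
        )
    return DiffusionSolution(f=f, alpha=alpha, residual=residual)


def prediction_zscores(solution: DiffusionSolution, y: LabelVector) -> ZScoreVector:
    """Normalize f over the unlabeled nodes to mean 0, population SD 1.

    With fewer than one unlabeled node there is nothing to predict. A
    zero-variance f (no signal reached any unlabeled node, or all received
    the same) yields all-zero z-scores rather than a division blow-up.
    """
    mask = y.unlabeled_mask
    if not mask.any():
        raise ValueError("nothing to predict: zero unlabeled nodes")
    fu = solution.f[mask]
    mu = float(fu.mean())
    sigma = float(fu.std())  # population SD
    names = [n for n, m in zip(y.nodes, mask) if m]
    if sigma < ZERO_VARIANCE_TOL:
        return ZScoreVector(z={n: 0.0 for n in names}, mu_f=mu, sigma_f=sigma)
    z = (fu - mu) / sigma
    return ZScoreVector(z=dict(zip(names, z.tolist())), mu_f=mu, sigma_f=sigma)
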