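"""Contiguity graphs, CAR precision matrices and Gaussian Markov random fields.

Municipalities are nodes of an undirected contiguity graph with 0/1
adjacency W.  Every spatial prior in the package is built from W:

* the intrinsic CAR (ICAR) precision ``Q = tau * (D - W)`` used for the
  structured random effect of the BYM model (improper; handled by a
  sum-to-zero constraint per connected component),
* the proper CAR precision ``Q = tau * (D - alpha * W)`` with propriety
  parameter ``0 <= alpha < 1`` used wherever a proper Gaussian prior is
  required (the latent confounder of the neighbourhood-adjustment model),
* the row-stochastic neighbourhood smoother ``S = D^-1 W`` (iterated
  ``order`` times) that carries the exposure's neighbourhood average into
  the confounder's conditional mean.

Isolated areas (degree 0, e.g. island municipalities) get identity rows in
the smoother, a zero structured effect under the ICAR, and a unit diagonal
entry in the proper CAR precision so it stays positive definite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .exceptions import ContractError, InputError, ParameterError

__all__ = [
    "AreaGraph",
    "CarStructure",
    "SmootherMatrix",
    "build_graph",
    "read_edge_list",
    "icar_precision",
    "proper_car_precision",
    "neighbourhood_smoother",
    "sample_gmrf",
    "moran_i",
]


@dataclass(frozen=True)
class AreaGraph:
    """An areal contiguity graph over an ordered list of area identifiers.

    Attributes
    ----------
    area_ids
        Ordered area identifiers; every matrix/vector in the package uses
        this ordering (0-based internally).
    W
        Symmetric 0/1 sparse adjacency with zero diagonal (CSR).
    """

    area_ids: tuple[str, ...]
    W: sp.csr_array = field(repr=False)

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.W.sum(axis=1)).ravel()

    @property
    def edges(self) -> set[tuple[str, str]]:
        coo = sp.coo_array(self.W)
        out = set()
        for i, j in zip(coo.row, coo.col):
            if i < j:
                out.add((self.area_ids[i], self.area_ids[j]))
        return out

    @property
    def isolated(self) -> tuple[str, ...]:
        """Area ids with no neighbours (degree 0)."""
        deg = self.degrees
        return tuple(self.area_ids[i] for i in np.flatnonzero(deg == 0))

    @property
    def component_labels(self) -> np.ndarray:
        """Connected-component label per node (isolated nodes are singletons)."""
        _, labels = connected_components(self.W, directed=False)
        return labels

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n_areas else 0

    def index_of(self, area_id: str) -> int:
        try:
            return self.area_ids.index(area_id)
        except ValueError:
            raise InputError(f"unknown area identifier: {area_id!r}") from None


@dataclass(frozen=True)
class CarStructure:
    """A CAR precision matrix Q with its variant and hyperparameters.

    ``variant`` is ``"icar"`` (Q = tau*(D - W), rank-deficient by one per
    connected component) or ``"proper"`` (Q = tau*(D - alpha*W), positive
    definite for alpha in [0, 1)).
    """

    Q: sp.csr_array = field(repr=False)
    variant: str
    tau: float
    alpha: float | None
    graph: AreaGraph = field(repr=False)

    @property
    def n(self) -> int:
        return self.Q.shape[0]


@dataclass(frozen=True)
class SmootherMatrix:
    """Row-stochastic neighbourhood averaging operator S (possibly iterated)."""

    S: sp.csr_array = field(repr=False)
    order: int
    graph: AreaGraph = field(repr=False)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.S @ np.asarray(x, dtype=float)


def build_graph(edge_list: Iterable[tuple[str, str]], area_ids: Sequence[str]) -> AreaGraph:
    """Build an :class:`AreaGraph` from an undirected edge list.

    Duplicate edges (in either orientation) collapse to a single edge.
    Unknown endpoints and self-loops raise :class:`InputError`.
    """
    area_ids = tuple(str(a) for a in area_ids)
    if len(set(area_ids)) != len(area_ids):
        raise InputError("area_ids contains duplicates")
    index = {a: i for i, a in enumerate(area_ids)}
    n = len(area_ids)
    rows: list[int] = []
    cols: list[int] = []
    seen: set[tuple[int, int]] = set()
    for a, b in edge_list:
        a, b = str(a), str(b)
        for endpoint in (a, b):
            if endpoint not in index:
                raise InputError(f"edge endpoint not in area_ids: {endpoint!r}")
        if a == b:
            raise InputError(f"self-loop on area {a!r}")
        i, j = index[a], index[b]
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        rows.extend((key[0], key[1]))
        cols.extend((key[1], key[0]))
    W = sp.csr_array(
        (np.ones(len(rows), dtype=float), (rows, cols)), shape=(n, n)
    )
    return AreaGraph(area_ids=area_ids, W=W)


def read_edge_list(path) -> list[tuple[str, str]]:
    """Read an undirected edge list from a text file.

    Two whitespace- or comma-separated area ids per line; ``#`` starts a
    comment; blank lines are ignored.  Area ids are opaque strings.
    """
    edges: list[tuple[str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise InputError(f"{path}:{lineno}: expected two area ids, got {line!r}")
            edges.append((parts[0], parts[1]))
    return edges


def icar_precision(graph: AreaGraph, tau: float) -> CarStructure:
    """Intrinsic CAR precision Q = tau * (D - W).

    Improper: rank deficiency equals the number of connected components.
    Rows of Q/tau sum to zero exactly (integer arithmetic before scaling).
    """
    if not tau > 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    D = sp.dia_array((graph.degrees, 0), shape=graph.W.shape)
    Q = sp.csr_array(tau * (D - graph.W))
    return CarStructure(Q=Q, variant="icar", tau=float(tau), alpha=None, graph=graph)


def proper_car_precision(graph: AreaGraph, tau: float, alpha: float) -> CarStructure:
    """Proper CAR precision Q = tau * (D - alpha * W), positive definite.

    Isolated nodes receive a unit diagonal entry (an iid effect with
    variance 1/tau) so Q stays positive definite on graphs with islands.
    """
    if not tau > 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    if not (0.0 <= alpha < 1.0):
        raise ParameterError(f"alpha must lie in [0, 1), got {alpha}")
    deg = graph.degrees
    diag = np.where(deg > 0, deg, 1.0)
    D = sp.dia_array((diag, 0), shape=graph.W.shape)
    Q = sp.csr_array(tau * (D - alpha * graph.W))
    return CarStructure(Q=Q, variant="proper", tau=float(tau), alpha=float(alpha), graph=graph)


def neighbourhood_smoother(graph: AreaGraph, order: int = 1) -> SmootherMatrix:
    """Row-normalised adjacency smoother S = D^-1 W, applied ``order`` times.

    Isolated nodes map to themselves (identity rows), so S is always
    row-stochastic and constant fields are preserved exactly.
    """
    if int(order) < 1:
        raise ParameterError(f"order must be >= 1, got {order}")
    order = int(order)
    deg = graph.degrees
    inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
    S1 = sp.csr_array(sp.dia_array((inv, 0), shape=graph.W.shape) @ graph.W)
    if len(graph.isolated):
        iso = np.flatnonzero(deg == 0)
        eye = sp.csr_array(
            (np.ones(iso.size), (iso, iso)), shape=graph.W.shape
        )
        S1 = sp.csr_array(S1 + eye)
    S = S1
    for _ in range(order - 1):
        S = sp.csr_array(S @ S1)
    return SmootherMatrix(S=S, order=order, graph=graph)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_gmrf(
    structure: CarStructure,
    seed=None,
    sum_to_zero: bool = False,
    size: int | None = None,
) -> np.ndarray:
    """Draw from the Gaussian Markov random field defined by ``structure``.

    Proper variant: exact draw from N(0, Q^-1) via Cholesky of Q.
    ICAR variant: draw from the intrinsic field spanned by the non-null
    eigenvectors of Q, which sums to zero within each connected component;
    ``sum_to_zero=True`` is mandatory (the impropriety is handled by
    centering, not jitter).

    Returns shape (n,) or (size, n).  Identical (structure, seed) give
    bit-identical output.
    """
    rng = _as_rng(seed)
    n = structure.n
    m = 1 if size is None else int(size)
    if structure.variant == "icar":
        if not sum_to_zero:
            raise ContractError("icar sampling requires sum_to_zero=True")
        Qd = structure.Q.toarray()
        evals, evecs = np.linalg.eigh(Qd)
        tol = n * np.finfo(float).eps * max(evals.max(), 1.0)
        keep = evals > tol
        z = rng.standard_normal((m, int(keep.sum())))
        x = (evecs[:, keep] / np.sqrt(evals[keep])) @ z.T  # (n, m)
        x = x.T
        # exact per-component centering (numerical cleanup of the null space)
        labels = structure.graph.component_labels
        for c in np.unique(labels):
            idx = labels == c
            x[:, idx] -= x[:, idx].mean(axis=1, keepdims=True)
    else:
        L = sla.cholesky(structure.Q.toarray(), lower=True)
        z = rng.standard_normal((m, n))
        x = sla.solve_triangular(L, z.T, lower=True, trans="T").T
        if sum_to_zero:
            x = x - x.mean(axis=1, keepdims=True)
    return x[0] if size is None else x


def moran_i(graph: AreaGraph, x: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of ``x`` under binary weights W."""
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n_areas,):
        raise InputError(f"x has shape {x.shape}, expected ({graph.n_areas},)")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0.0:
        return 0.0
    s0 = float(graph.W.sum())
    return graph.n_areas / s0 * float(z @ (graph.W @ z)) / denom
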