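"""Compartmental diffusion model of tracer spread through gap junctions.

A fluorescent tracer loaded into a "probe" cell spreads to neighboring cells
through gap junctions. Cells are indexed by their coupling distance x from the
probe cell (x = 0 is the probe, x = 1 its directly coupled neighbors, and so
on); physical distance never enters the model. Within a cell the tracer is
exported at a first-order rate k_out and enters nonspecifically from the bath
at rate k_in from a bath concentration C_solution; between adjacent cells it
moves at a rate D proportional to the concentration difference.

At steady state the excess concentration over the far-field background decays
exponentially with coupling distance,

    C(x) = (C0 - C_bg) * exp(-lambda * x) + C_bg,      lambda = sqrt(k_out / D),

where C_bg = k_in * C_solution / k_out. The coupling strength

    S = exp(-lambda)

is the fraction of probe-cell tracer found one coupling hop away. On a
discrete chain the exact shell-to-shell ratio is the root r of
r**2 - (2 + k_out/D) r + 1 = 0 in (0, 1]; -log(r) converges to the continuum
lambda as k_out/D -> 0. The discrete ratio is exposed here as an internal
oracle for the simulator and estimator tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .errors import InvalidParameterError, NoSteadyBackgroundError

__all__ = [
    "ModelParams",
    "CellLattice",
    "SteadyStateProfile",
    "background_concentration",
    "decay_constant_continuum",
    "decay_ratio_discrete",
    "steady_state_profile",
    "coupling_strength",
]


def background_concentration(k_in: float, C_solution: float, k_out: float) -> float:
    """Far-field background concentration C_bg = k_in * C_solution / k_out.

    Far from any probe cell the inter-cell flux vanishes and influx balances
    efflux, fixing the background level. With no efflux (``k_out == 0``) a
    nonzero influx accumulates without bound and no steady background exists.
    """
    if k_in < 0 or C_solution < 0 or k_out < 0:
        raise InvalidParameterError("k_in, C_solution and k_out must be non-negative")
    influx = k_in * C_solution
    if k_out == 0:
        if influx > 0:
            raise NoSteadyBackgroundError(
                "k_out = 0 with nonzero nonspecific influx: "
                "background concentration grows without bound"
            )
        return 0.0
    return influx / k_out


def decay_constant_continuum(k_out: float, D: float) -> float:
    """Continuum decay constant lambda = sqrt(k_out / D), per coupling hop."""
    if D <= 0:
        raise InvalidParameterError(f"D must be positive, got {D}")
    if k_out < 0:
        raise InvalidParameterError(f"k_out must be non-negative, got {k_out}")
    return math.sqrt(k_out / D)


def decay_ratio_discrete(k_out: float, D: float) -> float:
    """Exact shell-to-shell concentration ratio on an infinite 1D chain.

    The steady-state excess u(x) = C(x) - C_bg on the cell-indexed chain obeys
    u(x+1) - (2 + q) u(x) + u(x-1) = 0 with q = k_out / D, so u(x) = u(0) r**x
    with r the root of r**2 - (2 + q) r + 1 = 0 in (0, 1]. Computed in the
    numerically stable product form r = 2 / (2 + q + sqrt(q (q + 4))), exact
    for small q. -log(r) -> sqrt(q) as q -> 0 (the continuum decay constant).
    """
    if D <= 0:
        raise InvalidParameterError(f"D must be positive, got {D}")
    if k_out < 0:
        raise InvalidParameterError(f"k_out must be non-negative, got {k_out}")
    q = k_out / D
    return 2.0 / (2.0 + q + math.sqrt(q * (q + 4.0)))


def coupling_strength(lam: float) -> float:
    """Coupling strength S = exp(-lambda): the fraction of probe-cell tracer
    found in the directly coupled (one-hop) cells at steady state."""
    if lam < 0:
        raise InvalidParameterError(f"decay constant must be non-negative, got {lam}")
    return math.exp(-lam)


@dataclass(frozen=True)
class ModelParams:
    """Kinetic constants of the compartmental diffusion model.

    Parameters
    ----------
    D :
        Inter-cell diffusion rate constant (per hour, cell-index units).
    k_out :
        First-order tracer efflux rate constant (per hour).
    k_in :
        Nonspecific influx rate constant (per hour).
    C_solution :
        Extracellular (bath) tracer concentration (a.u.).
    C0 :
        Fixed probe-cell concentration (a.u.); Dirichlet loading mode.
    uptake_rate :
        Probe loading rate U (a.u. per hour); first-order-loading mode.

    Exactly one of ``C0`` and ``uptake_rate`` must be given. In fixed-C0 mode
    the probe concentration must exceed the background C_bg, otherwise the
    probe is indistinguishable from an uncoupled cell.
    """

    D: float
    k_out: float
    k_in: float
    C_solution: float
    C0: float | None = None
    uptake_rate: float | None = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise InvalidParameterError(f"D must be positive, got {self.D}")
        if self.k_out < 0 or self.k_in < 0 or self.C_solution < 0:
            raise InvalidParameterError(
                "k_out, k_in and C_solution must be non-negative"
            )
        if (self.C0 is None) == (self.uptake_rate is None):
            raise InvalidParameterError(
                "exactly one of C0 (fixed-concentration mode) and "
                "uptake_rate (loading-rate mode) must be set"
            )
        if self.C0 is not None and self.k_out > 0:
            if self.C0 <= self.C_bg:
                raise InvalidParameterError(
                    f"C0 = {self.C0} must exceed the background "
                    f"C_bg = {self.C_bg}"
                )

    @property
    def fixed_c0(self) -> bool:
        return self.C0 is not None

    @property
    def C_bg(self) -> float:
        """Far-field background concentration implied by the rate constants."""
        return background_concentration(self.k_in, self.C_solution, self.k_out)

    @property
    def lam(self) -> float:
        """Continuum decay constant sqrt(k_out / D)."""
        return decay_constant_continuum(self.k_out, self.D)

    def with_D(self, D: float) -> "ModelParams":
        return ModelParams(D, self.k_out, self.k_in, self.C_solution,
                           self.C0, self.uptake_rate)


@dataclass(frozen=True)
class SteadyStateProfile:
    """Closed-form steady-state concentration profile by coupling distance."""

    x: np.ndarray
    C: np.ndarray
    C0: float
    C_bg: float
    lam: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "C", np.asarray(self.C, dtype=float))
        if self.x.shape != self.C.shape:
            raise InvalidParameterError("x and C must have the same shape")


def steady_state_profile(params: ModelParams, x_values) -> SteadyStateProfile:
    """Evaluate the closed-form steady state C(x) = (C0 - C_bg) e^(-lam x) + C_bg.

    Requires fixed-C0 loading (the closed form is conditioned on the measured
    probe concentration). ``x_values`` are coupling distances in hops and may
    be non-integer when evaluating the continuum curve.
    """
    if not params.fixed_c0:
        raise InvalidParameterError(
            "steady_state_profile requires fixed-C0 loading mode"
        )
    x = np.asarray(x_values, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("coupling distances must be non-negative")
    lam = params.lam
    c_bg = params.C_bg
    C = (params.C0 - c_bg) * np.exp(-lam * x) + c_bg
    return SteadyStateProfile(x=x, C=C, C0=float(params.C0), C_bg=c_bg, lam=lam)


class CellLattice:
    """A lattice of cells with symmetric adjacency and a set of probe cells.

    Supports 1D chains (positions are integer indices), 2D mosaics (positions
    are micrometer coordinates) and arbitrary graphs. ``graph_distance`` gives
    each cell's shortest-path hop count to the nearest probe cell.
    """

    def __init__(self, topology: str, positions: np.ndarray,
                 adjacency: sp.spmatrix, probe_cells) -> None:
        if topology not in ("chain1d", "hex2d", "arbitrary"):
            raise InvalidParameterError(f"unknown topology {topology!r}")
        self.topology = topology
        self.positions = np.asarray(positions, dtype=float)
        adjacency = sp.csr_matrix(adjacency, dtype=float)
        n = self.positions.shape[0]
        if adjacency.shape != (n, n):
            raise InvalidParameterError("adjacency shape must match positions")
        if (adjacency != adjacency.T).nnz != 0:
            raise InvalidParameterError("adjacency must be symmetric")
        if adjacency.diagonal().any():
            raise InvalidParameterError("adjacency must have no self-edges")
        self.adjacency = adjacency
        probes = sorted(int(p) for p in probe_cells)
        if any(p < 0 or p >= n for p in probes):
            raise InvalidParameterError("probe cell index out of range")
        if len(set(probes)) != len(probes):
            raise InvalidParameterError("duplicate probe cell")
        self.probe_cells = tuple(probes)
        self._graph_distance: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def graph_distance(self) -> np.ndarray:
        """Hop count from each cell to its nearest probe cell (inf if unreachable)."""
        if self._graph_distance is None:
            if not self.probe_cells:
                raise InvalidParameterError("lattice has no probe cells")
            d = dijkstra(self.adjacency, unweighted=True, directed=False,
                         indices=list(self.probe_cells), min_only=True)
            self._graph_distance = d
        return self._graph_distance

    def hop_distances_from(self, cell: int) -> np.ndarray:
        """Hop count from every cell to ``cell``."""
        return dijkstra(self.adjacency, unweighted=True, directed=False,
                        indices=cell)

    def neighbors(self, cell: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[cell]:self.adjacency.indptr[cell + 1]
        ]

    def n_components(self) -> int:
        return connected_components(self.adjacency, directed=False,
                                    return_labels=False)

    # ---------------------------------------------------------------- builders

    @classmethod
    def chain(cls, n_cells: int, probe_cells=(0,)) -> "CellLattice":
        """1D chain of ``n_cells`` cells; positions are the cell indices."""
        if n_cells < 2:
            raise InvalidParameterError("chain needs at least 2 cells")
        i = np.arange(n_cells - 1)
        adj = sp.coo_matrix(
            (np.ones(2 * (n_cells - 1)),
             (np.concatenate([i, i + 1]), np.concatenate([i + 1, i]))),
            shape=(n_cells, n_cells),
        )
        return cls("chain1d", np.arange(n_cells, dtype=float), adj, probe_cells)

    @classmethod
    def from_positions(cls, positions: np.ndarray, max_link_dist: float,
                       probe_cells=(), topology: str = "arbitrary") -> "CellLattice":
        """Build adjacency by linking every pair of cells closer than
        ``max_link_dist`` (micrometers)."""
        positions = np.asarray(positions, dtype=float)
        tree = cKDTree(positions)
        pairs = tree.query_pairs(max_link_dist, output_type="ndarray")
        n = positions.shape[0]
        if pairs.size:
            rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
            cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
            adj = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
        else:
            adj = sp.coo_matrix((n, n))
        return cls(topology, positions, adj, probe_cells)

    def with_probes(self, probe_cells) -> "CellLattice":
        return CellLattice(self.topology, self.positions, self.adjacency,
                           probe_cells)
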