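"""Recursive causal structures among traits.

A recursive structural equation model augments a multi-trait mixed model with
a matrix ``Lambda`` of phenotype-to-phenotype causal coefficients: entry
``Lambda[y, x]`` is the direct effect of trait ``x`` on trait ``y``, in units
of y per unit of x.  The structure must be a directed acyclic graph, which
guarantees that ``I - Lambda`` is invertible with determinant one (under a
topological ordering ``Lambda`` is strictly triangular, hence nilpotent).

The canonical trait panel of this package is the four-trait milk panel
(somatic cell score, casein percentage, rennet coagulation time and curd
firmness 30 minutes after rennet addition), but every operation is generic in
the trait set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .exceptions import InputError, StructuralIdentifiabilityError

#: Canonical trait labels, in the fixed order used for all matrix layouts.
DEFAULT_TRAITS = ("SCS", "CAS", "RCT", "a30")

Edge = tuple[str, str]  # (cause x, effect y)


@dataclass(frozen=True)
class TraitSet:
    """An ordered panel of trait names.

    The declared order is fixed for a run and defines the row/column layout of
    every covariance and coefficient matrix downstream.
    """

    labels: tuple[str, ...] = DEFAULT_TRAITS

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise InputError(f"duplicate trait labels: {self.labels}")
        if not self.labels:
            raise InputError("trait set must contain at least one trait")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InputError(
                f"unknown trait {label!r}; declared traits are {self.labels}"
            ) from None


@dataclass(frozen=True)
class CausalStructure:
    """A validated directed acyclic graph among traits.

    ``edges`` are ordered ``(x, y)`` pairs meaning "x causally affects y";
    the associated coefficient is written lambda_yx and sits at row y, column
    x of the structural coefficient matrix.
    """

    traits: TraitSet
    edges: tuple[Edge, ...]
    topological_order: tuple[str, ...] = field(repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def has_edges(self) -> bool:
        return bool(self.edges)

    def edge_labels(self) -> tuple[str, ...]:
        """Human-readable labels like ``'RCT->a30'``, one per edge."""
        return tuple(f"{x}->{y}" for x, y in self.edges)

    def edge_positions(self) -> np.ndarray:
        """(n_edges, 2) array of (row y, col x) positions in Lambda."""
        pos = np.empty((len(self.edges), 2), dtype=int)
        for k, (x, y) in enumerate(self.edges):
            pos[k] = (self.traits.index(y), self.traits.index(x))
        return pos

    def lambda_matrix(self, values: Mapping[Edge, float] | Sequence[float]) -> np.ndarray:
        """Build Lambda from per-edge coefficients (see module function)."""
        return lambda_from_coefficients(self, values)


def make_structure(
    edges: Iterable[Edge], traits: TraitSet | Sequence[str] | None = None
) -> CausalStructure:
    """Validate a set of causal edges and return a :class:`CausalStructure`.

    Parameters
    ----------
    edges
        Ordered ``(x, y)`` trait-name pairs, each meaning "x -> y".
    traits
        Trait panel; defaults to the canonical four-trait milk panel.

    Raises
    ------
    StructuralIdentifiabilityError
        If the edges contain a cycle (including self-edges); the message names
        the offending cycle.
    InputError
        If an edge endpoint is not a declared trait or an edge is duplicated.
    """
    if traits is None:
        traits = TraitSet()
    elif not isinstance(traits, TraitSet):
        traits = TraitSet(tuple(traits))
    edges = tuple((str(x), str(y)) for x, y in edges)
    seen = set()
    for x, y in edges:
        traits.index(x)
        traits.index(y)
        if x == y:
            raise StructuralIdentifiabilityError(f"self-edge {x}->{y} forms a cycle")
        if (x, y) in seen:
            raise InputError(f"duplicate edge {x}->{y}")
        seen.add((x, y))

    graph = nx.DiGraph()
    graph.add_nodes_from(traits.labels)
    graph.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        pretty = " -> ".join([cycle[0][0]] + [v for _, v in cycle])
        raise StructuralIdentifiabilityError(
            f"causal structure contains the cycle {pretty}; only recursive "
            "(acyclic) systems are identifiable"
        )
    topo = tuple(nx.lexicographical_topological_sort(graph))
    return CausalStructure(traits=traits, edges=edges, topological_order=topo)


def lambda_from_coefficients(
    structure: CausalStructure, values: Mapping[Edge, float] | Sequence[float]
) -> np.ndarray:
    """Place per-edge coefficients into the structural matrix Lambda.

    ``values`` is either a mapping keyed exactly by the structure's edges, or
    a sequence aligned with ``structure.edges``.  Entry lambda_yx goes to row
    y, column x; everything else (including the diagonal) is zero.
    """
    n = structure.traits.n
    lam = np.zeros((n, n))
    if isinstance(values, Mapping):
        keys = {(str(x), str(y)) for x, y in values.keys()}
        missing = set(structure.edges) - keys
        extra = keys - set(structure.edges)
        if missing or extra:
            raise InputError(
                f"coefficient map does not match structure edges "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )
        seq = [float(values[edge]) for edge in structure.edges]
    else:
        seq = [float(v) for v in values]
        if len(seq) != structure.n_edges:
            raise InputError(
                f"expected {structure.n_edges} coefficients, got {len(seq)}"
            )
    for (x, y), v in zip(structure.edges, seq):
        lam[structure.traits.index(y), structure.traits.index(x)] = v
    return lam


def identity_minus_lambda_inverse(lam: np.ndarray) -> np.ndarray:
    """Return (I - Lambda)^-1 for an acyclic Lambda.

    For an acyclic structure Lambda is permutation-similar to a strictly
    triangular matrix, so I - Lambda is invertible with unit determinant and
    the inverse equals the finite Neumann series sum_k Lambda^k.
    """
    n = lam.shape[0]
    return np.linalg.inv(np.eye(n) - lam)


#: Named structure presets for the four-trait milk panel.  M0 is the plain
#: multi-trait model (no edges); M1 lets udder health (SCS) and casein act on
#: both coagulation traits; M2 has the single coagulation-time -> curd-firmness
#: edge; M3 lets all three upstream traits act on curd firmness.  M1-SCS and
#: M1-CAS are the single-cause reductions of M1.
PRESETS: dict[str, tuple[Edge, ...]] = {
    "M0": (),
    "M1": (("SCS", "RCT"), ("CAS", "RCT"), ("SCS", "a30"), ("CAS", "a30")),
    "M2": (("RCT", "a30"),),
    "M3": (("SCS", "a30"), ("CAS", "a30"), ("RCT", "a30")),
    "M1-SCS": (("SCS", "RCT"), ("SCS", "a30")),
    "M1-CAS": (("CAS", "RCT"), ("CAS", "a30")),
}


def preset_structure(name: str) -> CausalStructure:
    """Return one of the named preset structures (``M0`` ... ``M1-CAS``)."""
    try:
        edges = PRESETS[name]
    except KeyError:
        raise InputError(
            f"unknown model preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return make_structure(edges)
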