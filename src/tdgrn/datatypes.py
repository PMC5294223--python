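"""Core domain containers.

A :class:`TimeSeriesDataset` holds m genes, each observed in s independent
time series of n time points (e.g. the DREAM4 layout: 100 genes, 10 series
of 21 points).  :class:`EdgeSet` represents a gold-standard labelling of
directed gene pairs, and :class:`Network` an inferred directed, weighted
regulatory network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from ._util import natural_key, natural_sorted
from .exceptions import ValidationError


@dataclass(frozen=True, eq=False)
class TimeSeriesDataset:
    """Expression values for m genes over s series of n time points.

    ``values`` has shape (m, s, n); gene order is the natural identifier
    order and is the canonical iteration order everywhere in the package.
    """

    gene_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        ids = tuple(self.gene_ids)
        object.__setattr__(self, "gene_ids", ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if list(ids).count(g) > 1})
            raise ValidationError(f"duplicate gene identifiers: {dupes}")
        if list(ids) != natural_sorted(ids):
            raise ValidationError("gene_ids must be in natural sorted order")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 3 or vals.shape[0] != len(ids):
            raise ValidationError(
                f"values must have shape (m, s, n); got {vals.shape} for m={len(ids)}"
            )
        if vals.shape[2] < 2:
            raise ValidationError("need at least 2 time points per series (n >= 2)")
        if not np.isfinite(vals).all():
            raise ValidationError("expression values must be finite")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(ids)})

    @classmethod
    def from_profiles(cls, profiles: Mapping[str, np.ndarray]) -> "TimeSeriesDataset":
        """Build from a mapping gene id -> array of shape (s, n) or (n,)."""
        ids = natural_sorted(profiles)
        arrays = []
        shape = None
        for g in ids:
            a = np.atleast_2d(np.asarray(profiles[g], dtype=float))
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise ValidationError(
                    f"gene {g!r} has shape {a.shape}, expected {shape}"
                )
            arrays.append(a)
        if not arrays:
            raise ValidationError("dataset must contain at least one gene")
        return cls(tuple(ids), np.stack(arrays))

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def n_series(self) -> int:
        return self.values.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]

    def profile(self, gene: str) -> np.ndarray:
        """The (s, n) expression matrix of one gene."""
        return self.values[self._index[gene]]

    def __iter__(self) -> Iterator[str]:
        return iter(self.gene_ids)

    def __len__(self) -> int:
        return self.m


@dataclass(eq=False)
class GenePairRecord:
    """One unordered gene pair with both expression profiles.

    ``gene_a`` precedes ``gene_b`` in natural identifier order; a pair file
    contains exactly one record per unordered pair, m(m-1)/2 in total.
    """

    gene_a: str
    gene_b: str
    profiles_a: np.ndarray
    profiles_b: np.ndarray

    def __post_init__(self):
        if natural_key(self.gene_a) >= natural_key(self.gene_b):
            raise ValidationError(
                f"pair ({self.gene_a}, {self.gene_b}) not in identifier order"
            )

    def profiles(self) -> dict:
        return {self.gene_a: self.profiles_a, self.gene_b: self.profiles_b}


@dataclass(frozen=True)
class EdgeSet:
    """Gold-standard labelling of directed pairs.

    ``present`` lists true regulator->target edges; ``absent_listed`` the
    pairs the source file explicitly labelled 0.  Ordered pairs appearing in
    neither set default to absent.
    """

    present: frozenset
    universe: frozenset
    absent_listed: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "present", frozenset(self.present))
        object.__setattr__(self, "absent_listed", frozenset(self.absent_listed))
        endpoints = {g for e in self.present | self.absent_listed for g in e}
        object.__setattr__(self, "universe", frozenset(self.universe) | endpoints)
        for r, t in self.present | self.absent_listed:
            if r == t:
                raise ValidationError(f"self-loop {r}->{t} not allowed")
        clash = self.present & self.absent_listed
        if clash:
            raise ValidationError(f"pairs labelled both present and absent: {sorted(clash)}")

    def label(self, regulator: str, target: str) -> bool:
        """True iff the ordered pair is a gold-present edge."""
        return (regulator, target) in self.present

    @property
    def n_present(self) -> int:
        return len(self.present)


@dataclass(frozen=True)
class Network:
    """Inferred directed regulatory network.

    ``edges`` are (regulator, target, influence weight) sorted by natural
    (regulator, target) order; ``params`` records the thresholds and MI
    estimator settings that produced it (tau, epsilon, max_lag, n_bins,
    binning, log_base).
    """

    edges: tuple
    universe: frozenset
    params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        edges = tuple(
            sorted(
                ((r, t, float(w)) for r, t, w in self.edges),
                key=lambda e: (natural_key(e[0]), natural_key(e[1])),
            )
        )
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "universe", frozenset(self.universe))
        object.__setattr__(self, "params", dict(self.params))
        seen = set()
        for r, t, w in edges:
            if r == t:
                raise ValidationError(f"self-loop {r}->{t} not allowed")
            if (r, t) in seen:
                raise ValidationError(f"duplicate edge {r}->{t}")
            if (t, r) in seen:
                raise ValidationError(f"reciprocal edges between {r} and {t}")
            seen.add((r, t))
        eps = self.params.get("epsilon")
        if eps is not None:
            for r, t, w in edges:
                if not w > eps:
                    raise ValidationError(
                        f"edge {r}->{t} weight {w} does not exceed epsilon={eps}"
                    )
        missing = {g for e in seen for g in e} - self.universe
        if missing:
            raise ValidationError(f"edge endpoints outside universe: {sorted(missing)}")

    def edge_pairs(self) -> frozenset:
        """The predicted-present ordered pairs, without weights."""
        return frozenset((r, t) for r, t, _ in self.edges)

    def weight(self, regulator: str, target: str) -> float:
        for r, t, w in self.edges:
            if (r, t) == (regulator, target):
                return w
        raise KeyError((regulator, target))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(natural_sorted(self.universe))
        g.add_weighted_edges_from(self.edges)
        return g

    def __len__(self) -> int:
        return len(self.edges)
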