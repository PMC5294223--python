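"""Model/Results front end over the inference pipeline.

``GRNInference`` is built from a :class:`~tdgrn.datatypes.TimeSeriesDataset`
(or a DataFrame / file) with the inference thresholds; ``fit()`` executes
the three steps under one of the partitioning algorithms and returns a
``GRNResults`` carrying the inferred network, all influence decisions,
record counts and timings, with ``summary()``, scoring and plotting
attached.

Example
-------
>>> from tdgrn import simulate
>>> data, gold = simulate.simulate(simulate.SimConfig(m=20, seed=7))
>>> res = GRNInference(data).fit()
>>> print(res.summary())                       # doctest: +SKIP
>>> res.score(gold).accuracy                   # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import engine, evaluation, io
from .datatypes import EdgeSet, Network, TimeSeriesDataset


class GRNInference:
    """Directed GRN inference from time-series expression.

    Parameters
    ----------
    dataset
        Expression data: m genes x s series x n time points.
    tau
        Ratio threshold for substantial expression change (default 1.2).
    epsilon
        Influence threshold for edge creation (default 0.96).
    max_lag
        Largest time delay h searched for mutual information (default 3).
    n_bins, binning, log_base
        MI estimator settings (default: 3 equal-frequency bins, bits).
    """

    def __init__(
        self,
        dataset: TimeSeriesDataset,
        tau: float = 1.2,
        epsilon: float = 0.96,
        max_lag: int = 3,
        n_bins: int = 3,
        binning: str = "equal-frequency",
        log_base: float = 2.0,
    ):
        self.dataset = dataset
        self.config = engine.InferenceConfig(
            tau=tau, epsilon=epsilon, max_lag=max_lag,
            n_bins=n_bins, binning=binning, log_base=log_base,
        )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "GRNInference":
        """Rows = genes, columns = time points (single series per gene)."""
        profiles = {str(g): np.asarray(row, dtype=float) for g, row in frame.iterrows()}
        return cls(TimeSeriesDataset.from_profiles(profiles), **kwargs)

    @classmethod
    def from_file(cls, path, dialect: str = "dream4", **kwargs) -> "GRNInference":
        return cls(io.read_timeseries(path, dialect), **kwargs)

    def fit(
        self,
        algorithm: str = "M2",
        n_workers: int = 1,
        n_reducers: int = engine.DEFAULT_N_REDUCERS,
    ) -> "GRNResults":
        result = engine.run(self.dataset, algorithm, self.config, n_workers, n_reducers)
        return GRNResults(self, result)


class GRNResults:
    """Fitted network with diagnostics."""

    def __init__(self, model: GRNInference, run_result: engine.RunResult):
        self.model = model
        self.network: Network = run_result.network
        self.decisions = run_result.decisions
        self.plan = run_result.plan
        self.counts = dict(run_result.counts)
        self.seconds = dict(run_result.seconds)

    @property
    def params(self) -> dict:
        return self.model.config.as_params()

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.network.edges, columns=["regulator", "target", "influence"]
        )

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (d.source, d.target, d.influence, d.present)
                for d in self.decisions
            ],
            columns=["source", "target", "influence", "present"],
        )

    def score(self, gold: EdgeSet, universe=None) -> evaluation.EvalReport:
        shared = universe if universe is not None else (
            frozenset(self.model.dataset.gene_ids) | gold.universe
        )
        return evaluation.score_network(self.network, gold, shared)

    def save(self, path, format: str = "edge-tsv") -> None:
        io.write_network(self.network, path, format)

    def summary(self) -> str:
        d = self.model.dataset
        p = self.params
        lines = [
            "Time-delayed MI network inference",
            "=" * 44,
            f"genes (m):            {d.m}",
            f"series x time points: {d.n_series} x {d.n_timepoints}",
            f"algorithm:            {self.plan.algorithm} "
            f"(workers={self.plan.n_workers}, reducers={self.plan.n_reducers})",
            f"tau / epsilon / h:    {p['tau']} / {p['epsilon']} / {p['max_lag']}",
            f"bins / binning:       {p['n_bins']} / {p['binning']} "
            f"(log base {p['log_base']})",
            "-" * 44,
            f"gene pairs examined:  {self.counts.get('pairs', 0)}",
            f"records to reducers:  {self.counts.get('records_to_reducers', 0)}",
            f"edges inferred:       {len(self.network)}",
            f"wall clock (s):       {self.seconds.get('total', 0.0):.3f}",
        ]
        if len(self.network):
            lines.append("-" * 44)
            lines.append("regulator -> target   influence")
            for r, t, w in self.network.edges[:20]:
                lines.append(f"{r:>9} -> {t:<8} {w:9.4f}")
            if len(self.network) > 20:
                lines.append(f"... and {len(self.network) - 20} more edges")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Draw the inferred network (requires matplotlib)."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        g = self.network.to_networkx()
        pos = nx.circular_layout(g)
        nx.draw_networkx(g, pos=pos, ax=ax, node_size=300, font_size=7, arrows=True)
        ax.set_axis_off()
        return ax
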