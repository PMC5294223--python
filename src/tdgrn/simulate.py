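"""Synthetic benchmark generator: random directed networks and
regulator-driven lagged time series.

The generator emulates the DREAM4 data shape (default 100 genes, 10
independent series of 21 time points) with a known ground-truth network, so
the full inference pipeline can be validated end to end and parameter
recovery can be measured without external downloads.

Mechanics: each gene has a log-normal baseline.  In every series each
*source* gene (no regulators) holds its baseline until a random early time
point, then relaxes with first-order kinetics (geometric approach on the
log scale, rate 0.5 per step) toward a level shifted up or down by the
multiplicative ``effect_size`` — a substantial change, so its ScE is well
defined, with the smooth approach mimicking the mRNA kinetics of
ODE-generated benchmark data.  Each regulated gene tracks the product of
its regulators' realized (noisy) expression, raised to +1 for activation or
-1 for repression, delayed by the edge's lag; every value is finally
multiplied by log-normal noise (sd ``noise_sd`` on the log scale), keeping
all values positive and consistent with the ratio-based change rule.  The
generator deliberately expresses only the model class the inference can
represent: lagged pairwise dependence with at most one direction per
unordered pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import natural_sorted
from .datatypes import EdgeSet, TimeSeriesDataset
from .exceptions import ValidationError


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation settings.

    m, n_series, n_timepoints default to the DREAM4 shape (100, 10, 21).
    ``edge_density`` is the probability that an unordered pair carries a
    (single-direction) true edge.  ``effect_size`` is the multiplicative
    magnitude of a regulatory shift; ``noise_sd`` the standard deviation of
    the log-normal measurement noise on the log scale.
    """

    m: int = 100
    edge_density: float = 0.02
    n_timepoints: int = 21
    n_series: int = 10
    lag_range: tuple = (1, 3)
    effect_size: float = 3.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValidationError("m must be >= 1")
        if not 0 <= self.edge_density < 1:
            raise ValidationError("edge_density must be in [0, 1)")
        if self.n_timepoints < 2 or self.n_series < 1:
            raise ValidationError("need n_timepoints >= 2 and n_series >= 1")
        lo, hi = self.lag_range
        if not 1 <= lo <= hi:
            raise ValidationError("lag_range must satisfy 1 <= lo <= hi")
        if hi >= self.n_timepoints:
            raise ValidationError("lags must be smaller than the series length")
        if not self.effect_size > 1:
            raise ValidationError("effect_size must exceed 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def gene_ids(config: SimConfig) -> list:
    return [f"G{i}" for i in range(1, config.m + 1)]


def sample_network(config: SimConfig) -> EdgeSet:
    """Draw a random DAG-oriented gold standard at the requested density.

    Each unordered pair independently carries an edge with probability
    ``edge_density``; edges are oriented along a random gene permutation,
    which guarantees acyclicity and excludes reciprocal pairs.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 0xA11CE])
    ids = gene_ids(config)
    order = {g: r for r, g in enumerate(rng.permutation(ids))}
    present = set()
    for i in range(config.m):
        for j in range(i + 1, config.m):
            if rng.random() < config.edge_density:
                a, b = ids[i], ids[j]
                if order[a] > order[b]:
                    a, b = b, a
                present.add((a, b))
    return EdgeSet(frozenset(present), frozenset(ids))


def _edge_attributes(network: EdgeSet, config: SimConfig) -> dict:
    """Deterministic per-edge sign and lag, drawn in sorted edge order."""
    rng = np.random.default_rng([config.seed, 0xEDE])
    lo, hi = config.lag_range
    attrs = {}
    for edge in sorted(network.present):
        sign = 1 if rng.random() < 0.5 else -1
        lag = int(rng.integers(lo, hi + 1))
        attrs[edge] = (sign, lag)
    return attrs


def _topological_order(ids, regulators) -> list:
    indeg = {g: len(regulators.get(g, ())) for g in ids}
    ready = [g for g in ids if indeg[g] == 0]
    targets_of = {g: [] for g in ids}
    for tgt, regs in regulators.items():
        for reg, _, _ in regs:
            targets_of[reg].append(tgt)
    order = []
    while ready:
        g = ready.pop()
        order.append(g)
        for tgt in targets_of[g]:
            indeg[tgt] -= 1
            if indeg[tgt] == 0:
                ready.append(tgt)
    if len(order) != len(ids):
        raise ValidationError("regulatory network contains a cycle")
    return order


def simulate_timeseries(network: EdgeSet, config: SimConfig) -> TimeSeriesDataset:
    """Simulate expression driven by a known network; deterministic per seed."""
    ids = natural_sorted(network.universe) if network.universe else gene_ids(config)
    n, s = config.n_timepoints, config.n_series
    attrs = _edge_attributes(network, config)
    for (reg, tgt), (_, lag) in attrs.items():
        if lag >= n:
            raise ValidationError(f"edge {reg}->{tgt} lag {lag} >= n={n}")
    regulators: dict = {}
    for (reg, tgt), (sign, lag) in attrs.items():
        regulators.setdefault(tgt, []).append((reg, sign, lag))
    order = _topological_order(ids, regulators)

    rng = np.random.default_rng([config.seed, 0x5E71E5])
    baselines = {g: float(np.exp(rng.normal(0.0, 0.2))) for g in ids}
    max_lag = config.lag_range[1]
    # early shifts keep most of each series on the response, so the lagged
    # reaction is observable and pre-shift values stay a minority
    t_hi = min(max(2, 2 + n // 4), max(2, n - max_lag - 2))
    shift_times = {g: rng.integers(2, t_hi + 1, size=s) for g in ids}
    shift_dirs = {g: rng.choice([-1.0, 1.0], size=s) for g in ids}
    noise = {
        g: np.exp(rng.normal(0.0, config.noise_sd, size=(s, n)))
        if config.noise_sd > 0
        else np.ones((s, n))
        for g in ids
    }
    rho = 0.5  # per-step log-scale relaxation retention (first-order kinetics)

    realized: dict = {}
    for g in order:
        b = baselines[g]
        latent = np.full((s, n), b)
        regs = regulators.get(g)
        if regs is None:
            log_b = np.log(b)
            for si in range(s):
                t0 = int(shift_times[g][si])
                target = log_b + shift_dirs[g][si] * np.log(config.effect_size)
                cur = log_b
                for t in range(t0 - 1, n):
                    cur = rho * cur + (1.0 - rho) * target
                    latent[si, t] = np.exp(cur)
        else:
            for reg, sign, lag in regs:
                rel = np.ones((s, n))
                rel[:, lag:] = (realized[reg][:, : n - lag] / baselines[reg]) ** sign
                latent = latent * rel
        realized[g] = latent * noise[g]
    return TimeSeriesDataset.from_profiles(realized)


def simulate(config: SimConfig):
    """Convenience: draw a gold-standard network and its time series."""
    network = sample_network(config)
    return simulate_timeseries(network, config), network
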