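"""Step 2: time-delayed mutual information and the influence value.

For an ordered pair (g_x, g_y) and lag k the estimator is the plug-in

    I_k(g_x, g_y) = sum_i p(x_i, y_{i+k}) log[ p(x_i, y_{i+k})
                                               / (p(x_i) p(y_{i+k})) ]

over the lag-aligned overlap window i = 1..n-k within each series (lagged
pairs never span a series boundary).  Joint and marginal probabilities are
empirical frequencies over exactly that window, with joint counts held in a
hash map keyed by symbol pair.  Profiles are discretized once per gene into
B symbols (default B = 3, equal-frequency bins over the gene's pooled
values).  influence(g_x, g_y) = max over k = 1..h of I_k (h default 3);
the MI ceiling is log_base(B), so with B = 3 and base 2 influences live in
[0, 1.585] bits, commensurate with the default edge threshold 0.96.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import ValidationError
from .sce import CaseTag, PairCase

EQUAL_FREQUENCY = "equal-frequency"
EQUAL_WIDTH = "equal-width"


@dataclass(frozen=True)
class MiConfig:
    """MI estimator settings.

    max_lag
        h, the largest lag searched (default 3).
    n_bins
        B, number of discretization symbols (default 3: low/typical/high).
    binning
        'equal-frequency' (B-quantiles of the gene's pooled values, ties to
        the lower bin) or 'equal-width' (uniform partition of [min, max]).
    log_base
        2 for bits (default) or e for nats; recorded in every output.
    """

    max_lag: int = 3
    n_bins: int = 3
    binning: str = EQUAL_FREQUENCY
    log_base: float = 2.0

    def __post_init__(self):
        if self.max_lag < 1:
            raise ValidationError("max_lag must be >= 1")
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        if self.binning not in (EQUAL_FREQUENCY, EQUAL_WIDTH):
            raise ValidationError(f"unknown binning {self.binning!r}")
        if not self.log_base > 1:
            raise ValidationError("log_base must exceed 1")


@dataclass(frozen=True)
class InfluenceRecord:
    """Per-lag MI values and their maximum for one ordered pair."""

    source: str
    target: str
    mi_by_lag: Mapping = field(default_factory=dict)
    influence: float = 0.0
    best_lag: int = 1

    def __post_init__(self):
        object.__setattr__(self, "mi_by_lag", dict(self.mi_by_lag))
        if self.mi_by_lag:
            best = max(self.mi_by_lag.values())
            if not math.isclose(self.influence, best, abs_tol=1e-12):
                raise ValidationError("influence must equal max over lags")


def discretize_profile(values, config: MiConfig = MiConfig()) -> np.ndarray:
    """Map a gene's values to integer symbols in [0, B-1].

    Bin boundaries are computed over the pooled values across all of the
    gene's series (stable symbols across lags); the returned array has the
    input's shape.  Constant profiles map entirely to symbol 0.
    """
    vals = np.asarray(values, dtype=float)
    if not np.isfinite(vals).all():
        raise ValidationError("cannot discretize non-finite values")
    flat = vals.ravel()
    b = config.n_bins
    lo, hi = flat.min(), flat.max()
    if lo == hi:
        return np.zeros(vals.shape, dtype=np.int64)
    if config.binning == EQUAL_FREQUENCY:
        edges = np.quantile(flat, [j / b for j in range(1, b)])
        # side='left': a value equal to an edge falls in the lower bin
        syms = np.searchsorted(edges, vals, side="left")
    else:
        width = (hi - lo) / b
        syms = np.minimum(((vals - lo) / width).astype(np.int64), b - 1)
    return syms.astype(np.int64)


def lagged_samples(x_syms, y_syms, k: int) -> list:
    """All (x_i, y_{i+k}) pairs, series by series.

    Within each series of length n the window is i = 1..n-k; pairs never
    span a series boundary, so the total count is s*(n-k).
    """
    xs = np.atleast_2d(np.asarray(x_syms))
    ys = np.atleast_2d(np.asarray(y_syms))
    if xs.shape != ys.shape:
        raise ValidationError("x and y must share series structure")
    if k < 1:
        raise ValidationError("lag must be >= 1")
    n = xs.shape[1]
    if k >= n:
        return []
    pairs = []
    for xrow, yrow in zip(xs, ys):
        pairs.extend(zip(xrow[: n - k].tolist(), yrow[k:].tolist()))
    return pairs


def time_delayed_mi(x_syms, y_syms, k: int, config: MiConfig = MiConfig()) -> float:
    """Plug-in time-delayed MI at lag k, in units of log_base.

    Marginals are computed over the same lag-aligned overlap as the joint
    (mismatched supports can produce negative plug-in values); tiny negative
    rounding residues are clamped to 0.
    """
    pairs = lagged_samples(x_syms, y_syms, k)
    if not pairs:
        raise ValidationError(
            f"lag {k} leaves no overlapping samples (series too short)"
        )
    joint = Counter(pairs)  # hash map keyed by symbol pair
    n = len(pairs)
    px, py = Counter(), Counter()
    for (a, b), c in joint.items():
        px[a] += c
        py[b] += c
    log = math.log
    base = config.log_base
    mi = 0.0
    for (a, b), c in joint.items():
        mi += (c / n) * log(c * n / (px[a] * py[b]), base)
    return max(mi, 0.0)


def _record_for(
    source: str, target: str, x_prof, y_prof, config: MiConfig
) -> InfluenceRecord:
    x_syms = discretize_profile(x_prof, config)
    y_syms = discretize_profile(y_prof, config)
    n = np.atleast_2d(x_syms).shape[1]
    lags = range(1, min(config.max_lag, n - 1) + 1)
    mi_by_lag = {k: time_delayed_mi(x_syms, y_syms, k, config) for k in lags}
    best_lag = min(lags, key=lambda k: (-mi_by_lag[k], k))
    return InfluenceRecord(source, target, mi_by_lag, mi_by_lag[best_lag], best_lag)


def compute_influence(
    pair_case: PairCase, profiles: Mapping, config: MiConfig = MiConfig()
) -> InfluenceRecord:
    """Reduce a routed pair to a single ordered InfluenceRecord.

    Cases 1/2 evaluate the single forwarded ordering.  Case 3 evaluates
    both orderings and keeps the larger influence; an exact tie keeps the
    ordering whose source precedes its target in identifier order (the
    '>=' tie rule).
    """
    records = [
        _record_for(src, tgt, profiles[src], profiles[tgt], config)
        for src, tgt in pair_case.ordered_pairs
    ]
    if pair_case.case_tag is not CaseTag.CASE3:
        return records[0]
    first, second = records
    return first if first.influence >= second.influence else second
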