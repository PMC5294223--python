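"""Step 1: Substantial Change of Expression (ScE).

A gene g is *induced* at time point t (t > 1) when g(t)/g(1) > tau and
*repressed* when g(t)/g(1) < 1/tau, each series being compared against its
own first time point.  ScE(g) is the earliest within-series time index at
which either happens; a gene whose ratios never leave the band [1/tau, tau]
has no ScE (treated as +infinity when ordering genes).

For a gene pair (g_a, g_b), ordered so that g_a precedes g_b:

* Case 1 (ScE(g_a) < ScE(g_b)): only the ordered pair (g_a, g_b) goes on
  to the influence step — the earlier-changing gene is the candidate
  regulator.
* Case 2 (ScE(g_b) < ScE(g_a)): only (g_b, g_a) goes on.
* Case 3 (equal): both orderings go on, tagged, and the influence step
  keeps the stronger one.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: Sentinel for genes whose expression never leaves the neutral band.
UNDEFINED = None


class Change(enum.Enum):
    INDUCED = "induced"
    REPRESSED = "repressed"
    NEUTRAL = "neutral"


class CaseTag(enum.Enum):
    CASE1 = 1
    CASE2 = 2
    CASE3 = 3


@dataclass(frozen=True)
class SceConfig:
    """Ratio threshold tau > 1 defining substantial change (default 1.2)."""

    tau: float = 1.2

    def __post_init__(self):
        if not (math.isfinite(self.tau) and self.tau > 1):
            raise ValidationError(f"tau must be a finite real > 1, got {self.tau}")


@dataclass(frozen=True)
class SceResult:
    """Induced/repressed time points of one gene and its ScE.

    ``induced`` and ``repressed`` are frozensets of (series, t) with both
    indices 1-based and t in [2, n]; ``induced_timepoints`` /
    ``repressed_timepoints`` give the time-index views.  ``sce`` is the
    minimum t over both sets, or :data:`UNDEFINED`.
    """

    gene: str
    induced: frozenset
    repressed: frozenset
    sce: int | None = field(default=None)

    def __post_init__(self):
        if self.induced & self.repressed:
            raise ValidationError("a time point cannot be both induced and repressed")
        union = {t for _, t in self.induced | self.repressed}
        expected = min(union) if union else UNDEFINED
        if self.sce != expected:
            raise ValidationError(f"sce={self.sce} inconsistent with change sets")

    @property
    def induced_timepoints(self) -> set:
        return {t for _, t in self.induced}

    @property
    def repressed_timepoints(self) -> set:
        return {t for _, t in self.repressed}

    @property
    def sort_key(self) -> float:
        return math.inf if self.sce is UNDEFINED else self.sce


@dataclass(frozen=True)
class PairCase:
    """Routing decision for one unordered pair: the tag and the ordered
    pair(s) forwarded to the influence step (both orderings for Case 3)."""

    case_tag: CaseTag
    ordered_pairs: tuple

    def __post_init__(self):
        both = self.case_tag is CaseTag.CASE3
        if both != (len(self.ordered_pairs) == 2):
            raise ValidationError("CASE3 iff both orderings are carried")


def classify_ratio(g_t: float, g_1: float, tau: float) -> Change:
    """Classify one time point against the first-time-point baseline.

    Strict inequalities: the boundary ratios tau and 1/tau are NEUTRAL.
    A zero baseline cannot form a ratio; sign logic keeps the intended
    semantics (0 -> positive is induction, 0 -> negative repression).
    """
    if not (math.isfinite(g_t) and math.isfinite(g_1) and math.isfinite(tau)):
        raise ValidationError("classify_ratio requires finite inputs")
    if tau <= 1:
        raise ValidationError("tau must exceed 1")
    if g_1 == 0:
        if g_t > 0:
            return Change.INDUCED
        if g_t < 0:
            return Change.REPRESSED
        return Change.NEUTRAL
    ratio = g_t / g_1
    if ratio > tau:
        return Change.INDUCED
    if ratio < 1.0 / tau:
        return Change.REPRESSED
    return Change.NEUTRAL


def _shift_nonnegative(profile: np.ndarray) -> np.ndarray:
    """Shift a profile with negative values so its minimum is >= 0.

    Intensity data are assumed nonnegative; when negatives occur (e.g.
    log-ratio input) ratios would flip sign, so the whole gene is shifted by
    -min plus a tiny offset (1e-9 of the range) before classification.
    """
    lo = profile.min()
    if lo >= 0:
        return profile
    rng = profile.max() - lo
    offset = 1e-9 * (rng if rng > 0 else 1.0)
    return profile - lo + offset


def compute_sce(profile, config: SceConfig = SceConfig()) -> SceResult | tuple:
    """Detect induced/repressed time points and the ScE of one profile.

    ``profile`` is an (s, n) array (or a single series of length n); each
    series is classified against its own first value.  Returns the change
    sets and ScE without a gene id; see :func:`compute_sce_for_gene` for the
    named variant.
    """
    return compute_sce_for_gene("", profile, config)


def compute_sce_for_gene(
    gene: str, profile, config: SceConfig = SceConfig()
) -> SceResult:
    prof = np.atleast_2d(np.asarray(profile, dtype=float))
    if prof.shape[1] < 2:
        raise ValidationError("each series needs at least 2 time points")
    if not np.isfinite(prof).all():
        raise ValidationError("profile values must be finite")
    prof = _shift_nonnegative(prof)
    induced, repressed = set(), set()
    for si, series in enumerate(prof, start=1):
        baseline = series[0]
        for t in range(2, len(series) + 1):
            change = classify_ratio(series[t - 1], baseline, config.tau)
            if change is Change.INDUCED:
                induced.add((si, t))
            elif change is Change.REPRESSED:
                repressed.add((si, t))
    union = {t for _, t in induced} | {t for _, t in repressed}
    sce = min(union) if union else UNDEFINED
    return SceResult(gene, frozenset(induced), frozenset(repressed), sce)


def classify_pair(sce_a: SceResult, sce_b: SceResult) -> PairCase:
    """Route an unordered pair into Case 1/2/3 by comparing ScE values.

    UNDEFINED orders as +infinity: a gene that never changes cannot be the
    earlier-changing (regulating) gene; two such genes tie into Case 3.
    """
    ka, kb = sce_a.sort_key, sce_b.sort_key
    if ka < kb:
        return PairCase(CaseTag.CASE1, ((sce_a.gene, sce_b.gene),))
    if kb < ka:
        return PairCase(CaseTag.CASE2, ((sce_b.gene, sce_a.gene),))
    return PairCase(
        CaseTag.CASE3,
        ((sce_a.gene, sce_b.gene), (sce_b.gene, sce_a.gene)),
    )
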