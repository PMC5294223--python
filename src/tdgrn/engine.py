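"""Partitioned execution of the three inference steps.

The four algorithms M0-M3 split the work between the *mapper* and
*reducer* roles of a map/shuffle/reduce job:

========== =================== =================== =============================
algorithm  mapper steps        reducer steps       key-value schema
========== =================== =================== =============================
M0         (none)              1, 2, 3             key = gene pair; value = both
                                                   expression profiles
M1         1                   2, 3                key = gene pair; value =
                                                   profiles + case tag
M2         1, 2                3                   key = ordered pair; value =
                                                   influence record
M3         1, 2, 3             (none)              key = edge; value = influence
                                                   exceeding epsilon
========== =================== =================== =============================

All four produce the same network for the same input and configuration;
they differ only in where the steps run.  The cluster backend is replaced
by an in-process map/shuffle/reduce over a local ``multiprocessing.Pool``;
the shuffle partitions key-value records by a stable crc32 hash of the key,
so partitioning is reproducible across runs and processes.  Per-pair work
is O(1) in m, so mapping costs O(m^2/M) and reducing O(m^2/R) for M
workers and R reducer partitions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from multiprocessing import get_context
from typing import Mapping

from ._util import natural_key, stable_hash
from .datatypes import GenePairRecord, Network, TimeSeriesDataset
from .exceptions import ValidationError
from .influence import InfluenceRecord, MiConfig, compute_influence
from .io import generate_pairs
from .network import DEFAULT_EPSILON, EdgeDecision, assemble_network, decide_edge
from .sce import PairCase, SceConfig, classify_pair, compute_sce_for_gene

ALGORITHMS = ("M0", "M1", "M2", "M3")
STEPS = ("step1", "step2", "step3")

_MAPPER_STEPS = {
    "M0": frozenset(),
    "M1": frozenset({"step1"}),
    "M2": frozenset({"step1", "step2"}),
    "M3": frozenset(STEPS),
}

_KEY_SCHEMAS = {
    "M0": "key: gene pair; value: expression profiles",
    "M1": "key: gene pair; value: expression profiles + Step-1 case tag",
    "M2": "key: ordered gene pair; value: influence record",
    "M3": "key: edge; value: influence exceeding epsilon",
}

DEFAULT_N_REDUCERS = 20


@dataclass(frozen=True)
class InferenceConfig:
    """All thresholds and estimator settings for one inference run."""

    tau: float = 1.2
    epsilon: float = DEFAULT_EPSILON
    max_lag: int = 3
    n_bins: int = 3
    binning: str = "equal-frequency"
    log_base: float = 2.0

    def __post_init__(self):
        SceConfig(self.tau)  # validate
        self.mi()
        if self.epsilon < 0:
            raise ValidationError("epsilon must be >= 0")

    def sce(self) -> SceConfig:
        return SceConfig(self.tau)

    def mi(self) -> MiConfig:
        return MiConfig(self.max_lag, self.n_bins, self.binning, self.log_base)

    def as_params(self) -> dict:
        return {
            "tau": self.tau,
            "epsilon": self.epsilon,
            "max_lag": self.max_lag,
            "n_bins": self.n_bins,
            "binning": self.binning,
            "log_base": self.log_base,
        }


@dataclass(frozen=True)
class JobPlan:
    """Step assignment and key schema for one algorithm."""

    algorithm: str
    mapper_steps: frozenset
    reducer_steps: frozenset
    n_workers: int
    n_reducers: int
    key_schema: str


@dataclass(eq=False)
class KeyValue:
    key: tuple
    value: object


@dataclass(eq=False)
class RunResult:
    """Inferred network plus per-phase record counts and wall-clock times."""

    network: Network
    plan: JobPlan
    decisions: tuple
    counts: Mapping = field(default_factory=dict)
    seconds: Mapping = field(default_factory=dict)


def plan_job(algorithm: str, n_workers: int = 1, n_reducers: int = DEFAULT_N_REDUCERS) -> JobPlan:
    algo = str(algorithm).upper()
    if algo not in ALGORITHMS:
        raise ValidationError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if n_workers < 1 or n_reducers < 1:
        raise ValidationError("n_workers and n_reducers must be >= 1")
    mapper = _MAPPER_STEPS[algo]
    return JobPlan(
        algorithm=algo,
        mapper_steps=mapper,
        reducer_steps=frozenset(STEPS) - mapper,
        n_workers=n_workers,
        n_reducers=n_reducers,
        key_schema=_KEY_SCHEMAS[algo],
    )


def partition_by_key(kv_stream, n_reducers: int) -> list:
    """Assign records to reducer partitions by stable key hash."""
    if n_reducers < 1:
        raise ValidationError("n_reducers must be >= 1")
    partitions = [[] for _ in range(n_reducers)]
    for kv in kv_stream:
        partitions[stable_hash(kv.key) % n_reducers].append(kv)
    return partitions


def _step1(record: GenePairRecord, config: InferenceConfig) -> PairCase:
    sce_cfg = config.sce()
    sce_a = compute_sce_for_gene(record.gene_a, record.profiles_a, sce_cfg)
    sce_b = compute_sce_for_gene(record.gene_b, record.profiles_b, sce_cfg)
    return classify_pair(sce_a, sce_b)


def _step2(case: PairCase, record: GenePairRecord, config: InferenceConfig) -> InfluenceRecord:
    return compute_influence(case, record.profiles(), config.mi())


def map_record(record: GenePairRecord, plan: JobPlan, config: InferenceConfig) -> list:
    """Run the plan's mapper steps on one pair record."""
    try:
        if not plan.mapper_steps:
            return [KeyValue((record.gene_a, record.gene_b),
                             (record.profiles_a, record.profiles_b))]
        case = _step1(record, config)
        if "step2" not in plan.mapper_steps:
            return [KeyValue((record.gene_a, record.gene_b),
                             (record.profiles_a, record.profiles_b, case))]
        influence = _step2(case, record, config)
        if "step3" not in plan.mapper_steps:
            return [KeyValue((influence.source, influence.target), influence)]
        decision = decide_edge(influence, config.epsilon)
        return [KeyValue((decision.source, decision.target), decision.influence)] if decision.present else []
    except Exception as exc:
        raise type(exc)(
            f"mapper failed on pair ({record.gene_a}, {record.gene_b}): {exc}"
        ) from exc


def reduce_keyvalue(kv: KeyValue, plan: JobPlan, config: InferenceConfig) -> EdgeDecision:
    """Run the plan's reducer steps on one shuffled record."""
    try:
        if "step1" in plan.reducer_steps:
            a, b = kv.key
            prof_a, prof_b = kv.value[0], kv.value[1]
            record = GenePairRecord(a, b, prof_a, prof_b)
            case = _step1(record, config)
        elif "step2" in plan.reducer_steps:
            a, b = kv.key
            prof_a, prof_b, case = kv.value
            record = GenePairRecord(a, b, prof_a, prof_b)
        if "step2" in plan.reducer_steps:
            influence = _step2(case, record, config)
        elif "step3" in plan.reducer_steps:
            influence = kv.value
        if "step3" in plan.reducer_steps:
            return decide_edge(influence, config.epsilon)
        # M3: mappers already thresholded; reducers only write out
        source, target = kv.key
        return EdgeDecision(source, target, kv.value, True, config.epsilon)
    except ValidationError as exc:
        raise ValidationError(f"reducer failed on key {kv.key}: {exc}") from exc


def _map_chunk(records, plan, config):
    out = []
    for rec in records:
        out.extend(map_record(rec, plan, config))
    return out


def _reduce_partition(partition, plan, config):
    return [reduce_keyvalue(kv, plan, config) for kv in partition]


def _chunks(items, n):
    size = max(1, -(-len(items) // n))
    return [items[i:i + size] for i in range(0, len(items), size)]


def run(
    dataset: TimeSeriesDataset,
    algorithm: str = "M2",
    config: InferenceConfig = InferenceConfig(),
    n_workers: int = 1,
    n_reducers: int = DEFAULT_N_REDUCERS,
) -> RunResult:
    """Execute the full pipeline under one partitioning algorithm.

    The result is identical for all four algorithms and any worker/reducer
    counts on the same input and configuration; only the timing differs.
    """
    plan = plan_job(algorithm, n_workers, n_reducers)
    seconds, counts = {}, {}

    t0 = time.perf_counter()
    records = list(generate_pairs(dataset))
    counts["pairs"] = len(records)
    seconds["pairs"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if n_workers > 1 and records:
        ctx = get_context()
        with ctx.Pool(n_workers) as pool:
            mapped = pool.starmap(
                _map_chunk,
                [(chunk, plan, config) for chunk in _chunks(records, n_workers)],
            )
        kvs = [kv for part in mapped for kv in part]
    else:
        kvs = _map_chunk(records, plan, config)
    counts["records_to_reducers"] = len(kvs)
    seconds["map"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    partitions = partition_by_key(kvs, n_reducers)
    seconds["shuffle"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if n_workers > 1 and kvs:
        ctx = get_context()
        with ctx.Pool(min(n_workers, n_reducers)) as pool:
            reduced = pool.starmap(
                _reduce_partition, [(p, plan, config) for p in partitions]
            )
    else:
        reduced = [_reduce_partition(p, plan, config) for p in partitions]
    decisions = tuple(
        sorted(
            (d for part in reduced for d in part),
            key=lambda d: (natural_key(d.source), natural_key(d.target)),
        )
    )
    seconds["reduce"] = time.perf_counter() - t0

    network = assemble_network(decisions, dataset.gene_ids, config.as_params())
    counts["edges"] = len(network)
    seconds["total"] = sum(seconds.values())
    return RunResult(network, plan, decisions, counts, seconds)
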