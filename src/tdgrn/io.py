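"""Readers and writers for the text formats the tool exchanges.

Formats
-------
Time series (dialect ``dream4``)
    Header row ``Time<TAB>G1<TAB>G2...``, then one row per time point;
    a new series starts at a blank line or whenever the time value does
    not increase.  The time column is dropped after segmentation.
Time series (dialect ``generic-tsv``)
    One row per gene: ``gene_id<TAB>v1<TAB>v2...``; single series.
Gold standard
    Three-column TSV ``regulator<TAB>target<TAB>label`` with label 0/1
    (DREAM4 convention); pairs absent from the file default to absent.
Pair file
    One line per unordered pair: ``gene_a<TAB>gene_b<TAB>profiles_a<TAB>
    profiles_b`` with each profile's series joined by ';' and values by
    ','; values use shortest round-trip float rendering, so a write/read
    cycle is bit-exact.  m(m-1)/2 lines for m genes.
Networks
    Edge TSV ``regulator<TAB>target<TAB>weight`` (weight to 6 decimals)
    or Graphviz dot; header comments record the producing parameters.

All readers skip comment lines starting with ``#``.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

from ._util import natural_key, natural_sorted
from .datatypes import EdgeSet, GenePairRecord, Network, TimeSeriesDataset
from .exceptions import FormatError, ValidationError

DIALECTS = ("dream4", "generic-tsv")

_PARAM_KEYS = ("tau", "epsilon", "max_lag", "n_bins", "binning", "log_base")


def _data_lines(path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_timeseries(path, dialect: str = "dream4") -> TimeSeriesDataset:
    """Parse an expression matrix in the given dialect."""
    if dialect == "dream4":
        return _read_dream4(path)
    if dialect == "generic-tsv":
        return _read_generic(path)
    raise ValidationError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _read_dream4(path) -> TimeSeriesDataset:
    header = None
    series: list[list[list[float]]] = []
    current: list[list[float]] = []
    last_time = None
    for lineno, line in _data_lines(path):
        if not line.strip():
            if current:
                series.append(current)
                current, last_time = [], None
            continue
        fields = line.split("\t")
        if header is None:
            if fields[0].strip().lower() != "time":
                raise FormatError(
                    f"{path}:{lineno}: dream4 header must start with 'Time'"
                )
            header = [f.strip() for f in fields[1:]]
            if len(set(header)) != len(header):
                dupes = sorted({g for g in header if header.count(g) > 1})
                raise FormatError(f"{path}:{lineno}: duplicate gene ids {dupes}")
            if not header:
                raise FormatError(f"{path}:{lineno}: no gene columns")
            continue
        if len(fields) != len(header) + 1:
            raise FormatError(
                f"{path}:{lineno}: expected {len(header) + 1} fields, got {len(fields)}"
            )
        try:
            tval = float(fields[0])
            values = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
        if last_time is not None and tval <= last_time and current:
            series.append(current)
            current = []
        last_time = tval
        current.append(values)
    if current:
        series.append(current)
    if header is None:
        raise FormatError(f"{path}: empty dream4 file")
    if not series:
        raise FormatError(f"{path}: no expression rows")
    n = len(series[0])
    for si, block in enumerate(series, start=1):
        if len(block) != n:
            raise FormatError(
                f"{path}: series {si} has {len(block)} time points, "
                f"series 1 has {n} (ragged series)"
            )
    if n < 2:
        raise ValidationError(f"{path}: need at least 2 time points, got {n}")
    # arr[s][t][gene] -> (m, s, n)
    arr = np.asarray(series, dtype=float).transpose(2, 0, 1)
    order = sorted(range(len(header)), key=lambda i: natural_key(header[i]))
    return TimeSeriesDataset(tuple(header[i] for i in order), arr[order])


def _read_generic(path) -> TimeSeriesDataset:
    profiles: dict[str, list[float]] = {}
    width = None
    for lineno, line in _data_lines(path):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected gene id and values")
        gene = fields[0].strip()
        if gene in profiles:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gene!r}")
        try:
            values = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
        if width is None:
            width = len(values)
        elif len(values) != width:
            raise FormatError(
                f"{path}:{lineno}: row has {len(values)} values, expected {width}"
            )
        profiles[gene] = values
    if not profiles:
        raise FormatError(f"{path}: empty expression file")
    if width < 2:
        raise ValidationError(f"{path}: need at least 2 time points, got {width}")
    return TimeSeriesDataset.from_profiles(profiles)


def write_timeseries(dataset: TimeSeriesDataset, path, dialect: str = "dream4",
                     header_params: dict | None = None) -> None:
    """Write a dataset; dream4 uses blank-line separated series."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header_params or {}).items():
            fh.write(f"# {key}={val}\n")
        if dialect == "dream4":
            fh.write("Time\t" + "\t".join(dataset.gene_ids) + "\n")
            for s in range(dataset.n_series):
                if s:
                    fh.write("\n")
                for t in range(dataset.n_timepoints):
                    row = dataset.values[:, s, t]
                    fh.write(str(t) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
        elif dialect == "generic-tsv":
            if dataset.n_series != 1:
                raise ValidationError("generic-tsv holds a single series per gene")
            for g in dataset:
                vals = dataset.profile(g)[0]
                fh.write(g + "\t" + "\t".join(repr(float(v)) for v in vals) + "\n")
        else:
            raise ValidationError(f"unknown dialect {dialect!r}")


def generate_pairs(dataset: TimeSeriesDataset) -> Iterator[GenePairRecord]:
    """Stream the m(m-1)/2 unordered pair records in sorted order.

    Within each record gene_a precedes gene_b in natural identifier order;
    each unordered pair occurs exactly once.  m < 2 yields nothing.
    """
    for a, b in itertools.combinations(dataset.gene_ids, 2):
        yield GenePairRecord(a, b, dataset.profile(a), dataset.profile(b))


def _encode_profile(profile: np.ndarray) -> str:
    return ";".join(
        ",".join(repr(float(v)) for v in series) for series in np.atleast_2d(profile)
    )


def _decode_profile(text: str) -> np.ndarray:
    return np.asarray(
        [[float(v) for v in series.split(",")] for series in text.split(";")],
        dtype=float,
    )


def write_pair_file(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                f"{rec.gene_a}\t{rec.gene_b}\t"
                f"{_encode_profile(rec.profiles_a)}\t{_encode_profile(rec.profiles_b)}\n"
            )


def read_pair_file(path) -> Iterator[GenePairRecord]:
    for lineno, line in _data_lines(path):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 tab-delimited fields")
        try:
            yield GenePairRecord(
                fields[0], fields[1], _decode_profile(fields[2]), _decode_profile(fields[3])
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc


def read_gold_standard(path, universe=None) -> EdgeSet:
    """Parse a three-column gold standard (regulator, target, 0/1 label)."""
    present, absent = set(), set()
    seen = set()
    genes = set(universe or ())
    for lineno, line in _data_lines(path):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"{path}:{lineno}: expected 3 tab-delimited fields")
        reg, tgt, label_text = (f.strip() for f in fields)
        try:
            label = int(label_text)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer label {label_text!r}") from exc
        if label not in (0, 1):
            raise FormatError(f"{path}:{lineno}: label must be 0 or 1, got {label}")
        if reg == tgt:
            raise ValidationError(f"{path}:{lineno}: self-loop {reg}->{tgt}")
        if (reg, tgt) in seen:
            raise FormatError(f"{path}:{lineno}: duplicate pair {reg}->{tgt}")
        seen.add((reg, tgt))
        (present if label else absent).add((reg, tgt))
        genes.update((reg, tgt))
    return EdgeSet(frozenset(present), frozenset(genes), frozenset(absent))


def write_gold_standard(edges: EdgeSet, path, header_params: dict | None = None) -> None:
    """Write present edges with label 1 (unlisted pairs default to absent)."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in (header_params or {}).items():
            fh.write(f"# {key}={val}\n")
        for reg, tgt in sorted(
            edges.present, key=lambda e: (natural_key(e[0]), natural_key(e[1]))
        ):
            fh.write(f"{reg}\t{tgt}\t1\n")


def write_network(network: Network, path, format: str = "edge-tsv") -> None:
    """Write an inferred network as edge TSV or Graphviz dot."""
    params = {k: network.params.get(k) for k in _PARAM_KEYS if k in network.params}
    if format == "edge-tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for key, val in params.items():
                fh.write(f"# {key}={val}\n")
            fh.write(f"# universe={','.join(natural_sorted(network.universe))}\n")
            for reg, tgt, w in network.edges:
                fh.write(f"{reg}\t{tgt}\t{w:.6f}\n")
    elif format == "dot":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("digraph grn {\n")
            for key, val in params.items():
                fh.write(f"  // {key}={val}\n")
            for g in natural_sorted(network.universe):
                fh.write(f'  "{g}";\n')
            for reg, tgt, w in network.edges:
                fh.write(f'  "{reg}" -> "{tgt}" [weight={w:.6f}];\n')
            fh.write("}\n")
    else:
        raise ValidationError(f"unknown network format {format!r}")


def read_network(path) -> Network:
    """Read an edge-TSV network back, including its parameter header."""
    params: dict = {}
    universe: set = set()
    edges = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    if key == "universe":
                        universe.update(v for v in val.split(",") if v)
                    elif key in ("binning",):
                        params[key] = val.strip()
                    else:
                        try:
                            num = float(val)
                            params[key] = int(num) if num.is_integer() and key in (
                                "max_lag", "n_bins") else num
                        except ValueError:
                            params[key] = val.strip()
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-delimited fields")
            try:
                edges.append((fields[0], fields[1], float(fields[2])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad weight ({exc})") from exc
    universe.update(g for e in edges for g in e[:2])
    return Network(tuple(edges), frozenset(universe), params)
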