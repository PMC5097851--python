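"""Minimal deterministic map-shuffle-reduce runtime.

A MapReduce program is an ordered sequence of (mapper, reducer) rounds
operating over ``(key, value)`` pairs.  Mappers consume one pair and emit a
finite multiset of pairs; all mapper instances of a round halt before any
reducer of that round starts; reducers consume ``(key, values)`` groups and
emit pairs for the next round.

The engine guarantees *partition invariance*: for any program and input the
output is bit-identical for any worker count ``P``.  This is achieved by
(a) partitioning keys with a stable, non-randomised hash, (b) sorting each
reducer's value list by a canonical total order before the reducer runs
(so floating-point summation order is fixed), and (c) canonically sorting
each phase's output multiset.
"""

from __future__ import annotations

import zlib
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Any, Callable, Iterable, Sequence

__all__ = [
    "EngineConfig",
    "EngineError",
    "MapReduceProgram",
    "execute_program",
    "run_mapper_phase",
    "run_reducer_phase",
    "shuffle",
    "stable_hash",
]

KeyValue = tuple[Any, Any]
Mapper = Callable[[Any, Any], Iterable[KeyValue]]
Reducer = Callable[[Any, list], Iterable[KeyValue]]


class EngineError(RuntimeError):
    """A mapper or reducer failed; carries the offending key and round."""


@dataclass(frozen=True)
class EngineConfig:
    """Execution parameters: worker count and backend.

    ``serial`` runs the P partitions one after another in-process;
    ``process-pool`` fans them out to a :class:`ProcessPoolExecutor`
    (mappers/reducers must then be picklable).  Results are identical.
    """

    workers: int = 1
    backend: str = "serial"

    def __post_init__(self) -> None:
        if self.workers < 1:
            raise ValueError(f"workers must be >= 1, got {self.workers}")
        if self.backend not in ("serial", "process-pool"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class MapReduceProgram:
    """Ordered mapper/reducer rounds; executed for exactly ``len(rounds)`` rounds."""

    rounds: Sequence[tuple[Mapper, Reducer]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rounds) < 1:
            raise ValueError("a MapReduce program needs at least one round")


def _order_key(v: Any) -> tuple:
    """Canonical total order over the primitive/tuple values the engine carries."""
    if isinstance(v, bool):
        return (1, float(v))
    if isinstance(v, (int, float)):
        return (1, float(v))
    if isinstance(v, str):
        return (2, v)
    if isinstance(v, bytes):
        return (3, v)
    if isinstance(v, tuple):
        return (4, tuple(_order_key(x) for x in v))
    if v is None:
        return (0, 0.0)
    raise TypeError(f"value of type {type(v).__name__} has no canonical order")


def _pair_key(pair: KeyValue) -> tuple:
    return (_order_key(pair[0]), _order_key(pair[1]))


def stable_hash(key: Any) -> int:
    """Stable (non-randomised) hash used for key partitioning."""
    return zlib.crc32(repr(key).encode("utf-8"))


def _partition(pairs: Iterable[KeyValue], workers: int, by_key: bool) -> list[list]:
    parts: list[list] = [[] for _ in range(workers)]
    if by_key:
        for item in pairs:
            parts[stable_hash(item[0]) % workers].append(item)
    else:
        for i, item in enumerate(pairs):
            parts[i % workers].append(item)
    return parts


def _map_partition(args: tuple[Mapper, list[KeyValue]]) -> list[KeyValue]:
    mapper, part = args
    out: list[KeyValue] = []
    for key, value in part:
        try:
            emitted = mapper(key, value)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise EngineError(f"mapper failed on key {key!r}: {exc}") from exc
        if emitted is not None:
            out.extend(emitted)
    return out


def _reduce_partition(args: tuple[Reducer, list[tuple[Any, list]]]) -> list[KeyValue]:
    reducer, groups = args
    out: list[KeyValue] = []
    for key, values in groups:
        try:
            emitted = reducer(key, values)
        except Exception as exc:  # noqa: BLE001
            raise EngineError(f"reducer failed on key {key!r}: {exc}") from exc
        if emitted is not None:
            out.extend(emitted)
    return out


def _run_partitions(fn, tasks: list, config: EngineConfig) -> list[list[KeyValue]]:
    if config.backend == "process-pool" and config.workers > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            return list(pool.map(fn, tasks))
    return [fn(t) for t in tasks]


def run_mapper_phase(
    pairs: Iterable[KeyValue], mapper: Mapper, config: EngineConfig | None = None
) -> list[KeyValue]:
    """Apply ``mapper`` to every pair; return the canonically sorted multiset union.

    The result is independent of the worker count because the union is
    re-sorted before it is returned.
    """
    config = config or EngineConfig()
    parts = _partition(list(pairs), config.workers, by_key=False)
    results = _run_partitions(_map_partition, [(mapper, p) for p in parts], config)
    out = [pair for chunk in results for pair in chunk]
    out.sort(key=_pair_key)
    return out

def shuffle(pairs: Iterable[KeyValue]) -> dict:
    """Group pairs by key; each group's value list sorted by the canonical order."""
    groups: dict[Any, list] = {}
    for key, value in pairs:
        groups.setdefault(key, []).append(value)
    for key, values in groups.items():
        try:
            values.sort(key=_order_key)
        except TypeError as exc:
            raise EngineError(f"unorderable values under key {key!r}: {exc}") from exc
    return groups


def run_reducer_phase(
    groups: dict, reducer: Reducer, config: EngineConfig | None = None
) -> list[KeyValue]:
    """Apply ``reducer`` to every (key, values) group; canonically sorted union."""
    config = config or EngineConfig()
    items = sorted(groups.items(), key=lambda kv: _order_key(kv[0]))
    parts = _partition(items, config.workers, by_key=True)
    results = _run_partitions(_reduce_partition, [(reducer, p) for p in parts], config)
    out = [pair for chunk in results for pair in chunk]
    out.sort(key=_pair_key)
    return out


def execute_program(
    program: MapReduceProgram,
    pairs: Iterable[KeyValue],
    config: EngineConfig | None = None,
) -> list[KeyValue]:
    """Run every round of ``program`` on the input multiset.

    Output is the canonically sorted multiset emitted by the final reducer,
    bit-identical for any ``config.workers``.
    """
    config = config or EngineConfig()
    current = list(pairs)
    for r, (mapper, reducer) in enumerate(program.rounds, start=1):
        try:
            mapped = run_mapper_phase(current, mapper, config)
            grouped = shuffle(mapped)
            current = run_reducer_phase(grouped, reducer, config)
        except EngineError as exc:
            raise EngineError(f"round {r}: {exc}") from exc
    return current
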