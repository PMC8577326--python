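"""Roving-standard presentation blocks.

A block starts with 8 warm-up tokens of type A and continues with trains of
identical stimuli that alternate between the two types.  Train lengths run
from 4 to 8 tokens, each length occurring exactly 20 times per type, so each
type contributes 100 trains (600 tokens); with the warm-up this makes
608 + 600 = 1208 tokens.  Stimulus-onset asynchrony is 1.09 s, giving a
block of about 22 minutes.

Within a train, the first token serves as the *deviant* (it violates the
expectation built by the preceding train) and the last two as *standards*;
every token except a train-initial one also enters the sensory-ERP average.
The warm-up contributes neither deviants nor standards; its tokens 2-8 count
toward the sensory average (configurable).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "BlockConfig",
    "Event",
    "EventSequence",
    "generate_block",
    "label_roles",
    "block_duration_min",
]

ROLE_WARMUP = "warmup"
ROLE_DEVIANT = "deviant"
ROLE_STANDARD = "standard"
ROLE_SENSORY_ONLY = "sensory_only"


@dataclass(frozen=True)
class BlockConfig:
    """Combinatorics and timing of one presentation block."""

    type_a: str = "nonfocal_e"
    type_b: str = "focal_a"
    soa_s: float = 1.09
    warmup_tokens: int = 8
    train_lengths: tuple[int, ...] = (4, 5, 6, 7, 8)
    occurrences_per_length: int = 20
    seed: int = 0
    #: if True, warm-up tokens 2..n enter sensory averages (never MMR roles)
    warmup_in_sensory: bool = True

    @property
    def trains_per_type(self) -> int:
        return len(self.train_lengths) * self.occurrences_per_length

    def __post_init__(self) -> None:
        if self.soa_s <= 0 or self.warmup_tokens < 0:
            raise ValueError("invalid block configuration")
        if self.occurrences_per_length < 1 or not self.train_lengths:
            raise ValueError("invalid train-length plan")
        if min(self.train_lengths) < 3:
            raise ValueError("trains must have at least 3 tokens (deviant + 2 standards)")


@dataclass(frozen=True)
class Event:
    onset_s: float
    category: str
    train_index: int  # 0 = warm-up run
    position_in_train: int  # 1-based
    role: str
    sensory: bool  # enters the sensory-ERP average


@dataclass
class EventSequence:
    """Ordered stimulus events of one block."""

    events: list[Event]
    config: BlockConfig

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "category": [e.category for e in self.events],
                "train_index": [e.train_index for e in self.events],
                "position": [e.position_in_train for e in self.events],
                "role": [e.role for e in self.events],
                "sensory": [e.sensory for e in self.events],
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: BlockConfig) -> "EventSequence":
        events = [
            Event(
                onset_s=float(r.onset_s),
                category=str(r.category),
                train_index=int(r.train_index),
                position_in_train=int(r.position),
                role=str(r.role),
                sensory=bool(r.sensory),
            )
            for r in df.itertuples()
        ]
        return cls(events=events, config=config)

    def count_by(self, key) -> Counter:
        return Counter(key(e) for e in self.events)

    def train_length_histogram(self, category: str) -> Counter:
        """Occurrences of each train length for one type (warm-up excluded)."""
        lengths = Counter()
        for e in self.events:
            if e.train_index > 0 and e.category == category:
                lengths[e.train_index] = max(lengths[e.train_index], e.position_in_train)
        return Counter(lengths.values())


def _shuffled_lengths(cfg: BlockConfig, rng: np.random.Generator) -> np.ndarray:
    lengths = np.repeat(cfg.train_lengths, cfg.occurrences_per_length)
    rng.shuffle(lengths)
    return lengths


def generate_block(cfg: BlockConfig = BlockConfig()) -> EventSequence:
    """Generate one labelled roving-standard block.

    The warm-up run uses type A; the first real train then uses type B, so
    the warm-up functions as the opening run of type A and the type-A total
    is ``warmup + trains_per_type x mean-length`` tokens (608 by default).
    Each type's multiset of train lengths is exactly the configured plan,
    shuffled by ``cfg.seed`` (independently per type).
    """
    rng = np.random.default_rng(cfg.seed)
    lengths_b = _shuffled_lengths(cfg, rng)
    lengths_a = _shuffled_lengths(cfg, rng)

    events: list[Event] = []
    i_token = 0

    def emit(category: str, train_index: int, position: int, n_train: int, warmup: bool) -> None:
        nonlocal i_token
        if warmup:
            role = ROLE_WARMUP
            sensory = cfg.warmup_in_sensory and position > 1
        elif position == 1:
            role = ROLE_DEVIANT
            sensory = False
        elif position > n_train - 2:
            role = ROLE_STANDARD
            sensory = True
        else:
            role = ROLE_SENSORY_ONLY
            sensory = True
        events.append(
            Event(
                onset_s=round(i_token * cfg.soa_s, 9),
                category=category,
                train_index=train_index,
                position_in_train=position,
                role=role,
                sensory=sensory,
            )
        )
        i_token += 1

    for pos in range(1, cfg.warmup_tokens + 1):
        emit(cfg.type_a, 0, pos, cfg.warmup_tokens, warmup=True)

    # trains alternate B, A, B, A, ... after the type-A warm-up run
    train_index = 0
    for k in range(cfg.trains_per_type):
        for category, n in ((cfg.type_b, int(lengths_b[k])), (cfg.type_a, int(lengths_a[k]))):
            train_index += 1
            for pos in range(1, n + 1):
                emit(category, train_index, pos, n, warmup=False)

    return EventSequence(events=events, config=cfg)


def label_roles(seq: EventSequence) -> EventSequence:
    """Recompute role labels from train structure (idempotent check).

    ``generate_block`` already labels roles; this re-derives them from the
    (train_index, position) bookkeeping and raises if the sequence is
    malformed (non-contiguous positions or inconsistent train categories).
    """
    by_train: dict[int, list[Event]] = {}
    for e in seq.events:
        by_train.setdefault(e.train_index, []).append(e)
    cfg = seq.config
    relabelled: list[Event] = []
    for idx in sorted(by_train):
        train = sorted(by_train[idx], key=lambda e: e.position_in_train)
        positions = [e.position_in_train for e in train]
        if positions != list(range(1, len(train) + 1)):
            raise ValueError(f"train {idx} has non-contiguous positions {positions}")
        if len({e.category for e in train}) != 1:
            raise ValueError(f"train {idx} mixes stimulus categories")
        n = len(train)
        for e in train:
            if idx == 0:
                role = ROLE_WARMUP
                sensory = cfg.warmup_in_sensory and e.position_in_train > 1
            elif e.position_in_train == 1:
                role, sensory = ROLE_DEVIANT, False
            elif e.position_in_train > n - 2:
                role, sensory = ROLE_STANDARD, True
            else:
                role, sensory = ROLE_SENSORY_ONLY, True
            relabelled.append(
                Event(e.onset_s, e.category, e.train_index, e.position_in_train, role, sensory)
            )
    relabelled.sort(key=lambda e: e.onset_s)
    return EventSequence(events=relabelled, config=cfg)


def block_duration_min(seq: EventSequence) -> float:
    """Token count x SOA, in minutes."""
    if not seq.events:
        raise ValueError("empty event sequence")
    return len(seq.events) * seq.config.soa_s / 60.0
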