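"""Richness, versatility, and sexual display complexity (SDC) scoring.

For one fixed-window posture sequence, *richness* R is the number of distinct
postures used, *versatility* V is the number of transitions between different
postures, and SDC = R * V.  A complex display cycles through many postures
with many changes; a monotonous display (one posture held or re-logged) has
V = 0 and therefore SDC = 0.

Two readings of "number of transitions" are supported:

``change-count`` (default)
    Total number of posture *changes*: adjacent event pairs (p_i, p_{i+1})
    with p_i != p_{i+1}.  Re-logged identical states are collapsed first, so
    they never count.
``distinct-ordered-transitions``
    Number of *unique* ordered pairs (p_i, p_{i+1}), p_i != p_{i+1},
    occurring at least once (transition types rather than transition events).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .ethogram import BehavioralSequence, Repertoire, SequenceError

__all__ = [
    "VERSATILITY_MODES",
    "ComplexityScore",
    "collapse_repeats",
    "richness",
    "versatility",
    "sdc",
    "score_batch",
]

VERSATILITY_MODES = ("change-count", "distinct-ordered-transitions")


@dataclass(frozen=True)
class ComplexityScore:
    """Complexity components of one behavioral sequence."""

    subject_id: str
    richness: int
    versatility: int
    sdc: int
    mode: str = "change-count"

    def __post_init__(self) -> None:
        if self.sdc != self.richness * self.versatility:
            raise ValueError("sdc must equal richness * versatility")


def collapse_repeats(postures: Sequence[str]) -> list[str]:
    """Drop adjacent duplicates (a re-logged identical state is not a change)."""
    out: list[str] = []
    for code in postures:
        if not out or out[-1] != code:
            out.append(code)
    return out


def richness(sequence: BehavioralSequence, repertoire: Repertoire | None = None) -> int:
    """Number of distinct postures occurring at least once in the sequence."""
    postures = sequence.postures
    if not postures:
        raise SequenceError(f"{sequence.subject_id}: empty sequence")
    if repertoire is not None:
        sequence.validate_against(repertoire)
    return len(set(postures))


def versatility(sequence: BehavioralSequence, mode: str = "change-count") -> int:
    """Number of transitions between different postures in the sequence."""
    if mode not in VERSATILITY_MODES:
        raise ValueError(f"unknown versatility mode {mode!r}; expected one of {VERSATILITY_MODES}")
    collapsed = collapse_repeats(sequence.postures)
    if not collapsed:
        raise SequenceError(f"{sequence.subject_id}: empty sequence")
    if mode == "change-count":
        return len(collapsed) - 1
    return len({(a, b) for a, b in zip(collapsed, collapsed[1:])})


def sdc(
    sequence: BehavioralSequence,
    repertoire: Repertoire | None = None,
    mode: str = "change-count",
) -> ComplexityScore:
    """Score one sequence: SDC = richness * versatility."""
    r = richness(sequence, repertoire)
    v = versatility(sequence, mode)
    return ComplexityScore(
        subject_id=sequence.subject_id, richness=r, versatility=v, sdc=r * v, mode=mode
    )


def score_batch(
    sequences: Iterable[BehavioralSequence],
    metadata: pd.DataFrame,
    repertoire: Repertoire | None = None,
    mode: str = "change-count",
) -> pd.DataFrame:
    """Score a batch of sequences and join each score to its focal metadata.

    ``metadata`` is the table produced by :func:`sdckit.ethogram.load_metadata`
    (indexed by id).  Every sequence's subject_id must be present; missing ids
    raise with the full list.  Rows are ordered by subject_id.
    """
    sequences = list(sequences)
    scores = [sdc(s, repertoire, mode) for s in sequences]
    cols = ["id", "richness", "versatility", "sdc", "mode"]
    if not scores:
        out = pd.DataFrame(columns=cols + [c for c in metadata.columns if c != "id"])
        return out
    missing = sorted({s.subject_id for s in scores} - set(metadata.index.astype(str)))
    if missing:
        raise KeyError(f"subject ids missing from metadata: {missing}")
    tbl = pd.DataFrame(
        {
            "id": [s.subject_id for s in scores],
            "richness": [s.richness for s in scores],
            "versatility": [s.versatility for s in scores],
            "sdc": [s.sdc for s in scores],
            "mode": [s.mode for s in scores],
        }
    )
    meta = metadata.drop(columns=["id"], errors="ignore")
    out = tbl.join(meta, on="id").sort_values("id", kind="mergesort").reset_index(drop=True)
    return out
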