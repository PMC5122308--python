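"""Display repertoire, focal event logs, and fixed-window behavioral sequences.

A focal-animal observation is a continuous recording of one displaying
individual over a fixed window (five minutes by default), coded as a sequence
of timestamped posture events drawn from a finite display repertoire
(ethogram).  This module owns the repertoire definition, the event-log file
dialect, and the completeness filter that keeps only fully recorded windows.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "Repertoire",
    "BehavioralSequence",
    "FocalMetadata",
    "SEX_CODES",
    "DEFAULT_WINDOW",
    "load_repertoire",
    "parse_focal_log",
    "write_focal_log",
    "filter_complete",
    "load_metadata",
]

#: Seconds in the standard focal-sampling window.
DEFAULT_WINDOW = 300.0

#: Internal numeric coding for sex (used by the modelling layer).
SEX_CODES = {"F": 0, "M": 1}

# The nine ritualized group-display postures of the greater flamingo
# (Johnson & Cezilly repertoire).
_DEFAULT_POSTURES = (
    ("head-flagging", "Head-flagging"),
    ("wing-salute", "Wing-salute"),
    ("twist-preen", "Twist-preen"),
    ("inverted-wing-salute", "Inverted wing-salute"),
    ("wing-leg-stretch", "Wing-leg stretch"),
    ("marching", "Marching"),
    ("hooking", "Hooking"),
    ("broken-neck", "Broken-neck"),
    ("false-feeding", "False-feeding"),
)


class RepertoireError(ValueError):
    """Invalid repertoire definition (empty, duplicated, or unknown codes)."""


class SequenceError(ValueError):
    """Invalid behavioral sequence (ordering, window, or unknown codes)."""


@dataclass(frozen=True)
class Repertoire:
    """An ordered catalogue of discrete display postures.

    Parameters
    ----------
    labels
        Posture codes, unique and non-empty.
    display_names
        Human-readable name per code; defaults to the code itself.
    """

    labels: tuple[str, ...]
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.labels:
            raise RepertoireError("repertoire must contain at least one posture")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if list(self.labels).count(l) > 1})
            raise RepertoireError(f"duplicate posture codes: {dupes}")
        if any(not l for l in self.labels):
            raise RepertoireError("empty posture code")
        names = dict(self.display_names)
        for label in self.labels:
            names.setdefault(label, label)
        object.__setattr__(self, "display_names", names)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, code: str) -> bool:
        return code in self.labels

    @classmethod
    def default(cls) -> "Repertoire":
        """The built-in nine-posture flamingo group-display repertoire."""
        return cls(
            labels=tuple(code for code, _ in _DEFAULT_POSTURES),
            display_names={code: name for code, name in _DEFAULT_POSTURES},
        )


@dataclass
class BehavioralSequence:
    """Ordered posture events of one focal individual over a fixed window.

    ``events`` is a list of ``(t, posture)`` pairs with ``t`` in seconds from
    the window start, strictly increasing, within ``[0, window_length)``.
    ``observed_span`` records how long the focal individual was actually
    observed; ``None`` means the span is unknown and the last event time is
    used as a lower bound.
    """

    subject_id: str
    events: list[tuple[float, str]]
    window_length: float = DEFAULT_WINDOW
    observed_span: float | None = None

    def __post_init__(self) -> None:
        if not self.events:
            raise SequenceError(f"{self.subject_id}: sequence has no events")
        times = [t for t, _ in self.events]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise SequenceError(f"{self.subject_id}: event times not strictly increasing")
        if times[0] < 0 or times[-1] >= self.window_length:
            raise SequenceError(
                f"{self.subject_id}: event times outside [0, {self.window_length})"
            )

    @property
    def postures(self) -> list[str]:
        return [code for _, code in self.events]

    @property
    def span(self) -> float:
        """Observation span: recorded span if known, else last event time."""
        return self.observed_span if self.observed_span is not None else self.events[-1][0]

    def validate_against(self, repertoire: Repertoire) -> "BehavioralSequence":
        unknown = sorted({c for c in self.postures if c not in repertoire})
        if unknown:
            raise SequenceError(f"{self.subject_id}: unknown posture codes {unknown}")
        return self


@dataclass(frozen=True)
class FocalMetadata:
    """Per-individual covariates attached to one focal sequence.

    ``date`` is days since the season start (Nov 1 = day 0; the courtship
    season runs November-March, days 0-151).  ``sex`` is 'F' or 'M'
    (coded 0/1 internally, see :data:`SEX_CODES`).
    """

    subject_id: str
    sex: str
    age: int
    date: int
    hour: float
    group_size: int
    year: int

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise ValueError(f"sex must be one of {sorted(SEX_CODES)}, got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.group_size < 1:
            raise ValueError("group_size must be >= 1")
        if not 0 <= self.date <= 151:
            raise ValueError("date must be within the Nov 1 - Mar 31 season (0-151)")


def load_repertoire(path: str | Path | None = None) -> Repertoire:
    """Load a posture repertoire from a YAML file, or the built-in default.

    Accepted YAML shapes: a plain list of codes, a mapping ``code -> display
    name``, or a mapping with a ``labels`` key.  With ``path=None`` the
    built-in nine-posture flamingo repertoire is returned.
    """
    if path is None:
        return Repertoire.default()
    raw = yaml.safe_load(Path(path).read_text())
    if isinstance(raw, dict) and "labels" in raw:
        labels = raw["labels"]
        names = raw.get("display_names", {})
    elif isinstance(raw, dict):
        labels, names = list(raw), dict(raw)
    elif isinstance(raw, list):
        labels, names = raw, {}
    else:
        raise RepertoireError(f"cannot interpret repertoire file {path}")
    labels = [str(l) for l in labels]
    if len(set(labels)) != len(labels):
        raise RepertoireError(f"duplicate posture codes in {path}")
    return Repertoire(labels=tuple(labels), display_names={str(k): str(v) for k, v in names.items()})


def _sniff_delimiter(text: str) -> str:
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    for delim in ("\t", ",", ";"):
        if delim in first:
            return delim
    return ","  # single-column or whitespace; csv will cope for our 2-col dialect


def parse_focal_log(
    path: str | Path,
    repertoire: Repertoire,
    *,
    time_unit: str = "s",
    subject_id: str | None = None,
    window_length: float = DEFAULT_WINDOW,
    end_marker: str = "EOF",
) -> BehavioralSequence:
    """Read a two-column (time, posture-code) event log into a sequence.

    The dialect is deliberately minimal: comma- or tab-delimited, optional
    header, time in seconds (``time_unit='s'``) or milliseconds (``'ms'``).
    Times are rebased so the first event is at the window start.  A final row
    whose code equals ``end_marker`` terminates the observation and sets
    :attr:`BehavioralSequence.observed_span` (event-recorder convention);
    without one, the last event time is taken as the span.
    """
    path = Path(path)
    text = path.read_text()
    delim = _sniff_delimiter(text)
    scale = {"s": 1.0, "ms": 1e-3}.get(time_unit)
    if scale is None:
        raise ValueError(f"time_unit must be 's' or 'ms', got {time_unit!r}")

    rows: list[tuple[float, str]] = []
    span: float | None = None
    for lineno, row in enumerate(csv.reader(io.StringIO(text), delimiter=delim), start=1):
        row = [c.strip() for c in row if c.strip() != ""]
        if not row:
            continue
        if len(row) != 2:
            raise SequenceError(f"{path.name}:{lineno}: expected 2 columns, got {len(row)}")
        t_raw, code = row
        try:
            t = float(t_raw) * scale
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise SequenceError(f"{path.name}:{lineno}: unparseable time {t_raw!r}")
        if code == end_marker:
            span = t
            continue
        if code not in repertoire:
            raise SequenceError(f"{path.name}:{lineno}: unknown posture code {code!r}")
        rows.append((t, code))

    if not rows:
        raise SequenceError(f"{path.name}: no events")
    times = [t for t, _ in rows]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise SequenceError(f"{path.name}: event times not sorted strictly increasing")

    # Rebase wall-clock times to the window start.  Logs whose clock starts at
    # the session (times already inside [0, window)) are left untouched so
    # that write -> parse is the identity on valid files.
    shift = times[0] if times[-1] >= window_length else 0.0
    events_all = [(t - shift, code) for t, code in rows]
    raw_span = (span - shift) if span is not None else events_all[-1][0]
    events = [(t, c) for t, c in events_all if t < window_length]
    if not events:
        raise SequenceError(f"{path.name}: no events inside the observation window")
    return BehavioralSequence(
        subject_id=subject_id if subject_id is not None else path.stem,
        events=events,
        window_length=window_length,
        observed_span=raw_span,
    )


def write_focal_log(
    sequence: BehavioralSequence, path: str | Path, *, delimiter: str = ","
) -> Path:
    """Write a sequence back to the two-column dialect (inverse of parse)."""
    path = Path(path)
    lines = [f"{t!r}{delimiter}{code}" for t, code in sequence.events]
    if sequence.observed_span is not None:
        lines.append(f"{sequence.observed_span!r}{delimiter}EOF")
    path.write_text("\n".join(lines) + "\n")
    return path


def filter_complete(
    sequences: Iterable[BehavioralSequence], window_length: float = DEFAULT_WINDOW
) -> list[BehavioralSequence]:
    """Keep only sequences observed for the full window; truncate to it.

    A sequence whose observation span is shorter than ``window_length`` was
    interrupted (focal bird stopped displaying, moved off, agonistic
    interaction...) and is dropped; retained sequences have their events
    truncated to ``[0, window_length)``.
    """
    kept: list[BehavioralSequence] = []
    for seq in sequences:
        if seq.span < window_length:
            continue
        events = [(t, c) for t, c in seq.events if t < window_length]
        if not events:
            continue
        kept.append(
            BehavioralSequence(
                subject_id=seq.subject_id,
                events=events,
                window_length=window_length,
                observed_span=seq.observed_span,
            )
        )
    return kept


_METADATA_COLUMNS = ["id", "sex", "age", "date", "hour", "group_size", "year"]


def load_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the focal-metadata table (CSV).

    Required columns: id, sex (F/M), age (years), date (days since Nov 1),
    hour (decimal), group_size, year.  Returns a DataFrame indexed by id.
    """
    df = pd.read_csv(path)
    missing = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path} missing columns {missing}")
    df = df[_METADATA_COLUMNS].copy()
    df["id"] = df["id"].astype(str)
    for row in df.itertuples(index=False):
        FocalMetadata(
            subject_id=row.id, sex=row.sex, age=int(row.age), date=int(row.date),
            hour=float(row.hour), group_size=int(row.group_size), year=int(row.year),
        )
    return df.set_index("id", drop=False)
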