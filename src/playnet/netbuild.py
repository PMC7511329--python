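"""Construction of per-pen play-fighting networks from dyadic event logs.

A scored event is one play-fight initiation: an initiator directs a rapid
face-to-face push at a recipient, who either reciprocates (a successful bout)
or not.  Networks are built from reciprocated bouts only, in four variants:
directed or undirected crossed with weighted (bout counts) or binary.

Event files carry one row per initiation; a reciprocated bout therefore
appears once, credited to its initiator, never once per participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Animal",
    "InteractionEvent",
    "NetworkVariant",
    "PlayNetwork",
    "read_animals",
    "read_events",
    "build_network",
    "build_all_networks",
]

#: Lesion-count time points recorded for every animal, in study order.
LESION_TIME_POINTS = ("pre_contest", "post_contest", "pre_mix", "mix_24h", "mix_3wk")

EVENT_COLUMNS = ("pen_id", "day", "initiator_id", "recipient_id", "reciprocated")

_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n"}


@dataclass(frozen=True)
class Animal:
    """One piglet with its housing, treatment and outcome metadata.

    ``attack_latency_s`` is the mean latency over two resident-intruder tests
    and is missing (None) when the animal attacked in neither test.
    ``lesion_counts`` maps the time points in :data:`LESION_TIME_POINTS`
    (plus optional extras such as a socialisation-day count) to counts.
    """

    id: str
    pen_id: str
    litter_id: str
    sex: str  # "male" | "female"
    treatment: str  # "socialised" | "control"
    batch: int = 1
    body_weight_kg: dict = field(default_factory=dict)
    attack_latency_s: float | None = None
    lesion_counts: dict = field(default_factory=dict)
    #: study-structure extras: dyad_id, weight_diff_kg, mix_pen_id
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"animal {self.id}: sex must be male/female, got {self.sex!r}")
        if self.treatment not in ("socialised", "control"):
            raise ValueError(
                f"animal {self.id}: treatment must be socialised/control, got {self.treatment!r}"
            )


@dataclass(frozen=True)
class InteractionEvent:
    """A single play-fight initiation scored from video."""

    pen_id: str
    day: int
    initiator_id: str
    recipient_id: str
    reciprocated: bool

    def __post_init__(self):
        if self.initiator_id == self.recipient_id:
            raise ValueError(
                f"self-loop event in pen {self.pen_id}: {self.initiator_id}"
            )


@dataclass(frozen=True)
class NetworkVariant:
    """Which of the four network variants an adjacency represents."""

    directed: bool = False
    weighted: bool = False

    def label(self) -> str:
        d = "directed" if self.directed else "undirected"
        w = "weighted" if self.weighted else "binary"
        return f"{d}_{w}"

    @classmethod
    def parse(cls, text: str) -> "NetworkVariant":
        """Parse e.g. ``"directed,weighted"`` or ``"undirected_binary"``."""
        parts = {p.strip().lower() for p in text.replace("_", ",").split(",") if p.strip()}
        unknown = parts - {"directed", "undirected", "weighted", "binary", "unweighted"}
        if unknown:
            raise ValueError(f"unknown variant terms: {sorted(unknown)}")
        return cls(
            directed="directed" in parts,
            weighted="weighted" in parts,
        )


@dataclass
class PlayNetwork:
    """Per-pen adjacency over the full pen roster.

    Entries are reciprocated-bout counts (weighted) or 0/1 (binary).  The
    directed entry (i, j) counts bouts initiated by i toward j; the
    undirected weight of a dyad is the dyad's total bout count regardless
    of initiator.  Animals that never played remain as degree-0 nodes.
    """

    pen_id: str
    variant: NetworkVariant
    nodes: list
    adjacency: np.ndarray

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node list")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency must have zero diagonal")
        if not self.variant.directed and not np.allclose(self.adjacency, self.adjacency.T):
            raise ValueError("undirected adjacency must be symmetric")
        if not self.variant.weighted:
            vals = np.unique(self.adjacency)
            if not np.all(np.isin(vals, [0.0, 1.0])):
                raise ValueError("binary adjacency must contain only 0/1")

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, animal_id: str) -> int:
        return self.nodes.index(animal_id)

    def binarised(self) -> "PlayNetwork":
        return PlayNetwork(
            pen_id=self.pen_id,
            variant=NetworkVariant(self.variant.directed, weighted=False),
            nodes=list(self.nodes),
            adjacency=(self.adjacency > 0).astype(float),
        )

    def undirected(self) -> "PlayNetwork":
        if not self.variant.directed:
            return self
        a = self.adjacency + self.adjacency.T
        if not self.variant.weighted:
            a = (a > 0).astype(float)
        return PlayNetwork(
            pen_id=self.pen_id,
            variant=NetworkVariant(False, self.variant.weighted),
            nodes=list(self.nodes),
            adjacency=a,
        )

    def edge_list(self) -> pd.DataFrame:
        """Weighted edge list (columns from,to,weight); one row per dyad
        when undirected (i < j), one per ordered pair when directed."""
        rows = []
        a = self.adjacency
        for i in range(self.n):
            js = range(self.n) if self.variant.directed else range(i + 1, self.n)
            for j in js:
                if a[i, j] > 0:
                    rows.append((self.nodes[i], self.nodes[j], a[i, j]))
        return pd.DataFrame(rows, columns=["from", "to", "weight"])


class EventParseError(ValueError):
    """Malformed event row; carries the 1-based line number."""


class ReferentialIntegrityError(ValueError):
    """Event references an animal id absent from the metadata table."""


def _parse_bool(raw, line_no: int) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise EventParseError(f"line {line_no}: cannot parse reciprocated flag {raw!r}")


def read_events(path, animals: list[Animal] | None = None) -> list[InteractionEvent]:
    """Read a delimited event log (one row per initiation).

    The file must be CSV or TSV with a header naming the five fields
    ``pen_id, day, initiator_id, recipient_id, reciprocated``.  If
    ``animals`` is given, every referenced id must appear in it.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise EventParseError(f"event file missing columns: {sorted(missing)}")
    known = {a.id for a in animals} if animals is not None else None
    events = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        try:
            day = int(str(getattr(row, "day")).strip())
        except ValueError:
            raise EventParseError(f"line {line_no}: day {getattr(row, 'day')!r} is not an integer") from None
        init = str(row.initiator_id).strip()
        recip = str(row.recipient_id).strip()
        if known is not None:
            unknown = {i for i in (init, recip) if i not in known}
            if unknown:
                raise ReferentialIntegrityError(
                    f"line {line_no}: unknown animal id(s) {sorted(unknown)}"
                )
        try:
            ev = InteractionEvent(
                pen_id=str(row.pen_id).strip(),
                day=day,
                initiator_id=init,
                recipient_id=recip,
                reciprocated=_parse_bool(row.reciprocated, line_no),
            )
        except ValueError as exc:
            raise EventParseError(f"line {line_no}: {exc}") from None
        events.append(ev)
    return events


def read_animals(path) -> list[Animal]:
    """Read the animal metadata CSV.

    Required columns: ``id, pen_id, litter_id, sex, treatment``.  Optional:
    ``batch``, ``attack_latency_s`` (blank = missing), ``weight_<tp>_kg``
    and ``lesions_<tp>`` columns for any time point.
    """
    df = pd.read_csv(path, dtype={"id": str, "pen_id": str, "litter_id": str})
    required = {"id", "pen_id", "litter_id", "sex", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"animal file missing columns: {sorted(missing)}")
    weight_cols = [c for c in df.columns if c.startswith("weight_") and c.endswith("_kg")]
    lesion_cols = [c for c in df.columns if c.startswith("lesions_")]
    animals = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        lat = d.get("attack_latency_s")
        lat = None if lat is None or (isinstance(lat, float) and np.isnan(lat)) else float(lat)
        weights = {
            c[len("weight_"):-len("_kg")]: float(d[c])
            for c in weight_cols
            if not pd.isna(d[c])
        }
        lesions = {
            c[len("lesions_"):]: int(d[c]) for c in lesion_cols if not pd.isna(d[c])
        }
        extra = {
            c: d[c]
            for c in ("dyad_id", "mix_pen_id", "weight_diff_kg")
            if c in df.columns and not pd.isna(d[c])
        }
        animals.append(
            Animal(
                id=str(d["id"]),
                pen_id=str(d["pen_id"]),
                litter_id=str(d["litter_id"]),
                sex=str(d["sex"]),
                treatment=str(d["treatment"]),
                batch=int(d.get("batch", 1)),
                body_weight_kg=weights,
                attack_latency_s=lat,
                lesion_counts=lesions,
                extra=extra,
            )
        )
    ids = [a.id for a in animals]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate animal ids in metadata")
    _check_pen_litters(animals)
    return animals


def _check_pen_litters(animals: list[Animal]) -> None:
    pens: dict[str, tuple[str, set]] = {}
    for a in animals:
        treat, litters = pens.setdefault(a.pen_id, (a.treatment, set()))
        if treat != a.treatment:
            raise ValueError(f"pen {a.pen_id}: mixed treatments")
        litters.add(a.litter_id)
    for pen_id, (treat, litters) in pens.items():
        expected = 2 if treat == "socialised" else 1
        if len(litters) != expected:
            raise ValueError(
                f"pen {pen_id} ({treat}) has {len(litters)} litters, expected {expected}"
            )


def build_network(
    events: list[InteractionEvent],
    animals: list[Animal],
    pen_id: str,
    variant: NetworkVariant,
) -> PlayNetwork:
    """Aggregate reciprocated bouts of one pen into an adjacency matrix.

    Only reciprocated events contribute edges.  Events tagged with another
    pen are excluded with a warning; the node set is the full pen roster
    (isolated animals kept) so per-pen normalisation is well-defined.
    """
    roster = [a.id for a in animals if a.pen_id == pen_id]
    if not roster:
        raise ValueError(f"pen {pen_id}: no animals in metadata")
    idx = {aid: i for i, aid in enumerate(roster)}
    n = len(roster)
    directed = np.zeros((n, n))
    n_foreign = 0
    for ev in events:
        if ev.pen_id != pen_id:
            continue
        if ev.initiator_id not in idx or ev.recipient_id not in idx:
            n_foreign += 1
            continue
        if ev.reciprocated:
            directed[idx[ev.initiator_id], idx[ev.recipient_id]] += 1
    if n_foreign:
        warnings.warn(
            f"pen {pen_id}: excluded {n_foreign} event(s) referencing animals outside the pen",
            stacklevel=2,
        )
    a = directed if variant.directed else directed + directed.T
    if not variant.weighted:
        a = (a > 0).astype(float)
    return PlayNetwork(pen_id=pen_id, variant=variant, nodes=roster, adjacency=a)


def build_all_networks(
    events: list[InteractionEvent],
    animals: list[Animal],
    variant: NetworkVariant,
) -> dict[str, PlayNetwork]:
    """One network per pen, in pen-id sorted order."""
    pens = sorted({a.pen_id for a in animals})
    return {p: build_network(events, animals, p, variant) for p in pens}
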