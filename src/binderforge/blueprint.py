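"""Ferredoxin (EHEEHE) blueprint representation, enumeration and ranking.

A blueprint lists the secondary-structure segments of a βαββαβ ferredoxin
fold in sequence order::

    E1 L1 H1 L2 E2 L3 E3 L4 H2 L5 E4

Strands (E) and helices (H) carry only a residue length; loops (L)
additionally carry an ABEGO string — one torsion-bin letter per residue —
that constrains loop backbone geometry.  Blueprints are enumerated as the
Cartesian product of the most frequently observed options in a topology
survey (loop ABEGO strings, helix lengths, strand-pairing arrangements)
and ranked by a joint log-frequency score.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "ABEGO_LABELS",
    "ELEMENT_ORDER",
    "LOOP_IDS",
    "HELIX_IDS",
    "STRAND_IDS",
    "TorsionTriple",
    "SegmentSpec",
    "Blueprint",
    "TopologyStats",
    "classify_abego",
    "normalize_angle",
    "enumerate_blueprints",
    "rank_and_select_blueprints",
    "blueprints_to_jsonl",
    "blueprints_from_jsonl",
    "blueprint_to_text",
    "blueprint_from_text",
]

ABEGO_LABELS = ("A", "B", "E", "G", "O")

#: Segment order along the chain for the EHEEHE ferredoxin fold.
ELEMENT_ORDER = ("E1", "L1", "H1", "L2", "E2", "L3", "E3", "L4", "H2", "L5", "E4")
LOOP_IDS = ("L1", "L2", "L3", "L4", "L5")
HELIX_IDS = ("H1", "H2")
STRAND_IDS = ("E1", "E2", "E3", "E4")


def normalize_angle(angle: float) -> float:
    """Map an angle in degrees onto the half-open interval [-180, 180)."""
    a = math.fmod(float(angle) + 180.0, 360.0)
    if a < 0:
        a += 360.0
    return a - 180.0


@dataclass(frozen=True)
class TorsionTriple:
    """Backbone torsions (φ, ψ, ω) of one residue, degrees in [-180, 180)."""

    phi: float
    psi: float
    omega: float = 180.0 - 1e-9  # trans; kept inside the half-open interval

    def __post_init__(self):
        for name in ("phi", "psi", "omega"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"non-finite torsion angle {name}={v!r}")
            object.__setattr__(self, name, normalize_angle(v))


def classify_abego(t: TorsionTriple) -> str:
    """Assign the ABEGO torsion-bin letter of one residue.

    Bins: ``O`` cis peptide (|ω| < 90°); ``A`` helical (φ<0, −75≤ψ<50);
    ``B`` extended (φ<0 otherwise); ``G`` left-handed helical
    (φ≥0, −100<ψ≤100); ``E`` left-handed extended (φ≥0 otherwise).
    The function is total: every finite triple maps to exactly one letter.
    """
    if abs(t.omega) < 90.0:
        return "O"
    if t.phi < 0.0:
        return "A" if -75.0 <= t.psi < 50.0 else "B"
    return "G" if -100.0 < t.psi <= 100.0 else "E"


@dataclass(frozen=True)
class SegmentSpec:
    """One secondary-structure segment of a blueprint."""

    element_id: str
    ss_type: str  # E, H or L
    length: int
    abego: str = ""

    def __post_init__(self):
        if self.element_id not in ELEMENT_ORDER:
            raise InvalidInputError(f"unknown element id {self.element_id!r}")
        if self.ss_type not in ("E", "H", "L"):
            raise InvalidInputError(f"unknown ss type {self.ss_type!r}")
        if self.length < 1:
            raise InvalidInputError("segment length must be >= 1")
        if self.ss_type == "L":
            if len(self.abego) != self.length:
                raise InvalidInputError(
                    f"loop {self.element_id}: abego string {self.abego!r} "
                    f"does not match length {self.length}"
                )
            bad = set(self.abego) - set(ABEGO_LABELS)
            if bad:
                raise InvalidInputError(f"invalid abego letters {sorted(bad)}")
        elif self.abego:
            raise InvalidInputError("strands/helices carry no abego string")

    def as_text(self) -> str:
        abego = self.abego if self.ss_type == "L" else "-"
        return f"{self.element_id} {self.ss_type} {self.length} {abego}"


@dataclass(frozen=True)
class Blueprint:
    """An ordered segment list plus sheet arrangement and occurrence score."""

    segments: tuple[SegmentSpec, ...]
    sheet_combination_id: str
    score: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(self.segments))
        pattern = "".join(s.ss_type for s in self.segments if s.ss_type != "L")
        if pattern != "EHEEHE":
            raise InvalidInputError(
                f"non-loop secondary structure pattern {pattern!r} != 'EHEEHE'"
            )

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def segment(self, element_id: str) -> SegmentSpec:
        for s in self.segments:
            if s.element_id == element_id:
                return s
        raise KeyError(element_id)

    def key(self) -> str:
        """Canonical text key used for deterministic tie-breaking."""
        return "|".join(s.as_text() for s in self.segments) + f"|{self.sheet_combination_id}"

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"element_id": s.element_id, "ss_type": s.ss_type,
                 "length": s.length, "abego": s.abego}
                for s in self.segments
            ],
            "sheet_combination_id": self.sheet_combination_id,
            "score": self.score,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Blueprint":
        segs = tuple(SegmentSpec(**s) for s in d["segments"])
        return cls(segments=segs, sheet_combination_id=d["sheet_combination_id"],
                   score=float(d.get("score", 0.0)))


@dataclass
class TopologyStats:
    """Occurrence statistics of fold options from a topology survey.

    ``loop_abego_counts`` maps each loop id to ``{abego_string: count}``;
    ``helix_length_counts`` maps each helix id to ``{length: count}``;
    ``sheet_combination_counts`` maps strand-arrangement ids to counts;
    ``strand_length_defaults`` fixes each strand's residue count.
    """

    loop_abego_counts: dict[str, dict[str, int]]
    helix_length_counts: dict[str, dict[int, int]]
    sheet_combination_counts: dict[str, int]
    strand_length_defaults: dict[str, int] = field(
        default_factory=lambda: {"E1": 5, "E2": 5, "E3": 5, "E4": 5})

    def __post_init__(self):
        for loop, table in self.loop_abego_counts.items():
            if not any(c > 0 for c in table.values()):
                raise ConfigurationError(f"loop {loop} has no positive count")
            if any(c < 0 for c in table.values()):
                raise ConfigurationError(f"loop {loop} has a negative count")
        for table in (*self.helix_length_counts.values(),
                      self.sheet_combination_counts):
            if any(c < 0 for c in table.values()):
                raise ConfigurationError("negative occurrence count")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for loop, table in sorted(self.loop_abego_counts.items()):
            rows += [(loop, opt, c) for opt, c in sorted(table.items())]
        for helix, table in sorted(self.helix_length_counts.items()):
            rows += [(helix, str(length), c) for length, c in sorted(table.items())]
        rows += [("SHEET", combo, c)
                 for combo, c in sorted(self.sheet_combination_counts.items())]
        rows += [(strand, str(length), 1)
                 for strand, length in sorted(self.strand_length_defaults.items())]
        return pd.DataFrame(rows, columns=["element", "option", "count"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TopologyStats":
        missing = {"element", "option", "count"} - set(df.columns)
        if missing:
            raise ConfigurationError(f"stats table missing columns {sorted(missing)}")
        loops: dict[str, dict[str, int]] = {}
        helices: dict[str, dict[int, int]] = {}
        sheets: dict[str, int] = {}
        strands: dict[str, int] = {}
        for element, option, count in df[["element", "option", "count"]].itertuples(index=False):
            count = int(count)
            if element in LOOP_IDS:
                loops.setdefault(element, {})[str(option)] = count
            elif element in HELIX_IDS:
                helices.setdefault(element, {})[int(option)] = count
            elif element == "SHEET":
                sheets[str(option)] = count
            elif element in STRAND_IDS:
                strands[element] = int(option)
            else:
                raise ConfigurationError(f"unknown element {element!r} in stats table")
        kwargs = {}
        if strands:
            kwargs["strand_length_defaults"] = strands
        return cls(loops, helices, sheets, **kwargs)

    @classmethod
    def from_csv(cls, path) -> "TopologyStats":
        return cls.from_frame(pd.read_csv(path))


def _top_options(table: Mapping, n: int, what: str) -> list[tuple[object, float]]:
    """Select the n most frequent options; returns (option, log frequency).

    Ties on count break lexicographically on the option's text form so the
    selection is deterministic.
    """
    if len(table) < n:
        raise ConfigurationError(
            f"{what}: requested top {n} options but only {len(table)} available")
    total = sum(table.values())
    items = sorted(table.items(), key=lambda kv: (-kv[1], str(kv[0])))[:n]
    return [(opt, math.log(cnt / total)) for opt, cnt in items if cnt > 0] or []


def enumerate_blueprints(
    stats: TopologyStats,
    n_abego_per_loop: int = 5,
    n_lengths_per_helix: int = 4,
    n_sheet_combos: int = 5,
) -> list[Blueprint]:
    """Enumerate the full Cartesian product of top-ranked fold options.

    With the defaults (5 ABEGO strings per loop, 4 lengths per helix, 5
    sheet combinations) this yields 5^5 x 4^2 x 5 = 250,000 blueprints.
    Each blueprint is scored as the sum of log occurrence frequencies of
    its chosen options, treating the factors as independent; the returned
    list is sorted score-descending, ties broken lexicographically on the
    blueprint's canonical segment text.
    """
    for loop in LOOP_IDS:
        if loop not in stats.loop_abego_counts:
            raise ConfigurationError(f"stats table lacks loop {loop}")
    for helix in HELIX_IDS:
        if helix not in stats.helix_length_counts:
            raise ConfigurationError(f"stats table lacks helix {helix}")
    for strand in STRAND_IDS:
        if strand not in stats.strand_length_defaults:
            raise ConfigurationError(f"stats table lacks strand {strand}")

    loop_opts = {
        loop: [
            (SegmentSpec(loop, "L", len(abego), abego), logf)
            for abego, logf in _top_options(
                stats.loop_abego_counts[loop], n_abego_per_loop, loop)
        ]
        for loop in LOOP_IDS
    }
    helix_opts = {
        helix: [
            (SegmentSpec(helix, "H", length), logf)
            for length, logf in _top_options(
                stats.helix_length_counts[helix], n_lengths_per_helix, helix)
        ]
        for helix in HELIX_IDS
    }
    sheet_opts = _top_options(stats.sheet_combination_counts, n_sheet_combos, "SHEET")
    strand_segs = {
        strand: SegmentSpec(strand, "E", stats.strand_length_defaults[strand])
        for strand in STRAND_IDS
    }

    # Shared frozen SegmentSpec instances keep 250k blueprints lightweight.
    varying = [loop_opts[e] if e in LOOP_IDS else helix_opts[e]
               for e in ELEMENT_ORDER if e not in STRAND_IDS]
    varying_ids = [e for e in ELEMENT_ORDER if e not in STRAND_IDS]

    blueprints: list[Blueprint] = []
    for combo in itertools.product(*varying, sheet_opts):
        *segment_choices, (sheet_id, sheet_logf) = combo
        score = sheet_logf + sum(logf for _, logf in segment_choices)
        chosen = dict(zip(varying_ids, (seg for seg, _ in segment_choices)))
        segments = tuple(
            strand_segs[e] if e in STRAND_IDS else chosen[e] for e in ELEMENT_ORDER
        )
        blueprints.append(Blueprint(segments, str(sheet_id), score))
    blueprints.sort(key=lambda bp: (-bp.score, bp.key()))
    return blueprints


def rank_and_select_blueprints(blueprints: list[Blueprint], top_k: int) -> list[Blueprint]:
    """Return the top_k blueprints by score (desc), ties lexicographic.

    Idempotent: re-selecting top_k from an already selected set returns it
    unchanged.
    """
    if top_k > len(blueprints):
        raise InvalidInputError(
            f"top_k={top_k} exceeds the {len(blueprints)} available blueprints")
    ranked = sorted(blueprints, key=lambda bp: (-bp.score, bp.key()))
    return ranked[:top_k]


# ---------------------------------------------------------------------------
# serialization

def blueprints_to_jsonl(blueprints: Iterable[Blueprint], path) -> None:
    with open(path, "w") as fh:
        for bp in blueprints:
            fh.write(json.dumps(bp.to_dict(), sort_keys=True) + "\n")


def blueprints_from_jsonl(path) -> list[Blueprint]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(Blueprint.from_dict(json.loads(line)))
    return out


def blueprint_to_text(bp: Blueprint) -> str:
    """Plain-text blueprint dialect: one 'element ss length abego' line per
    segment, with a trailing SHEET line carrying the arrangement id."""
    lines = [s.as_text() for s in bp.segments]
    lines.append(f"SHEET - 0 {bp.sheet_combination_id}")
    return "\n".join(lines) + "\n"


def blueprint_from_text(text: str) -> Blueprint:
    segments = []
    sheet_id = "unspecified"
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, ss, length, abego = line.split()
        if element == "SHEET":
            sheet_id = abego
            continue
        segments.append(SegmentSpec(element, ss, int(length),
                                    "" if abego == "-" else abego))
    return Blueprint(tuple(segments), sheet_id)
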