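"""Activity catalogue and the timed collection protocol.

The study protocol records eight two-minute runs, one per *action group* (the
base hand grip family: hammer, tip pinch, 3-jaw chuck, key, scissors, door
knob, jar lid, ball).  Each run holds twelve 10-second repetitions of the
group's grip plus its follow-on movements, starting at seconds 5, 15, ..., 115,
with neutral/rest (NR) filling the first five seconds and the tail of every
repetition.  Together the eight rows cover 24 grip/movement classes plus NR,
a 25-class problem.

Some one-second slots in the script were performed inconsistently by subjects
(the grip may already have been released); those are *hybrid* slots such as
``HG/NR`` and are represented explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ACTIVITIES",
    "CLASS_CODES",
    "CLASS_INDEX",
    "GROUPS",
    "GROUP_GRIP",
    "NR",
    "HybridSlot",
    "ProtocolSchedule",
    "make_schedule",
]

NR = "NR"

#: (group, code, description) in catalogue order; NR is the shared 25th class.
ACTIVITIES: list[tuple[str, str, str]] = [
    ("hammer", "HG", "hammer grip"),
    ("hammer", "HR", "hammer raise"),
    ("hammer", "HGR", "hammer grip - raised pos."),
    ("hammer", "HL", "hammer lower"),
    ("tip pinch", "TPG", "tip pinch grip"),
    ("tip pinch", "TPR", "tip pinch raise"),
    ("tip pinch", "TPL", "tip pinch lower"),
    ("3-jaw chuck", "3JCG", "3-jaw chuck grip"),
    ("3-jaw chuck", "3JCR", "3-jaw chuck raise"),
    ("3-jaw chuck", "3JCL", "3-jaw chuck lower"),
    ("key", "KG", "key grip"),
    ("key", "KTS", "key turn - supination"),
    ("key", "KTP", "key turn - pronation"),
    ("scissors", "SCG", "scissors grip"),
    ("scissors", "SCO", "scissors open"),
    ("scissors", "SCC", "scissors close"),
    ("door knob", "DKG", "door knob grip"),
    ("door knob", "DKS", "door knob turn - supination"),
    ("door knob", "DKP", "door knob turn - pronation"),
    ("jar lid", "JLG", "jar lid grip"),
    ("jar lid", "JLS", "jar lid turn - supination"),
    ("jar lid", "JLP", "jar lid turn - pronation"),
    ("ball", "BG", "ball grip"),
    ("ball", "BSQ", "ball squeeze"),
    ("all", NR, "neutral/rest"),
]

CLASS_CODES: list[str] = [code for _, code, _ in ACTIVITIES]
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASS_CODES)}

GROUPS: list[str] = [
    "hammer",
    "tip pinch",
    "3-jaw chuck",
    "key",
    "scissors",
    "door knob",
    "jar lid",
    "ball",
]

#: base grip code of each group
GROUP_GRIP: dict[str, str] = {
    "hammer": "HG",
    "tip pinch": "TPG",
    "3-jaw chuck": "3JCG",
    "key": "KG",
    "scissors": "SCG",
    "door knob": "DKG",
    "jar lid": "JLG",
    "ball": "BG",
}


@dataclass(frozen=True)
class HybridSlot:
    """A one-second slot performed inconsistently: either ``activity`` or NR."""

    activity: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.activity}/{NR}"


# Per-repetition scripts: ten one-second slots, offsets 0..9 from repetition
# start.  Offsets 6..9 are always NR (5..9 for the ball group).
_REP_CODES: dict[str, list[object]] = {
    "hammer": ["HG", "HG", HybridSlot("HG"), "HR", "HGR", "HL", NR, NR, NR, NR],
    "tip pinch": ["TPG", "TPG", HybridSlot("TPG"), "TPR", HybridSlot("TPR"), "TPL", NR, NR, NR, NR],
    "3-jaw chuck": ["3JCG", "3JCG", HybridSlot("3JCG"), "3JCR", HybridSlot("3JCR"), "3JCL", NR, NR, NR, NR],
    "key": ["KG", "KG", HybridSlot("KG"), "KTS", NR, "KTP", NR, NR, NR, NR],
    "scissors": ["SCG", "SCG", HybridSlot("SCG"), "SCO", HybridSlot("SCO"), "SCC", NR, NR, NR, NR],
    "door knob": ["DKG", "DKG", HybridSlot("DKG"), "DKS", NR, "DKP", NR, NR, NR, NR],
    "jar lid": ["JLG", "JLG", HybridSlot("JLG"), "JLP", HybridSlot("JLP"), "JLS", NR, NR, NR, NR],
    "ball": ["BG", "BG", HybridSlot("BG"), "BSQ", "BSQ", NR, NR, NR, NR, NR],
}


@dataclass(frozen=True)
class ProtocolSchedule:
    """Timed script of one collection run for one action group."""

    group_id: str
    rep_count: int = 12
    rep_duration: float = 10.0
    run_duration: float = 120.0
    first_rep_start: float = 5.0
    per_second_codes: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        starts = self.rep_starts
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("repetition starts must be strictly increasing")
        if starts and starts[-1] >= self.run_duration:
            raise ValueError("repetition starts must lie inside the run")
        for code in self.per_second_codes:
            base = code.activity if isinstance(code, HybridSlot) else code
            if base not in CLASS_INDEX:
                raise ValueError(f"unknown activity code {base!r}")

    @property
    def rep_starts(self) -> list[float]:
        return [
            self.first_rep_start + k * self.rep_duration for k in range(self.rep_count)
        ]

    @property
    def grip_code(self) -> str:
        return GROUP_GRIP[self.group_id]

    def rep_index_at(self, t: float) -> int:
        """1-based repetition index containing time ``t`` (0 before first rep)."""
        if t < self.first_rep_start:
            return 0
        return min(int((t - self.first_rep_start) // self.rep_duration) + 1, self.rep_count)

    def nominal_intervals(self, hybrid_as_activity: bool = True) -> list[tuple[str, float, float]]:
        """(code, onset_s, offset_s) intervals tiling [0, run_duration].

        Hybrid slots resolve to their first-named activity by default, or to NR
        when ``hybrid_as_activity`` is False.  Consecutive equal codes merge.
        """
        # one code per second of the run
        seconds: list[str] = [NR] * int(self.run_duration)
        for start in self.rep_starts:
            for off, code in enumerate(self.per_second_codes):
                s = int(start) + off
                if s >= len(seconds):
                    break
                if isinstance(code, HybridSlot):
                    seconds[s] = code.activity if hybrid_as_activity else NR
                else:
                    seconds[s] = code
        out: list[tuple[str, float, float]] = []
        for s, code in enumerate(seconds):
            if out and out[-1][0] == code and out[-1][2] == float(s):
                out[-1] = (code, out[-1][1], float(s + 1))
            else:
                out.append((code, float(s), float(s + 1)))
        # close at exact run duration
        if out[-1][2] != self.run_duration:
            last = out[-1]
            out[-1] = (last[0], last[1], self.run_duration)
        return out


def make_schedule(group_id: str) -> ProtocolSchedule:
    """Build the timed script for one of the eight action groups."""
    if group_id not in _REP_CODES:
        raise ValueError(
            f"unknown action group {group_id!r}; valid groups: {', '.join(GROUPS)}"
        )
    return ProtocolSchedule(group_id=group_id, per_second_codes=tuple(_REP_CODES[group_id]))
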