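"""Clinical-trial phase grouping.

Free-text phase labels (as found in trial registries) are collapsed into
five groups: Phase I, Phase II, Phase III, Indicated (Phase IV / approved
use), and Unknown.  Combination labels collapse to the more advanced phase
("Phase 2/Phase 3" is a Phase III trial).  Matching is case-insensitive
and tolerant of roman vs. arabic numeral spellings.
"""

from __future__ import annotations

import enum
import re

__all__ = ["PhaseGroup", "group_phase", "phase_rank"]


class PhaseGroup(enum.Enum):
    """Grouped drug-development phase for a (drug, disease) pair."""

    PHASE_I = "Phase 1"
    PHASE_II = "Phase 2"
    PHASE_III = "Phase 3"
    UNKNOWN = "Unknown"
    INDICATED = "Indicated"

    @property
    def label(self) -> str:
        return self.value

    @property
    def ordered(self) -> bool:
        """Whether the group participates in the advancement order."""
        return self is not PhaseGroup.UNKNOWN


# Advancement order; UNKNOWN sits below every known phase so that any
# informative record wins when duplicates are collapsed to the maximum.
_RANK = {
    PhaseGroup.UNKNOWN: 0,
    PhaseGroup.PHASE_I: 1,
    PhaseGroup.PHASE_II: 2,
    PhaseGroup.PHASE_III: 3,
    PhaseGroup.INDICATED: 4,
}


def phase_rank(phase: PhaseGroup) -> int:
    """Advancement rank used to collapse duplicate evidence records."""
    return _RANK[phase]


_ROMAN = [(r"\biv\b", "4"), (r"\biii\b", "3"), (r"\bii\b", "2"), (r"\bi\b", "1")]

_LOOKUP = {
    "early phase 1": PhaseGroup.PHASE_I,
    "phase 1": PhaseGroup.PHASE_I,
    "phase 1/phase 2": PhaseGroup.PHASE_II,
    "phase 2": PhaseGroup.PHASE_II,
    "phase 2/phase 3": PhaseGroup.PHASE_III,
    "phase 3": PhaseGroup.PHASE_III,
    "phase 4": PhaseGroup.INDICATED,
    "indicated": PhaseGroup.INDICATED,
    "unknown": PhaseGroup.UNKNOWN,
}


def _normalize(raw: str) -> str:
    s = raw.strip().lower()
    for pattern, digit in _ROMAN:
        s = re.sub(pattern, digit, s)
    s = re.sub(r"\s*/\s*", "/", s)
    s = re.sub(r"phase\s*(\d)", r"phase \1", s)
    s = re.sub(r"\s+", " ", s)
    return s


def group_phase(raw_phase: str) -> PhaseGroup:
    """Map a free-text phase label to its :class:`PhaseGroup`.

    Total function: any unrecognised label (including the empty string,
    meaning no phase information) maps to ``PhaseGroup.UNKNOWN``.
    Idempotent on the canonical labels of the groups themselves.
    """
    return _LOOKUP.get(_normalize(raw_phase), PhaseGroup.UNKNOWN)
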