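"""The nine stereotyped Morris Water Maze exploration strategies.

Two-letter codes follow the field's usual abbreviations: wall hugging
(thigmotaxis) through to a direct run onto the platform.  ``UNDEFINED`` is a
sentinel for segments or intervals that no classifier, or a tied vote, could
place; it is never a valid expert label.
"""

from __future__ import annotations

import enum


class StrategyClass(enum.Enum):
    TT = "TT"   # thigmotaxis: moves on the arena periphery, touching the wall
    IC = "IC"   # incursion: wall-bound swimming with inward excursions
    SC = "SC"   # scanning: random search focused on the arena centre
    FS = "FS"   # focused search: active search of one small region
    CR = "CR"   # chaining response: circles at the platform-to-wall distance
    SO = "SO"   # self orienting: performs a loop to orient itself
    SS = "SS"   # scanning surroundings: crosses close to the platform, departs
    ST = "ST"   # target scanning: searches around the platform position
    DF = "DF"   # direct finding: navigates straight to the platform
    UNDEFINED = "--"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The closed set of classes an expert may assign (excludes UNDEFINED).
LABELLABLE: tuple[StrategyClass, ...] = tuple(
    c for c in StrategyClass if c is not StrategyClass.UNDEFINED
)

#: Stable integer codes used for vectorised vote counting.
CLASS_INDEX: dict[StrategyClass, int] = {c: i for i, c in enumerate(LABELLABLE)}
UNDEFINED_INDEX: int = len(LABELLABLE)
INDEX_CLASS: dict[int, StrategyClass] = {i: c for c, i in CLASS_INDEX.items()}
INDEX_CLASS[UNDEFINED_INDEX] = StrategyClass.UNDEFINED


def parse_strategy(code: str) -> StrategyClass:
    """Parse a two-letter strategy code, rejecting anything else."""
    code = code.strip().upper()
    try:
        cls = StrategyClass(code)
    except ValueError:
        valid = ", ".join(c.value for c in LABELLABLE)
        raise ValueError(f"unknown strategy code {code!r}; valid codes: {valid}") from None
    if cls is StrategyClass.UNDEFINED:
        valid = ", ".join(c.value for c in LABELLABLE)
        raise ValueError(f"UNDEFINED is not a valid label; valid codes: {valid}")
    return cls
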