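"""Declarations of multi-item ordinal outcome profiles.

A *profile* is the set of M target items a cohort model predicts in
parallel: each item has an ordered set of level codes and is either a
binary or a multinomial prediction task.  Two fixture profiles mirror the
standard clinical instruments this package targets: the 10-item Barthel
Index (BI, activities of daily living, items on 2/3/4-point scales coded
in steps of 5, total score 0-100) and the EQ-5D-3L quality-of-life
questionnaire (five 3-level descriptive dimensions plus the EQ-VAS
overall health score binned into 4 classes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ItemSpec:
    """One target item: a name, its ordered level codes, and output kind."""

    name: str
    levels: tuple[int, ...]
    kind: str = field(init=False)

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError(f"item {self.name!r} needs >= 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"item {self.name!r} has duplicate level codes")
        object.__setattr__(self, "kind", "binary" if len(self.levels) == 2 else "multinomial")

    @property
    def n_classes(self) -> int:
        return len(self.levels)

    def class_index(self, level: int) -> int:
        """Map a level code to its contiguous class index (declared order)."""
        try:
            return self.levels.index(level)
        except ValueError:
            raise ValueError(f"level {level!r} not in item {self.name!r} levels {self.levels}")


@dataclass(frozen=True)
class ProfileSpec:
    """The M >= 2 target items predicted jointly."""

    items: tuple[ItemSpec, ...]

    def __post_init__(self) -> None:
        if len(self.items) < 2:
            raise ValueError("a profile needs at least 2 items")
        if len({it.name for it in self.items}) != len(self.items):
            raise ValueError("item names must be unique")

    @property
    def M(self) -> int:
        return len(self.items)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(it.name for it in self.items)

    def item(self, name: str) -> ItemSpec:
        for it in self.items:
            if it.name == name:
                return it
        raise KeyError(name)

    def n_profiles(self, names: tuple[str, ...] | None = None) -> int:
        """Number of distinct joint level assignments over the given items."""
        items = self.items if names is None else tuple(self.item(n) for n in names)
        return math.prod(it.n_classes for it in items)


#: BI items and their scales: 2-point items are coded {0, 5}, 3-point
#: {0, 5, 10}, 4-point {0, 5, 10, 15}; per-item maxima sum to 100.
_BI_ITEMS: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("Feeding", (0, 5, 10)),
    ("Bathing", (0, 5)),
    ("Grooming", (0, 5)),
    ("Dressing", (0, 5, 10)),
    ("Bowel", (0, 5, 10)),
    ("Bladder", (0, 5, 10)),
    ("Toilet", (0, 5, 10)),
    ("Transfers", (0, 5, 10, 15)),
    ("Mobility", (0, 5, 10, 15)),
    ("Stairs", (0, 5, 10)),
)

EQ5D_DIMENSIONS = ("Mobility", "Self-care", "Activities", "Pain", "Anxiety")


def bi_profile_spec() -> ProfileSpec:
    """The 10-item Barthel Index profile (total score range 0-100)."""
    return ProfileSpec(tuple(ItemSpec(n, lv) for n, lv in _BI_ITEMS))


def eq5d_profile_spec() -> ProfileSpec:
    """EQ-5D-3L: five 3-level descriptive items plus the 4-class binned EQ-VAS."""
    items = [ItemSpec(n, (1, 2, 3)) for n in EQ5D_DIMENSIONS]
    items.append(ItemSpec("EQ-VAS", (1, 2, 3, 4)))
    return ProfileSpec(tuple(items))


def synthetic_profile_spec(M: int, n_levels: int = 3) -> ProfileSpec:
    """A generic M-item profile with identical n_levels-point items."""
    return ProfileSpec(tuple(ItemSpec(f"item_{i}", tuple(range(n_levels))) for i in range(M)))
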