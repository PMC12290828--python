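"""Nested stimulus category hierarchy.

The image set is organised in three embedded levels: 2 top-level categories
(object, scene), each split into 2 middle-level categories (animate/inanimate
for objects, indoor/outdoor for scenes), each of which branches into 4
bottom-level categories holding 12 specific image instances. The full set
therefore contains 2 x 2 x 4 x 12 = 192 leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["StimulusHierarchy", "build_hierarchy"]

# bottom-level categories per (top, middle) branch
_BOTTOM: dict[tuple[str, str], list[str]] = {
    ("object", "animate"): ["bird", "insect", "mammal", "marine_animal"],
    ("object", "inanimate"): ["food", "instrument", "tool", "vehicle"],
    ("scene", "indoor"): ["kitchen", "office", "shop", "theatre"],
    ("scene", "outdoor"): ["beach", "forest", "mountain", "street"],
}

N_INSTANCES = 12


@dataclass(frozen=True)
class StimulusHierarchy:
    """Leaf table of the 3-level nested category structure.

    Attributes
    ----------
    leaves : pandas.DataFrame
        One row per image instance with columns ``top``, ``middle``,
        ``bottom``, ``instance`` (0-based within its bottom category) and a
        unique ``image_id``.
    """

    leaves: pd.DataFrame = field(repr=False)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def counts(self, level: str) -> pd.Series:
        """Leaf counts per category at ``level`` ('top', 'middle' or 'bottom')."""
        if level not in ("top", "middle", "bottom"):
            raise ValueError(f"unknown level {level!r}")
        return self.leaves.groupby(level, observed=True).size()

    def validate(self) -> None:
        """Check the structural invariants of the nested design."""
        if self.n_leaves != 192:
            raise ValueError(f"expected 192 leaves, got {self.n_leaves}")
        if not (self.counts("top") == 96).all():
            raise ValueError("top-level categories must each hold 96 leaves")
        if not (self.counts("middle") == 48).all():
            raise ValueError("middle-level categories must each hold 48 leaves")
        if not (self.counts("bottom") == 12).all():
            raise ValueError("bottom-level categories must each hold 12 leaves")
        if self.leaves["image_id"].duplicated().any():
            raise ValueError("image ids must be unique")


def build_hierarchy() -> StimulusHierarchy:
    """Construct the full 2x2x4x12 stimulus hierarchy.

    Returns a :class:`StimulusHierarchy` whose leaf table enumerates all 192
    image identities with their label at every level.
    """
    rows = []
    image_id = 0
    for (top, middle), bottoms in _BOTTOM.items():
        for bottom in bottoms:
            for instance in range(N_INSTANCES):
                rows.append(
                    {
                        "image_id": image_id,
                        "top": top,
                        "middle": middle,
                        "bottom": bottom,
                        "instance": instance,
                    }
                )
                image_id += 1
    leaves = pd.DataFrame(rows)
    hier = StimulusHierarchy(leaves=leaves)
    hier.validate()
    return hier
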