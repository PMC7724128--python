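"""List designs for item-count (list experiment) surveys.

A list is a set of J non-sensitive statements; treated respondents receive
the same statements plus the sensitive one and report only the total count
they agree with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


@dataclass(frozen=True)
class ListDesign:
    """A single non-sensitive item list.

    Parameters
    ----------
    list_id :
        Label for the list, conventionally ``"A"`` or ``"B"``.
    item_probs :
        Per-item population agreement probabilities, one per non-sensitive
        statement (length J, J >= 2).
    sensitive_position :
        Ordinal position at which the sensitive statement is read to treated
        respondents. Presentation metadata only; the count is order-free.
    """

    list_id: str
    item_probs: tuple[float, ...] = field(default=(0.9, 0.5, 0.1))
    sensitive_position: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_probs", tuple(float(p) for p in self.item_probs))
        if len(self.item_probs) < 2:
            raise ValueError("a list needs at least 2 non-sensitive items")
        if any(not 0.0 <= p <= 1.0 for p in self.item_probs):
            raise ValueError(f"item probabilities must lie in [0, 1]: {self.item_probs}")

    @property
    def n_items(self) -> int:
        """Number of non-sensitive items J."""
        return len(self.item_probs)

    @property
    def guideline_compliant(self) -> bool:
        """True when the list contains one item most respondents agree with
        (p >= 0.8) and one most disagree with (p <= 0.2), the standard
        recipe for avoiding ceiling and floor effects."""
        return max(self.item_probs) >= 0.8 and min(self.item_probs) <= 0.2


def default_designs(j: int = 3) -> tuple[ListDesign, ListDesign]:
    """Two guideline-compliant lists of ``j`` items (profile 0.9/0.5/0.1)."""
    if j == 3:
        probs: Sequence[float] = (0.9, 0.5, 0.1)
    else:
        # interpolate between a high- and a low-agreement anchor
        import numpy as np

        probs = tuple(np.linspace(0.9, 0.1, j))
    return ListDesign("A", tuple(probs)), ListDesign("B", tuple(probs))
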