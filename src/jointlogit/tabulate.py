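"""Cross-tabulation of the 2^3 joint outcome patterns and their margins."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .errors import EmptyTableError

PATTERNS = tuple(product((0, 1), repeat=3))


@dataclass
class PatternTable:
    """Counts and percentages of the 8 ordered (y1, y2, y3) patterns.

    Pattern order is (blood test, aware of HIV/AIDS, aware of campaign);
    zero-count patterns are retained.
    """

    counts: dict
    total: int = 0
    percentages: dict = field(default_factory=dict)
    n_missing_excluded: int = 0

    def __post_init__(self):
        self.counts = {p: int(self.counts.get(p, 0)) for p in PATTERNS}
        self.total = int(sum(self.counts.values()))
        if self.total == 0:
            raise EmptyTableError("pattern table has zero total count")
        self.percentages = {
            p: round(100.0 * c / self.total, 2) for p, c in self.counts.items()
        }

    @classmethod
    def from_counts(cls, counts: dict) -> "PatternTable":
        """Build directly from pattern -> count (e.g. a printed table)."""
        return cls(counts={tuple(k): v for k, v in counts.items()})

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "y1": [p[0] for p in PATTERNS],
                "y2": [p[1] for p in PATTERNS],
                "y3": [p[2] for p in PATTERNS],
                "count": [self.counts[p] for p in PATTERNS],
                "percent": [self.percentages[p] for p in PATTERNS],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_text(self) -> str:
        lines = ["y1 y2 y3      count  percent"]
        for p in PATTERNS:
            lines.append(
                f" {p[0]}  {p[1]}  {p[2]}  {self.counts[p]:9d}  {self.percentages[p]:7.2f}"
            )
        lines.append(f"total       {self.total:9d}   100.00")
        return "\n".join(lines)


def tabulate_patterns(dataset) -> PatternTable:
    """Count the 8 joint outcome patterns over complete-outcome records."""
    y = dataset.outcomes
    complete = ~np.isnan(y).any(axis=1)
    if not complete.any():
        raise EmptyTableError("all records have missing outcomes")
    yc = y[complete].astype(int)
    counts = {p: 0 for p in PATTERNS}
    keys, freq = np.unique(yc, axis=0, return_counts=True)
    for k, f in zip(keys, freq):
        counts[tuple(k)] = int(f)
    return PatternTable(
        counts=counts, n_missing_excluded=int((~complete).sum())
    )


def marginal_counts(table: PatternTable, outcome: int):
    """Marginal (count, percent to 1 dp) of one outcome from the pattern table."""
    if outcome not in (1, 2, 3):
        raise ValueError("outcome must be 1, 2, or 3")
    if table.total == 0:
        raise EmptyTableError("pattern table has zero total count")
    count = sum(c for p, c in table.counts.items() if p[outcome - 1] == 1)
    return count, round(100.0 * count / table.total, 1)
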