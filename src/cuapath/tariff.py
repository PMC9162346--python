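"""EQ-5D-3L utility scoring.

A tariff (value set) maps a 5-dimension response, each level in {1,2,3}, to a
single utility anchored at 1 for full health.  The packaged default is the UK
time-trade-off value set: a constant decrement for any dysfunction, ten
per-dimension level-2/level-3 decrements, and an extra constant when any
dimension is at level 3.  The worst state (3,3,3,3,3) scores -0.594 under
these weights.  Other value sets can be supplied as a CSV of the same terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd

DIMENSIONS = (
    "mobility",
    "selfcare",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)

__all__ = ["TariffTable", "DIMENSIONS", "score_eq5d"]


@dataclass(frozen=True)
class TariffTable:
    any_dysfunction: float
    any_level3: float
    decrements: dict[str, float]  # keys like "mobility_2"

    @classmethod
    def from_csv(cls, path_or_buf) -> "TariffTable":
        df = pd.read_csv(path_or_buf)
        vals = dict(zip(df["term"], df["value"].astype(float)))
        dec = {k: v for k, v in vals.items() if k not in ("any_dysfunction", "any_level3")}
        expected = {f"{d}_{lvl}" for d in DIMENSIONS for lvl in (2, 3)}
        missing = expected - set(dec)
        if missing:
            raise ValueError(f"tariff file missing terms: {sorted(missing)}")
        return cls(
            any_dysfunction=float(vals["any_dysfunction"]),
            any_level3=float(vals["any_level3"]),
            decrements=dec,
        )

    @classmethod
    def uk_default(cls) -> "TariffTable":
        with resources.files("cuapath.data").joinpath("uk_tariff.csv").open() as fh:
            return cls.from_csv(fh)

    @property
    def min_value(self) -> float:
        """Value of the worst state (3,3,3,3,3)."""
        return self.score((3, 3, 3, 3, 3))

    def score(self, levels) -> float | None:
        """Utility for a response; ``None`` if any dimension is blank.

        Blank is represented by None or NaN.  Levels outside {1,2,3} raise.
        """
        lv = list(levels)
        if len(lv) != 5:
            raise ValueError("EQ-5D-3L response must have 5 dimensions")
        clean: list[int | None] = []
        for x in lv:
            if x is None or (isinstance(x, float) and np.isnan(x)):
                clean.append(None)
                continue
            xi = int(x)
            if xi not in (1, 2, 3):
                raise ValueError(f"EQ-5D level must be in {{1,2,3}}, got {x!r}")
            clean.append(xi)
        if any(x is None for x in clean):
            return None  # partial questionnaires are deemed missing
        if all(x == 1 for x in clean):
            return 1.0
        u = 1.0 - self.any_dysfunction
        for dim, lvl in zip(DIMENSIONS, clean):
            if lvl > 1:
                u -= self.decrements[f"{dim}_{lvl}"]
        if any(x == 3 for x in clean):
            u -= self.any_level3
        return u

    def all_states(self) -> pd.DataFrame:
        """All 243 responses with their tariff values (profile, utility)."""
        rows = []
        for combo in product((1, 2, 3), repeat=5):
            rows.append(dict(zip(DIMENSIONS, combo)) | {"utility": self.score(combo)})
        return pd.DataFrame(rows)


def score_eq5d(levels, tariff: TariffTable | None = None) -> float | None:
    """Score one EQ-5D-3L response; missing if any dimension is blank."""
    return (tariff or TariffTable.uk_default()).score(levels)
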