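"""Water Matrix Absorbance Coordinates (WAMACS) bookkeeping.

Twelve spectral ranges C1-C12 inside the first overtone of water
(1300-1600 nm) where specific water molecular conformations absorb.  The
exact interval bounds vary between instruments and studies, so the table
ships as an overridable configuration (CSV: label, lo, hi, center,
annotation); the package guarantees only the structural invariants: exactly
12 ordered, non-overlapping intervals of 6-20 nm width inside [1300, 1600],
with C1-C3 inside 1342-1374 nm (free and weakly solvated OH), C7-C8 inside
1440-1452 nm (water hydration / dimers), and C10-C12 inside 1476-1512 nm
(strongly hydrogen-bonded water).
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import pandas as pd

__all__ = ["WAMACSTable", "default_wamacs_table"]

FIRST_OVERTONE = (1300.0, 1600.0)

_DEFAULT = """label,lo,hi,center,annotation
C1,1342,1352,1344,free OH stretch (v3)
C2,1354,1364,1360,water solvation shell OH-(H2O)n n=1..4
C3,1366,1374,1370,free OH stretch (v1+v3 asymmetric)
C4,1380,1388,1384,superoxide hydration / OH-(H2O)n
C5,1398,1418,1412,free water molecules (S0)
C6,1421,1430,1426,hydrogen-bonded water / H-OH bend
C7,1440,1446,1444,water hydration shell (S1 dimer)
C8,1446,1452,1450,water dimers / first overtone OH stretch
C9,1458,1468,1462,water solvation shell (S2)
C10,1476,1484,1480,strongly bound water (S3)
C11,1486,1496,1490,strongly bound water (S4)
C12,1500,1512,1506,strongly hydrogen-bonded water networks
"""


@dataclass
class WAMACSTable:
    entries: pd.DataFrame  # label, lo, hi, center, annotation

    def __post_init__(self) -> None:
        e = self.entries.reset_index(drop=True)
        required = {"label", "lo", "hi", "center"}
        missing = required - set(e.columns)
        if missing:
            raise ValueError(f"WAMACS table missing columns {sorted(missing)}")
        if "annotation" not in e.columns:
            e["annotation"] = ""
        if len(e) != 12:
            raise ValueError(f"WAMACS table must have exactly 12 entries, got {len(e)}")
        widths = e["hi"] - e["lo"]
        if ((widths < 6) | (widths > 20)).any():
            bad = e.loc[(widths < 6) | (widths > 20), "label"].tolist()
            raise ValueError(f"WAMACS interval widths outside 6-20 nm: {bad}")
        lo_all, hi_all = FIRST_OVERTONE
        if (e["lo"] < lo_all).any() or (e["hi"] > hi_all).any():
            raise ValueError("WAMACS intervals must lie inside [1300, 1600] nm")
        if not (e["lo"] < e["hi"]).all():
            raise ValueError("each WAMACS interval needs lo < hi")
        if not ((e["center"] >= e["lo"]) & (e["center"] <= e["hi"])).all():
            raise ValueError("WAMACS centers must lie inside their intervals")
        if (e["lo"].to_numpy()[1:] < e["hi"].to_numpy()[:-1]).any():
            raise ValueError("WAMACS intervals must be ordered and non-overlapping")
        for labels, (lo, hi) in {
            ("C1", "C2", "C3"): (1342, 1374),
            ("C7", "C8"): (1440, 1452),
            ("C10", "C11", "C12"): (1476, 1512),
        }.items():
            sub = e[e["label"].isin(labels)]
            if (sub["lo"] < lo).any() or (sub["hi"] > hi).any():
                raise ValueError(
                    f"coordinates {labels} must lie inside [{lo}, {hi}] nm"
                )
        self.entries = e

    @property
    def labels(self) -> list[str]:
        return self.entries["label"].tolist()

    @property
    def centers(self) -> list[float]:
        return self.entries["center"].astype(float).tolist()

    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.entries["lo"].astype(float),
                        self.entries["hi"].astype(float)))

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WAMACSTable":
        return cls(pd.read_csv(path))


def default_wamacs_table() -> WAMACSTable:
    """The package's default first-overtone coordinate table."""
    return WAMACSTable(pd.read_csv(StringIO(_DEFAULT)))
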