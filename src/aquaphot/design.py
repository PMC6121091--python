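"""Randomized measurement plans with interleaved environmental controls.

A plan lists the order in which samples are put in the instrument.  The
(level, replicate) pairs are randomized (seeded), and a deionized-water
control is measured before the first sample block and after every
``control_interval`` samples, so an n-sample run with controls every 5
carries floor(n/5) + 1 control positions.  Every position is scanned
``n_consecutives`` times back-to-back (consecutive spectra); controls may
use their own consecutive count via ``control_consecutives``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MeasurementPlan", "generate_measurement_plan"]


@dataclass
class MeasurementPlan:
    entries: pd.DataFrame  # position, sample_id, level, replicate, role
    n_levels: int
    n_replicates: int
    n_consecutives: int
    control_interval: int
    control_consecutives: int
    rng_seed: int

    @property
    def n_sample_entries(self) -> int:
        return int((self.entries["role"] == "sample").sum())

    @property
    def n_control_entries(self) -> int:
        return int((self.entries["role"] == "control").sum())

    @property
    def total_spectra(self) -> int:
        """Recorded spectrum count once every entry is scanned consecutively."""
        return (
            self.n_sample_entries * self.n_consecutives
            + self.n_control_entries * self.control_consecutives
        )

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def generate_measurement_plan(
    n_levels: int,
    n_replicates: int,
    n_consecutives: int,
    control_interval: int,
    rng_seed: int,
    control_consecutives: int | None = None,
    lead_control: bool = True,
) -> MeasurementPlan:
    """Seeded random acquisition order for a levels × replicates design.

    ``control_interval = 0`` disables controls entirely.  With controls on,
    a leading control opens the run (``lead_control``, default True) and one
    control follows every ``control_interval`` sample measurements, so the
    10-level × 2-replicate design with controls every 5 yields 20 sample
    entries + 5 control positions; at 3 consecutive scans per position that
    is 60 + 15 = 75 recorded spectra.
    """
    for name, v in [
        ("n_levels", n_levels),
        ("n_replicates", n_replicates),
        ("n_consecutives", n_consecutives),
    ]:
        if int(v) < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    if control_interval < 0:
        raise ValueError("control_interval must be >= 0")
    if control_consecutives is None:
        control_consecutives = n_consecutives

    rng = np.random.default_rng(rng_seed)
    pairs = [(lvl, rep) for lvl in range(1, n_levels + 1)
             for rep in range(1, n_replicates + 1)]
    order = rng.permutation(len(pairs))

    rows = []
    n_controls = 0

    def add_control() -> None:
        nonlocal n_controls
        n_controls += 1
        rows.append(
            {"sample_id": f"control_{n_controls}", "level": 0,
             "replicate": 1, "role": "control"}
        )

    if control_interval and lead_control:
        add_control()
    for i, k in enumerate(order, start=1):
        lvl, rep = pairs[k]
        rows.append(
            {"sample_id": f"L{lvl:02d}", "level": lvl,
             "replicate": rep, "role": "sample"}
        )
        if control_interval and i % control_interval == 0:
            add_control()
    entries = pd.DataFrame(rows)
    entries.insert(0, "position", np.arange(len(entries)))
    return MeasurementPlan(
        entries=entries,
        n_levels=n_levels,
        n_replicates=n_replicates,
        n_consecutives=n_consecutives,
        control_interval=control_interval,
        control_consecutives=control_consecutives,
        rng_seed=rng_seed,
    )
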