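"""Bliss-independence scoring of dose-matrix drug-combination experiments.

Under Bliss independence two drugs act as independent probabilistic events:
with single-agent inhibition fractions fa and fb, the expected combination
inhibition is e = fa + fb - fa*fb.  The Bliss excess of a well is the
observed combination inhibition minus e; positive mean excess over the
nonzero-dose grid indicates synergy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DoseMatrix", "BlissResult", "normalize_viability", "bliss_excess"]


@dataclass
class DoseMatrix:
    """Viability fractions on a dose grid; rows = doses of drug A, cols = drug B.

    Both axes must be strictly increasing and include dose 0 (single-agent
    row/column); viability at (0, 0) is 1 by normalization.
    """

    viability: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.viability
        rows = np.asarray(v.index, dtype=float)
        cols = np.asarray(v.columns, dtype=float)
        for name, axis in (("drug A", rows), ("drug B", cols)):
            if len(axis) < 2 or np.any(np.diff(axis) <= 0):
                raise ValueError(f"{name} dose axis must be strictly increasing")
            if axis[0] != 0:
                raise ValueError(f"{name} dose axis must include dose 0 first")
        self.viability = v.astype(float)

    @property
    def doses_a(self) -> np.ndarray:
        return np.asarray(self.viability.index, dtype=float)

    @property
    def doses_b(self) -> np.ndarray:
        return np.asarray(self.viability.columns, dtype=float)


@dataclass
class BlissResult:
    inhibition: pd.DataFrame      # observed per-well inhibition fab
    expected: pd.DataFrame        # Bliss expectation e = fa + fb - fa*fb
    excess: pd.DataFrame          # fab - e
    mean_excess: float            # mean over wells with both doses > 0
    synergy: bool
    tolerance: float


def normalize_viability(raw: pd.DataFrame, vehicle_wells: np.ndarray | list) -> DoseMatrix:
    """Relative viability = raw / mean(vehicle), clipped to [0, 1.05] then capped at 1.

    The cap keeps inhibition = 1 - viability within [0, 1] for the Bliss
    arithmetic; the intermediate 1.05 clip only bounds pathological wells.
    """
    vehicle = np.asarray(vehicle_wells, dtype=float)
    if vehicle.size == 0 or vehicle.mean() <= 0:
        raise ValueError("vehicle wells must have positive mean signal")
    v = raw.astype(float) / vehicle.mean()
    v = v.clip(lower=0.0, upper=1.05).clip(upper=1.0)
    v.loc[v.index[0], v.columns[0]] = 1.0
    return DoseMatrix(v)


def bliss_excess(matrix: DoseMatrix, min_excess: float = 0.05) -> BlissResult:
    """Per-well Bliss excess and mean-excess synergy call.

    fa comes from the dose-0 column of drug B (single-agent A), fb from the
    dose-0 row of drug A; the summary mean runs over wells where both doses
    are nonzero.  ``synergy`` is mean excess > ``min_excess``.
    """
    v = matrix.viability
    inhibition = 1.0 - v
    fa = inhibition.iloc[:, 0].to_numpy()   # single-agent drug A (B dose = 0)
    fb = inhibition.iloc[0, :].to_numpy()   # single-agent drug B (A dose = 0)
    expected = fa[:, None] + fb[None, :] - fa[:, None] * fb[None, :]
    expected = pd.DataFrame(expected, index=v.index, columns=v.columns)
    excess = inhibition - expected
    combo = excess.iloc[1:, 1:]
    mean_excess = float(combo.to_numpy().mean())
    return BlissResult(
        inhibition=inhibition,
        expected=expected,
        excess=excess,
        mean_excess=mean_excess,
        synergy=mean_excess > min_excess,
        tolerance=min_excess,
    )
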