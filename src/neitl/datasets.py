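"""Lifetime samples and the bundled application datasets.

Two classical uncensored-lifetime datasets are embedded verbatim:

``guinea_pigs``
    Survival times (days) of 72 guinea pigs infected with virulent
    tubercle bacilli (Bjerkedal, 1960).
``fluid_group1`` / ``fluid_group2``
    Two groups of 10 breakdown times (minutes) of an insulating fluid
    under high voltage stress (Nelson, ch. 10).  Group 1 is conventionally
    the strength sample and Group 2 the stress sample in stress-strength
    analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["LifetimeSample", "load_sample", "FIXTURES"]


@dataclass(frozen=True)
class LifetimeSample:
    """An ordered sample of strictly positive lifetimes.

    Parameters
    ----------
    values : sequence of float
        Observations, all > 0, length >= 1. Order is preserved.
    label : str
        Free-text provenance label.
    """

    values: np.ndarray
    label: str = ""

    def __init__(self, values: Sequence[float], label: str = ""):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 1:
            arr = arr.reshape(-1)
        if arr.size < 1:
            raise ValueError("a lifetime sample needs at least one observation")
        if not np.all(np.isfinite(arr)):
            raise ValueError("lifetimes must be finite")
        if np.any(arr <= 0):
            raise ValueError("lifetimes must be strictly positive")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "label", label)

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def sorted_values(self) -> np.ndarray:
        """A sorted copy, for spacing computations."""
        return np.sort(self.values)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.values)


_GUINEA_PIGS = [
    0.1, 0.33, 0.44, 0.56, 0.59, 0.59, 0.72, 0.74, 0.92, 0.93, 0.96, 1.0,
    1.0, 1.02, 1.05, 1.07, 1.07, 1.08, 1.08, 1.08, 1.09, 1.12, 1.13, 1.15,
    1.16, 1.2, 1.21, 1.22, 1.22, 1.24, 1.3, 1.34, 1.36, 1.39, 1.44, 1.46,
    1.53, 1.59, 1.6, 1.63, 1.63, 1.68, 1.71, 1.72, 1.76, 1.83, 1.95, 1.96,
    1.97, 2.02, 2.13, 2.15, 2.16, 2.22, 2.3, 2.31, 2.4, 2.45, 2.51, 2.53,
    2.54, 2.54, 2.78, 2.93, 3.27, 3.42, 3.47, 3.61, 4.02, 4.32, 4.58, 5.55,
]

_FLUID_GROUP1 = [0.31, 0.66, 1.54, 1.70, 1.82, 1.89, 2.17, 2.24, 4.03, 9.99]
_FLUID_GROUP2 = [0.49, 0.64, 0.82, 0.93, 1.08, 1.99, 2.06, 2.15, 2.57, 4.75]

FIXTURES = {
    "guinea_pigs": _GUINEA_PIGS,
    "fluid_group1": _FLUID_GROUP1,
    "fluid_group2": _FLUID_GROUP2,
}


def load_sample(source: str | Path) -> LifetimeSample:
    """Load a lifetime sample from a fixture name or a one-column text file.

    Parameters
    ----------
    source : str or Path
        Either one of the fixture names in :data:`FIXTURES` or a path to a
        plain-text / single-column CSV file of positive numbers.  Lines that
        are blank or start with ``#`` are skipped.

    Returns
    -------
    LifetimeSample

    Raises
    ------
    ValueError
        On non-numeric rows or non-positive values (with the line number).
    FileNotFoundError
        If ``source`` is neither a fixture name nor an existing file.
    """
    key = str(source)
    if key in FIXTURES:
        return LifetimeSample(FIXTURES[key], label=key)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a bundled dataset "
            f"({', '.join(sorted(FIXTURES))}) nor an existing file"
        )
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            # tolerate a single-column CSV with trailing separators
            text = text.rstrip(",;").strip()
            try:
                value = float(text)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric entry {text!r}"
                ) from None
            if value <= 0:
                raise ValueError(
                    f"{path}:{lineno}: lifetimes must be positive, got {value}"
                )
            values.append(value)
    if not values:
        raise ValueError(f"{path}: no observations found")
    return LifetimeSample(values, label=str(path))
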