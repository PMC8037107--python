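"""Annual background-mortality life tables.

A life table maps integer attained age to qx, the probability of dying
within one year conditional on being alive at exact age x. Queries above
the table's last covered age return 1.0 (certain death), which keeps the
Markov horizon finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LifeTable", "LifeTableError", "read_lifetable", "write_lifetable"]


class LifeTableError(ValueError):
    """A life table file or query violates the format contract."""


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual death probabilities.

    ``qx`` holds one value per integer age from ``age_min`` to
    ``age_max_table`` inclusive, each in [0, 1].
    """

    age_min: int
    qx: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "qx", q)
        if q.ndim != 1 or q.size == 0:
            raise LifeTableError("qx must be a non-empty 1-D array")
        if np.any(~np.isfinite(q)) or np.any(q < 0) or np.any(q > 1):
            raise LifeTableError("every qx must be a finite probability in [0, 1]")
        q.setflags(write=False)

    @property
    def age_max_table(self) -> int:
        return self.age_min + len(self.qx) - 1

    def qx_at(self, age: int) -> float:
        """Annual death probability at an attained age.

        Ages beyond the table's last row return 1.0; ages below
        ``age_min`` are an error.
        """
        if age < self.age_min:
            raise LifeTableError(
                f"age {age} below table minimum {self.age_min}")
        if age > self.age_max_table:
            return 1.0
        return float(self.qx[age - self.age_min])

    def qx_vector(self, age_start: int, n: int) -> np.ndarray:
        """qx for ``n`` consecutive attained ages starting at ``age_start``."""
        return np.array([self.qx_at(age_start + i) for i in range(n)])

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.age_min, self.age_max_table + 1)
        return pd.DataFrame({"age": ages, "qx": self.qx})


def read_lifetable(path: str | Path, *, require_max_age: int = 100) -> LifeTable:
    """Read a life table from CSV with header columns ``age,qx``.

    Ages must be contiguous integers; the table must cover at least up to
    ``require_max_age`` (default 100, the model's maximum age).
    """
    df = pd.read_csv(path)
    missing = {"age", "qx"} - set(df.columns)
    if missing:
        raise LifeTableError(f"{path}: missing column(s) {sorted(missing)}")
    ages = df["age"].to_numpy()
    if len(ages) == 0:
        raise LifeTableError(f"{path}: empty table")
    if not np.array_equal(ages, ages.astype(int)):
        raise LifeTableError(f"{path}: ages must be integers")
    ages = ages.astype(int)
    if not np.array_equal(np.diff(ages), np.ones(len(ages) - 1, dtype=int)):
        raise LifeTableError(f"{path}: ages must be contiguous with no gaps")
    q = df["qx"].to_numpy(dtype=float)
    if np.any(~np.isfinite(q)) or np.any(q < 0) or np.any(q > 1):
        raise LifeTableError(f"{path}: qx values must lie in [0, 1]")
    if ages[-1] < require_max_age:
        raise LifeTableError(
            f"{path}: table ends at age {ages[-1]}, must cover age "
            f"{require_max_age}")
    return LifeTable(age_min=int(ages[0]), qx=q)


def write_lifetable(table: LifeTable, path: str | Path) -> None:
    """Write a life table as ``age,qx`` CSV (the dialect ``read_lifetable`` reads)."""
    table.to_frame().to_csv(path, index=False)
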