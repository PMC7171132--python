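"""Core in-memory containers shared across the pipeline.

Abundance matrices are held as pandas DataFrames with genes in rows and a
two-level (condition, replicate) column index, in mmol gDW^-1 unless stated
otherwise.  Condition order is meaningful: the first condition is the
carbon-limited reference and later conditions are progressively more
nitrogen-limited.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OmicsMatrix", "CalibrationCurve"]


@dataclass
class OmicsMatrix:
    """Gene x condition x replicate absolute abundance matrix.

    Parameters
    ----------
    values : DataFrame
        Genes in rows; columns are a MultiIndex ``(condition, replicate)``.
        Non-negative absolute abundances (mmol gDW^-1 by default).
    layer : str
        ``"mRNA"`` or ``"protein"``.
    total_content : Series, optional
        Per-condition biomass content the matrix was scaled to
        (g gDW^-1 or mmol gDW^-1, see ``units``).
    units : str
        Unit of ``values``.
    meta : dict
        Free-form metadata (dilution rate, C/N ratios, assumptions).
    """

    values: pd.DataFrame
    layer: str
    total_content: pd.Series | None = None
    units: str = "mmol gDW^-1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layer not in ("mRNA", "protein"):
            raise ValueError(f"layer must be 'mRNA' or 'protein', got {self.layer!r}")
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise ValueError("values must have (condition, replicate) MultiIndex columns")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        reps = pd.Series(self.values.columns.get_level_values(0)).value_counts()
        if reps.nunique() != 1:
            raise ValueError("replicate count must be constant across conditions")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def conditions(self) -> list:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    @property
    def n_replicates(self) -> int:
        return len(self.values[self.conditions[0]].columns)

    def condition_mean(self) -> pd.DataFrame:
        """Average replicates, preserving condition order (genes x conditions)."""
        out = self.values.T.groupby(level=0, sort=False).mean().T
        return out[self.conditions]

    def condition_sum(self) -> pd.Series:
        """Total molar abundance per condition (replicate-averaged)."""
        return self.condition_mean().sum(axis=0)

    def to_tsv(self, path) -> None:
        flat = self.values.copy()
        flat.columns = [f"{c}_{r}" for c, r in flat.columns]
        flat.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, layer: str, **kwargs) -> "OmicsMatrix":
        flat = pd.read_csv(path, sep="\t", index_col=0)
        cols = [tuple(c.rsplit("_", 1)) for c in flat.columns]
        flat.columns = pd.MultiIndex.from_tuples(cols)
        return cls(values=flat, layer=layer, **kwargs)


@dataclass
class CalibrationCurve:
    """Fitted log10-log10 standard curve and its validity range.

    ``signal_range`` is the (min, max) of the standards' log10 signals;
    applying the curve outside this range is extrapolation and is flagged,
    not refused.
    """

    slope: float
    intercept: float
    adjusted_r2: float
    p_value: float
    n_points: int
    signal_range: tuple[float, float]
    space: str = "log10-log10"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("calibration requires at least 3 standards")
        if not self.signal_range[0] < self.signal_range[1]:
            raise ValueError("signal_range must satisfy min < max")
        if self.adjusted_r2 > 1 + 1e-12:
            raise ValueError("adjusted R^2 cannot exceed 1")

    def to_dict(self) -> dict:
        return {
            "slope": float(self.slope),
            "intercept": float(self.intercept),
            "adjusted_r2": float(self.adjusted_r2),
            "p_value": float(self.p_value),
            "n_points": int(self.n_points),
            "signal_range": [float(self.signal_range[0]), float(self.signal_range[1])],
            "space": self.space,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        d = dict(d)
        d["signal_range"] = tuple(d["signal_range"])
        return cls(**d)


def make_columns(conditions, n_replicates: int) -> pd.MultiIndex:
    """(condition, replicate) column index in the given condition order."""
    return pd.MultiIndex.from_tuples(
        [(c, f"r{i + 1}") for c in conditions for i in range(n_replicates)]
    )


def lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=shape)
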