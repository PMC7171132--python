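"""Absolute-quantification calibration chain.

Platform signals (FPKM, iBAQ intensities, TMT reporter ratios, S/N values)
are converted to absolute molar abundances by: (1) a log10-log10 standard
curve fitted on spike-in calibrators, (2) per-condition rescaling to a
measured total content, (3) reference-anchored conversion of relative
ratios, and (4) a zero-intercept spike-in peptide mini-calibration for
targeted validation.

Zero signals map to zero abundance (calibration is undefined at zero and
molar sums must not be inflated); signals outside the standards' range are
converted anyway but flagged as extrapolated.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .containers import CalibrationCurve

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23  # mol^-1

__all__ = [
    "fit_calibration",
    "apply_calibration",
    "scale_to_total",
    "tmt_to_absolute",
    "peptide_minicalibration",
    "molecules_per_cell",
    "rrna_abundance",
]


def fit_calibration(standards: pd.DataFrame) -> CalibrationCurve:
    """Ordinary least squares of log10(signal) on log10(concentration).

    ``standards`` needs columns ``known_concentration`` and ``signal``, all
    strictly positive, with at least 3 rows.
    """
    required = {"known_concentration", "signal"}
    if not required.issubset(standards.columns):
        raise ValueError(f"standards table needs columns {sorted(required)}")
    bad = standards.index[
        (standards["known_concentration"] <= 0) | (standards["signal"] <= 0)
    ]
    if len(bad):
        raise ValueError(
            f"nonpositive concentration or signal in rows {list(bad)}"
        )
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    x = np.log10(standards["known_concentration"].to_numpy(float))
    y = np.log10(standards["signal"].to_numpy(float))
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return CalibrationCurve(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        adjusted_r2=min(float(fit.rsquared_adj), 1.0),
        p_value=float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else 0.0,
        n_points=len(standards),
        signal_range=(float(y.min()), float(y.max())),
    )


def apply_calibration(curve: CalibrationCurve, signals: pd.Series) -> pd.DataFrame:
    """Invert the standard curve: concentration = 10^((log10 s - b) / m).

    Zero signals map to zero concentration.  Signals outside the curve's
    fitted signal range are converted but flagged ``extrapolated``; nothing
    is dropped.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; curve cannot be inverted")
    s = pd.Series(signals, dtype=float)
    if (s < 0).any():
        raise ValueError("signals must be non-negative")
    out = pd.DataFrame(index=s.index, columns=["concentration", "extrapolated"])
    pos = s > 0
    logsig = np.log10(s[pos].to_numpy())
    out.loc[pos, "concentration"] = 10 ** ((logsig - curve.intercept) / curve.slope)
    out.loc[~pos, "concentration"] = 0.0
    lo, hi = curve.signal_range
    out["extrapolated"] = False
    out.loc[pos, "extrapolated"] = (logsig < lo) | (logsig > hi)
    out["concentration"] = out["concentration"].astype(float)
    out["extrapolated"] = out["extrapolated"].astype(bool)
    return out


def scale_to_total(
    abundances: pd.DataFrame | pd.Series,
    measured_total,
    weights: pd.Series | None = None,
) -> pd.DataFrame | pd.Series:
    """Rescale each condition so the (weighted) sum equals a measured total.

    ``abundances`` is genes x conditions (or a single condition Series);
    ``weights`` are optional per-gene masses for a mass-weighted total
    (molar sum by default).  Relative proportions within a condition are
    preserved exactly.
    """
    single = isinstance(abundances, pd.Series)
    mat = abundances.to_frame() if single else abundances.copy()
    totals = pd.Series(measured_total, index=mat.columns, dtype=float) \
        if np.isscalar(measured_total) else pd.Series(measured_total).reindex(mat.columns)
    if (totals <= 0).any():
        raise ValueError("measured totals must be positive")
    w = np.ones(len(mat)) if weights is None else weights.reindex(mat.index).to_numpy(float)
    current = mat.mul(w, axis=0).sum(axis=0)
    if (current <= 0).any():
        raise ValueError("total abundance is zero before scaling")
    scaled = mat.mul(totals / current, axis=1)
    return scaled.iloc[:, 0] if single else scaled


def tmt_to_absolute(
    reference_abs: pd.Series, relative_ratios: pd.DataFrame
) -> pd.DataFrame:
    """Absolute abundance per sample from reference-anchored ratios.

    ``sample_abs(g, s) = reference_abs(g) * ratio(g, s)``.  Genes missing
    from the reference are dropped with a logged count.
    """
    if (relative_ratios.to_numpy(float) < 0).any():
        raise ValueError("ratios must be non-negative")
    shared = relative_ratios.index.intersection(reference_abs.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between reference and ratio table")
    dropped = len(relative_ratios.index) - len(shared)
    if dropped:
        logger.info("tmt_to_absolute: dropped %d genes absent from reference", dropped)
    return relative_ratios.loc[shared].mul(reference_abs.loc[shared], axis=0)


def peptide_minicalibration(
    standard_points: pd.DataFrame,
    sample_signal: float,
    r2_threshold: float = 0.95,
) -> tuple[float, bool]:
    """Quantify a peptide against its synthetic-standard mini-curve.

    Fits a zero-intercept line of S/N signal vs known amount; the sample
    amount is ``sample_signal / slope``.  The linearity flag is true iff the
    sample signal lies within the standards' S/N range and the uncentered
    R^2 of the fit reaches ``r2_threshold``.

    ``standard_points`` needs columns ``known_amount`` and ``signal`` with
    strictly increasing amounts (>= 2 points; the study design uses 4).
    """
    pts = standard_points
    if len(pts) < 2:
        raise ValueError("need at least 2 standard points")
    amounts = pts["known_amount"].to_numpy(float)
    signals = pts["signal"].to_numpy(float)
    if not (np.diff(amounts) > 0).all():
        raise ValueError("standard amounts must be strictly increasing")
    slope = float(np.dot(amounts, signals) / np.dot(amounts, amounts))
    if slope <= 0:
        raise ValueError("non-responsive peptide: fitted slope <= 0")
    resid = signals - slope * amounts
    ss_tot = float(np.dot(signals, signals))
    r2 = 1.0 - float(np.dot(resid, resid)) / ss_tot if ss_tot > 0 else 0.0
    in_range = signals.min() <= sample_signal <= signals.max()
    return sample_signal / slope, bool(in_range and r2 >= r2_threshold)


def molecules_per_cell(conc: float, cells_per_gDW: float):
    """Convert mmol gDW^-1 to copies per cell.

    ``cells_per_gDW`` is a configured constant (cell count per gram dry
    weight); the assumption travels with any copies/cell output.
    """
    if np.any(np.asarray(conc) < 0) or cells_per_gDW <= 0:
        raise ValueError("concentration must be >= 0 and cells_per_gDW > 0")
    return conc * 1e-3 * AVOGADRO / cells_per_gDW


def rrna_abundance(
    total_rna: float, rrna_fraction: float = 0.8, ribosome_rna_mass: float = 1.7e6 * 1e-3
) -> float:
    """Ribosome concentration (mmol gDW^-1) from total RNA content.

    By default 80% of total RNA is taken to be rRNA; ``ribosome_rna_mass``
    is the rRNA mass per ribosome (g mmol^-1; default corresponds to the
    ~1.7 MDa of rRNA in one yeast ribosome).
    """
    if not 0 < rrna_fraction <= 1:
        raise ValueError("rrna_fraction must be in (0, 1]")
    if total_rna <= 0 or ribosome_rna_mass <= 0:
        raise ValueError("masses must be positive")
    return total_rna * rrna_fraction / ribosome_rna_mass
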