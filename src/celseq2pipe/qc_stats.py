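"""QC statistics: spike-in efficiency, expression noise, detection curves.

Capture efficiency is estimated from spike-in molecules of known input
abundance: plotting mean observed molecules per cell against expected
molecules on log10-log10 axes, a straight-line fit has slope ≈ 1 when
counting is linear, and its y-intercept measures the fraction of input
molecules recovered (``efficiency = 10**intercept``).  The slope is fit
free by default and reported; ``fix_slope=True`` constrains it to 1.

Expression noise per gene is summarised by the squared coefficient of
variation, CV² = variance / mean², computed with the unbiased (n − 1)
variance — material at the 20–72-cell scale typical of these
experiments.  Under pure Poisson sampling CV² = 1/mean, which provides
both a sanity check and a baseline for flagging highly variable genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EfficiencyFit",
    "expected_molecules",
    "build_spikein_table",
    "estimate_efficiency",
    "gene_noise",
    "select_high_variability",
    "detection_curve",
]

AVOGADRO = 6.02214076e23


class InsufficientDataError(ValueError):
    """Not enough usable observations for the requested statistic."""


def expected_molecules(attomoles_per_ul: float, dilution_factor: float, volume_ul: float) -> float:
    """Molecules delivered per cell from a spike-in concentration sheet.

    ``attomoles_per_ul`` is the stock concentration, diluted by
    ``dilution_factor`` and added at ``volume_ul`` microlitres per cell.
    """
    if attomoles_per_ul <= 0 or dilution_factor <= 0 or volume_ul <= 0:
        raise ValueError("all arguments must be positive")
    return attomoles_per_ul * 1e-18 * AVOGADRO * volume_ul / dilution_factor


def build_spikein_table(
    molecule_matrix: pd.DataFrame,
    expected: pd.DataFrame | str | Path,
) -> pd.DataFrame:
    """Join expected molecules with observed per-cell means.

    ``expected`` is a DataFrame (or TSV path) with columns
    ``spikein_id`` and ``expected_molecules``; observed means are
    averaged across all cells of ``molecule_matrix`` (genes × cells),
    with spike-ins absent from the matrix treated as observed 0.
    """
    if not isinstance(expected, pd.DataFrame):
        expected = pd.read_csv(expected, sep="\t")
    table = expected[["spikein_id", "expected_molecules"]].copy()
    means = molecule_matrix.mean(axis=1)
    table["observed_mean_molecules"] = (
        table["spikein_id"].map(means).fillna(0.0).to_numpy()
    )
    return table


@dataclass(frozen=True)
class EfficiencyFit:
    """Result of the log-log spike-in regression."""

    slope: float
    intercept_log10: float
    efficiency: float
    n_points: int
    n_excluded_zero: int

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([self.__dict__]).round(6).to_csv(path, sep="\t", index=False)


def estimate_efficiency(table: pd.DataFrame, fix_slope: bool = False) -> EfficiencyFit:
    """Capture efficiency as the y-intercept of the log-log spike-in fit.

    Ordinary least squares of log10(observed mean molecules) on
    log10(expected molecules) over spike-ins observed at least once;
    zero-observation rows cannot enter a log fit and are excluded with
    their count reported (no pseudocounts — they would bias the
    intercept, which is the quantity of interest).  With
    ``fix_slope=True`` the slope is constrained to 1 and the intercept
    is the mean log-ratio.
    """
    if (table["expected_molecules"] <= 0).any():
        raise ValueError("expected_molecules must be positive for all rows")
    usable = table[table["observed_mean_molecules"] > 0]
    n_excluded = len(table) - len(usable)
    if len(usable) < 3:
        raise InsufficientDataError(
            f"only {len(usable)} spike-ins with nonzero observations (need >= 3)"
        )
    x = np.log10(usable["expected_molecules"].to_numpy(dtype=float))
    y = np.log10(usable["observed_mean_molecules"].to_numpy(dtype=float))
    if fix_slope:
        slope = 1.0
        intercept = float(np.mean(y - x))
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    return EfficiencyFit(slope, intercept, 10.0**intercept, len(usable), n_excluded)


def gene_noise(matrix: pd.DataFrame, layer_name: str = "molecule_estimates") -> pd.DataFrame:
    """Per-gene mean and CV² across cells.

    ``matrix`` is genes × cells (either layer of a count matrix).  Genes
    with zero mean carry no CV² and are omitted.  Requires at least two
    cells.
    """
    if matrix.shape[1] < 2:
        raise InsufficientDataError("CV² requires at least 2 cells")
    means = matrix.mean(axis=1)
    variances = matrix.var(axis=1, ddof=1)
    keep = means > 0
    out = pd.DataFrame(
        {
            "gene": matrix.index[keep],
            "mean": means[keep].to_numpy(),
            "cv2": (variances[keep] / means[keep] ** 2).to_numpy(),
        }
    ).reset_index(drop=True)
    out.attrs["layer"] = layer_name
    return out


def select_high_variability(table: pd.DataFrame, ratio: float = 1.5) -> pd.DataFrame:
    """Flag genes whose CV² is high relative to their expression level.

    A technical-noise baseline CV² = a/mean + b is fit by least squares
    (linear in 1/mean); genes whose observed CV² exceeds ``ratio`` times
    the fitted baseline are flagged.  Returns the table with ``baseline``
    and ``high_variability`` columns added.
    """
    if len(table) < 10:
        raise InsufficientDataError("high-variability selection requires >= 10 genes")
    means = table["mean"].to_numpy(dtype=float)
    if np.allclose(means, means[0]):
        raise InsufficientDataError("all gene means identical; baseline fit is degenerate")
    design = np.column_stack([1.0 / means, np.ones_like(means)])
    coef, *_ = np.linalg.lstsq(design, table["cv2"].to_numpy(dtype=float), rcond=None)
    a, b = coef
    out = table.copy()
    out["baseline"] = np.maximum(design @ coef, 1e-12)
    out["high_variability"] = out["cv2"] > ratio * out["baseline"]
    out.attrs["baseline_coefficients"] = (float(a), float(b))
    return out


def detection_curve(matrix: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Average detection fraction per log-spaced mean-expression bin.

    Per gene, the mean expression across cells and the fraction of cells
    with a nonzero count are computed; genes are then binned by mean on
    a log10-spaced grid and the per-bin average fraction reported.
    All-zero genes are excluded (mean 0).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    means = matrix.mean(axis=1)
    fractions = (matrix > 0).mean(axis=1)
    keep = means > 0
    means, fractions = means[keep], fractions[keep]
    if means.empty:
        return pd.DataFrame(
            columns=["bin_low", "bin_high", "mean_expression", "detected_fraction", "n_genes"]
        )
    lo, hi = np.log10(means.min()), np.log10(means.max())
    if lo == hi:
        edges = np.array([means.min() * 0.999, means.max() * 1.001])
        n_bins = 1
    else:
        edges = np.logspace(lo, hi, n_bins + 1)
        edges[-1] *= 1 + 1e-9  # right edge inclusive
    idx = np.clip(np.digitize(means.to_numpy(), edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_expression": float(means.to_numpy()[mask].mean()),
                "detected_fraction": float(fractions.to_numpy()[mask].mean()),
                "n_genes": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)
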