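"""Quantile normalization of the two libraries and DHE/CHE calling.

After stage 1 removes noisy and biased bins, the remaining bins of the two
libraries are assumed to share a common bincount distribution up to a library-
specific monotone distortion (differences in sequencing depth, amplification
factor and signal-to-noise ratio).  Mapping library 1 through
``f = F2^{-1} ∘ F1`` — its percentile under its own inverse CDF, evaluated on
the other library's inverse CDF — puts both on one scale, so a plain fold
change identifies differentially enriched (DHE) and constitutively highly
enriched (CHE) bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io_binning import GenomeLayout, RegionSet

logger = logging.getLogger(__name__)

NONE, DHE_LIB1, DHE_LIB2, CHE = 0, 1, 2, 3
LABEL_NAMES = {DHE_LIB1: "DHE_LIB1", DHE_LIB2: "DHE_LIB2", CHE: "CHE", NONE: "NONE"}


@dataclass
class QuantileFunction:
    """Smoothed monotone percentile → bin-value map (an inverse CDF).

    Fitted as a monotone piecewise-cubic (PCHIP) interpolant through
    evenly-spaced percentile knots of the empirical inverse CDF; monotone
    interpolation cannot oscillate, so the map stays invertible.
    """

    knots: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self._spline = PchipInterpolator(self.knots, self.values)
        # dense grid for numerical inversion (percentile lookup)
        self._grid_p = np.linspace(0.0, 1.0, 4097)
        gv = np.asarray(self._spline(self._grid_p), dtype=float)
        self._grid_v = np.maximum.accumulate(gv)  # guard against round-off dips

    def __call__(self, p: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the inverse CDF; percentiles are clamped to [0, 1]."""
        p_arr = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
        out = np.asarray(self._spline(p_arr), dtype=float)
        return float(out) if np.isscalar(p) else out

    def percentile(self, x: np.ndarray | float) -> np.ndarray | float:
        """Percentile of a value under this distribution (clamped to [0, 1]).

        A value sitting on a flat stretch of the inverse CDF (an atom of the
        fitted distribution) returns the midpoint of its percentile range,
        so the atom's mass is centred rather than pushed to one edge.
        """
        x_arr = np.atleast_1d(np.asarray(x, dtype=float))
        gv, gp = self._grid_v, self._grid_p
        iL = np.searchsorted(gv, x_arr, side="left")
        iR = np.searchsorted(gv, x_arr, side="right")
        out = np.empty_like(x_arr)
        # strictly between grid values: linear interpolation
        between = iR == iL
        hi = np.clip(iL, 1, len(gv) - 1)
        lo = hi - 1
        denom = gv[hi] - gv[lo]
        frac = np.where(denom > 0, (x_arr - gv[lo]) / np.where(denom > 0, denom, 1.0), 0.5)
        out[between] = (gp[lo] + frac * (gp[hi] - gp[lo]))[between]
        out[between & (x_arr < gv[0])] = 0.0
        out[between & (x_arr > gv[-1])] = 1.0
        # exact hits (possibly a whole flat stretch): midpoint of the range
        on_flat = ~between
        out[on_flat] = 0.5 * (gp[iL[on_flat]] + gp[iR[on_flat] - 1])
        return float(out[0]) if np.isscalar(x) else out


def fit_quantile_function(values: np.ndarray, n_knots: int = 101) -> QuantileFunction:
    """Fit the smoothed empirical inverse CDF of a value set.

    Knots are evenly spaced percentiles (one per percentile by default —
    coarse decile knots oversmooth the staircase inverse CDF of discrete
    counts).  Requires at least 10 values; a constant input yields a flat
    function with a warning.
    """
    n_knots = int(min(n_knots, max(2, len(np.atleast_1d(values)))))
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError(f"need at least 10 values to fit a quantile function, got {len(values)}")
    if np.ptp(values) == 0:
        logger.warning("constant input: quantile function is flat")
    knots = np.linspace(0.0, 1.0, n_knots)
    qv = np.quantile(values, knots)
    return QuantileFunction(knots=knots, values=np.maximum.accumulate(qv))


def quantile_transform(
    x: np.ndarray, qf1: QuantileFunction, qf2: QuantileFunction
) -> np.ndarray:
    """Map values of library 1 onto library 2's scale: ``qf2(F1(x))``.

    Values outside library 1's fitted range evaluate at clamped percentile
    0 or 1.  The map is non-decreasing.
    """
    return np.asarray(qf2(qf1.percentile(np.asarray(x, dtype=float))))


@dataclass
class BinLabels:
    """Per-bin DHE/CHE/NONE calls with both libraries' normalized values.

    ``labels`` uses the integer codes ``NONE``/``DHE_LIB1``/``DHE_LIB2``/
    ``CHE``; bins outside the stage-2 set are NONE and carry NaN values.
    """

    labels: np.ndarray  # int8 codes, one per genome bin
    norm1: np.ndarray  # library 1 on library 2's scale
    norm2: np.ndarray  # library 2 (its own scale)
    stage2: np.ndarray  # bool, the bins that were compared

    def counts_by_label(self) -> dict[str, int]:
        return {
            name: int((self.labels == code).sum())
            for code, name in LABEL_NAMES.items()
        }


def call_dhe_che(
    x1: np.ndarray,
    x2: np.ndarray,
    qf1: QuantileFunction,
    qf2: QuantileFunction,
    t: float = 3.0,
    percentile_cutoff: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Label stage-2 bins as DHE_LIB1 / DHE_LIB2 / CHE / NONE.

    With ``y1`` the library-1 value mapped onto library 2's scale:

    * DHE_LIB1 — library 1's value sits above the percentile cutoff on its
      own inverse CDF and ``y1 / x2 >= t``;
    * DHE_LIB2 — the mirror condition;
    * CHE — both values sit above the cutoff and the fold change lies
      strictly inside ``(1/t, t)``.

    A zero denominator gives fold +inf (no pseudocounts: stage-1 filtering
    makes true zeros rare here); two zeros give NONE.  Labels are mutually
    exclusive by construction.  Returns (label codes, y1).
    """
    if t <= 1.0:
        raise ValueError("fold threshold t must exceed 1")
    if not (0.0 <= percentile_cutoff < 1.0):
        raise ValueError("percentile_cutoff must lie in [0, 1)")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("stage-2 vectors differ in length")

    y1 = quantile_transform(x1, qf1, qf2)
    p1 = np.asarray(qf1.percentile(x1))
    p2 = np.asarray(qf2.percentile(x2))
    hi1 = p1 > percentile_cutoff
    hi2 = p2 > percentile_cutoff

    with np.errstate(divide="ignore", invalid="ignore"):
        fold12 = np.where(x2 > 0, y1 / x2, np.where(y1 > 0, np.inf, np.nan))
        fold21 = np.where(y1 > 0, x2 / y1, np.where(x2 > 0, np.inf, np.nan))

    labels = np.full(x1.shape, NONE, dtype=np.int8)
    labels[hi1 & (fold12 >= t)] = DHE_LIB1
    labels[hi2 & (fold21 >= t)] = DHE_LIB2
    che = hi1 & hi2 & (fold12 > 1.0 / t) & (fold12 < t)
    labels[che] = CHE
    return labels, y1


def label_bins(
    counts1: np.ndarray,
    counts2: np.ndarray,
    stage2: np.ndarray,
    t: float = 3.0,
    percentile_cutoff: float = 0.5,
) -> BinLabels:
    """Fit both quantile functions on the stage-2 bins and label the genome."""
    stage2 = np.asarray(stage2, dtype=bool)
    x1 = np.asarray(counts1, dtype=float)[stage2]
    x2 = np.asarray(counts2, dtype=float)[stage2]
    labels = np.full(len(stage2), NONE, dtype=np.int8)
    norm1 = np.full(len(stage2), np.nan)
    norm2 = np.full(len(stage2), np.nan)
    if stage2.sum() >= 10:
        qf1 = fit_quantile_function(x1)
        qf2 = fit_quantile_function(x2)
        codes, y1 = call_dhe_che(x1, x2, qf1, qf2, t, percentile_cutoff)
        labels[stage2] = codes
        norm1[stage2] = y1
        norm2[stage2] = x2
    elif stage2.any():
        logger.warning(
            "stage-2 set has %d bins (< 10): nothing labeled", int(stage2.sum())
        )
    return BinLabels(labels=labels, norm1=norm1, norm2=norm2, stage2=stage2)


def merge_regions(labels: BinLabels | np.ndarray, layout: GenomeLayout) -> RegionSet:
    """Group maximal runs of identically-labeled adjacent bins into regions.

    Runs never cross chromosome boundaries; region ends are truncated at the
    chromosome end.
    """
    codes = labels.labels if isinstance(labels, BinLabels) else np.asarray(labels)
    if len(codes) != layout.n_bins:
        raise ValueError("labels do not match layout")
    rows = []
    offsets = layout.chrom_offsets()
    nbins = layout.bins_per_chrom()
    bs = layout.bin_size
    for name, length in layout.chromosomes:
        chrom_codes = codes[offsets[name] : offsets[name] + nbins[name]]
        # run-length encode
        change = np.flatnonzero(np.diff(chrom_codes)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(chrom_codes)]))
        for s, e in zip(starts, ends):
            code = int(chrom_codes[s])
            if code == NONE:
                continue
            rows.append(
                (name, int(s * bs), int(min(e * bs, length)), LABEL_NAMES[code])
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return RegionSet(df)
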