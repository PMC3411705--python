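"""Amplified-binomial null model for background bin counts.

Antibody capture without specificity scatters fragments uniformly over bins,
so a background bin count is Binomial(n0, 1/B); constant-factor PCR
amplification then multiplies every count by ``a``.  The resulting law —
a binomial scaled by a constant — is the amplified binomial distribution
(ABD) used as the null when deciding which bins carry real signal.

Both parameters are identified from two invariants of amplification: it
preserves the set of empty bins and scales the library total.  Matching the
observed number of zero bins ``Z0`` to its null expectation
``B (1 - 1/B)^{n0}`` gives ``n0``; matching totals gives ``a = N / n0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import special

from .io_binning import BinnedLibrary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ABDParams:
    """Null-model parameters: pre-amplification total and amplification factor."""

    n0: float  # pre-amplification fragment count (real-valued)
    amp: float  # amplification factor a >= 1
    bins: int  # number of bins B

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if self.amp < 1:
            raise ValueError("amplification factor must be >= 1")
        if self.bins < 2:
            raise ValueError("need at least 2 bins")


@dataclass
class SignificanceCall:
    """Minimal count threshold meeting the FDR target, and the bins above it."""

    count_threshold: float
    fdr_at_threshold: float
    mask: np.ndarray  # boolean per bin

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())


def estimate_abd(lib: BinnedLibrary) -> ABDParams:
    """Estimate the ABD null from the zero-bin count and the library total.

    Solves ``B (1 - 1/B)^{n0} = Z0`` for ``n0`` and sets ``a = N / n0``.
    Raises if the library has no empty bins (null not estimable at this bin
    size) or only empty bins.  An ``a`` estimate below 1 — possible under
    sampling noise — is clamped to 1 with a warning, since amplification
    cannot shrink a library.
    """
    B = lib.n_bins
    Z0 = lib.zero_bins
    N = lib.total
    if Z0 == B or N == 0:
        raise ValueError("empty library: every bin has zero count")
    if Z0 == 0:
        raise ValueError(
            "null not estimable: no empty bins; use a larger genome or smaller bins"
        )
    n0 = math.log(Z0 / B) / math.log(1.0 - 1.0 / B)
    amp = N / n0
    if amp < 1.0:
        logger.warning("estimated amplification %.3f < 1; clamping to 1", amp)
        amp = 1.0
    return ABDParams(n0=n0, amp=amp, bins=B)


def _binom_sf_real_n(k: float, n: float, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p) with real-valued n.

    Uses the regularized incomplete beta identity
    ``P(X >= k) = I_p(k, n - k + 1)``, which extends the binomial tail to
    non-integer n via the gamma function.
    """
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    return float(special.betainc(k, n - k + 1.0, p))


def abd_survival(params: ABDParams, c: float) -> float:
    """P(a·X >= c) under the null: the binomial tail at ``ceil(c / a)``.

    Counts stay on the observed (amplified) scale; the threshold is rescaled
    instead, so integer counts are never divided.
    """
    if c < 0:
        raise ValueError("count must be non-negative")
    if c == 0:
        return 1.0
    k = math.ceil(c / params.amp)
    return _binom_sf_real_n(k, params.n0, 1.0 / params.bins)


def fdr_threshold(
    lib: BinnedLibrary, params: ABDParams, target_fdr: float = 0.05
) -> SignificanceCall:
    """Call significant bins by empirical FDR against the ABD null.

    For an integer count threshold ``c`` the empirical FDR is the expected
    number of null bins at or above ``c`` over the observed number at or
    above ``c`` (capped at 1).  The call uses the smallest ``c`` with
    ``FDR(c) <= target_fdr`` and a non-empty observed tail; if no threshold
    qualifies the mask is empty and a warning is logged.
    """
    if not (0.0 < target_fdr < 1.0):
        raise ValueError("target_fdr must lie in (0, 1)")
    counts = lib.counts
    B = lib.n_bins
    cmax = int(counts.max())
    # observed tail sizes for every integer threshold in one pass
    hist = np.bincount(counts.astype(np.int64), minlength=cmax + 2)
    tail = np.cumsum(hist[::-1])[::-1]  # tail[c] = #{counts >= c}
    for c in range(1, cmax + 1):
        observed = int(tail[c])
        if observed == 0:
            break
        expected_null = B * abd_survival(params, c)
        fdr = min(1.0, expected_null / observed)
        if fdr <= target_fdr:
            return SignificanceCall(
                count_threshold=c, fdr_at_threshold=fdr, mask=counts >= c
            )
    logger.warning(
        "no count threshold achieves FDR <= %.3g; library indistinguishable "
        "from noise",
        target_fdr,
    )
    return SignificanceCall(
        count_threshold=math.inf,
        fdr_at_threshold=math.nan,
        mask=np.zeros(B, dtype=bool),
    )
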