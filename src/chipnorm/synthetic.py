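"""Seeded simulator of paired ChIP-seq libraries with known per-bin truth.

The generator reproduces the noise structure the two-stage method targets:

* background fragments scattered without specificity — multinomial
  (conditioned binomial) over bins, so per-bin background is binomial
  marginally and library totals are exact;
* constant-factor PCR amplification of every captured fragment;
* planted enriched bins with configurable fold differences between the two
  conditions;
* per-library differences in amplification factor and signal-to-noise ratio;
* a shared per-bin multiplicative bias (open chromatin / mappability) that
  affects the ChIP library and its matched input-DNA control alike.

It does not model fragment-length variation, sequence content, stochastic
PCR, or mappability at the read level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_binning import BinnedLibrary, GeneSet, GenomeLayout

TRUTH_NULL, TRUTH_DIFF1, TRUTH_DIFF2, TRUTH_SHARED = 0, 1, 2, 3
TRUTH_NAMES = {
    TRUTH_NULL: "NULL",
    TRUTH_DIFF1: "DIFF_1",
    TRUTH_DIFF2: "DIFF_2",
    TRUTH_SHARED: "SHARED",
}


def default_layout(
    n_bins: int = 50_000, bin_size: int = 1000, name: str = "chrS"
) -> GenomeLayout:
    """One synthetic chromosome tiled by ``n_bins`` bins."""
    return GenomeLayout(((name, n_bins * bin_size),), bin_size)


@dataclass
class SyntheticTruth:
    """Planted per-bin enrichment state and the intensities that made it."""

    labels: np.ndarray  # TRUTH_* codes per bin
    intensity1: np.ndarray  # signal intensity per bin, condition 1
    intensity2: np.ndarray  # signal intensity per bin, condition 2

    def swapped(self) -> "SyntheticTruth":
        labels = self.labels.copy()
        labels[self.labels == TRUTH_DIFF1] = TRUTH_DIFF2
        labels[self.labels == TRUTH_DIFF2] = TRUTH_DIFF1
        return SyntheticTruth(labels, self.intensity2.copy(), self.intensity1.copy())

    def signal_mask(self, condition: int) -> np.ndarray:
        """Bins carrying true signal in the given condition (1 or 2)."""
        intensity = self.intensity1 if condition == 1 else self.intensity2
        return intensity > 0


def make_truth(
    layout: GenomeLayout,
    n_diff1: int = 500,
    n_diff2: int = 500,
    n_shared: int = 100,
    signal: float = 100.0,
    signal_spread: float = 0.25,
    diff_fold: float = 4.0,
    placement: str = "uniform",
    seed: int = 0,
) -> SyntheticTruth:
    """Plant enriched bins on a layout.

    ``signal`` is the typical enrichment intensity of a fully enriched bin in
    units of the per-bin background weight (strong histone-mark domains sit
    one to two orders of magnitude above background at kb resolution); each
    planted bin draws its own intensity, lognormal around ``signal`` with
    log-sd ``signal_spread``, so enrichment forms a continuum rather than a
    single atom.  A DIFF bin carries its intensity in the enriched condition
    and ``1 / diff_fold`` of it in the other; a SHARED bin carries the same
    intensity in both.  ``placement="gradient"`` makes the chance that a bin
    is chosen rise linearly along the genome, mimicking the gene-density
    gradient of real chromosomes; ``"uniform"`` places bins anywhere.
    """
    if diff_fold <= 1:
        raise ValueError("diff_fold must exceed 1")
    rng = np.random.default_rng(seed)
    B = layout.n_bins
    n_total = n_diff1 + n_diff2 + n_shared
    if n_total > B:
        raise ValueError("more planted bins than bins in the layout")
    if placement == "uniform":
        p = None
    elif placement == "gradient":
        w = np.arange(1, B + 1, dtype=float)
        p = w / w.sum()
    else:
        raise ValueError("placement must be 'uniform' or 'gradient'")
    chosen = rng.choice(B, size=n_total, replace=False, p=p)
    labels = np.full(B, TRUTH_NULL, dtype=np.int8)
    labels[chosen[:n_diff1]] = TRUTH_DIFF1
    labels[chosen[n_diff1 : n_diff1 + n_diff2]] = TRUTH_DIFF2
    labels[chosen[n_diff1 + n_diff2 :]] = TRUTH_SHARED
    amplitude = signal * rng.lognormal(0.0, signal_spread, size=n_total)
    i1 = np.zeros(B)
    i2 = np.zeros(B)
    i1[chosen[:n_diff1]] = amplitude[:n_diff1]
    i2[chosen[:n_diff1]] = amplitude[:n_diff1] / diff_fold
    i2[chosen[n_diff1 : n_diff1 + n_diff2]] = amplitude[n_diff1 : n_diff1 + n_diff2]
    i1[chosen[n_diff1 : n_diff1 + n_diff2]] = (
        amplitude[n_diff1 : n_diff1 + n_diff2] / diff_fold
    )
    i1[chosen[n_diff1 + n_diff2 :]] = amplitude[n_diff1 + n_diff2 :]
    i2[chosen[n_diff1 + n_diff2 :]] = amplitude[n_diff1 + n_diff2 :]
    return SyntheticTruth(labels, i1, i2)


@dataclass
class SimConfig:
    """Everything one simulated library needs; the seed fixes all randomness."""

    layout: GenomeLayout
    n_fragments: int | None = None  # captured fragments before amplification;
    # default 10 per bin, the depth regime of a typical 1-kb binned library
    amp: float = 1.0  # constant amplification factor
    background_rate: float = 1.0  # uniform background weight per bin
    truth_intensity: np.ndarray | None = None  # per-bin signal weight
    control_bias: np.ndarray | None = None  # shared local bias multiplier
    control_fragments: int | None = None  # default: n_fragments
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fragments is None:
            self.n_fragments = 10 * self.layout.n_bins
        if self.n_fragments <= 0:
            raise ValueError("n_fragments must be positive")
        if self.amp < 1:
            raise ValueError("amplification factor must be >= 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be non-negative")


def simulate_library(cfg: SimConfig) -> tuple[BinnedLibrary, BinnedLibrary]:
    """Draw one ChIP library and its matched input-DNA control.

    Fragment destinations are multinomial with probability proportional to
    ``control_bias × (background_rate + truth_intensity)``; the control draws
    from ``control_bias`` alone.  Amplification multiplies the drawn counts
    by the constant factor (rounded to integers).  Pre-amplification totals
    equal ``n_fragments`` exactly.
    """
    B = cfg.layout.n_bins
    rng = np.random.default_rng(cfg.seed)
    truth = (
        np.zeros(B) if cfg.truth_intensity is None else np.asarray(cfg.truth_intensity)
    )
    bias = np.ones(B) if cfg.control_bias is None else np.asarray(cfg.control_bias)
    weights = bias * (cfg.background_rate + truth)
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total intensity: nothing to sample")
    pre = rng.multinomial(cfg.n_fragments, weights / total)
    counts = np.round(pre * cfg.amp).astype(np.int64)
    lib = BinnedLibrary(cfg.layout, counts)

    n_ctrl = cfg.control_fragments or cfg.n_fragments
    ctrl_counts = rng.multinomial(n_ctrl, bias / bias.sum())
    ctrl = BinnedLibrary(cfg.layout, ctrl_counts.astype(np.int64))
    return lib, ctrl


@dataclass
class SimPair:
    lib1: BinnedLibrary
    ctrl1: BinnedLibrary
    lib2: BinnedLibrary
    ctrl2: BinnedLibrary
    truth: SyntheticTruth


def simulate_pair(cfg1: SimConfig, cfg2: SimConfig, truth: SyntheticTruth) -> SimPair:
    """Draw the two conditions of one truth profile.

    The configs carry the per-library nuisance parameters (depth,
    amplification, background, seed); their ``truth_intensity`` fields are
    overwritten from ``truth`` so the pair stays consistent with it.
    """
    if cfg1.layout != cfg2.layout:
        raise ValueError("both conditions must share a layout")
    cfg1 = replace(cfg1, truth_intensity=truth.intensity1)
    cfg2 = replace(cfg2, truth_intensity=truth.intensity2)
    lib1, ctrl1 = simulate_library(cfg1)
    lib2, ctrl2 = simulate_library(cfg2)
    return SimPair(lib1, ctrl1, lib2, ctrl2, truth)


def open_chromatin_bias(
    layout: GenomeLayout, fraction: float = 0.05, strength: float = 4.0, seed: int = 0
) -> np.ndarray:
    """A per-bin multiplier with a few strongly accessible regions.

    Shared by a library and its control, this is the local genomic bias the
    control-normalization stage is meant to absorb.
    """
    rng = np.random.default_rng(seed)
    bias = np.ones(layout.n_bins)
    n = int(fraction * layout.n_bins)
    idx = rng.choice(layout.n_bins, size=n, replace=False)
    bias[idx] = strength
    return bias


def simulate_genes_expression(
    truth: SyntheticTruth,
    layout: GenomeLayout,
    n_genes: int = 300,
    anti_corr: float = 1.0,
    base_expr: float = 100.0,
    expr_fold: float = 8.0,
    seed: int = 0,
) -> tuple[GeneSet, pd.DataFrame]:
    """Genes whose expression opposes the repressive-mark truth at the promoter.

    TSSs are placed at the centers of planted DIFF bins (and of NULL bins for
    the remainder).  With probability ``anti_corr`` a gene on a DIFF_1 bin —
    mark present in condition 1, hence repressed there — is ``expr_fold``
    over-expressed in condition 2, and symmetrically; otherwise (and on
    non-DIFF bins) both conditions get similar expression with lognormal
    noise.
    """
    if not (0.0 <= anti_corr <= 1.0):
        raise ValueError("anti_corr must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    intervals = layout.bin_intervals()

    def pool(code: int) -> np.ndarray:
        # promoter windows span neighbouring bins too; keep only bins whose
        # neighbours carry no conflicting label so expression and promoter
        # state stay consistent by construction
        idx = np.flatnonzero(truth.labels == code)
        ok = []
        for b in idx:
            nbrs = truth.labels[max(0, b - 1) : b + 2]
            if all(l in (code, TRUTH_NULL) for l in nbrs):
                ok.append(b)
        return np.asarray(ok, dtype=int)

    pools = {
        TRUTH_DIFF1: pool(TRUTH_DIFF1),
        TRUTH_DIFF2: pool(TRUTH_DIFF2),
        TRUTH_NULL: pool(TRUTH_NULL),
    }
    # a third of the genes on each DIFF class, the rest on background bins
    n_d1 = min(n_genes // 3, len(pools[TRUTH_DIFF1]))
    n_d2 = min(n_genes // 3, len(pools[TRUTH_DIFF2]))
    n_bg = min(n_genes - n_d1 - n_d2, len(pools[TRUTH_NULL]))
    chosen = np.concatenate(
        [
            rng.choice(pools[TRUTH_DIFF1], n_d1, replace=False),
            rng.choice(pools[TRUTH_DIFF2], n_d2, replace=False),
            rng.choice(pools[TRUTH_NULL], n_bg, replace=False),
        ]
    ).astype(int)
    gene_rows = []
    expr_rows = []
    for k, b in enumerate(chosen):
        gid = f"gene{k:05d}"
        chrom = intervals["chrom"].iloc[b]
        tss = int((intervals["start"].iloc[b] + intervals["end"].iloc[b]) // 2)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((gid, chrom, tss, strand))
        noise = rng.lognormal(0.0, 0.1, size=2)
        label = truth.labels[b]
        follows = rng.random() < anti_corr
        if label == TRUTH_DIFF1 and follows:  # repressed in condition 1
            e1, e2 = base_expr, base_expr * expr_fold
        elif label == TRUTH_DIFF2 and follows:
            e1, e2 = base_expr * expr_fold, base_expr
        else:
            e1 = e2 = base_expr
        expr_rows.append((gid, e1 * noise[0], e2 * noise[1]))
    genes = GeneSet(pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand"]))
    expr = (
        pd.DataFrame(expr_rows, columns=["gene_id", "expr_cond1", "expr_cond2"])
        .set_index("gene_id")
    )
    return genes, expr


# ---------------------------------------------------------------------------
# canned study conditions


def matched_pair(
    layout: GenomeLayout | None = None,
    seed: int = 0,
    placement: str = "uniform",
    **truth_kwargs,
) -> SimPair:
    """A well-behaved pair: equal depth, no amplification or bias asymmetry."""
    layout = layout or default_layout()
    truth = make_truth(layout, placement=placement, seed=seed, **truth_kwargs)
    cfg1 = SimConfig(layout, seed=seed * 2 + 1)
    cfg2 = SimConfig(layout, seed=seed * 2 + 2)
    return simulate_pair(cfg1, cfg2, truth)


def amp_asymmetric_pair(
    layout: GenomeLayout | None = None,
    seed: int = 0,
    amp1: float = 4.0,
    placement: str = "uniform",
    **truth_kwargs,
) -> SimPair:
    """Equal backgrounds but a four-fold amplification difference.

    The scale mismatch alone defeats naive count comparison; quantile
    normalization should absorb it entirely.
    """
    layout = layout or default_layout()
    truth = make_truth(layout, placement=placement, seed=seed, **truth_kwargs)
    bias = open_chromatin_bias(layout, seed=seed + 1)
    cfg1 = SimConfig(layout, amp=amp1, control_bias=bias, seed=seed * 2 + 1)
    cfg2 = SimConfig(layout, amp=1.0, control_bias=bias, seed=seed * 2 + 2)
    return simulate_pair(cfg1, cfg2, truth)


def noisy_pair(
    layout: GenomeLayout | None = None,
    seed: int = 0,
    background2: float = 5.0,
    amp1: float = 4.0,
    placement: str = "gradient",
    **truth_kwargs,
) -> SimPair:
    """The adversarial pair the method is built for.

    Library 2 has five times the uniform background (lower signal-to-noise
    ratio) and a quarter of library 1's amplification factor; signal bins
    follow a density gradient along the genome.  Both libraries share an
    open-chromatin bias with their controls.  The default truth emulates a
    broad repressive mark: domains cover ~16% of the genome and are mostly
    shared between the two cell types, so dense windows are high in both
    libraries.
    """
    layout = layout or default_layout()
    B = layout.n_bins
    truth_kwargs.setdefault("n_diff1", B // 25)  # 4% of bins each direction
    truth_kwargs.setdefault("n_diff2", B // 25)
    truth_kwargs.setdefault("n_shared", B // 12)  # ~8% shared domains
    truth = make_truth(layout, placement=placement, seed=seed, **truth_kwargs)
    bias = open_chromatin_bias(layout, seed=seed + 1)
    cfg1 = SimConfig(
        layout, amp=amp1, background_rate=1.0, control_bias=bias, seed=seed * 2 + 1
    )
    cfg2 = SimConfig(
        layout,
        amp=1.0,
        background_rate=background2,
        control_bias=bias,
        seed=seed * 2 + 2,
    )
    return simulate_pair(cfg1, cfg2, truth)


def replicate_pair(
    layout: GenomeLayout | None = None, seed: int = 0, **truth_kwargs
) -> SimPair:
    """Two draws of the same condition: any differential call is false."""
    layout = layout or default_layout()
    truth_kwargs.setdefault("n_shared", 1000)
    truth = make_truth(layout, n_diff1=0, n_diff2=0, seed=seed, **truth_kwargs)
    bias = open_chromatin_bias(layout, seed=seed + 1)
    cfg1 = SimConfig(layout, control_bias=bias, seed=seed * 2 + 1)
    cfg2 = SimConfig(layout, control_bias=bias, seed=seed * 2 + 2)
    return simulate_pair(cfg1, cfg2, truth)
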