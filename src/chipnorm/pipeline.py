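"""End-to-end orchestration of the two-stage method.

Stage 1, per library: estimate the amplified-binomial null and call
significant bins at the FDR target; normalize the input-DNA control
iteratively and call control-enriched bins; intersect the two masks into
enriched-significant bins.  The union of both libraries' enriched-significant
bins, with their original counts, feeds stage 2: quantile normalization of
library 1 onto library 2's scale and DHE/CHE labeling by fold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abd_null import ABDParams, estimate_abd, fdr_threshold
from .control_norm import (
    enriched_significant,
    iterative_normalize_control,
    stage2_bin_set,
)
from .diff_norm import BinLabels, label_bins, merge_regions
from .io_binning import BinnedLibrary, GenomeLayout, RegionSet


@dataclass
class ChipnormResult:
    labels: BinLabels
    regions: RegionSet
    stage2: np.ndarray
    report: dict = field(default_factory=dict)


def _slice_library(lib: BinnedLibrary, name: str) -> BinnedLibrary:
    layout = lib.layout
    sub_layout = GenomeLayout(
        ((name, layout.chrom_length(name)),), layout.bin_size
    )
    off = layout.chrom_offsets()[name]
    n = layout.bins_per_chrom()[name]
    return BinnedLibrary(sub_layout, lib.counts[off : off + n])


def run_chipnorm(
    lib1: BinnedLibrary,
    ctrl1: BinnedLibrary,
    lib2: BinnedLibrary,
    ctrl2: BinnedLibrary,
    target_fdr: float = 0.05,
    control_fold: float = 2.0,
    control_iters: int = 2,
    t: float = 3.0,
    percentile_cutoff: float = 0.5,
    per_chromosome: bool = False,
) -> ChipnormResult:
    """Run both stages and merge labeled bins into regions.

    With ``per_chromosome=True`` the null estimation, control normalization
    and quantile fits are all chromosome-local; by default they are
    genome-wide.
    """
    layouts = {lib.layout for lib in (lib1, ctrl1, lib2, ctrl2)}
    if len(layouts) != 1:
        a, b = lib1.layout, next(l for l in layouts if l != lib1.layout)
        for (n1, l1), (n2, l2) in zip(a.chromosomes, b.chromosomes):
            if (n1, l1) != (n2, l2):
                raise ValueError(
                    f"libraries disagree on chromosome {n1!r}/{n2!r}"
                )
        raise ValueError("libraries do not share a genome layout")
    layout = lib1.layout

    if per_chromosome and len(layout.chromosomes) > 1:
        offsets = layout.chrom_offsets()
        nbins = layout.bins_per_chrom()
        labels = np.zeros(layout.n_bins, dtype=np.int8)
        norm1 = np.full(layout.n_bins, np.nan)
        norm2 = np.full(layout.n_bins, np.nan)
        stage2 = np.zeros(layout.n_bins, dtype=bool)
        reports = {}
        for name, _ in layout.chromosomes:
            sub = run_chipnorm(
                _slice_library(lib1, name),
                _slice_library(ctrl1, name),
                _slice_library(lib2, name),
                _slice_library(ctrl2, name),
                target_fdr=target_fdr,
                control_fold=control_fold,
                control_iters=control_iters,
                t=t,
                percentile_cutoff=percentile_cutoff,
            )
            sl = slice(offsets[name], offsets[name] + nbins[name])
            labels[sl] = sub.labels.labels
            norm1[sl] = sub.labels.norm1
            norm2[sl] = sub.labels.norm2
            stage2[sl] = sub.stage2
            reports[name] = sub.report
        bl = BinLabels(labels=labels, norm1=norm1, norm2=norm2, stage2=stage2)
        return ChipnormResult(
            labels=bl,
            regions=merge_regions(bl, layout),
            stage2=stage2,
            report={"per_chromosome": reports, **bl.counts_by_label()},
        )

    params1 = estimate_abd(lib1)
    params2 = estimate_abd(lib2)
    sig1 = fdr_threshold(lib1, params1, target_fdr)
    sig2 = fdr_threshold(lib2, params2, target_fdr)
    enr1 = iterative_normalize_control(lib1, ctrl1, control_fold, control_iters)
    enr2 = iterative_normalize_control(lib2, ctrl2, control_fold, control_iters)
    es1 = enriched_significant(sig1, enr1)
    es2 = enriched_significant(sig2, enr2)
    stage2 = stage2_bin_set(es1, es2)

    bl = label_bins(
        lib1.counts, lib2.counts, stage2, t=t, percentile_cutoff=percentile_cutoff
    )
    regions = merge_regions(bl, layout)
    report = {
        "abd_lib1": {"n0": params1.n0, "amp": params1.amp, "bins": params1.bins},
        "abd_lib2": {"n0": params2.n0, "amp": params2.amp, "bins": params2.bins},
        "count_threshold_lib1": sig1.count_threshold,
        "count_threshold_lib2": sig2.count_threshold,
        "n_significant": [int(sig1.mask.sum()), int(sig2.mask.sum())],
        "n_control_enriched": [int(enr1.mask.sum()), int(enr2.mask.sum())],
        "n_enriched_significant": [int(es1.sum()), int(es2.sum())],
        "n_stage2": int(stage2.sum()),
        **bl.counts_by_label(),
        "n_regions": len(regions),
        "params": {
            "target_fdr": target_fdr,
            "control_fold": control_fold,
            "control_iters": control_iters,
            "t": t,
            "percentile_cutoff": percentile_cutoff,
        },
    }
    return ChipnormResult(labels=bl, regions=regions, stage2=stage2, report=report)
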