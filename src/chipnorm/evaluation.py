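"""Evaluation procedures: gene-density bias, promoter sensitivity, ROC,
replicate false-positive rate, and promoter-state gene classifiers.

Differential histone-mark calls cannot be validated directly (no ground truth
exists for real libraries), so these procedures score calls indirectly:
against gene density (marks concentrate in gene-rich regions), against
two-condition expression data (a repressive mark's differential enrichment
should oppose expression), and against replicate pairs (where every
differential call is a false positive).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .diff_norm import CHE, DHE_LIB1, DHE_LIB2, NONE, BinLabels, LABEL_NAMES
from .io_binning import GeneSet, GenomeLayout, RegionSet

PROMOTER_HALFWIDTH = 1000  # TSS +/- 1 kbp

STATE_NAMES = {
    (False, False): "none",
    (True, False): "K4",
    (False, True): "K27",
    (True, True): "K4+K27",
}


def labels_from_regions(regions: RegionSet, layout: GenomeLayout) -> BinLabels:
    """Paint labeled regions (possibly from an external caller) onto bins."""
    code_of = {name: code for code, name in LABEL_NAMES.items()}
    labels = np.full(layout.n_bins, NONE, dtype=np.int8)
    offsets = layout.chrom_offsets()
    bs = layout.bin_size
    for row in regions.df.itertuples(index=False):
        if row.chrom not in offsets or row.label not in code_of:
            continue
        first = row.start // bs
        last = (row.end - 1) // bs
        labels[offsets[row.chrom] + first : offsets[row.chrom] + last + 1] = code_of[
            row.label
        ]
    n = layout.n_bins
    return BinLabels(
        labels=labels,
        norm1=np.full(n, np.nan),
        norm2=np.full(n, np.nan),
        stage2=labels != NONE,
    )


# ---------------------------------------------------------------------------
# gene-density bias


def window_values(
    values: np.ndarray, layout: GenomeLayout, window: int = 1_000_000
) -> pd.DataFrame:
    """Sum a per-bin vector within fixed windows; one row per window."""
    rows = []
    offsets = layout.chrom_offsets()
    nbins = layout.bins_per_chrom()
    bs = layout.bin_size
    if window % bs != 0:
        raise ValueError("window must be a multiple of the bin size")
    bins_per_window = window // bs
    for name, length in layout.chromosomes:
        chrom_vals = np.asarray(values, dtype=float)[
            offsets[name] : offsets[name] + nbins[name]
        ]
        for w0 in range(0, nbins[name], bins_per_window):
            rows.append(
                (name, w0 * bs, float(chrom_vals[w0 : w0 + bins_per_window].sum()))
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "value"])


def _gene_counts_per_window(
    genes: GeneSet, layout: GenomeLayout, window: int
) -> pd.DataFrame:
    rows = []
    for name, length in layout.chromosomes:
        sub = genes.df[genes.df["chrom"] == name]
        # a gene counts once per window even with multiple TSS records
        per_gene_window = (
            sub.assign(win=sub["tss"] // window)
            .drop_duplicates(["gene_id", "win"])["win"]
            .value_counts()
        )
        for w0 in range(0, length, window):
            rows.append((name, w0, int(per_gene_window.get(w0 // window, 0))))
    return pd.DataFrame(rows, columns=["chrom", "start", "genes"])


def gene_density_profile(
    values: np.ndarray,
    genes: GeneSet,
    layout: GenomeLayout,
    window: int = 1_000_000,
    classes: int = 10,
) -> np.ndarray:
    """Mean per-window value across gene-density classes.

    The genome is tiled into ``window``-bp regions, ranked by gene count and
    split into ``classes`` equal-occupancy classes (lowest density first);
    the return value is the mean summed ``values`` per window in each class.
    ``values`` may be fragment counts or a 0/1 enriched-bin indicator.
    """
    if classes < 2:
        raise ValueError("need at least 2 classes")
    wv = window_values(values, layout, window)
    gc = _gene_counts_per_window(genes, layout, window)
    merged = wv.merge(gc, on=["chrom", "start"])
    if len(merged) < classes:
        raise ValueError(f"only {len(merged)} windows for {classes} classes")
    order = np.argsort(merged["genes"].to_numpy(), kind="stable")
    groups = np.array_split(order, classes)
    return np.array([merged["value"].to_numpy()[g].mean() for g in groups])


def density_bias_spearman(
    enriched: np.ndarray,
    truth_signal: np.ndarray,
    layout: GenomeLayout,
    window: int = 1_000_000,
) -> float:
    """Spearman correlation between windowed call density and true-signal density."""
    a = window_values(np.asarray(enriched, dtype=float), layout, window)["value"]
    b = window_values(np.asarray(truth_signal, dtype=float), layout, window)["value"]
    rho = spearmanr(a, b).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# promoter machinery


def promoter_label_sets(
    labels: BinLabels,
    genes: GeneSet,
    layout: GenomeLayout,
    halfwidth: int = PROMOTER_HALFWIDTH,
) -> dict[str, set[int]]:
    """Label codes present in any promoter bin, per gene.

    A gene's promoter set is the union over its TSS records of
    ``TSS ± halfwidth``; a bin counts if its interval overlaps that window
    (half-open intersection).
    """
    offsets = layout.chrom_offsets()
    nbins = layout.bins_per_chrom()
    bs = layout.bin_size
    out: dict[str, set[int]] = {g: set() for g in genes.gene_ids}
    for row in genes.df.itertuples(index=False):
        if row.chrom not in offsets:
            continue
        length = layout.chrom_length(row.chrom)
        lo = max(0, row.tss - halfwidth)
        hi = min(length, row.tss + halfwidth + 1)  # inclusive +/- halfwidth
        if lo >= hi:
            continue
        first = lo // bs
        last = (hi - 1) // bs
        sl = labels.labels[offsets[row.chrom] + first : offsets[row.chrom] + last + 1]
        out[row.gene_id].update(int(c) for c in np.unique(sl))
    for s in out.values():
        s.discard(0)
    return out


def select_differential_genes(
    expr: pd.DataFrame, fold: float = 4.0, pseudocount: float = 1.0
) -> tuple[list[str], list[str]]:
    """Genes at least ``fold`` over-expressed in condition 2 resp. condition 1.

    Ratios are computed with a pseudocount to guard zero expression.
    """
    r = (expr["expr_cond2"] + pseudocount) / (expr["expr_cond1"] + pseudocount)
    cond2_over = list(expr.index[r >= fold])
    cond1_over = list(expr.index[r <= 1.0 / fold])
    return cond2_over, cond1_over


def promoter_sensitivity(
    labels: BinLabels,
    genes: GeneSet,
    expr: pd.DataFrame,
    layout: GenomeLayout,
    fold: float = 4.0,
    halfwidth: int = PROMOTER_HALFWIDTH,
) -> dict:
    """Promoter-level sensitivity/error against differential expression.

    Under the repressive-mark convention, genes over-expressed in condition 2
    should carry condition-1 differential enrichment (DHE_LIB1) at their
    promoter; a DHE_LIB2 bin there instead is an error.  Percentages are out
    of the selected genes on each side; a gene with several promoters counts
    once if any qualifies.
    """
    if fold <= 1.0:
        raise ValueError("expression fold must exceed 1")
    cond2_over, cond1_over = select_differential_genes(expr, fold)
    if not cond2_over and not cond1_over:
        raise ValueError(
            f"no gene passes the {fold}-fold expression filter "
            f"({len(expr)} genes tested)"
        )
    promo = promoter_label_sets(labels, genes, layout, halfwidth)

    def side(selected: list[str], expect: int, oppose: int) -> dict:
        n = len(selected)
        hits = sum(1 for g in selected if expect in promo.get(g, set()))
        errs = sum(1 for g in selected if oppose in promo.get(g, set()))
        return {
            "n_genes": n,
            "sensitivity_pct": 100.0 * hits / n if n else float("nan"),
            "error_pct": 100.0 * errs / n if n else float("nan"),
        }

    return {
        "cond2_over": side(cond2_over, DHE_LIB1, DHE_LIB2),
        "cond1_over": side(cond1_over, DHE_LIB2, DHE_LIB1),
    }


def roc_points(
    labels_by_threshold: list[tuple[float, BinLabels]],
    genes: GeneSet,
    expr: pd.DataFrame,
    layout: GenomeLayout,
    fold: float = 4.0,
    halfwidth: int = PROMOTER_HALFWIDTH,
) -> dict[str, list[tuple[float, float]]]:
    """ROC points over a threshold sweep, one curve per direction.

    The three-way decision (enriched toward 1 / toward 2 / neither) is cast
    as two one-sided problems.  First curve: Class 1 = genes over-expressed
    in condition 2, a positive call = DHE_LIB1 at the promoter.  Second
    curve: the mirror.  Points are ordered by threshold.
    """
    if len(labels_by_threshold) < 1:
        raise ValueError("need at least one threshold")
    cond2_over, cond1_over = select_differential_genes(expr, fold)
    if not cond2_over or not cond1_over:
        raise ValueError("empty gene class: cannot build ROC")
    all_genes = genes.gene_ids
    curves: dict[str, list[tuple[float, float]]] = {"cond2_over": [], "cond1_over": []}
    for thr, labels in sorted(labels_by_threshold, key=lambda kv: kv[0]):
        promo = promoter_label_sets(labels, genes, layout, halfwidth)
        for key, class1, code in (
            ("cond2_over", set(cond2_over), DHE_LIB1),
            ("cond1_over", set(cond1_over), DHE_LIB2),
        ):
            tp = fn = fp = tn = 0
            for g in all_genes:
                called = code in promo.get(g, set())
                if g in class1:
                    tp += called
                    fn += not called
                else:
                    fp += called
                    tn += not called
            tpr = tp / (tp + fn) if tp + fn else float("nan")
            fpr = fp / (fp + tn) if fp + tn else float("nan")
            curves[key].append((fpr, tpr))
    return curves


def replicate_fpr(labels: BinLabels) -> float:
    """Percentage of evaluated (stage-2) bins called differential.

    On a replicate pair no true differences exist, so every DHE call is a
    false positive.
    """
    evaluated = int(labels.stage2.sum())
    if evaluated == 0:
        return 0.0
    n_dhe = int(np.isin(labels.labels, (DHE_LIB1, DHE_LIB2)).sum())
    return 100.0 * n_dhe / evaluated


# ---------------------------------------------------------------------------
# gene classifiers


def classify_gene_types(
    labels: BinLabels,
    genes: GeneSet,
    layout: GenomeLayout,
    halfwidth: int = PROMOTER_HALFWIDTH,
) -> dict[str, int]:
    """Four-way promoter classification for one mark.

    Type 1: no DHE or CHE bin at the promoter.  Type 2: at least one
    DHE_LIB1 bin but no CHE and no DHE_LIB2.  Type 4: the mirror.  Type 3:
    at least one CHE bin, or bins of both DHE labels.  The four types are
    exhaustive and mutually exclusive.
    """
    promo = promoter_label_sets(labels, genes, layout, halfwidth)
    out: dict[str, int] = {}
    for g, codes in promo.items():
        has1, has2, has_che = DHE_LIB1 in codes, DHE_LIB2 in codes, CHE in codes
        if not (has1 or has2 or has_che):
            out[g] = 1
        elif has_che or (has1 and has2):
            out[g] = 3
        elif has1:
            out[g] = 2
        else:
            out[g] = 4
    return out


def promoter_mark_state(
    labels: BinLabels,
    genes: GeneSet,
    layout: GenomeLayout,
    halfwidth: int = PROMOTER_HALFWIDTH,
) -> dict[str, tuple[bool, bool]]:
    """Per gene: is the mark present in cell type 1 resp. cell type 2?

    Present means enriched *for* that cell type — DHE toward it or CHE;
    a mark detected but depleted relative to the other cell type counts as
    absent.
    """
    promo = promoter_label_sets(labels, genes, layout, halfwidth)
    return {
        g: (DHE_LIB1 in codes or CHE in codes, DHE_LIB2 in codes or CHE in codes)
        for g, codes in promo.items()
    }


def bivalent_classes(
    k27_labels: BinLabels,
    k27_layout: GenomeLayout,
    k4_labels: BinLabels,
    k4_layout: GenomeLayout,
    genes: GeneSet,
    halfwidth: int = PROMOTER_HALFWIDTH,
) -> dict[str, str]:
    """16-class promoter state across two marks and two cell types.

    Each cell type's promoter state is one of {none, K4, K27, K4+K27} from
    the per-mark presence calls; the class label is "state1-state2" (cell
    type 1 first).  The two marks may be binned on different layouts.
    """
    k27 = promoter_mark_state(k27_labels, genes, k27_layout, halfwidth)
    k4 = promoter_mark_state(k4_labels, genes, k4_layout, halfwidth)
    out: dict[str, str] = {}
    for g in genes.gene_ids:
        k27_1, k27_2 = k27.get(g, (False, False))
        k4_1, k4_2 = k4.get(g, (False, False))
        s1 = STATE_NAMES[(k4_1, k27_1)]
        s2 = STATE_NAMES[(k4_2, k27_2)]
        out[g] = f"{s1}-{s2}"
    return out
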