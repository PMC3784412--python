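"""Co-expression as a function of genomic distance, with a cross-chromosome baseline.

Pair distance is measured between gene start sites; a pair whose starts are
351 kb apart contributes to the 350-360 kb bin.  Pairs with undefined
correlation (zero-variance profiles) are dropped from both numerator and
denominator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from chromnest.expression import ExpressionMatrix, correlation_matrix
from chromnest.genome import GenomeAnnotation

DEFAULT_BIN_WIDTH = 10_000
DEFAULT_MAX_DIST = 60_000_000
DEFAULT_MAX_CROSS_PAIRS = 2_000_000


def _aligned_matrix(m: ExpressionMatrix, ann: GenomeAnnotation, method: str):
    """Correlation matrix and per-gene (chrom code, start) aligned to ann order."""
    ids = [g.gene_id for g in ann if g.gene_id in m.values.index]
    sub = m.subset_genes(ids)
    corr = correlation_matrix(sub, method=method)
    by_id = {g.gene_id: g for g in ann}
    chroms = np.array([by_id[i].interval.chrom for i in ids])
    starts = np.array([by_id[i].interval.start for i in ids], dtype=np.int64)
    return ids, corr, chroms, starts


def binned_distance_correlation(
    m: ExpressionMatrix,
    ann: GenomeAnnotation,
    bin_width: int = DEFAULT_BIN_WIDTH,
    max_dist: int = DEFAULT_MAX_DIST,
    method: str = "spearman",
) -> pd.DataFrame:
    """Mean pairwise correlation of same-chromosome gene pairs, binned by distance.

    Returns a table (bin_lo, bin_hi, mean_corr, n_pairs) with half-open bins
    [lo, hi); empty bins are reported with n_pairs = 0 and NaN mean.  The
    table's ``attrs`` carry ``n_pairs_beyond_max`` (same-chromosome pairs at or
    past ``max_dist``) and ``n_cross_chrom_pairs`` so total pair counts can be
    audited.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ids, corr, chroms, starts = _aligned_matrix(m, ann, method)
    n = len(ids)
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    beyond = 0
    cross = 0
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        k = len(idx)
        cross += k * (n - k)
        if k < 2:
            continue
        s = starts[idx]
        iu, ju = np.triu_indices(k, 1)
        d = np.abs(s[ju] - s[iu])
        r = corr[np.ix_(idx, idx)][iu, ju]
        ok = ~np.isnan(r)
        d, r = d[ok], r[ok]
        far = d >= max_dist
        beyond += int(far.sum())
        d, r = d[~far], r[~far]
        b = d // bin_width
        sums += np.bincount(b, weights=r, minlength=n_bins)
        counts += np.bincount(b, minlength=n_bins)
    cross //= 2
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    lo = np.arange(n_bins, dtype=np.int64) * bin_width
    out = pd.DataFrame(
        {"bin_lo": lo, "bin_hi": lo + bin_width, "mean_corr": means, "n_pairs": counts}
    )
    out.attrs["n_pairs_beyond_max"] = beyond
    out.attrs["n_cross_chrom_pairs"] = cross
    return out


def cross_chromosome_baseline(
    m: ExpressionMatrix,
    ann: GenomeAnnotation,
    method: str = "spearman",
    max_pairs: int = DEFAULT_MAX_CROSS_PAIRS,
    seed: int = 0,
) -> dict:
    """Mean correlation of gene pairs on different chromosomes.

    Enumerates all cross-chromosome pairs when there are at most ``max_pairs``
    of them; otherwise draws ``max_pairs`` pairs uniformly without replacement
    using ``seed``.  Returns mean, SE, the number of pairs used, and whether
    the estimate was subsampled.
    """
    ids, corr, chroms, _ = _aligned_matrix(m, ann, method)
    if len(set(chroms)) < 2:
        raise ValueError("cross-chromosome baseline needs >= 2 chromosomes")
    n = len(ids)
    iu, ju = np.triu_indices(n, 1)
    mask = chroms[iu] != chroms[ju]
    iu, ju = iu[mask], ju[mask]
    total = len(iu)
    subsampled = total > max_pairs
    if subsampled:
        rng = np.random.default_rng(seed)
        take = rng.choice(total, size=max_pairs, replace=False)
        iu, ju = iu[take], ju[take]
    r = corr[iu, ju]
    r = r[~np.isnan(r)]
    if len(r) == 0:
        raise ValueError("no defined cross-chromosome correlations")
    return {
        "mean": float(r.mean()),
        "se": float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else float("nan"),
        "n_pairs": int(len(r)),
        "subsampled": bool(subsampled),
        "seed": int(seed),
    }


def plot_distance_profile(profile: pd.DataFrame, baseline: float, path) -> None:
    """Write a diagnostic scatter: circle area ~ n_pairs, baseline as a red line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = profile[profile["n_pairs"] > 0]
    x = (sub["bin_lo"] + sub["bin_hi"]) / 2000.0  # kb
    sizes = 4 + 60 * sub["n_pairs"] / max(sub["n_pairs"].max(), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.scatter(x, sub["mean_corr"], s=sizes, alpha=0.6, edgecolors="none")
    ax.axhline(baseline, color="red", lw=1)
    ax.set_xlabel("genomic distance (kb)")
    ax.set_ylabel("mean pairwise correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
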