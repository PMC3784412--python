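"""Distribution comparisons between gene sets and the hub-enrichment test.

Thin, configurable wrappers: Wilcoxon rank-sum with continuity correction
(Mann-Whitney U) and the two-sample Kolmogorov-Smirnov test for comparing
score distributions, plus a 2x2 chi-square for protein-interaction "hub"
enrichment.  Significance calls (p <= 0.05 in the source analyses) are left
to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ComparisonResult:
    wilcoxon_stat: float
    wilcoxon_p: float
    ks_stat: float
    ks_p: float


def _clean(sample) -> np.ndarray:
    arr = np.asarray(sample, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        raise ValueError("empty sample")
    return arr


def compare_distributions(
    sample_a, sample_b, alternative: str = "two-sided"
) -> ComparisonResult:
    """Wilcoxon rank-sum (with continuity correction) + two-sample KS.

    Missing values are removed first; each sample needs n >= 3.
    """
    a, b = _clean(sample_a), _clean(sample_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 values")
    mw = stats.mannwhitneyu(a, b, alternative=alternative, use_continuity=True)
    ks = stats.ks_2samp(a, b, alternative="two-sided" if alternative == "two-sided" else alternative)
    return ComparisonResult(
        wilcoxon_stat=float(mw.statistic),
        wilcoxon_p=float(mw.pvalue),
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
    )


def hub_enrichment(
    interaction_counts: pd.Series,
    set_a,
    set_b,
    hub_min: int = 10,
    yates: bool = False,
) -> dict:
    """Chi-square test of hub proportion (>= hub_min interactions) between sets.

    Raises if either set is empty or a gene lacks an interaction count.
    """
    set_a, set_b = list(set_a), list(set_b)
    if not set_a or not set_b:
        raise ValueError("both gene sets must be non-empty")
    for gid in set_a + set_b:
        if gid not in interaction_counts.index:
            raise KeyError(f"no interaction count for gene {gid}")
    hubs_a = int((interaction_counts.loc[set_a] >= hub_min).sum())
    hubs_b = int((interaction_counts.loc[set_b] >= hub_min).sum())
    table = np.array(
        [[hubs_a, len(set_a) - hubs_a], [hubs_b, len(set_b) - hubs_b]], dtype=float
    )
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=yates)
    return {
        "table": table,
        "chi2": float(chi2),
        "p": float(p),
        "dof": int(dof),
        "hub_frac_a": hubs_a / len(set_a),
        "hub_frac_b": hubs_b / len(set_b),
    }


def tns_by_regulation_class(
    best_tns: pd.Series, gene_classes: pd.Series, alternative: str = "two-sided"
) -> pd.DataFrame:
    """Pairwise distribution comparisons of best-TNS between regulation classes.

    ``gene_classes`` maps gene_id to a label (e.g. up / down / unregulated /
    expressed / not_expressed); labels partition the genes.  Returns one row
    per unordered class pair with both tests' statistics and p-values; a
    single class yields an empty table.
    """
    labels = [l for l in pd.unique(gene_classes) if pd.notna(l)]
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            a = best_tns.loc[gene_classes.index[gene_classes == la].intersection(best_tns.index)]
            b = best_tns.loc[gene_classes.index[gene_classes == lb].intersection(best_tns.index)]
            res = compare_distributions(a, b, alternative=alternative)
            rows.append(
                {
                    "class_a": la,
                    "class_b": lb,
                    "n_a": len(a.dropna()),
                    "n_b": len(b.dropna()),
                    "wilcoxon_stat": res.wilcoxon_stat,
                    "wilcoxon_p": res.wilcoxon_p,
                    "ks_stat": res.ks_stat,
                    "ks_p": res.ks_p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "class_a", "class_b", "n_a", "n_b",
            "wilcoxon_stat", "wilcoxon_p", "ks_stat", "ks_p",
        ],
    )


def read_interaction_counts(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["n_interactions"].values, index=df["gene_id"].astype(str))
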