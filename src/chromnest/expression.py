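"""Expression-matrix model: detection-call filtering, log transform, tissue calls.

The matrix emulates Affymetrix-style data: log2 intensity values plus MAS5-like
Present/Marginal/Absent detection calls per gene x sample, with sample metadata
(tissue, timepoint, replicate).  Marginal calls count as not-Present throughout
(the conservative MAS5 convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CALLS = ("P", "M", "A")

#: Intensities are floored here before log2 so synthetic zeros stay finite.
INTENSITY_FLOOR = 1.0

MIN_SAMPLES_FOR_CORRELATION = 5


@dataclass
class ExpressionMatrix:
    """log2 intensities and detection calls, genes x samples.

    ``values`` and ``calls`` are DataFrames indexed by gene_id with identical
    shape and column order; ``samples`` is a DataFrame with one row per column
    of ``values`` carrying (sample_id, tissue, timepoint, replicate).
    """

    values: pd.DataFrame
    calls: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.calls.shape:
            raise ValueError("values and calls must be congruent in shape")
        if not self.values.columns.equals(self.calls.columns):
            raise ValueError("values and calls must share sample columns")
        if not self.values.index.equals(self.calls.index):
            raise ValueError("values and calls must share the gene index")
        required = {"sample_id", "tissue", "timepoint", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if list(self.samples["sample_id"]) != list(self.values.columns):
            raise ValueError("sample sheet order must match matrix columns")
        bad = set(np.unique(self.calls.to_numpy())) - set(CALLS)
        if bad:
            raise ValueError(f"invalid detection calls: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def tissues(self) -> list[str]:
        out: list[str] = []
        for t in self.samples["tissue"]:
            if t not in out:
                out.append(t)
        return out

    def tissue_columns(self, tissue: str) -> list[str]:
        cols = list(self.samples.loc[self.samples["tissue"] == tissue, "sample_id"])
        if not cols:
            raise KeyError(f"unknown tissue: {tissue!r}")
        return cols

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = pd.Index(gene_ids)
        return ExpressionMatrix(
            self.values.loc[idx], self.calls.loc[idx], self.samples.copy()
        )


def log2_transform(raw: pd.DataFrame, *, floor: float = INTENSITY_FLOOR) -> pd.DataFrame:
    """Elementwise log2 of raw intensities after flooring at ``floor``.

    Raises if anything is still non-positive after the floor (a floor of 0
    disables flooring).
    """
    arr = raw.to_numpy(dtype=float)
    if floor > 0:
        arr = np.maximum(arr, floor)
    if (arr <= 0).any():
        raise ValueError("non-positive intensities remain after flooring")
    return pd.DataFrame(np.log2(arr), index=raw.index, columns=raw.columns)


def filter_min_present(m: ExpressionMatrix, k: int = 5) -> ExpressionMatrix:
    """Drop genes with fewer than ``k`` Present calls across all samples.

    k = 5 is the default because pairwise correlation needs at least 5 values.
    Monotone in k: the genes removed at k are a subset of those removed at k+1.
    """
    if k > m.n_samples:
        raise ValueError(f"k={k} exceeds sample count {m.n_samples}")
    keep = (m.calls == "P").sum(axis=1) >= k
    return ExpressionMatrix(m.values.loc[keep], m.calls.loc[keep], m.samples.copy())


def expressed_in_tissue(m: ExpressionMatrix, tissue: str, rule: str = "all") -> pd.Series:
    """Per-gene boolean expressed flag for one tissue.

    rule="all" (default): Present in every replicate/sample of the tissue.
    rule="any": Present in at least one.
    """
    cols = m.tissue_columns(tissue)
    present = m.calls[cols] == "P"
    if rule == "all":
        return present.all(axis=1)
    if rule == "any":
        return present.any(axis=1)
    raise ValueError(f"unknown rule: {rule!r}")


def pairwise_correlation(
    m: ExpressionMatrix, gene_a: str, gene_b: str, method: str = "spearman"
) -> float:
    """Correlation between two genes' profiles over all samples of the matrix.

    Spearman rho by default.  Requires >= 5 samples; a zero-variance profile
    makes the correlation undefined and returns NaN.
    """
    if m.n_samples < MIN_SAMPLES_FOR_CORRELATION:
        raise ValueError(
            f"at least {MIN_SAMPLES_FOR_CORRELATION} samples are needed for correlation"
        )
    a = m.values.loc[gene_a].to_numpy(dtype=float)
    b = m.values.loc[gene_b].to_numpy(dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    if method == "spearman":
        rho = stats.spearmanr(a, b).statistic
    elif method == "pearson":
        rho = stats.pearsonr(a, b).statistic
    else:
        raise ValueError(f"unknown method: {method!r}")
    return float(rho)


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Average-tie ranks of each row across samples (Spearman preprocessing)."""
    return np.apply_along_axis(stats.rankdata, 1, values)


def correlation_matrix(m: ExpressionMatrix, method: str = "spearman") -> np.ndarray:
    """Gene x gene correlation matrix over all samples.

    Spearman = Pearson on within-gene ranks.  Rows with zero variance get NaN
    against every partner (undefined, later treated as unscorable).
    """
    vals = m.values.to_numpy(dtype=float)
    if method == "spearman":
        vals = rank_transform(vals)
    elif method != "pearson":
        raise ValueError(f"unknown method: {method!r}")
    sd = vals.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals)
    corr = np.asarray(corr, dtype=float)
    bad = sd == 0
    corr[bad, :] = np.nan
    corr[:, bad] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr[bad, bad] = np.nan
    return corr


# ---------------------------------------------------------------------------
# IO: TSV matrix + congruent call file + sample sheet


def read_expression(values_path, calls_path, samples_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    calls = pd.read_csv(calls_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str, "tissue": str})
    values.index = values.index.astype(str)
    calls.index = calls.index.astype(str)
    return ExpressionMatrix(values, calls, samples)


def write_expression(m: ExpressionMatrix, values_path, calls_path, samples_path) -> None:
    m.values.to_csv(values_path, sep="\t", float_format="%.6g")
    m.calls.to_csv(calls_path, sep="\t")
    m.samples.to_csv(samples_path, sep="\t", index=False)
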