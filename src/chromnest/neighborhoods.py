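"""Neighborhood scoring: windows of adjacent genes scored by co-expression and synteny.

A candidate neighborhood is a run of 2-10 consecutive probed genes.  Its Total
Neighborhood Score is

    TNS = SS * ANC   if the permutation p-value <= alpha and ANC > 0, else 0

where ANC (Average Neighborhood Correlation) is the mean of all pairwise
expression correlations among the window's genes, SS (Synteny Score) is the
fraction of comparison genomes in which all window genes lie in one syntenic
block, and p is estimated against randomized transcriptomes: expression
profiles are shuffled across genome positions with the annotation fixed, and
the null ANC distribution is pooled over windows of the same size.

Windows containing an undefined pairwise correlation are unscorable: their ANC
and TNS are NaN (not 0) and they are excluded from downstream distribution
tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from chromnest.expression import ExpressionMatrix, correlation_matrix
from chromnest.genome import Gene, GenomeAnnotation, GenomicInterval

DEFAULT_MIN_GENES = 2
DEFAULT_MAX_GENES = 10
DEFAULT_ALPHA = 0.05


@dataclass
class SyntenyMap:
    """Per comparison genome: gene_id -> (block_id, order_index).

    The reference genome itself must not appear among the comparison genomes
    (it is trivially syntenic with itself and would inflate SS).
    """

    genomes: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    reference: str = "reference"

    def __post_init__(self) -> None:
        if self.reference in self.genomes:
            raise ValueError("reference genome must not be a comparison genome")
        for name, mapping in self.genomes.items():
            seen: dict[int, set[int]] = {}
            for block, order in mapping.values():
                if order in seen.setdefault(block, set()):
                    raise ValueError(
                        f"duplicate order_index {order} in block {block} of {name}"
                    )
                seen[block].add(order)

    @property
    def genome_names(self) -> list[str]:
        return list(self.genomes)

    def __len__(self) -> int:
        return len(self.genomes)


@dataclass
class ScoredWindow:
    """One scored candidate neighborhood."""

    genes: list[Gene]
    interval: GenomicInterval
    anc: float
    ss: float
    p: float
    tns: float
    ncadr: float = float("nan")
    ncsdr: float = float("nan")

    def __post_init__(self) -> None:
        if not (DEFAULT_MIN_GENES <= len(self.genes) <= DEFAULT_MAX_GENES):
            raise ValueError("a window holds 2-10 genes")


def enumerate_windows(
    ann: GenomeAnnotation, min_k: int = DEFAULT_MIN_GENES, max_k: int = DEFAULT_MAX_GENES
):
    """Yield every run of k consecutive probed genes per chromosome, k in [min_k, max_k].

    The annotation must already be ordered, overlap-resolved and restricted to
    probed genes.  Per chromosome with n genes the count is
    sum_k max(0, n - k + 1).
    """
    if min_k < 2:
        raise ValueError("min_k must be >= 2")
    if max_k < min_k:
        raise ValueError("max_k must be >= min_k")
    for chrom in ann.chromosomes:
        genes = ann.by_chromosome(chrom)
        n = len(genes)
        for k in range(min_k, max_k + 1):
            for i in range(n - k + 1):
                yield genes[i : i + k]


def window_interval(genes: list[Gene]) -> GenomicInterval:
    return GenomicInterval(
        genes[0].interval.chrom,
        min(g.interval.start for g in genes),
        max(g.interval.end for g in genes),
    )


def anc(genes, m: ExpressionMatrix, method: str = "spearman") -> float:
    """Mean of all C(k,2) pairwise correlations among the window's genes.

    NaN (unscorable) if any pair's correlation is undefined.
    """
    sub = m.subset_genes([g.gene_id for g in genes])
    corr = correlation_matrix(sub, method=method)
    iu, ju = np.triu_indices(len(genes), 1)
    vals = corr[iu, ju]
    if np.isnan(vals).any():
        return float("nan")
    return float(vals.mean())


def synteny_score(genes, smap: SyntenyMap, strict_order: bool = False) -> float:
    """Fraction of comparison genomes in which all window genes share one block.

    A gene missing from a genome's map breaks synteny in that genome.  With
    ``strict_order=True`` the genes' order indices must additionally step by
    +/-1 in one consistent direction (colinearity within the block).
    """
    if not smap.genomes:
        raise ValueError("synteny map is empty")
    kept = 0
    for mapping in smap.genomes.values():
        entries = [mapping.get(g.gene_id) for g in genes]
        if any(e is None for e in entries):
            continue
        blocks = {b for b, _ in entries}
        if len(blocks) != 1:
            continue
        if strict_order:
            orders = [o for _, o in entries]
            diffs = np.diff(orders)
            if not (np.all(diffs == 1) or np.all(diffs == -1)):
                continue
        kept += 1
    return kept / len(smap.genomes)


def tns(anc_value: float, ss: float, p: float, alpha: float = DEFAULT_ALPHA) -> float:
    """TNS = SS * ANC when p <= alpha and ANC > 0, else 0; clamped to [0, 1].

    NaN inputs (unscorable windows) propagate to NaN.
    """
    if np.isnan(anc_value) or np.isnan(p):
        return float("nan")
    if p > alpha or anc_value <= 0:
        return 0.0
    return float(min(max(ss * anc_value, 0.0), 1.0))


def permutation_p(observed: float, null_sample: np.ndarray) -> float:
    """Upper-tail permutation probability with the plus-one estimator."""
    null_sample = null_sample[~np.isnan(null_sample)]
    return (1 + int(np.sum(null_sample >= observed))) / (1 + len(null_sample))


# ---------------------------------------------------------------------------
# Vectorized whole-genome scoring


def _chromosome_slices(ann: GenomeAnnotation, ids: list[str]) -> list[tuple[int, int]]:
    by_id = {g.gene_id: g.interval.chrom for g in ann}
    chroms = [by_id[i] for i in ids]
    slices = []
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[i - 1]:
            slices.append((start, i))
            start = i
    return slices


def _window_anc_by_k(corr: np.ndarray, seq: np.ndarray, min_k: int, max_k: int):
    """Window ANCs for one chromosome's gene sequence, every k in [min_k, max_k].

    seq holds row indices into corr; windows are consecutive runs in seq.
    Returns {k: array of length len(seq)-k+1}.  Built incrementally: the pair
    sum of a k-window extends the (k-1)-window by the new gene's correlations
    with the k-1 existing members.
    """
    n = len(seq)
    out: dict[int, np.ndarray] = {}
    if n < 2:
        return out
    pair_sum = corr[seq[:-1], seq[1:]].astype(float)  # k = 2
    if min_k <= 2 <= max_k:
        out[2] = pair_sum.copy()  # C(2,2) = 1 pair
    for k in range(3, max_k + 1):
        m = n - k + 1
        if m <= 0:
            break
        new_col = np.zeros(m)
        last = seq[k - 1 : k - 1 + m]
        for d in range(k - 1):
            new_col += corr[seq[d : d + m], last]
        pair_sum = pair_sum[:m] + new_col
        if k >= min_k:
            out[k] = pair_sum / comb(k, 2)
    return out


def anc_null(
    m: ExpressionMatrix,
    ann: GenomeAnnotation,
    k: int,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "spearman",
    exhaustive: bool = False,
) -> np.ndarray:
    """Pooled null ANC sample for windows of size ``k``.

    Each permutation shuffles expression profiles across genome positions
    (annotation fixed, profiles permuted) and recomputes the ANC of every
    size-k window; the samples are pooled over windows and permutations.
    ``exhaustive=True`` enumerates all gene permutations (tiny genomes only).
    """
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100 (or use exhaustive=True)")
    ids = [g.gene_id for g in ann if g.gene_id in m.values.index]
    corr = correlation_matrix(m.subset_genes(ids), method=method)
    slices = _chromosome_slices(ann, ids)
    n = len(ids)
    null_vals: list[np.ndarray] = []
    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive enumeration is limited to <= 8 genes")
        perms = [np.array(p) for p in itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
    for perm in perms:
        for a, b in slices:
            got = _window_anc_by_k(corr, perm[a:b], k, k)
            if k in got:
                null_vals.append(got[k])
    if not null_vals:
        return np.array([])
    pooled = np.concatenate(null_vals)
    return pooled[~np.isnan(pooled)]


def score_windows(
    ann: GenomeAnnotation,
    m: ExpressionMatrix,
    smap: SyntenyMap,
    min_k: int = DEFAULT_MIN_GENES,
    max_k: int = DEFAULT_MAX_GENES,
    n_perm: int = 1000,
    seed: int = 0,
    method: str = "spearman",
    alpha: float = DEFAULT_ALPHA,
    strict_order: bool = False,
) -> pd.DataFrame:
    """Score every candidate window on the genome; the package's main computation.

    Returns a DataFrame with columns (chrom, start, end, n_genes, gene_ids,
    ANC, SS, p, TNS); gene_ids is a tuple of gene identifiers.  The null is
    conditioned on window size and pooled across windows and permutations; the
    plus-one estimator keeps p > 0.
    """
    if min_k < 2:
        raise ValueError("min_k must be >= 2")
    ids = [g.gene_id for g in ann if g.gene_id in m.values.index]
    id_to_gene = {g.gene_id: g for g in ann}
    corr = correlation_matrix(m.subset_genes(ids), method=method)
    slices = _chromosome_slices(ann, ids)
    n = len(ids)
    base = np.arange(n)

    # Observed ANC per window, grouped by k, remembering window locations.
    rows: dict[int, list[tuple[int, int]]] = {}  # k -> [(slice start, offset)]
    obs: dict[int, list[np.ndarray]] = {}
    for a, b in slices:
        got = _window_anc_by_k(corr, base[a:b], min_k, max_k)
        for k, arr in got.items():
            obs.setdefault(k, []).append(arr)
            rows.setdefault(k, []).extend((a, i) for i in range(len(arr)))
    obs_flat = {k: np.concatenate(v) for k, v in obs.items()}

    # Pooled null per k: count null values >= each observed value, streaming
    # over permutations to bound memory.
    ge_counts = {k: np.zeros(len(v), dtype=np.int64) for k, v in obs_flat.items()}
    n_null = {k: 0 for k in obs_flat}
    order = {k: np.argsort(v) for k, v in obs_flat.items()}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        per_k: dict[int, list[np.ndarray]] = {}
        for a, b in slices:
            got = _window_anc_by_k(corr, perm[a:b], min_k, max_k)
            for k, arr in got.items():
                per_k.setdefault(k, []).append(arr)
        for k, chunks in per_k.items():
            null_arr = np.concatenate(chunks)
            null_arr = null_arr[~np.isnan(null_arr)]
            null_arr.sort()
            n_null[k] += len(null_arr)
            sorted_obs = obs_flat[k][order[k]]
            # #{null >= o} = n - first index with null >= o
            pos = np.searchsorted(null_arr, sorted_obs, side="left")
            ge_counts[k][order[k]] += len(null_arr) - pos

    records = []
    for k in sorted(obs_flat):
        p_vals = (1.0 + ge_counts[k]) / (1.0 + n_null[k])
        for (a, off), anc_val, p_val in zip(rows[k], obs_flat[k], p_vals):
            genes = [id_to_gene[i] for i in ids[a + off : a + off + k]]
            iv = window_interval(genes)
            ss = synteny_score(genes, smap, strict_order=strict_order)
            p_out = float("nan") if np.isnan(anc_val) else float(p_val)
            records.append(
                {
                    "chrom": iv.chrom,
                    "start": iv.start,
                    "end": iv.end,
                    "n_genes": k,
                    "gene_ids": tuple(g.gene_id for g in genes),
                    "ANC": float(anc_val),
                    "SS": float(ss),
                    "p": p_out,
                    "TNS": tns(float(anc_val), float(ss), p_out, alpha=alpha),
                }
            )
    df = pd.DataFrame.from_records(
        records,
        columns=["chrom", "start", "end", "n_genes", "gene_ids", "ANC", "SS", "p", "TNS"],
    )
    return df.sort_values(["chrom", "start", "n_genes"], kind="stable").reset_index(drop=True)


def best_tns_per_gene(scored: pd.DataFrame, ann: GenomeAnnotation) -> pd.Series:
    """Highest TNS over all windows containing each gene.

    Genes in no window (chromosome singletons) score 0.  NaN-TNS (unscorable)
    windows are ignored.
    """
    best = {g.gene_id: 0.0 for g in ann}
    for gene_ids, t in zip(scored["gene_ids"], scored["TNS"]):
        if np.isnan(t):
            continue
        for gid in gene_ids:
            if t > best.get(gid, 0.0):
                best[gid] = float(t)
    return pd.Series(best, name="best_TNS")


# ---------------------------------------------------------------------------
# Run-based (detection-call) neighborhoods


def _ordered_flags(calls: pd.Series, ann: GenomeAnnotation):
    genes = list(ann)
    flags = np.array([bool(calls.get(g.gene_id, False)) for g in genes])
    return genes, flags


def present_run_neighborhoods(calls: pd.Series, ann: GenomeAnnotation) -> list[dict]:
    """Maximal runs of >= 2 adjacent expressed probed genes, per chromosome.

    ``calls`` is a per-gene boolean expressed flag (missing genes count as not
    expressed).  Each run reports its genes, interval and sizes in genes/bp.
    """
    runs = []
    for chrom in ann.chromosomes:
        genes = ann.by_chromosome(chrom)
        flags = np.array([bool(calls.get(g.gene_id, False)) for g in genes])
        i = 0
        while i < len(genes):
            if flags[i]:
                j = i
                while j + 1 < len(genes) and flags[j + 1]:
                    j += 1
                if j > i:
                    members = genes[i : j + 1]
                    iv = window_interval(members)
                    runs.append(
                        {
                            "chrom": chrom,
                            "gene_ids": tuple(g.gene_id for g in members),
                            "n_genes": len(members),
                            "start": iv.start,
                            "end": iv.end,
                            "span_bp": iv.span,
                        }
                    )
                i = j + 1
            else:
                i += 1
    return runs


def isolated_genes(calls: pd.Series, ann: GenomeAnnotation) -> list[str]:
    """Expressed genes whose flanking probed genes are all not expressed.

    At chromosome ends only the single existing flank is checked.
    """
    out = []
    for chrom in ann.chromosomes:
        genes = ann.by_chromosome(chrom)
        flags = np.array([bool(calls.get(g.gene_id, False)) for g in genes])
        for i, g in enumerate(genes):
            if not flags[i]:
                continue
            left = flags[i - 1] if i > 0 else False
            right = flags[i + 1] if i + 1 < len(genes) else False
            if not left and not right:
                out.append(g.gene_id)
    return out


def shared_fraction(neighborhoods: list[dict], calls_b: pd.Series) -> float:
    """Percentage of tissue-A neighborhoods whose every gene is expressed in B."""
    if not neighborhoods:
        return float("nan")
    shared = sum(
        1
        for nb in neighborhoods
        if all(bool(calls_b.get(gid, False)) for gid in nb["gene_ids"])
    )
    return 100.0 * shared / len(neighborhoods)


def _run_and_isolated_counts(flags: np.ndarray, breaks: np.ndarray) -> tuple[int, int]:
    """(# expressed genes inside runs of >= 2, # isolated expressed genes).

    ``breaks[i]`` is True where position i starts a new chromosome, so
    adjacency never crosses a chromosome boundary.
    """
    n = len(flags)
    if n == 0:
        return 0, 0
    left = np.zeros(n, dtype=bool)
    left[1:] = flags[:-1] & ~breaks[1:]
    right = np.zeros(n, dtype=bool)
    right[:-1] = flags[1:] & ~breaks[1:]
    in_run = flags & (left | right)
    isolated = flags & ~(left | right)
    return int(in_run.sum()), int(isolated.sum())


def membership_excess_test(
    calls: pd.Series,
    ann: GenomeAnnotation,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> dict:
    """Are expressed genes in runs more often — and isolated less often — than chance?

    The null permutes the expressed-flag vector across genome positions.  The
    in-run count is tested on the upper tail, the isolated count on the lower
    tail; sampled nulls use the plus-one estimator, exhaustive enumeration
    (all placements of the expressed flags) is exact.
    """
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100 (or use exhaustive=True)")
    genes, flags = _ordered_flags(calls, ann)
    chroms = [g.interval.chrom for g in genes]
    breaks = np.zeros(len(genes), dtype=bool)
    for i in range(1, len(genes)):
        breaks[i] = chroms[i] != chroms[i - 1]
    obs_run, obs_iso = _run_and_isolated_counts(flags, breaks)

    n, n_on = len(flags), int(flags.sum())
    if exhaustive:
        if comb(n, n_on) > 200_000:
            raise ValueError("exhaustive enumeration too large")
        ge = le = total = 0
        for ones in itertools.combinations(range(n), n_on):
            f = np.zeros(n, dtype=bool)
            f[list(ones)] = True
            r, s = _run_and_isolated_counts(f, breaks)
            ge += r >= obs_run
            le += s <= obs_iso
            total += 1
        p_run, p_iso = ge / total, le / total
    else:
        rng = np.random.default_rng(seed)
        ge = le = 0
        for _ in range(n_perm):
            f = rng.permutation(flags)
            r, s = _run_and_isolated_counts(f, breaks)
            ge += r >= obs_run
            le += s <= obs_iso
        p_run = (1 + ge) / (1 + n_perm)
        p_iso = (1 + le) / (1 + n_perm)
    return {
        "observed_in_run": obs_run,
        "p_in_run": float(p_run),
        "observed_isolated": obs_iso,
        "p_isolated": float(p_iso),
    }
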