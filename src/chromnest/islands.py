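"""Simplified broad-island calling from mapped tags, with the gap-size scan.

This is deliberately a reduced model of SICER-style island calling: the genome
is tiled with fixed windows (200 bp by default, about a nucleosome plus
linker), windows whose tag counts beat a Poisson background are "eligible",
and eligible windows separated by at most a gap of ineligible windows are
merged into islands.  There is no control-library window testing, redundancy
filtering or fragment-shift model; an input (unenriched) library, when given,
only rescales the background rate.  The pipeline's main path consumes
externally produced island files — this module exists to exercise the
gap-size optimization end to end.

The gap is chosen by scanning increasing gap multiples and maximizing the
aggregate island score.  For the scan to have an interior maximum the island
score must penalize bridged background: here an island's score is the sum of
its eligible windows' scores (-ln of the Poisson upper tail) minus a
per-window penalty for the ineligible windows it spans, and only islands whose
score clears a significance floor count toward the aggregate.  The penalty
defaults to the eligibility score floor, -ln(p_thresh): a bridged background
window counts against an island exactly as much as the weakest admissible
evidence counts for it, so widening the gap pays off only where it rescues
clustered sub-threshold fragments (internally gappy broad domains) and never
for absorbing isolated background windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from chromnest.chromatin import Island, IslandSet
from chromnest.genome import GenomicInterval

DEFAULT_WINDOW = 200
DEFAULT_P_THRESH = 1e-4
DEFAULT_MIN_ISLAND_SCORE = 40.0


@dataclass
class TagLibrary:
    """Mapped tag positions: (chrom, position, strand) plus genome metadata."""

    tags: pd.DataFrame
    chrom_sizes: dict[str, int]
    effective_genome_length: int | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand"}
        missing = required - set(self.tags.columns)
        if missing:
            raise ValueError(f"tag table missing columns: {sorted(missing)}")
        if self.effective_genome_length is None:
            self.effective_genome_length = int(sum(self.chrom_sizes.values()))
        for chrom, grp in self.tags.groupby("chrom"):
            size = self.chrom_sizes.get(str(chrom))
            if size is None:
                raise ValueError(f"tag on unknown chromosome {chrom}")
            if (grp["pos"] < 0).any() or (grp["pos"] >= size).any():
                raise ValueError(f"tag position outside chromosome {chrom}")

    @property
    def total_count(self) -> int:
        return len(self.tags)


@dataclass
class WindowTrack:
    """Per-window tag counts along each chromosome at fixed window size W."""

    window_size: int
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window size must be positive")

    @property
    def total_tags(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    @property
    def n_windows(self) -> int:
        return int(sum(len(c) for c in self.counts.values()))


def window_counts(lib: TagLibrary, w: int = DEFAULT_WINDOW) -> WindowTrack:
    """Bin tags into fixed windows: a tag at position p falls in window floor(p/W)."""
    if w <= 0:
        raise ValueError("window size must be positive")
    counts: dict[str, np.ndarray] = {}
    for chrom, size in lib.chrom_sizes.items():
        n_win = int(np.ceil(size / w)) if size > 0 else 0
        counts[chrom] = np.zeros(n_win, dtype=np.int64)
    for chrom, grp in lib.tags.groupby("chrom"):
        idx = (grp["pos"].to_numpy(dtype=np.int64)) // w
        counts[str(chrom)] += np.bincount(idx, minlength=len(counts[str(chrom)]))
    return WindowTrack(window_size=w, counts=counts)


def background_rate(
    lib: TagLibrary, w: int = DEFAULT_WINDOW, control: TagLibrary | None = None
) -> float:
    """Expected background tags per window, lambda0 = total * W / effective length.

    A control library rescales the estimate by the ratio of library sizes, the
    only use made of the control in this simplified model.
    """
    lam = lib.total_count * w / lib.effective_genome_length
    if control is not None and control.total_count > 0:
        ctrl_lam = control.total_count * w / control.effective_genome_length
        lam = max(lam, ctrl_lam * lib.total_count / control.total_count)
    return float(lam)


def window_score(count: np.ndarray, lambda0: float) -> np.ndarray:
    """-ln P(X >= count | Poisson(lambda0)); zero-count windows score 0."""
    with np.errstate(divide="ignore"):
        tail = stats.poisson.sf(np.asarray(count) - 1, lambda0)
        return -np.log(np.maximum(tail, np.finfo(float).tiny))


def expected_background_score(lambda0: float, max_count: int = 200) -> float:
    """E[window score] under the background Poisson: the default gap penalty."""
    counts = np.arange(max_count + 1)
    probs = stats.poisson.pmf(counts, lambda0)
    return float(np.sum(probs * window_score(counts, lambda0)))


def eligible_windows(
    track: WindowTrack, lambda0: float, p_thresh: float = DEFAULT_P_THRESH
):
    """Flag windows whose Poisson upper-tail probability beats ``p_thresh``.

    Returns ({chrom: bool flags}, {chrom: window scores}); scores are finite
    for all counts.
    """
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    flags: dict[str, np.ndarray] = {}
    scores: dict[str, np.ndarray] = {}
    for chrom, counts in track.counts.items():
        tail = stats.poisson.sf(counts - 1, lambda0)
        flags[chrom] = tail < p_thresh
        scores[chrom] = window_score(counts, lambda0)
    return flags, scores


def call_islands(
    track: WindowTrack,
    flags: dict[str, np.ndarray],
    scores: dict[str, np.ndarray],
    gap_bp: int,
    gap_penalty: float = 0.0,
) -> list[Island]:
    """Merge eligible windows separated by at most ``gap_bp`` of ineligible ones.

    ``gap_bp`` must be a multiple of the window size.  Each island spans the
    first eligible window's start to the last one's end; its score is the sum
    of its eligible windows' scores minus ``gap_penalty`` per spanned
    ineligible window (0 by default: the pure merge), and its height is
    score / width.
    """
    w = track.window_size
    if gap_bp % w != 0:
        raise ValueError("gap must be a multiple of the window size")
    max_gap = gap_bp // w
    islands: list[Island] = []
    for chrom in track.counts:
        f = flags[chrom]
        s = scores[chrom]
        elig = np.flatnonzero(f)
        if len(elig) == 0:
            continue
        group_start = elig[0]
        prev = elig[0]
        score_sum = float(s[elig[0]])
        n_gap = 0
        for i in elig[1:]:
            hole = i - prev - 1
            if hole <= max_gap:
                score_sum += float(s[i])
                n_gap += hole
            else:
                islands.append(
                    _make_island(chrom, group_start, prev, w, score_sum, n_gap, gap_penalty)
                )
                group_start = i
                score_sum = float(s[i])
                n_gap = 0
            prev = i
        islands.append(
            _make_island(chrom, group_start, prev, w, score_sum, n_gap, gap_penalty)
        )
    return islands


def _make_island(chrom, first_win, last_win, w, score_sum, n_gap, gap_penalty) -> Island:
    start = int(first_win) * w
    end = (int(last_win) + 1) * w
    score = max(score_sum - gap_penalty * n_gap, 0.0)
    return Island(GenomicInterval(chrom, start, end), score / (end - start))


def island_score(island: Island) -> float:
    """Recover an island's score from its height x width representation."""
    return island.height * island.interval.span


def aggregate_score(islands: list[Island], min_score: float = 0.0) -> float:
    """Total score of islands whose score clears ``min_score``."""
    return float(sum(s for s in (island_score(i) for i in islands) if s >= min_score))


def gap_scan(
    lib: TagLibrary,
    w: int = DEFAULT_WINDOW,
    p_thresh: float = DEFAULT_P_THRESH,
    gap_multiples: list[int] | None = None,
    min_island_score: float = DEFAULT_MIN_ISLAND_SCORE,
    control: TagLibrary | None = None,
    gap_penalty: float | None = None,
) -> tuple[pd.DataFrame, int]:
    """Scan gap sizes and choose the one maximizing the aggregate island score.

    ``gap_multiples`` are multiples of the window size (default 0..20 with a
    coarser tail up to 100, i.e. gaps up to 20 kb at W = 200).  The aggregate
    counts only islands scoring at least ``min_island_score``; bridged
    ineligible windows cost ``gap_penalty`` each (default -ln(p_thresh)).
    Ties break to the smallest gap (parsimony).  Returns (table of
    gap_bp/aggregate rows, chosen gap in bp).
    """
    if gap_multiples is None:
        gap_multiples = [0, 1, 2, 3, 4, 5, 6, 8, 10, 15, 20, 30, 50, 100]
    if not gap_multiples or sorted(gap_multiples) != list(gap_multiples):
        raise ValueError("gap_multiples must be non-empty and ascending")
    lam = background_rate(lib, w, control=control)
    track = window_counts(lib, w)
    flags, scores = eligible_windows(track, lam, p_thresh)
    penalty = -np.log(p_thresh) if gap_penalty is None else gap_penalty
    rows = []
    for mult in gap_multiples:
        gap_bp = mult * w
        islands = call_islands(track, flags, scores, gap_bp, gap_penalty=penalty)
        rows.append({"gap_bp": gap_bp, "aggregate_score": aggregate_score(islands, min_island_score)})
    table = pd.DataFrame(rows)
    best = table["aggregate_score"].max()
    chosen = int(table.loc[table["aggregate_score"] == best, "gap_bp"].iloc[0])
    return table, chosen


# ---------------------------------------------------------------------------
# IO


def read_tags(path, chrom_sizes: dict[str, int]) -> TagLibrary:
    """Read a tag TSV (chrom, pos, strand); BED3+strand also accepted."""
    df = pd.read_csv(path, sep="\t", dtype={0: str}, comment="#")
    if {"chrom", "pos", "strand"} - set(df.columns):
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "strand"], dtype={0: str},
        )
        df = pd.DataFrame(
            {"chrom": df["chrom"], "pos": df["start"], "strand": df["strand"].fillna("+")}
        )
    df["pos"] = df["pos"].astype(np.int64)
    return TagLibrary(tags=df[["chrom", "pos", "strand"]], chrom_sizes=chrom_sizes)


def write_tags(lib: TagLibrary, path) -> None:
    lib.tags.to_csv(path, sep="\t", index=False)


def islands_to_set(islands: list[Island], mark: str, tissue: str) -> IslandSet:
    return IslandSet(mark=mark, tissue=tissue, islands=islands)
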