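"""Chromatin domain ratios and the Domain Score from broad histone-mark islands.

For a genomic region, the mammary-to-liver Chromatin Active Domain Ratio
(CADR) is the summed mass (island height x overlapping width) of the active
marks H3K4me2 + H3K36me3 in mammary divided by the same sum in liver; the
Chromatin Silenced Domain Ratio (CSDR) is the analogous ratio for the
silencing mark H3K27me3.  The Domain Score combines them:

    DS = log2(CADR + 1) - log2(CSDR + 1)

A positive DS means more active and/or less silenced chromatin in mammary
relative to liver; near zero means the chromatin state is shared.  A small
symmetric pseudomass eps is added to both numerator and denominator so
regions with no islands get finite ratios (no-island regions score exactly 1,
hence DS = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from chromnest.genome import Gene, GenomeAnnotation, GenomicInterval, overlap_length

MARKS = ("H3K4me2", "H3K36me3", "H3K27me3")
DEFAULT_EPS = 1.0
DEFAULT_LOG_BASE = 2.0
DEFAULT_LOG_THRESH = 8.0
DEFAULT_PAIR_T = 2.0


@dataclass(frozen=True)
class Island:
    """A broad enrichment domain: interval plus a nonnegative height."""

    interval: GenomicInterval
    height: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ValueError("island height must be >= 0")

    @property
    def mass(self) -> float:
        return self.height * self.interval.span


@dataclass
class IslandSet:
    """Non-overlapping islands of one histone mark in one tissue, sorted."""

    mark: str
    tissue: str
    islands: list[Island] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.islands = sorted(
            self.islands, key=lambda i: (i.interval.chrom, i.interval.start)
        )
        prev: Island | None = None
        for isl in self.islands:
            if (
                prev is not None
                and isl.interval.chrom == prev.interval.chrom
                and isl.interval.start < prev.interval.end
            ):
                raise ValueError(
                    f"overlapping islands in {self.mark}/{self.tissue} at "
                    f"{isl.interval.chrom}:{isl.interval.start}"
                )
            prev = isl
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for isl in self.islands:
            self._index.setdefault(isl.interval.chrom, None)  # type: ignore[arg-type]
        for chrom in list(self._index):
            sub = [i for i in self.islands if i.interval.chrom == chrom]
            self._index[chrom] = (
                np.array([i.interval.start for i in sub], dtype=np.int64),
                np.array([i.interval.end for i in sub], dtype=np.int64),
                np.array([i.height for i in sub], dtype=float),
            )

    def __len__(self) -> int:
        return len(self.islands)

    def mass_in(self, region: GenomicInterval) -> float:
        """Sum of height x clipped-width over islands intersecting ``region``."""
        idx = self._index.get(region.chrom)
        if idx is None:
            return 0.0
        starts, ends, heights = idx
        lo = int(np.searchsorted(ends, region.start, side="right"))
        hi = int(np.searchsorted(starts, region.end, side="left"))
        if hi <= lo:
            return 0.0
        s, e, h = starts[lo:hi], ends[lo:hi], heights[lo:hi]
        widths = np.minimum(e, region.end) - np.maximum(s, region.start)
        return float(np.sum(h * np.maximum(widths, 0)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [i.interval.chrom for i in self.islands],
                "start": [i.interval.start for i in self.islands],
                "end": [i.interval.end for i in self.islands],
                "score": [i.height for i in self.islands],
            }
        )


@dataclass(frozen=True)
class ChromatinScores:
    """CADR/CSDR/DS over one region; DS = log2(CADR+1) - log2(CSDR+1)."""

    region: GenomicInterval
    cadr: float
    csdr: float
    ds: float


def region_mass(sets: list[IslandSet], region: GenomicInterval) -> float:
    """Total island mass over ``region``: sum of height x overlap width.

    Islands partially overlapping the region contribute only the clipped width
    — the only convention under which the mass is additive over a partition of
    the region.
    """
    return float(sum(s.mass_in(region) for s in sets))


def cadr(
    region: GenomicInterval,
    mam_k4: IslandSet,
    mam_k36: IslandSet,
    liv_k4: IslandSet,
    liv_k36: IslandSet,
    eps: float = DEFAULT_EPS,
) -> float:
    """Mammary-to-liver active-mark mass ratio over ``region``."""
    mam = region_mass([mam_k4, mam_k36], region)
    liv = region_mass([liv_k4, liv_k36], region)
    return (mam + eps) / (liv + eps)


def csdr(
    region: GenomicInterval,
    mam_k27: IslandSet,
    liv_k27: IslandSet,
    eps: float = DEFAULT_EPS,
) -> float:
    """Mammary-to-liver silencing-mark (H3K27me3) mass ratio over ``region``."""
    mam = region_mass([mam_k27], region)
    liv = region_mass([liv_k27], region)
    return (mam + eps) / (liv + eps)


def domain_score(
    cadr_value: float, csdr_value: float, log_base: float = DEFAULT_LOG_BASE
) -> float:
    """DS = log(CADR+1) - log(CSDR+1), log base 2 by default."""
    if cadr_value < 0 or csdr_value < 0:
        raise ValueError("CADR/CSDR must be >= 0")
    return float(
        (np.log(cadr_value + 1) - np.log(csdr_value + 1)) / np.log(log_base)
    )


@dataclass
class MarkLibrary:
    """The six island sets of the two-tissue, three-mark design."""

    mam_k4: IslandSet
    mam_k36: IslandSet
    mam_k27: IslandSet
    liv_k4: IslandSet
    liv_k36: IslandSet
    liv_k27: IslandSet

    def scores(self, region: GenomicInterval, eps: float = DEFAULT_EPS) -> ChromatinScores:
        c_a = cadr(region, self.mam_k4, self.mam_k36, self.liv_k4, self.liv_k36, eps=eps)
        c_s = csdr(region, self.mam_k27, self.liv_k27, eps=eps)
        return ChromatinScores(region, c_a, c_s, domain_score(c_a, c_s))


def gene_chromatin_table(
    ann: GenomeAnnotation, marks: MarkLibrary, eps: float = DEFAULT_EPS
) -> pd.DataFrame:
    """Per-gene CADR/CSDR/DS over the span from transcription start to end."""
    rows = []
    for g in ann:
        sc = marks.scores(g.interval, eps=eps)
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.interval.chrom,
                "start": g.interval.start,
                "end": g.interval.end,
                "CADR": sc.cadr,
                "CSDR": sc.csdr,
                "DS": sc.ds,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def neighborhood_ratios(
    interval: GenomicInterval, marks: MarkLibrary, eps: float = DEFAULT_EPS
) -> tuple[float, float]:
    """(NCADR, NCSDR): the same ratios over a whole neighborhood span."""
    c_a = cadr(interval, marks.mam_k4, marks.mam_k36, marks.liv_k4, marks.liv_k36, eps=eps)
    c_s = csdr(interval, marks.mam_k27, marks.liv_k27, eps=eps)
    return c_a, c_s


def annotate_windows_with_chromatin(
    scored: pd.DataFrame, marks: MarkLibrary, eps: float = DEFAULT_EPS
) -> pd.DataFrame:
    """Add NCADR/NCSDR columns to a scored-window table."""
    ncadr, ncsdr = [], []
    for chrom, start, end in zip(scored["chrom"], scored["start"], scored["end"]):
        a, s = neighborhood_ratios(GenomicInterval(chrom, start, end), marks, eps=eps)
        ncadr.append(a)
        ncsdr.append(s)
    out = scored.copy()
    out["NCADR"] = ncadr
    out["NCSDR"] = ncsdr
    return out


def classify_gene(
    log_cadr: float,
    log_csdr: float,
    active_thresh: float = DEFAULT_LOG_THRESH,
    silent_thresh: float = DEFAULT_LOG_THRESH,
) -> str:
    """Classify a gene from its log-scale CADR and CSDR.

    uniquely_active: logCADR > active_thresh and logCSDR <= silent_thresh;
    uniquely_silenced: the mirror case; both above -> inconsistent (active and
    silenced marks disagree); neither -> shared chromatin state.
    """
    active = log_cadr > active_thresh
    silenced = log_csdr > silent_thresh
    if active and silenced:
        return "inconsistent"
    if active:
        return "uniquely_active"
    if silenced:
        return "uniquely_silenced"
    return "shared"


def _gene_state(ds: float, t: float) -> str:
    if ds > t:
        return "active"
    if ds < -t:
        return "silent"
    return "neutral"


def classify_pair(ds_a: float, ds_b: float, t: float = DEFAULT_PAIR_T) -> str:
    """Classify an adjacent gene pair by the two Domain Scores.

    Each gene is active (DS > t), silent (DS < -t) or neutral; the pair is
    active/silent when both genes are, discordant when one is active and the
    other silent, and concordant otherwise.  Symmetric in its arguments.
    """
    a, b = _gene_state(ds_a, t), _gene_state(ds_b, t)
    if a == "active" and b == "active":
        return "active"
    if a == "silent" and b == "silent":
        return "silent"
    if {a, b} == {"active", "silent"}:
        return "discordant"
    return "concordant"


def classify_adjacent_pairs(
    gene_table: pd.DataFrame, ann: GenomeAnnotation, t: float = DEFAULT_PAIR_T
) -> pd.DataFrame:
    """Classify every adjacent probed gene pair along each chromosome."""
    rows = []
    for chrom in ann.chromosomes:
        genes = ann.by_chromosome(chrom)
        for g1, g2 in zip(genes, genes[1:]):
            if g1.gene_id not in gene_table.index or g2.gene_id not in gene_table.index:
                continue
            ds_a = float(gene_table.loc[g1.gene_id, "DS"])
            ds_b = float(gene_table.loc[g2.gene_id, "DS"])
            rows.append(
                {
                    "chrom": chrom,
                    "gene_a": g1.gene_id,
                    "gene_b": g2.gene_id,
                    "DS_a": ds_a,
                    "DS_b": ds_b,
                    "pair_class": classify_pair(ds_a, ds_b, t=t),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "gene_a", "gene_b", "DS_a", "DS_b", "pair_class"])


def ds_summary(ds_values) -> dict:
    """(min, max, fraction with -2 <= DS <= 2) over per-gene Domain Scores."""
    arr = np.asarray(ds_values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        raise ValueError("ds_summary needs at least one value")
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "frac_within_2": float(np.mean((arr >= -2) & (arr <= 2))),
    }


def active_gene_partition(
    best_tns: pd.Series,
    ds: pd.Series,
    ds_min: float = 2.0,
    tns_hi: float = 0.4,
    tns_lo: float = 0.01,
) -> dict:
    """Partition "active" genes (DS >= ds_min) by their best TNS.

    in_neighborhoods: TNS > tns_hi; not_in_neighborhoods: TNS < tns_lo;
    indeterminate: strictly between; values exactly at either threshold fall
    in neither open set and are counted separately as ``boundary``.
    """
    common = best_tns.index.intersection(ds.index)
    t = best_tns.loc[common].astype(float)
    d = ds.loc[common].astype(float)
    active = d >= ds_min
    t = t[active]
    return {
        "n_active": int(active.sum()),
        "in_neighborhoods": int((t > tns_hi).sum()),
        "not_in_neighborhoods": int((t < tns_lo).sum()),
        "indeterminate": int(((t > tns_lo) & (t < tns_hi)).sum()),
        "boundary": int(((t == tns_lo) | (t == tns_hi)).sum()),
    }


# ---------------------------------------------------------------------------
# IO: SICER-style island files (BED-like TSV, 0-based half-open)


def read_island_set(path, mark: str, tissue: str) -> IslandSet:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "score"],
        dtype={"chrom": str}, comment="#",
    )
    islands = [
        Island(GenomicInterval(r.chrom, int(r.start), int(r.end)), float(r.score))
        for r in df.itertuples(index=False)
    ]
    return IslandSet(mark=mark, tissue=tissue, islands=islands)


def write_island_set(iset: IslandSet, path) -> None:
    iset.to_frame().to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
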