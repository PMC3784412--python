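"""Synthetic-data generator with planted ground truth.

Emulates the statistical structure the analysis assumes, at desk scale:

* a gene annotation with exponential gene lengths and intergenic gaps
  (default 2,000 genes on 4 chromosomes);
* an expression matrix in the two designs the analysis consumes — a
  "timecourse" set (one tissue, 10 timepoints x 4 replicates, 40 arrays) and
  an "atlas"-style set (many tissues x 2 replicates) — with planted
  co-expressed neighborhoods that share a latent profile mixed to a target
  average pairwise correlation, a chromosome-local distance decay
  corr(d) = c * exp(-d / tau), and Present/Marginal/Absent detection calls
  thresholded so that roughly 28% of genes are expressed per tissue (most
  genes are expressed in neither of two contrasted tissues, as in real
  two-tissue comparisons);
* synteny-block tables for 10 comparison genomes, built by fragmenting the
  reference gene order with Poisson breakpoints and random gene dropout,
  with planted neighborhoods protected from breakage in a stated number of
  genomes (and deliberately broken in the rest, so their synteny score is
  exactly protected/total);
* island sets for the three marks in two tissues: planted mammary-active
  domains carry H3K4me2+H3K36me3 islands, planted mammary-silenced domains
  carry broad H3K27me3 blocks, and background islands are placed identically
  in both tissues (heights jittered) — chromatin state is mostly shared
  between tissues, and only the planted domains are tissue-specific;
* tag libraries for the island caller, uniform at a high rate inside planted
  domains (with internal dropout holes for broad marks) and a low rate
  outside.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from chromnest.chromatin import Island, IslandSet, MarkLibrary
from chromnest.expression import ExpressionMatrix
from chromnest.genome import Gene, GenomeAnnotation, GenomicInterval, order_genes
from chromnest.islands import TagLibrary
from chromnest.neighborhoods import SyntenyMap

DEFAULT_N_GENES = 2000
DEFAULT_N_CHROMS = 4
DEFAULT_MEAN_GENE_LEN = 15_000
DEFAULT_MEAN_GAP = 60_000
DEFAULT_DECAY_C = 0.2
DEFAULT_DECAY_TAU = 300_000.0
DEFAULT_EXPRESSED_FRACTION = 0.28
CALL_THRESHOLD = 8.0  # log2 intensity above which a sample is called Present
EXPRESSED_SHIFT = 5.0
BASE_SD = 0.7
MARGINAL_BAND = 0.25  # half-width of the Marginal band around the call threshold


@dataclass
class SyntheticTruth:
    """Planted structure emitted alongside every synthetic bundle."""

    seed: int
    decay_c: float = DEFAULT_DECAY_C
    decay_tau: float = DEFAULT_DECAY_TAU
    noise_sd: float = 1.0
    planted_neighborhoods: list[dict] = field(default_factory=list)
    planted_domains: list[dict] = field(default_factory=list)

    def gene_chromatin_state(self) -> dict[str, str]:
        """gene_id -> planted chromatin state (active / silenced / background)."""
        out: dict[str, str] = {}
        for dom in self.planted_domains:
            for gid in dom["gene_ids"]:
                out[gid] = dom["kind"]
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def simulate_genome(
    n_genes: int = DEFAULT_N_GENES,
    n_chroms: int = DEFAULT_N_CHROMS,
    mean_gene_len: int = DEFAULT_MEAN_GENE_LEN,
    mean_gap: int = DEFAULT_MEAN_GAP,
    seed: int = 0,
) -> GenomeAnnotation:
    """Non-overlapping genes with exponential lengths and intergenic gaps."""
    rng = np.random.default_rng(seed)
    per_chrom = [n_genes // n_chroms] * n_chroms
    for i in range(n_genes - sum(per_chrom)):
        per_chrom[i] += 1
    genes: list[Gene] = []
    chrom_sizes: dict[str, int] = {}
    gid = 0
    for c in range(n_chroms):
        chrom = f"chr{c + 1}"
        pos = int(rng.exponential(mean_gap)) + 1
        for _ in range(per_chrom[c]):
            length = max(int(rng.exponential(mean_gene_len)), 200)
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(
                Gene(
                    gene_id=f"g{gid:05d}",
                    symbol=f"Gene{gid}",
                    interval=GenomicInterval(chrom, pos, pos + length),
                    strand=strand,
                )
            )
            pos += length + max(int(rng.exponential(mean_gap)), 100)
        chrom_sizes[chrom] = pos + mean_gap
    return order_genes(GenomeAnnotation(genes, chrom_sizes))


def plant_neighborhoods(
    ann: GenomeAnnotation,
    n_plants: int = 20,
    size_range: tuple[int, int] = (3, 5),
    target_anc: float = 0.8,
    syntenic_genomes: int = 8,
    n_genomes: int = 10,
    seed: int = 0,
) -> list[dict]:
    """Choose non-overlapping runs of adjacent genes as planted neighborhoods."""
    rng = np.random.default_rng(seed)
    plants: list[dict] = []
    taken: set[str] = set()
    chroms = ann.chromosomes
    attempts = 0
    while len(plants) < n_plants and attempts < 10_000:
        attempts += 1
        chrom = chroms[rng.integers(len(chroms))]
        genes = ann.by_chromosome(chrom)
        k = int(rng.integers(size_range[0], size_range[1] + 1))
        if len(genes) < k + 2:
            continue
        i = int(rng.integers(1, len(genes) - k - 1))
        members = genes[i : i + k]
        # keep one unplanted gene on each side so plants never abut
        guard = genes[i - 1 : i + k + 1]
        if any(g.gene_id in taken for g in guard):
            continue
        taken.update(g.gene_id for g in guard)
        plants.append(
            {
                "chrom": chrom,
                "gene_ids": [g.gene_id for g in members],
                "start_index": i,
                "anc": target_anc,
                "syntenic_genomes": syntenic_genomes,
                "n_genomes": n_genomes,
            }
        )
    if len(plants) < n_plants:
        raise RuntimeError("could not place the requested number of plants")
    return plants


def _sample_sheet(tissues: list[str], timepoints: list[str], reps: int) -> pd.DataFrame:
    rows = []
    for t_i, tissue in enumerate(tissues):
        tps = timepoints if len(tissues) == 1 else ["na"]
        for tp in tps:
            for r in range(1, reps + 1):
                rows.append(
                    {
                        "sample_id": f"{tissue}.{tp}.r{r}",
                        "tissue": tissue,
                        "timepoint": tp,
                        "replicate": r,
                    }
                )
    return pd.DataFrame(rows)


def simulate_expression(
    ann: GenomeAnnotation,
    truth: SyntheticTruth,
    tissues: list[str] | None = None,
    timepoints: list[str] | None = None,
    reps: int = 4,
    seed: int = 0,
    expressed_fraction: float = DEFAULT_EXPRESSED_FRACTION,
    noise_sd: float = 1.0,
) -> ExpressionMatrix:
    """Simulate a log2 expression matrix with calls for the given design.

    Default design is the timecourse set: one tissue, 10 timepoints x ``reps``
    replicates.  Planted neighborhoods share a per-sample latent factor with
    weight sqrt(target ANC); outside plants, a chromosome-local factor with
    spatial correlation length tau contributes weight sqrt(c), implementing
    the corr(d) = c*exp(-d/tau) decay.  Detection calls are thresholded on the
    simulated log2 value, with a narrow Marginal band around the threshold;
    the expressed-state shift and threshold are set so that about
    ``expressed_fraction`` of genes are Present in all replicates of a tissue.
    """
    rng = np.random.default_rng(seed)
    if tissues is None:
        tissues = ["mammary"]
    if timepoints is None:
        timepoints = [f"tp{i:02d}" for i in range(1, 11)] if len(tissues) == 1 else ["na"]
    samples = _sample_sheet(tissues, timepoints, reps)
    n_s = len(samples)
    genes = list(ann)
    n_g = len(genes)
    gene_ids = [g.gene_id for g in genes]
    gene_pos = {gid: i for i, gid in enumerate(gene_ids)}

    plant_of = np.full(n_g, -1)
    plant_rho = np.zeros(n_g)
    for pi, plant in enumerate(truth.planted_neighborhoods):
        for gid in plant["gene_ids"]:
            plant_of[gene_pos[gid]] = pi
            plant_rho[gene_pos[gid]] = plant["anc"]

    # chromosome-local spatial factor, one independent field per sample
    c = truth.decay_c
    tau = truth.decay_tau
    u = np.zeros((n_g, n_s))
    if c > 0:
        for chrom in ann.chromosomes:
            idx = [gene_pos[g.gene_id] for g in ann.by_chromosome(chrom)]
            starts = np.array([genes[i].interval.start for i in idx], dtype=float)
            a = np.exp(-np.diff(starts) / tau)
            field_vals = rng.standard_normal((len(idx), n_s))
            for j in range(1, len(idx)):
                field_vals[j] = a[j - 1] * field_vals[j - 1] + np.sqrt(
                    1 - a[j - 1] ** 2
                ) * field_vals[j]
            u[idx, :] = field_vals

    n_plants = len(truth.planted_neighborhoods)
    f = rng.standard_normal((max(n_plants, 1), n_s))
    z = rng.standard_normal((n_g, n_s))

    in_plant = plant_of >= 0
    w_plant = np.sqrt(plant_rho)[:, None]
    w_decay = np.where(in_plant, 0.0, np.sqrt(c))[:, None]
    w_noise = np.sqrt(np.clip(1.0 - w_plant**2 - w_decay**2, 0.0, None))
    latent = w_plant * f[np.clip(plant_of, 0, None), :] + w_decay * u + w_noise * z

    # expressed state per gene x tissue: spatially clustered propensity so that
    # expressed genes form runs, plus tissue-specific variation
    base = rng.normal(6.0, BASE_SD, size=n_g)
    e_shared = np.zeros(n_g)
    for chrom in ann.chromosomes:
        idx = [gene_pos[g.gene_id] for g in ann.by_chromosome(chrom)]
        vals = rng.standard_normal(len(idx))
        for j in range(1, len(idx)):
            vals[j] = 0.5 * vals[j - 1] + np.sqrt(1 - 0.25) * vals[j]
        e_shared[idx] = vals
    from scipy.stats import norm

    q = norm.ppf(1 - expressed_fraction)
    expressed = {}
    for tissue in tissues:
        v = 0.6 * e_shared + 0.8 * rng.standard_normal(n_g)
        flags = v > q * np.sqrt(0.6**2 + 0.8**2)
        flags[in_plant] = True  # planted neighborhoods are co-expressed
        expressed[tissue] = flags

    mu = np.zeros((n_g, n_s))
    for s_i, row in enumerate(samples.itertuples(index=False)):
        mu[:, s_i] = base + EXPRESSED_SHIFT * expressed[row.tissue]
    values = mu + noise_sd * latent

    calls = np.where(
        values > CALL_THRESHOLD + MARGINAL_BAND,
        "P",
        np.where(values > CALL_THRESHOLD - MARGINAL_BAND, "M", "A"),
    )
    cols = list(samples["sample_id"])
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=cols),
        calls=pd.DataFrame(calls, index=gene_ids, columns=cols),
        samples=samples,
    )


def simulate_atlas_expression(
    ann: GenomeAnnotation, truth: SyntheticTruth, n_tissues: int = 12, seed: int = 0
) -> ExpressionMatrix:
    """Atlas-style design: ``n_tissues`` tissues x 2 replicates."""
    tissues = [f"tissue{i:02d}" for i in range(1, n_tissues + 1)]
    return simulate_expression(
        ann, truth, tissues=tissues, timepoints=["na"], reps=2, seed=seed
    )


def simulate_synteny(
    ann: GenomeAnnotation,
    truth: SyntheticTruth,
    n_genomes: int = 10,
    breakpoint_rate: float = 0.02,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> SyntenyMap:
    """Fragment the reference gene order into blocks per comparison genome.

    Breakpoints fall between adjacent genes with probability
    ``breakpoint_rate`` (always at chromosome boundaries); genes drop out at
    ``missing_rate``.  Planted neighborhoods are protected from breakage and
    dropout in their first ``syntenic_genomes`` genomes and deliberately
    broken in the remainder, so their synteny score is exact.
    """
    rng = np.random.default_rng(seed)
    genes = list(ann)
    n = len(genes)
    chroms = [g.interval.chrom for g in genes]
    gene_pos = {g.gene_id: i for i, g in enumerate(genes)}

    protected_adj: dict[int, set[int]] = {gi: set() for gi in range(n_genomes)}
    forced_adj: dict[int, set[int]] = {gi: set() for gi in range(n_genomes)}
    protected_genes: dict[int, set[int]] = {gi: set() for gi in range(n_genomes)}
    for plant in truth.planted_neighborhoods:
        idxs = sorted(gene_pos[g] for g in plant["gene_ids"])
        adjacencies = set(range(idxs[0] + 1, idxs[-1] + 1))  # breaks before position i
        n_prot = plant["syntenic_genomes"]
        for gi in range(n_genomes):
            if gi < n_prot:
                protected_adj[gi] |= adjacencies
                protected_genes[gi] |= set(idxs)
            else:
                forced_adj[gi].add(idxs[len(idxs) // 2])

    genomes: dict[str, dict[str, tuple[int, int]]] = {}
    for gi in range(n_genomes):
        name = f"genome{gi + 1:02d}"
        breaks = rng.random(n) < breakpoint_rate
        breaks[0] = True
        for i in range(1, n):
            if chroms[i] != chroms[i - 1]:
                breaks[i] = True
        for i in protected_adj[gi]:
            breaks[i] = False
        for i in forced_adj[gi]:
            breaks[i] = True
        block_ids = np.cumsum(breaks) - 1
        drop = rng.random(n) < missing_rate
        for i in protected_genes[gi]:
            drop[i] = False
        mapping: dict[str, tuple[int, int]] = {}
        order_in_block: dict[int, int] = {}
        for i, g in enumerate(genes):
            if drop[i]:
                continue
            b = int(block_ids[i])
            o = order_in_block.get(b, 0)
            order_in_block[b] = o + 1
            mapping[g.gene_id] = (b, o)
        genomes[name] = mapping
    return SyntenyMap(genomes=genomes, reference="reference")


def plant_chromatin_domains(
    ann: GenomeAnnotation,
    truth: SyntheticTruth,
    n_active: int = 10,
    n_silenced: int = 10,
    margin: int = 2_000,
    seed: int = 0,
) -> None:
    """Choose planted active (1 gene) and silenced (2-3 gene, broad) domains.

    Appends to ``truth.planted_domains``; domains avoid each other and the
    expression plants' guard zones are irrelevant here (chromatin plants may
    coincide with expression plants).
    """
    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    domains: list[dict] = []

    def try_place(kind: str, span_genes: int) -> bool:
        chroms = ann.chromosomes
        chrom = chroms[rng.integers(len(chroms))]
        genes = ann.by_chromosome(chrom)
        if len(genes) < span_genes + 2:
            return False
        i = int(rng.integers(1, len(genes) - span_genes - 1))
        members = genes[i : i + span_genes]
        guard = genes[i - 1 : i + span_genes + 1]
        if any(g.gene_id in taken for g in guard):
            return False
        taken.update(g.gene_id for g in guard)
        # margins stop short of the flanking guard genes, so a planted domain
        # never adds tissue-specific mass over a background gene and two
        # domains can never overlap (at least one untouched gene lies between)
        left_limit = genes[i - 1].interval.end
        right_limit = genes[i + span_genes].interval.start
        start = max(members[0].interval.start - margin, left_limit, 0)
        end = min(members[-1].interval.end + margin, right_limit)
        domains.append(
            {
                "chrom": chrom,
                "start": start,
                "end": end,
                "kind": kind,
                "tissue": "mammary",
                "gene_ids": [g.gene_id for g in members],
            }
        )
        return True

    want = [("active", 1)] * n_active + [("silenced", int(rng.integers(2, 4)))] * n_silenced
    attempts = 0
    placed = 0
    while placed < len(want) and attempts < 20_000:
        attempts += 1
        kind, span = want[placed]
        if kind == "silenced":
            span = int(rng.integers(2, 4))
        if try_place(kind, span):
            placed += 1
    if placed < len(want):
        raise RuntimeError("could not place the requested chromatin domains")
    truth.planted_domains.extend(domains)


def _background_islands(
    rng: np.random.Generator,
    chrom_sizes: dict[str, int],
    exclude: list[GenomicInterval],
    rate_per_mb: float,
    mean_len: int,
) -> list[tuple[GenomicInterval, float]]:
    """Sorted non-overlapping background islands avoiding the excluded regions."""
    out: list[tuple[GenomicInterval, float]] = []
    for chrom, size in chrom_sizes.items():
        n = rng.poisson(rate_per_mb * size / 1e6)
        if n == 0:
            continue
        starts = np.sort(rng.integers(0, max(size - mean_len * 4, 1), size=n))
        prev_end = -1
        for s in starts:
            length = max(int(rng.exponential(mean_len)), 400)
            iv = GenomicInterval(chrom, int(s), min(int(s) + length, size))
            if iv.start < prev_end:
                continue
            if any(
                iv.chrom == e.chrom and iv.start < e.end and e.start < iv.end
                for e in exclude
            ):
                continue
            out.append((iv, float(rng.uniform(0.5, 2.0))))
            prev_end = iv.end
    return out


def simulate_islands(
    ann: GenomeAnnotation,
    truth: SyntheticTruth,
    background_rate_per_mb: float = 3.0,
    planted_height: float = 5.0,
    seed: int = 0,
) -> MarkLibrary:
    """Six island sets (3 marks x 2 tissues) realizing the planted domains.

    Planted mammary-active domains get H3K4me2 + H3K36me3 islands in mammary
    only; planted mammary-silenced domains get a broad H3K27me3 block in
    mammary only.  Background islands are shared between tissues: identical
    intervals with independently jittered heights (+/-10%), and none inside a
    planted domain.
    """
    rng = np.random.default_rng(seed)
    sizes = ann.chrom_sizes
    exclude = [
        GenomicInterval(d["chrom"], d["start"], d["end"]) for d in truth.planted_domains
    ]
    mean_len = {"H3K4me2": 1_000, "H3K36me3": 3_000, "H3K27me3": 10_000}
    sets: dict[tuple[str, str], list[Island]] = {}
    for mark in ("H3K4me2", "H3K36me3", "H3K27me3"):
        shared = _background_islands(
            rng, sizes, exclude, background_rate_per_mb, mean_len[mark]
        )
        for tissue in ("mammary", "liver"):
            jitter = rng.uniform(0.9, 1.1, size=len(shared))
            sets[(mark, tissue)] = [
                Island(iv, h * j) for (iv, h), j in zip(shared, jitter)
            ]
    for d in truth.planted_domains:
        iv = GenomicInterval(d["chrom"], d["start"], d["end"])
        if d["kind"] == "active":
            sets[("H3K4me2", d["tissue"])].append(Island(iv, planted_height))
            sets[("H3K36me3", d["tissue"])].append(Island(iv, planted_height))
        else:
            sets[("H3K27me3", d["tissue"])].append(Island(iv, planted_height))
    return MarkLibrary(
        mam_k4=IslandSet("H3K4me2", "mammary", sets[("H3K4me2", "mammary")]),
        mam_k36=IslandSet("H3K36me3", "mammary", sets[("H3K36me3", "mammary")]),
        mam_k27=IslandSet("H3K27me3", "mammary", sets[("H3K27me3", "mammary")]),
        liv_k4=IslandSet("H3K4me2", "liver", sets[("H3K4me2", "liver")]),
        liv_k36=IslandSet("H3K36me3", "liver", sets[("H3K36me3", "liver")]),
        liv_k27=IslandSet("H3K27me3", "liver", sets[("H3K27me3", "liver")]),
    )


def simulate_tags(
    domains: list[GenomicInterval],
    chrom_sizes: dict[str, int],
    reads_per_kb_in: float = 10.0,
    reads_per_kb_out: float = 0.5,
    hole_len: int = 1_500,
    hole_fraction: float = 0.0,
    seed: int = 0,
) -> TagLibrary:
    """Uniform tags at a high rate inside domains, low outside.

    ``hole_fraction`` > 0 carves dropout holes of about ``hole_len`` bp out of
    each domain (broad, internally gappy marks); tags falling in holes are
    removed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, size in chrom_sizes.items():
        n_bg = rng.poisson(reads_per_kb_out * size / 1000.0)
        pos = rng.integers(0, size, size=n_bg)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    for dom in domains:
        holes: list[tuple[int, int]] = []
        if hole_fraction > 0:
            n_holes = max(int(dom.span * hole_fraction / hole_len), 1)
            for _ in range(n_holes):
                hs = int(rng.integers(dom.start, max(dom.end - hole_len, dom.start + 1)))
                holes.append((hs, hs + hole_len))
        n_in = rng.poisson(reads_per_kb_in * dom.span / 1000.0)
        pos = rng.integers(dom.start, dom.end, size=n_in)
        for hs, he in holes:
            pos = pos[(pos < hs) | (pos >= he)]
        rows.append(pd.DataFrame({"chrom": dom.chrom, "pos": pos}))
    tags = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        {"chrom": [], "pos": []}
    )
    tags["strand"] = np.where(
        np.random.default_rng(seed + 1).random(len(tags)) < 0.5, "+", "-"
    )
    tags = tags.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return TagLibrary(tags=tags, chrom_sizes=dict(chrom_sizes))


def default_truth(seed: int = 0) -> SyntheticTruth:
    return SyntheticTruth(seed=seed)


def simulate_bundle(
    seed: int = 0,
    n_genes: int = DEFAULT_N_GENES,
    n_chroms: int = DEFAULT_N_CHROMS,
    n_plants: int = 20,
    target_anc: float = 0.8,
    syntenic_genomes: int = 8,
    n_genomes: int = 10,
    decay_c: float = DEFAULT_DECAY_C,
    decay_tau: float = DEFAULT_DECAY_TAU,
):
    """Generate the full input bundle with planted truth (in memory).

    Returns (annotation, truth, expression, synteny, marks).  Seeds for the
    individual generators are derived deterministically from ``seed``.
    """
    ann = simulate_genome(n_genes=n_genes, n_chroms=n_chroms, seed=seed)
    truth = SyntheticTruth(seed=seed, decay_c=decay_c, decay_tau=decay_tau)
    truth.planted_neighborhoods = plant_neighborhoods(
        ann,
        n_plants=n_plants,
        target_anc=target_anc,
        syntenic_genomes=syntenic_genomes,
        n_genomes=n_genomes,
        seed=seed + 1,
    )
    plant_chromatin_domains(ann, truth, seed=seed + 2)
    expr = simulate_expression(ann, truth, seed=seed + 3)
    smap = simulate_synteny(ann, truth, n_genomes=n_genomes, seed=seed + 4)
    marks = simulate_islands(ann, truth, seed=seed + 5)
    return ann, truth, expr, smap, marks
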