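"""Synthetic MAGIC population generator.

Simulates the data structure of an eight-founder multi-parent advanced
generation inter-cross (MAGIC) wheat population: a genetic map over 21
chromosomes, founder SNP alleles, funnel-structured crossing followed by
selfing, founder-probability grids, and multi-trait / multi-year phenotypes
with planted pleiotropic QTL and target heritabilities.  Every downstream
inference stage can therefore be tested against known ground truth.

Crossover model: Poisson crossover counts per chromosome (mean = length in
Morgans), uniform positions, no interference — i.e. the Haldane model
implied by a centimorgan map.  Lines are represented as a single founder
mosaic per chromosome (fully inbred after selfing); residual heterozygosity
is ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_N_CHROMOSOMES = 21
DEFAULT_TOTAL_CM = 5405.0  # 54.05 Morgans genome-wide
DEFAULT_N_FOUNDERS = 8
DEFAULT_N_FUNNELS = 210
DEFAULT_N_LINES = 231
DEFAULT_SELFING_GENERATIONS = 4

#: wheat-style chromosome names (7 groups x 3 sub-genomes)
DEFAULT_CHROM_NAMES = [f"{g}{s}" for g in range(1, 8) for s in "ABD"]


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker positions (cM) over a set of chromosomes.

    ``markers`` has columns ``marker_id``, ``chrom``, ``cM`` sorted by
    chromosome then position; ``chrom_lengths`` maps chromosome name to its
    length in cM.  Positions are 0-based continuous; intervals are closed.
    """

    markers: pd.DataFrame
    chrom_lengths: dict[str, float]

    def __post_init__(self) -> None:
        required = {"marker_id", "chrom", "cM"}
        if not required.issubset(self.markers.columns):
            raise ValueError(f"map needs columns {sorted(required)}")
        if self.markers["marker_id"].duplicated().any():
            raise ValueError("duplicate marker_ids in map")
        for chrom, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["cM"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"positions not sorted on {chrom}")
            if pos.size and (pos[0] < 0 or pos[-1] > self.chrom_lengths[chrom]):
                raise ValueError(f"marker position outside {chrom} bounds")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def total_length_cM(self) -> float:
        return float(sum(self.chrom_lengths.values()))

    def chrom_positions(self, chrom: str) -> np.ndarray:
        return self.markers.loc[self.markers["chrom"] == chrom, "cM"].to_numpy()

    def chrom_marker_ids(self, chrom: str) -> np.ndarray:
        return self.markers.loc[
            self.markers["chrom"] == chrom, "marker_id"
        ].to_numpy()


def make_map(
    n_chromosomes: int = DEFAULT_N_CHROMOSOMES,
    lengths_cM: list[float] | None = None,
    markers_per_chromosome: int = 346,
    seed: int = 0,
) -> GeneticMap:
    """Place markers uniformly at random on each chromosome, then sort.

    Defaults emulate a 21-chromosome genome of 54.05 Morgans with
    ~7.3k markers.  Deterministic given ``seed``.
    """
    if lengths_cM is None:
        lengths_cM = [DEFAULT_TOTAL_CM / n_chromosomes] * n_chromosomes
    if len(lengths_cM) != n_chromosomes:
        raise ValueError("lengths_cM must have one entry per chromosome")
    if any(length <= 0 for length in lengths_cM):
        raise ValueError("chromosome lengths must be positive")
    if markers_per_chromosome < 2:
        raise ValueError("need at least 2 markers per chromosome")
    if n_chromosomes <= len(DEFAULT_CHROM_NAMES):
        names = DEFAULT_CHROM_NAMES[:n_chromosomes]
    else:
        names = [f"chr{i + 1:02d}" for i in range(n_chromosomes)]
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, length in zip(names, lengths_cM):
        pos = np.sort(rng.uniform(0.0, length, markers_per_chromosome))
        for j, p in enumerate(pos):
            rows.append((f"{chrom}_m{j:04d}", chrom, float(p)))
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "cM"])
    return GeneticMap(markers, dict(zip(names, map(float, lengths_cM))))


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

@dataclass
class FounderSet:
    """Founder labels plus a founder x marker biallelic allele matrix."""

    founder_ids: list[str]
    alleles: np.ndarray  # (n_founders, n_markers) in {0, 1}

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)


def simulate_founder_alleles(
    gmap: GeneticMap, maf_min: float = 0.125, seed: int = 0
) -> FounderSet:
    """Draw founder alleles so every marker segregates.

    The number of founders carrying the ``1`` allele is sampled uniformly
    from the feasible counts ``ceil(maf_min*8) .. 8-ceil(maf_min*8)``, then
    carriers are chosen uniformly without replacement.  ``maf_min`` below
    1/8 is clamped (a single founder is the smallest possible class).
    """
    n_f = DEFAULT_N_FOUNDERS
    if not 0 < maf_min <= 0.5:
        raise ValueError("maf_min must be in (0, 0.5]")
    if maf_min < 1.0 / n_f:
        warnings.warn("maf_min below 1/8 is infeasible for 8 founders; clamping")
        maf_min = 1.0 / n_f
    rng = np.random.default_rng(seed)
    lo = int(np.ceil(maf_min * n_f))
    hi = n_f - lo
    counts = rng.integers(lo, hi + 1, size=gmap.n_markers)
    alleles = np.zeros((n_f, gmap.n_markers), dtype=np.int8)
    for j, c in enumerate(counts):
        alleles[rng.choice(n_f, size=c, replace=False), j] = 1
    ids = [f"F{i + 1}" for i in range(n_f)]
    return FounderSet(ids, alleles)


# ---------------------------------------------------------------------------
# funnels
# ---------------------------------------------------------------------------

@dataclass
class FunnelPlan:
    """Crossing design: founder order and line count per funnel.

    Each funnel combines all eight founders once: four two-way crosses, two
    four-way crosses, one eight-way cross, then selfing.  Line counts per
    funnel may be unequal.
    """

    founder_orders: list[np.ndarray]  # permutation of 0..7 per funnel
    line_counts: list[int]

    def __post_init__(self) -> None:
        for order in self.founder_orders:
            if sorted(order) != list(range(DEFAULT_N_FOUNDERS)):
                raise ValueError("funnel order must use each founder exactly once")
        if len(self.founder_orders) != len(self.line_counts):
            raise ValueError("one line count per funnel required")

    @property
    def n_funnels(self) -> int:
        return len(self.founder_orders)

    @property
    def n_lines(self) -> int:
        return int(sum(self.line_counts))


def make_funnel_plan(
    n_funnels: int = DEFAULT_N_FUNNELS,
    n_lines: int = DEFAULT_N_LINES,
    seed: int = 0,
) -> FunnelPlan:
    """Random funnel orders with skewed (unequal) line counts.

    Every funnel gets one line; the surplus ``n_lines - n_funnels`` is
    scattered multinomially, so most funnels contribute a single line and a
    few contribute several — mirroring unequal funnel representation.
    """
    if n_lines < n_funnels:
        raise ValueError("need at least one line per funnel")
    rng = np.random.default_rng(seed)
    orders = [rng.permutation(DEFAULT_N_FOUNDERS) for _ in range(n_funnels)]
    counts = np.ones(n_funnels, dtype=int)
    extra = n_lines - n_funnels
    if extra:
        counts += rng.multinomial(extra, np.full(n_funnels, 1.0 / n_funnels))
    return FunnelPlan(orders, counts.tolist())


# ---------------------------------------------------------------------------
# mosaics and meiosis
# ---------------------------------------------------------------------------

@dataclass
class FounderMosaic:
    """Founder-of-origin segments per chromosome.

    ``segments[chrom] = (breaks, founders)`` where ``breaks`` holds the
    internal breakpoints (strictly increasing, within (0, L)) and
    ``founders`` the founder index of each of the ``len(breaks)+1``
    segments tiling [0, L].  Adjacent segments differ in founder.
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray]]

    def founder_at(self, chrom: str, pos: np.ndarray | float) -> np.ndarray:
        breaks, founders = self.segments[chrom]
        return founders[np.searchsorted(breaks, np.atleast_1d(pos), side="right")]


def _merge_adjacent(breaks: np.ndarray, founders: np.ndarray):
    """Drop breakpoints between segments of identical founder origin."""
    if len(founders) <= 1:
        return breaks, founders
    keep = founders[1:] != founders[:-1]
    return breaks[keep], np.concatenate([[founders[0]], founders[1:][keep]])


def _extract(breaks, founders, lo, hi):
    """Segment structure of a mosaic chromosome restricted to [lo, hi)."""
    i0 = np.searchsorted(breaks, lo, side="right")
    i1 = np.searchsorted(breaks, hi, side="left")
    return breaks[i0:i1], founders[i0 : i1 + 1]


def founder_mosaic(founder_index: int, gmap: GeneticMap) -> FounderMosaic:
    """Whole-genome single-founder mosaic (a founder's haploid genome)."""
    empty = np.empty(0)
    segs = {
        c: (empty, np.array([founder_index], dtype=np.int16)) for c in gmap.chroms
    }
    return FounderMosaic(segs)


def meiosis(
    mosaic_a: FounderMosaic,
    mosaic_b: FounderMosaic,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> FounderMosaic:
    """One gamete from a diploid parent carrying ``mosaic_a`` / ``mosaic_b``.

    Crossover count per chromosome is Poisson(length in Morgans) with
    uniform positions and no interference; the gamete alternates parental
    origin at each crossover starting from a random strand.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in gmap.chrom_lengths.items():
        n_xo = rng.poisson(length / 100.0) if length > 0 else 0
        xo = np.sort(rng.uniform(0.0, length, n_xo))
        sources = (mosaic_a.segments[chrom], mosaic_b.segments[chrom])
        cur = int(rng.integers(2))
        bounds = np.concatenate([[0.0], xo, [length]])
        all_breaks: list[np.ndarray] = []
        all_founders: list[np.ndarray] = []
        for k in range(len(bounds) - 1):
            lo, hi = bounds[k], bounds[k + 1]
            br, fo = _extract(*sources[cur], lo, hi)
            if k > 0:
                all_breaks.append(np.array([lo]))
            all_breaks.append(br)
            all_founders.append(fo)
            cur ^= 1
        breaks = np.concatenate(all_breaks) if all_breaks else np.empty(0)
        founders = np.concatenate(all_founders)
        out[chrom] = _merge_adjacent(breaks, founders)
    return FounderMosaic(out)


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

@dataclass
class RILPopulation:
    """Recombinant inbred lines: mosaics, derived genotypes, funnel ids."""

    line_ids: list[str]
    mosaics: list[FounderMosaic]
    genotypes: pd.DataFrame  # lines x markers, {0,1} with NaN for missing
    funnel_ids: list[str]
    gmap: GeneticMap
    founders: FounderSet

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def founders_at(self, chrom: str, pos: float) -> np.ndarray:
        """Founder index of every line's mosaic at one genome position."""
        return np.array(
            [int(m.founder_at(chrom, pos)[0]) for m in self.mosaics], dtype=int
        )


def _derive_genotypes(
    mosaics: list[FounderMosaic],
    gmap: GeneticMap,
    founders: FounderSet,
    line_ids: list[str],
    missing_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_lines, n_mark = len(mosaics), gmap.n_markers
    geno = np.empty((n_lines, n_mark), dtype=float)
    col = 0
    for chrom in gmap.chroms:
        pos = gmap.chrom_positions(chrom)
        for i, mosaic in enumerate(mosaics):
            f_idx = mosaic.founder_at(chrom, pos)
            geno[i, col : col + len(pos)] = founders.alleles[f_idx, col + np.arange(len(pos))]
        col += len(pos)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = np.nan
    return pd.DataFrame(geno, index=line_ids, columns=gmap.markers["marker_id"].tolist())


def simulate_population(
    gmap: GeneticMap,
    founders: FounderSet,
    funnel_plan: FunnelPlan,
    selfing_generations: int = DEFAULT_SELFING_GENERATIONS,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> RILPopulation:
    """Run each funnel's crossing tree, then selfing, to produce RILs.

    Within a funnel the four two-way, two four-way and one eight-way cross
    are made once; each line then descends through ``selfing_generations``
    independent selfing meioses, and the line's single mosaic is a final
    gamete of the last selfed plant (residual heterozygosity discarded).
    """
    if selfing_generations < 1:
        raise ValueError("selfing_generations must be >= 1 for near-inbred lines")
    rng = np.random.default_rng(seed)
    line_ids: list[str] = []
    mosaics: list[FounderMosaic] = []
    funnel_ids: list[str] = []
    for fi, (order, count) in enumerate(
        zip(funnel_plan.founder_orders, funnel_plan.line_counts)
    ):
        fid = f"FUN{fi + 1:03d}"
        base = [founder_mosaic(int(f), gmap) for f in order]
        # two-way crosses: founders are homozygous, so F1 = the two mosaics
        two_way = [(base[2 * k], base[2 * k + 1]) for k in range(4)]
        four_way = [
            (meiosis(*two_way[0], gmap, rng), meiosis(*two_way[1], gmap, rng)),
            (meiosis(*two_way[2], gmap, rng), meiosis(*two_way[3], gmap, rng)),
        ]
        eight_way = (
            meiosis(*four_way[0], gmap, rng),
            meiosis(*four_way[1], gmap, rng),
        )
        for li in range(count):
            plant = eight_way
            for _ in range(selfing_generations):
                plant = (
                    meiosis(*plant, gmap, rng),
                    meiosis(*plant, gmap, rng),
                )
            mosaics.append(meiosis(*plant, gmap, rng))
            line_ids.append(f"MEL{len(line_ids) + 1:04d}")
            funnel_ids.append(fid)
    genotypes = _derive_genotypes(
        mosaics, gmap, founders, line_ids, missing_rate, rng
    )
    return RILPopulation(line_ids, mosaics, genotypes, funnel_ids, gmap, founders)


# ---------------------------------------------------------------------------
# founder-probability grid
# ---------------------------------------------------------------------------

@dataclass
class FounderProbabilityGrid:
    """Per-line founder-origin probabilities on a fixed-step cM grid."""

    positions: pd.DataFrame  # columns chrom, cM (grid order)
    probs: np.ndarray  # (n_lines, n_positions, n_founders)
    line_ids: list[str]

    @property
    def n_positions(self) -> int:
        return len(self.positions)


def probability_grid(
    pop: RILPopulation, step_cM: float = 1.0, uncertainty: float = 0.0
) -> FounderProbabilityGrid:
    """Founder probabilities at fixed grid steps from the true mosaics.

    The true founder receives ``1 - uncertainty``; the remaining mass is
    spread uniformly over the other seven founders, emulating the softness
    of HMM-inferred probabilities without re-implementing the inference.
    """
    if step_cM <= 0:
        raise ValueError("step_cM must be positive")
    if not 0 <= uncertainty < 1:
        raise ValueError("uncertainty must be in [0, 1)")
    n_f = pop.founders.n_founders
    rows = []
    for chrom, length in pop.gmap.chrom_lengths.items():
        grid = np.arange(0.0, length + 1e-9, step_cM)
        rows.append(pd.DataFrame({"chrom": chrom, "cM": grid}))
    positions = pd.concat(rows, ignore_index=True)
    probs = np.full(
        (pop.n_lines, len(positions), n_f), uncertainty / (n_f - 1), dtype=float
    )
    col = 0
    for chrom, length in pop.gmap.chrom_lengths.items():
        grid = np.arange(0.0, length + 1e-9, step_cM)
        for i, mosaic in enumerate(pop.mosaics):
            f_idx = mosaic.founder_at(chrom, grid)
            probs[i, col + np.arange(len(grid)), f_idx] = 1.0 - uncertainty
        col += len(grid)
    return FounderProbabilityGrid(positions, probs, list(pop.line_ids))


# ---------------------------------------------------------------------------
# trait architecture and phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PlantedQTL:
    """One causal locus: genome position, founder pattern, trait effects."""

    chrom: str
    pos_cM: float
    mode: str  # "biallelic" | "founder"
    trait_effects: np.ndarray  # effect size per trait
    year_multipliers: np.ndarray  # GxE scaling per year
    founder_pattern: np.ndarray | None = None  # length-8 scores (founder mode)


@dataclass
class TraitArchitecture:
    """Planted QTL, per-trait heritability targets and residual structure."""

    trait_ids: list[str]
    qtls: list[PlantedQTL]
    h2: np.ndarray  # target broad-sense heritability per trait, in [0, 1]
    residual_corr: np.ndarray | None = None  # trait x trait, PSD
    funnel_var: float = 0.0

    def __post_init__(self) -> None:
        self.h2 = np.asarray(self.h2, dtype=float)
        if np.any((self.h2 < 0) | (self.h2 > 1)):
            raise ValueError("h2 targets must lie in [0, 1]")
        n_t = len(self.trait_ids)
        if self.residual_corr is None:
            self.residual_corr = np.eye(n_t)
        R = np.asarray(self.residual_corr, dtype=float)
        if R.shape != (n_t, n_t) or not np.allclose(R, R.T, atol=1e-10):
            raise ValueError("residual_corr must be a symmetric trait x trait matrix")
        if np.min(np.linalg.eigvalsh(R)) < -1e-8:
            raise ValueError("residual_corr must be positive semi-definite")
        self.residual_corr = R


@dataclass
class PhenotypeTable:
    """Long-format phenotypes: one value per (line, trait, year[, rep])."""

    data: pd.DataFrame  # line_id, trait, year, rep, value

    def means(self) -> pd.DataFrame:
        """Replicate-averaged adjusted means (the BLUP stand-in)."""
        return (
            self.data.groupby(["line_id", "trait", "year"], sort=False, observed=True)[
                "value"
            ]
            .mean()
            .reset_index()
        )

    def wide(self, year: int | str | None = None) -> pd.DataFrame:
        """Line x trait matrix of replicate means, optionally one year."""
        m = self.means()
        if year is not None:
            m = m[m["year"] == year]
            return m.pivot(index="line_id", columns="trait", values="value")
        m = m.copy()
        m["trait_year"] = m["trait"] + "__Y" + m["year"].astype(str)
        return m.pivot(index="line_id", columns="trait_year", values="value")

    @property
    def trait_ids(self) -> list[str]:
        return list(pd.unique(self.data["trait"]))


def genetic_values(pop: RILPopulation, arch: TraitArchitecture) -> np.ndarray:
    """Additive genetic value per (line, trait, year) from the planted QTL."""
    n_years = len(arch.qtls[0].year_multipliers) if arch.qtls else 1
    G = np.zeros((pop.n_lines, len(arch.trait_ids), n_years))
    for q in arch.qtls:
        f_idx = pop.founders_at(q.chrom, q.pos_cM)
        if q.mode == "biallelic":
            mk = _nearest_marker_index(pop.gmap, q.chrom, q.pos_cM)
            scores = pop.founders.alleles[:, mk].astype(float)[f_idx]
        elif q.mode == "founder":
            if q.founder_pattern is None:
                raise ValueError("founder-mode QTL needs a founder_pattern")
            scores = np.asarray(q.founder_pattern, dtype=float)[f_idx]
        else:
            raise ValueError(f"unknown QTL mode {q.mode!r}")
        G += (
            scores[:, None, None]
            * np.asarray(q.trait_effects)[None, :, None]
            * np.asarray(q.year_multipliers)[None, None, :]
        )
    return G


def _nearest_marker_index(gmap: GeneticMap, chrom: str, pos: float) -> int:
    on = gmap.markers["chrom"] == chrom
    idx = np.flatnonzero(on.to_numpy())
    pos_arr = gmap.markers.loc[on, "cM"].to_numpy()
    return int(idx[np.argmin(np.abs(pos_arr - pos))])


def simulate_phenotypes(
    pop: RILPopulation,
    arch: TraitArchitecture,
    years: int = 2,
    replicates: int = 1,
    seed: int = 0,
) -> PhenotypeTable:
    """Phenotypes = planted genetic value x year multiplier + funnel effect
    + correlated residual.

    The residual variance of each trait is solved from the *empirical*
    genetic variance of the simulated lines so that the broad-sense
    heritability of replicate-averaged line means matches the target:
    ``Vr_plot = replicates * Vg_hat * (1 - h2) / h2``.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if arch.qtls and len(arch.qtls[0].year_multipliers) < years:
        raise ValueError("architecture year_multipliers shorter than years")
    rng = np.random.default_rng(seed)
    n_l, n_t = pop.n_lines, len(arch.trait_ids)
    G = genetic_values(pop, arch)[:, :, :years] if arch.qtls else np.zeros(
        (n_l, n_t, years)
    )
    vg = G.var(axis=0, ddof=1).mean(axis=1)  # per trait, averaged over years
    vr = np.empty(n_t)
    for t in range(n_t):
        h2 = arch.h2[t]
        if vg[t] <= 1e-12:
            if h2 >= 1.0:
                raise ValueError(
                    f"trait {arch.trait_ids[t]}: h2=1 infeasible with zero genetic variance"
                )
            if h2 > 0:
                warnings.warn(
                    f"trait {arch.trait_ids[t]}: no genetic variance; h2 target unreachable"
                )
            vr[t] = float(replicates)
        elif h2 <= 0:
            raise ValueError(
                f"trait {arch.trait_ids[t]}: h2=0 unreachable with nonzero genetic variance"
            )
        else:
            vr[t] = replicates * vg[t] * (1.0 - h2) / h2
    # residual covariance across traits at plot level
    sd = np.sqrt(vr)
    cov = arch.residual_corr * np.outer(sd, sd)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_t))
    funnels = pd.Categorical(pop.funnel_ids)
    records = []
    for y in range(years):
        if arch.funnel_var > 0:
            fun_eff = rng.normal(
                0.0, np.sqrt(arch.funnel_var), (len(funnels.categories), n_t)
            )
        else:
            fun_eff = np.zeros((len(funnels.categories), n_t))
        for r in range(replicates):
            eps = rng.standard_normal((n_l, n_t)) @ L.T
            vals = G[:, :, y] + fun_eff[funnels.codes] + eps
            for t, trait in enumerate(arch.trait_ids):
                records.append(
                    pd.DataFrame(
                        {
                            "line_id": pop.line_ids,
                            "trait": trait,
                            "year": y + 1,
                            "rep": r + 1,
                            "value": vals[:, t],
                        }
                    )
                )
    return PhenotypeTable(pd.concat(records, ignore_index=True))


def default_architecture(
    pop: RILPopulation,
    n_traits: int = 38,
    n_qtl: int = 15,
    years: int = 2,
    seed: int = 0,
) -> TraitArchitecture:
    """A study-scale trait panel: pleiotropic QTL across correlated traits.

    Heritability targets span 0.05-0.95; year multipliers jitter around 1
    to induce genotype-by-year interaction, giving between-year trait
    correlations spanning roughly 0-0.9; residual correlations follow a
    block structure so traits form natural clusters.
    """
    rng = np.random.default_rng(seed)
    trait_ids = [f"T{t + 1:02d}" for t in range(n_traits)]
    chrom_names = pop.gmap.chroms
    qtls = []
    for _ in range(n_qtl):
        chrom = chrom_names[rng.integers(len(chrom_names))]
        pos = float(rng.uniform(0, pop.gmap.chrom_lengths[chrom]))
        mode = "biallelic" if rng.random() < 0.6 else "founder"
        pattern = None
        if mode == "founder":
            pattern = np.zeros(DEFAULT_N_FOUNDERS)
            pattern[rng.integers(DEFAULT_N_FOUNDERS)] = 1.0
        # sparse pleiotropy: each QTL touches a handful of traits
        effects = np.zeros(n_traits)
        hit = rng.choice(n_traits, size=rng.integers(1, 6), replace=False)
        effects[hit] = rng.normal(0, 1, len(hit)) * rng.uniform(0.5, 1.5)
        mult = np.clip(rng.normal(1.0, 0.3, years), 0.0, None)
        qtls.append(PlantedQTL(chrom, pos, mode, effects, mult, pattern))
    h2 = rng.uniform(0.05, 0.95, n_traits)
    # block-structured residual correlations (4 blocks, within-block r=0.4)
    R = np.eye(n_traits)
    block = np.array_split(np.arange(n_traits), 4)
    for b in block:
        for i in b:
            for j in b:
                if i != j:
                    R[i, j] = 0.4
    return TraitArchitecture(trait_ids, qtls, h2, R)
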