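"""Simulation of multi-family DH/RIL breeding populations and quantitative traits.

The generator emulates elite small-grain breeding material: a pool of fully
inbred founder parents, many two-parent crosses, and either doubled-haploid
(DH) lines — one meiosis from the F1, genome doubled — or recombinant inbred
lines (RIL) — single-seed descent through several selfing generations, which
roughly doubles the number of recombination junctions per line.

Recombination follows the Haldane map function (no crossover interference):
the recombination fraction between adjacent markers at genetic distance
``d`` Morgans is ``r = 0.5 * (1 - exp(-2 d))``; chromosomes assort
independently.

Traits are additive: a set of QTL markers with normal effects defines the
genetic value, and Gaussian noise is added to hit a requested line-mean
heritability.  Partially shared architectures between two populations are
produced by drawing independent subsets of a common QTL set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import GeneticMap, MarkerMatrix


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed (or an existing Generator) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# genome / founders


def uniform_map(
    n_chromosomes: int = 21,
    chrom_length_cM: float = 150.0,
    markers_per_chromosome: int = 120,
    prefix: str = "M",
) -> GeneticMap:
    """Evenly spaced marker map; default genome is 21 chromosomes x 150 cM."""
    entries = {}
    k = 0
    for c in range(1, n_chromosomes + 1):
        pos = np.linspace(0.0, chrom_length_cM, markers_per_chromosome)
        for p in pos:
            entries[f"{prefix}{k:05d}"] = (str(c), float(p))
            k += 1
    return GeneticMap(entries)


@dataclass
class FounderSet:
    """Inbred founder parents: one binary haplotype each.

    ``haplotypes`` is parents x markers (0/1); marker columns follow
    ``marker_ids`` which are ordered along ``map`` (chromosome by
    chromosome, increasing position).
    """

    haplotypes: np.ndarray
    map: GeneticMap
    marker_ids: list
    parent_ids: list
    allele_freq_spec: object = None

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("founder haplotypes must be binary")
        if self.haplotypes.shape != (len(self.parent_ids), len(self.marker_ids)):
            raise ValueError("haplotype shape does not match parent/marker ids")

    def monomorphic_mask(self) -> np.ndarray:
        """Markers with zero polymorphism among the founders."""
        return self.haplotypes.min(axis=0) == self.haplotypes.max(axis=0)


def _draw_frequencies(freq_spec, n_markers, rng):
    if freq_spec is None:
        freq_spec = ("beta", 0.15, 0.15)
    if np.isscalar(freq_spec):
        return np.full(n_markers, float(freq_spec))
    if isinstance(freq_spec, (list, np.ndarray)) and not isinstance(freq_spec[0], str):
        f = np.asarray(freq_spec, dtype=float)
        if f.shape != (n_markers,):
            raise ValueError("per-marker frequency array has wrong length")
        return f
    kind = freq_spec[0]
    if kind == "beta":
        return rng.beta(freq_spec[1], freq_spec[2], size=n_markers)
    if kind == "uniform":
        return rng.uniform(freq_spec[1], freq_spec[2], size=n_markers)
    raise ValueError(f"unknown allele frequency spec {freq_spec!r}")


def _map_ordered_markers(gmap: GeneticMap) -> list:
    out = []
    for c in gmap.chromosomes():
        out.extend(gmap.ordered_markers(c))
    return out


def simulate_founders(n_parents: int, gmap: GeneticMap, freq_spec=None, seed=None) -> FounderSet:
    """Draw inbred founder haplotypes with per-marker allele frequencies.

    Each parent carries allele 1 at marker ``j`` with probability ``f_j``,
    where the ``f_j`` are drawn once from ``freq_spec``.  The default
    U-shaped Beta(0.15, 0.15) spectrum mimics a dominant-marker panel in
    which a sizeable share of markers is (nearly) fixed in any one breeding
    pool, so that two populations built from overlapping parent subsets
    share only part of their polymorphic markers.
    """
    if n_parents < 2:
        raise ValueError("need at least two parents")
    rng = as_rng(seed)
    marker_ids = _map_ordered_markers(gmap)
    freqs = _draw_frequencies(freq_spec, len(marker_ids), rng)
    hap = (rng.random((n_parents, len(marker_ids))) < freqs[None, :]).astype(np.int8)
    return FounderSet(
        haplotypes=hap,
        map=gmap,
        marker_ids=marker_ids,
        parent_ids=[f"P{i:03d}" for i in range(n_parents)],
        allele_freq_spec=freq_spec,
    )


# ---------------------------------------------------------------------------
# meiosis


class _MeiosisEngine:
    """Precomputed per-chromosome marker blocks and Haldane recombination
    fractions for a fixed marker order."""

    def __init__(self, gmap: GeneticMap, marker_ids):
        index = {m: i for i, m in enumerate(marker_ids)}
        mapped = set(gmap.marker_ids)
        for m in gmap.marker_ids:
            if m not in index:
                raise ValueError(f"marker {m!r} on map but absent from haplotypes")
        for m in marker_ids:
            if m not in mapped:
                raise ValueError(f"marker {m!r} not on the genetic map")
        self.blocks = []
        for c in gmap.chromosomes():
            mk = gmap.ordered_markers(c)
            idx = np.array([index[m] for m in mk], dtype=np.intp)
            pos = np.array([gmap.position_of(m) for m in mk])
            d_morgan = np.diff(pos) / 100.0
            r = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
            self.blocks.append((idx, r))
        self.n_markers = len(marker_ids)

    def gamete_phase(self, rng) -> np.ndarray:
        """Sample the parental-origin vector (0/1) of one gamete."""
        phase = np.empty(self.n_markers, dtype=np.int8)
        for idx, r in self.blocks:
            cross = rng.random(r.shape[0]) < r
            first = rng.integers(0, 2)
            ph = (first + np.concatenate(([0], np.cumsum(cross)))) % 2
            phase[idx] = ph
        return phase

    def junctions(self, haplotype) -> int:
        """Count switches between adjacent markers within chromosomes."""
        n = 0
        for idx, _ in self.blocks:
            h = haplotype[idx]
            n += int(np.count_nonzero(np.diff(h)))
        return n


def meiotic_gamete(hap_a, hap_b, gmap: GeneticMap, seed=None, marker_ids=None):
    """One recombinant gamete from an individual with haplotypes ``hap_a``/``hap_b``.

    Crossovers between adjacent markers occur with Haldane probability;
    chromosomes are independent and the starting haplotype of each
    chromosome is chosen uniformly.  ``marker_ids`` gives the column order
    of the haplotypes (defaults to map order).
    """
    rng = as_rng(seed)
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    if marker_ids is None:
        marker_ids = _map_ordered_markers(gmap)
    eng = _MeiosisEngine(gmap, marker_ids)
    phase = eng.gamete_phase(rng)
    return np.where(phase == 0, hap_a, hap_b)


# ---------------------------------------------------------------------------
# populations


@dataclass
class CrossPlan:
    """A list of two-parent crosses and the line type derived from each.

    ``crosses`` holds (parent_a, parent_b, n_lines) with parent ids from the
    FounderSet; ``line_type`` is "DH" (one meiosis, genome doubled) or "RIL"
    (single-seed descent for ``selfing_generations`` selfing meioses).
    """

    crosses: list
    line_type: str = "DH"
    selfing_generations: int = 8

    def __post_init__(self):
        if self.line_type not in ("DH", "RIL"):
            raise ValueError("line_type must be 'DH' or 'RIL'")
        if self.line_type == "RIL" and self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        for a, b, n in self.crosses:
            if a == b:
                raise ValueError(f"selfing cross {a!r} x {a!r} not allowed")
            if n < 1:
                raise ValueError("n_lines must be >= 1")

    @property
    def n_lines(self) -> int:
        return sum(n for _, _, n in self.crosses)


def random_cross_plan(
    parent_ids,
    n_crosses: int,
    lines_per_cross=(8, 10),
    line_type: str = "DH",
    selfing_generations: int = 8,
    seed=None,
) -> CrossPlan:
    """Random crossing design: distinct parent pairs, a random number of
    lines per cross drawn uniformly from ``lines_per_cross`` (inclusive)."""
    rng = as_rng(seed)
    parent_ids = list(parent_ids)
    lo, hi = (lines_per_cross, lines_per_cross) if np.isscalar(lines_per_cross) else lines_per_cross
    crosses = []
    for _ in range(n_crosses):
        a, b = rng.choice(len(parent_ids), size=2, replace=False)
        n = int(rng.integers(lo, hi + 1))
        crosses.append((parent_ids[a], parent_ids[b], n))
    return CrossPlan(crosses=crosses, line_type=line_type, selfing_generations=selfing_generations)


def _dh_ancestry(eng, rng):
    # DH genotype = single F1 gamete, doubled
    return eng.gamete_phase(rng)


def _ril_ancestry(eng, generations, rng):
    # single-seed descent from the F1; each generation is one selfing,
    # i.e. two independent meioses of the current plant
    h1 = np.zeros(eng.n_markers, dtype=np.int8)
    h2 = np.ones(eng.n_markers, dtype=np.int8)
    for _ in range(generations):
        g1 = np.where(eng.gamete_phase(rng) == 0, h1, h2)
        g2 = np.where(eng.gamete_phase(rng) == 0, h1, h2)
        h1, h2 = g1, g2
    het = h1 != h2
    if het.any():
        coin = rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
        h1 = h1.copy()
        h1[het] = coin
    return h1


def simulate_population(
    founders: FounderSet,
    plan: CrossPlan,
    seed=None,
    population_id: str = "pop",
    return_ancestry: bool = False,
):
    """Simulate the inbred lines of a crossing plan.

    Each line's genome is a mosaic of its two parents' haplotypes.  DH lines
    take a single F1 gamete; RIL lines are propagated by single-seed descent
    for ``plan.selfing_generations`` selfing meioses, with residual
    heterozygous positions resolved by a fair coin.  Monomorphic markers are
    retained.

    Returns a :class:`MarkerMatrix`; with ``return_ancestry=True`` also
    returns the lines x markers parental-origin array (0 = first parent)
    from which recombination junctions can be counted.
    """
    rng = as_rng(seed)
    eng = _MeiosisEngine(founders.map, founders.marker_ids)
    pidx = {p: i for i, p in enumerate(founders.parent_ids)}
    rows, anc_rows, line_ids = [], [], []
    for ci, (pa, pb, n_lines) in enumerate(plan.crosses):
        if pa not in pidx or pb not in pidx:
            raise ValueError(f"cross parents {pa!r}/{pb!r} not in founder set")
        hap_a = founders.haplotypes[pidx[pa]]
        hap_b = founders.haplotypes[pidx[pb]]
        for li in range(n_lines):
            if plan.line_type == "DH":
                anc = _dh_ancestry(eng, rng)
            else:
                anc = _ril_ancestry(eng, plan.selfing_generations, rng)
            rows.append(np.where(anc == 0, hap_a, hap_b))
            if return_ancestry:
                anc_rows.append(anc)
            line_ids.append(f"{population_id}_c{ci:03d}_l{li:02d}")
    mat = MarkerMatrix(
        line_ids=line_ids,
        marker_ids=list(founders.marker_ids),
        genotypes=np.array(rows, dtype=float),
        population_id=population_id,
    )
    if return_ancestry:
        return mat, np.array(anc_rows, dtype=np.int8)
    return mat


def mean_junction_count(ancestry: np.ndarray, gmap: GeneticMap, marker_ids) -> float:
    """Mean number of observed recombination junctions per line."""
    eng = _MeiosisEngine(gmap, list(marker_ids))
    return float(np.mean([eng.junctions(a) for a in ancestry]))


def study_populations(
    seed=None,
    markers_per_chromosome: int = 120,
    n_chromosomes: int = 21,
    chrom_length_cM: float = 150.0,
    pool_size: int = 160,
    parents_per_population: int = 110,
    n_crosses: int = 70,
    lines_per_cross: int = 5,
    line_type_a: str = "DH",
    line_type_b: str = "RIL",
    selfing_generations: int = 8,
    freq_spec=None,
):
    """Two ~350-line breeding populations from overlapping founder subsets.

    Emulates a pair of elite breeding populations: a common founder pool,
    each population built from its own (overlapping) subset of ~110 parents
    through ~70 crosses, one population of doubled haploids and one of
    recombinant inbred lines by default.  With the default U-shaped founder
    allele-frequency spectrum, roughly half of the ~2,500 markers segregate
    in both populations at once.

    Returns ``(pop_a, pop_b, founders)``.
    """
    rng = as_rng(seed)
    gmap = uniform_map(n_chromosomes, chrom_length_cM, markers_per_chromosome)
    founders = simulate_founders(pool_size, gmap, freq_spec, rng)
    overlap_start = pool_size - parents_per_population
    parents_a = founders.parent_ids[:parents_per_population]
    parents_b = founders.parent_ids[overlap_start:]
    pops = []
    for pid, parents, ltype in (
        ("popA", parents_a, line_type_a),
        ("popB", parents_b, line_type_b),
    ):
        plan = random_cross_plan(
            parents,
            n_crosses,
            lines_per_cross,
            line_type=ltype,
            selfing_generations=selfing_generations,
            seed=rng,
        )
        pops.append(simulate_population(founders, plan, seed=rng, population_id=pid))
    return pops[0], pops[1], founders


def simulate_field_trial(
    line_values,
    n_locations: int = 3,
    n_sub_blocks: int = 10,
    n_controls: int = 4,
    location_sd: float = 0.5,
    block_sd: float = 0.5,
    residual_sd: float = 0.3,
    trait_name: str = "trait",
    seed=None,
):
    """Emulate an unreplicated multi-location trial with repeated controls.

    ``line_values`` maps line id -> true genetic value.  At every location
    the lines are randomized into ``n_sub_blocks`` sub-blocks; each
    sub-block additionally contains the same ``n_controls`` control
    cultivars.  Observed value = true value + location effect + sub-block
    effect + residual noise.  Returns a :class:`~gsel.io.PhenotypeTable`.
    """
    from .io import PhenotypeTable
    import pandas as pd

    rng = as_rng(seed)
    lines = list(line_values)
    g = np.array([line_values[l] for l in lines])
    ctrl_ids = [f"CTRL{k + 1}" for k in range(n_controls)]
    ctrl_g = rng.normal(g.mean(), g.std() if g.std() > 0 else 1.0, size=n_controls)
    rows = []
    for l in range(n_locations):
        loc = f"loc{l + 1}"
        loc_eff = rng.normal(0.0, location_sd)
        block_eff = rng.normal(0.0, block_sd, size=n_sub_blocks)
        assignment = rng.integers(0, n_sub_blocks, size=len(lines))
        for line, gv, b in zip(lines, g, assignment):
            rows.append(
                {
                    "line": line,
                    "location": loc,
                    "sub_block": f"b{b + 1}",
                    "is_control": False,
                    "trait": trait_name,
                    "value": gv + loc_eff + block_eff[b] + rng.normal(0, residual_sd),
                }
            )
        for b in range(n_sub_blocks):
            for cid, cg in zip(ctrl_ids, ctrl_g):
                rows.append(
                    {
                        "line": cid,
                        "location": loc,
                        "sub_block": f"b{b + 1}",
                        "is_control": True,
                        "trait": trait_name,
                        "value": cg + loc_eff + block_eff[b] + rng.normal(0, residual_sd),
                    }
                )
    return PhenotypeTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# trait architecture


@dataclass
class TraitArchitecture:
    """Additive QTL model: marker indices, effects and target heritability."""

    qtl_marker_indices: np.ndarray
    effects: np.ndarray
    h2: float = 1.0
    trait_name: str = "trait"

    def __post_init__(self):
        self.qtl_marker_indices = np.asarray(self.qtl_marker_indices, dtype=np.intp)
        self.effects = np.asarray(self.effects, dtype=float)
        if len(np.unique(self.qtl_marker_indices)) != len(self.qtl_marker_indices):
            raise ValueError("QTL indices must be unique")
        if self.effects.shape != self.qtl_marker_indices.shape:
            raise ValueError("effects and QTL indices differ in length")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")

    @property
    def n_qtl(self) -> int:
        return len(self.qtl_marker_indices)


def draw_architecture(
    common_markers, n_qtl: int = 100, sigma_a: float = 1.0, seed=None, h2: float = 1.0,
    trait_name: str = "trait",
) -> TraitArchitecture:
    """Sample ``n_qtl`` distinct QTL positions uniformly from a marker pool
    and give them i.i.d. Normal(0, sigma_a^2) additive effects."""
    common_markers = np.asarray(common_markers)
    if n_qtl > len(common_markers):
        raise ValueError(f"n_qtl={n_qtl} exceeds {len(common_markers)} available markers")
    rng = as_rng(seed)
    idx = rng.choice(common_markers, size=n_qtl, replace=False)
    effects = rng.normal(0.0, sigma_a, size=n_qtl)
    return TraitArchitecture(idx, effects, h2=h2, trait_name=trait_name)


def shared_subsets(arch: TraitArchitecture, fraction: float, seed=None):
    """Two architectures drawing the same fraction of ``arch``'s QTLs
    independently (without replacement, keeping the original effects); one
    for the training population's trait, one for the validation
    population's.  With fraction f, the expected realized overlap is
    f^2 * n_qtl QTLs."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = int(round(fraction * arch.n_qtl))
    if k < 1:
        raise ValueError("fraction too small: empty QTL subset")
    rng = as_rng(seed)
    out = []
    for _ in range(2):
        pick = rng.choice(arch.n_qtl, size=k, replace=False)
        out.append(
            TraitArchitecture(
                arch.qtl_marker_indices[pick],
                arch.effects[pick],
                h2=arch.h2,
                trait_name=arch.trait_name,
            )
        )
    return out[0], out[1]


def shared_subsets_overlap(
    arch: TraitArchitecture, subset_fraction: float, overlap: float, seed=None
):
    """Two equal-size QTL subsets with an *explicitly set* shared proportion.

    Each architecture gets ``k = round(subset_fraction * n_qtl)`` QTLs of
    which ``round(overlap * k)`` are common to both; the rest are drawn
    disjointly from the remaining pool.  Requires
    ``k * (2 - overlap) <= n_qtl``.
    """
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    k = int(round(subset_fraction * arch.n_qtl))
    n_shared = int(round(overlap * k))
    need = 2 * k - n_shared
    if need > arch.n_qtl:
        raise ValueError(
            f"cannot place two {k}-QTL subsets with overlap {overlap} in "
            f"{arch.n_qtl} QTLs"
        )
    rng = as_rng(seed)
    perm = rng.permutation(arch.n_qtl)
    shared = perm[:n_shared]
    own_a = perm[n_shared : n_shared + (k - n_shared)]
    own_b = perm[n_shared + (k - n_shared) : need]
    out = []
    for own in (own_a, own_b):
        pick = np.concatenate([shared, own]).astype(np.intp)
        out.append(
            TraitArchitecture(
                arch.qtl_marker_indices[pick], arch.effects[pick],
                h2=arch.h2, trait_name=arch.trait_name,
            )
        )
    return out[0], out[1]


def simulate_trait(m: MarkerMatrix, arch: TraitArchitecture, seed=None, h2=None):
    """Simulate line phenotypes: additive genetic value plus Gaussian noise.

    ``g_i = sum_k effects[k] * genotype[i, qtl_k]``; the noise variance is
    set from the realized variance of ``g`` in this population so that the
    simulated line-mean heritability equals ``h2`` (``arch.h2`` by default):
    ``sigma_e^2 = Var(g) * (1 - h2) / h2``.

    Returns ``(phenotype, genetic_value)``.
    """
    if h2 is None:
        h2 = arch.h2
    if not 0 < h2 <= 1:
        raise ValueError("h2 must be in (0, 1]")
    if arch.qtl_marker_indices.max(initial=-1) >= m.n_markers:
        raise ValueError("architecture indexes markers beyond the matrix")
    G = m.genotypes
    if np.isnan(G).any():
        raise ValueError("genotypes contain missing values; impute first")
    g = G[:, arch.qtl_marker_indices] @ arch.effects
    if h2 >= 1.0:
        return g.copy(), g
    var_g = float(np.var(g, ddof=1))
    if var_g == 0:
        raise ValueError("genetic variance is zero; heritability undefined")
    sigma_e = np.sqrt(var_g * (1.0 - h2) / h2)
    rng = as_rng(seed)
    y = g + rng.normal(0.0, sigma_e, size=g.shape[0])
    return y, g
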