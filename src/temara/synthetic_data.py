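"""Forward simulator for TE gain/loss in asexual diploid lineages.

Emulates a mutation-accumulation (MA) design: a diploid starting control
(SC) genotype carries TE copies at genomic sites in zygosity state 1
(heterozygous) or 2 (homozygous); descendant lines are propagated for G
generations during which each site can undergo one of four transitions per
generation — a novel insertion seeded by an existing copy (0->1), a gain at
a heterozygous site (1->2), loss of a heterozygous copy (1->0), or loss at
a homozygous site (2->1). Every realized transition is recorded in a
ground-truth event log so downstream callers can be benchmarked. Junction
read evidence is sampled per site at Poisson coverage, TE copy sequences
diverge from their consensus by point mutation, and multi-population
insertion-site panels reproduce shared / population-private / singleton
site classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import (
    Config,
    Dataset,
    RatesConfig,
    TESite,
    ValidationError,
    rng_from_seed,
)
from .te_profiles import TIPMatrix

EVENT_TYPES = ("gain01", "gain12", "loss10", "loss21")

TRUTH_COLUMNS = ["line_id", "site_id", "family_id", "type", "generation"]


@dataclass
class SimulationParams:
    """Per-family transition rates plus the evidence-model parameters.

    ``rates`` applies to every family unless ``family_rates`` overrides a
    family. Rates are probabilities per copy per generation.
    """

    rates: RatesConfig = field(default_factory=RatesConfig)
    family_rates: dict[str, RatesConfig] = field(default_factory=dict)
    generations: int = 12
    n_lines: int = 8
    depth: float = 50.0
    epsilon: float = 0.01
    detect_weight: float = 1.0
    het_fraction: float = 0.3
    seed: int = 0

    def rates_for(self, family_id: str) -> RatesConfig:
        return self.family_rates.get(family_id, self.rates)

    def validate(self) -> None:
        for r in [self.rates, *self.family_rates.values()]:
            r.validate()
        if self.depth <= 0:
            raise ValidationError("depth must be > 0")
        if not (0 <= self.epsilon < 0.5):
            raise ValidationError("epsilon must be in [0, 0.5)")
        if not (0 <= self.het_fraction <= 1):
            raise ValidationError("het_fraction must be in [0, 1]")


@dataclass(frozen=True)
class TrueEvent:
    line_id: str
    site_id: str
    family_id: str
    type: str
    generation: int


@dataclass
class AncestorGenome:
    """Occupied TE sites of an SC genotype plus a pool of empty positions."""

    sites: list[TESite]
    zygosity: np.ndarray  # parallel to sites; values 1 or 2
    candidate_positions: list[tuple[str, int]]

    @property
    def copy_number(self) -> dict[str, int]:
        """N_SC: occupied-site count per family (site-level copies)."""
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.family_id] = counts.get(s.family_id, 0) + 1
        return counts


@dataclass
class LineResult:
    """Descendant state of one propagated line.

    ``sites`` lists the ancestor's sites followed by any sites gained in
    this line; ``zygosity`` is parallel (0 = lost, 1, 2).
    """

    sites: list[TESite]
    zygosity: np.ndarray
    events: list[TrueEvent]

    def zygosity_map(self) -> dict[str, int]:
        return {s.site_id: int(z) for s, z in zip(self.sites, self.zygosity)}


def _distinct_positions(
    rng: np.random.Generator, total: int, genome_size: int, n_contigs: int
) -> list[tuple[str, int]]:
    span = genome_size * n_contigs
    if total > span:
        raise ValidationError("genome too small to host requested sites")
    chosen: set[int] = set()
    while len(chosen) < total:
        draw = rng.integers(0, span, size=2 * (total - len(chosen)))
        chosen.update(int(v) for v in draw)
        while len(chosen) > total:
            chosen.pop()
    flat = sorted(chosen)
    rng.shuffle(flat)
    return [(f"contig{v // genome_size + 1}", v % genome_size) for v in flat]


def make_ancestor(
    params: SimulationParams,
    family_spec: dict[str, int],
    genome_size: int = 1_000_000,
    n_contigs: int = 10,
    candidate_pool: int = 5_000,
    seed: int | None = None,
    site_prefix: str = "s",
) -> AncestorGenome:
    """Construct an SC genome with exact per-family copy numbers.

    Each occupied site is heterozygous with probability ``het_fraction``,
    homozygous otherwise. Unoccupied candidate positions (the insertion
    pool) are disjoint from occupied sites.
    """
    params.validate()
    if any(n < 0 for n in family_spec.values()):
        raise ValidationError("family copy numbers must be >= 0")
    rng = rng_from_seed(params.seed if seed is None else seed, 1)
    n_occupied = sum(family_spec.values())
    positions = _distinct_positions(rng, n_occupied + candidate_pool, genome_size, n_contigs)

    sites: list[TESite] = []
    idx = 0
    for family_id in family_spec:  # insertion order: deterministic
        for _ in range(family_spec[family_id]):
            contig, pos = positions[idx]
            sites.append(TESite(f"{site_prefix}{idx:06d}", contig, pos, family_id))
            idx += 1
    zygosity = np.where(rng.random(n_occupied) < params.het_fraction, 1, 2).astype(int)
    return AncestorGenome(
        sites=sites,
        zygosity=zygosity,
        candidate_positions=positions[idx:],
    )


def _gain_site_id(contig: str, position: int, family_id: str) -> str:
    # stable across lines: two lines inserting at the same pooled position
    # share the site in a joint table
    return f"g_{contig}_{position}_{family_id}"


def propagate_line(
    ancestor: AncestorGenome,
    params: SimulationParams,
    seed: int,
    line_id: str = "",
    generations: int | None = None,
) -> LineResult:
    """Propagate one descendant line for G generations.

    Per generation, independently and based on the state at the start of
    the generation: every occupied site (z >= 1) seeds a novel insertion
    with probability u01 (target drawn from the candidate pool, new site
    heterozygous, event attributed to the new site; the source copy is
    unchanged); each z = 1 site moves to 2 with probability u12 or to 0
    with probability u10; each z = 2 site moves to 1 with probability u21.
    At most one transition per site per generation.
    """
    params.validate()
    G = params.generations if generations is None else generations
    rng = rng_from_seed(seed, 2)

    sites = list(ancestor.sites)
    z = ancestor.zygosity.astype(int).copy()
    # per-site rate vectors, extended as gains are appended
    def rate_vec(attr: str) -> list[float]:
        return [getattr(params.rates_for(s.family_id), attr) for s in sites]

    u01 = np.array(rate_vec("u01"))
    u12 = np.array(rate_vec("u12"))
    u10 = np.array(rate_vec("u10"))
    u21 = np.array(rate_vec("u21"))

    pool = list(ancestor.candidate_positions)
    rng.shuffle(pool)  # popping the tail == sequential uniform draws
    events: list[TrueEvent] = []

    for gen in range(1, G + 1):
        occupied = z >= 1
        het = z == 1
        hom = z == 2

        # draws based on start-of-generation state
        seed_gain = occupied & (rng.random(len(z)) < u01)
        r = rng.random(len(z))
        to_hom = het & (r < u12)
        to_absent = het & ~to_hom & (r < u12 + u10)
        to_het = hom & (rng.random(len(z)) < u21)

        z[to_hom] = 2
        z[to_absent] = 0
        z[to_het] = 1
        for idx in np.flatnonzero(to_hom):
            events.append(TrueEvent(line_id, sites[idx].site_id, sites[idx].family_id, "gain12", gen))
        for idx in np.flatnonzero(to_absent):
            events.append(TrueEvent(line_id, sites[idx].site_id, sites[idx].family_id, "loss10", gen))
        for idx in np.flatnonzero(to_het):
            events.append(TrueEvent(line_id, sites[idx].site_id, sites[idx].family_id, "loss21", gen))

        new_sites = []
        for idx in np.flatnonzero(seed_gain):
            if not pool:
                raise ValidationError(
                    "candidate pool exhausted; re-run with a larger candidate_pool"
                )
            contig, pos = pool.pop()
            family_id = sites[idx].family_id
            site = TESite(_gain_site_id(contig, pos, family_id), contig, pos, family_id)
            new_sites.append(site)
            events.append(TrueEvent(line_id, site.site_id, family_id, "gain01", gen))
        if new_sites:
            sites.extend(new_sites)
            z = np.concatenate([z, np.ones(len(new_sites), dtype=int)])
            for attr, arr in (("u01", u01), ("u12", u12), ("u10", u10), ("u21", u21)):
                extra = [getattr(params.rates_for(s.family_id), attr) for s in new_sites]
                arr = np.concatenate([arr, extra])
                if attr == "u01":
                    u01 = arr
                elif attr == "u12":
                    u12 = arr
                elif attr == "u10":
                    u10 = arr
                else:
                    u21 = arr

    return LineResult(sites=sites, zygosity=z, events=events)


def simulate_evidence(
    sites: list[TESite],
    zygosity: np.ndarray | dict[str, int],
    params: SimulationParams,
    seed: int,
    line_id: str = "line",
) -> pd.DataFrame:
    """Sample junction-read evidence for one line over a site list.

    Total reads per site ~ Poisson(depth); presence reads ~ Binomial(n, f)
    with f = epsilon (z = 0), 0.5 (z = 1) or 1 - epsilon (z = 2), scaled by
    ``detect_weight`` (a stand-in for length-dependent detectability).
    """
    params.validate()
    rng = rng_from_seed(seed, 3)
    if isinstance(zygosity, dict):
        z = np.array([zygosity.get(s.site_id, 0) for s in sites], dtype=int)
    else:
        z = np.asarray(zygosity, dtype=int)
    if len(z) != len(sites):
        raise ValidationError("zygosity length must match the site list")
    n = rng.poisson(params.depth, size=len(sites))
    f = np.select([z == 0, z == 1], [params.epsilon, 0.5], default=1.0 - params.epsilon)
    f = np.clip(f * params.detect_weight, 0.0, 1.0)
    p = rng.binomial(n, f)
    return pd.DataFrame({
        "line_id": line_id,
        "site_id": [s.site_id for s in sites],
        "presence_reads": p,
        "absence_reads": n - p,
    })


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def evolve_copies(
    consensus: str,
    n_copies: int,
    mu_t: float,
    seed: int = 0,
) -> list[str]:
    """Diverge copies independently from a consensus (star tree).

    Each copy substitutes each site with probability ``mu_t`` to a
    uniformly chosen different base, i.i.d. across sites and copies.
    """
    if not consensus:
        raise ValidationError("consensus must be non-empty")
    if not (0 <= mu_t < 0.3):
        raise ValidationError("mu_t must be in [0, 0.3)")
    rng = rng_from_seed(seed, 4)
    base_idx = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
    arr = np.array([base_idx.get(b, 0) for b in consensus.upper().encode()], dtype=int)
    copies = []
    for _ in range(n_copies):
        mutate = rng.random(len(arr)) < mu_t
        shift = rng.integers(1, 4, size=len(arr))
        new = np.where(mutate, (arr + shift) % 4, arr)
        copies.append(b"".join(_BASES[new]).decode())
    return copies


def make_population_panel(
    n_populations: int,
    genotypes_per_pop: int,
    n_shared: int,
    n_pop_private: int,
    n_singleton: int,
    seed: int = 0,
) -> TIPMatrix:
    """Build a TIP panel with known site-class counts.

    Exactly ``n_shared`` sites are occupied in >= 2 genotypes spanning >= 2
    populations, ``n_pop_private`` sites (total, spread as evenly as
    possible across populations) in >= 2 genotypes of a single population,
    and ``n_singleton`` sites in exactly one genotype. Occupying genotypes
    are drawn uniformly at random given the class.
    """
    if min(n_shared, n_pop_private, n_singleton) < 0:
        raise ValidationError("site-class counts must be >= 0")
    if genotypes_per_pop < 1:
        raise ValidationError("genotypes_per_pop must be >= 1")
    if n_pop_private > 0 and genotypes_per_pop < 2:
        raise ValidationError("population-private sites need >= 2 genotypes per population")
    if n_shared > 0 and (n_populations < 2 or n_populations * genotypes_per_pop < 2):
        raise ValidationError("shared sites need >= 2 populations")
    rng = rng_from_seed(seed, 5)
    pops = [f"pop{i + 1}" for i in range(n_populations)]
    genotypes = [f"{p}-g{j + 1}" for p in pops for j in range(genotypes_per_pop)]
    pop_of = {g: g.split("-")[0] for g in genotypes}
    n_genotypes = len(genotypes)
    geno_pop = np.array([pop_of[g] for g in genotypes])

    rows = []
    for _ in range(n_shared):
        # cap at n_genotypes - 1 so shared sites stay polymorphic
        while True:
            m = int(rng.integers(2, max(n_genotypes, 3)))
            chosen = rng.choice(n_genotypes, size=m, replace=False)
            if len(set(geno_pop[chosen])) >= 2:
                break
        row = np.zeros(n_genotypes, dtype=int)
        row[chosen] = 1
        rows.append(row)

    # spread private sites across populations as evenly as possible
    order = list(range(n_populations))
    rng.shuffle(order)
    for i in range(n_pop_private):
        pop_idx = order[i % n_populations]
        members = np.flatnonzero(geno_pop == pops[pop_idx])
        m = int(rng.integers(2, genotypes_per_pop + 1))
        chosen = rng.choice(members, size=m, replace=False)
        row = np.zeros(n_genotypes, dtype=int)
        row[chosen] = 1
        rows.append(row)

    for _ in range(n_singleton):
        row = np.zeros(n_genotypes, dtype=int)
        row[int(rng.integers(n_genotypes))] = 1
        rows.append(row)

    matrix = pd.DataFrame(
        np.array(rows, dtype=int) if rows else np.zeros((0, n_genotypes), dtype=int),
        columns=genotypes,
        index=[f"tip{i:05d}" for i in range(len(rows))],
    )
    return TIPMatrix(matrix=matrix, populations=pop_of)


# ---------------------------------------------------------------------------
# Full-experiment generator
# ---------------------------------------------------------------------------

@dataclass
class SimulatedExperiment:
    """A full synthetic MA/EC study with its ground truth."""

    dataset: Dataset
    truth: pd.DataFrame           # TRUTH_COLUMNS
    ancestors: dict[str, AncestorGenome]
    true_zygosity: dict[str, dict[str, int]]  # line_id -> site_id -> z


def _ec_rates(rates: RatesConfig, gain_factor: float, loss_factor: float) -> RatesConfig:
    return replace(
        rates,
        u01=rates.u01 * gain_factor,
        u12=rates.u12 * gain_factor,
        u10=rates.u10 * loss_factor,
        u21=rates.u21 * loss_factor,
    )


def simulate_experiment(config: Config) -> SimulatedExperiment:
    """Simulate SC + MA + EC lines for every genotype of every population.

    EC (extant control) lines evolve under the MA rates scaled by the
    configured selection-retention factors (gains and losses purged to the
    realized degree selection achieves at large population size).
    """
    sim = config.simulation
    params = SimulationParams(
        rates=config.rates,
        generations=sim.generations,
        n_lines=sim.n_ma_lines,
        depth=sim.depth,
        epsilon=sim.epsilon,
        detect_weight=sim.detect_weight,
        het_fraction=sim.het_fraction,
        seed=config.seed,
    )
    ec_params = replace(
        params, rates=_ec_rates(config.rates, sim.ec_gain_factor, sim.ec_loss_factor)
    )

    master = rng_from_seed(config.seed, 0)

    def child_seed() -> int:
        return int(master.integers(2**31))

    lineage_rows = []
    evidence_frames = []
    truth_rows = []
    site_union: dict[str, TESite] = {}
    ancestors: dict[str, AncestorGenome] = {}
    true_z: dict[str, dict[str, int]] = {}

    genotype_index = 0
    for p in range(sim.n_populations):
        pop_id = f"pop{p + 1}"
        for g in range(sim.genotypes_per_population):
            genotype_id = f"{pop_id}-G{g + 1}"
            ancestor = make_ancestor(
                params,
                sim.families,
                genome_size=sim.genome_size,
                n_contigs=sim.n_contigs,
                candidate_pool=sim.candidate_pool,
                seed=child_seed(),
                site_prefix=f"{genotype_id}_s",
            )
            ancestors[genotype_id] = ancestor

            lines: dict[str, LineResult] = {}
            sc_id = f"{genotype_id}-sc"
            lineage_rows.append((sc_id, genotype_id, pop_id, "SC", 0))
            for i in range(sim.n_ma_lines):
                line_id = f"{genotype_id}-ma{i + 1}"
                res = propagate_line(
                    ancestor, params,
                    seed=child_seed(),
                    line_id=line_id,
                )
                lines[line_id] = res
                lineage_rows.append((line_id, genotype_id, pop_id, "MA", sim.generations))
            for i in range(sim.n_ec_lines):
                line_id = f"{genotype_id}-ec{i + 1}"
                res = propagate_line(
                    ancestor, ec_params,
                    seed=child_seed(),
                    line_id=line_id,
                )
                lines[line_id] = res
                lineage_rows.append((line_id, genotype_id, pop_id, "EC", sim.generations))

            # genotype-local site union: ancestor sites + any line's gains
            local: dict[str, TESite] = {s.site_id: s for s in ancestor.sites}
            for res in lines.values():
                for s in res.sites:
                    local.setdefault(s.site_id, s)
            site_union.update(local)
            local_sites = list(local.values())

            sc_map = {s.site_id: int(z) for s, z in zip(ancestor.sites, ancestor.zygosity)}
            true_z[sc_id] = sc_map
            evidence_frames.append(
                simulate_evidence(
                    local_sites, sc_map, params,
                    seed=child_seed(), line_id=sc_id,
                )
            )
            for k, (line_id, res) in enumerate(lines.items()):
                zmap = res.zygosity_map()
                true_z[line_id] = zmap
                evidence_frames.append(
                    simulate_evidence(
                        local_sites, zmap, params,
                        seed=child_seed(),
                        line_id=line_id,
                    )
                )
                truth_rows.extend(
                    (e.line_id, e.site_id, e.family_id, e.type, e.generation)
                    for e in res.events
                )
            genotype_index += 1

    sites_df = pd.DataFrame(
        [(s.site_id, s.contig, s.position, s.family_id) for s in site_union.values()],
        columns=["site_id", "contig", "position", "family_id"],
    ).sort_values("site_id", kind="stable").reset_index(drop=True)
    lineages_df = pd.DataFrame(
        lineage_rows,
        columns=["line_id", "genotype_id", "population_id", "role", "generations"],
    )
    evidence_df = pd.concat(evidence_frames, ignore_index=True)[
        ["line_id", "site_id", "presence_reads", "absence_reads"]
    ]
    truth_df = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    dataset = Dataset(sites=sites_df, lineages=lineages_df, evidence=evidence_df)
    return SimulatedExperiment(
        dataset=dataset, truth=truth_df, ancestors=ancestors, true_zygosity=true_z
    )
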