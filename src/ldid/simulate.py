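"""Coalescent synthetic data: panels, diploid individuals, sparse observations.

The generator reproduces the structure of the method's simulation study:
many independent 500-kb segments are simulated under a coalescent with
recombination (msprime's Hudson model), a phased reference panel is taken
from haplotypes NOT used for the test individuals, segregating sites with
low minor allele frequency are removed, and single-base observations are
drawn sparsely from each chromosome copy with double-draw discard. Each
segment becomes an independent pseudo-chromosome, so aggregation windows
never straddle segments.

Defaults are the study conditions: 3000 segments x 500 kb (1.5 Gb total),
constant effective population size 10,000, 200-haplotype panels, MAF >= 10%
(computed on the panel haplotypes), observation rate 0.01 per chromosome
copy (~0.02-fold coverage after discard). An optional symmetric population
split lets the panel come from a population diverged from the sample
individuals by a configurable number of generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aggregate import PairingConfig, compare_samples
from .observe import Observation, ObservationSet
from .panel import ReferencePanel, SnpSite

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimScenario:
    """Demographic and sampling parameters for one synthetic cohort.

    ``split_generations=0`` draws panel and individuals from a single
    constant-size population; a positive value splits an ancestral
    population of ``effective_size`` into two equal-sized daughters that
    many generations ago, drawing the individuals from one daughter and the
    panel from the other (no subsequent migration).
    """

    n_segments: int = 3000
    segment_length_bp: int = 500_000
    effective_size: int = 10_000
    mutation_rate: float = 1.25e-8
    recombination_rate: float = 1e-8
    panel_haplotypes: int = 200
    maf_floor: float = 0.10
    split_generations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not 0.0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in [0, 0.5)")
        if self.panel_haplotypes < 2:
            raise ValueError("panel needs at least 2 haplotypes")


@dataclass
class Diploid:
    """A simulated diploid genome: two haplotype vectors over panel sites."""

    name: str
    haplotypes: np.ndarray  # uint8, shape (2, n_sites)

    def allele(self, copy: int, site_index: int) -> int:
        return int(self.haplotypes[copy, site_index])


@dataclass
class SimCohort:
    """A reference panel plus diploid individuals drawn from the same run.

    Individual haplotypes are excluded from the panel (no overlap), and all
    are defined at exactly the panel's sites.
    """

    panel: ReferencePanel
    individuals: list[Diploid]
    provenance: dict = field(default_factory=dict)


def _segment_tables(scenario: SimScenario, n_individuals: int, seeds: np.ndarray):
    """Yield (positions, genotype matrix) per segment from msprime.

    Columns 0 .. 2*n_individuals-1 of the genotype matrix are the test
    individuals' haplotypes (population 1 under the split model), the
    remaining ``panel_haplotypes`` columns the panel (population 2).
    """
    import msprime

    n_ind_haps = 2 * n_individuals
    for si in range(scenario.n_segments):
        if scenario.split_generations > 0:
            demography = msprime.Demography()
            demography.add_population(
                name="samples", initial_size=scenario.effective_size
            )
            demography.add_population(
                name="panel", initial_size=scenario.effective_size
            )
            demography.add_population(
                name="ancestral", initial_size=scenario.effective_size
            )
            demography.add_population_split(
                time=scenario.split_generations,
                derived=["samples", "panel"],
                ancestral="ancestral",
            )
            sample_sets = [
                msprime.SampleSet(n_ind_haps, population="samples", ploidy=1),
                msprime.SampleSet(
                    scenario.panel_haplotypes, population="panel", ploidy=1
                ),
            ]
            ts = msprime.sim_ancestry(
                samples=sample_sets,
                demography=demography,
                sequence_length=scenario.segment_length_bp,
                recombination_rate=scenario.recombination_rate,
                random_seed=int(seeds[si, 0]),
            )
        else:
            ts = msprime.sim_ancestry(
                samples=[
                    msprime.SampleSet(
                        n_ind_haps + scenario.panel_haplotypes, ploidy=1
                    )
                ],
                population_size=scenario.effective_size,
                sequence_length=scenario.segment_length_bp,
                recombination_rate=scenario.recombination_rate,
                random_seed=int(seeds[si, 0]),
            )
        mts = msprime.sim_mutations(
            ts,
            rate=scenario.mutation_rate,
            random_seed=int(seeds[si, 1]),
            model=msprime.BinaryMutationModel(),
        )
        positions = np.floor(mts.sites_position).astype(np.int64)
        G = mts.genotype_matrix()  # sites x haplotypes, codes 0/1
        yield positions, G


def simulate_cohort(scenario: SimScenario, n_individuals: int = 2) -> SimCohort:
    """Simulate a reference panel and ``n_individuals`` diploid genomes.

    Per segment: coalescent haplotypes are generated, sites with panel
    minor allele frequency below ``scenario.maf_floor`` are removed, two
    haplotypes per individual are taken from columns disjoint from the
    panel's, and the segment is emitted as pseudo-chromosome ``segNNNN``.
    Ref/alt bases are assigned at random so the data exercise the same
    base-level code paths as real input.
    """
    n_ind_haps = 2 * n_individuals
    ss = np.random.SeedSequence(entropy=scenario.seed, spawn_key=(0,))
    rng = np.random.default_rng(ss)
    seeds = rng.integers(1, 2**31 - 1, size=(scenario.n_segments, 2))
    base_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.seed, spawn_key=(1,))
    )

    sites: list[SnpSite] = []
    panel_cols: list[np.ndarray] = []
    ind_cols: list[np.ndarray] = []
    for si, (positions, G) in enumerate(
        _segment_tables(scenario, n_individuals, seeds)
    ):
        chrom = f"seg{si + 1:04d}"
        ind_G = G[:, :n_ind_haps]
        panel_G = G[:, n_ind_haps:]
        P = panel_G.shape[1]
        alt = panel_G.sum(axis=1)
        maf = np.minimum(alt, P - alt) / P
        keep = maf >= max(scenario.maf_floor, 1 / P)  # also drops monomorphic
        # integer positions must be strictly increasing within the segment
        keep &= np.concatenate(([True], np.diff(positions) > 0))
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        refs = base_rng.integers(0, 4, size=idx.size)
        alts = (refs + base_rng.integers(1, 4, size=idx.size)) % 4
        for k, j in enumerate(idx):
            sites.append(
                SnpSite(
                    chrom,
                    int(positions[j]) + 1,
                    str(_BASES[refs[k]]),
                    str(_BASES[alts[k]]),
                )
            )
        panel_cols.append(panel_G[idx].astype(np.uint8))
        ind_cols.append(ind_G[idx].astype(np.uint8))

    if not sites:
        raise ValueError("no segregating sites survived the MAF filter")
    panel_matrix = np.concatenate(panel_cols, axis=0).T  # haplotypes x sites
    ind_matrix = np.concatenate(ind_cols, axis=0).T
    label = (
        "sim-split" if scenario.split_generations > 0 else "sim-constant"
    )
    mac_floor = int(np.ceil(scenario.maf_floor * scenario.panel_haplotypes))
    panel = ReferencePanel(
        sites,
        panel_matrix,
        population_label=label,
        metadata={
            "scenario": {
                k: getattr(scenario, k) for k in SimScenario.__dataclass_fields__
            },
            "min_minor_count": mac_floor,
        },
    )
    individuals = [
        Diploid(f"ind{i}", ind_matrix[2 * i : 2 * i + 2]) for i in range(n_individuals)
    ]
    provenance = {
        "individuals_population": "samples" if scenario.split_generations else "single",
        "panel_population": "panel" if scenario.split_generations else "single",
    }
    return SimCohort(panel=panel, individuals=individuals, provenance=provenance)


def mate(
    parent1: Diploid,
    parent2: Diploid,
    panel: ReferencePanel,
    recombination_rate: float,
    seed: int,
    name: str = "child",
) -> Diploid:
    """Generate a child: one recombinant gamete from each parent.

    Per pseudo-chromosome, crossover count is Poisson(rate x span) with
    uniform breakpoints; the transmitted allele at each site comes from the
    currently active parental copy. Mendelian consistency (child allele is
    carried by the contributing parent) holds by construction.
    """
    for p in (parent1, parent2):
        if p.haplotypes.shape[1] != panel.n_sites:
            raise ValueError(f"{p.name}: haplotypes not defined on panel sites")
    rng = np.random.default_rng(seed)
    pos = panel.positions
    child = np.empty((2, panel.n_sites), dtype=np.uint8)
    for copy, parent in enumerate((parent1, parent2)):
        gamete = np.empty(panel.n_sites, dtype=np.uint8)
        for chrom, (start, stop) in panel.chrom_ranges().items():
            p = pos[start:stop]
            span = int(p[-1] - p[0]) + 1
            n_cross = rng.poisson(recombination_rate * span)
            breaks = np.sort(rng.uniform(p[0], p[-1] + 1, size=n_cross))
            active = (
                rng.integers(2) + np.searchsorted(breaks, p, side="right")
            ) % 2
            seg = parent.haplotypes[:, start:stop]
            gamete[start:stop] = seg[active, np.arange(stop - start)]
        child[copy] = gamete
    return Diploid(name, child)


def sample_observations(
    individual: Diploid,
    panel: ReferencePanel,
    rate: float = 0.01,
    seed: int = 0,
    sample_id: str | None = None,
) -> ObservationSet:
    """Draw sparse allele observations from one diploid individual.

    Each chromosome copy is sampled independently at every panel site with
    probability ``rate``; sites where both copies were drawn are discarded
    (a real single-read observation cannot show both), so the expected
    observed fraction is 2 r (1 - r) — about 0.0198 at the default rate.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError(f"rate must be in (0, 1), got {rate}")
    rng = np.random.default_rng(seed)
    draw = rng.random((2, panel.n_sites)) < rate
    single = draw[0] ^ draw[1]
    copy = np.where(draw[1], 1, 0)
    obs = [
        Observation(int(i), int(individual.haplotypes[copy[i], i]))
        for i in np.flatnonzero(single)
    ]
    return ObservationSet(
        sample_id or f"{individual.name}-obs{seed}", panel.fingerprint(), obs
    )


def run_replicates(
    scenario: SimScenario,
    n_replicates: int,
    observation_rate: float = 0.01,
    config: PairingConfig | None = None,
    relatives: bool = False,
):
    """Replicate the five-panel comparison layout and tabulate mean Lambda.

    Per replicate: simulate a cohort with two individuals (A, B), draw two
    observation sets from A and one from B, and run within-sample
    comparisons on each set, the across-set same-individual comparison
    (A1 vs A2) and the different-individuals comparison (A1 vs B1). With
    ``relatives=True`` a child and a second child of A x B are added for
    parent-child and sibling-sibling comparisons. Returns a tidy pandas
    DataFrame with one row per comparison.
    """
    import pandas as pd

    if config is None:
        config = PairingConfig()
    rows = []
    for rep in range(n_replicates):
        ss = np.random.SeedSequence(entropy=scenario.seed, spawn_key=(100 + rep,))
        sub = ss.generate_state(8) % (2**31 - 1)
        cohort = simulate_cohort(
            replace(scenario, seed=int(sub[0])), n_individuals=2
        )
        a, b = cohort.individuals
        panel = cohort.panel
        obs_a1 = sample_observations(a, panel, observation_rate, int(sub[1]), "A1")
        obs_a2 = sample_observations(a, panel, observation_rate, int(sub[2]), "A2")
        obs_b1 = sample_observations(b, panel, observation_rate, int(sub[3]), "B1")
        comparisons = [
            ("within:A1", "within_sample", obs_a1, None),
            ("within:A2", "within_sample", obs_a2, None),
            ("within:B1", "within_sample", obs_b1, None),
            ("same:A1-A2", "same_individual", obs_a1, obs_a2),
            ("diff:A1-B1", "different_individuals", obs_a1, obs_b1),
        ]
        if relatives:
            child1 = mate(a, b, panel, scenario.recombination_rate, int(sub[4]), "C1")
            child2 = mate(a, b, panel, scenario.recombination_rate, int(sub[5]), "C2")
            obs_c1 = sample_observations(
                child1, panel, observation_rate, int(sub[6]), "C1"
            )
            obs_c2 = sample_observations(
                child2, panel, observation_rate, int(sub[7]), "C2"
            )
            comparisons += [
                ("parent-child:A1-C1", "parent_child", obs_a1, obs_c1),
                ("siblings:C1-C2", "siblings", obs_c1, obs_c2),
            ]
        for label, kind, o1, o2 in comparisons:
            cfg = replace(config, seed=config.seed + rep)
            result = compare_samples(o1, o2, panel, cfg)
            rows.append(
                {
                    "replicate": rep,
                    "label": label,
                    "comparison": kind,
                    "n_windows_used": result.n_windows_used,
                    "mean_llr": result.mean_llr,
                    "sd_llr": result.sd_llr,
                    "ci_low": result.ci_low,
                    "ci_high": result.ci_high,
                    "verdict": result.verdict,
                }
            )
    return pd.DataFrame(rows)
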