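"""Coalescent simulation of neutral and hard-sweep haplotype samples.

This module produces the labeled training data for the sweep-detection
pipeline: binary haplotype matrices (rows = phased chromosomes, columns =
segregating sites with base-pair coordinates) simulated under

* a single-population "three epoch" demography -- ancestral size 10,000,
  an instantaneous crash to 2,000 at 3,500 generations before present,
  and an expansion to 20,000 at 3,000 generations; and
* the Gravel et al. three-population (YRI/CEU/CHB) out-of-Africa model
  with bottlenecks, exponential growth and pairwise migration.

Hard sweeps are simulated with msprime's structured-coalescent sweep model.
The beneficial allele segregates at low frequency (default 1%) at the sweep
onset (default 600 generations ago); its terminal sample-time frequency is
drawn from a forward Wright-Fisher trajectory with genotype fitnesses
``(1, 1 + s_het, 1 + s_hom)``, conditioned on the allele not being lost.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import msprime
import numpy as np

__all__ = [
    "DemographyModel",
    "PopulationHistory",
    "SimRegionParams",
    "SweepParams",
    "HaplotypeMatrix",
    "LabeledDataset",
    "SimulationError",
    "ParameterError",
    "build_single_pop_demography",
    "build_three_pop_demography",
    "simulate_neutral",
    "simulate_sweep",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
]

ENGINE = "msprime-structured-coalescent"


class ParameterError(ValueError):
    """Invalid simulation parameters."""


class SimulationError(RuntimeError):
    """Simulation failed after the allowed number of retries."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationHistory:
    """Piecewise size history of one population, looking into the past.

    ``epochs`` is a tuple of ``(start_time_generations, size, growth_rate)``
    entries with strictly increasing start times.  ``size`` is the size at
    the epoch's recent boundary and ``growth_rate`` the per-generation
    exponential rate forward in time within the epoch (0 = constant).
    """

    name: str
    epochs: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        times = [e[0] for e in self.epochs]
        if not self.epochs or times[0] != 0:
            raise ParameterError("population history must start at time 0")
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ParameterError("epoch times must strictly increase into the past")
        if any(e[1] <= 0 for e in self.epochs):
            raise ParameterError("population sizes must be positive")

    def size_at(self, time: float) -> float:
        """Population size ``time`` generations before present."""
        if time < 0:
            raise ParameterError("time must be non-negative")
        current = self.epochs[0]
        for epoch in self.epochs:
            if epoch[0] <= time:
                current = epoch
            else:
                break
        t0, size, rate = current
        return size * math.exp(-rate * (time - t0))


@dataclass(frozen=True)
class DemographyModel:
    """Declarative demographic model shared by all simulation entry points.

    For the single-population model, ``epochs`` mirrors the (time, size)
    pairs of the unique population.  Migration is a per-generation fraction
    matrix over ``populations`` describing the most recent epoch and is
    ``None`` for single-population models.
    """

    populations: tuple[PopulationHistory, ...]
    migration: np.ndarray | None = None
    generation_time_years: float = 25.0
    name: str = "demography"

    def __post_init__(self) -> None:
        if not self.populations:
            raise ParameterError("at least one population required")
        if len(self.populations) == 1 and self.migration is not None:
            raise ParameterError("single-population model admits no migration")
        if self.migration is not None:
            m = np.asarray(self.migration, dtype=float)
            if m.shape != (len(self.populations),) * 2:
                raise ParameterError("migration matrix shape mismatch")
            if ((m < 0) | (m >= 1)).any():
                raise ParameterError("migration entries must lie in [0, 1)")

    @property
    def population_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.populations)

    @property
    def epochs(self) -> tuple[tuple[float, float], ...]:
        """(time, size) pairs of the first population (single-pop view)."""
        return tuple((t, s) for t, s, _ in self.populations[0].epochs)

    def size_at(self, time: float, population: str | None = None) -> float:
        pop = self._pop(population)
        return pop.size_at(time)

    def _pop(self, population: str | None) -> PopulationHistory:
        if population is None:
            return self.populations[0]
        for p in self.populations:
            if p.name == population:
                return p
        raise ParameterError(f"unknown population {population!r}")

    # -- msprime assembly ---------------------------------------------------

    def to_msprime(self) -> msprime.Demography:
        if len(self.populations) == 1:
            return self._single_pop_msprime()
        if self.name == "gravel_three_pop":
            return _gravel_msprime()
        raise ParameterError("unsupported multi-population model")

    def _single_pop_msprime(self) -> msprime.Demography:
        dem = msprime.Demography()
        hist = self.populations[0]
        t0, size0, rate0 = hist.epochs[0]
        dem.add_population(name=hist.name, initial_size=size0, growth_rate=rate0)
        for t, size, rate in hist.epochs[1:]:
            dem.add_population_parameters_change(
                time=t, initial_size=size, growth_rate=rate
            )
        return dem

    def collapsed(self, population: str) -> "DemographyModel":
        """Single-population approximation following one sampled population.

        Used for sweep simulation in multi-population models (the
        structured-coalescent sweep supports a single deme): migration is
        dropped and exponential-growth epochs are flattened to their size at
        the epoch's recent boundary -- the sweep engine forbids demographic
        events during the sweep phase, so the growth curve cannot be
        discretized into steps there.
        """
        pop = self._pop(population)
        flat = tuple((t0, size, 0.0) for t0, size, _ in pop.epochs)
        hist = PopulationHistory(name=pop.name, epochs=flat)
        return DemographyModel(
            populations=(hist,),
            generation_time_years=self.generation_time_years,
            name=f"{self.name}-collapsed-{population}",
        )


@dataclass(frozen=True)
class SimRegionParams:
    """Region and sample parameters for one simulated window."""

    sequence_length_bp: int = 80_000
    mutation_rate_per_bp_per_gen: float = 1.5e-8
    recombination_rate_per_bp_per_gen: float = 1e-8
    n_haplotypes: int = 128
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sequence_length_bp <= 0:
            raise ParameterError("sequence_length_bp must be positive")
        if self.mutation_rate_per_bp_per_gen < 0 or self.recombination_rate_per_bp_per_gen < 0:
            raise ParameterError("rates must be non-negative")
        if self.n_haplotypes < 2:
            raise ParameterError("need at least two haplotypes")


@dataclass(frozen=True)
class SweepParams:
    """Hard-sweep parameters.

    ``s_het`` is the heterozygote selection coefficient; the homozygote
    coefficient is ``s_het / dominance`` (additive dominance 0.5 doubles it,
    matching "s = 0.01 for heterozygotes, 0.02 for homozygotes").
    ``start_frequency`` is the allele frequency when selection begins.
    """

    s_het: float
    dominance: float = 0.5
    start_time_generations: float = 600.0
    position_fraction: float = 0.5
    target_population: str | None = None
    start_frequency: float = 0.01
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.s_het <= 0:
            raise ParameterError("s_het must be positive")
        if not 0 <= self.position_fraction <= 1:
            raise ParameterError("position_fraction must lie in [0, 1]")
        if self.start_time_generations <= 0:
            raise ParameterError("start_time_generations must be positive")
        if not 0 < self.dominance <= 1:
            raise ParameterError("dominance must lie in (0, 1]")
        if not 0 < self.start_frequency < 1:
            raise ParameterError("start_frequency must lie in (0, 1)")

    @property
    def s_hom(self) -> float:
        return self.s_het / self.dominance


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass
class HaplotypeMatrix:
    """Binary haplotype alignment: ``alleles[i, j]`` is 1 when haplotype i
    carries the derived (or, after recoding, minor) allele at site j."""

    alleles: np.ndarray  # (n_haplotypes, n_sites) uint8
    positions: np.ndarray  # (n_sites,) float bp
    label: str | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.alleles.ndim != 2:
            raise ParameterError("alleles must be 2-D")
        if self.alleles.shape[1] != self.positions.shape[0]:
            raise ParameterError("positions / alleles column mismatch")
        if not set(np.unique(self.alleles)) <= {0, 1}:
            raise ParameterError("alleles must be binary")
        if self.positions.size > 1 and not (np.diff(self.positions) > 0).all():
            raise ParameterError("positions must strictly increase")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def segregating_mask(self) -> np.ndarray:
        counts = self.alleles.sum(axis=0)
        return (counts > 0) & (counts < self.n_haplotypes)


@dataclass
class LabeledDataset:
    """Balanced, split collection of haplotype matrices.

    ``splits`` maps split name to index arrays into ``samples``; labels are
    0 (neutral) / 1 (sweep).
    """

    samples: list[HaplotypeMatrix]
    labels: np.ndarray
    splits: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def subset_labels(self, split: str) -> np.ndarray:
        return self.labels[self.splits[split]]

    def __len__(self) -> int:
        return len(self.samples)


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------


def build_single_pop_demography() -> DemographyModel:
    """Three-epoch single-population model: N = 10,000 ancestrally, 2,000
    between 3,500 and 3,000 generations ago, 20,000 since."""
    hist = PopulationHistory(
        name="pop0",
        epochs=((0.0, 20_000.0, 0.0), (3_000.0, 2_000.0, 0.0), (3_500.0, 10_000.0, 0.0)),
    )
    return DemographyModel(populations=(hist,), name="single_pop_three_epoch")


# Gravel et al. three-population inference (exon + low-coverage data),
# 25 years per generation.
_GRAVEL = dict(
    N_A=7_310.0,
    N_AF=14_474.0,
    N_B=1_861.0,
    N_EU0=1_032.0,
    N_AS0=554.0,
    r_EU=0.0038,
    r_AS=0.0048,
    T_AF=148_000.0 / 25,  # 5920 generations
    T_B=51_000.0 / 25,  # 2040
    T_EU_AS=23_000.0 / 25,  # 920
    m_AF_B=15e-5,
    m_AF_EU=2.5e-5,
    m_AF_AS=0.78e-5,
    m_EU_AS=3.11e-5,
)


def build_three_pop_demography() -> DemographyModel:
    """Gravel et al. YRI/CEU/CHB out-of-Africa model with migration."""
    g = _GRAVEL
    n_eu_now = g["N_EU0"] * math.exp(g["r_EU"] * g["T_EU_AS"])
    n_as_now = g["N_AS0"] * math.exp(g["r_AS"] * g["T_EU_AS"])
    yri = PopulationHistory(
        "YRI", ((0.0, g["N_AF"], 0.0), (g["T_AF"], g["N_A"], 0.0))
    )
    ceu = PopulationHistory(
        "CEU",
        (
            (0.0, n_eu_now, g["r_EU"]),
            (g["T_EU_AS"], g["N_B"], 0.0),
            (g["T_B"], g["N_AF"], 0.0),
            (g["T_AF"], g["N_A"], 0.0),
        ),
    )
    chb = PopulationHistory(
        "CHB",
        (
            (0.0, n_as_now, g["r_AS"]),
            (g["T_EU_AS"], g["N_B"], 0.0),
            (g["T_B"], g["N_AF"], 0.0),
            (g["T_AF"], g["N_A"], 0.0),
        ),
    )
    mig = np.array(
        [
            [0.0, g["m_AF_EU"], g["m_AF_AS"]],
            [g["m_AF_EU"], 0.0, g["m_EU_AS"]],
            [g["m_AF_AS"], g["m_EU_AS"], 0.0],
        ]
    )
    return DemographyModel(
        populations=(yri, ceu, chb),
        migration=mig,
        generation_time_years=25.0,
        name="gravel_three_pop",
    )


def _gravel_msprime() -> msprime.Demography:
    g = _GRAVEL
    dem = msprime.Demography()
    dem.add_population(name="YRI", initial_size=g["N_AF"])
    dem.add_population(
        name="CEU",
        initial_size=g["N_EU0"] * math.exp(g["r_EU"] * g["T_EU_AS"]),
        growth_rate=g["r_EU"],
    )
    dem.add_population(
        name="CHB",
        initial_size=g["N_AS0"] * math.exp(g["r_AS"] * g["T_EU_AS"]),
        growth_rate=g["r_AS"],
    )
    dem.add_population(name="OOA", initial_size=g["N_B"])
    dem.add_population(name="AMH", initial_size=g["N_AF"])
    dem.add_population(name="ANC", initial_size=g["N_A"])
    dem.set_symmetric_migration_rate(["YRI", "CEU"], g["m_AF_EU"])
    dem.set_symmetric_migration_rate(["YRI", "CHB"], g["m_AF_AS"])
    dem.set_symmetric_migration_rate(["CEU", "CHB"], g["m_EU_AS"])
    dem.add_population_split(time=g["T_EU_AS"], derived=["CEU", "CHB"], ancestral="OOA")
    dem.add_symmetric_migration_rate_change(
        time=g["T_EU_AS"], populations=["YRI", "OOA"], rate=g["m_AF_B"]
    )
    dem.add_population_split(time=g["T_B"], derived=["YRI", "OOA"], ancestral="AMH")
    dem.add_population_split(time=g["T_AF"], derived=["AMH"], ancestral="ANC")
    dem.sort_events()
    return dem


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _sample_spec(region: SimRegionParams, population: str):
    n_ind = (region.n_haplotypes + 1) // 2
    return {population: n_ind}


def _ts_to_matrix(ts, region: SimRegionParams, label: str, provenance: dict) -> HaplotypeMatrix:
    alleles = ts.genotype_matrix().T.astype(np.uint8)
    alleles = alleles[: region.n_haplotypes]
    positions = ts.tables.sites.position.copy()
    # drop columns fixed within the retained sample (possible after trimming
    # an odd-sized sample from diploid individuals)
    counts = alleles.sum(axis=0)
    seg = (counts > 0) & (counts < alleles.shape[0])
    if not seg.all():
        alleles = alleles[:, seg]
        positions = positions[seg]
    return HaplotypeMatrix(alleles=alleles, positions=positions, label=label, provenance=provenance)


def simulate_neutral(
    dem: DemographyModel,
    region: SimRegionParams,
    population: str | None = None,
) -> HaplotypeMatrix:
    """Simulate a neutral sample of ``region.n_haplotypes`` haplotypes.

    Deterministic given ``region.seed``; only segregating sites are emitted,
    coded ancestral (0) / derived (1).
    """
    population = population or dem.population_names[0]
    anc_seed, mut_seed = _derive_seeds(region.seed, 2)
    ts = msprime.sim_ancestry(
        samples=_sample_spec(region, population),
        ploidy=2,
        demography=dem.to_msprime(),
        sequence_length=region.sequence_length_bp,
        recombination_rate=region.recombination_rate_per_bp_per_gen,
        discrete_genome=False,
        random_seed=anc_seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=region.mutation_rate_per_bp_per_gen,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=mut_seed,
    )
    prov = {
        "engine": ENGINE,
        "model": dem.name,
        "population": population,
        "region": dataclasses.asdict(region),
        "rescaling": 1.0,
    }
    return _ts_to_matrix(ts, region, "neutral", prov)


def wf_trajectory_end_frequency(
    rng: np.random.Generator,
    sweep: SweepParams,
    n_effective: float,
) -> tuple[float, int]:
    """Terminal allele frequency of a forward Wright-Fisher sweep trajectory.

    Runs ``start_time_generations`` generations of binomial sampling with
    genotype fitnesses (1, 1+s_het, 1+s_hom) from ``start_frequency``,
    retrying (up to ``max_retries``) until the allele survives to sampling
    time.  Returns the surviving frequency and the number of attempts.
    """
    two_n = max(int(round(2 * n_effective)), 2)
    s_het, s_hom = sweep.s_het, sweep.s_hom
    n_gen = int(round(sweep.start_time_generations))
    for attempt in range(1, sweep.max_retries + 1):
        x = sweep.start_frequency
        for _ in range(n_gen):
            w_bar = 1 + 2 * x * (1 - x) * s_het + x * x * s_hom
            x = (x * (1 - x) * (1 + s_het) + x * x * (1 + s_hom)) / w_bar
            x = rng.binomial(two_n, min(x, 1.0)) / two_n
            if x == 0.0:
                break
        if x > 0.0:
            return min(x, 1 - 1 / two_n), attempt
    raise SimulationError(
        f"beneficial allele lost in all {sweep.max_retries} trajectory attempts"
    )


def simulate_sweep(
    dem: DemographyModel,
    region: SimRegionParams,
    sweep: SweepParams,
) -> HaplotypeMatrix:
    """Simulate a sample whose genealogy carries a hard sweep.

    The sweep sits at ``position_fraction`` of the region; the genealogy is
    distorted by msprime's structured-coalescent sweep phase between the
    onset frequency and the (conditioned, stochastic) terminal frequency.
    For multi-population models the target population's collapsed size
    history is used during the sweep (see :meth:`DemographyModel.collapsed`).
    """
    population = sweep.target_population or dem.population_names[0]
    sweep_dem = dem if len(dem.populations) == 1 else dem.collapsed(population)
    sweep_pop = sweep_dem.population_names[0]
    n_now = sweep_dem.size_at(0.0)

    traj_seed, *_ = _derive_seeds(region.seed, 1, salt=7)
    rng = np.random.default_rng(traj_seed)
    x_end, attempts = wf_trajectory_end_frequency(rng, sweep, n_now)

    prov = {
        "engine": ENGINE,
        "model": dem.name,
        "population": population,
        "region": dataclasses.asdict(region),
        "sweep": dataclasses.asdict(sweep),
        "end_frequency": x_end,
        "trajectory_attempts": attempts,
        "rescaling": 1.0,
    }

    if x_end <= sweep.start_frequency:
        # The allele survived but drifted at/below its onset frequency: the
        # sweep phase left no genealogical footprint; genealogy is neutral.
        out = simulate_neutral(sweep_dem, region, population=sweep_pop)
        out.label = "sweep"
        prov["degenerate_trajectory"] = True
        out.provenance = prov
        return out

    position = sweep.position_fraction * region.sequence_length_bp
    position = min(max(position, 1e-9), region.sequence_length_bp - 1e-9)
    model = msprime.SweepGenicSelection(
        position=position,
        start_frequency=sweep.start_frequency,
        end_frequency=x_end,
        s=sweep.s_hom,
        dt=1 / (40 * n_now),
    )
    last_err: Exception | None = None
    for attempt in range(1, sweep.max_retries + 1):
        anc_seed, mut_seed = _derive_seeds(region.seed, 2, salt=11 + attempt)
        try:
            ts = msprime.sim_ancestry(
                samples=_sample_spec(region, sweep_pop),
                ploidy=2,
                demography=sweep_dem.to_msprime(),
                sequence_length=region.sequence_length_bp,
                recombination_rate=region.recombination_rate_per_bp_per_gen,
                discrete_genome=False,
                model=[model, msprime.StandardCoalescent()],
                random_seed=anc_seed,
            )
        except Exception as err:  # rare numerical failures in the sweep phase
            last_err = err
            continue
        ts = msprime.sim_mutations(
            ts,
            rate=region.mutation_rate_per_bp_per_gen,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            random_seed=mut_seed,
        )
        prov["coalescent_attempts"] = attempt
        return _ts_to_matrix(ts, region, "sweep", prov)
    raise SimulationError(
        f"sweep coalescent failed after {sweep.max_retries} retries: {last_err}"
    )


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def _derive_seeds(seed: int, n: int, salt: int = 0) -> list[int]:
    ss = np.random.SeedSequence([int(seed), int(salt)])
    return [int(s % (2**31 - 2)) + 1 for s in ss.generate_state(n, dtype=np.uint64)]


def generate_dataset(
    dem: DemographyModel,
    region: SimRegionParams,
    sweep: SweepParams,
    n_per_class: int,
    split_fractions: Sequence[float] = (0.8, 0.1, 0.1),
    seed: int = 1,
    progress: bool = False,
) -> LabeledDataset:
    """Simulate a balanced neutral/sweep dataset with stratified splits.

    Every split holds equal class counts; splits are disjoint and the whole
    procedure is deterministic given ``seed``.
    """
    if n_per_class < 10:
        raise ParameterError("n_per_class must be at least 10")
    fr = np.asarray(split_fractions, dtype=float)
    if fr.size != 3 or not math.isclose(fr.sum(), 1.0, abs_tol=1e-9) or (fr < 0).any():
        raise ParameterError("split fractions must be three non-negative values summing to 1")

    sim_seeds = _derive_seeds(seed, 2 * n_per_class, salt=1)
    samples: list[HaplotypeMatrix] = []
    labels = np.zeros(2 * n_per_class, dtype=np.int64)
    iterator = range(n_per_class)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm  # type: ignore

        iterator = tqdm(iterator, desc="simulating")
    for i in iterator:
        r_neu = dataclasses.replace(region, seed=sim_seeds[2 * i])
        r_swp = dataclasses.replace(region, seed=sim_seeds[2 * i + 1])
        samples.append(simulate_neutral(dem, r_neu, population=sweep.target_population))
        samples.append(simulate_sweep(dem, r_swp, sweep))
        labels[2 * i + 1] = 1

    rng = np.random.default_rng(_derive_seeds(seed, 1, salt=2)[0])
    splits: dict[str, np.ndarray] = {"train": [], "val": [], "test": []}
    counts = _split_counts(n_per_class, fr)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        start = 0
        for split_name, k in zip(("train", "val", "test"), counts):
            splits[split_name].append(idx[start : start + k])
            start += k
    split_arrays = {
        k: np.sort(np.concatenate(v)) for k, v in splits.items()
    }
    metadata = {
        "engine": ENGINE,
        "demography": dem.name,
        "region": dataclasses.asdict(region),
        "sweep": dataclasses.asdict(sweep),
        "n_per_class": n_per_class,
        "split_fractions": list(map(float, fr)),
        "seed": int(seed),
        "rescaling": 1.0,
    }
    return LabeledDataset(samples=samples, labels=labels, splits=split_arrays, metadata=metadata)


def _split_counts(n_per_class: int, fractions: np.ndarray) -> list[int]:
    counts = [int(math.floor(n_per_class * f)) for f in fractions]
    counts[0] += n_per_class - sum(counts)  # remainder to the training split
    return counts


# ---------------------------------------------------------------------------
# Dataset archive (JSON metadata + per-split arrays)
# ---------------------------------------------------------------------------


def save_dataset(ds: LabeledDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = dict(ds.metadata)
    meta["n_samples"] = len(ds.samples)
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    arrays: dict[str, np.ndarray] = {"labels": ds.labels}
    for name, idx in ds.splits.items():
        arrays[f"split_{name}"] = idx
    for i, m in enumerate(ds.samples):
        arrays[f"alleles_{i}"] = m.alleles
        arrays[f"positions_{i}"] = m.positions
    np.savez_compressed(directory / "arrays.npz", **arrays)
    return directory


def load_dataset(directory: str | Path) -> LabeledDataset:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    with np.load(directory / "arrays.npz") as data:
        labels = data["labels"]
        splits = {
            k[len("split_") :]: data[k] for k in data.files if k.startswith("split_")
        }
        samples = []
        for i in range(meta["n_samples"]):
            samples.append(
                HaplotypeMatrix(
                    alleles=data[f"alleles_{i}"],
                    positions=data[f"positions_{i}"],
                    label="sweep" if labels[i] else "neutral",
                )
            )
    return LabeledDataset(samples=samples, labels=labels, splits=splits, metadata=meta)
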