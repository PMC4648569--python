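"""The daily movement/oviposition engine and the generational loop.

A simulation starts from founding females placed on random native-host
cells, runs a 54-day flight season per generation (movement, oviposition,
phenology, lifespan), applies host-dependent egg-to-adult survival, adds
female immigrants in proportion to the surviving population, and censuses
the number of emerging females N_t and the acceptance-allele frequency p_t
at each adult emergence.  The summary rates are the geometric means of
successive ratios: R for population size, G for allele frequency.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .genetics import (ACCEPT, REJECT, AlleleFrequencies, Genotype, Sex,
                       allele_frequencies_from_arrays)
from .landscape import GridMap, PhenologyCalendar, Species
from .life_history import (LifeHistoryParams, build_emergence_schedule,
                           daily_egg_load, egg_load_table, sample_daily_flight_distance,
                           sample_lifespan)

__all__ = [
    "Butterfly", "Egg", "EggBatch", "Cohort", "SimConfig", "Trajectory",
    "fly_one_day", "run_flight_season", "advance_generation",
    "run_simulation", "geometric_rate", "extinction_generation",
]


@dataclass
class Butterfly:
    """One adult female agent."""

    id: int
    genotype: Genotype
    mate: Genotype
    natal_cell: tuple[int, int]
    emergence_day: int
    lifespan: int
    age: int = 0
    position: tuple[float, float] = (0.0, 0.0)
    eggs_laid_today: int = 0
    distance_flown_today: float = 0.0
    alive: bool = True

    def __post_init__(self):
        if self.genotype.sex != Sex.FEMALE:
            raise ValueError("simulated agents are females")
        if self.mate is not None and self.mate.sex != Sex.MALE:
            raise ValueError("mate must be a male genotype")


@dataclass
class Egg:
    cell: tuple[int, int]
    host_species: Species
    sex: Sex
    genotype: Genotype
    day_laid: int


@dataclass
class EggBatch:
    """Vectorised container for a season's eggs (structure-of-arrays)."""

    row: np.ndarray
    col: np.ndarray
    day: np.ndarray
    sex: np.ndarray          # 1 = female, 0 = male
    z_paternal: np.ndarray   # allele transmitted by the father
    z_maternal: np.ndarray   # the mother's allele (used by sons)
    on_thlaspi: np.ndarray

    def __len__(self) -> int:
        return int(self.row.shape[0])

    @property
    def n_native(self) -> int:
        return int((~self.on_thlaspi).sum())

    @property
    def n_thlaspi(self) -> int:
        return int(self.on_thlaspi.sum())

    @classmethod
    def empty(cls) -> "EggBatch":
        z = np.empty(0, dtype=np.uint8)
        return cls(np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int32),
                   np.empty(0, dtype=np.int16), z.copy(), z.copy(), z.copy(),
                   np.empty(0, dtype=bool))

    def to_list(self, gmap: GridMap) -> list[Egg]:
        eggs = []
        for i in range(len(self)):
            r, c = int(self.row[i]), int(self.col[i])
            sex = Sex.FEMALE if self.sex[i] else Sex.MALE
            if sex == Sex.FEMALE:
                g = Genotype.female(int(self.z_paternal[i]))
            else:
                g = Genotype.male(int(self.z_paternal[i]), int(self.z_maternal[i]))
            eggs.append(Egg((r, c), Species(int(gmap.host[r, c])), sex, g,
                            int(self.day[i])))
        return eggs


@dataclass
class Cohort:
    """A generation's emerging females (structure-of-arrays) plus the male
    pool they mate from."""

    natal_r: np.ndarray
    natal_c: np.ndarray
    z: np.ndarray            # each female's single Z allele
    fa1: np.ndarray          # her mate's two alleles
    fa2: np.ndarray
    has_mate: np.ndarray
    emergence_day: np.ndarray
    lifespan: np.ndarray
    x: np.ndarray
    y: np.ndarray
    male_pool: np.ndarray    # (m, 2) allele pairs of surviving males

    @property
    def n(self) -> int:
        return int(self.z.shape[0])

    @classmethod
    def empty(cls) -> "Cohort":
        u8 = np.empty(0, dtype=np.uint8)
        i32 = np.empty(0, dtype=np.int32)
        f8 = np.empty(0, dtype=np.float64)
        return cls(i32.copy(), i32.copy(), u8.copy(), u8.copy(), u8.copy(),
                   np.empty(0, dtype=bool), i32.copy(), i32.copy(),
                   f8.copy(), f8.copy(), np.empty((0, 2), dtype=np.uint8))

    @classmethod
    def from_butterflies(cls, adults: list[Butterfly], gmap: GridMap) -> "Cohort":
        n = len(adults)
        c = cls.empty()
        if n == 0:
            return c
        c.natal_r = np.array([b.natal_cell[0] for b in adults], dtype=np.int32)
        c.natal_c = np.array([b.natal_cell[1] for b in adults], dtype=np.int32)
        c.z = np.array([b.genotype.z1 for b in adults], dtype=np.uint8)
        c.fa1 = np.array([b.mate.z1 for b in adults], dtype=np.uint8)
        c.fa2 = np.array([b.mate.z2 for b in adults], dtype=np.uint8)
        c.has_mate = np.ones(n, dtype=bool)
        c.emergence_day = np.array([b.emergence_day for b in adults], dtype=np.int32)
        c.lifespan = np.array([b.lifespan for b in adults], dtype=np.int32)
        xy = [gmap.cell_center(*b.natal_cell) for b in adults]
        c.x = np.array([p[0] for p in xy], dtype=np.float64)
        c.y = np.array([p[1] for p in xy], dtype=np.float64)
        c.male_pool = np.array([[b.mate.z1, b.mate.z2] for b in adults], dtype=np.uint8)
        return c


@dataclass
class SimConfig:
    params: LifeHistoryParams = field(default_factory=LifeHistoryParams)
    initial_females: int = 150
    p0: float = 0.5
    generations: int = 100
    replicates: int = 50
    seed: int = 0
    #: 'focal' ties immigrant allele frequency to the focal population's
    #: current frequency; a float fixes the source-pool frequency.
    immigrant_p: object = "focal"

    def __post_init__(self):
        if self.initial_females <= 0:
            raise ValueError("initial_females must be positive")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if self.generations < 0 or self.replicates <= 0:
            raise ValueError("generations must be >= 0 and replicates positive")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class Trajectory:
    """Per-generation census series of one simulation run."""

    N: np.ndarray
    p_pop: np.ndarray
    p_female: np.ndarray
    p_male: np.ndarray
    eggs_native: np.ndarray
    eggs_thlaspi: np.ndarray
    extinct_at: int | None = None

    @property
    def generations(self) -> int:
        return len(self.N) - 1

    @property
    def R(self) -> float:
        return geometric_rate(self.N)

    @property
    def G(self) -> float:
        return geometric_rate(self.p_pop)

    def to_dataframe(self) -> pd.DataFrame:
        t = np.arange(len(self.N))
        eggs_n = np.full(len(self.N), np.nan)
        eggs_t = np.full(len(self.N), np.nan)
        eggs_n[1:1 + len(self.eggs_native)] = self.eggs_native
        eggs_t[1:1 + len(self.eggs_thlaspi)] = self.eggs_thlaspi
        return pd.DataFrame({
            "generation": t, "N": self.N, "p_pop": self.p_pop,
            "p_female": self.p_female, "p_male": self.p_male,
            "eggs_native": eggs_n, "eggs_thlaspi": eggs_t,
        })


# ---------------------------------------------------------------------------
# Flight season
# ---------------------------------------------------------------------------

def _season_arrays(gmap: GridMap, cal: PhenologyCalendar):
    avail3 = cal.available_masks(gmap)
    is_thl = gmap.thlaspi_mask
    return avail3, is_thl


def fly_one_day(b: Butterfly, gmap: GridMap, day: int, cal: PhenologyCalendar,
                params: LifeHistoryParams, rng) -> list[Egg]:
    """One day of flight and oviposition for a single female; returns the
    eggs she laid and updates her position and daily counters in place."""
    rng = np.random.default_rng(rng)
    if not 1 <= day <= params.season_length:
        raise ValueError("day outside the flight season")
    if day < b.emergence_day:
        raise ValueError("female has not emerged yet")
    age = day - b.emergence_day + 1
    if age > b.lifespan:
        raise ValueError("female has exceeded her lifespan")
    if b.mate is None:
        raise ValueError("an unmated female does not oviposit")
    b.age = age
    budget = sample_daily_flight_distance(params, rng)
    load = daily_egg_load(age, params)
    b.eggs_laid_today = 0
    b.distance_flown_today = 0.0
    if load == 0:
        return []
    avail3, is_thl = _season_arrays(gmap, cal)
    tri = cal.trimester(day)
    egg_r = np.empty(load, dtype=np.int32)
    egg_c = np.empty(load, dtype=np.int32)
    egg_sex = np.empty(load, dtype=np.uint8)
    egg_z1 = np.empty(load, dtype=np.uint8)
    egg_z2 = np.empty(load, dtype=np.uint8)
    egg_thl = np.empty(load, dtype=bool)
    _kernels.seed_kernel_rng(int(rng.integers(2**31)))
    cs = gmap.cell_size
    x, y, laid, dist = _kernels.fly_day(
        float(b.position[0]), float(b.position[1]), avail3[tri - 1], is_thl,
        gmap.aridity, bool(b.genotype.z1 == ACCEPT),
        np.uint8(b.mate.z1), np.uint8(b.mate.z2), np.uint8(b.genotype.z1),
        int(load), float(budget), params.ovi_prob,
        params.step_wet * cs, params.step_intermediate * cs,
        params.step_dry * cs, params.step_on_host * cs, cs,
        egg_r, egg_c, egg_sex, egg_z1, egg_z2, egg_thl, 0)
    b.position = (x, y)
    b.eggs_laid_today = laid
    b.distance_flown_today = dist
    batch = EggBatch(egg_r[:laid], egg_c[:laid],
                     np.full(laid, day, dtype=np.int16), egg_sex[:laid],
                     egg_z1[:laid], egg_z2[:laid], egg_thl[:laid])
    return batch.to_list(gmap)


def run_flight_season(adults, gmap: GridMap, cal: PhenologyCalendar,
                      params: LifeHistoryParams, rng) -> EggBatch:
    """A whole cohort's flight season; returns every egg laid, day-stamped.

    ``adults`` is a :class:`Cohort` (or a list of :class:`Butterfly`, which
    is converted).  Positions are advanced in place across days; unmated
    females stay inactive.
    """
    rng = np.random.default_rng(rng)
    if isinstance(adults, list):
        adults = Cohort.from_butterflies(adults, gmap)
    n = adults.n
    if n == 0:
        return EggBatch.empty()
    sl = params.season_length
    budgets = sample_daily_flight_distance(params, rng, size=(n, sl))
    load_table = egg_load_table(params, sl)
    cum = np.concatenate([[0], np.cumsum(load_table[1:])])
    active_days = np.minimum(adults.lifespan, sl - adults.emergence_day + 1)
    active_days = np.clip(active_days, 0, sl)
    capacity = int(cum[active_days[adults.has_mate]].sum())
    if capacity == 0:
        return EggBatch.empty()
    egg_r = np.empty(capacity, dtype=np.int32)
    egg_c = np.empty(capacity, dtype=np.int32)
    egg_day = np.empty(capacity, dtype=np.int16)
    egg_sex = np.empty(capacity, dtype=np.uint8)
    egg_z1 = np.empty(capacity, dtype=np.uint8)
    egg_z2 = np.empty(capacity, dtype=np.uint8)
    egg_thl = np.empty(capacity, dtype=bool)
    avail3, is_thl = _season_arrays(gmap, cal)
    cs = gmap.cell_size
    seed = int(rng.integers(2**31))
    n_eggs = _kernels.run_season(
        avail3, is_thl, gmap.aridity,
        adults.emergence_day.astype(np.int64), adults.lifespan.astype(np.int64),
        np.asarray(budgets, dtype=np.float64), load_table,
        adults.x, adults.y, (adults.z == ACCEPT),
        adults.fa1, adults.fa2, adults.z, adults.has_mate,
        params.ovi_prob, params.step_wet * cs, params.step_intermediate * cs,
        params.step_dry * cs, params.step_on_host * cs, cs, sl, seed,
        egg_r, egg_c, egg_day, egg_sex, egg_z1, egg_z2, egg_thl)
    return EggBatch(egg_r[:n_eggs].copy(), egg_c[:n_eggs].copy(),
                    egg_day[:n_eggs].copy(), egg_sex[:n_eggs].copy(),
                    egg_z1[:n_eggs].copy(), egg_z2[:n_eggs].copy(),
                    egg_thl[:n_eggs].copy())


# ---------------------------------------------------------------------------
# Generation turnover
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Cross-generation context needed to build the next cohort."""

    gmap: GridMap
    native_cells: np.ndarray          # (k, 2) cells occupied by native hosts
    immigrant_p: object = "focal"     # 'focal' or a fixed source frequency
    focal_p: float = 0.5              # last census p (fallback for 'focal')

    @classmethod
    def from_map(cls, gmap: GridMap, immigrant_p="focal", focal_p=0.5) -> "SimState":
        cells = np.argwhere(gmap.native_mask)
        return cls(gmap, cells.astype(np.int32), immigrant_p, focal_p)


def _assign_emergence(n, params, rng):
    counts = build_emergence_schedule(n, params, rng)
    days = np.repeat(np.arange(1, params.season_length + 1, dtype=np.int32), counts)
    rng.shuffle(days)
    return days


def advance_generation(eggs: EggBatch, state: SimState,
                       params: LifeHistoryParams, rng) -> Cohort:
    """Egg-to-adult survival, immigration, mate assignment and scheduling.

    Survival is Bernoulli per egg (native-host eggs only; eggs on the
    non-native host never survive).  Surviving females become the next
    cohort, starting from their natal cells; surviving males form the mating
    pool.  Female immigrants arrive in proportion to the surviving female
    count (stochastic rounding), start on random native-host cells, and carry
    genotypes at the immigrant-source frequency; having mated outside the
    focal habitat, their mates are drawn at Hardy-Weinberg proportions at
    that same frequency.
    """
    rng = np.random.default_rng(rng)
    n_eggs = len(eggs)
    if n_eggs:
        u = rng.random(n_eggs)
        p_egg = np.where(eggs.on_thlaspi, params.juvenile_survival_thlaspi,
                         params.juvenile_survival_native)
        alive = u < p_egg
    else:
        alive = np.zeros(0, dtype=bool)

    fem = alive & (eggs.sex == 1)
    mal = alive & (eggs.sex == 0)
    male_pool = np.stack([eggs.z_paternal[mal], eggs.z_maternal[mal]],
                         axis=1).astype(np.uint8)
    n_f = int(fem.sum())
    n_m = male_pool.shape[0]

    # immigrant-source allele frequency
    if state.immigrant_p == "focal":
        z_sum = float(eggs.z_paternal[fem].sum()) + float(male_pool.sum())
        z_tot = n_f + 2 * n_m
        p_imm = z_sum / z_tot if z_tot else state.focal_p
    else:
        p_imm = float(state.immigrant_p)

    # stochastic rounding of the proportional immigrant count
    x = params.immigration_rate * n_f
    n_imm = int(x) + (1 if rng.random() < x - int(x) else 0)

    natal_r = eggs.row[fem].astype(np.int32)
    natal_c = eggs.col[fem].astype(np.int32)
    z = eggs.z_paternal[fem].astype(np.uint8)
    if n_m > 0:
        idx = rng.integers(0, n_m, n_f)
        fa1 = male_pool[idx, 0].copy()
        fa2 = male_pool[idx, 1].copy()
        has_mate = np.ones(n_f, dtype=bool)
    else:
        fa1 = np.zeros(n_f, dtype=np.uint8)
        fa2 = np.zeros(n_f, dtype=np.uint8)
        has_mate = np.zeros(n_f, dtype=bool)

    if n_imm > 0:
        cells = state.native_cells[rng.integers(0, len(state.native_cells), n_imm)]
        natal_r = np.concatenate([natal_r, cells[:, 0].astype(np.int32)])
        natal_c = np.concatenate([natal_c, cells[:, 1].astype(np.int32)])
        z = np.concatenate([z, (rng.random(n_imm) < p_imm).astype(np.uint8)])
        ia = (rng.random(n_imm) < p_imm).astype(np.uint8)
        ib = (rng.random(n_imm) < p_imm).astype(np.uint8)
        fa1 = np.concatenate([fa1, np.minimum(ia, ib)])
        fa2 = np.concatenate([fa2, np.maximum(ia, ib)])
        has_mate = np.concatenate([has_mate, np.ones(n_imm, dtype=bool)])

    n_total = n_f + n_imm
    cohort = Cohort.empty()
    if n_total == 0:
        return cohort
    cohort.natal_r, cohort.natal_c = natal_r, natal_c
    cohort.z, cohort.fa1, cohort.fa2, cohort.has_mate = z, fa1, fa2, has_mate
    cohort.emergence_day = _assign_emergence(n_total, params, rng)
    cohort.lifespan = sample_lifespan(params, rng, size=n_total).astype(np.int32)
    cs = state.gmap.cell_size
    cohort.x = (natal_c + 0.5) * cs
    cohort.y = (natal_r + 0.5) * cs
    cohort.male_pool = male_pool
    return cohort


# ---------------------------------------------------------------------------
# Whole simulation
# ---------------------------------------------------------------------------

def _founding_cohort(gmap, native_cells, config, params, rng) -> Cohort:
    n0 = config.initial_females
    cells = native_cells[rng.integers(0, len(native_cells), n0)]
    c = Cohort.empty()
    c.natal_r = cells[:, 0].astype(np.int32)
    c.natal_c = cells[:, 1].astype(np.int32)
    c.z = (rng.random(n0) < config.p0).astype(np.uint8)
    a = (rng.random(n0) < config.p0).astype(np.uint8)
    b = (rng.random(n0) < config.p0).astype(np.uint8)
    c.fa1, c.fa2 = np.minimum(a, b), np.maximum(a, b)
    c.has_mate = np.ones(n0, dtype=bool)
    c.emergence_day = _assign_emergence(n0, params, rng)
    c.lifespan = sample_lifespan(params, rng, size=n0).astype(np.int32)
    cs = gmap.cell_size
    c.x = (c.natal_c + 0.5) * cs
    c.y = (c.natal_r + 0.5) * cs
    c.male_pool = np.stack([c.fa1, c.fa2], axis=1).astype(np.uint8)
    return c


def _census(cohort: Cohort) -> AlleleFrequencies:
    return allele_frequencies_from_arrays(
        cohort.z.astype(np.float64),
        cohort.male_pool.astype(np.float64).reshape(-1, 2))


def run_simulation(gmap: GridMap, config: SimConfig,
                   cal: PhenologyCalendar | None = None) -> Trajectory:
    """Run one replicate: the generational loop of flight season, survival
    and immigration, recording N_t and p_t at each emergence census."""
    cal = cal or PhenologyCalendar(season_length=config.params.season_length)
    rng = np.random.default_rng(config.seed)
    native_cells = np.argwhere(gmap.native_mask).astype(np.int32)
    if len(native_cells) == 0:
        raise ValueError("map has no native host cells; the population "
                         "cannot be seeded")
    params = config.params
    state = SimState(gmap, native_cells, config.immigrant_p, config.p0)

    cohort = _founding_cohort(gmap, native_cells, config, params, rng)
    freqs = _census(cohort)
    N = [cohort.n]
    p_pop, p_f, p_m = [freqs.p_pop], [freqs.p_female], [freqs.p_male]
    eggs_native, eggs_thlaspi = [], []
    extinct_at = None

    for gen in range(1, config.generations + 1):
        eggs = run_flight_season(cohort, gmap, cal, params, rng)
        eggs_native.append(eggs.n_native)
        eggs_thlaspi.append(eggs.n_thlaspi)
        cohort = advance_generation(eggs, state, params, rng)
        if cohort.n == 0:
            extinct_at = gen
            N.append(0)
            p_pop.append(math.nan)
            p_f.append(math.nan)
            p_m.append(math.nan)
            break
        freqs = _census(cohort)
        # pooled frequency falls back to the female side if no males survived
        pp = freqs.p_pop if not math.isnan(freqs.p_male) else freqs.p_female
        state.focal_p = pp
        N.append(cohort.n)
        p_pop.append(pp)
        p_f.append(freqs.p_female)
        p_m.append(freqs.p_male)

    return Trajectory(
        N=np.array(N, dtype=np.int64),
        p_pop=np.array(p_pop, dtype=np.float64),
        p_female=np.array(p_f, dtype=np.float64),
        p_male=np.array(p_m, dtype=np.float64),
        eggs_native=np.array(eggs_native, dtype=np.int64),
        eggs_thlaspi=np.array(eggs_thlaspi, dtype=np.int64),
        extinct_at=extinct_at,
    )


# ---------------------------------------------------------------------------
# Summary rates
# ---------------------------------------------------------------------------

def geometric_rate(series) -> float:
    """Geometric mean of successive ratios of a positive series, equal to
    (last/first)^(1/(len-1)).  The series is truncated at its first
    non-positive or undefined entry; fewer than two valid entries give NaN.
    """
    s = np.asarray(series, dtype=np.float64)
    valid = np.isfinite(s) & (s > 0)
    stop = int(np.argmin(valid)) if not valid.all() else len(s)
    s = s[:stop]
    if len(s) < 2:
        return math.nan
    return float((s[-1] / s[0]) ** (1.0 / (len(s) - 1)))


def extinction_generation(n0: int, r: float):
    """Smallest generation t at which n0 * r^t drops below one individual.

    Defined only for a declining population (0 < r < 1); a non-declining
    rate returns None (the deterministic projection never goes extinct).
    """
    if n0 < 1:
        raise ValueError("n0 must be at least 1")
    if r <= 0:
        raise ValueError("r must be positive")
    if r >= 1:
        return None
    t = math.ceil(math.log(n0) / -math.log(r))
    while n0 * r**t >= 1.0:
        t += 1
    while t > 0 and n0 * r ** (t - 1) < 1.0:
        t -= 1
    return t
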