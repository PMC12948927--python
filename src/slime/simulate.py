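"""Synthetic multi-experiment ASV time series with engineered structure.

The generator emulates the statistical features the downstream analysis
relies on, for a batch high-pressure-reactor study of H2 injection into
deep-aquifer communities:

* several experiments sampled on a day grid centered on the first H2
  injection (day 0), with per-sample ASV richness in a realistic range;
* partially overlapping ASV pools: designated experiments share a
  persistent "core" of ASVs (a common ranked pool; each sample holds a
  prefix of the ranking, so the same core members co-occur across
  experiments), while other experiments assemble independently from the
  global pool;
* an injection response applied to presence and abundance independently:
  fermenter-guild ASVs are excluded with a configurable probability
  (presence effect) and sulfate-reducer/methanogen ASVs have their
  abundance weights multiplied by a boost factor (abundance effect);
* water refills that lift the richness suppression (recovery of
  diversity), and a small per-ASV turnover between successive samples so
  that within-experiment beta diversity stays far below the null;
* log-normal abundance weights resampled multinomially to a fixed depth,
  producing realistic dominance curves.

The community model is presence-first: a per-experiment presence chain is
evolved through time, then counts are drawn conditional on presence
(every present ASV receives at least one read, so realized richness is
exactly the chain's richness and per-sample depth is exact).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_rng
from .beta import pair_label
from .guilds import GUILDS, load_guild_table
from .io import (
    CommunityTable,
    DataError,
    ExperimentDesign,
    write_events,
    write_feature_table,
    write_metadata,
    write_taxonomy,
)

__all__ = ["SimConfig", "SyntheticDataset", "simulate_dataset", "write_dataset",
           "default_designs", "GENUS_BY_GUILD"]

# genera available per guild for synthetic taxonomy (all present in the
# packaged guild table, so synthetic ASVs are annotatable by default)
GENUS_BY_GUILD: dict[str, tuple[str, ...]] = {
    "fermentation": (
        "Rectinema", "Caldicoprobacter", "Pelotomaculum", "Tepidanaerobacter",
        "Anaerovorax", "Macellibacteroides", "Proteiniphilum",
    ),
    "sulfate_reduction": (
        "Thermodesulfovibrio", "Desulfotomaculum", "Desulfocucumis",
        "Desulfofarcimen", "Desulfocurvus", "Desulfolutivibrio",
    ),
    "wood_ljungdahl": ("Acetobacterium", "Moorella"),
    "methanogenesis": ("Methanothermobacter", "Methanobacterium"),
}

HYDROGENOTROPH_GUILDS = ("sulfate_reduction", "methanogenesis")

_DEFAULT_SAMPLING = (-29, -15, -1, 3, 8, 14, 28, 42, 56)

# five-experiment default design: experiments 1 and 2 receive one 10% H2
# injection, 3 and 5 three 2% injections, 4 one 2% injection; water refills
# on the 31st, 9th, 6th and 7th day after injection for experiments 1, 3,
# 4 and 5.
_DEFAULT_INJECTIONS = ((0,), (0,), (0, 35, 70), (0,), (0, 35, 70))
_DEFAULT_REFILLS = ((31,), (), (9,), (6,), (7,))
_DEFAULT_H2 = (10.0, 10.0, 2.0, 2.0, 2.0)


def _per_experiment(value, n: int, name: str):
    """Broadcast a single sequence or return a length-n tuple of sequences."""
    value = tuple(value)
    if len(value) and not isinstance(value[0], (list, tuple)):
        return tuple(tuple(value) for _ in range(n))
    if len(value) != n:
        raise DataError(f"{name}: expected {n} per-experiment entries, got {len(value)}")
    return tuple(tuple(v) for v in value)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the emulated five-experiment design: per-sample
    richness bounded by the observed 27-86 range, five experiments with
    injection/refill schedules shaped like the real ones, a fermenter loss
    probability of 0.5 (about half the active fermenters disappear after
    the pulse) and a four-fold abundance boost of hydrogenotrophs.
    """

    n_experiments: int = 5
    richness_range: tuple[int, int] = (27, 86)
    base_richness_range: tuple[int, int] = (40, 60)
    richness_jitter: float = 0.05
    global_pool_size: int = 400
    shared_pool_size: int = 120
    shared_experiments: tuple[int, ...] = (2, 3, 4)  # 1-based experiment numbers
    shared_pool_fraction: float = 0.6
    fermenter_loss_prob: float = 0.5
    hydrogenotroph_boost: float = 4.0
    turnover: float = 0.15
    core_turnover: float = 0.01
    injection_recruit_fraction: float = 0.5
    refill_recruit_fraction: float = 0.15
    depth: int = 10_000
    lognormal_sigma: float = 1.2
    sampling_days: tuple = _DEFAULT_SAMPLING
    injections: tuple = _DEFAULT_INJECTIONS
    refills: tuple = _DEFAULT_REFILLS
    h2_percent: tuple = _DEFAULT_H2
    guild_mix: tuple[tuple[str, float], ...] = (
        ("fermentation", 0.45),
        ("sulfate_reduction", 0.25),
        ("wood_ljungdahl", 0.15),
        ("methanogenesis", 0.15),
    )
    emit_dna: bool = False
    necromass_size: int = 15
    singleton_spike: int = 0
    seed: int = 0

    # -- validation ----------------------------------------------------------

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise DataError("n_experiments must be >= 1")
        lo, hi = self.richness_range
        if lo <= 0 or lo > hi:
            raise DataError(f"richness bounds must be positive with lower <= upper, got {lo, hi}")
        if hi > self.global_pool_size:
            raise DataError(
                f"richness upper bound {hi} exceeds global pool size {self.global_pool_size}"
            )
        blo, bhi = self.base_richness_range
        if not (lo <= blo <= bhi <= hi):
            raise DataError("base_richness_range must lie within richness_range")
        for name in ("shared_pool_fraction", "fermenter_loss_prob", "turnover",
                     "core_turnover", "richness_jitter", "injection_recruit_fraction",
                     "refill_recruit_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.hydrogenotroph_boost < 1.0:
            raise DataError("hydrogenotroph_boost must be >= 1")
        if self.shared_pool_size > self.global_pool_size:
            raise DataError("shared pool cannot exceed the global pool")
        mix = dict(self.guild_mix)
        if set(mix) - set(GUILDS):
            raise DataError(f"unknown guilds in guild_mix: {sorted(set(mix) - set(GUILDS))}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise DataError(f"guild_mix must sum to 1, got {sum(mix.values())}")
        bad = [e for e in self.shared_experiments if not 1 <= e <= self.n_experiments]
        if bad:
            raise DataError(f"shared_experiments outside 1..n_experiments: {bad}")
        if len(set(self.shared_experiments)) != len(self.shared_experiments):
            raise DataError("shared_experiments must be distinct")
        for days in self.sampling_days_per_experiment():
            if list(days) != sorted(set(days)):
                raise DataError(f"sampling_days must be strictly increasing, got {days}")
        if self.shared_pool_fraction > 0 and len(self.shared_experiments) >= 2:
            if self.core_size() > self.shared_pool_size:
                raise DataError(
                    f"shared core ({self.core_size()}) exceeds shared pool size "
                    f"{self.shared_pool_size}; raise shared_pool_size or lower "
                    f"shared_pool_fraction"
                )
        if self.depth < self.richness_range[1]:
            raise DataError("depth must be at least the richness upper bound")

    # -- derived views -------------------------------------------------------

    def sampling_days_per_experiment(self) -> tuple[tuple[int, ...], ...]:
        return _per_experiment(self.sampling_days, self.n_experiments, "sampling_days")

    def injections_per_experiment(self) -> tuple[tuple[int, ...], ...]:
        return _per_experiment(self.injections, self.n_experiments, "injections")

    def refills_per_experiment(self) -> tuple[tuple[int, ...], ...]:
        return _per_experiment(self.refills, self.n_experiments, "refills")

    def h2_per_experiment(self) -> tuple[float, ...]:
        h2 = self.h2_percent
        if isinstance(h2, (int, float)):
            return tuple(float(h2) for _ in range(self.n_experiments))
        if len(h2) == self.n_experiments:
            return tuple(float(v) for v in h2)
        if len(h2) >= self.n_experiments:
            return tuple(float(v) for v in h2[: self.n_experiments])
        raise DataError("h2_percent must be scalar or one value per experiment")

    def experiment_ids(self) -> tuple[str, ...]:
        return tuple(f"exp{i}" for i in range(1, self.n_experiments + 1))

    def core_size(self) -> int:
        """Size of the ranked shared core held in common by designated experiments."""
        return int(
            math.ceil(
                self.shared_pool_fraction
                * (1.0 + self.richness_jitter)
                * self.base_richness_range[1]
            )
        )


@dataclass
class SyntheticDataset:
    """Output bundle: tables, taxonomy, guilds, designs and the engineered truth."""

    tables: dict[str, CommunityTable]
    taxonomy: dict[str, str]
    guild_frame: pd.DataFrame
    designs: dict[str, ExperimentDesign]
    truth: dict[str, object] = field(default_factory=dict)
    config: SimConfig | None = None


def default_designs(cfg: SimConfig) -> dict[str, ExperimentDesign]:
    designs = {}
    for i, exp in enumerate(cfg.experiment_ids()):
        designs[exp] = ExperimentDesign(
            exp,
            cfg.injections_per_experiment()[i],
            cfg.refills_per_experiment()[i],
            cfg.sampling_days_per_experiment()[i],
            cfg.h2_per_experiment()[i],
        )
    return designs


# ---------------------------------------------------------------------------
# generator internals


def _build_pool(cfg: SimConfig, rng: np.random.Generator):
    """Global ASV pool with guild and genus labels, plus the shared subset."""
    n = cfg.global_pool_size
    mix = dict(cfg.guild_mix)
    # largest-remainder apportionment of guild counts
    raw = {g: mix.get(g, 0.0) * n for g in GUILDS}
    counts = {g: int(math.floor(v)) for g, v in raw.items()}
    short = n - sum(counts.values())
    for g in sorted(GUILDS, key=lambda g: raw[g] - counts[g], reverse=True)[:short]:
        counts[g] += 1
    guild_of = np.empty(n, dtype=object)
    start = 0
    for g in GUILDS:
        guild_of[start : start + counts[g]] = g
        start += counts[g]
    rng.shuffle(guild_of)
    genus_of = np.array(
        [rng.choice(GENUS_BY_GUILD[g]) for g in guild_of], dtype=object
    )
    shared = np.sort(rng.choice(n, size=cfg.shared_pool_size, replace=False))
    return guild_of, genus_of, shared


class _CoreChain:
    """Ranked shared core common to the designated experiments.

    An ordered list of ASVs from the shared pool, evolved over the union of
    the designated experiments' sampling days with slow in-place turnover.
    At the injection (day 0) each fermenter member is replaced with the
    fermenter loss probability and permanently barred from re-entry, so
    the post-injection core is a shifted but again persistent community.
    Every designated sample holds a prefix of the current ranking, which
    is what makes the engineered pairs share the same ASVs rather than
    merely drawing from the same pool.
    """

    def __init__(self, cfg: SimConfig, shared_pool: np.ndarray,
                 guild_of: np.ndarray, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.guild_of = guild_of
        self.pool = list(shared_pool)
        self.excluded: set[int] = set()
        size = cfg.core_size()
        members = rng.choice(shared_pool, size=size, replace=False)
        self.by_day: dict[int, np.ndarray] = {}
        designated = [i - 1 for i in cfg.shared_experiments]
        all_days = sorted(
            {d for i in designated for d in cfg.sampling_days_per_experiment()[i]}
        )
        prev_day = None
        current = np.array(members, dtype=np.int64)
        for day in all_days:
            if prev_day is not None and prev_day < 0 <= day:
                current = self._injection_shift(current)
            if prev_day is not None:
                current = self._turnover(current)
            self.by_day[day] = current.copy()
            prev_day = day

    def _candidates(self, current: np.ndarray) -> list[int]:
        busy = set(current.tolist()) | self.excluded
        return [a for a in self.pool if a not in busy]

    def _injection_shift(self, current: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        out = current.copy()
        # every fermenter in the shared pool is barred with the loss probability
        for asv in self.pool:
            if self.guild_of[asv] == "fermentation" and self.rng.random() < cfg.fermenter_loss_prob:
                self.excluded.add(asv)
        for pos, asv in enumerate(out):
            if asv in self.excluded:
                cands = self._candidates(out)
                if cands:
                    out[pos] = self.rng.choice(cands)
        return out

    def _turnover(self, current: np.ndarray) -> np.ndarray:
        out = current.copy()
        flips = np.flatnonzero(self.rng.random(len(out)) < self.cfg.core_turnover)
        for pos in flips:
            cands = self._candidates(out)
            if cands:
                out[pos] = self.rng.choice(cands)
        return out

    def prefix(self, day: int, k: int) -> np.ndarray:
        ranking = self.by_day[day]
        return ranking[: min(k, len(ranking))]


def _simulate_experiment(
    cfg: SimConfig,
    index: int,
    guild_of: np.ndarray,
    core: _CoreChain | None,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray, np.ndarray, np.ndarray]:
    """Presence/abundance chain for one experiment.

    Returns (experiment_id, days, presence bool matrix over the global
    pool, count matrix).
    """
    exp_id = cfg.experiment_ids()[index]
    days = np.array(cfg.sampling_days_per_experiment()[index], dtype=np.int64)
    refills = set(cfg.refills_per_experiment()[index])
    n_pool = cfg.global_pool_size
    designated = core is not None and (index + 1) in cfg.shared_experiments

    base_richness = int(rng.integers(cfg.base_richness_range[0], cfg.base_richness_range[1] + 1))
    # per-ASV log-normal abundance weights, fixed through the experiment
    weights = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=n_pool)

    lo, hi = cfg.richness_range
    excluded: set[int] = set()  # fermenters barred after the injection
    suppression = 0  # richness deficit opened by the injection, lifted at refill
    private: list[int] = []
    presence = np.zeros((len(days), n_pool), dtype=bool)
    counts = np.zeros((len(days), n_pool), dtype=np.int64)
    prev_day: int | None = None

    for row, day in enumerate(days):
        jitter = 1.0 + rng.uniform(-cfg.richness_jitter, cfg.richness_jitter)
        r_target = int(np.clip(round(base_richness * jitter), lo, hi))

        shared_part = np.empty(0, dtype=np.int64)
        if designated and cfg.shared_pool_fraction > 0:
            n_sh = int(round(cfg.shared_pool_fraction * r_target))
            shared_part = core.prefix(int(day), n_sh)

        crossed_injection = prev_day is not None and prev_day < 0 <= day
        crossed_refill = prev_day is not None and any(
            prev_day < rd <= day for rd in refills
        )

        if crossed_injection:
            # each fermenter ASV of the pool becomes unavailable with the
            # loss probability -- present ones drop out, absent ones are
            # barred from (re)colonizing while H2 is high
            losers = np.flatnonzero(
                (guild_of == "fermentation") & (rng.random(n_pool) < cfg.fermenter_loss_prob)
            )
            excluded.update(int(a) for a in losers)
            survivors = [a for a in private if a not in excluded]
            n_lost = len(private) - len(survivors)
            n_recruit = int(round(cfg.injection_recruit_fraction * n_lost))
            suppression = max(0, n_lost - n_recruit)
            private = survivors
        if crossed_refill:
            # refill water carries nutrients: suppressed diversity recovers and
            # rare taxa rise above the detection limit (a transient richness bump)
            suppression = -int(round(cfg.refill_recruit_fraction * r_target))

        # small per-ASV turnover keeps successive samples similar
        if prev_day is not None and private:
            keep = rng.random(len(private)) >= cfg.turnover
            private = [a for a, k in zip(private, keep) if k]

        target_private = max(1, r_target - len(shared_part) - suppression)
        busy = set(private) | set(int(a) for a in shared_part) | excluded
        if len(private) > target_private:
            drop = rng.choice(len(private), size=len(private) - target_private, replace=False)
            private = [a for i, a in enumerate(private) if i not in set(drop.tolist())]
        elif len(private) < target_private:
            candidates = np.array([a for a in range(n_pool) if a not in busy], dtype=np.int64)
            need = min(target_private - len(private), len(candidates))
            new = rng.choice(candidates, size=need, replace=False)
            private = private + [int(a) for a in new]

        members = np.array(sorted(set(private) | set(int(a) for a in shared_part)),
                           dtype=np.int64)
        presence[row, members] = True

        w = weights[members].copy()
        if day >= 0 and cfg.hydrogenotroph_boost > 1.0:
            hydro = np.isin(guild_of[members], HYDROGENOTROPH_GUILDS)
            w[hydro] *= cfg.hydrogenotroph_boost
        p = w / w.sum()
        # one guaranteed read per present ASV, remainder multinomial: exact
        # depth and realized richness equal to the presence set
        extra = rng.multinomial(cfg.depth - len(members), p)
        counts[row, members] = 1 + extra
        prev_day = int(day)
        if suppression < 0:
            suppression = 0  # the refill bump is transient

    return exp_id, days, presence, counts


def _spike_singletons(cfg: SimConfig, counts: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Append artificial singleton ASVs (total count 1) for filter testing."""
    for i in range(cfg.singleton_spike):
        col = f"SPIKE_{i + 1:03d}"
        vec = np.zeros(len(counts), dtype=np.int64)
        vec[rng.integers(0, len(counts))] = 1
        counts[col] = vec
    return counts


def simulate_dataset(cfg: SimConfig) -> SyntheticDataset:
    """Generate the full multi-experiment dataset. Deterministic given cfg.seed."""
    pool_rng = child_rng(cfg.seed, "pool")
    guild_of, genus_of, shared_pool = _build_pool(cfg, pool_rng)

    core = None
    if cfg.shared_pool_fraction > 0 and len(cfg.shared_experiments) >= 2:
        core = _CoreChain(cfg, shared_pool, guild_of, child_rng(cfg.seed, "core"))

    asv_ids = np.array(
        [f"ASV_{i + 1:04d}" for i in range(cfg.global_pool_size)], dtype=object
    )
    designs = default_designs(cfg)
    tables: dict[str, CommunityTable] = {}
    taxonomy = {asv_ids[i]: genus_of[i] for i in range(cfg.global_pool_size)}

    for index in range(cfg.n_experiments):
        rng = child_rng(cfg.seed, "exp", index)
        exp_id, days, presence, counts = _simulate_experiment(
            cfg, index, guild_of, core, rng
        )
        ever = presence.any(axis=0)
        frame = pd.DataFrame(
            counts[:, ever],
            index=[f"{exp_id}_d{int(d)}" for d in days],
            columns=asv_ids[ever],
        )
        if cfg.singleton_spike:
            frame = _spike_singletons(cfg, frame, child_rng(cfg.seed, "spike", index))
            for col in frame.columns:
                taxonomy.setdefault(col, "Rectinema")
        day_series = pd.Series(days, index=frame.index, dtype=np.int64)
        nucleic = pd.Series("cDNA", index=frame.index)
        tables[exp_id] = CommunityTable(exp_id, frame, day_series, nucleic)

        if cfg.emit_dna:
            dna = _dna_companion(cfg, tables[exp_id], weights_seed=(cfg.seed, index))
            tables[exp_id] = _concat_tables(tables[exp_id], dna)

    truth_pairs = []
    if core is not None:
        ids = cfg.experiment_ids()
        shared_ids = sorted(ids[i - 1] for i in cfg.shared_experiments)
        truth_pairs = [pair_label(a, b) for a, b in itertools.combinations(shared_ids, 2)]
    truth = {
        "shared_pairs": truth_pairs,
        "shared_experiments": [cfg.experiment_ids()[i - 1] for i in cfg.shared_experiments],
        "shared_pool_fraction": cfg.shared_pool_fraction,
    }

    guild_rows = load_guild_table()
    guild_frame = pd.DataFrame(
        {
            "genus": list(guild_rows),
            "guilds": [";".join(sorted(a.guilds)) for a in guild_rows.values()],
            "kegg_modules": [";".join(sorted(a.kegg_modules)) for a in guild_rows.values()],
            "ko_ids": [";".join(a.ko_ids) for a in guild_rows.values()],
        }
    )
    return SyntheticDataset(tables, taxonomy, guild_frame, designs, truth, cfg)


def _dna_companion(cfg: SimConfig, cdna: CommunityTable, weights_seed) -> CommunityTable:
    """DNA-labelled twin of a cDNA table plus a persistent necromass ASV set."""
    rng = child_rng(cfg.seed, "dna", cdna.experiment_id)
    necro_pool = [a for a in cdna.asv_ids]
    n_necro = min(cfg.necromass_size, len(necro_pool))
    necromass = rng.choice(necro_pool, size=n_necro, replace=False)
    counts = cdna.counts.copy()
    for asv in necromass:
        counts[asv] = np.maximum(counts[asv], 1 + rng.integers(0, 5, size=len(counts)))
    counts.index = [f"{sid}_dna" for sid in counts.index]
    day = pd.Series(cdna.day.to_numpy(), index=counts.index, dtype=np.int64)
    nucleic = pd.Series("DNA", index=counts.index)
    return CommunityTable(cdna.experiment_id, counts, day, nucleic)


def _concat_tables(a: CommunityTable, b: CommunityTable) -> CommunityTable:
    counts = pd.concat([a.counts, b.counts]).fillna(0).astype(np.int64)
    day = pd.concat([a.day, b.day])
    nucleic = pd.concat([a.nucleic_acid, b.nucleic_acid])
    return CommunityTable(a.experiment_id, counts, day, nucleic)


# ---------------------------------------------------------------------------
# writer


def write_dataset(
    ds: SyntheticDataset, directory: str | Path, overwrite: bool = False
) -> dict[str, Path]:
    """Write feature tables, metadata, taxonomy, guild table and event log.

    Returns a manifest mapping logical names to paths. Refuses to touch an
    existing non-empty directory unless ``overwrite`` is set. Round-trips
    losslessly through :func:`slime.io.load_dataset` (the engineered truth
    stays in memory only).
    """
    if not ds.tables:
        raise DataError("dataset has no experiments")
    for exp, table in ds.tables.items():
        if table.n_samples == 0:
            raise DataError(f"experiment {exp!r} has no samples")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    planned = {f"feature_table_{exp}": directory / f"feature_table_{exp}.tsv"
               for exp in ds.tables}
    planned["metadata"] = directory / "metadata.tsv"
    planned["taxonomy"] = directory / "taxonomy.tsv"
    planned["guild_table"] = directory / "guild_table.tsv"
    planned["events"] = directory / "events.tsv"
    clashes = [p for p in planned.values() if p.exists()]
    if clashes and not overwrite:
        raise FileExistsError(
            f"refusing to overwrite existing files (pass overwrite=True): {clashes[:3]}"
        )
    for exp, table in ds.tables.items():
        write_feature_table(table, planned[f"feature_table_{exp}"])
    write_metadata(ds.tables.values(), planned["metadata"])
    used = sorted({a for t in ds.tables.values() for a in t.asv_ids})
    write_taxonomy({a: ds.taxonomy[a] for a in used}, planned["taxonomy"])
    ds.guild_frame.to_csv(planned["guild_table"], sep="\t", index=False)
    write_events(ds.designs.values(), planned["events"])
    manifest.update(planned)
    return manifest
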