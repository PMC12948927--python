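"""End-to-end run: simulate/load -> filter -> align -> alpha -> null beta -> guilds.

One :func:`run` call executes the whole analysis deterministically from a
:class:`RunConfig` and writes a machine-readable report (JSON) plus tidy
TSV/CSV outputs. All randomness is funneled through one root seed with
label-derived child streams, so reruns are byte-identical (timestamps are
not written) and adding an experiment never changes existing pairs'
results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import INDEX_NAMES, alpha_trajectory
from .beta import (
    BetaResult,
    BiasCheck,
    PairwiseBetaResult,
    pairwise_beta,
    within_experiment_beta,
)
from .guilds import annotate, chord_edges, core_community, guild_trajectory, \
    guild_table_from_frame, load_guild_table
from .io import (
    DataError,
    assign_timepoints,
    load_dataset,
    remove_singletons,
)
from .simulate import SimConfig, simulate_dataset

__all__ = ["RunConfig", "RunReport", "run"]

log = logging.getLogger("slime")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of a pipeline run.

    Either ``input_dir`` (a dataset written in the community_io formats) or
    ``sim`` (generator conditions) must be provided; with neither, the
    default synthetic five-experiment study is generated.
    """

    input_dir: str | None = None
    sim: SimConfig | None = None
    out_dir: str | None = None
    seed: int = 0
    remove_singleton_asvs: bool = True
    nucleic_acid: str = "cDNA"
    n_mock: int = 10_000
    n_pairs: int = 1_000
    threshold: float = 1.96
    richness_rule: str = "matched"
    within_mode: str = "consecutive"
    core_categories: tuple[str, ...] = ("After", "Furthest")

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise DataError("significance threshold must be > 0")
        if 2 * self.n_pairs > self.n_mock:
            raise DataError(f"n_pairs={self.n_pairs} requires n_pairs <= n_mock/2={self.n_mock // 2}")
        if self.nucleic_acid not in ("DNA", "cDNA"):
            raise DataError("nucleic_acid must be 'DNA' or 'cDNA'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        if sim is not None:
            for key in ("sampling_days", "injections", "refills", "shared_experiments",
                        "richness_range", "base_richness_range", "h2_percent"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in sim[key]
                    )
            if "guild_mix" in sim and isinstance(sim["guild_mix"], dict):
                sim["guild_mix"] = tuple(sim["guild_mix"].items())
            sim = SimConfig(**sim)
        known = {k: v for k, v in raw.items()}
        if "core_categories" in known:
            known["core_categories"] = tuple(known["core_categories"])
        return cls(sim=sim, **known)

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one run computed, serializable to JSON + TSV."""

    alpha: pd.DataFrame
    beta: pd.DataFrame
    within: pd.DataFrame
    patterns: pd.DataFrame
    bias: BiasCheck | None
    core: dict[str, pd.DataFrame]
    guild_fractions: pd.DataFrame
    edges: pd.DataFrame
    provenance: dict[str, Any] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "provenance": self.provenance,
            "alpha": self.alpha.to_dict(orient="records"),
            "beta": self.beta.to_dict(orient="records"),
            "within": self.within.to_dict(orient="records"),
            "patterns": self.patterns.to_dict(orient="records"),
            "bias": None if self.bias is None else {
                "rho": self.bias.rho, "p_value": self.bias.p_value,
                "n": self.bias.n, "biased": self.bias.biased, "note": self.bias.note,
            },
            "core": {cat: frame.to_dict(orient="records") for cat, frame in self.core.items()},
        }


def _beta_frame(results: list[BetaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pair": r.pair,
                "category": r.category,
                "observed": r.observed,
                "z": r.z,
                "significant": r.significant,
                "convergent": r.convergent,
                "day_a": r.day_a,
                "day_b": r.day_b,
                "reason": r.reason,
            }
            for r in results
        ],
        columns=["pair", "category", "observed", "z", "significant", "convergent",
                 "day_a", "day_b", "reason"],
    )


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline; write outputs when ``config.out_dir`` is set."""
    # ---- load or simulate -------------------------------------------------
    if config.input_dir is not None:
        tables, designs, taxonomy, guild_frame = load_dataset(config.input_dir)
        log.info("loaded %d experiments from %s", len(tables), config.input_dir)
        truth: Mapping[str, Any] = {}
    else:
        sim_cfg = config.sim if config.sim is not None else SimConfig(seed=config.seed)
        ds = simulate_dataset(sim_cfg)
        tables, designs = ds.tables, ds.designs
        taxonomy, guild_frame, truth = ds.taxonomy, ds.guild_frame, ds.truth
        log.info("simulated %d experiments (seed %d)", len(tables), sim_cfg.seed)
    guild_table = guild_table_from_frame(guild_frame) if guild_frame is not None \
        else load_guild_table()

    # ---- filter ------------------------------------------------------------
    tables = {e: t.select_nucleic_acid(config.nucleic_acid) for e, t in tables.items()}
    for e, t in tables.items():
        if t.n_samples == 0:
            raise DataError(f"experiment {e!r} has no {config.nucleic_acid} samples")
    if config.remove_singleton_asvs:
        before = {e: len(t.asv_ids) for e, t in tables.items()}
        tables = {e: remove_singletons(t) for e, t in tables.items()}
        for e, t in tables.items():
            log.info("%s: singleton filter kept %d/%d ASVs", e, len(t.asv_ids), before[e])

    # ---- align -------------------------------------------------------------
    assignments = {e: assign_timepoints(t, designs[e]) for e, t in tables.items()}

    # ---- alpha -------------------------------------------------------------
    alpha_rows = []
    for e, t in tables.items():
        for index_name in INDEX_NAMES:
            series = alpha_trajectory(t, index_name, designs[e])
            for d, v in zip(series.days, series.values):
                alpha_rows.append(
                    {"experiment": e, "day": int(d), "index": index_name, "value": v}
                )
    alpha_frame = pd.DataFrame(alpha_rows, columns=["experiment", "day", "index", "value"])

    # ---- beta --------------------------------------------------------------
    pw: PairwiseBetaResult = pairwise_beta(
        tables, designs,
        n_mock=config.n_mock, n_pairs=config.n_pairs, seed=config.seed,
        threshold=config.threshold, richness_rule=config.richness_rule,
    )
    beta_frame = _beta_frame(pw.results)
    try:
        bias = pw.bias_check()
    except ValueError:
        bias = None
    within_rows = []
    for e, t in tables.items():
        for r in within_experiment_beta(
            t, n_mock=config.n_mock, n_pairs=config.n_pairs, seed=config.seed,
            threshold=config.threshold, mode=config.within_mode,
        ):
            within_rows.append({"experiment": e, "pair": r.pair, "observed": r.observed,
                                "z": r.z, "day_a": r.day_a, "day_b": r.day_b})
    within_frame = pd.DataFrame(
        within_rows, columns=["experiment", "pair", "observed", "z", "day_a", "day_b"]
    )
    pattern_frame = pd.DataFrame(
        [
            {"pair": p.pair, "pattern": p.label, "partial": p.partial, "atypical": p.atypical}
            for p in pw.patterns.values()
        ],
        columns=["pair", "pattern", "partial", "atypical"],
    )

    # ---- guilds ------------------------------------------------------------
    annotated = {e: annotate(t, taxonomy, guild_table) for e, t in tables.items()}
    guild_rows = []
    for e, at in annotated.items():
        gs = guild_trajectory(at)
        frame = gs.fractions.reset_index().melt(
            id_vars="day", var_name="guild", value_name="fraction"
        )
        frame.insert(0, "experiment", e)
        guild_rows.append(frame)
    guild_frame_out = pd.concat(guild_rows, ignore_index=True) if guild_rows else pd.DataFrame()
    core = {}
    for cat in config.core_categories:
        have = [e for e in annotated if any(t.category == cat for t in assignments[e])]
        if len(have) == len(annotated):
            core[cat] = core_community(annotated, assignments, cat)
    edges = pd.concat([chord_edges(at) for at in annotated.values()], ignore_index=True)

    provenance = {
        "slime_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_experiments": len(tables),
        "truth": dict(truth) if truth else {},
    }
    report = RunReport(alpha_frame, beta_frame, within_frame, pattern_frame, bias,
                       core, guild_frame_out, edges, provenance)
    if config.out_dir is not None:
        _write_outputs(report, Path(config.out_dir))
    return report


def _write_outputs(report: RunReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.alpha.to_csv(out_dir / "alpha.tsv", sep="\t", index=False)
    report.beta.to_csv(out_dir / "beta.tsv", sep="\t", index=False)
    report.within.to_csv(out_dir / "within_beta.tsv", sep="\t", index=False)
    report.patterns.to_csv(out_dir / "patterns.tsv", sep="\t", index=False)
    report.guild_fractions.to_csv(out_dir / "guild_fractions.tsv", sep="\t", index=False)
    report.edges.to_csv(out_dir / "chord_edges.csv", index=False)
    for cat, frame in report.core.items():
        frame.to_csv(out_dir / f"core_{cat.lower()}.tsv", sep="\t", index=False)
    (out_dir / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=2, sort_keys=True, default=_json_default)
        + "\n"
    )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
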