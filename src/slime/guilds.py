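"""Metabolic guild profiling: genus -> guild/KEGG-module annotation.

ASVs are mapped (via their genus) to four energy-metabolism guilds:
hydrogenotrophic methanogenesis (KEGG module M00567), dissimilatory
sulfate reduction (M00596), the Wood-Ljungdahl pathway of acetogens
(M00377), and fermentation (a configurable KO list shipped under the
placeholder module id FERM -- the published enrichment-derived KO list is
external, so the default set is an editable stand-in).

The annotation is a static, shipped genus table rather than a marker-gene
functional inference: transparent, offline, and user-replaceable. On top
of it sit per-day guild relative-abundance trajectories, core (shared)
community computation across experiments, and the chord-diagram edge-list
export (ASV x timepoint x KO with relative-abundance weights).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import CommunityTable, DataError, TimepointAssignment

__all__ = [
    "GUILDS",
    "MODULE_BY_GUILD",
    "GuildAnnotation",
    "AnnotatedTable",
    "GuildSeries",
    "load_guild_table",
    "guild_table_from_frame",
    "annotate",
    "guild_trajectory",
    "core_community",
    "chord_edges",
]

GUILDS = ("fermentation", "sulfate_reduction", "wood_ljungdahl", "methanogenesis")

# one-to-one guild <-> module correspondence
MODULE_BY_GUILD = {
    "methanogenesis": "M00567",
    "sulfate_reduction": "M00596",
    "wood_ljungdahl": "M00377",
    "fermentation": "FERM",
}
GUILD_BY_MODULE = {v: k for k, v in MODULE_BY_GUILD.items()}


@dataclass(frozen=True)
class GuildAnnotation:
    """Functional annotation of one genus."""

    genus: str
    guilds: frozenset[str]
    ko_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.guilds:
            raise DataError(f"{self.genus}: guild set must be nonempty")
        unknown = self.guilds - set(GUILDS)
        if unknown:
            raise DataError(f"{self.genus}: unknown guilds {sorted(unknown)}")

    @property
    def kegg_modules(self) -> frozenset[str]:
        return frozenset(MODULE_BY_GUILD[g] for g in self.guilds)


def guild_table_from_frame(frame: pd.DataFrame) -> dict[str, GuildAnnotation]:
    """Build genus -> annotation from a TSV frame (guilds/KOs semicolon-split)."""
    out: dict[str, GuildAnnotation] = {}
    for _, row in frame.iterrows():
        genus = str(row["genus"])
        if genus in out:
            raise DataError(f"genus {genus!r} appears twice in the guild table")
        guilds = frozenset(g for g in str(row["guilds"]).split(";") if g)
        kos = tuple(k for k in str(row.get("ko_ids", "") or "").split(";") if k and k != "nan")
        out[genus] = GuildAnnotation(genus, guilds, kos)
    return out


def load_guild_table(path: str | Path | None = None) -> dict[str, GuildAnnotation]:
    """Load the genus -> guild/KO table (packaged default when path is None)."""
    if path is None:
        source = resources.files("slime.data").joinpath("guild_table.tsv")
        with resources.as_file(source) as p:
            frame = pd.read_csv(p, sep="\t", dtype=str)
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str)
    return guild_table_from_frame(frame)


@dataclass
class AnnotatedTable:
    """A community table plus per-ASV genus / guild / KO annotation.

    ``features`` is indexed by ASV id with columns ``genus`` (str),
    ``guilds`` (tuple, possibly empty = unannotated) and ``kos`` (tuple).
    """

    table: CommunityTable
    features: pd.DataFrame


def annotate(
    table: CommunityTable,
    taxonomy: Mapping[str, str],
    guild_table: Mapping[str, GuildAnnotation],
) -> AnnotatedTable:
    """Attach genus and guild sets to every ASV of a table.

    The taxonomy must cover all ASVs; the guild table may be partial (a
    genus absent from it yields an unannotated ASV, counted separately in
    trajectories).
    """
    missing = [a for a in table.asv_ids if a not in taxonomy]
    if missing:
        raise DataError(f"ASVs missing from taxonomy: {missing[:10]}"
                        + (" ..." if len(missing) > 10 else ""))
    records = []
    for asv in table.asv_ids:
        genus = taxonomy[asv]
        ann = guild_table.get(genus)
        records.append(
            {
                "genus": genus,
                "guilds": tuple(sorted(ann.guilds)) if ann else (),
                "kos": ann.ko_ids if ann else (),
            }
        )
    features = pd.DataFrame(records, index=pd.Index(table.asv_ids, name="asv_id"))
    return AnnotatedTable(table, features)


@dataclass
class GuildSeries:
    """Per-day relative-abundance fractions per guild, plus the unannotated rest.

    Multi-guild ASVs contribute their full weight to each of their guilds
    (dual counting, stated in ``overlap_note``); for single-guild
    annotations the guild fractions plus ``unannotated`` sum to 1 per day.
    """

    experiment_id: str
    days: np.ndarray
    fractions: pd.DataFrame  # index: day, columns: GUILDS + ('unannotated',)
    overlap_note: str = (
        "ASVs with multiple guilds contribute full weight to each guild; "
        "fractions can then sum to more than 1."
    )


def guild_trajectory(annotated: AnnotatedTable) -> GuildSeries:
    """Summed relative abundance per guild at each sampling day."""
    table = annotated.table.sorted_by_day()
    days = table.day.to_numpy()
    rows = []
    for sid in table.sample_ids:
        counts = table.counts.loc[sid]
        total = counts.sum()
        if total == 0:
            rows.append({g: np.nan for g in (*GUILDS, "unannotated")})
            continue
        rel = counts / total
        frac = {g: 0.0 for g in GUILDS}
        unann = 0.0
        for asv, w in rel.items():
            if w == 0:
                continue
            guilds = annotated.features.at[asv, "guilds"]
            if not guilds:
                unann += w
            else:
                for g in guilds:
                    frac[g] += w
        frac["unannotated"] = unann
        rows.append(frac)
    fractions = pd.DataFrame(rows, index=pd.Index(days, name="day"))
    return GuildSeries(table.experiment_id, days, fractions)


def core_community(
    annotated_tables: Mapping[str, AnnotatedTable],
    assignments: Mapping[str, Iterable[TimepointAssignment]],
    category: str,
    scope: Iterable[str] | None = None,
) -> pd.DataFrame:
    """ASVs present in the given category's sample of every experiment in scope.

    Returns a frame with columns ``asv_id`` and ``genus``, sorted by genus.
    Anti-monotone in scope: adding an experiment can only shrink the core.
    """
    scope = sorted(scope) if scope is not None else sorted(annotated_tables)
    presence_sets = []
    genus_of: dict[str, str] = {}
    for exp in scope:
        if exp not in annotated_tables:
            raise DataError(f"experiment {exp!r} not among the annotated tables")
        tp = next((t for t in assignments[exp] if t.category == category), None)
        if tp is None:
            raise DataError(f"experiment {exp!r} has no sample for category {category!r}")
        at = annotated_tables[exp]
        present = at.table.presence(tp.sample_id)
        presence_sets.append(present)
        for asv in present:
            genus_of.setdefault(asv, at.features.at[asv, "genus"])
    core = frozenset.intersection(*presence_sets) if presence_sets else frozenset()
    frame = pd.DataFrame(
        {"asv_id": sorted(core), "genus": [genus_of[a] for a in sorted(core)]}
    )
    return frame.sort_values(["genus", "asv_id"], ignore_index=True)


def chord_edges(annotated: AnnotatedTable) -> pd.DataFrame:
    """Edge list for a chord diagram: one edge per (present ASV, timepoint, KO).

    The weight of an edge is the ASV's relative abundance at that timepoint
    -- edges are attribute fan-outs, so all of an ASV's KO edges at one
    timepoint carry the same weight. Rows are ordered by timepoint, genus,
    then decreasing abundance within genus.
    """
    table = annotated.table.sorted_by_day()
    if table.n_samples < 1:
        raise DataError("chord_edges needs at least one sample")
    records = []
    for t_index, sid in enumerate(table.sample_ids):
        counts = table.counts.loc[sid]
        total = counts.sum()
        if total == 0:
            continue
        rel = counts / total
        for asv in table.asv_ids:
            w = float(rel[asv])
            if w == 0:
                continue
            genus = annotated.features.at[asv, "genus"]
            guilds = annotated.features.at[asv, "guilds"]
            kos = annotated.features.at[asv, "kos"]
            for guild in guilds:
                for ko in kos:
                    records.append(
                        {
                            "asv_id": asv,
                            "timepoint": t_index,
                            "day": int(table.day[sid]),
                            "genus": genus,
                            "ko": ko,
                            "guild": guild,
                            "weight": w,
                        }
                    )
    edges = pd.DataFrame(
        records,
        columns=["asv_id", "timepoint", "day", "genus", "ko", "guild", "weight"],
    )
    if len(edges):
        edges = edges.sort_values(
            ["timepoint", "genus", "weight", "asv_id", "ko"],
            ascending=[True, True, False, True, True],
            ignore_index=True,
        )
    return edges
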