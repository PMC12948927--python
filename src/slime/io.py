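"""Community tables, experiment designs and the on-disk formats.

The central observational object is the :class:`CommunityTable`: one
experiment's samples x ASVs integer count matrix, with a per-sample day
(relative to the first H2 injection, which is day 0) and nucleic-acid flag
(DNA or cDNA). Feature tables are exchanged as QIIME2-export-style TSV
(ASVs as rows, ``#OTU ID`` header token), sample metadata, event logs and
chemistry series as plain TSV.

Also here: the table-level singleton filter, the assignment of samples to
the Before / After / Furthest time categories used by the beta-diversity
comparisons, and the mass-balance correction of chemical time series for
the material withdrawn at each sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "DataError",
    "CommunityTable",
    "ExperimentDesign",
    "TimepointAssignment",
    "ChemSeries",
    "CATEGORIES",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_events",
    "write_events",
    "read_taxonomy",
    "write_taxonomy",
    "read_chemistry",
    "write_chemistry",
    "remove_singletons",
    "assign_timepoints",
    "correct_sampling_loss",
    "load_dataset",
]

CATEGORIES = ("Before", "After", "Furthest")

METADATA_COLUMNS = ["sample-id", "experiment", "day", "nucleic_acid"]
EVENT_COLUMNS = ["experiment", "event", "day", "h2_percent"]


class ParseError(ValueError):
    """A file did not conform to the expected dialect."""


class DataError(ValueError):
    """In-memory data violated a structural invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CommunityTable:
    """Samples x ASVs count matrix for one experiment.

    ``counts`` has sample ids as the index and ASV ids as columns; entries
    are nonnegative integers. ``day`` and ``nucleic_acid`` are per-sample
    series aligned to ``counts.index``.
    """

    experiment_id: str
    counts: pd.DataFrame
    day: pd.Series
    nucleic_acid: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise DataError(f"duplicate ASV ids: {dups}")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise DataError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if values.size and (values < 0).any():
            raise DataError("counts must be nonnegative")
        self.day = pd.Series(self.day, dtype=np.int64).reindex(self.counts.index)
        if self.day.isna().any():
            missing = self.day.index[self.day.isna()].tolist()
            raise DataError(f"samples missing a day value: {missing}")
        self.nucleic_acid = pd.Series(self.nucleic_acid).reindex(self.counts.index)
        bad = set(self.nucleic_acid.dropna()) - {"DNA", "cDNA"}
        if bad:
            raise DataError(f"nucleic_acid must be DNA or cDNA, got {sorted(bad)}")
        if self.counts.shape[0] and self.counts.shape[1]:
            empty = self.counts.index[(self.counts.sum(axis=1) == 0)].tolist()
            if empty:
                warnings.warn(
                    f"{self.experiment_id}: samples with all-zero counts: {empty}",
                    stacklevel=2,
                )

    # -- convenience views ---------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def presence(self, sample_id: str) -> frozenset[str]:
        """Set of ASVs with count > 0 in one sample."""
        row = self.counts.loc[sample_id]
        return frozenset(row.index[row > 0])

    def total_pool(self) -> frozenset[str]:
        """Union of ASVs observed (count > 0) in any sample, regardless of time."""
        if self.counts.empty:
            return frozenset()
        return frozenset(self.counts.columns[(self.counts > 0).any(axis=0)])

    def select_nucleic_acid(self, kind: str) -> "CommunityTable":
        keep = self.nucleic_acid == kind
        return replace(
            self,
            counts=self.counts.loc[keep],
            day=self.day.loc[keep],
            nucleic_acid=self.nucleic_acid.loc[keep],
        )

    def sorted_by_day(self) -> "CommunityTable":
        order = self.day.sort_values(kind="stable").index
        return replace(
            self,
            counts=self.counts.loc[order],
            day=self.day.loc[order],
            nucleic_acid=self.nucleic_acid.loc[order],
        )


@dataclass(frozen=True)
class ExperimentDesign:
    """Event log of one experiment: H2 injections, water refills, sampling grid."""

    experiment_id: str
    injection_days: tuple[int, ...]
    refill_days: tuple[int, ...] = ()
    sampling_days: tuple[int, ...] = ()
    h2_percent: float | None = None

    def __post_init__(self) -> None:
        if not self.injection_days:
            raise DataError(f"{self.experiment_id}: at least one injection required")
        if self.injection_days[0] != 0:
            raise DataError(
                f"{self.experiment_id}: days are centered on the first injection "
                f"(must be 0, got {self.injection_days[0]})"
            )
        for name in ("injection_days", "refill_days", "sampling_days"):
            vals = getattr(self, name)
            if list(vals) != sorted(vals):
                raise DataError(f"{self.experiment_id}: {name} must be sorted ascending")
        if len(set(self.sampling_days)) != len(self.sampling_days):
            raise DataError(f"{self.experiment_id}: sampling_days must be distinct")


@dataclass(frozen=True)
class TimepointAssignment:
    """One sample chosen to represent a time category for an experiment."""

    experiment_id: str
    category: str  # Before | After | Furthest
    sample_id: str
    day: int


@dataclass
class ChemSeries:
    """Time series of a chemical analyte with per-sampling withdrawals (mmol)."""

    analyte: str
    days: np.ndarray
    measured: np.ndarray
    removed: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.measured = np.asarray(self.measured, dtype=float)
        self.removed = np.asarray(self.removed, dtype=float)
        if not (len(self.days) == len(self.measured) == len(self.removed)):
            raise DataError(f"{self.analyte}: days/measured/removed lengths differ")
        if (self.removed < 0).any():
            raise DataError(f"{self.analyte}: removals must be nonnegative")


# ---------------------------------------------------------------------------
# feature tables


def _read_tsv_lines(path: Path) -> list[list[str]]:
    rows = []
    for raw in path.read_text().splitlines():
        if not raw.strip():
            continue
        rows.append(raw.split("\t"))
    return rows


def read_feature_table(
    path: str | Path,
    *,
    metadata: pd.DataFrame | None = None,
    experiment_id: str | None = None,
) -> CommunityTable:
    """Read a QIIME2-export-style TSV feature table (ASVs rows, samples columns).

    An optional leading ``# Constructed from biom file`` comment is skipped;
    the header may start with the ``#OTU ID`` token. When a ``metadata`` frame
    (columns ``sample-id``, ``experiment``, ``day``, ``nucleic_acid``) is
    given, per-sample day and nucleic-acid flags are attached from it;
    otherwise day defaults to 0 and nucleic acid to cDNA.
    """
    path = Path(path)
    rows = _read_tsv_lines(path)
    # drop pure comment lines (but keep a '#OTU ID' header)
    while rows and rows[0][0].startswith("#") and rows[0][0] not in ("#OTU ID", "#OTU_ID"):
        rows.pop(0)
    if not rows:
        raise ParseError(f"{path}: empty feature table")
    header = rows[0]
    if header[0] not in ("#OTU ID", "#OTU_ID", "OTU ID", "ASV ID", "asv_id", "feature-id"):
        raise ParseError(f"{path}: unrecognized header token {header[0]!r}")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = [s for s in sample_ids if sample_ids.count(s) > 1]
        raise ParseError(f"{path}: duplicated sample id in header: {sorted(set(dup))}")
    asv_ids: list[str] = []
    data: list[list[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"{path}: line {lineno}: expected {len(header)} fields, got {len(row)}")
        asv = row[0]
        if asv in asv_ids:
            raise ParseError(f"{path}: line {lineno}: duplicated ASV id {asv!r}")
        vals = []
        for sample, cell in zip(sample_ids, row[1:]):
            try:
                v = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno} (ASV {asv!r}, sample {sample!r}): "
                    f"non-numeric count {cell!r}"
                ) from None
            if v != int(v):
                raise ParseError(
                    f"{path}: line {lineno} (ASV {asv!r}, sample {sample!r}): "
                    f"non-integer count {cell!r}"
                )
            vals.append(int(v))
        asv_ids.append(asv)
        data.append(vals)
    counts = pd.DataFrame(data, index=asv_ids, columns=sample_ids, dtype=np.int64).T
    if experiment_id is None:
        experiment_id = path.stem.replace("feature_table_", "")
    if metadata is not None:
        meta = metadata.set_index("sample-id")
        missing = [s for s in sample_ids if s not in meta.index]
        if missing:
            raise ParseError(f"{path}: samples absent from metadata: {missing}")
        day = meta.loc[sample_ids, "day"].astype(np.int64)
        nucleic = meta.loc[sample_ids, "nucleic_acid"]
        exps = set(meta.loc[sample_ids, "experiment"])
        if len(exps) == 1:
            experiment_id = next(iter(exps))
    else:
        day = pd.Series(0, index=sample_ids, dtype=np.int64)
        nucleic = pd.Series("cDNA", index=sample_ids)
    return CommunityTable(experiment_id, counts, day, nucleic)


def write_feature_table(table: CommunityTable, path: str | Path) -> None:
    """Write a table in the TSV dialect read by :func:`read_feature_table`."""
    path = Path(path)
    out = table.counts.T  # ASVs as rows
    with path.open("w") as fh:
        fh.write("#OTU ID\t" + "\t".join(map(str, out.columns)) + "\n")
        for asv, row in out.iterrows():
            fh.write(str(asv) + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# metadata / events / taxonomy / chemistry


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample-id": str, "experiment": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing columns {missing}")
    if meta["sample-id"].duplicated().any():
        dups = meta.loc[meta["sample-id"].duplicated(), "sample-id"].tolist()
        raise ParseError(f"{path}: duplicated sample ids {dups}")
    meta["day"] = meta["day"].astype(np.int64)
    return meta


def write_metadata(tables: Iterable[CommunityTable], path: str | Path) -> None:
    records = []
    for t in tables:
        for sid in t.sample_ids:
            records.append(
                {
                    "sample-id": sid,
                    "experiment": t.experiment_id,
                    "day": int(t.day[sid]),
                    "nucleic_acid": t.nucleic_acid[sid],
                }
            )
    pd.DataFrame(records, columns=METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(
    path: str | Path, metadata: pd.DataFrame | None = None
) -> dict[str, ExperimentDesign]:
    """Read an event log and build one :class:`ExperimentDesign` per experiment.

    Sampling grids are taken from ``metadata`` when provided.
    """
    ev = pd.read_csv(path, sep="\t", dtype={"experiment": str, "event": str})
    missing = [c for c in ("experiment", "event", "day") if c not in ev.columns]
    if missing:
        raise ParseError(f"{path}: event log missing columns {missing}")
    bad = set(ev["event"]) - {"injection", "refill"}
    if bad:
        raise ParseError(f"{path}: unknown event kinds {sorted(bad)}")
    designs = {}
    for exp, grp in ev.groupby("experiment", sort=True):
        inj = tuple(sorted(grp.loc[grp["event"] == "injection", "day"].astype(int)))
        ref = tuple(sorted(grp.loc[grp["event"] == "refill", "day"].astype(int)))
        h2 = None
        if "h2_percent" in grp.columns:
            vals = grp.loc[grp["event"] == "injection", "h2_percent"].dropna()
            if len(vals):
                h2 = float(vals.iloc[0])
        sampling: tuple[int, ...] = ()
        if metadata is not None:
            sel = metadata.loc[metadata["experiment"] == exp, "day"]
            sampling = tuple(sorted(set(int(d) for d in sel)))
        designs[exp] = ExperimentDesign(exp, inj, ref, sampling, h2)
    return designs


def write_events(designs: Iterable[ExperimentDesign], path: str | Path) -> None:
    records = []
    for d in designs:
        for day in d.injection_days:
            records.append(
                {"experiment": d.experiment_id, "event": "injection", "day": day,
                 "h2_percent": d.h2_percent}
            )
        for day in d.refill_days:
            records.append(
                {"experiment": d.experiment_id, "event": "refill", "day": day,
                 "h2_percent": ""}
            )
    pd.DataFrame(records, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """ASV id -> genus mapping from a two-column TSV."""
    tax = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("asv_id", "genus"):
        if col not in tax.columns:
            raise ParseError(f"{path}: taxonomy missing column {col!r}")
    if tax["asv_id"].duplicated().any():
        dups = tax.loc[tax["asv_id"].duplicated(), "asv_id"].tolist()
        raise ParseError(f"{path}: ASV ids appear more than once: {dups}")
    return dict(zip(tax["asv_id"], tax["genus"]))


def write_taxonomy(taxonomy: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"asv_id": list(taxonomy.keys()), "genus": list(taxonomy.values())}
    ).to_csv(path, sep="\t", index=False)


def read_chemistry(path: str | Path) -> dict[str, ChemSeries]:
    """Long-format TSV analyte/day/measured/removed -> one series per analyte."""
    chem = pd.read_csv(path, sep="\t")
    missing = [c for c in ("analyte", "day", "measured", "removed") if c not in chem.columns]
    if missing:
        raise ParseError(f"{path}: chemistry missing columns {missing}")
    out = {}
    for analyte, grp in chem.groupby("analyte", sort=True):
        grp = grp.sort_values("day")
        out[analyte] = ChemSeries(
            analyte, grp["day"].to_numpy(), grp["measured"].to_numpy(), grp["removed"].to_numpy()
        )
    return out


def write_chemistry(series: Iterable[ChemSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"analyte": s.analyte, "day": s.days, "measured": s.measured, "removed": s.removed}
        )
        for s in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# table-level operations


def remove_singletons(table: CommunityTable) -> CommunityTable:
    """Drop ASVs whose total count across the experiment's samples equals 1.

    The filter is applied per experiment table, mirroring per-experiment
    upstream processing; it is idempotent (surviving totals are >= 2 or 0).
    """
    totals = table.counts.sum(axis=0)
    keep = totals != 1
    if not keep.any() and len(keep):
        warnings.warn(
            f"{table.experiment_id}: all ASVs were singletons; table now has no ASVs",
            stacklevel=2,
        )
    return replace(table, counts=table.counts.loc[:, keep])


def assign_timepoints(
    table: CommunityTable, design: ExperimentDesign
) -> list[TimepointAssignment]:
    """Pick the samples representing the Before / After / Furthest categories.

    Before   latest sample before the first injection (day < 0);
    After    earliest sample on or after the injection day (day 0 counts as After);
    Furthest latest post-injection sample strictly before the first disturbance
             after the injection (next injection or first refill), or the last
             sample when no such event exists.

    Only categories with an eligible sample are returned.
    """
    days = sorted(int(d) for d in table.day)
    extra = set(days) - set(design.sampling_days) if design.sampling_days else set()
    if extra:
        raise DataError(
            f"{table.experiment_id}: sample days {sorted(extra)} not in the design grid"
        )
    by_day = {}
    for sid in table.sample_ids:
        by_day[int(table.day[sid])] = sid  # one sample per day expected

    out = []
    pre = [d for d in days if d < 0]
    if pre:
        d = max(pre)
        out.append(TimepointAssignment(table.experiment_id, "Before", by_day[d], d))
    else:
        warnings.warn(f"{table.experiment_id}: no pre-injection sample; Before omitted",
                      stacklevel=2)
    post = [d for d in days if d >= 0]
    if post:
        d_after = min(post)
        out.append(TimepointAssignment(table.experiment_id, "After", by_day[d_after], d_after))
        cutoffs = [d for d in design.injection_days if d > 0]
        cutoffs += [d for d in design.refill_days if d > 0]
        if cutoffs:
            eligible = [d for d in post if d < min(cutoffs)]
        else:
            eligible = post
        if eligible:
            d_far = max(eligible)
            out.append(
                TimepointAssignment(table.experiment_id, "Furthest", by_day[d_far], d_far)
            )
    return out


def correct_sampling_loss(series: ChemSeries) -> ChemSeries:
    """Add back cumulative withdrawals: corrected(t_k) = measured(t_k) + sum_{j<=k} removed(t_j).

    ``removed[k]`` is the amount withdrawn by the sampling event that
    produced measurement k, and each measurement reflects the closed system
    after its withdrawal; adding the running total of withdrawals therefore
    reconstructs the inventory the system would show had nothing been
    removed. In a closed, non-reacting system the corrected series is
    constant, so any residual trend reflects reaction, not sampling.
    """
    return ChemSeries(
        series.analyte, series.days.copy(),
        series.measured + np.cumsum(series.removed),
        series.removed.copy(),
    )


# ---------------------------------------------------------------------------
# dataset-level loading


def load_dataset(directory: str | Path):
    """Read a directory written by ``slime.simulate.write_dataset``.

    Returns ``(tables, designs, taxonomy, guild_frame)`` where ``tables`` and
    ``designs`` are dicts keyed by experiment id.
    """
    directory = Path(directory)
    meta = read_metadata(directory / "metadata.tsv")
    designs = read_events(directory / "events.tsv", metadata=meta)
    taxonomy = read_taxonomy(directory / "taxonomy.tsv")
    tables = {}
    for exp in sorted(meta["experiment"].unique()):
        table_path = directory / f"feature_table_{exp}.tsv"
        if not table_path.exists():
            raise ParseError(f"missing feature table for experiment {exp!r}: {table_path}")
        tables[exp] = read_feature_table(table_path, metadata=meta, experiment_id=exp)
    guild_frame = pd.read_csv(directory / "guild_table.tsv", sep="\t", dtype=str)
    return tables, designs, taxonomy, guild_frame
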