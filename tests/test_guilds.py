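import dataclasses

import numpy as np
import pandas as pd
import pytest

from slime.guilds import (
    MODULE_BY_GUILD,
    annotate,
    chord_edges,
    core_community,
    guild_table_from_frame,
    guild_trajectory,
    load_guild_table,
)
from slime.io import DataError, assign_timepoints, ExperimentDesign
from slime.simulate import SimConfig, simulate_dataset

from conftest import make_table


@pytest.fixture(scope="module")
def packaged_guilds():
    return load_guild_table()


def test_packaged_table_module_guild_correspondence(packaged_guilds):
    assert packaged_guilds["Methanothermobacter"].guilds == {"methanogenesis"}
    assert "M00567" in packaged_guilds["Methanothermobacter"].kegg_modules
    assert packaged_guilds["Desulfocucumis"].kegg_modules == {"M00596"}
    assert packaged_guilds["Acetobacterium"].kegg_modules == {"M00377"}
    assert packaged_guilds["Rectinema"].kegg_modules == {"FERM"}
    for ann in packaged_guilds.values():
        assert ann.guilds  # nonempty by construction
        assert ann.kegg_modules == {MODULE_BY_GUILD[g] for g in ann.guilds}


def test_annotate_basic_and_partial(packaged_guilds):
    table = make_table("e", [[5, 3, 2]], days=[0], asv_ids=["m1", "f1", "u1"])
    taxonomy = {"m1": "Methanothermobacter", "f1": "Rectinema", "u1": "Candidatus_X"}
    at = annotate(table, taxonomy, packaged_guilds)
    assert at.features.at["m1", "guilds"] == ("methanogenesis",)
    assert at.features.at["f1", "guilds"] == ("fermentation",)
    assert at.features.at["u1", "guilds"] == ()  # genus not in the guild table


def test_annotate_missing_taxonomy_errors(packaged_guilds):
    table = make_table("e", [[1, 1]], days=[0], asv_ids=["a", "b"])
    with pytest.raises(DataError, match="missing from taxonomy"):
        annotate(table, {"a": "Rectinema"}, packaged_guilds)


def test_annotate_empty_guild_table():
    table = make_table("e", [[1, 1]], days=[0], asv_ids=["a", "b"])
    at = annotate(table, {"a": "Rectinema", "b": "Moorella"}, {})
    assert all(at.features["guilds"] == ())


def test_guild_trajectory_fractions(packaged_guilds):
    table = make_table("e", [[5, 5], [2, 6]], days=[-1, 3], asv_ids=["m1", "s1"])
    taxonomy = {"m1": "Methanothermobacter", "s1": "Thermodesulfovibrio"}
    gs = guild_trajectory(annotate(table, taxonomy, packaged_guilds))
    assert gs.fractions.loc[-1, "methanogenesis"] == pytest.approx(0.5)
    assert gs.fractions.loc[-1, "sulfate_reduction"] == pytest.approx(0.5)
    assert gs.fractions.loc[3, "methanogenesis"] == pytest.approx(0.25)
    # single-guild annotations: fractions + unannotated sum to 1 per day
    assert np.allclose(gs.fractions.sum(axis=1), 1.0)


def test_guild_trajectory_single_guild_and_unannotated(packaged_guilds):
    table = make_table("e", [[4, 4]], days=[0], asv_ids=["f1", "u1"])
    gs = guild_trajectory(
        annotate(table, {"f1": "Rectinema", "u1": "Unknownia"}, packaged_guilds)
    )
    assert gs.fractions.loc[0, "fermentation"] == pytest.approx(0.5)
    assert gs.fractions.loc[0, "unannotated"] == pytest.approx(0.5)


def test_guild_trajectory_dual_counting_documented():
    """An ASV with two guilds contributes full weight to each."""
    frame = pd.DataFrame(
        [{"genus": "Bigenus", "guilds": "fermentation;sulfate_reduction",
          "ko_ids": "K1;K2"}]
    )
    gt = guild_table_from_frame(frame)
    table = make_table("e", [[10]], days=[0], asv_ids=["x"])
    gs = guild_trajectory(annotate(table, {"x": "Bigenus"}, gt))
    assert gs.fractions.loc[0, "fermentation"] == pytest.approx(1.0)
    assert gs.fractions.loc[0, "sulfate_reduction"] == pytest.approx(1.0)
    assert "full weight" in gs.overlap_note


def test_hydrogenotroph_boost_raises_their_fraction():
    """With a strong abundance boost, the sulfate-reducer + methanogen share
    of reads increases from Before to the last post-injection sample."""
    base = SimConfig(
        n_experiments=2, shared_experiments=(), shared_pool_fraction=0.0,
        global_pool_size=200, sampling_days=(-1, 3, 8),
        injections=((0,), (0,)), refills=((), ()), h2_percent=(10.0, 10.0),
        fermenter_loss_prob=0.0, hydrogenotroph_boost=10.0, depth=2_000,
    )
    gt = load_guild_table()
    rises = 0
    n = 100
    for seed in range(n):
        ds = simulate_dataset(dataclasses.replace(base, seed=seed))
        for table in ds.tables.values():
            gs = guild_trajectory(annotate(table, ds.taxonomy, gt))
            hydro = gs.fractions["sulfate_reduction"] + gs.fractions["methanogenesis"]
            rises += hydro.iloc[-1] > hydro.iloc[0]
    assert rises >= 0.9 * 2 * n


# ---------------------------------------------------------------------------
# core community


def _annotated_pair(packaged_guilds, counts_a, counts_b, asv_ids):
    taxonomy = {a: "Rectinema" for a in asv_ids}
    ta = make_table("e1", counts_a, days=[-1, 3], asv_ids=asv_ids)
    tb = make_table("e2", counts_b, days=[-1, 3], asv_ids=asv_ids)
    ann = {
        "e1": annotate(ta, taxonomy, packaged_guilds),
        "e2": annotate(tb, taxonomy, packaged_guilds),
    }
    design = {e: ExperimentDesign(e, (0,), (), (-1, 3)) for e in ann}
    assignments = {e: assign_timepoints(ann[e].table, design[e]) for e in ann}
    return ann, assignments


def test_core_single_experiment_is_presence_set(packaged_guilds):
    ann, assignments = _annotated_pair(
        packaged_guilds, [[1, 0, 1], [1, 1, 0]], [[0, 1, 1], [1, 1, 1]], ["a", "b", "c"]
    )
    core = core_community(ann, assignments, "After", scope=["e1"])
    assert set(core["asv_id"]) == {"a", "b"}


def test_core_disjoint_experiments_empty(packaged_guilds):
    ann, assignments = _annotated_pair(
        packaged_guilds, [[1, 1, 0, 0]] * 2, [[0, 0, 1, 1]] * 2, ["a", "b", "c", "d"]
    )
    core = core_community(ann, assignments, "After")
    assert core.empty


def test_core_anti_monotone_in_scope(packaged_guilds):
    ann, assignments = _annotated_pair(
        packaged_guilds, [[1, 1, 1], [1, 1, 0]], [[1, 1, 1], [1, 0, 1]], ["a", "b", "c"]
    )
    small = set(core_community(ann, assignments, "After", scope=["e1"])["asv_id"])
    big = set(core_community(ann, assignments, "After", scope=["e1", "e2"])["asv_id"])
    assert big <= small


def test_core_missing_category_errors(packaged_guilds):
    ann, assignments = _annotated_pair(
        packaged_guilds, [[1, 1], [1, 1]], [[1, 1], [1, 1]], ["a", "b"]
    )
    assignments["e2"] = [t for t in assignments["e2"] if t.category != "After"]
    with pytest.raises(DataError, match="no sample for category"):
        core_community(ann, assignments, "After")


def test_engineered_shared_core_is_recovered(default_dataset):
    """The designated experiments share their engineered core at matched times."""
    from slime.guilds import annotate as _annotate

    gt = guild_table_from_frame(default_dataset.guild_frame)
    shared = default_dataset.truth["shared_experiments"]
    ann = {
        e: _annotate(default_dataset.tables[e], default_dataset.taxonomy, gt)
        for e in shared
    }
    assignments = {
        e: assign_timepoints(default_dataset.tables[e], default_dataset.designs[e])
        for e in shared
    }
    core = core_community(ann, assignments, "Before", scope=shared)
    cfg = default_dataset.config
    min_richness = min(
        len(default_dataset.tables[e].presence(t.sample_id))
        for e in shared
        for t in assignments[e]
        if t.category == "Before"
    )
    # all designated samples hold a prefix of the same core ranking
    assert len(core) >= 0.8 * cfg.shared_pool_fraction * min_richness


# ---------------------------------------------------------------------------
# chord edges


def test_chord_edges_minimal(packaged_guilds):
    frame = pd.DataFrame([{"genus": "Solo", "guilds": "methanogenesis", "ko_ids": "K1"}])
    gt = guild_table_from_frame(frame)
    table = make_table("e", [[7]], days=[0], asv_ids=["x"])
    edges = chord_edges(annotate(table, {"x": "Solo"}, gt))
    assert len(edges) == 1
    assert edges.loc[0, "weight"] == pytest.approx(1.0)


def test_chord_edges_product_count():
    """One methanogen with 3 KOs + one fermenter with 2 KOs, 2 days -> 10 edges."""
    frame = pd.DataFrame(
        [
            {"genus": "Metha", "guilds": "methanogenesis", "ko_ids": "K1;K2;K3"},
            {"genus": "Fermi", "guilds": "fermentation", "ko_ids": "K4;K5"},
        ]
    )
    gt = guild_table_from_frame(frame)
    table = make_table("e", [[3, 5], [2, 8]], days=[-1, 3], asv_ids=["m", "f"])
    edges = chord_edges(annotate(table, {"m": "Metha", "f": "Fermi"}, gt))
    assert len(edges) == 10


def test_chord_edges_presence_gating_and_weight_fanout():
    frame = pd.DataFrame([{"genus": "G", "guilds": "fermentation", "ko_ids": "K1;K2"}])
    gt = guild_table_from_frame(frame)
    table = make_table("e", [[4, 4], [6, 0]], days=[-1, 3], asv_ids=["a", "b"])
    edges = chord_edges(annotate(table, {"a": "G", "b": "G"}, gt))
    # b absent on day 3: no edge there
    assert not ((edges["asv_id"] == "b") & (edges["day"] == 3)).any()
    # per (ASV, timepoint) all KO edges carry the same weight
    for (_, _), grp in edges.groupby(["asv_id", "timepoint"]):
        assert grp["weight"].nunique() == 1
    # within genus, ordered by decreasing abundance at each timepoint
    day3 = edges[edges["day"] == 3]
    assert (day3["asv_id"] == "a").all()
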