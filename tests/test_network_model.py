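"""Attribute coding, network construction and tabular round-trips."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from egosmoke import (
    Alter,
    Ego,
    EgoNetwork,
    SmokingStatus3,
    dichotomize,
    read_networks,
    recode_smoking,
    to_graphml,
    write_networks,
)
from egosmoke.network_model import RAW_SMOKING_LEVELS

from conftest import make_network


@pytest.mark.parametrize("raw, expected", [
    ("smoker", SmokingStatus3.SMOKER),
    ("occasional_smoker", SmokingStatus3.SMOKER),
    ("former_smoker", SmokingStatus3.FORMER),
    ("non_smoker", SmokingStatus3.NONSMOKER),
    ("never_smoker", SmokingStatus3.NONSMOKER),
    (None, None),
    ("NA", None),
])
def test_recode_smoking_collapses_five_levels_to_three(raw, expected):
    assert recode_smoking(raw) is expected


def test_recode_smoking_rejects_unknown_level_naming_it():
    with pytest.raises(ValueError, match="vaper"):
        recode_smoking("vaper")


@pytest.mark.parametrize("raw", sorted(RAW_SMOKING_LEVELS))
def test_dichotomized_outcomes_partition(raw):
    status = recode_smoking(raw)
    indicators = [dichotomize(status, c) for c in SmokingStatus3]
    assert sum(indicators) == 1
    assert dichotomize(status, status) == 1


def test_network_invariants_rejected():
    with pytest.raises(ValueError, match="self-tie|malformed"):
        make_network(3, edges=[(0, 0)])
    with pytest.raises(ValueError, match="not alters"):
        EgoNetwork(ego=Ego(ego_id="e0"),
                   alters=[Alter(alter_id="a00")],
                   ties={frozenset(("a00", "ghost"))})
    with pytest.raises(ValueError, match="duplicate"):
        EgoNetwork(ego=Ego(ego_id="e0"),
                   alters=[Alter(alter_id="a00"), Alter(alter_id="a00")])
    with pytest.raises(ValueError, match="age"):
        Ego(ego_id="e0", age=12)


def test_isolates_are_retained_on_load(tmp_path):
    net = make_network(3, edges=[(0, 1)])
    write_networks([net], tmp_path / "ego.csv", tmp_path / "alter.csv",
                   tmp_path / "tie.csv")
    (back,) = read_networks(tmp_path / "ego.csv", tmp_path / "alter.csv",
                            tmp_path / "tie.csv")
    assert back.n_alters == 3
    assert back.neighbours("a02") == []


def test_dangling_tie_endpoint_names_ego_and_alter(tmp_path):
    net = make_network(2, edges=[(0, 1)])
    write_networks([net], tmp_path / "ego.csv", tmp_path / "alter.csv",
                   tmp_path / "tie.csv")
    (tmp_path / "tie.csv").write_text("ego_id,source,target\ne0,a00,zz\n")
    with pytest.raises(ValueError, match="e0.*'zz'"):
        read_networks(tmp_path / "ego.csv", tmp_path / "alter.csv",
                      tmp_path / "tie.csv")


def test_empty_population_round_trips_to_header_only_tables(tmp_path):
    write_networks([], tmp_path / "ego.csv", tmp_path / "alter.csv",
                   tmp_path / "tie.csv")
    assert read_networks(tmp_path / "ego.csv", tmp_path / "alter.csv",
                         tmp_path / "tie.csv") == []
    assert (tmp_path / "tie.csv").read_text().strip() == "ego_id,source,target"


@settings(max_examples=25, deadline=None, derandomize=True)
@given(data=st.data())
def test_round_trip_is_identity_on_modelled_fields(tmp_path_factory, data):
    """write -> read preserves every modelled field of arbitrary networks."""
    raw_levels = sorted(RAW_SMOKING_LEVELS) + [None]
    networks = []
    for e in range(data.draw(st.integers(1, 3))):
        n = data.draw(st.integers(1, 6))
        alters = [
            Alter(
                alter_id=f"a{i:02d}",
                sex=data.draw(st.sampled_from([0, 1, None])),
                age=data.draw(st.sampled_from([18.0, 40.0, 95.0, None])),
                education=data.draw(st.sampled_from([0, 1, None])),
                marital=data.draw(st.sampled_from([0, 1, None])),
                smoking_raw=data.draw(st.sampled_from(raw_levels)),
                tie_type=data.draw(st.sampled_from(
                    ["family", "close_friend", "simple_friend",
                     "acquaintance", None])),
                meet_weekly=data.draw(st.sampled_from([0, 1, None])),
            ) for i in range(n)
        ]
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        edges = [p for p in pairs if data.draw(st.booleans())]
        networks.append(EgoNetwork(
            ego=Ego(ego_id=f"e{e}", sex=data.draw(st.sampled_from([0, 1])),
                    age=50.0, smoking_raw=data.draw(st.sampled_from(raw_levels))),
            alters=alters,
            ties={frozenset((f"a{i:02d}", f"a{j:02d}")) for i, j in edges},
        ))
    out = tmp_path_factory.mktemp("rt")
    paths = (out / "ego.csv", out / "alter.csv", out / "tie.csv")
    write_networks(networks, *paths)
    back = read_networks(*paths)
    assert len(back) == len(networks)
    for orig, copy in zip(sorted(networks, key=lambda x: x.ego.ego_id), back):
        assert copy.ego == orig.ego
        assert sorted(copy.alters, key=lambda a: a.alter_id) == \
            sorted(orig.alters, key=lambda a: a.alter_id)
        assert copy.ties == orig.ties


def test_population_round_trip_lossless(tmp_path):
    """A full synthetic population survives write -> read unchanged."""
    from egosmoke import generate_population

    networks, _ = generate_population(seed=3)
    paths = (tmp_path / "ego.csv", tmp_path / "alter.csv", tmp_path / "tie.csv")
    write_networks(networks, *paths)
    back = read_networks(*paths)
    assert len(back) == len(networks)
    by_id = {n.ego.ego_id: n for n in back}
    for orig in networks:
        copy = by_id[orig.ego.ego_id]
        assert copy.ego == orig.ego
        assert copy.alters == orig.alters
        assert copy.ties == orig.ties


def test_graphml_export_has_all_nodes_and_edges(tmp_path):
    import networkx as nx

    net = make_network(3, edges=[(0, 1)], statuses=["smoker"] * 3)
    to_graphml(net, tmp_path / "net.graphml")
    g = nx.read_graphml(tmp_path / "net.graphml")
    assert g.number_of_nodes() == 3
    assert g.number_of_edges() == 1
    assert g.nodes["a00"]["smoking"] == "SMOKER"
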