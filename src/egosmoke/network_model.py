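"""Domain types for personal (ego-centred) networks and their tabular I/O.

A personal network consists of a focal respondent (the *ego*), the social
contacts the ego nominates (*alters*), and the undirected ties the ego
reports among those alters.  The ego itself is deliberately excluded from
the alter–alter graph: by construction the ego is connected to every alter,
so including it would saturate density and centralization.

Attribute coding follows the study conventions: binary sex (0 male,
1 female), education (1 = university degree), employment (1 = employed;
retired counts as unemployed), marital status (1 = in a relationship,
married included), and a five-level raw smoking status that is collapsed to
three analysis categories (smoker / former smoker / non-smoker).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SmokingStatusRaw",
    "SmokingStatus3",
    "Ego",
    "Alter",
    "EgoNetwork",
    "TIE_TYPES",
    "MISSING",
    "recode_smoking",
    "dichotomize",
    "read_networks",
    "write_networks",
    "to_graphml",
]

#: Sentinel used in tables for missing values. Never silently zero.
MISSING = "NA"

#: Raw five-level smoking answers, as asked of both egos and alters.
RAW_SMOKING_LEVELS = frozenset(
    {"smoker", "occasional_smoker", "former_smoker", "non_smoker", "never_smoker"}
)

#: The four ego–alter relationship types.
TIE_TYPES = ("family", "close_friend", "simple_friend", "acquaintance")


class SmokingStatusRaw(str, enum.Enum):
    SMOKER = "smoker"
    OCCASIONAL_SMOKER = "occasional_smoker"
    FORMER_SMOKER = "former_smoker"
    NON_SMOKER = "non_smoker"
    NEVER_SMOKER = "never_smoker"


class SmokingStatus3(str, enum.Enum):
    """Three-category analysis coding of smoking status."""

    SMOKER = "SMOKER"
    FORMER = "FORMER"
    NONSMOKER = "NONSMOKER"


_RECODE = {
    SmokingStatusRaw.SMOKER: SmokingStatus3.SMOKER,
    SmokingStatusRaw.OCCASIONAL_SMOKER: SmokingStatus3.SMOKER,
    SmokingStatusRaw.FORMER_SMOKER: SmokingStatus3.FORMER,
    SmokingStatusRaw.NON_SMOKER: SmokingStatus3.NONSMOKER,
    SmokingStatusRaw.NEVER_SMOKER: SmokingStatus3.NONSMOKER,
}


def recode_smoking(raw: SmokingStatusRaw | str | None) -> SmokingStatus3 | None:
    """Collapse the five raw smoking levels to the three analysis categories.

    Regular and occasional smokers become SMOKER; non-smokers and never
    smokers become NONSMOKER; former smokers stay FORMER.  Missing (None)
    propagates.  Unknown tokens raise ``ValueError`` naming the value.
    """
    if raw is None:
        return None
    if isinstance(raw, str):
        if raw == MISSING:
            return None
        try:
            raw = SmokingStatusRaw(raw)
        except ValueError:
            raise ValueError(f"unknown smoking status level: {raw!r}") from None
    return _RECODE[raw]


def dichotomize(status: SmokingStatus3, category: SmokingStatus3) -> int:
    """Binary indicator: 1 iff ``status`` equals ``category``.

    Each of the three categories yields one 0/1 outcome; for any observed
    status the three indicators partition (sum to 1).
    """
    if status is None:
        raise ValueError("cannot dichotomize a missing smoking status")
    return int(SmokingStatus3(status) is SmokingStatus3(category))


def _check_binary(value: int | None, name: str) -> int | None:
    if value is None:
        return None
    if value not in (0, 1):
        raise ValueError(f"{name} must be 0 or 1, got {value!r}")
    return int(value)


@dataclass
class Ego:
    """The focal respondent of one personal network (level-2 unit)."""

    ego_id: str
    sex: int | None = None  # 0 male, 1 female
    age: float | None = None  # years, >= 18
    education: int | None = None  # 1 = university degree
    employment: int | None = None  # 1 = employed (retired -> 0)
    marital: int | None = None  # 1 = in a relationship (incl. married)
    smoking_raw: SmokingStatusRaw | None = None
    # Carried, never modelled:
    medical_condition: int | None = None
    sports: int | None = None
    family_cancer_cvd: int | None = None

    def __post_init__(self) -> None:
        for f in ("sex", "education", "employment", "marital",
                  "medical_condition", "sports", "family_cancer_cvd"):
            setattr(self, f, _check_binary(getattr(self, f), f))
        if self.age is not None and self.age < 18:
            raise ValueError(f"ego {self.ego_id}: age must be >= 18, got {self.age}")
        if isinstance(self.smoking_raw, str):
            self.smoking_raw = (None if self.smoking_raw == MISSING
                                else SmokingStatusRaw(self.smoking_raw))

    @property
    def smoking(self) -> SmokingStatus3 | None:
        return recode_smoking(self.smoking_raw)


@dataclass
class Alter:
    """One nominated contact of an ego (level-1 unit).

    ``alter_id`` is scoped to its ego: the same person nominated by two egos
    is two distinct records.
    """

    alter_id: str
    sex: int | None = None
    age: float | None = None
    education: int | None = None
    marital: int | None = None
    smoking_raw: SmokingStatusRaw | None = None
    tie_type: str | None = None  # one of TIE_TYPES
    meet_weekly: int | None = None  # 1 = meets ego at least weekly
    closeness: int | None = None  # ordinal, carried only

    def __post_init__(self) -> None:
        for f in ("sex", "education", "marital", "meet_weekly"):
            setattr(self, f, _check_binary(getattr(self, f), f))
        if self.tie_type is not None and self.tie_type not in TIE_TYPES:
            raise ValueError(
                f"alter {self.alter_id}: tie_type must be one of {TIE_TYPES}, "
                f"got {self.tie_type!r}"
            )
        if isinstance(self.smoking_raw, str):
            self.smoking_raw = (None if self.smoking_raw == MISSING
                                else SmokingStatusRaw(self.smoking_raw))

    @property
    def smoking(self) -> SmokingStatus3 | None:
        return recode_smoking(self.smoking_raw)


@dataclass
class EgoNetwork:
    """One ego, its alters, and the undirected alter–alter tie set."""

    ego: Ego
    alters: list[Alter] = field(default_factory=list)
    ties: set[frozenset[str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [a.alter_id for a in self.alters]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(
                f"ego {self.ego.ego_id}: duplicate alter ids {sorted(dupes)}"
            )
        id_set = set(ids)
        norm: set[frozenset[str]] = set()
        for tie in self.ties:
            pair = frozenset(tie)
            if len(pair) != 2:
                raise ValueError(
                    f"ego {self.ego.ego_id}: self-tie or malformed tie {set(tie)}"
                )
            missing = pair - id_set
            if missing:
                raise ValueError(
                    f"ego {self.ego.ego_id}: tie endpoint(s) {sorted(missing)} "
                    "are not alters of this ego"
                )
            if self.ego.ego_id in pair:
                raise ValueError(
                    f"ego {self.ego.ego_id}: the ego cannot be a tie endpoint"
                )
            norm.add(pair)
        self.ties = norm

    @property
    def n_alters(self) -> int:
        return len(self.alters)

    def alter(self, alter_id: str) -> Alter:
        for a in self.alters:
            if a.alter_id == alter_id:
                return a
        raise KeyError(f"ego {self.ego.ego_id} has no alter {alter_id!r}")

    def neighbours(self, alter_id: str) -> list[str]:
        """Alter ids tied to ``alter_id``, in stable (insertion) order."""
        self.alter(alter_id)  # membership check
        nbrs = {next(iter(t - {alter_id})) for t in self.ties if alter_id in t}
        return [a.alter_id for a in self.alters if a.alter_id in nbrs]

    def graph(self) -> nx.Graph:
        """The alter–alter graph (ego excluded), isolates included."""
        g = nx.Graph()
        g.add_nodes_from(a.alter_id for a in self.alters)
        g.add_edges_from(tuple(sorted(t)) for t in self.ties)
        return g


# ---------------------------------------------------------------------------
# Tabular I/O: three delimiter-separated tables with fixed headers.
# ---------------------------------------------------------------------------

EGO_COLUMNS = [
    "ego_id", "sex", "age", "education", "employment", "marital",
    "smoking_raw", "medical_condition", "sports", "family_cancer_cvd",
]
ALTER_COLUMNS = [
    "ego_id", "alter_id", "sex", "age", "education", "marital",
    "smoking_raw", "tie_type", "meet_weekly", "closeness",
]
TIE_COLUMNS = ["ego_id", "source", "target"]

_INT_FIELDS = {
    "sex", "education", "employment", "marital", "meet_weekly",
    "closeness", "medical_condition", "sports", "family_cancer_cvd",
}


def _cell(value):
    if value is None:
        return MISSING
    if isinstance(value, enum.Enum):
        return value.value
    return value


def _parse(row: Mapping[str, object], key: str):
    v = row.get(key)
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == MISSING:
        return None
    if key in _INT_FIELDS:
        return int(v)
    if key == "age":
        return float(v)
    return v


def write_networks(
    networks: Iterable[EgoNetwork],
    ego_path: str | Path,
    alter_path: str | Path,
    tie_path: str | Path,
    sep: str = ",",
) -> None:
    """Write a population to the three standard tables.

    Lossless for all modelled fields; rows are sorted by (ego_id, alter_id)
    and ties by (ego_id, source, target) so output is reproducible.
    """
    ego_rows, alter_rows, tie_rows = [], [], []
    for net in networks:
        e = net.ego
        ego_rows.append({c: _cell(getattr(e, c)) for c in EGO_COLUMNS})
        for a in net.alters:
            row = {c: _cell(getattr(a, c, None)) for c in ALTER_COLUMNS}
            row["ego_id"] = e.ego_id
            alter_rows.append(row)
        for t in sorted(tuple(sorted(p)) for p in net.ties):
            tie_rows.append({"ego_id": e.ego_id, "source": t[0], "target": t[1]})

    ego_df = pd.DataFrame(ego_rows, columns=EGO_COLUMNS)
    alter_df = pd.DataFrame(alter_rows, columns=ALTER_COLUMNS)
    tie_df = pd.DataFrame(tie_rows, columns=TIE_COLUMNS)
    if len(ego_df):
        ego_df = ego_df.sort_values("ego_id", kind="stable")
        alter_df = alter_df.sort_values(["ego_id", "alter_id"], kind="stable")
        tie_df = tie_df.sort_values(TIE_COLUMNS, kind="stable")
    for df, path in ((ego_df, ego_path), (alter_df, alter_path), (tie_df, tie_path)):
        df.to_csv(path, sep=sep, index=False, na_rep=MISSING)


def read_networks(
    ego_path: str | Path,
    alter_path: str | Path,
    tie_path: str | Path,
    sep: str = ",",
) -> list[EgoNetwork]:
    """Load a population from the three standard tables.

    Every tie endpoint must resolve to an alter of the same ego; alters with
    no ties are retained as isolates.  Dangling endpoints and duplicate alter
    ids raise ``ValueError`` naming the offending ego and alter.
    """
    ego_df = pd.read_csv(ego_path, sep=sep, dtype=str, keep_default_na=False)
    alter_df = pd.read_csv(alter_path, sep=sep, dtype=str, keep_default_na=False)
    tie_df = pd.read_csv(tie_path, sep=sep, dtype=str, keep_default_na=False)

    networks: list[EgoNetwork] = []
    alters_by_ego = dict(tuple(alter_df.groupby("ego_id", sort=False))) if len(alter_df) else {}
    ties_by_ego = dict(tuple(tie_df.groupby("ego_id", sort=False))) if len(tie_df) else {}

    for _, erow in ego_df.iterrows():
        ego = Ego(**{c: _parse(erow, c) for c in EGO_COLUMNS})
        alters = []
        sub = alters_by_ego.get(ego.ego_id)
        if sub is not None:
            for _, arow in sub.iterrows():
                kwargs = {c: _parse(arow, c) for c in ALTER_COLUMNS if c != "ego_id"}
                alters.append(Alter(**kwargs))
        ties: set[frozenset[str]] = set()
        tsub = ties_by_ego.get(ego.ego_id)
        if tsub is not None:
            known = {a.alter_id for a in alters}
            for _, trow in tsub.iterrows():
                s, t = trow["source"], trow["target"]
                if s == t:
                    raise ValueError(f"ego {ego.ego_id}: self-tie on alter {s!r}")
                for end in (s, t):
                    if end not in known:
                        raise ValueError(
                            f"ego {ego.ego_id}: tie endpoint {end!r} is not a "
                            "known alter"
                        )
                ties.add(frozenset((s, t)))
        networks.append(EgoNetwork(ego=ego, alters=alters, ties=ties))

    orphan_egos = set(alters_by_ego) - {n.ego.ego_id for n in networks}
    if orphan_egos:
        raise ValueError(f"alter rows reference unknown ego ids: {sorted(orphan_egos)}")
    return networks


def to_graphml(net: EgoNetwork, path: str | Path) -> None:
    """Export one alter–alter graph as GraphML with node attributes."""
    g = net.graph()
    for a in net.alters:
        node = g.nodes[a.alter_id]
        node["smoking"] = a.smoking.value if a.smoking else MISSING
        node["sex"] = a.sex if a.sex is not None else -1
        node["tie_type"] = a.tie_type or MISSING
    nx.write_graphml(g, path)
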