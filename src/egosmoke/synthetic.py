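"""Synthetic ego-network populations with planted smoking homophily.

The generator emulates the marginal structure of a field study of 76
personal networks from a rural community (about 22–25 alters per ego,
1681 alters in total): three-category smoking prevalences for egos
(26.3/31.6/42.1% smoker/former/non-smoker) and alters (27.1/11.3/61.6%),
sex/age/education/marital/employment marginals, a tie-type mix dominated
by family members, and multi-component alter–alter graphs (median two
components, mean density around 0.3).

Structure is produced by a planted-partition scheme: each ego's alters are
split into clusters (one designated the *family* cluster), wired densely
within clusters (``p_in``) and sparsely between (``p_out``).  Homophily is
planted at the cluster level: every cluster has a modal smoking status, and
each member copies it with probability ``h`` (drawing from the marginal
prevalence otherwise).  ``h = 0`` gives statuses independent of structure;
``h = 1`` with ``p_out = 0`` gives status-homogeneous components.  The
family cluster's modal status is tilted toward the ego's own status with
the same strength ``h``, so family-member-smoker indicators carry signal.
Configured ego-effect odds ratios (family-member smoker, female sex) are
injected through a mean-centred logistic tilt of the smoker category, which
preserves the marginal prevalences while creating covariate effects.

Covariates are drawn independently of each other except where a configured
effect links them; real data would carry richer joint structure (age ×
smoking, sex × tie type) that the generator does not attempt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assortativity import alter_assortativity
from .metrics import count_components, degree_centralization, density, network_metrics
from .network_model import (
    Alter,
    Ego,
    EgoNetwork,
    SmokingStatus3,
    SmokingStatusRaw,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_population",
    "generate_regression_population",
    "planted_assortativity_scores",
    "summarize_population",
]

_CATS = (SmokingStatus3.SMOKER, SmokingStatus3.FORMER, SmokingStatus3.NONSMOKER)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults reproduce the study's marginals."""

    n_egos: int = 76
    alters_min: int = 20
    alters_max: int = 25
    # (smoker, former, non-smoker)
    ego_smoking_prev: tuple[float, float, float] = (0.263, 0.316, 0.421)
    alter_smoking_prev: tuple[float, float, float] = (0.271, 0.113, 0.616)
    ego_p_female: float = 0.500
    alter_p_female: float = 0.527
    ego_p_degree: float = 0.421
    alter_p_degree: float = 0.370  # plus explicit missing share below
    alter_p_edu_missing: float = 0.035
    ego_p_employed: float = 0.526
    ego_p_relationship: float = 0.868
    alter_p_relationship: float = 0.801
    p_meet_weekly: float = 0.564
    ego_age_mean: float = 54.0
    alter_age_mean: float = 52.0
    age_sd: float = 16.1
    age_min: float = 18.0
    age_max: float = 95.0
    # family / close friend / simple friend / acquaintance
    tie_type_probs: tuple[float, float, float, float] = (0.49, 0.21, 0.21, 0.09)
    cluster_rate: float = 1.5  # clusters per ego: 1 + Poisson(rate)
    p_in: float = 0.55
    p_out: float = 0.02
    homophily: float = 0.3  # h in [0, 1]
    or_family_smoker: float = 2.5
    or_female_smoker: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        for name, prev in (("ego_smoking_prev", self.ego_smoking_prev),
                           ("alter_smoking_prev", self.alter_smoking_prev)):
            if len(prev) != 3 or any(p < 0 for p in prev) or abs(sum(prev) - 1) > 1e-6:
                raise ValueError(f"{name} must be 3 non-negative values summing to 1")
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not 0 <= self.homophily <= 1:
            raise ValueError("homophily must lie in [0, 1]")
        if not 1 <= self.alters_min <= self.alters_max:
            raise ValueError("need 1 <= alters_min <= alters_max")
        if self.n_egos < 1:
            raise ValueError("n_egos must be >= 1")


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    homophily: float
    cluster_of: dict[tuple[str, str], int]  # (ego_id, alter_id) -> cluster
    modal_status: dict[tuple[str, int], SmokingStatus3]  # (ego_id, cluster)
    coefficients: dict[str, float] = field(default_factory=dict)


def _trunc_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    while True:
        bad = (x < lo) | (x > hi)
        if not bad.any():
            return np.round(x)
        x[bad] = rng.normal(mean, sd, bad.sum())


def _raw_status(rng, status: SmokingStatus3) -> SmokingStatusRaw:
    # Spread the three analysis categories over the five raw answers so the
    # recoding path is exercised end to end.
    if status is SmokingStatus3.SMOKER:
        return (SmokingStatusRaw.SMOKER if rng.random() < 0.8
                else SmokingStatusRaw.OCCASIONAL_SMOKER)
    if status is SmokingStatus3.FORMER:
        return SmokingStatusRaw.FORMER_SMOKER
    return (SmokingStatusRaw.NON_SMOKER if rng.random() < 0.5
            else SmokingStatusRaw.NEVER_SMOKER)


def generate_population(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[list[EgoNetwork], GroundTruth]:
    """Draw a population of ego networks; deterministic given (config, seed)."""
    config = config or SyntheticConfig()
    config.validate()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    prev = np.array(config.alter_smoking_prev)
    h = config.homophily

    truth = GroundTruth(homophily=h, cluster_of={}, modal_status={},
                        coefficients={
                            "log_or_family_smoker": math.log(config.or_family_smoker),
                            "log_or_female_smoker": math.log(config.or_female_smoker),
                        })

    # Pass 1: draw everything except final alter statuses, accumulating the
    # covariate log-odds tilts so they can be mean-centred before use.
    plans = []
    deltas = []
    for i in range(config.n_egos):
        ego_id = f"e{i:03d}"
        ego_status = _CATS[rng.choice(3, p=config.ego_smoking_prev)]
        ego = Ego(
            ego_id=ego_id,
            sex=int(rng.random() < config.ego_p_female),
            age=float(_trunc_normal(rng, config.ego_age_mean, config.age_sd,
                                    config.age_min, config.age_max, 1)[0]),
            education=int(rng.random() < config.ego_p_degree),
            employment=int(rng.random() < config.ego_p_employed),
            marital=int(rng.random() < config.ego_p_relationship),
            smoking_raw=_raw_status(rng, ego_status),
        )
        n = int(rng.integers(config.alters_min, config.alters_max + 1))
        k = min(1 + int(rng.poisson(config.cluster_rate)), n)
        clusters = rng.integers(0, k, n)

        # Cluster 0 is the family cluster; its modal status leans toward the
        # ego's own status with strength h.
        modal = {}
        for c in range(k):
            if c == 0 and rng.random() < h:
                modal[c] = ego_status
            else:
                modal[c] = _CATS[rng.choice(3, p=prev)]
            truth.modal_status[(ego_id, c)] = modal[c]

        other = np.array(config.tie_type_probs[1:])
        other = other / other.sum()
        alter_rows = []
        for j in range(n):
            aid = f"a{j:02d}"
            truth.cluster_of[(ego_id, aid)] = int(clusters[j])
            tie = ("family" if clusters[j] == 0 else
                   ("close_friend", "simple_friend", "acquaintance")[
                       rng.choice(3, p=other)])
            sex = int(rng.random() < config.alter_p_female)
            edu_draw = rng.random()
            if edu_draw < config.alter_p_edu_missing:
                edu = None
            else:
                edu = int(rng.random() < config.alter_p_degree
                          / (1 - config.alter_p_edu_missing))
            alter_rows.append(dict(
                alter_id=aid, sex=sex,
                age=float(_trunc_normal(rng, config.alter_age_mean, config.age_sd,
                                        config.age_min, config.age_max, 1)[0]),
                education=edu,
                marital=int(rng.random() < config.alter_p_relationship),
                tie_type=tie,
                meet_weekly=int(rng.random() < config.p_meet_weekly),
                closeness=int(rng.integers(1, 6)),
            ))
            delta = 0.0
            if tie == "family" and ego_status is SmokingStatus3.SMOKER:
                delta += truth.coefficients["log_or_family_smoker"]
            if sex == 1:
                delta += truth.coefficients["log_or_female_smoker"]
            deltas.append(delta)

        # Ties: planted partition wiring.
        ties = set()
        for a in range(n):
            for b in range(a + 1, n):
                p = config.p_in if clusters[a] == clusters[b] else config.p_out
                if rng.random() < p:
                    ties.add(frozenset((f"a{a:02d}", f"a{b:02d}")))
        plans.append((ego, alter_rows, clusters, modal, ties))

    delta_mean = float(np.mean(deltas)) if deltas else 0.0

    # Pass 2: draw statuses from the cluster-tilted, covariate-tilted mix.
    networks = []
    di = 0
    for ego, alter_rows, clusters, modal, ties in plans:
        alters = []
        for j, row in enumerate(alter_rows):
            p = (1 - h) * prev + h * np.eye(3)[_CATS.index(modal[int(clusters[j])])]
            ps = p[0]
            if 0 < ps < 1:  # logistic tilt of the smoker category
                odds = ps / (1 - ps) * math.exp(deltas[di] - delta_mean)
                ps_new = odds / (1 + odds)
                scale = (1 - ps_new) / (1 - ps)
                p = np.array([ps_new, p[1] * scale, p[2] * scale])
            status = _CATS[rng.choice(3, p=p)]
            alters.append(Alter(smoking_raw=_raw_status(rng, status), **row))
            di += 1
        networks.append(EgoNetwork(ego=ego, alters=alters, ties=ties))
    return networks, truth


def planted_assortativity_scores(
    networks: list[EgoNetwork], truth: GroundTruth
) -> list[float]:
    """Each alter's assortativity for its own cluster's planted category.

    Undefined scores (isolates) are omitted.  The mean of these scores is
    the natural summary of how much structure the homophily parameter h
    actually induced: about 0 at h = 0, increasing in h.
    """
    out = []
    for net in networks:
        for a in net.alters:
            cat = truth.modal_status[
                (net.ego.ego_id, truth.cluster_of[(net.ego.ego_id, a.alter_id)])]
            s = alter_assortativity(net, a.alter_id, cat)
            if s.defined:
                out.append(s.score)
    return out


def generate_regression_population(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
    log_or_assort: float = math.log(3.0),
    intercept: float = -1.0,
    sigma_u: float = 0.7,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Population with a known logistic effect of the assortativity score.

    Two-stage design: networks and statuses are generated first, the
    smoker-assortativity covariate is computed from them, and then a fresh
    binary outcome is drawn from the two-level logistic model

        y_ij ~ Bernoulli( logit^-1( b0 + b1 * assort_ij + u_j ) ),
        u_j ~ Normal(0, sigma_u^2)

    so a random-intercept logistic fit of ``y ~ assort`` is correctly
    specified and maximum likelihood should recover ``b1``.  Alters with an
    undefined score (isolates) are dropped.  Returns the model-ready frame
    (ego_id, alter_id, assort, y) and the true parameter values.
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    networks, _ = generate_population(config)
    rng = np.random.default_rng(config.seed + 1_000_003)

    rows = []
    for net in networks:
        u = rng.normal(0.0, sigma_u)
        for a in net.alters:
            s = alter_assortativity(net, a.alter_id, SmokingStatus3.SMOKER)
            if not s.defined:
                continue
            eta = intercept + log_or_assort * s.score + u
            rows.append(dict(ego_id=net.ego.ego_id, alter_id=a.alter_id,
                             assort=s.score,
                             y=int(rng.random() < 1 / (1 + math.exp(-eta)))))
    frame = pd.DataFrame(rows)
    return frame, {"intercept": intercept, "log_or_assort": log_or_assort,
                   "sigma_u": sigma_u}


def _freq(values, level) -> tuple[int, float]:
    obs = [v for v in values if v is not None]
    n = sum(v == level for v in obs)
    return n, 100.0 * n / len(values) if values else float("nan")


def summarize_population(networks: list[EgoNetwork]) -> pd.DataFrame:
    """Descriptive table of ego, alter and structural characteristics.

    One row per characteristic with columns for the ego side (n = number of
    egos) and the alter side (n = total alters), mirroring how personal-
    network studies report their sample.
    """
    if not networks:
        raise ValueError("cannot summarize an empty population")
    egos = [n.ego for n in networks]
    alters = [a for n in networks for a in n.alters]
    mets = [network_metrics(n) for n in networks]

    def agg(vals):
        v = np.array([x for x in vals if x is not None], dtype=float)
        return (f"{v.mean():.2f} ({v.std(ddof=1):.2f})" if v.size > 1
                else f"{v.mean():.2f} (—)" if v.size else "—")

    rows = []

    def add(label, ego_val, alter_val):
        rows.append({"characteristic": label, "ego": ego_val, "alter": alter_val})

    add("n", len(egos), len(alters))
    add("age mean (sd)", agg([e.age for e in egos]), agg([a.age for a in alters]))
    add("age median", float(np.median([e.age for e in egos if e.age is not None])),
        float(np.median([a.age for a in alters if a.age is not None])))
    for cat, label in ((SmokingStatus3.SMOKER, "smokers"),
                       (SmokingStatus3.FORMER, "former smokers"),
                       (SmokingStatus3.NONSMOKER, "non-smokers")):
        en, ep = _freq([e.smoking for e in egos], cat)
        an, ap = _freq([a.smoking for a in alters], cat)
        add(f"smoking: {label} n (%)", f"{en} ({ep:.1f}%)", f"{an} ({ap:.1f}%)")
    for lv, label in ((0, "male"), (1, "female")):
        en, ep = _freq([e.sex for e in egos], lv)
        an, ap = _freq([a.sex for a in alters], lv)
        add(f"sex: {label} n (%)", f"{en} ({ep:.1f}%)", f"{an} ({ap:.1f}%)")
    en, ep = _freq([e.education for e in egos], 1)
    an, ap = _freq([a.education for a in alters], 1)
    add("university degree n (%)", f"{en} ({ep:.1f}%)", f"{an} ({ap:.1f}%)")
    an = sum(a.education is None for a in alters)
    add("education missing n (%)", "0 (0.0%)",
        f"{an} ({100.0 * an / len(alters):.1f}%)")
    en, ep = _freq([e.employment for e in egos], 1)
    add("employed n (%)", f"{en} ({ep:.1f}%)", "—")
    en, ep = _freq([e.marital for e in egos], 1)
    an, ap = _freq([a.marital for a in alters], 1)
    add("in a relationship n (%)", f"{en} ({ep:.1f}%)", f"{an} ({ap:.1f}%)")
    an, ap = _freq([a.meet_weekly for a in alters], 1)
    add("meets ego at least weekly n (%)", "—", f"{an} ({ap:.1f}%)")

    comp = [m.n_components for m in mets]
    add("mean components (sd)", agg(comp), "—")
    add("median components", float(np.median(comp)), "—")
    add("mean degree centralization (sd)",
        agg([m.degree_centralization for m in mets]), "—")
    add("mean density (sd)", agg([m.density for m in mets]), "—")
    add("mean alter degree, normalized (sd)", "—",
        agg([d for m in mets for d in m.degree_norm.values()]))
    add("mean alter betweenness, normalized (sd)", "—",
        agg([b for m in mets for b in m.betweenness_norm.values()]))
    return pd.DataFrame(rows, columns=["characteristic", "ego", "alter"])
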