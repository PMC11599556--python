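"""End-to-end orchestration: filtering, model matrix, model battery, reports.

The analysis flow mirrors how the study handled its field data:

1. keep only networks with at least 20 alters of fully observed smoking
   status (``filter_networks``), logging every exclusion;
2. build the alter-level model matrix (``build_model_matrix``): three
   dichotomized outcomes, pooled z-scores for ages and centralities,
   network-level structure attached to every alter, tie-type × ego-status
   indicators, leave-one-out composition proportions for the GLM
   robustness models, and listwise deletion with logged reasons;
3. fit the four-model battery per outcome (``run_battery``): M0 intercept
   only, M1 individual attributes, M2 network characteristics, M3 both.

Every alter of the input appears exactly once in either the model matrix
or the exclusion log — the 1681 → 1622 style accounting is explicit here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assortativity import alter_assortativity
from .metrics import network_metrics, zscore
from .multilevel import ModelFit, ModelSpec, fit_random_intercept_logistic
from .network_model import TIE_TYPES, EgoNetwork, SmokingStatus3

__all__ = [
    "PipelineConfig",
    "filter_networks",
    "build_model_matrix",
    "model_spec_for",
    "run_battery",
    "battery_table",
    "descriptive_report",
]

log = logging.getLogger(__name__)

_CATS = {
    "smoker": SmokingStatus3.SMOKER,
    "former": SmokingStatus3.FORMER,
    "nonsmoker": SmokingStatus3.NONSMOKER,
}
OUTCOMES = {"smoker": "y_smoker", "former": "y_former", "nonsmoker": "y_nonsmoker"}
MODEL_IDS = ("M0", "M1", "M2", "M3")


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level options for the full analysis."""

    min_alters_complete: int = 20
    outcomes: tuple[str, ...] = ("smoker", "former", "nonsmoker")
    models: tuple[str, ...] = MODEL_IDS
    n_quad: int = 15
    #: "ego_status": tie-type indicator fires when the EGO's status matches
    #: the outcome category (default reading). "network_composition": fires
    #: when the alter has at least one network neighbour of that tie type
    #: in the category.
    interaction_mode: str = "ego_status"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_alters_complete < 1:
            raise ValueError("min_alters_complete must be >= 1")
        if self.interaction_mode not in ("ego_status", "network_composition"):
            raise ValueError(f"unknown interaction_mode {self.interaction_mode!r}")
        unknown = set(self.outcomes) - set(OUTCOMES)
        if unknown:
            raise ValueError(f"unknown outcomes {sorted(unknown)}")


def filter_networks(
    networks: list[EgoNetwork], min_alters_complete: int = 20
) -> tuple[list[EgoNetwork], pd.DataFrame]:
    """Retain networks with >= threshold alters of observed smoking status.

    Returns the retained networks and an exclusion log with one row per
    dropped network (ego_id, n_alters, n_status_complete, reason).
    """
    keep, dropped = [], []
    for net in networks:
        n_complete = sum(a.smoking is not None for a in net.alters)
        if n_complete >= min_alters_complete:
            keep.append(net)
        else:
            dropped.append({
                "ego_id": net.ego.ego_id,
                "n_alters": net.n_alters,
                "n_status_complete": n_complete,
                "reason": f"fewer than {min_alters_complete} alters with "
                          "observed smoking status",
            })
    logbook = pd.DataFrame(
        dropped, columns=["ego_id", "n_alters", "n_status_complete", "reason"])
    if len(dropped):
        log.info("filter_networks: excluded %d of %d networks",
                 len(dropped), len(networks))
    return keep, logbook


_MODEL_COLUMNS = [
    "alter_sex", "alter_age", "alter_education", "alter_marital",
    "ego_sex", "ego_age", "ego_education", "ego_marital", "ego_employment",
    "meet_weekly", "degree_norm", "betweenness_norm",
    "n_components", "degree_centralization", "density",
    "assort_smoker", "assort_former", "assort_nonsmoker",
]


def build_model_matrix(
    networks: list[EgoNetwork],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alter-level model matrix plus a per-alter exclusion log.

    Per retained alter: the three 0/1 outcomes; recoded attributes;
    normalized then pooled-z-scored degree and betweenness; the ego
    network's density, component count and centralization; the three
    leave-one-out assortativity scores; four tie-type × ego-status
    indicator columns per outcome category (reference = "other"); and the
    per-category leave-one-out composition proportions used by the GLM
    robustness models.  Ages are z-scored pooled within role (alter ages
    over all alters, ego ages over distinct egos) on the retained rows.

    Rows with a missing modelled value or an undefined assortativity score
    (isolates) are dropped and logged with the first applicable reason.
    """
    config = config or PipelineConfig()
    rows, excluded = [], []
    for net in networks:
        mets = network_metrics(net)
        statuses = {a.alter_id: a.smoking for a in net.alters}
        obs = [s for s in statuses.values() if s is not None]
        n_obs = len(obs)
        counts = {k: sum(s is c for s in obs) for k, c in _CATS.items()}
        for a in net.alters:
            row = {
                "ego_id": net.ego.ego_id, "alter_id": a.alter_id,
                "alter_sex": a.sex, "alter_age": a.age,
                "alter_education": a.education, "alter_marital": a.marital,
                "tie_type": a.tie_type, "meet_weekly": a.meet_weekly,
                "ego_sex": net.ego.sex, "ego_age": net.ego.age,
                "ego_education": net.ego.education,
                "ego_marital": net.ego.marital,
                "ego_employment": net.ego.employment,
                "degree_norm": mets.degree_norm[a.alter_id],
                "betweenness_norm": mets.betweenness_norm[a.alter_id],
                "n_components": mets.n_components,
                "degree_centralization": mets.degree_centralization,
                "density": mets.density,
            }
            status = a.smoking
            if status is not None:
                for key, cat in _CATS.items():
                    row[f"y_{key}"] = int(status is cat)
            for key, cat in _CATS.items():
                score = alter_assortativity(net, a.alter_id, cat)
                row[f"assort_{key}"] = score.score if score.defined else np.nan
                # leave-one-out composition: share of category among the
                # other status-observed alters of this ego
                others = n_obs - (1 if status is not None else 0)
                loo = counts[key] - (1 if status is cat else 0)
                row[f"p_loo_{key}"] = loo / others if others else np.nan
                for tie in TIE_TYPES:
                    if config.interaction_mode == "ego_status":
                        hit = (a.tie_type == tie and net.ego.smoking is cat)
                    else:
                        hit = any(
                            net.alter(nb).tie_type == tie
                            and statuses[nb] is cat
                            for nb in net.neighbours(a.alter_id)
                        )
                    row[f"tie_{tie}_x_{key}"] = int(hit)
            rows.append(row)

    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("no alters in input networks")

    required = (["y_smoker", "y_former", "y_nonsmoker"] + _MODEL_COLUMNS)
    reasons = pd.Series("", index=frame.index, dtype=object)
    missing_y = frame[["y_smoker", "y_former", "y_nonsmoker"]].isna().any(axis=1) \
        if "y_smoker" in frame else pd.Series(True, index=frame.index)
    undef_assort = frame[["assort_smoker", "assort_former",
                          "assort_nonsmoker"]].isna().any(axis=1)
    missing_cov = frame[[c for c in _MODEL_COLUMNS
                         if not c.startswith("assort")]].isna().any(axis=1)
    reasons[missing_cov] = "missing covariate"
    reasons[undef_assort] = "undefined assortativity (isolate)"
    reasons[missing_y] = "missing smoking status"
    drop = reasons != ""
    excluded = frame.loc[drop, ["ego_id", "alter_id"]].copy()
    excluded["reason"] = reasons[drop]
    kept = frame.loc[~drop].reset_index(drop=True)
    if kept.empty:
        raise ValueError("model matrix empty after listwise deletion")
    log.info("build_model_matrix: kept %d of %d alters (%d excluded)",
             len(kept), len(frame), int(drop.sum()))

    kept = kept.copy()
    kept["alter_age_z"] = zscore(kept["alter_age"], name="alter_age")
    ego_age = kept.groupby("ego_id")["ego_age"].first()
    ego_z = pd.Series(zscore(ego_age, name="ego_age"), index=ego_age.index)
    kept["ego_age_z"] = kept["ego_id"].map(ego_z)
    kept["degree_z"] = zscore(kept["degree_norm"], name="degree_norm")
    kept["betweenness_z"] = zscore(kept["betweenness_norm"],
                                   name="betweenness_norm")
    return kept, excluded.reset_index(drop=True)


def model_spec_for(model_id: str, outcome: str, n_quad: int = 15) -> ModelSpec:
    """Term lists for the four-model battery, per outcome category.

    M1 = individual attributes (alter and ego sociodemographics plus the
    four tie-type × ego-status indicators); M2 = network characteristics
    (meeting frequency, centralities, structure, and two assortativity
    scores: smoker plus the outcome's own category, with former standing
    in as the second score for the smoker outcome); M3 = M1 ∪ M2.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    attr = (
        "alter_sex", "alter_age_z", "alter_education", "alter_marital",
        "ego_sex", "ego_age_z", "ego_education", "ego_marital",
        "ego_employment",
        *(f"tie_{t}_x_{outcome}" for t in TIE_TYPES),
    )
    # Each outcome's network block carries two assortativity scores: the
    # smoker score plus the outcome's own (former for the smoker outcome).
    assort = (("assort_smoker", "assort_former") if outcome in ("smoker", "former")
              else ("assort_smoker", "assort_nonsmoker"))
    net = ("meet_weekly", "degree_z", "betweenness_z", "n_components",
           "degree_centralization", "density") + assort
    terms = {"M0": (), "M1": attr, "M2": net, "M3": attr + net}
    if model_id not in terms:
        raise ValueError(f"unknown model id {model_id!r}")
    return ModelSpec(outcome=OUTCOMES[outcome], terms=terms[model_id],
                     model_id=model_id, n_quad=n_quad)


def run_battery(
    records: pd.DataFrame, config: PipelineConfig | None = None
) -> dict[tuple[str, str], ModelFit | Exception]:
    """Fit every requested (outcome, model) pair; failures don't abort.

    Returns a mapping (outcome, model_id) -> ModelFit, or the exception a
    failed fit raised (recorded so the battery continues).
    """
    config = config or PipelineConfig()
    results: dict[tuple[str, str], ModelFit | Exception] = {}
    for outcome in config.outcomes:
        for model_id in config.models:
            spec = model_spec_for(model_id, outcome, n_quad=config.n_quad)
            try:
                results[(outcome, model_id)] = fit_random_intercept_logistic(
                    records, spec)
            except Exception as err:  # keep going, report at the end
                log.warning("fit %s/%s failed: %s", outcome, model_id, err)
                results[(outcome, model_id)] = err
    return results


def battery_table(
    fits: dict[tuple[str, str], ModelFit | Exception], outcome: str
) -> pd.DataFrame:
    """One outcome's four-model comparison in the published layout.

    Rows are coefficient terms (OR with 95% CI and p) followed by the fit
    statistic block (n, groups, ICC, AIC, BIC, log likelihood, deviance,
    marginal/conditional R^2); columns are the fitted models.
    """
    cols: dict[str, dict[str, str]] = {}
    all_terms: list[str] = ["intercept"]
    for (out, model_id), fit in sorted(fits.items()):
        if out != outcome or isinstance(fit, Exception):
            continue
        tab = fit.table().set_index("term")
        col = {}
        for term, r in tab.iterrows():
            col[term] = (f"{r.OR:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f}) "
                         f"p={r.p:.3f}")
            if term not in all_terms:
                all_terms.append(term)
        col["num.obs"] = str(fit.n_obs)
        col["num.groups"] = str(fit.n_groups)
        col["ICC"] = f"{fit.icc:.3f}"
        col["AIC"] = f"{fit.aic:.3f}"
        col["BIC"] = f"{fit.bic:.3f}"
        col["log likelihood"] = f"{fit.loglik:.3f}"
        col["deviance"] = f"{fit.deviance:.3f}"
        col["marginal R2 / conditional R2"] = (
            f"{fit.r2_marginal:.3f}/{fit.r2_conditional:.3f}")
        cols[model_id] = col
    stat_rows = ["num.obs", "num.groups", "ICC", "AIC", "BIC",
                 "log likelihood", "deviance", "marginal R2 / conditional R2"]
    index = [t for t in all_terms if t != "intercept"] + ["intercept"] + stat_rows
    return pd.DataFrame({m: {k: c.get(k, "") for k in index}
                         for m, c in cols.items()}).reindex(index)


def _pct_block(values, levels, labels):
    obs = [v for v in values if v is not None]
    out = {}
    for lv, lab in zip(levels, labels):
        n = sum(v == lv for v in obs)
        pct = 100.0 * n / len(obs) if obs else float("nan")
        out[lab] = f"{n} ({pct:.1f}%)"
    return out


def descriptive_report(networks: list[EgoNetwork]) -> dict[str, pd.DataFrame]:
    """Descriptive tables: pooled, egos by status, alters by status.

    ``by_ego_status`` includes the tie-type cross-tab (each ego-status
    column counts that group's ego–alter ties, percentages normalized
    within column); ``by_alter_status`` includes meeting frequency.
    """
    if not networks:
        raise ValueError("cannot report on an empty population")
    from .synthetic import summarize_population

    def stat_cols(units_by_status, extra):
        table: dict[str, dict[str, str]] = {}
        for label, units in units_by_status.items():
            col: dict[str, str] = {}
            ages = np.array([u.age for u in units if u.age is not None], float)
            col["n"] = str(len(units))
            if ages.size:
                sd = ages.std(ddof=1) if ages.size > 1 else float("nan")
                col["age mean (sd)"] = f"{ages.mean():.1f} ({sd:.1f})"
                col["age median (range)"] = (
                    f"{np.median(ages):.1f} ({ages.min():.0f}-{ages.max():.0f})")
            col.update(_pct_block([u.sex for u in units], (0, 1),
                                  ("sex: male", "sex: female")))
            col.update(_pct_block([u.education for u in units], (0, 1),
                                  ("lower education", "university degree")))
            col.update(_pct_block([u.marital for u in units], (0, 1),
                                  ("single", "in a relationship")))
            col.update(extra(units))
            table[label] = col
        return pd.DataFrame(table)

    by_ego = {k: [n.ego for n in networks
                  if n.ego.smoking is c] for k, c in _CATS.items()}

    def ego_extra(egos):
        ids = {e.ego_id for e in egos}
        alters = [a for n in networks if n.ego.ego_id in ids for a in n.alters]
        out = _pct_block([e.employment for e in egos], (0, 1),
                         ("unemployed (incl. retired)", "employed"))
        out.update(_pct_block([a.tie_type for a in alters], TIE_TYPES,
                              [f"tie: {t}" for t in TIE_TYPES]))
        return out

    alters_all = [a for n in networks for a in n.alters]
    by_alter = {k: [a for a in alters_all if a.smoking is c]
                for k, c in _CATS.items()}

    def alter_extra(alters):
        return _pct_block([a.meet_weekly for a in alters], (0, 1),
                          ("meets less than weekly", "meets at least weekly"))

    return {
        "pooled": summarize_population(networks),
        "by_ego_status": stat_cols(by_ego, ego_extra),
        "by_alter_status": stat_cols(by_alter, alter_extra),
    }
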