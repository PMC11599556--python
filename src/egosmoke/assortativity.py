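"""Per-alter leave-one-out assortativity for categorical smoking status.

For a focal alter *k* in an ego network of *n* alters, and a dichotomized
status category (smoker / former smoker / non-smoker), the score is

    a_k = (proportion of k's neighbours in the category)
        − (proportion of the other n−1 alters in the category)

The focal alter is excluded from the network proportion ("leave one out"),
so the score compares k's immediate circle against the rest of the ego
network.  Scores lie in [−1, 1]; positive values mean the category is
over-represented among k's direct contacts.  Isolated alters (no
neighbours) have no defined score and are excluded from modelling.

Alters with missing smoking status are excluded from both the numerator
and the denominator of each proportion (complete-case within the
statistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .network_model import EgoNetwork, SmokingStatus3

__all__ = ["AssortativityScore", "alter_assortativity", "all_assortativities"]


@dataclass(frozen=True)
class AssortativityScore:
    ego_id: str
    alter_id: str
    category: SmokingStatus3
    score: float  # NaN when undefined (isolate)
    p_neighbours: float
    p_rest: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.score)


def alter_assortativity(
    net: EgoNetwork, alter_k: str, category: SmokingStatus3
) -> AssortativityScore:
    """Leave-one-out assortativity of one alter for one status category.

    Raises ``KeyError`` if ``alter_k`` is not an alter of ``net`` and
    ``ValueError`` if no alter has an observed smoking status.  Returns a
    score of NaN (undefined) when the focal alter has no neighbours.
    """
    net.alter(alter_k)  # KeyError if absent
    status = {a.alter_id: a.smoking for a in net.alters}
    if all(s is None for s in status.values()):
        raise ValueError(
            f"ego {net.ego.ego_id}: no alter has an observed smoking status"
        )

    nbrs = net.neighbours(alter_k)
    if not nbrs:
        return AssortativityScore(net.ego.ego_id, alter_k, category,
                                  float("nan"), float("nan"), float("nan"))

    nbr_obs = [status[a] for a in nbrs if status[a] is not None]
    rest_obs = [s for a, s in status.items()
                if a != alter_k and s is not None]
    if not nbr_obs or not rest_obs:
        return AssortativityScore(net.ego.ego_id, alter_k, category,
                                  float("nan"), float("nan"), float("nan"))

    p_nbr = sum(s is category for s in nbr_obs) / len(nbr_obs)
    p_rest = sum(s is category for s in rest_obs) / len(rest_obs)
    return AssortativityScore(net.ego.ego_id, alter_k, category,
                              p_nbr - p_rest, p_nbr, p_rest)


def all_assortativities(net: EgoNetwork) -> list[AssortativityScore]:
    """Scores for every alter and every category, in stable order.

    Order: alters in network order, categories SMOKER, FORMER, NONSMOKER.
    With complete status data the three scores of one alter sum to 0
    (the categories partition both the neighbour set and the rest).
    """
    return [
        alter_assortativity(net, a.alter_id, cat)
        for a in net.alters
        for cat in (SmokingStatus3.SMOKER, SmokingStatus3.FORMER,
                    SmokingStatus3.NONSMOKER)
    ]
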