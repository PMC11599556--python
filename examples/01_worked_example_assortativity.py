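"""Leave-one-out assortativity on a hand-built 25-alter ego network.

An ego network of 25 alters contains 9 smokers.  The focal alter a00 is a
smoker with four neighbours, all of them smokers.  The score compares the
smoker share among a00's neighbours (4/4 = 1.00) with the share among the
other 24 alters (8/24 = 0.33): the difference, 0.67, says a00's immediate
circle is far more smoker-heavy than the rest of the network.
"""

from egosmoke import Alter, Ego, EgoNetwork, SmokingStatus3, alter_assortativity

alters = [
    Alter(alter_id=f"a{i:02d}", smoking_raw="smoker" if i < 9 else "non_smoker")
    for i in range(25)
]
ties = {frozenset(("a00", f"a{i:02d}")) for i in range(1, 5)}
net = EgoNetwork(ego=Ego(ego_id="ego_j"), alters=alters, ties=ties)

score = alter_assortativity(net, "a00", SmokingStatus3.SMOKER)
print(f"smoker share among a00's neighbours : {score.p_neighbours:.2f}")
print(f"smoker share among the other alters : {score.p_rest:.2f}")
print(f"assortativity score for a00         : {score.score:.2f}")
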