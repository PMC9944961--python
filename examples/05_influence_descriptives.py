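"""Peer-influence descriptives: friend composition and network thresholds.

Partitions ties into persisting/new/dropped, categorizes each ego by
their favorable/against transition, and compares the baseline share of
favorable-side friends across ego categories. With planted influence,
egos who end up on the favorable side started with noticeably more
favorable friends — the network-threshold signature. A chi-square tests
whether transitions to the against side depend on the intervention arm.
"""

import pandas as pd

from normnet import CohortConfig, generate_study
from normnet.data import side_of_group
from normnet.influence import (
    baseline_threshold_table,
    categorize_ego,
    friend_change_profile,
    transition_intervention_chisq,
)

config = CohortConfig(n_schools=6, school_size_range=(90, 120), seed=17)
study = generate_study(config)
networks = [net for _, net in study]
table = pd.concat([t for t, _ in study], ignore_index=True)

# true planted sides stand in for fitted assignments in this example
rows = []
for tbl, net in study:
    base = tbl[tbl["wave"] == "baseline"].set_index("student")
    follow = tbl[tbl["wave"] == "followup"].set_index("student")
    for stu in net.roster:
        s0 = side_of_group(base.loc[stu, "true_group"])
        s1 = side_of_group(follow.loc[stu, "true_group"])
        rows.append(
            {"school": net.school, "student": stu, "side_t0": s0, "side_t1": s1,
             "transition_category": categorize_ego(s0, s1)}
        )
assignments = pd.DataFrame(rows)

print("baseline favorable-friend share by ego transition category:")
thresh = baseline_threshold_table(assignments, networks)
for r in thresh.itertuples():
    print(
        f"  {r.ego_category:22s} {100 * r.mean_favorable_share:5.1f}% "
        f"(n = {r.n_egos})"
    )
print("favorable-side egos start with more favorable friends: the threshold effect")

profile = friend_change_profile(assignments, networks)
persisting = profile[
    (profile["tie_class"] == "persisting")
    & (profile["friend_category"] == "maintain-against")
]
print(
    "\nmean share of persisting friends who maintain against-smoking norms, "
    "by ego category:"
)
print(
    persisting.groupby("ego_category")["proportion"].mean().round(2).to_string()
)

stat, dof, p, obs = transition_intervention_chisq(assignments, table)
print(f"\nchi-square of change-to-against x intervention: "
      f"{stat:.2f} (df = {dof}, p = {p:.3f})")
print("(peer-led schools push more at-risk students toward against-smoking norms)")
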