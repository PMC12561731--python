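"""Trail mechanics on a toy table: deposit, evaporate, select, explain.

Builds a three-helper trail table, applies a few ratings, shows how the
selection probabilities respond, decays the trails for a day, and prints a
match explanation.
"""

import numpy as np

from trailmap import (
    RatingEvent,
    RoutingParams,
    TrailTable,
    deposit,
    evaporate,
    explain_match,
    halflife_to_rate,
    selection_probabilities,
    selection_weights,
)

params = RoutingParams()  # alpha=1, tau_min=0.1, half-life 48 h
table = TrailTable(["ana", "ben", "caro"])

# ana gives two great answers, ben one poor one, caro is never tried
for event in [
    RatingEvent("seeker1", "ana", 5),
    RatingEvent("seeker2", "ana", 4),
    RatingEvent("seeker3", "ben", 2),
]:
    deposit(table, event)

print("trails after three ratings:", table.as_dict())
probs = selection_probabilities(
    selection_weights(table, ["ana", "ben", "caro"], params)
)
print("selection probabilities:   ", {k: round(v, 3) for k, v in probs.items()})
# ana dominates, but ben and caro keep the tau_min exploration floor:
# a negative trail suppresses a helper without ever excluding them.

evaporate(table, halflife_to_rate(48.0), n_steps=24)  # one day of decay
print("trails after 24 h of decay:", {k: round(v, 3) for k, v in table.as_dict().items()})
# every trail shrank by the same factor 0.5^(24/48) ~ 0.707: the community
# slowly forgets both good and bad reputations.

print(explain_match("ana", table.tau("ana"), threshold=1.0))
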