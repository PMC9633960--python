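"""Drive the intention circuit from abstract trajectory views.

The trajectory tracker reduces each camera frame to one of six views (line
centered / absent / left / right / turning left / turning right), one-hot
encoded over six neurons. The circuit then learns which motor action each
view demands, exactly as in the gesture experiment but with N = 6 states.
"""

from spikeintent import RuleSet, train_rule_set
from spikeintent.gestures import (
    TRAJECTORY_ACTIONS,
    TRAJECTORY_STATES,
    encode_trajectory_state,
)

for label in TRAJECTORY_STATES:
    code = encode_trajectory_state(label)
    action = TRAJECTORY_ACTIONS[int(code.argmax())]
    print(f"{label:18s} -> neuron {int(code.argmax())} -> {action}")

# the view->action assignment is the identity rule over the six indices
rule = RuleSet.identity(len(TRAJECTORY_STATES))
result = train_rule_set(rule)
print(f"\nlearning the six view->action rules took {result.interactions} "
      f"interactions (minimum possible: {rule.n})")
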