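"""Change some of the learned rules and watch the circuit relearn.

Because weight updates are ratios of the current weight, an intensively
reinforced synapse is forgotten after a handful of wrong predictions, while
states whose rules did not change keep predicting correctly (cost 1 each).
"""

from spikeintent import RuleSet, build_network, relearn_after_rule_change, train_rule_set

old = RuleSet.from_one_based([1, 2, 3, 4, 5, 6])
new = RuleSet.from_one_based([2, 1, 3, 4, 5, 6])  # states 1 and 2 swap intentions

network = build_network(old.n)
first = train_rule_set(old, network=network)
print(f"initial training: {first.interactions} interactions")

second = relearn_after_rule_change(network, old, new)
print("relearning per state:",
      {s + 1: c for s, c in second.per_state_interactions.items()})
print("wrong predictions of the old intention (abandonment):",
      {s + 1: c for s, c in second.abandonment_counts.items()})
unchanged = [s + 1 for s in range(old.n) if old[s] == new[s]]
print(f"unchanged states {unchanged} each cost exactly 1 interaction —")
print("the changed rules were relearned without disturbing the others.")
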