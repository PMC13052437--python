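"""Small builders shared across test modules."""

from ahprank import Criterion, DecisionHierarchy, PriorityVector


def mini_hierarchy(weights, per_criterion):
    """Build a hierarchy from raw (unnormalized) weights and utility dicts."""
    crits = []
    for name, prios in per_criterion.items():
        labels = tuple(prios)
        crits.append(Criterion(name, labels, PriorityVector.from_raw(labels, prios.values())))
    return DecisionHierarchy("test", tuple(crits),
                             PriorityVector.from_raw(tuple(per_criterion), weights))
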