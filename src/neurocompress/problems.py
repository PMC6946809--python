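"""Stimulus space and classification rules for the three learning problems.

The experiment uses eight stimuli formed by all combinations of three binary
feature attributes. The same eight stimuli are classified under three rules
of increasing complexity:

* ``low``    — unidimensional: class is the value of attribute 1.
* ``medium`` — exclusive-or of attributes 2 and 3 (attribute 1 irrelevant).
* ``high``   — three-way parity: class depends on all three attributes.

Each rule splits the stimuli 4/4 between categories ``A`` and ``B``.
Physical stimulus features (legs, antennae, mandible) are randomly permuted
onto the abstract attributes per participant, with the permutation held
fixed across the three problems.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

PROBLEMS = ("low", "medium", "high")

#: all 8 stimulus codes as strings of attribute bits, in canonical order
CODES = tuple("".join(map(str, bits)) for bits in itertools.product((0, 1), repeat=3))


def _classify(code: str, problem: str) -> str:
    b = [int(c) for c in code]
    if problem == "low":
        parity = b[0]
    elif problem == "medium":
        parity = b[1] ^ b[2]
    elif problem == "high":
        # odd number of set attributes -> A
        parity = 1 - (b[0] ^ b[1] ^ b[2])
    else:
        raise ValueError(f"unknown problem {problem!r}")
    return "B" if parity else "A"


@dataclass(frozen=True)
class ProblemBank:
    """The 8 binary stimulus codes and their class assignments per problem."""

    stimuli: tuple[str, ...]
    class_map: dict[str, dict[str, str]]
    #: feature_to_attribute[i] = abstract attribute index of physical feature i
    feature_to_attribute: tuple[int, int, int] = (0, 1, 2)

    def true_class(self, code: str, problem: str) -> str:
        return self.class_map[problem][code]

    def relevant_attributes(self, problem: str) -> tuple[int, ...]:
        """Indices of the attributes a perfect rule must attend to."""
        return {"low": (0,), "medium": (1, 2), "high": (0, 1, 2)}[problem]


def make_problem_bank(seed: int = 0, randomize_feature_mapping: bool = False) -> ProblemBank:
    """Build the canonical problem structure.

    Parameters
    ----------
    seed : int
        Seeds the feature-to-attribute permutation.
    randomize_feature_mapping : bool
        If True, draw a participant-specific permutation mapping physical
        features onto abstract attributes (fixed across the three problems).
    """
    class_map = {p: {c: _classify(c, p) for c in CODES} for p in PROBLEMS}
    if randomize_feature_mapping:
        rng = np.random.default_rng(seed)
        perm = tuple(int(i) for i in rng.permutation(3))
    else:
        perm = (0, 1, 2)
    return ProblemBank(stimuli=CODES, class_map=class_map, feature_to_attribute=perm)
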