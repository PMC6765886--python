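"""Exception types shared across the package."""

from __future__ import annotations


class ScenarioValidationError(ValueError):
    """A scenario violated one or more invariants.

    Carries the full list of problems so a user fixing a config file
    sees every offending key at once, not just the first.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid scenario: " + "; ".join(self.problems)
        )
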