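"""Exception hierarchy for the MHQ engine."""


class MHQError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(MHQError):
    """An item bank / parameter / rule configuration is structurally invalid."""


class SchemaError(MHQError):
    """A respondent record violates the response schema."""


class IncompleteRecordError(SchemaError):
    """One or more item ratings are missing.

    Attributes
    ----------
    missing : list of str
        Item ids with no rating.
    """

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            f"record is missing ratings for {len(self.missing)} item(s): "
            + ", ".join(self.missing)
        )


class RatingRangeError(SchemaError):
    """A rating falls outside the 1-9 response scale."""


class IneligibleError(SchemaError):
    """The respondent does not meet eligibility requirements (e.g. age < 18)."""


class ScoreRangeError(MHQError):
    """A score falls outside its defined range."""
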