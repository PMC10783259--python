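"""Exception hierarchy.

Everything raised on bad user input derives from :class:`PlastattrError`
so callers can catch one type at the CLI boundary.
"""


class PlastattrError(Exception):
    """Base class for all package-specific errors."""


class InventoryError(PlastattrError, ValueError):
    """Invalid use-share inventory (negative share, empty profile, mixed bases...)."""


class ProfileParseError(InventoryError):
    """A profile file could not be parsed; message names the row and field."""


class BurdenParseError(PlastattrError, ValueError):
    """A disease-burden table file could not be parsed."""


class RuleError(PlastattrError, ValueError):
    """Attribution-rule configuration error: unmatched or ambiguously matched row."""


class PRFLookupError(PlastattrError, KeyError):
    """A rule names a chemical for which no PRF triple is available."""
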