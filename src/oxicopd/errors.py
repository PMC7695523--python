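"""Exception hierarchy for the oxicopd pipeline."""


class OxiCopdError(Exception):
    """Base class for all oxicopd errors."""


class FormatError(OxiCopdError):
    """A file does not conform to the expected CSV schema."""


class DataError(OxiCopdError):
    """Input values violate a semantic constraint (ranges, duplicates, labels)."""


class DegenerateBaselineError(OxiCopdError):
    """A stable-window SD of zero: Z scores are undefined for this baseline."""
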