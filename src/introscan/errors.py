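"""Exception types shared across the scan pipeline."""


class IntroscanError(Exception):
    """Base class for all package errors."""


class NewickParseError(IntroscanError):
    """Malformed Newick input; the message names the offending position."""


class MissingTaxonError(IntroscanError):
    """A required taxon label is absent from a tree or alignment."""


class ConfigError(IntroscanError):
    """Invalid simulation or scan configuration."""


class EmptyCountsError(IntroscanError):
    """No usable loci for a triplet test."""


class UndefinedStatisticError(IntroscanError):
    """A statistic's denominator is empty (e.g. ABBA+BABA = 0)."""


class BlockCountError(IntroscanError):
    """Fewer SNPs than requested jackknife blocks."""


class AlignmentFormatError(IntroscanError):
    """Ragged or otherwise inconsistent alignment input."""
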