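"""Exception hierarchy mapped to CLI exit codes.

Exit-code contract: 0 success, 2 configuration error, 3 data/format error,
4 statistical degeneracy.
"""

from __future__ import annotations


class EvmirnaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(EvmirnaError):
    """Invalid configuration, thresholds, rule names or missing inputs."""

    exit_code = 2


class DataFormatError(EvmirnaError):
    """Malformed count/metadata/annotation files."""

    exit_code = 3


class MetadataError(DataFormatError):
    """Samples missing from, or inconsistent with, the metadata table."""


class StatisticalError(EvmirnaError):
    """Degenerate inputs that make a statistical procedure undefined."""

    exit_code = 4


class NormalizationError(StatisticalError):
    """All-zero sample columns or an empty median-of-ratios reference set."""


class DesignError(StatisticalError):
    """Experimental design insufficient for the requested procedure."""
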