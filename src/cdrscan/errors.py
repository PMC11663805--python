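"""Exception hierarchy shared across the package.

Distinct classes exist so the CLI can map failure modes to distinct exit
codes (usage 2, parse 3, empty-signal 4).
"""

from __future__ import annotations


class CdrScanError(Exception):
    """Base class for all package errors."""


class UsageError(CdrScanError):
    """Invalid parameter or argument combination."""


class ParseError(CdrScanError):
    """A malformed input file.

    Parameters
    ----------
    message:
        Human-readable description.
    path:
        Offending file, if known.
    line_number:
        1-based line number of the offending row, if known.
    """

    def __init__(self, message: str, path: str | None = None,
                 line_number: int | None = None):
        self.path = path
        self.line_number = line_number
        prefix = ""
        if path is not None:
            prefix = f"{path}"
            if line_number is not None:
                prefix += f":{line_number}"
            prefix += ": "
        super().__init__(prefix + message)


class EmptyRegionError(CdrScanError):
    """A requested region contains no usable methylation records."""

    def __init__(self, region, message: str | None = None):
        self.region = region
        super().__init__(
            message or f"no methylation records overlap region {region}")


class NoRegionsError(CdrScanError):
    """A region BED file contained no intervals."""


class NoAlphaSignalError(CdrScanError):
    """A region has no valid alpha-satellite bins to analyse."""


class GenerationError(CdrScanError):
    """The simulator could not satisfy its placement constraints."""
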