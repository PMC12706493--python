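"""Exception types shared across the package."""

from __future__ import annotations


class EthnogridError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EthnogridError):
    """One or more input rows or values violated an invariant.

    ``errors`` carries every collected message so curators can fix a file
    in one pass rather than replaying load-fail cycles.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class ConfigError(EthnogridError):
    """A configuration value is missing, unresolvable, or inconsistent."""
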