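"""Exception hierarchy.

All validation failures raise :class:`ValidationError` (a ``ValueError``)
so callers can distinguish bad data from bad parameters
(:class:`ParameterError`) and malformed files (:class:`FormatError`).
"""


class SpikekitError(Exception):
    """Base class for all spikekit errors."""


class ValidationError(SpikekitError, ValueError):
    """Input data violates an invariant (duplicate spikes, mismatched counts, ...)."""


class ParameterError(SpikekitError, ValueError):
    """A parameter is outside its legal range or inconsistent with the data."""


class FormatError(SpikekitError, ValueError):
    """A file does not conform to one of the native on-disk formats."""


class ProvenanceError(SpikekitError):
    """A provenance record cannot be restored (bad version, missing source, ...)."""
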