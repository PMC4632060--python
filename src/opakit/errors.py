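"""Exception types raised across the toolkit."""


class OpakitError(Exception):
    """Base class for all toolkit errors."""


class MalformedRepeatError(OpakitError, ValueError):
    """A codon run is not a valid single-histidine CAX repeat."""


class EmptyInputError(OpakitError, ValueError):
    """An operation requiring data received an empty input."""


class RegistryIntegrityError(OpakitError, ValueError):
    """An allele registry violates its uniqueness invariants."""


class NoLocusError(OpakitError, ValueError):
    """No anchored repeat locus could be found in a sequence."""


class AmbiguousLocusError(OpakitError, ValueError):
    """More than one candidate repeat locus matched the anchors."""

    def __init__(self, message, candidates=()):
        super().__init__(message)
        self.candidates = list(candidates)


class UndefinedRateError(OpakitError, ZeroDivisionError):
    """A rate was requested over an empty denominator."""


class SimConfigError(OpakitError, ValueError):
    """A synthetic-data configuration is internally inconsistent."""
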