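"""Exception hierarchy for the arpcm package."""


class ArpcmError(Exception):
    """Base class for all arpcm errors."""


class MalformedCurveError(ArpcmError):
    """A dose-response curve violates its structural invariants."""


class DuplicateRecordError(ArpcmError):
    """Two curves share the same (mutant_id, drug_id) key."""


class EmptyInputError(ArpcmError):
    """An operation that requires data received an empty collection."""


class UnclassifiableCurveError(ArpcmError):
    """Strict mode: a curve fell into the residual case the rules do not cover."""


class MutantParseError(ArpcmError):
    """A mutant token does not match the W742C-style grammar or its invariants."""


class SequenceMismatchError(ArpcmError):
    """A substitution's expected wild-type residue disagrees with the sequence."""


class EncodingError(ArpcmError):
    """A protein sequence contains a residue outside the 20-letter alphabet."""


class ChemistryError(ArpcmError):
    """A SMILES string could not be parsed into a molecule."""


class AssemblyError(ArpcmError):
    """Feature blocks with incompatible shapes were combined."""


class DimensionError(ArpcmError):
    """Feature dimensionality does not match what a fitted object expects."""


class ResamplingError(ArpcmError):
    """Oversampling preconditions are violated (e.g. a singleton class)."""


class DivergenceError(ArpcmError):
    """Training produced a non-finite loss."""


class SimulationError(ArpcmError):
    """The curve simulator exhausted its rejection budget."""


class FileFormatError(ArpcmError):
    """An input file is malformed; message carries the offending line number."""
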