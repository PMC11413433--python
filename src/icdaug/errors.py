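"""Exception hierarchy for the icdaug pipeline."""


class IcdAugError(Exception):
    """Base class for all package errors."""


class MalformedCodeError(IcdAugError, ValueError):
    """A string could not be parsed as a diagnosis/procedure code."""


class UnknownLeafError(IcdAugError, KeyError):
    """A code is not a leaf of the hierarchy in use."""


class MalformedRecordError(IcdAugError, ValueError):
    """A corpus line is missing fields or otherwise unparseable."""


class DuplicateIdError(IcdAugError, ValueError):
    """Two corpus documents share a document id."""


class MissingDescriptionError(IcdAugError, KeyError):
    """A code referenced by a prompt has no entry in the code table."""


class InsufficientFamiliesError(IcdAugError, ValueError):
    """Fewer retained families than the requested sample size."""


class NoSourcesError(IcdAugError, ValueError):
    """A generation code has no source documents to clone."""


class NoSiblingError(IcdAugError, ValueError):
    """A document carries no sibling of the zero-shot code to substitute."""


class EmptyTrainError(IcdAugError, ValueError):
    """The training split is empty."""


class DivergenceError(IcdAugError, RuntimeError):
    """Training produced a non-finite loss."""


class UndefinedMetricError(IcdAugError, ValueError):
    """A metric is undefined for the given inputs (e.g. no positive label)."""


class DegenerateAgreementError(IcdAugError, ValueError):
    """Chance agreement is 1 so Fleiss' kappa is undefined."""


class InfeasibleStrataError(IcdAugError, ValueError):
    """The document budget cannot host the required label populations."""


class GeneratorFailureError(IcdAugError, RuntimeError):
    """A document generator raised while producing text."""
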