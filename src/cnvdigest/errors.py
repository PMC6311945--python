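"""Exception hierarchy shared across the package."""


class CnvDigestError(Exception):
    """Base class for all package errors."""


class CorpusFormatError(CnvDigestError):
    """Raised for malformed or schema-violating corpus XML."""


class LexiconFormatError(CnvDigestError):
    """Raised for malformed disease or trigger lexicon files."""


class CytobandParseError(CnvDigestError, ValueError):
    """Raised when a string does not conform to the cytoband grammar."""


class ContractViolation(CnvDigestError):
    """Raised when an operation is called with an invalid domain object."""


class ConfigError(CnvDigestError):
    """Raised for invalid generator or pipeline configuration."""


class IntegrityError(CnvDigestError):
    """Raised when combined artifacts are mutually inconsistent."""
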