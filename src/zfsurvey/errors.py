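"""Exception hierarchy shared across the package."""


class ZfSurveyError(Exception):
    """Base class for all zfsurvey errors."""


class FastaFormatError(ZfSurveyError):
    """A protein/CDS FASTA file violates the format contract."""


class GeneIdError(ZfSurveyError):
    """An identifier does not follow the Traes_<chr><sub><arm>_<hash>[.<n>] dialect."""


class GffFormatError(ZfSurveyError):
    """A GFF3 gene-model file violates the format contract."""


class CodonError(ZfSurveyError):
    """A coding sequence or aligned pair is not a valid codon string."""


class ExpressionError(ZfSurveyError):
    """An expression matrix or CT table violates its contract."""


class SpecError(ZfSurveyError):
    """A synthetic-data specification is impossible to realise."""


class ConfigError(ZfSurveyError):
    """A pipeline run configuration is invalid."""
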