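"""Exception hierarchy.

Every error raised by plastkit derives from :class:`PlastkitError` so callers
can catch the package's failures with a single except clause.
"""


class PlastkitError(Exception):
    """Base class for all plastkit errors."""


class FormatError(PlastkitError):
    """A file could not be parsed in the expected format (empty FASTA, bad newick...)."""


class AlphabetError(PlastkitError):
    """A sequence or residue contains a character outside the permitted alphabet."""


class CoordinateError(PlastkitError):
    """Feature coordinates are inconsistent or fall outside the genome."""


class SchemaError(PlastkitError):
    """A table row or record violates the expected schema."""


class UndefinedValueError(PlastkitError):
    """A statistic is undefined for the given input (e.g. GC of a zero-length window)."""


class NoInvertedRepeatError(PlastkitError):
    """No inverted-repeat pair at or above the detection floor was found."""


class DegeneratePartitionError(PlastkitError):
    """The IR pair leaves a zero-length single-copy segment; no quadripartite partition exists."""


class GeneLookupError(PlastkitError):
    """A requested gene name is absent from the annotation set."""


class NotACandidateError(PlastkitError):
    """The queried position is not an editable C on the coding strand."""


class PanelAlignmentError(PlastkitError):
    """CDS length and homolog-panel column count disagree."""


class SyntheticSpecError(PlastkitError):
    """A synthetic-data specification is infeasible or self-contradictory."""


class GenerationError(PlastkitError):
    """Rejection sampling failed to produce a sequence meeting its constraints."""


class FixtureIntegrityError(PlastkitError):
    """A packaged fixture failed its checksum."""


class ConfigError(PlastkitError):
    """A pipeline configuration is invalid (unknown stage, missing field)."""


class StageDependencyError(ConfigError):
    """A pipeline stage is missing an upstream artifact it depends on."""


class CharacterStateError(PlastkitError):
    """A character state falls outside the declared alphabet."""
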