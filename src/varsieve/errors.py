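"""Exception hierarchy for varsieve."""


class VarsieveError(Exception):
    """Base class for all varsieve errors."""


class VcfParseError(VarsieveError):
    """A VCF record could not be parsed."""


class AmbiguousAlleleError(VarsieveError):
    """An allele contains a character other than A, C, G or T."""


class ReferenceMismatchError(VarsieveError):
    """A call's REF allele disagrees with the reference sequence."""


class TagInconsistencyError(VarsieveError):
    """Mutually inconsistent tag values (e.g. depth 0 with alt reads > 0)."""


class UnsortedInputError(VarsieveError):
    """Calls were required to be coordinate-sorted but are not."""


class ContigMismatchError(VarsieveError):
    """A contig is present in one input but missing from another."""
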