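"""Structured exceptions raised across the package.

Every error names the offending record or coordinate so that pipeline
failures on real annotation files can be traced back to their source line.
"""


class IntronEvoError(Exception):
    """Base class for all package errors."""


class StructureParseError(IntronEvoError):
    """A gene-structure record is malformed (overlapping exons, bad strand,
    CDS length not a multiple of three, ...)."""


class CoordinateError(IntronEvoError):
    """A residue or column index falls outside the sequence it refers to."""


class ProjectionError(IntronEvoError):
    """An intron site cannot be mapped onto the protein alignment
    (typically an anchor codon at or beyond the stop codon)."""


class TaxonMappingError(IntronEvoError):
    """A gene has no taxon assignment, or a taxon carries more than one
    gene of the same family when building a presence/absence matrix."""


class TreeError(IntronEvoError):
    """Newick parsing or tree/matrix leaf-set mismatch problems."""


class GenerationError(IntronEvoError):
    """The synthetic-data generator cannot satisfy its constraints
    (e.g. more intron gains requested than distinct sites available)."""
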