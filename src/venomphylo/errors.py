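"""Exception hierarchy with structured provenance fields.

Every tabular validation error carries ``row`` (1-based data row, header
excluded) and ``column`` so callers can report exactly where a file is
broken; lookup errors carry the offending taxon names.
"""

from __future__ import annotations


class VenomPhyloError(Exception):
    """Base class for all package errors."""


class NewickParseError(VenomPhyloError):
    """Malformed newick input.

    Parameters
    ----------
    message:
        Human-readable description.
    offset:
        0-based character offset of the offending position, when known.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class DuplicateLabelError(VenomPhyloError):
    """Tree has duplicate tip labels."""

    def __init__(self, duplicates: list[str]):
        self.duplicates = sorted(duplicates)
        super().__init__(
            "duplicate tip labels: " + ", ".join(self.duplicates)
        )


class TreeValidationError(VenomPhyloError):
    """Tree violates a structural invariant (negative lengths, etc.)."""


class NotUltrametricError(TreeValidationError):
    """Operation requires an ultrametric tree and the tree is not."""


class SchemaError(VenomPhyloError):
    """A delimited-text table violates its registered schema."""

    def __init__(self, message: str, row: int | None = None,
                 column: str | None = None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class VocabularyError(VenomPhyloError):
    """A label is outside its controlled vocabulary."""


class TaxonLookupError(VenomPhyloError):
    """One or more taxa cannot be resolved on a tree."""

    def __init__(self, taxa: list[str] | str):
        self.taxa = [taxa] if isinstance(taxa, str) else list(taxa)
        super().__init__(
            "taxa not resolvable on tree: " + ", ".join(self.taxa)
        )


class MappingError(VenomPhyloError):
    """A prey taxon has no class-map entry."""

    def __init__(self, taxon: str):
        self.taxon = taxon
        super().__init__(f"prey taxon {taxon!r} missing from class map")


class DomainError(VenomPhyloError):
    """Numeric argument outside its mathematical domain."""


class InsufficientDataError(VenomPhyloError):
    """Too few observations (or no variation) for the requested fit."""


class RankDeficiencyError(VenomPhyloError):
    """Fixed-effect design matrix is singular."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(
            "fixed-effect design is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class ConvergenceError(VenomPhyloError):
    """Optimization failed to converge; carries the best point found."""

    def __init__(self, message: str, best=None):
        self.best = best
        super().__init__(message)
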