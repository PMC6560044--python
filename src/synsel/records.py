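"""Core gene record container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field

from .genetic_code import translate


@dataclass(frozen=True)
class GeneRecord:
    """One gene: identity, coordinates, strand, and its CDS / 3'UTR.

    Coordinates are 1-based inclusive base pairs on the annotation's
    assembly (the assembly itself is opaque to this package). The protein
    is derived lazily from the CDS under the standard genetic code.
    """

    gene_id: str
    species: str = ""
    symbol: str = ""
    chrom: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"
    cds: str = ""
    utr3: str = ""

    def __post_init__(self) -> None:
        if self.start and self.end and self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def protein(self) -> str:
        """Translation of the CDS (terminal stop dropped)."""
        return translate(self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)
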