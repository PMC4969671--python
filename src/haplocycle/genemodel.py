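"""Gene models for coding-sequence aware operations.

A :class:`GeneModel` describes the protein-coding stretch of one gene on a
contig as a reference nucleotide sequence plus one or more transcripts, each a
list of CDS intervals.  Genes frequently have several, mutually overlapping
transcripts; the gene's coding stretch is the union of the coverage of all of
its transcripts.  Coordinates are 0-based half-open internally; VCF emission
adds 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

#: codon -> amino acid (single letter), stop codons mapped to '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: "*" for c in standard_dna_table.stop_codons})

NUCLEOTIDES = "ACGT"

SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
OTHER = "other"


class GeneModelError(ValueError):
    """Raised for inconsistent gene-model configurations."""


@dataclass(frozen=True)
class Transcript:
    """One transcript: an ordered list of CDS intervals on the gene's contig."""

    name: str
    cds: tuple[tuple[int, int], ...]  # 0-based half-open, sorted, disjoint

    def __post_init__(self) -> None:
        if not self.cds:
            raise GeneModelError(f"transcript {self.name} has no CDS interval")
        last = None
        for start, end in self.cds:
            if end <= start:
                raise GeneModelError(f"empty CDS interval in {self.name}")
            if last is not None and start < last:
                raise GeneModelError(f"unsorted/overlapping CDS in {self.name}")
            last = end
        if self.length % 3 != 0:
            raise GeneModelError(
                f"transcript {self.name} CDS length {self.length} not a codon multiple"
            )

    @property
    def length(self) -> int:
        return sum(end - start for start, end in self.cds)

    def positions(self) -> list[int]:
        """All contig positions covered by the CDS, in transcription order."""
        out: list[int] = []
        for start, end in self.cds:
            out.extend(range(start, end))
        return out

    def index_of(self, pos: int) -> int | None:
        """Index of contig position ``pos`` within the spliced CDS, or None."""
        offset = 0
        for start, end in self.cds:
            if start <= pos < end:
                return offset + (pos - start)
            offset += end - start
        return None


@dataclass
class GeneModel:
    """A gene: contig-relative reference sequence plus its transcripts."""

    name: str
    contig: str
    sequence: str  # reference nucleotides for [0, len) on the synthetic contig
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise GeneModelError(f"gene {self.name} has no transcripts")
        for tr in self.transcripts:
            if tr.cds[-1][1] > len(self.sequence):
                raise GeneModelError(
                    f"transcript {tr.name} extends beyond sequence of {self.name}"
                )

    @property
    def coding_positions(self) -> list[int]:
        """Sorted union of all transcripts' CDS coverage (the coding stretch)."""
        cover: set[int] = set()
        for tr in self.transcripts:
            cover.update(tr.positions())
        return sorted(cover)

    def codon_at(self, transcript: Transcript, pos: int, sequence: str | None = None):
        """Return ``(codon, within_codon_index)`` for ``pos`` in ``transcript``.

        ``sequence`` overrides the reference (e.g. a mutated copy).
        """
        seq = self.sequence if sequence is None else sequence
        idx = transcript.index_of(pos)
        if idx is None:
            return None
        codon_start = idx - idx % 3
        spliced = transcript.positions()
        codon = "".join(seq[p] for p in spliced[codon_start : codon_start + 3])
        return codon, idx % 3

    def classify_in_transcript(
        self, transcript: Transcript, pos: int, ref: str, alt: str
    ) -> str:
        """Consequence of ``ref->alt`` at ``pos`` within one transcript."""
        hit = self.codon_at(transcript, pos, None)
        if hit is None:
            return OTHER
        codon, frame = hit
        if codon[frame] != ref:
            raise GeneModelError(
                f"reference mismatch at {self.name}:{pos}: model {codon[frame]} vs {ref}"
            )
        alt_codon = codon[:frame] + alt + codon[frame + 1 :]
        return (
            SYNONYMOUS if CODON_TABLE[codon] == CODON_TABLE[alt_codon] else NONSYNONYMOUS
        )

    def classify(self, pos: int, ref: str, alt: str) -> str:
        """Consequence of a substitution across all transcripts.

        A change is nonsynonymous if it is nonsynonymous in at least one
        transcript; synonymous if it lies in a CDS and is synonymous in every
        transcript containing it; "other" when outside all CDS.
        """
        seen_cds = False
        for tr in self.transcripts:
            cls = self.classify_in_transcript(tr, pos, ref, alt)
            if cls == NONSYNONYMOUS:
                return NONSYNONYMOUS
            if cls == SYNONYMOUS:
                seen_cds = True
        return SYNONYMOUS if seen_cds else OTHER


def translate(seq: str) -> str:
    """Translate an in-frame CDS with the standard genetic code."""
    if len(seq) % 3:
        raise GeneModelError("sequence length not a codon multiple")
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))
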