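"""Core domain types: transposase records and codon alignments.

A :class:`TransposaseRecord` is one cloned transposase-domain fragment
(~360 bp of coding sequence, optionally interrupted by a short spliceosomal
intron) together with its host taxonomy and QC/classification state.
A :class:`CodonAlignment` is a column-aligned set of coding sequences in a
fixed reading frame with the intron removed.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCLEOTIDES = "ACGT"
GAP = "-"
ALPHABET = set("ACGTN-")

#: transition partners (purine<->purine, pyrimidine<->pyrimidine)
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

STATUS_FUNCTIONAL = "functional"
STATUS_FRAMESHIFT = "frameshift"
STATUS_PREMATURE_STOP = "premature_stop"
STATUS_UNCLASSIFIED = "unclassified"
STATUSES = (
    STATUS_FUNCTIONAL,
    STATUS_FRAMESHIFT,
    STATUS_PREMATURE_STOP,
    STATUS_UNCLASSIFIED,
)


def codon_table(table_id: int = 1):
    """Return the biopython codon table for a genetic code id (default: standard)."""
    return unambiguous_dna_by_id[table_id]


def stop_codons(table_id: int = 1) -> frozenset[str]:
    return frozenset(codon_table(table_id).stop_codons)


def translate_codon(codon: str, table_id: int = 1) -> str:
    """Translate one codon; stop codons yield '*', ambiguous codons yield 'X'."""
    table = codon_table(table_id)
    if codon in table.stop_codons:
        return "*"
    try:
        return table.forward_table[codon]
    except KeyError:
        return "X"


def translate(seq: str, table_id: int = 1) -> str:
    """Translate a nucleotide string codon-by-codon, dropping a trailing partial codon."""
    return "".join(
        translate_codon(seq[i : i + 3], table_id) for i in range(0, len(seq) - len(seq) % 3, 3)
    )


_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def ungap(seq: str) -> str:
    return seq.replace(GAP, "")


def internal_stop_count(coding_seq: str, table_id: int = 1) -> int:
    """Number of stop codons before the final (possibly terminal-stop) codon."""
    aa = translate(ungap(coding_seq), table_id)
    return aa[:-1].count("*") if aa else 0


@dataclass
class TransposaseRecord:
    """One cloned transposase-domain fragment.

    ``raw_seq`` is the sequence as read (possibly gapped if the input was
    aligned). ``coding_seq`` / ``intron_seq`` are filled by intron excision;
    ``coding_seq`` starts at the located reading frame. ``status`` is one of
    functional / frameshift / premature_stop / unclassified.
    """

    id: str
    raw_seq: str
    genus: str = ""
    species: str = ""
    individual_tag: str = ""
    clone_number: int | None = None
    frame_offset: int = 0
    strand: str = "+"
    coding_seq: str = ""
    intron_seq: str = ""
    status: str = STATUS_UNCLASSIFIED
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.raw_seq = self.raw_seq.upper()
        bad = set(self.raw_seq) - ALPHABET
        if bad:
            raise ValueError(f"record {self.id}: illegal characters {sorted(bad)!r}")
        if self.status not in STATUSES:
            raise ValueError(f"record {self.id}: unknown status {self.status!r}")

    @property
    def individual_key(self) -> tuple[str, str, str]:
        """Key grouping clones from the same sampled individual."""
        return (self.genus, self.species, self.individual_tag)

    def with_(self, **changes) -> "TransposaseRecord":
        return replace(self, **changes)


@dataclass
class CodonAlignment:
    """Column-aligned coding sequences in a common reading frame, intron removed."""

    records: list[tuple[str, str]]
    codon_table: int = 1

    def __post_init__(self) -> None:
        if self.records:
            lengths = {len(s) for _, s in self.records}
            if len(lengths) != 1:
                raise ValueError("aligned sequences have unequal lengths")
            (n,) = lengths
            if n % 3 != 0:
                raise ValueError(f"alignment length {n} is not a multiple of 3")
        ids = [i for i, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sequence ids in alignment")

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    @property
    def n_sites(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    @property
    def n_codons(self) -> int:
        return self.n_sites // 3

    def __len__(self) -> int:
        return len(self.records)

    def sequence(self, rec_id: str) -> str:
        for i, s in self.records:
            if i == rec_id:
                return s
        raise KeyError(rec_id)

    def codons(self, rec_id: str) -> list[str]:
        s = self.sequence(rec_id)
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def subset(self, keep_ids) -> "CodonAlignment":
        keep = set(keep_ids)
        return CodonAlignment(
            [(i, s) for i, s in self.records if i in keep], codon_table=self.codon_table
        )

    @classmethod
    def from_records(cls, records: list[TransposaseRecord], table_id: int = 1) -> "CodonAlignment":
        """Build an alignment from records whose coding_seq are already column-compatible."""
        return cls([(r.id, r.coding_seq) for r in records], codon_table=table_id)
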