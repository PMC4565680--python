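"""Sequence QC, reading-frame location, intron excision, functional classification.

The QC rules mirror a clone-library workflow: within each sampled
individual, exact duplicate clones are collapsed, and clones exactly one
substitution away from the per-individual majority consensus are removed as
likely polymerase errors. The reading frame is located by a conserved
amino-acid anchor motif (default GAMDGTH, upstream of the DD portion of the
DDE catalytic triad), the short spliceosomal intron is excised as the
GT..AG-bounded segment whose removal restores an open reading frame, and
records are classified functional / frameshift / premature_stop.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .records import (
    GAP,
    STATUS_FRAMESHIFT,
    STATUS_FUNCTIONAL,
    STATUS_PREMATURE_STOP,
    TransposaseRecord,
    internal_stop_count,
    revcomp,
    translate,
    ungap,
)

DEFAULT_UPSTREAM_MOTIF = "GAMDGTH"
DEFAULT_DOWNSTREAM_MOTIF = "ELFNPRH"
DEFAULT_INTRON_RANGE = (50, 120)


@dataclass
class AnchorSpec:
    """Conserved amino-acid motifs flanking the catalytic DD region."""

    upstream_motif: str = DEFAULT_UPSTREAM_MOTIF
    downstream_motif: str = DEFAULT_DOWNSTREAM_MOTIF
    max_mismatches: int = 1

    def __post_init__(self) -> None:
        if not self.upstream_motif or not self.downstream_motif:
            raise ValueError("anchor motifs must be nonempty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass
class QCReport:
    """Counts and per-record actions for one QC pass."""

    n_input: int = 0
    n_exact_duplicates_removed: int = 0
    n_taq_filtered: int = 0
    n_retained: int = 0
    per_record_actions: dict[str, str] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_input != (
            self.n_exact_duplicates_removed + self.n_taq_filtered + self.n_retained
        ):
            raise AssertionError("QCReport counts do not reconcile")


class AmbiguousFrameError(ValueError):
    pass


def _group_by_individual(records):
    groups: dict[tuple, list[TransposaseRecord]] = {}
    for r in records:
        groups.setdefault(r.individual_key, []).append(r)
    return groups


def dedup_exact(records: list[TransposaseRecord]) -> tuple[list[TransposaseRecord], QCReport]:
    """Collapse identical raw sequences within each individual (first kept).

    Identical sequences carried by *different* individuals are all retained:
    cross-host duplicates are exactly the signal the downstream
    horizontal-transfer screen looks for.
    """
    report = QCReport(n_input=len(records))
    kept: list[TransposaseRecord] = []
    seen: dict[tuple, set[str]] = {}
    for r in records:
        key = r.individual_key
        pool = seen.setdefault(key, set())
        if r.raw_seq in pool:
            report.n_exact_duplicates_removed += 1
            report.per_record_actions[r.id] = "removed_exact_duplicate"
        else:
            pool.add(r.raw_seq)
            kept.append(r)
            report.per_record_actions[r.id] = "retained"
    report.n_retained = len(kept)
    report.check()
    return kept, report


def consensus_sequence(seqs: list[str]) -> str:
    """Strict-majority column consensus; tie columns become 'N' (matches nothing)."""
    if not seqs:
        return ""
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("consensus requires equal-length sequences (align or pad first)")
    cols = []
    for i in range(length):
        counts = Counter(s[i] for s in seqs)
        (char, top), *rest = counts.most_common()
        if rest and rest[0][1] == top:
            cols.append("N")
        else:
            cols.append(char)
    return "".join(cols)


def taq_filter(records: list[TransposaseRecord]) -> tuple[list[TransposaseRecord], QCReport]:
    """Remove clones exactly 1 substitution from their individual's consensus.

    The consensus is strict majority per column; tie columns are 'N', which
    matches no base, so no record can owe its single difference to a tie
    column. Records at distance 0 or >= 2 are retained; singleton groups are
    their own consensus and always retained.
    """
    report = QCReport(n_input=len(records))
    kept: list[TransposaseRecord] = []
    for group in _group_by_individual(records).values():
        if len(group) == 1:
            kept.extend(group)
            report.per_record_actions[group[0].id] = "retained"
            continue
        if len({len(r.raw_seq) for r in group}) != 1:
            # unequal lengths (unaligned indel variants): no consensus is
            # defined, so the group passes through unfiltered
            kept.extend(group)
            for r in group:
                report.per_record_actions[r.id] = "retained_unequal_length"
            continue
        cons = consensus_sequence([r.raw_seq for r in group])
        for r in group:
            dist = sum(a != b for a, b in zip(r.raw_seq, cons))
            if dist == 1:
                report.n_taq_filtered += 1
                report.per_record_actions[r.id] = "removed_taq_1bp"
            else:
                kept.append(r)
                report.per_record_actions[r.id] = "retained"
    # preserve input order
    order = {r.id: i for i, r in enumerate(records)}
    kept.sort(key=lambda r: order[r.id])
    report.n_retained = len(kept)
    report.check()
    return kept, report


def _motif_best_hit(protein: str, motif: str) -> tuple[int, int] | None:
    """(mismatches, position) of the best motif placement, or None if protein too short."""
    m = len(motif)
    if len(protein) < m:
        return None
    best = None
    for i in range(len(protein) - m + 1):
        mm = sum(a != b for a, b in zip(protein[i : i + m], motif))
        if best is None or mm < best[0]:
            best = (mm, i)
    return best


def locate_frame(
    record: TransposaseRecord, anchors: AnchorSpec | None = None, table_id: int = 1
) -> tuple[int, str]:
    """Find (frame_offset, strand) of the transposase reading frame.

    The frame whose conceptual translation carries the upstream anchor motif
    (within ``max_mismatches``) wins; with no motif hit anywhere, the frame
    with the fewest internal stop codons wins. Ties prefer the + strand,
    then the lowest offset. All six frames carrying the motif, or a
    too-short sequence, is an ambiguity error.
    """
    anchors = anchors or AnchorSpec()
    seq = ungap(record.raw_seq)
    if len(seq) < 60:
        raise AmbiguousFrameError(f"record {record.id}: sequence too short to locate frame")
    frames = []  # (offset, strand, protein)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for off in (0, 1, 2):
            frames.append((off, strand, translate(s[off:], table_id)))

    hits = []
    for off, strand, prot in frames:
        hit = _motif_best_hit(prot, anchors.upstream_motif)
        if hit is not None and hit[0] <= anchors.max_mismatches:
            hits.append((hit[0], 0 if strand == "+" else 1, off, strand))
    if len(hits) == 6:
        raise AmbiguousFrameError(
            f"record {record.id}: anchor motif found in all six frames (ambiguous)"
        )
    if hits:
        hits.sort()
        _, _, off, strand = hits[0]
        return off, strand
    stops = [
        (prot[:-1].count("*"), 0 if strand == "+" else 1, off, strand)
        for off, strand, prot in frames
    ]
    stops.sort()
    _, _, off, strand = stops[0]
    return off, strand


def oriented_sequence(record: TransposaseRecord) -> str:
    """The raw sequence in + orientation of the located frame, gaps removed."""
    seq = ungap(record.raw_seq)
    return seq if record.strand == "+" else revcomp(seq)


def excise_intron(
    record: TransposaseRecord,
    anchors: AnchorSpec | None = None,
    intron_range: tuple[int, int] = DEFAULT_INTRON_RANGE,
    table_id: int = 1,
) -> TransposaseRecord:
    """Excise the spliceosomal intron, filling ``coding_seq`` and ``intron_seq``.

    The intron is the GT..AG-bounded segment, with plausible length
    (default 50-120 nt), whose removal yields a stop-free reading frame from
    the located frame offset. A sequence already stop-free and in frame is
    taken as intron-less. Among several stop-free candidates, placements
    whose spliced translation carries the downstream anchor motif are
    preferred; residual ties are flagged ambiguous and resolved leftmost.
    Records with no valid segment keep ``intron_seq == \"\"`` and the raw
    coding region.
    """
    anchors = anchors or AnchorSpec()
    lo, hi = intron_range
    seq = oriented_sequence(record)
    off = record.frame_offset
    frame_seq = seq[off:]

    if len(frame_seq) % 3 == 0 and internal_stop_count(frame_seq, table_id) == 0:
        return record.with_(coding_seq=frame_seq, intron_seq="")

    candidates = []  # (anchor_miss, start, end)
    for i in range(off, len(seq) - 3):
        if seq[i : i + 2] != "GT":
            continue
        for length in range(lo, hi + 1):
            j = i + length
            if j > len(seq) or seq[j - 2 : j] != "AG":
                continue
            spliced = seq[off:i] + seq[j:]
            if len(spliced) % 3 != 0 or internal_stop_count(spliced, table_id) > 0:
                continue
            prot = translate(spliced, table_id)
            hit = _motif_best_hit(prot, anchors.downstream_motif)
            anchor_miss = hit[0] if hit else len(anchors.downstream_motif)
            candidates.append((anchor_miss, i, j))

    if not candidates:
        return record.with_(coding_seq=frame_seq, intron_seq="")

    candidates.sort()
    best_miss = candidates[0][0]
    top = [c for c in candidates if c[0] == best_miss]
    flags = list(record.flags)
    if len(top) > 1:
        flags = flags + ["ambiguous_intron_placement"]
    _, i, j = top[0]
    return record.with_(
        coding_seq=seq[off:i] + seq[j:], intron_seq=seq[i:j], flags=flags
    )


def classify_functional(record: TransposaseRecord, table_id: int = 1) -> str:
    """Classify a record by its extracted coding sequence.

    frameshift: ungapped coding length not divisible by 3, or (for aligned
    input) an internal gap run of length not divisible by 3; premature_stop:
    an in-frame stop before the final codon; otherwise functional.
    """
    coding = record.coding_seq
    if not coding:
        raise ValueError(f"record {record.id}: coding_seq not extracted")
    plain = ungap(coding)
    if len(plain) % 3 != 0:
        return STATUS_FRAMESHIFT
    run = 0
    inner = coding.strip(GAP)
    for ch in inner:
        if ch == GAP:
            run += 1
        elif run:
            if run % 3 != 0:
                return STATUS_FRAMESHIFT
            run = 0
    if internal_stop_count(plain, table_id) > 0:
        return STATUS_PREMATURE_STOP
    return STATUS_FUNCTIONAL


def classify_all(records: list[TransposaseRecord], table_id: int = 1) -> list[TransposaseRecord]:
    return [r.with_(status=classify_functional(r, table_id)) for r in records]
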