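"""Identity-based horizontal-transfer screen.

The conservative criterion: a pair of coding sequences from *different*
genera that are fully identical cannot plausibly have diverged vertically
with their hosts over tribe-scale time (~13-25 My), because purifying
selection does not prevent synonymous changes from accumulating. Identical
cross-genus pairs are therefore flagged as HT-consistent; near-identical
pairs (default >= 99%) are reported as secondary candidates, and intron
identity is attached as corroborating evidence where both introns exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
from Bio import Align

from .evometrics import ng_pairwise, pairwise_identity
from .records import STATUS_FUNCTIONAL, TransposaseRecord, ungap


@dataclass
class HTCandidate:
    """A cross-genus sequence pair implicating horizontal transfer."""

    id_a: str
    id_b: str
    genus_a: str
    genus_b: str
    coding_identity: float
    intron_identity: float | None = None
    tier: str = "identical"
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genus_a == self.genus_b:
            raise ValueError("HT candidate requires distinct genera")
        if self.tier == "identical" and self.coding_identity != 1.0:
            raise ValueError("tier=identical requires coding_identity == 1.0")


def _cross_genus_pairs(records: list[TransposaseRecord]):
    for a, b in combinations(records, 2):
        if a.genus and b.genus and a.genus != b.genus:
            yield a, b


def find_identical_cross_genus(records: list[TransposaseRecord]) -> list[HTCandidate]:
    """All cross-genus pairs with fully identical coding regions.

    Identity is computed over aligned coding sequences with gap/N columns
    excluded pairwise; same-genus identical pairs are ignored (within-genus
    duplication explains them without transfer).
    """
    out = []
    for a, b in _cross_genus_pairs(records):
        ident = pairwise_identity(a.coding_seq, b.coding_seq)
        if ident == 1.0:
            out.append(
                HTCandidate(
                    id_a=a.id, id_b=b.id, genus_a=a.genus, genus_b=b.genus,
                    coding_identity=1.0, tier="identical",
                )
            )
    return out


def find_near_identical(
    records: list[TransposaseRecord], threshold: float = 0.99
) -> list[HTCandidate]:
    """Cross-genus pairs with threshold <= identity < 1, identity-descending."""
    out = []
    for a, b in _cross_genus_pairs(records):
        ident = pairwise_identity(a.coding_seq, b.coding_seq)
        if threshold <= ident < 1.0:
            out.append(
                HTCandidate(
                    id_a=a.id, id_b=b.id, genus_a=a.genus, genus_b=b.genus,
                    coding_identity=ident, tier="near_identical",
                )
            )
    out.sort(key=lambda c: (-c.coding_identity, c.id_a, c.id_b))
    return out


def _global_intron_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def corroborate_with_intron(
    candidate: HTCandidate, introns: dict[str, str]
) -> HTCandidate:
    """Attach intron identity (global alignment) to a candidate.

    A recent transfer leaves the fast-evolving intron nearly identical too;
    a missing intron on either side yields ``intron_identity = None`` with a
    note.
    """
    ia = ungap(introns.get(candidate.id_a) or "")
    ib = ungap(introns.get(candidate.id_b) or "")
    if not ia or not ib:
        candidate.intron_identity = None
        candidate.notes.append("intron missing on one or both members")
        return candidate
    aln = _global_intron_aligner().align(ia, ib)[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    candidate.intron_identity = matches / len(sa)
    return candidate


def ht_report(
    candidates: list[HTCandidate],
    records: list[TransposaseRecord],
    host_divergence_mya: tuple[float, float] = (13.0, 25.0),
    syn_clock: float = 1e-8,
    table_id: int = 1,
) -> pd.DataFrame:
    """Contextualize candidates against expected vertical-descent divergence.

    For each pair the expected number of synonymous substitutions under
    vertical descent is 2 x divergence-time x syn_clock x synonymous sites
    (reported for both ends of the host-divergence window, in years). A
    candidate is flagged HT-consistent when even the minimum expectation is
    >= 1 substitution yet the observed synonymous differences are below a
    tenth of it. The functional status of both members is included: a
    nonfunctional member cannot owe its conservation to selection, which
    strengthens the HT interpretation.
    """
    by_id = {r.id: r for r in records}
    rows = []
    t_lo, t_hi = host_divergence_mya
    for c in candidates:
        ra, rb = by_id[c.id_a], by_id[c.id_b]
        res = ng_pairwise(ra.coding_seq, rb.coding_seq, table_id)
        exp_lo = 2.0 * t_lo * 1e6 * syn_clock * res.S
        exp_hi = 2.0 * t_hi * 1e6 * syn_clock * res.S
        flagged = exp_lo >= 1.0 and res.Sd < 0.1 * exp_lo
        notes = list(c.notes)
        if ra.status != STATUS_FUNCTIONAL or rb.status != STATUS_FUNCTIONAL:
            notes.append("member not under selective constraint (nonfunctional)")
        rows.append(
            {
                "id_a": c.id_a, "id_b": c.id_b,
                "genus_a": c.genus_a, "genus_b": c.genus_b,
                "tier": c.tier,
                "coding_identity": c.coding_identity,
                "intron_identity": c.intron_identity,
                "status_a": ra.status, "status_b": rb.status,
                "syn_sites": res.S,
                "observed_syn_diffs": res.Sd,
                "expected_syn_min": exp_lo,
                "expected_syn_max": exp_hi,
                "ht_consistent": flagged,
                "notes": "; ".join(notes),
            }
        )
    return pd.DataFrame(rows)
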