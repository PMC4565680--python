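"""Pairwise divergence and codon-level selection statistics.

Synonymous/nonsynonymous counting follows the Nei-Gojobori approach with an
optional transition/transversion weighting: at every codon position each of
the three possible changes gets weight R (the transition) or 0.5 (each
transversion), changes creating stop codons are excluded from numerator and
denominator, and the synonymous fraction of each position is the weighted
fraction of synonymous changes. With R = 0.5 all changes are weighted
equally and the counting reduces to the unmodified method. Observed
synonymous/nonsynonymous differences per codon pair are averaged with equal
weight over all minimal mutational pathways, excluding pathways through
stop codons. Proportions are corrected with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p), and omega = dN/dS (undefined when dS = 0).

The neutrality Z-test uses Z = (dN - dS) / SE, with SE estimated by a
seeded bootstrap over codon columns, and a standard-normal reference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm

from .records import (
    GAP,
    NUCLEOTIDES,
    TRANSITIONS,
    CodonAlignment,
    stop_codons,
    translate_codon,
)


class SaturationError(ValueError):
    """p-distance at or beyond the Jukes-Cantor domain boundary (p >= 0.75)."""


class IdenticalSequencesError(ValueError):
    """Operation undefined for an identical sequence pair (division by zero)."""


def pairwise_identity(a: str, b: str, policy: str = "pairwise_deletion") -> float:
    """Fraction of matching sites between two equal-length (gapped) sequences.

    Under ``pairwise_deletion`` columns with a gap or N in either sequence
    are skipped; under ``complete`` every column is compared and gap/N
    mismatch everything (N matches nothing, including N).
    """
    if len(a) != len(b):
        raise ValueError("sequences must have equal (aligned) length")
    if policy not in ("pairwise_deletion", "complete"):
        raise ValueError(f"unknown policy {policy!r}")
    matches = compared = 0
    for x, y in zip(a.upper(), b.upper()):
        if policy == "pairwise_deletion" and (x in (GAP, "N") or y in (GAP, "N")):
            continue
        compared += 1
        if x == y and x not in (GAP, "N"):
            matches += 1
    if compared == 0:
        raise ValueError("no comparable columns between sequences")
    return matches / compared


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3) p) for p in [0, 0.75)."""
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"p = {p} is at/beyond the Jukes-Cantor saturation bound 0.75")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def _change_weight(x: str, y: str, R: float) -> float:
    return R if (x, y) in TRANSITIONS else 0.5


@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, table_id: int, R: float) -> tuple[float, float]:
    stops = stop_codons(table_id)
    if codon in stops:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = translate_codon(codon, table_id)
    s = 0.0
    for pos in range(3):
        syn_w = tot_w = 0.0
        for alt in NUCLEOTIDES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if mutant in stops:
                continue
            w = _change_weight(codon[pos], alt, R)
            tot_w += w
            if translate_codon(mutant, table_id) == aa:
                syn_w += w
        if tot_w > 0:
            s += syn_w / tot_w
    return s, 3.0 - s


def ng_site_counts(codon: str, table_id: int = 1, R: float = 0.5) -> tuple[float, float]:
    """Potential (synonymous, nonsynonymous) site counts for one codon.

    Codons containing N or gaps signal exclusion with ``ValueError``;
    callers drop such codons pairwise.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(c not in NUCLEOTIDES for c in codon):
        raise ValueError(f"codon {codon!r} contains non-ACGT characters (excluded)")
    return _site_counts_cached(codon, table_id, float(R))


@lru_cache(maxsize=None)
def _pair_differences_cached(c1: str, c2: str, table_id: int) -> tuple[float, float]:
    """(syn, nonsyn) difference counts, averaged over minimal pathways.

    Pathways passing through stop codons are excluded; if every pathway is
    blocked, all pathways count (keeps Sd + Nd equal to the observed
    nucleotide difference count).
    """
    stops = stop_codons(table_id)
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops:
                blocked = True
            if translate_codon(cur, table_id) == translate_codon(nxt, table_id):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd, blocked

    paths = [walk(order) for order in itertools.permutations(diff_pos)]
    open_paths = [p for p in paths if not p[2]]
    use = open_paths if open_paths else paths
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def codon_pair_differences(c1: str, c2: str, table_id: int = 1) -> tuple[float, float]:
    """Observed (Sd, Nd) contribution of one aligned codon pair."""
    c1, c2 = c1.upper(), c2.upper()
    stops = stop_codons(table_id)
    if c1 in stops or c2 in stops:
        raise ValueError("stop codon in compared pair (excluded)")
    return _pair_differences_cached(c1, c2, table_id)


@dataclass
class CodonCountResult:
    """Nei-Gojobori counts and distances for one sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None
    n_codons: int
    identical: bool = False

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        return d


def _usable_codon(c: str) -> bool:
    return all(ch in NUCLEOTIDES for ch in c)


def _ng_components(a: str, b: str, table_id: int = 1, R: float = 0.5):
    """Per-codon arrays (s_avg, n_avg, sd, nd) over pairwise-comparable codons."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal aligned length")
    if len(a) % 3 != 0:
        raise ValueError("aligned length must be a multiple of 3")
    stops = stop_codons(table_id)
    s_arr, n_arr, sd_arr, nd_arr = [], [], [], []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3].upper(), b[i : i + 3].upper()
        if not (_usable_codon(ca) and _usable_codon(cb)):
            continue
        if ca in stops or cb in stops:
            continue
        sa, na = ng_site_counts(ca, table_id, R)
        sb, nb = ng_site_counts(cb, table_id, R)
        sd, nd = codon_pair_differences(ca, cb, table_id)
        s_arr.append(0.5 * (sa + sb))
        n_arr.append(0.5 * (na + nb))
        sd_arr.append(sd)
        nd_arr.append(nd)
    return (np.array(s_arr), np.array(n_arr), np.array(sd_arr), np.array(nd_arr))


def ng_pairwise(a: str, b: str, table_id: int = 1, R: float = 0.5) -> CodonCountResult:
    """Nei-Gojobori counts, proportions, JC distances and omega for a pair.

    Codons with gaps, N, or a stop in either sequence are dropped pairwise.
    An identical pair is returned with ``identical=True`` and undefined
    omega rather than a silent 0/0.
    """
    s_arr, n_arr, sd_arr, nd_arr = _ng_components(a, b, table_id, R)
    if s_arr.size == 0:
        raise ValueError("no comparable codons between sequences")
    S, N = float(s_arr.sum()), float(n_arr.sum())
    Sd, Nd = float(sd_arr.sum()), float(nd_arr.sum())
    pS, pN = Sd / S, Nd / N
    dS, dN = jc_correct(pS), jc_correct(pN)
    identical = (Sd + Nd) == 0
    omega = (dN / dS) if dS > 0 else None
    return CodonCountResult(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, dS=dS, dN=dN,
        omega=omega, n_codons=int(s_arr.size), identical=identical,
    )


@dataclass
class NeutralityTest:
    """Codon-based Z-test of the neutral null dN = dS."""

    statistic: float
    p_value: float
    alternative: str
    n_bootstrap: int
    seed: int
    n_codons: int
    low_power: bool = False

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _jc_safe(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, np.nan)
    ok = p < 0.75
    out[ok] = -0.75 * np.log1p(-(4.0 / 3.0) * p[ok])
    return out


def z_test_neutrality(
    a: str,
    b: str,
    table_id: int = 1,
    R: float = 0.5,
    n_bootstrap: int = 1000,
    seed: int = 0,
    alternative: str = "two_sided",
) -> NeutralityTest:
    """Z-test of neutrality for one pair, SE by codon-column bootstrap.

    ``alternative``: ``two_sided`` (dN != dS), ``purifying`` (dN < dS), or
    ``positive`` (dN > dS). Raises on an identical pair.
    """
    if alternative not in ("two_sided", "purifying", "positive"):
        raise ValueError(f"unknown alternative {alternative!r}")
    s_arr, n_arr, sd_arr, nd_arr = _ng_components(a, b, table_id, R)
    m = s_arr.size
    if m == 0:
        raise ValueError("no comparable codons between sequences")
    if sd_arr.sum() + nd_arr.sum() == 0:
        raise IdenticalSequencesError(
            "identical sequence pair: dN - dS is 0/0, Z-test undefined"
        )
    dN = jc_correct(float(nd_arr.sum() / n_arr.sum()))
    dS = jc_correct(float(sd_arr.sum() / s_arr.sum()))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, m, size=(n_bootstrap, m))
    S_b = s_arr[idx].sum(axis=1)
    N_b = n_arr[idx].sum(axis=1)
    Sd_b = sd_arr[idx].sum(axis=1)
    Nd_b = nd_arr[idx].sum(axis=1)
    stat_b = _jc_safe(Nd_b / N_b) - _jc_safe(Sd_b / S_b)
    stat_b = stat_b[np.isfinite(stat_b)]
    se = float(np.std(stat_b, ddof=1)) if stat_b.size > 1 else float("nan")
    if not se or math.isnan(se):
        raise ValueError("bootstrap standard error is zero/undefined; Z-test not computable")
    z = (dN - dS) / se
    if alternative == "two_sided":
        p = 2.0 * float(norm.sf(abs(z)))
    elif alternative == "purifying":
        p = float(norm.cdf(z))
    else:
        p = float(norm.sf(z))
    return NeutralityTest(
        statistic=z, p_value=min(p, 1.0), alternative=alternative,
        n_bootstrap=n_bootstrap, seed=seed, n_codons=int(m), low_power=m < 10,
    )


def drop_identical_duplicates(aln: CodonAlignment) -> tuple[CodonAlignment, list[tuple[str, str]]]:
    """Keep the first of every identical-sequence group; report (kept, removed) pairs."""
    kept: list[tuple[str, str]] = []
    removed: list[tuple[str, str]] = []
    seen: dict[str, str] = {}
    for rec_id, seq in aln.records:
        if seq in seen:
            removed.append((seen[seq], rec_id))
        else:
            seen[seq] = rec_id
            kept.append((rec_id, seq))
    return CodonAlignment(kept, codon_table=aln.codon_table), removed


def summarize_selection(
    aln: CodonAlignment,
    R: float = 0.5,
    n_bootstrap: int = 1000,
    seed: int = 0,
    alternative: str = "two_sided",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """All-pairs selection scan over a functional codon alignment.

    One member of every identical-sequence pair is removed first (the
    earlier record is kept). Returns the per-pair table and a summary with
    the mean of defined omegas and the fraction of testable pairs rejecting
    neutrality at ``alpha``.
    """
    if len(aln) < 2:
        raise ValueError("selection summary needs at least 2 sequences")
    aln, removed = drop_identical_duplicates(aln)
    if len(aln) < 2:
        raise ValueError("all sequences identical; selection summary undefined")
    rows = []
    table_id = aln.codon_table
    ids = aln.ids
    for k, (ia, ib) in enumerate(itertools.combinations(range(len(ids)), 2)):
        a, b = aln.records[ia][1], aln.records[ib][1]
        res = ng_pairwise(a, b, table_id, R)
        z = p = None
        if not res.identical:
            try:
                t = z_test_neutrality(
                    a, b, table_id, R, n_bootstrap, seed + k, alternative
                )
                z, p = t.statistic, t.p_value
            except ValueError:
                pass
        rows.append(
            {
                "id_a": ids[ia], "id_b": ids[ib],
                "S": res.S, "N": res.N, "Sd": res.Sd, "Nd": res.Nd,
                "dS": res.dS, "dN": res.dN, "omega": res.omega,
                "Z": z, "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    omegas = table["omega"].dropna()
    tested = table["p_value"].dropna()
    summary = {
        "n_sequences": len(aln),
        "n_identical_removed": len(removed),
        "identical_pairs_removed": removed,
        "n_pairs": len(table),
        "mean_omega": float(omegas.mean()) if len(omegas) else None,
        "frac_rejecting_neutrality": float((tested < alpha).mean()) if len(tested) else None,
    }
    return table, summary


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered ids."""

    ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.values < 0).any():
            raise ValueError("negative distances")

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(
    aln: CodonAlignment, model: str = "jc", policy: str = "pairwise_deletion"
) -> DistanceMatrix:
    """Nucleotide distance matrix from an alignment (p-distance or JC)."""
    if model not in ("jc", "p"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = aln.ids
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = 1.0 - pairwise_identity(aln.records[i][1], aln.records[j][1], policy)
            mat[i, j] = mat[j, i] = jc_correct(p) if model == "jc" else p
    return DistanceMatrix(ids=ids, values=mat)


def identity_range(aln: CodonAlignment, policy: str = "pairwise_deletion") -> tuple[float, float, tuple[str, str]]:
    """(min_identity, max_identity, most-divergent pair) over all pairs."""
    best = None
    lo, hi = 1.0, 0.0
    for (ia, sa), (ib, sb) in itertools.combinations(aln.records, 2):
        ident = pairwise_identity(sa, sb, policy)
        hi = max(hi, ident)
        if best is None or ident < lo:
            lo, best = ident, (ia, ib)
    if best is None:
        raise ValueError("identity range needs at least 2 sequences")
    return lo, hi, best
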