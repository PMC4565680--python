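"""Forward simulation of a transposase family within a host genus phylogeny.

The generator emulates the statistical structure the analysis pipeline
assumes: several deeply diverged ancestral transposase lineages transmitted
vertically through an ultrametric host-genus tree (genus splits confined to
the 13-25 My window of the wheat tribe's radiation), purifying selection on
functional copies (nonsynonymous changes accepted with probability omega,
changes creating stop codons rejected), pseudogenization events that insert
a literal frameshift or premature stop and switch the copy to neutral
evolution, a fast-evolving spliceosomal intron with conserved GT..AG splice
dinucleotides, and optional horizontal transfers that copy a donor sequence
verbatim into another genus.

Indels are modelled as deletions in a fixed master coordinate system, so
the emitted alignment is exact by construction. All output is a pure
function of (params, seed).
"""

from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import yaml

from .phylo import Phylogeny
from .records import NUCLEOTIDES, TransposaseRecord, stop_codons, translate_codon

_GENUS_NAMES = [f"Genus{chr(65 + i)}" for i in range(26)]


@dataclass
class SimParams:
    """Simulation parameters; rates are per copy per million years.

    ``clock_rate`` is the accepted neutral substitution rate per site per
    My; ``burn_in`` is the expected pairwise proposal divergence
    (substitutions/site) between ancestral lineage founders.
    """

    n_genera: int = 8
    tribe_age: float = 25.0
    min_split_frac: float = 13.0 / 25.0
    n_ancestral_lineages: int = 4
    dup_rate: float = 0.03
    loss_rate: float = 0.02
    pseudo_rate: float = 0.025
    ht_rate: float = 0.0
    forced_ht_age: float | None = None
    omega_functional: float = 0.2
    kappa: float = 1.0
    coding_codons: int = 120
    intron_length: int = 80
    intron_rate_multiplier: float = 2.0
    intron_del_rate: float = 0.01
    intron_min_length: int = 50
    intron_after_codon: int = 78
    clock_rate: float = 0.003
    burn_in: float = 0.3
    max_copies: int = 10_000
    codon_table: int = 1

    def __post_init__(self) -> None:
        for name in ("dup_rate", "loss_rate", "pseudo_rate", "ht_rate",
                     "clock_rate", "burn_in", "intron_del_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.omega_functional <= 0:
            raise ValueError("omega_functional must be > 0")
        if self.coding_codons < 10:
            raise ValueError("coding_codons must be >= 10")
        if self.n_genera < 2:
            raise ValueError("n_genera must be >= 2")
        if not (0 <= self.min_split_frac < 1):
            raise ValueError("min_split_frac must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground-truth event log and per-record labels."""

    events: list[dict] = field(default_factory=list)
    lineage_of: dict[str, str] = field(default_factory=dict)
    status_of: dict[str, str] = field(default_factory=dict)
    ht_pairs: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# Host tree


def simulate_host_tree(
    n_genera: int, tribe_age: float = 25.0, seed: int = 0, min_split_frac: float = 13.0 / 25.0
) -> Phylogeny:
    """Seeded ultrametric genus tree: root at ``tribe_age``, Yule-style topology.

    All split ages (including the root) lie in
    ``[min_split_frac * tribe_age, tribe_age]``, reflecting a radiation in
    which extant genera are separated by deep divergences.
    """
    if n_genera < 2:
        raise ValueError("need at least 2 genera")
    rng = np.random.default_rng(seed)
    ages = [tribe_age]
    if n_genera > 2:
        lo = min_split_frac * tribe_age
        ages += sorted(rng.uniform(lo, tribe_age, size=n_genera - 2), reverse=True)

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    root = tree.seed_node
    root.age_my = ages[0]
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append(child)
    for age in ages[1:]:
        idx = int(rng.integers(0, len(active)))
        node = active.pop(idx)
        node.age_my = age
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append(child)
    for i, leaf in enumerate(active):
        leaf.age_my = 0.0
        leaf.taxon = tns.new_taxon(_GENUS_NAMES[i % 26] + ("" if i < 26 else str(i)))
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age_my - node.age_my
    return Phylogeny(tree=tree)


# ---------------------------------------------------------------------------
# Sequence machinery


@dataclass
class _Copy:
    coding: list  # master coords, '-' for deleted sites
    intron: list
    functional: bool
    lineage: str
    uid: int


def _random_coding(rng, n_codons: int, table_id: int) -> list:
    stops = stop_codons(table_id)
    out = []
    for _ in range(n_codons):
        while True:
            codon = "".join(rng.choice(list(NUCLEOTIDES), size=3))
            if codon not in stops:
                break
        out.extend(codon)
    return out


def _random_intron(rng, length: int) -> list:
    body = list(rng.choice(list(NUCLEOTIDES), size=length - 4))
    return list("GT") + body + list("AG")


def _propose_alt(rng, base: str, kappa: float) -> str:
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
    transversions = [n for n in NUCLEOTIDES if n != base and n != transition]
    total = kappa + 2.0
    u = rng.random() * total
    if u < kappa:
        return transition
    return transversions[0] if u < kappa + 1.0 else transversions[1]


def _evolve_coding(rng, cp: _Copy, expected_per_site: float, params: SimParams) -> None:
    sites = [i for i, ch in enumerate(cp.coding) if ch != "-"]
    if not sites:
        return
    stops = stop_codons(params.codon_table)
    n_events = rng.poisson(expected_per_site * len(sites))
    for _ in range(n_events):
        pos = sites[int(rng.integers(0, len(sites)))]
        old = cp.coding[pos]
        alt = _propose_alt(rng, old, params.kappa)
        if cp.functional:
            k = pos // 3
            codon = "".join(cp.coding[3 * k : 3 * k + 3])
            mutant = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
            if mutant in stops:
                continue
            if translate_codon(mutant, params.codon_table) != translate_codon(
                codon, params.codon_table
            ):
                if rng.random() >= params.omega_functional:
                    continue
        cp.coding[pos] = alt


def _evolve_intron(rng, cp: _Copy, dt: float, params: SimParams) -> None:
    # ends (GT..AG) are conserved; interior evolves neutrally and faster
    interior = [i for i in range(2, len(cp.intron) - 2) if cp.intron[i] != "-"]
    if not interior:
        return
    rate = params.clock_rate * params.intron_rate_multiplier
    for _ in range(rng.poisson(rate * dt * len(interior))):
        pos = interior[int(rng.integers(0, len(interior)))]
        cp.intron[pos] = _propose_alt(rng, cp.intron[pos], params.kappa)
    for _ in range(rng.poisson(params.intron_del_rate * dt)):
        ungapped = sum(ch != "-" for ch in cp.intron)
        run = int(rng.integers(1, 4))
        if ungapped - run < params.intron_min_length:
            continue
        live = [i for i in range(2, len(cp.intron) - 2) if cp.intron[i] != "-"]
        if len(live) <= run:
            continue
        start = int(rng.integers(0, len(live) - run + 1))
        for i in live[start : start + run]:
            cp.intron[i] = "-"


def _pseudogenize(rng, cp: _Copy, params: SimParams) -> str:
    """Insert a literal lesion and release selective constraint."""
    cp.functional = False
    stops = list(stop_codons(params.codon_table))
    live = [i for i, ch in enumerate(cp.coding) if ch != "-"]
    if rng.random() < 0.5:
        run = int(rng.integers(1, 3))  # 1-2 nt frameshift deletion
        start = int(rng.integers(0, len(live) - run))
        for i in live[start : start + run]:
            cp.coding[i] = "-"
        return "frameshift"
    k = int(rng.integers(1, params.coding_codons - 1))
    stop = stops[int(rng.integers(0, len(stops)))]
    cp.coding[3 * k : 3 * k + 3] = list(stop)
    return "stop"


# ---------------------------------------------------------------------------
# Main simulation


def simulate_te_evolution(
    host: Phylogeny, params: SimParams, seed: int = 0
) -> tuple[list[TransposaseRecord], SimTruth]:
    """Evolve a transposase family down the host tree; return records + truth.

    Within each inter-split epoch every copy independently experiences
    duplication / loss / pseudogenization as Poisson processes (Gillespie
    within the epoch) while its coding and intron sequences accumulate
    substitutions; horizontal transfers copy a random extant copy verbatim
    from one genus into another at the event time.
    """
    rng = np.random.default_rng(seed)
    truth = SimTruth()
    uid_counter = [0]

    def new_uid() -> int:
        uid_counter[0] += 1
        return uid_counter[0]

    # ancestral lineage founders, pre-diverged by burn-in
    ancestor = _random_coding(rng, params.coding_codons, params.codon_table)
    base_intron = _random_intron(rng, params.intron_length)
    founders = []
    for li in range(params.n_ancestral_lineages):
        cp = _Copy(
            coding=list(ancestor), intron=list(base_intron),
            functional=True, lineage=f"L{li + 1}", uid=new_uid(),
        )
        _evolve_coding(rng, cp, params.burn_in / 2.0, params)
        # intron burn-in on the same per-site scale, sped up by its multiplier
        _evolve_intron(rng, cp, params.burn_in / 2.0 / params.clock_rate, params)
        founders.append(cp)

    tree = host.tree
    # epochs between node ages; each host-tree edge is segmented by epoch
    node_ages = {}
    for node in tree.preorder_node_iter():
        node_ages[node] = getattr(node, "age_my", None)
    if any(v is None for v in node_ages.values()):
        # recover ages from edge lengths (leaves at 0)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node_ages[node] = 0.0
            else:
                child = node.child_nodes()[0]
                node_ages[node] = node_ages[child] + (child.edge.length or 0.0)

    root = tree.seed_node
    root_age = node_ages[root]
    # genomes: active host branch -> list of copies; branch identified by child node
    genomes: dict = {child: [ _copy.deepcopy(f) for f in founders ] for child in root.child_nodes()}
    for copies in genomes.values():
        for cp in copies:
            cp.uid = new_uid()

    split_nodes = sorted(
        (n for n in tree.preorder_node_iter() if not n.is_leaf() and n is not root),
        key=lambda n: -node_ages[n],
    )
    boundaries = [root_age] + [node_ages[n] for n in split_nodes] + [0.0]

    ht_times: list[tuple[float, str]] = []
    if params.ht_rate > 0:
        total_len = sum(
            (n.edge.length or 0.0) for n in tree.preorder_node_iter() if n.parent_node
        )
        for _ in range(rng.poisson(params.ht_rate * total_len)):
            ht_times.append((float(rng.uniform(0.0, root_age)), "rate"))
    if params.forced_ht_age is not None:
        ht_times.append((float(params.forced_ht_age), "forced"))
    ht_times.sort(reverse=True)

    def genus_of(branch_node) -> str:
        leaf = next(branch_node.leaf_iter())
        return leaf.taxon.label

    def evolve_epoch(copies: list, t_hi: float, t_lo: float) -> list:
        """Gillespie per copy over [t_lo, t_hi] (ages, decreasing)."""
        out = []
        stack = [(cp, t_hi) for cp in copies]
        total_rate = params.dup_rate + params.loss_rate + params.pseudo_rate
        while stack:
            if len(out) + len(stack) > params.max_copies:
                raise RuntimeError(
                    f"copy-number explosion: > max_copies={params.max_copies} "
                    "extant copies within one epoch"
                )
            cp, t = stack.pop()
            while True:
                dt_next = (
                    rng.exponential(1.0 / total_rate) if total_rate > 0 else float("inf")
                )
                dt = min(dt_next, t - t_lo)
                _evolve_coding(rng, cp, params.clock_rate * dt, params)
                _evolve_intron(rng, cp, dt, params)
                t -= dt
                if dt < dt_next or t <= t_lo:
                    out.append(cp)
                    break
                u = rng.random() * total_rate
                if u < params.dup_rate:
                    dup = _copy.deepcopy(cp)
                    dup.uid = new_uid()
                    truth.events.append(
                        {"time": t, "type": "duplication", "lineage": cp.lineage}
                    )
                    stack.append((dup, t))
                elif u < params.dup_rate + params.loss_rate:
                    truth.events.append(
                        {"time": t, "type": "loss", "lineage": cp.lineage}
                    )
                    break
                else:
                    if cp.functional:
                        lesion = _pseudogenize(rng, cp, params)
                        truth.events.append(
                            {
                                "time": t,
                                "type": "pseudogenization",
                                "lineage": cp.lineage,
                                "lesion": lesion,
                            }
                        )
        return out

    split_iter = iter(split_nodes)
    next_split = next(split_iter, None)
    ht_queue = list(ht_times)
    for t_hi, t_lo in zip(boundaries[:-1], boundaries[1:]):
        if t_hi <= t_lo:
            pass
        else:
            # horizontal transfers inside this epoch, in time order
            seg_hi = t_hi
            while ht_queue and t_lo <= ht_queue[0][0] < t_hi and len(genomes) > 1:
                ht_age, kind = ht_queue.pop(0)
                for br in list(genomes):
                    genomes[br] = evolve_epoch(genomes[br], seg_hi, ht_age)
                donors = [br for br in genomes if genomes[br]]
                if donors:
                    donor = donors[int(rng.integers(0, len(donors)))]
                    others = [br for br in genomes if br is not donor]
                    recipient = others[int(rng.integers(0, len(others)))]
                    src = genomes[donor][int(rng.integers(0, len(genomes[donor])))]
                    xfer = _copy.deepcopy(src)
                    xfer.uid = new_uid()
                    genomes[recipient].append(xfer)
                    ev = {
                        "time": ht_age,
                        "type": "ht",
                        "kind": kind,
                        "lineage": src.lineage,
                        "donor_genus": genus_of(donor),
                        "recipient_genus": genus_of(recipient),
                    }
                    truth.events.append(ev)
                    truth.ht_pairs.append(
                        {
                            "donor_uid": src.uid,
                            "recipient_uid": xfer.uid,
                            "donor_genus": genus_of(donor),
                            "recipient_genus": genus_of(recipient),
                            "time": ht_age,
                        }
                    )
                seg_hi = ht_age
            for br in list(genomes):
                genomes[br] = evolve_epoch(genomes[br], seg_hi, t_lo)
            n_total = sum(len(v) for v in genomes.values())
            if n_total > params.max_copies:
                raise RuntimeError(
                    f"copy-number explosion: {n_total} copies > max_copies={params.max_copies}"
                )
        # split at t_lo?
        if next_split is not None and abs(node_ages[next_split] - t_lo) < 1e-12:
            copies = genomes.pop(next_split)
            for child in next_split.child_nodes():
                genomes[child] = [_copy.deepcopy(cp) for cp in copies]
                for cp in genomes[child]:
                    cp.uid = new_uid()
            # daughters of the split inherit uid ancestry only via truth events
            next_split = next(split_iter, None)

    # collect records at the leaves
    records: list[TransposaseRecord] = []
    uid_to_id: dict[int, str] = {}
    pos = 3 * params.intron_after_codon
    for branch, copies in sorted(genomes.items(), key=lambda kv: genus_of(kv[0])):
        genus = genus_of(branch)
        for k, cp in enumerate(copies, start=1):
            rec_id = f"{genus}_sp|1|{k}"
            coding_aln = "".join(cp.coding)
            intron_aln = "".join(cp.intron)
            coding = coding_aln.replace("-", "")
            intron = intron_aln.replace("-", "")
            raw = coding[:pos] + intron + coding[pos:]
            rec = TransposaseRecord(
                id=rec_id,
                raw_seq=raw,
                genus=genus,
                species="sp",
                individual_tag="1",
                clone_number=k,
                coding_seq=coding_aln,
                intron_seq=intron_aln,
            )
            records.append(rec)
            uid_to_id[cp.uid] = rec_id
            truth.lineage_of[rec_id] = cp.lineage
            truth.status_of[rec_id] = "functional" if cp.functional else "pseudogene"
    for pair in truth.ht_pairs:
        pair["donor_id"] = uid_to_id.get(pair["donor_uid"])
        pair["recipient_id"] = uid_to_id.get(pair["recipient_uid"])
    return records, truth


def simulate_codon_pair(
    n_codons: int,
    divergence: float,
    omega: float,
    kappa: float = 1.0,
    seed: int = 0,
    table_id: int = 1,
) -> tuple[str, str]:
    """A single sequence pair from a common ancestor, for calibration.

    ``divergence`` is the total expected pairwise proposal density
    (substitutions/site); each descendant evolves half of it. Nonsynonymous
    proposals are accepted with probability ``omega``; stop-creating
    proposals are rejected.
    """
    rng = np.random.default_rng(seed)
    params = SimParams(
        coding_codons=n_codons, omega_functional=omega, kappa=kappa, codon_table=table_id
    )
    ancestor = _random_coding(rng, n_codons, table_id)
    pair = []
    for _ in range(2):
        cp = _Copy(
            coding=list(ancestor), intron=list("GTAG"), functional=True,
            lineage="L1", uid=0,
        )
        _evolve_coding(rng, cp, divergence / 2.0, params)
        pair.append("".join(cp.coding))
    return pair[0], pair[1]


def emit_fixture(records, truth: SimTruth, params: SimParams, out_dir) -> dict:
    """Write raw FASTA, exact alignments, truth JSON and params YAML."""
    from .seqio import write_fasta

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    files["raw"] = str(out_dir / "sim_raw.fasta")
    write_fasta(records, files["raw"], attr="raw_seq")
    files["coding_aligned"] = str(out_dir / "sim_coding_aligned.fasta")
    write_fasta(records, files["coding_aligned"], attr="coding_seq")
    files["intron_aligned"] = str(out_dir / "sim_intron_aligned.fasta")
    write_fasta(records, files["intron_aligned"], attr="intron_seq")
    files["truth"] = str(out_dir / "truth.json")
    Path(files["truth"]).write_text(truth.to_json() + "\n")
    files["params"] = str(out_dir / "params.yaml")
    Path(files["params"]).write_text(yaml.safe_dump(asdict(params), sort_keys=True))
    return files
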