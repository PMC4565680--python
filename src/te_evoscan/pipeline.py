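"""End-to-end pipeline: QC -> classification -> trees -> selection -> HT screen.

The complete (all nonredundant sequences) and reduced (functional-only)
sets are analyzed separately: a distance tree with bootstrap support and
midpoint rooting for each, pairwise-identity summaries, the all-pairs
selection scan on the reduced set only, and the cross-genus identity screen
on the complete set.

Multiple sequence alignment is deliberately external: the pipeline accepts
either an aligned coding FASTA (e.g. the simulator's exact alignment or a
curated alignment from an external aligner) or unaligned raw fragments, in
which case it performs QC, frame location, intron excision and
classification, and stops before alignment-dependent stages unless the
spliced coding sequences happen to be column-compatible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import htscreen as ht
from . import qc as qcmod
from .evometrics import identity_range, summarize_selection
from .phylo import bootstrap_support, extract_supported_clades, midpoint_root
from .records import STATUS_FUNCTIONAL, CodonAlignment
from .seqio import read_fasta, write_outputs

log = logging.getLogger("te_evoscan")


class ConfigError(ValueError):
    """Invalid pipeline configuration; ``errors`` collects every problem."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class PipelineConfig:
    input_fasta: str = ""
    input_is_coding_alignment: bool = False
    intron_fasta: str | None = None
    out_dir: str = "teva_out"
    seed: int = 0
    taq_filter: bool = True
    anchor_upstream: str = qcmod.DEFAULT_UPSTREAM_MOTIF
    anchor_downstream: str = qcmod.DEFAULT_DOWNSTREAM_MOTIF
    anchor_max_mismatches: int = 1
    intron_range: tuple[int, int] = qcmod.DEFAULT_INTRON_RANGE
    tree_distance: str = "jc"
    tree_bootstrap: int = 100
    support_threshold: float = 80.0
    ts_tv_ratio: float = 0.5
    dnds_bootstrap: int = 1000
    dnds_alternative: str = "two_sided"
    ht_near_threshold: float = 0.99
    ht_divergence_mya: tuple[float, float] = (13.0, 25.0)
    ht_syn_clock: float = 1e-8

    def anchors(self) -> qcmod.AnchorSpec:
        return qcmod.AnchorSpec(
            upstream_motif=self.anchor_upstream,
            downstream_motif=self.anchor_downstream,
            max_mismatches=self.anchor_max_mismatches,
        )


_VALIDATORS = {
    "input_fasta": lambda v: isinstance(v, str) and bool(v),
    "input_is_coding_alignment": lambda v: isinstance(v, bool),
    "intron_fasta": lambda v: v is None or isinstance(v, str),
    "out_dir": lambda v: isinstance(v, str) and bool(v),
    "seed": lambda v: isinstance(v, int) and not isinstance(v, bool) and v >= 0,
    "taq_filter": lambda v: isinstance(v, bool),
    "anchor_upstream": lambda v: isinstance(v, str) and v.isalpha(),
    "anchor_downstream": lambda v: isinstance(v, str) and v.isalpha(),
    "anchor_max_mismatches": lambda v: isinstance(v, int) and v >= 0,
    "intron_range": lambda v: (
        isinstance(v, (list, tuple)) and len(v) == 2 and 0 < v[0] <= v[1]
    ),
    "tree_distance": lambda v: v in ("jc", "p"),
    "tree_bootstrap": lambda v: isinstance(v, int) and v >= 1,
    "support_threshold": lambda v: isinstance(v, (int, float)) and 0 <= v <= 100,
    "ts_tv_ratio": lambda v: isinstance(v, (int, float)) and v > 0,
    "dnds_bootstrap": lambda v: isinstance(v, int) and v >= 2,
    "dnds_alternative": lambda v: v in ("two_sided", "purifying", "positive"),
    "ht_near_threshold": lambda v: isinstance(v, (int, float)) and 0 < v <= 1,
    "ht_divergence_mya": lambda v: (
        isinstance(v, (list, tuple)) and len(v) == 2 and 0 < v[0] <= v[1]
    ),
    "ht_syn_clock": lambda v: isinstance(v, (int, float)) and v > 0,
}


def validate_config(source) -> PipelineConfig:
    """Validate a YAML path or a dict; unknown keys and bad values are
    collected and reported together."""
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a mapping"])
    errors = []
    known = set(_VALIDATORS)
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    cfg_kwargs = {}
    for key, check in _VALIDATORS.items():
        if key in raw:
            val = raw[key]
            if isinstance(val, list):
                val = tuple(val)
            if not check(val):
                errors.append(f"invalid value for {key!r}: {raw[key]!r}")
            else:
                cfg_kwargs[key] = val
    if "input_fasta" not in raw:
        errors.append("missing required key 'input_fasta'")
    if errors:
        raise ConfigError(errors)
    return PipelineConfig(**cfg_kwargs)


@dataclass
class RunReport:
    """Stage-by-stage counts and headline numbers for one pipeline run."""

    n_input: int = 0
    n_exact_duplicates_removed: int = 0
    n_taq_filtered: int = 0
    n_complete: int = 0
    n_reduced: int = 0
    n_nonfunctional: int = 0
    status_counts: dict = field(default_factory=dict)
    identity_complete: dict | None = None
    identity_reduced: dict | None = None
    clades_complete: list = field(default_factory=list)
    clades_reduced: list = field(default_factory=list)
    selection: dict | None = None
    ht_n_identical: int = 0
    ht_n_near_identical: int = 0
    notices: list = field(default_factory=list)
    stages_run: list = field(default_factory=list)

    def check_conservation(self) -> None:
        if self.n_input != (
            self.n_exact_duplicates_removed + self.n_taq_filtered + self.n_complete
        ):
            raise AssertionError("pipeline counts do not reconcile")
        if self.n_complete != self.n_reduced + self.n_nonfunctional:
            raise AssertionError("reduced/nonfunctional split does not reconcile")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(report: RunReport, name: str, t0: float) -> None:
    dt = time.perf_counter() - t0
    report.stages_run.append(name)
    log.info("stage %-12s done in %.2fs", name, dt)


def _clade_rows(groups):
    return [
        {
            "label": g.label,
            "support": g.support,
            "n_members": len(g.member_ids),
            "members": ",".join(sorted(g.member_ids)),
            "note": g.note,
        }
        for g in groups
    ]


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the whole analysis per the configuration; see module docs."""
    report = RunReport()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    )

    t0 = time.perf_counter()
    records = read_fasta(config.input_fasta)
    report.n_input = len(records)
    _stage(report, "read", t0)

    t0 = time.perf_counter()
    records, dedup_report = qcmod.dedup_exact(records)
    report.n_exact_duplicates_removed = dedup_report.n_exact_duplicates_removed
    if config.taq_filter:
        records, taq_report = qcmod.taq_filter(records)
        report.n_taq_filtered = taq_report.n_taq_filtered
    _stage(report, "qc", t0)

    t0 = time.perf_counter()
    introns: dict[str, str] = {}
    if config.input_is_coding_alignment:
        records = [r.with_(coding_seq=r.raw_seq) for r in records]
        if config.intron_fasta:
            introns = {r.id: r.raw_seq for r in read_fasta(config.intron_fasta)}
            records = [r.with_(intron_seq=introns.get(r.id, "")) for r in records]
    else:
        anchors = config.anchors()
        located = []
        for r in records:
            off, strand = qcmod.locate_frame(r, anchors)
            r = r.with_(frame_offset=off, strand=strand)
            located.append(qcmod.excise_intron(r, anchors, config.intron_range))
        records = located
        introns = {r.id: r.intron_seq for r in records}
    records = qcmod.classify_all(records)
    report.n_complete = len(records)
    counts = {}
    for r in records:
        counts[r.status] = counts.get(r.status, 0) + 1
    report.status_counts = counts
    report.n_reduced = counts.get(STATUS_FUNCTIONAL, 0)
    report.n_nonfunctional = report.n_complete - report.n_reduced
    report.check_conservation()
    _stage(report, "classify", t0)

    lengths = {len(r.coding_seq) for r in records}
    if len(lengths) != 1 or (next(iter(lengths)) % 3) != 0:
        report.notices.append(
            "coding sequences are not column-compatible; alignment-dependent "
            "stages skipped — supply an aligned coding FASTA "
            "(input_is_coding_alignment: true) from an external aligner"
        )
        _write_report(report, records, None, out_dir)
        return report

    complete_aln = CodonAlignment.from_records(records)
    reduced = [r for r in records if r.status == STATUS_FUNCTIONAL]

    t0 = time.perf_counter()
    lo, hi, pair = identity_range(complete_aln) if len(complete_aln) >= 2 else (None, None, None)
    if lo is not None:
        report.identity_complete = {
            "min_pct": 100.0 * lo, "max_pct": 100.0 * hi, "most_divergent_pair": list(pair),
        }
    if len(reduced) >= 2:
        reduced_aln = complete_aln.subset([r.id for r in reduced])
        lo, hi, pair = identity_range(reduced_aln)
        report.identity_reduced = {
            "min_pct": 100.0 * lo, "max_pct": 100.0 * hi, "most_divergent_pair": list(pair),
        }
    _stage(report, "identity", t0)

    trees = {}
    t0 = time.perf_counter()
    if len(complete_aln) >= 3:
        phy = bootstrap_support(
            complete_aln, n_reps=config.tree_bootstrap, seed=config.seed,
            model=config.tree_distance,
        )
        rooted = midpoint_root(phy)
        trees["tree_complete"] = rooted
        report.clades_complete = _clade_rows(
            extract_supported_clades(rooted, config.support_threshold)
        )
    if len(reduced) >= 3:
        reduced_aln = complete_aln.subset([r.id for r in reduced])
        phy = bootstrap_support(
            reduced_aln, n_reps=config.tree_bootstrap, seed=config.seed + 1,
            model=config.tree_distance,
        )
        rooted = midpoint_root(phy)
        trees["tree_reduced"] = rooted
        report.clades_reduced = _clade_rows(
            extract_supported_clades(rooted, config.support_threshold)
        )
    _stage(report, "trees", t0)

    t0 = time.perf_counter()
    tables: dict[str, pd.DataFrame] = {}
    if len(reduced) >= 2:
        reduced_aln = complete_aln.subset([r.id for r in reduced])
        try:
            sel_table, sel_summary = summarize_selection(
                reduced_aln, R=config.ts_tv_ratio, n_bootstrap=config.dnds_bootstrap,
                seed=config.seed, alternative=config.dnds_alternative,
            )
            tables["selection_pairs"] = sel_table
            sel_summary["identical_pairs_removed"] = [
                list(p) for p in sel_summary["identical_pairs_removed"]
            ]
            report.selection = sel_summary
        except ValueError as exc:
            report.notices.append(f"selection summary skipped: {exc}")
    else:
        report.notices.append(
            "fewer than 2 functional sequences: reduced-set selection stage skipped"
        )
    _stage(report, "selection", t0)

    t0 = time.perf_counter()
    identical = ht.find_identical_cross_genus(records)
    near = ht.find_near_identical(records, threshold=config.ht_near_threshold)
    candidates = [ht.corroborate_with_intron(c, introns) for c in identical + near]
    report.ht_n_identical = len(identical)
    report.ht_n_near_identical = len(near)
    if candidates:
        tables["ht_report"] = ht.ht_report(
            candidates, records,
            host_divergence_mya=config.ht_divergence_mya,
            syn_clock=config.ht_syn_clock,
        )
    _stage(report, "ht_screen", t0)

    if report.clades_complete:
        tables["clades_complete"] = pd.DataFrame(report.clades_complete)
    if report.clades_reduced:
        tables["clades_reduced"] = pd.DataFrame(report.clades_reduced)
    _write_report(report, records, trees, out_dir, tables)
    return report


def _write_report(report, records, trees, out_dir, tables=None):
    write_outputs(records, trees or {}, tables or {}, out_dir)
    (Path(out_dir) / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True, default=str) + "\n"
    )
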