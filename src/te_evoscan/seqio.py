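"""Sequence and tree I/O, plus taxon-label parsing.

Two header dialects are understood:

* pipeline-native: ``Genus_species|individual|clone``
  (e.g. ``Pseudoroegneria_tauri|1|14``)
* compact figure-style labels that combine the first four letters of the
  genus and species names, the individual number, and the clone number in
  parentheses (e.g. ``Pseutaur1(14)``), parsed best-effort.

Headers matching neither convention yield records with empty taxonomy
fields; nothing downstream requires taxonomy until grouping by individual
or genus is requested.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import ALPHABET, TransposaseRecord

_NATIVE = re.compile(r"^(?P<genus>[A-Za-z]+)_(?P<species>[A-Za-z.\-]+)\|(?P<ind>[^|]+)\|(?P<clone>\d+)$")
_COMPACT = re.compile(r"^(?P<genus>[A-Z][a-z]{3})(?P<species>[a-z]{4})(?P<ind>\d+)\((?P<clone>\d+)\)$")


def parse_header(header: str) -> dict:
    """Parse a FASTA header into taxonomy fields (empty fields if unrecognized)."""
    token = header.split()[0] if header.split() else ""
    m = _NATIVE.match(token)
    if m:
        return {
            "genus": m["genus"],
            "species": m["species"],
            "individual_tag": m["ind"],
            "clone_number": int(m["clone"]),
        }
    m = _COMPACT.match(token)
    if m:
        return {
            "genus": m["genus"],
            "species": m["species"],
            "individual_tag": m["ind"],
            "clone_number": int(m["clone"]),
        }
    return {"genus": "", "species": "", "individual_tag": "", "clone_number": None}


def read_fasta(path) -> list[TransposaseRecord]:
    """Read a FASTA file into unclassified TransposaseRecords (uppercased).

    Raises ``ValueError`` on an empty file and on sequence characters outside
    the A/C/G/T/N/- alphabet.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for i, sr in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(sr.seq).upper()
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(
                f"{path}: entry {i + 1} ({sr.id}) contains illegal characters {sorted(bad)!r}"
            )
        fields = parse_header(sr.description)
        records.append(TransposaseRecord(id=sr.id, raw_seq=seq, **fields))
    if not records:
        raise ValueError(f"{path}: no FASTA records found (empty input)")
    return records


def write_fasta(records, path, attr: str = "raw_seq") -> int:
    """Write records to FASTA using the named sequence attribute; returns count."""
    path = Path(path)
    seqs = [
        SeqRecord(Seq(getattr(r, attr)), id=r.id, description="")
        for r in records
        if getattr(r, attr)
    ]
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta-2line")
    return len(seqs)


def write_outputs(records, trees, tables, out_dir) -> dict:
    """Write sequence subsets, newick trees and TSV tables; return a manifest.

    ``trees`` maps name -> Phylogeny (see :mod:`te_evoscan.phylo`) or any
    object with ``as_newick()``; ``tables`` maps name -> pandas DataFrame.
    The manifest (also written as ``manifest.json``) lists every file with
    its record/row count.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    fasta_path = out_dir / "sequences.fasta"
    n = write_fasta(records, fasta_path) if records else 0
    if not records:
        fasta_path.write_text("")
    manifest["sequences.fasta"] = {"kind": "fasta", "n_records": n}

    for name, tree in (trees or {}).items():
        p = out_dir / f"{name}.nwk"
        p.write_text(tree.as_newick() + "\n")
        manifest[p.name] = {"kind": "newick", "n_leaves": tree.n_leaves}

    for name, table in (tables or {}).items():
        p = out_dir / f"{name}.tsv"
        table.to_csv(p, sep="\t", index=False)
        manifest[p.name] = {"kind": "tsv", "n_rows": int(table.shape[0])}

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
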