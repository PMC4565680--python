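#!/usr/bin/env python
"""One-time download of the deposited transposase fragments (network required).

Fetches GenBank nuccore records KT024997-KT025236 (240 cloned transposase
fragments from 16 Triticeae genera) plus the maize reference AY362811 via
NCBI E-utilities, renames each record to the pipeline-native header
``Genus_species|individual|clone`` parsed from the definition line, runs
frame location / intron excision through the package, aligns the spliced
coding regions with mafft, and writes everything under ``data/deposited/``:

    raw.fasta            fetched sequences, native headers
    coding_aligned.fasta mafft alignment of spliced coding regions
    intron.fasta         excised introns
    accession_map.tsv    accession -> header mapping

The analysis pipeline and test suite never fetch anything themselves; they
only consume these files if present. Definition-line parsing is
best-effort: records whose organism/clone cannot be parsed keep their
accession as header and are listed in the map with empty taxonomy.

Usage:
    python scripts/fetch_accessions.py [--out data/deposited]
"""

from __future__ import annotations

import argparse
import re
import shutil
import subprocess
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSIONS = [f"KT{n:06d}" for n in range(24997, 25237)]


def fetch_batch(ids: list[str]) -> str:
    query = urllib.parse.urlencode(
        {"db": "nuccore", "id": ",".join(ids), "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=60) as fh:
        return fh.read().decode()


DEFLINE = re.compile(
    r"^>(?P<acc>\S+)\s+(?P<genus>[A-Z][a-z]+)\s+(?P<species>[a-z\-]+)"
    r".*?(?:isolate|clone)\s+(?P<clone>[\w.\-]+)",
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="data/deposited")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    chunks = []
    for i in range(0, len(ACCESSIONS), 100):
        chunks.append(fetch_batch(ACCESSIONS[i : i + 100]))
        time.sleep(0.5)  # NCBI rate courtesy
    text = "\n".join(chunks)

    entries = [e for e in text.split(">") if e.strip()]
    renamed, mapping = [], []
    per_tag_counter: dict[str, int] = {}
    for entry in entries:
        header, _, body = entry.partition("\n")
        m = DEFLINE.match(">" + header)
        if m:
            tag = f"{m['genus']}_{m['species']}"
            per_tag_counter[tag] = per_tag_counter.get(tag, 0) + 1
            clone = re.sub(r"\D", "", m["clone"]) or str(per_tag_counter[tag])
            new_id = f"{tag}|1|{clone}"
            mapping.append((m["acc"], new_id, m["genus"], m["species"]))
        else:
            new_id = header.split()[0]
            mapping.append((new_id, new_id, "", ""))
        renamed.append(f">{new_id}\n{body.strip()}\n")

    raw_path = out / "raw.fasta"
    raw_path.write_text("".join(renamed))
    (out / "accession_map.tsv").write_text(
        "accession\theader\tgenus\tspecies\n"
        + "".join("\t".join(row) + "\n" for row in mapping)
    )
    print(f"fetched {len(renamed)} records -> {raw_path}", file=sys.stderr)

    # splice out introns through the package, then align coding regions
    from te_evoscan.qc import AnchorSpec, excise_intron, locate_frame
    from te_evoscan.seqio import read_fasta, write_fasta

    records = read_fasta(raw_path)
    anchors = AnchorSpec()
    spliced = []
    for r in records:
        off, strand = locate_frame(r, anchors)
        spliced.append(excise_intron(r.with_(frame_offset=off, strand=strand), anchors))
    write_fasta(spliced, out / "coding_unaligned.fasta", attr="coding_seq")
    write_fasta([r for r in spliced if r.intron_seq], out / "intron.fasta", attr="intron_seq")

    if shutil.which("mafft"):
        with open(out / "coding_aligned.fasta", "w") as fh:
            subprocess.run(
                ["mafft", "--auto", str(out / "coding_unaligned.fasta")],
                stdout=fh, check=True,
            )
        print(f"aligned coding regions -> {out / 'coding_aligned.fasta'}", file=sys.stderr)
    else:
        print("mafft not found: align coding_unaligned.fasta yourself and save "
              "it as coding_aligned.fasta", file=sys.stderr)


if __name__ == "__main__":
    main()
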