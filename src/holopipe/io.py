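"""FASTA/TSV/JSON helpers shared across the pipeline stages."""

from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read a (possibly wrapped) FASTA file into an id -> sequence dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path_or_handle, width: int = 80) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    if hasattr(path_or_handle, "write"):
        SeqIO.FastaIO.FastaWriter(path_or_handle, wrap=width).write_file(records)
        return
    with open(path_or_handle, "w") as fh:
        SeqIO.FastaIO.FastaWriter(fh, wrap=width).write_file(records)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
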