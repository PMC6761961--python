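"""Readers/writers for the plain-text formats the pipeline exchanges.

FASTA and FASTQ go through Biopython; tables through pandas.  Depth tracks are
either a 2-column TSV (pos, depth; one file per chromosome) or a BED-like
4-column table (chrom, start, end, depth) with constant-depth runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass(frozen=True)
class Read:
    """A sequencing read; quality is a placeholder constant."""

    id: str
    seq: str
    qual: str = ""


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path, descriptions: dict[str, str] | None = None):
    descriptions = descriptions or {}
    records = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> list[Read]:
    return [
        Read(rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"]))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads, path):
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual or "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def write_depth_tsv(track: np.ndarray, path):
    pd.DataFrame({"pos": np.arange(track.size), "depth": track}).to_csv(
        path, sep="\t", index=False
    )


def read_depth_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    track = np.zeros(int(df["pos"].max()) + 1)
    track[df["pos"].to_numpy()] = df["depth"].to_numpy()
    return track


def write_depth_bed(tracks: dict[str, np.ndarray], path):
    """Run-length encode per-base depth into chrom/start/end/depth rows."""
    rows = []
    for chrom, track in tracks.items():
        if track.size == 0:
            continue
        change = np.flatnonzero(np.diff(track)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [track.size]])
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e), float(track[s])))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"]).to_csv(
        path, sep="\t", index=False, header=False
    )


def read_depth_bed(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "depth"])
    tracks: dict[str, np.ndarray] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        track = np.zeros(int(grp["end"].max()))
        for _, row in grp.iterrows():
            track[int(row["start"]) : int(row["end"])] = row["depth"]
        tracks[str(chrom)] = track
    return tracks


def write_json(obj, path):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
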