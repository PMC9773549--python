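"""Reading and writing of the standard formats used across the toolkit.

Sequence files go through Biopython's SeqIO; hit tables use the BLAST
tabular (outfmt 6) dialect via pandas. FASTQ qualities are accepted and
ignored so SRA dumps can be screened directly.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .aligner import OUTFMT6_COLUMNS


class InputFormatError(ValueError):
    """A sequence file could not be parsed; names the file and record."""


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def read_sequences(path: str | Path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ into ordered (id, sequence) pairs.

    The format is inferred from the extension unless ``fmt`` is given.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    records: list[tuple[str, str]] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            records.append((rec.id, str(rec.seq).upper()))
    except (ValueError, FileNotFoundError) as exc:
        at = f" after record {records[-1][0]!r}" if records else ""
        raise InputFormatError(f"cannot parse {path} as {fmt}{at}: {exc}") from exc
    if not records and path.stat().st_size > 0 and fmt == "fasta":
        # SeqIO silently yields nothing for non-FASTA text
        raise InputFormatError(f"cannot parse {path} as {fmt}: no records found")
    return records


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_hits(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


def read_hits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS,
                       na_values=[], keep_default_na=False)


def blastn_available() -> bool:
    return shutil.which("blastn") is not None


def run_blastn(queries, subjects, task: str = "megablast",
               extra_args: tuple[str, ...] = ()) -> pd.DataFrame:
    """Run the external blastn program on in-memory sequence sets.

    Optional cross-validation backend for the internal aligner; returns the
    tabular hit frame (all HSPs, not reduced to per-pair best).
    """
    if not blastn_available():
        raise RuntimeError("blastn is not on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "q.fasta"
        spath = Path(tmp) / "s.fasta"
        write_fasta(queries, qpath)
        write_fasta(subjects, spath)
        cmd = ["blastn", "-task", task, "-query", str(qpath),
               "-subject", str(spath), "-outfmt", "6", *extra_args]
        proc = subprocess.run(cmd, capture_output=True, text=True, check=True)
    rows = [line.split("\t") for line in proc.stdout.splitlines() if line.strip()]
    frame = pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)
    for col in ("pident", "evalue", "bitscore"):
        frame[col] = frame[col].astype(float)
    for col in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
        frame[col] = frame[col].astype(int)
    return frame
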