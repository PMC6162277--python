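"""Reading and writing of the plain-text formats used across the pipeline.

FASTA/FASTQ parsing is delegated to Biopython; sequences are normalised to
upper case on read. K-mer sets travel as sorted one-word-per-line text
files with an optional second (support) column.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
from Bio import SeqIO

from . import dna


@dataclass(frozen=True)
class FastqRecord:
    id: str
    seq: str
    qual: str

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"FASTQ record {self.id!r}: sequence and quality lengths differ"
            )


def _open_text(path: str | Path) -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file -> ordered {name: upper-case sequence}."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, records: dict[str, str] | Iterable[tuple[str, str]],
                width: int = 80) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[FastqRecord]:
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield FastqRecord(rec.id, str(rec.seq).upper(), qual)


def write_fastq(path: str | Path, records: Iterable[FastqRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")


def read_kmer_set(path: str | Path, k: int | None = None) -> tuple[np.ndarray, np.ndarray | None]:
    """K-mer set file -> (sorted codes, support array or None).

    Lines are ``WORD`` or ``WORD<TAB>SUPPORT``. All words must share one
    length; codes are canonicalised and sorted.
    """
    words: list[str] = []
    support: list[int] = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            words.append(parts[0].upper())
            if len(parts) > 1:
                support.append(int(parts[1]))
    if not words:
        return np.empty(0, dtype=np.uint64), None
    klen = len(words[0])
    if any(len(w) != klen for w in words):
        raise ValueError(f"{path}: k-mers of mixed length")
    if k is not None and klen != k:
        raise ValueError(f"{path}: expected k={k}, found k={klen}")
    codes = np.array([dna.kmer_to_code(dna.canonical(w)) for w in words], dtype=np.uint64)
    sup = np.array(support, dtype=np.int64) if support else None
    order = np.argsort(codes, kind="stable")
    return codes[order], (sup[order] if sup is not None else None)


def write_kmer_set(path: str | Path, codes: np.ndarray, k: int,
                   support: np.ndarray | None = None) -> None:
    order = np.argsort(codes, kind="stable")
    with open(path, "w") as fh:
        for i in order:
            word = dna.code_to_kmer(int(codes[i]), k)
            if support is not None:
                fh.write(f"{word}\t{int(support[i])}\n")
            else:
                fh.write(word + "\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """BED3/BED4 -> list of (chrom, start, end, name); 0-based half-open."""
    out = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line with <3 fields")
            name = parts[3] if len(parts) > 3 else ""
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out


def write_bed(path: str | Path, intervals: Iterable[tuple[str, int, int, str]]) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    """Simple TSV reader -> (header, rows); '#'-prefixed header allowed."""
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return [], []
    header = lines[0].lstrip("#").split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    return header, rows


def write_tsv(path: str | Path, header: list[str], rows: Iterable[Iterable]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_snp_positions(path: str | Path) -> dict[str, np.ndarray]:
    """SNP track from 2-column TSV (scaffold, 0-based position) or minimal VCF.

    VCF input (``.vcf`` suffix or ``##fileformat=VCF`` header) uses 1-based
    POS and is converted to 0-based.
    """
    path = Path(path)
    with _open_text(path) as fh:
        first = fh.readline()
    is_vcf = path.name.endswith(".vcf") or first.startswith("##fileformat=VCF")
    per_scaffold: dict[str, list[int]] = {}
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                pos = int(parts[1]) - 1 if is_vcf else int(parts[1])
            except (ValueError, IndexError):
                if ln == 1:  # tolerate a header row
                    continue
                raise ValueError(f"{path}:{ln}: malformed SNP line") from None
            per_scaffold.setdefault(parts[0], []).append(pos)
    return {
        sc: np.unique(np.array(ps, dtype=np.int64)) for sc, ps in per_scaffold.items()
    }


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
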