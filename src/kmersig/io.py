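"""Reading/writing FASTA, GFF3 and metadata tables; CDS extraction.

Internal coordinates are 0-based half-open; GFF3 is read and written with
its native 1-based inclusive convention, converted only at this boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import reverse_complement

logger = logging.getLogger(__name__)

VALID_CHARS = set("ACGTN")

NICHE_HALOPHILE = "halophile"
TEMPERATURE_CLASSES = [
    "weak mesophile",
    "mesophile",
    "moderate thermophile",
    "thermophile",
    "extreme thermophile",
    "hyperthermophile",
    "extreme hyperthermophile",
]
# growth-temperature classes at or above the 80 degC partition
HYPERTHERMOPHILE_CLASSES = ["hyperthermophile", "extreme hyperthermophile"]
NICHE_CATEGORIES = [NICHE_HALOPHILE] + TEMPERATURE_CLASSES


def is_halophile(niche: str) -> bool:
    return niche == NICHE_HALOPHILE


def is_hyperthermophile(niche: str) -> bool:
    """80 degC partition of the temperature classes (halophiles excluded)."""
    if niche == NICHE_HALOPHILE:
        raise ValueError("hyperthermophily is undefined for halophiles")
    if niche not in TEMPERATURE_CLASSES:
        raise ValueError(f"unknown niche category: {niche!r}")
    return niche in HYPERTHERMOPHILE_CLASSES


class FastaParseError(ValueError):
    pass


@dataclass
class GenomeRecord:
    """One genome sequence with the factor variables used downstream."""

    id: str
    sequence: str
    element_type: str = "cell"  # cell | plasmid | virus | provirus
    taxonomy: tuple[str, str, str] = ("", "", "")  # phylum, order, genus
    mge_family: str | None = None
    host_taxonomy: tuple[str, str, str] | None = None
    niche: str = ""
    cds: list[tuple[int, int, str]] = field(default_factory=list)  # 1-based inclusive

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)

    @property
    def order(self) -> str:
        return self.taxonomy[1]

    @property
    def host_order(self) -> str:
        return self.host_taxonomy[1] if self.host_taxonomy else ""

    @property
    def size_class(self) -> str:
        """Plasmid size class: small (<100 kb), large (100-150 kb), mega (>150 kb)."""
        if self.element_type != "plasmid":
            raise ValueError("size classes apply to plasmids only")
        if self.length_bp > 150_000:
            return "mega"
        if self.length_bp >= 100_000:
            return "large"
        return "small"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records, preserving order and uppercasing sequences.

    Characters outside {A, C, G, T, N} are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = line
                break
        if not first:
            raise FastaParseError(f"{path}: empty FASTA file")
        if not first.startswith(">"):
            raise FastaParseError(f"{path}:{lineno}: expected '>' header, got {first[:30]!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_CHARS
        if bad:
            raise FastaParseError(
                f"{path}: record {rec.id!r} contains invalid characters {sorted(bad)}"
            )
        records.append((rec.id, seq))
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    recs = [SeqRecord(Seq(seq), id=gid, description="") for gid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff3(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Read CDS features: {seqid: [(start, end, strand), ...]} (1-based inclusive)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLUMNS, header=None, dtype={"seqid": str}
    )
    cds: dict[str, list[tuple[int, int, str]]] = {}
    for row in df.itertuples(index=False):
        if row.type != "CDS":
            continue
        cds.setdefault(row.seqid, []).append((int(row.start), int(row.end), row.strand))
    return cds


def write_gff3(annotations: dict[str, list[tuple[int, int, str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for seqid, intervals in annotations.items():
            for i, (start, end, strand) in enumerate(intervals, start=1):
                attrs = f"ID=cds-{seqid}-{i}"
                fh.write(
                    f"{seqid}\tkmersig\tCDS\t{start}\t{end}\t.\t{strand}\t0\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# metadata and dataset loading
# ---------------------------------------------------------------------------


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError(f"{path}: metadata table must have an 'id' column")
    return df


def load_genomes(
    fasta: str | Path,
    gff3: str | Path | None = None,
    metadata: str | Path | pd.DataFrame | None = None,
) -> list[GenomeRecord]:
    """Assemble GenomeRecords from a FASTA file plus optional GFF3/metadata."""
    seqs = read_fasta(fasta)
    cds = read_gff3(gff3) if gff3 is not None else {}
    meta = None
    if metadata is not None:
        meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
        meta = meta.set_index("id")
    records = []
    for gid, seq in seqs:
        rec = GenomeRecord(id=gid, sequence=seq, cds=cds.get(gid, []))
        if meta is not None and gid in meta.index:
            row = meta.loc[gid]
            rec.element_type = row.get("type", "cell")
            rec.taxonomy = (row.get("phylum", ""), row.get("order", ""), row.get("genus", ""))
            fam = row.get("family", "")
            rec.mge_family = fam or None
            host = row.get("host_order", "")
            rec.host_taxonomy = ("", host, "") if host else None
            rec.niche = row.get("niche", "")
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# sequence operations
# ---------------------------------------------------------------------------


class NoCodingSequenceError(ValueError):
    """Genome has no CDS annotation; it is excluded from coding analyses."""


def extract_cds(record: GenomeRecord) -> str:
    """Concatenate the coding regions of a genome, in frame.

    Minus-strand intervals are reverse-complemented before concatenation;
    each interval's contribution is trimmed to a multiple of 3 (trailing
    partial codons dropped with a warning), so the result is a frame-
    consistent concatenation whose length is a multiple of 3.
    """
    if not record.cds:
        raise NoCodingSequenceError(f"genome {record.id} has no CDS annotation")
    parts = []
    L = record.length_bp
    for start, end, strand in record.cds:
        if not (1 <= start <= end <= L):
            raise ValueError(
                f"genome {record.id}: CDS ({start}, {end}) outside [1, {L}]"
            )
        piece = record.sequence[start - 1 : end]
        if strand == "-":
            piece = reverse_complement(piece)
        trimmed = len(piece) % 3
        if trimmed:
            logger.warning(
                "genome %s: CDS (%d, %d, %s) length %d not a multiple of 3; "
                "trimming %d trailing base(s)",
                record.id, start, end, strand, len(piece), trimmed,
            )
            piece = piece[: len(piece) - trimmed]
        parts.append(piece)
    return "".join(parts)


def gc_content(sequence: str) -> float:
    """(G + C) / (A + C + G + T); N excluded from both sides."""
    if not sequence:
        raise ValueError("empty sequence")
    g = sequence.count("G")
    c = sequence.count("C")
    acgt = g + c + sequence.count("A") + sequence.count("T")
    if acgt == 0:
        raise ValueError("GC content undefined: sequence contains no A/C/G/T")
    return (g + c) / acgt
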