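"""Sequence records, FASTA/GFF3/TSV I/O, and elementary sequence operations.

Coordinates are 1-based inclusive throughout (GenBank/GFF3 convention) so that
outputs interleave with public annotations. Nucleotide records are restricted
to the {A,C,G,T,N} alphabet: other IUPAC ambiguity codes are rejected rather
than silently translated, because downstream integrity checks (internal stop
codons, motif identity) require unambiguous bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio.Data.CodonTable import standard_dna_table

NUC_ALPHABET = frozenset("ACGTN")
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

FEATURE_TYPES = frozenset(
    {"LTR", "element", "ORF", "motif", "TM", "sequon", "GN_region", "GC_region"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# codon -> amino acid, with explicit stop codons as '*'
_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


class SeqIoError(ValueError):
    """Malformed sequence input (parse errors carry a line number)."""


@dataclass(frozen=True)
class GenomeRecord:
    """A named nucleotide sequence (one contig of an assembly)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIoError("genome record id must be non-empty")
        bad = set(self.seq) - NUC_ALPHABET
        if bad:
            raise SeqIoError(
                f"illegal nucleotide characters in record {self.id!r}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence over the 20 residues plus X and * (stop)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIoError("protein record id must be non-empty")
        if len(self.seq) < 1:
            raise SeqIoError(f"protein record {self.id!r} is empty")
        bad = set(self.seq) - AA_ALPHABET
        if bad:
            raise SeqIoError(
                f"illegal amino-acid characters in record {self.id!r}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class FeatureRecord:
    """One annotation interval on a contig (GFF3 row).

    start/end are 1-based inclusive; type comes from the controlled
    vocabulary used by the screen (LTR, element, ORF, motif, TM, sequon,
    GN_region, GC_region).
    """

    contig: str
    start: int
    end: int
    strand: str
    type: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise SeqIoError(f"unknown feature type {self.type!r}")
        if not (1 <= self.start <= self.end):
            raise SeqIoError(
                f"bad coordinates {self.start}..{self.end} on {self.contig}"
            )
        if self.strand not in {"+", "-"}:
            raise SeqIoError(f"bad strand {self.strand!r}")


Record = Union[GenomeRecord, ProteinRecord]


def _looks_protein(seq: str) -> bool:
    return bool(set(seq) - NUC_ALPHABET)


def read_fasta(path, kind: str = "auto") -> list:
    """Read a FASTA file into GenomeRecord/ProteinRecord objects.

    kind: "nucleotide", "protein", or "auto" (per-record guess: sequences
    using only A/C/G/T/N become GenomeRecord). Parse errors name the
    offending line. The FASTA grammar is parsed here rather than delegated
    so that diagnostics carry exact line numbers.
    """
    path = Path(path)
    if kind not in {"auto", "nucleotide", "protein"}:
        raise ValueError(f"bad kind {kind!r}")
    records: list = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush(end_line: int) -> None:
        if header is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise SeqIoError(
                f"{path}:{header_line}: record {header!r} has an empty sequence"
            )
        if kind == "nucleotide" or (kind == "auto" and not _looks_protein(seq)):
            cls = GenomeRecord
        else:
            cls = ProteinRecord
        try:
            records.append(cls(id=header, seq=seq))
        except SeqIoError as exc:
            raise SeqIoError(f"{path}:{header_line}: {exc}") from exc

    with open(path) as fh:
        lineno = 0
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush(lineno)
                header = line[1:].split()[0] if line[1:].strip() else ""
                if not header:
                    raise SeqIoError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise SeqIoError(
                        f"{path}:{lineno}: sequence data before first header"
                    )
                chunks.append(line.replace(" ", ""))
        _flush(lineno + 1)
    if not records:
        raise SeqIoError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[Record], path, width: int = 60) -> None:
    """Write records as FASTA with fixed line width (round-trips byte-identically)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - NUC_ALPHABET
    if bad:
        raise SeqIoError(f"illegal nucleotide characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(seq: str, frame: int = 0) -> str:
    """Translate one forward frame with the standard genetic code.

    Stops render as '*'; a trailing partial codon is dropped; codons
    containing N translate to X.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    out = []
    for i in range(0, len(sub), 3):
        codon = sub[i : i + 3]
        out.append(_CODON_TABLE.get(codon, "X"))
    return "".join(out)


def six_frame_translations(record: GenomeRecord) -> dict[int, str]:
    """All six reading frames, keyed +1..+3 (forward) and -1..-3 (reverse).

    Frame +f starts at nucleotide f of the contig; frame -f starts at
    nucleotide f of the reverse complement.
    """
    rc = revcomp(record.seq)
    frames = {}
    for f in (0, 1, 2):
        frames[f + 1] = translate(record.seq, f)
        frames[-(f + 1)] = translate(rc, f)
    return frames


def frame_to_genome(frame: int, aa_start: int, aa_end: int, contig_len: int) -> tuple[int, int]:
    """Map a residue span (1-based, inclusive) in a frame translation to
    1-based inclusive nucleotide coordinates on the forward strand."""
    off = abs(frame) - 1
    p1 = off + 3 * (aa_start - 1) + 1  # first nt in frame-local coords
    p2 = off + 3 * (aa_end - 1) + 3
    if frame > 0:
        return p1, p2
    # frame-local coords are on the reverse complement
    return contig_len - p2 + 1, contig_len - p1 + 1


def write_gff3(features: Sequence[FeatureRecord], path, contig_lengths: dict | None = None) -> None:
    """Write features as GFF3 (version pragma, 1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            if contig_lengths is not None:
                clen = contig_lengths.get(feat.contig)
                if clen is not None and feat.end > clen:
                    raise SeqIoError(
                        f"feature {feat.type} {feat.start}..{feat.end} exceeds "
                        f"contig {feat.contig} length {clen}"
                    )
            attrs = ";".join(
                f"{k}={_gff3_escape(str(v))}" for k, v in feat.attributes.items()
            ) or "."
            fh.write(
                f"{feat.contig}\tevescout\t{feat.type}\t{feat.start}\t{feat.end}"
                f"\t.\t{feat.strand}\t.\t{attrs}\n"
            )


def _gff3_escape(value: str) -> str:
    return re.sub(r"[;=&,\t\n]", lambda m: "%%%02X" % ord(m.group()), value)


def read_gff3(path) -> list[FeatureRecord]:
    """Read back GFF3 rows written by write_gff3 (screen vocabulary only)."""
    feats = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise SeqIoError(f"{path}:{lineno}: expected 9 GFF3 columns")
            attrs = {}
            if cols[8] != ".":
                for pair in cols[8].split(";"):
                    if pair:
                        key, _, val = pair.partition("=")
                        attrs[key] = re.sub(
                            r"%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), val
                        )
            feats.append(
                FeatureRecord(
                    contig=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    type=cols[2],
                    attributes=attrs,
                )
            )
    return feats


REPORT_COLUMNS = [
    "locus_id",
    "element_length_bp",
    "ltr_length_bp",
    "ltr_identity_pct",
    "polyprotein_length_aa",
    "rt_motif",
    "env_class",
    "verdict",
]


def write_report_table(rows: Sequence[dict], path) -> None:
    """Write the per-locus screen report as TSV (schema = REPORT_COLUMNS)."""
    import pandas as pd

    df = pd.DataFrame(list(rows), columns=REPORT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
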