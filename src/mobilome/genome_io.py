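"""Sequence and annotation I/O with fixed coordinate conventions.

Every interval handed to or returned by this package is 0-based,
half-open. On-disk GFF3 is 1-based, inclusive; the conversion happens
here and nowhere else. Sequences are uppercase DNA over {A,C,G,T,N};
other IUPAC ambiguity codes are rejected at parse time so that exact
string matching downstream is well-defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised for malformed FASTA/GFF input."""


@dataclass
class GenomeRecord:
    """A named DNA sequence.

    Topology is informational: genomes are treated as linear (deposited
    assemblies are linearized) and wrap-around matches are not searched.
    """

    id: str
    seq: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ParseError(
                f"record {self.id!r}: illegal characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Feature:
    """A located annotation, 0-based half-open in memory."""

    genome_id: str
    start: int
    end: int
    strand: str
    ftype: str
    attributes: dict[str, str] = field(default_factory=dict)
    source: str = "."
    score: str = "."
    phase: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval ({self.start}, {self.end})")

    @property
    def gene_id(self) -> str | None:
        """`ID` wins, then `locus_tag`; None if neither is present."""
        return self.attributes.get("ID") or self.attributes.get("locus_tag")

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords, uppercased.

    An empty file yields an empty list. A file whose first non-blank
    character is not ``>`` is rejected.
    """
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                text_head = line
                break
    if text_head and not text_head.startswith(">"):
        raise ParseError(f"{path}: not FASTA, first record line is {text_head!r}")
    return [
        GenomeRecord(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_gff(path: str | Path) -> list[Feature]:
    """Read GFF3 features, converting to 0-based half-open coordinates.

    Records with end < start on disk are skipped with a log message
    rather than aborting the whole file.
    """
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                gf = feature_from_line(line)
            except Exception as exc:  # malformed column count etc.
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if gf.end < gf.start:
                logger.warning("%s:%d: end < start, feature skipped", path, lineno)
                continue
            attrs = {k: ",".join(v) for k, v in gf.attributes.items()}
            feats.append(
                Feature(
                    genome_id=gf.seqid,
                    start=gf.start - 1,
                    end=gf.end,
                    strand=gf.strand,
                    ftype=gf.featuretype,
                    attributes=attrs,
                    source=gf.source,
                    score=str(gf.score),
                    phase=str(gf.frame),
                )
            )
    return feats


def _format_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def feature_to_gff_line(feat: Feature) -> str:
    """Render a Feature as a 1-based inclusive GFF3 line."""
    return "\t".join(
        [
            feat.genome_id,
            feat.source,
            feat.ftype,
            str(feat.start + 1),
            str(feat.end),
            feat.score,
            feat.strand,
            feat.phase,
            _format_attributes(feat.attributes),
        ]
    )


def write_gff(features: Iterable[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(feature_to_gff_line(feat) + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq) - ALPHABET
    if bad:
        raise ValueError(f"illegal characters for revcomp: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def translate_cds(seq: str) -> str:
    """Translate an in-frame CDS with the bacterial code (table 11).

    Stop codons render as ``*``. GTG/TTG starts are translated as
    written (V/L); forcing the initiator methionine is the caller's
    concern, not ours.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not divisible by 3")
    return str(Seq(seq).translate(table=11))


def iter_windows(seq: str, k: int) -> Iterator[str]:
    for i in range(len(seq) - k + 1):
        yield seq[i : i + k]
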