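"""Input/output for the formats the pipeline touches.

Sequences are normalized to an uppercase RNA alphabet (A, C, G, U, N) on
ingest; DNA input is accepted and T is converted to U.  All coordinates
are 1-based inclusive on the mRNA.

The TIS-call table is a strict tab-separated dialect defined by this
package (there is no community standard for TIS calls)::

    transcript_id  pos  codon  init_score  is_canonical

with ``pos`` the 1-based position of the first nucleotide of the start
codon and ``is_canonical`` one of true/false (case-insensitive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .screen import IuOrfCandidate

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGUN")

#: codons accepted as observed start codons in TIS-call tables
TIS_CODONS = frozenset({"AUG", "CUG", "GUG", "ACG", "AUA", "AUU", "AUC", "UUG"})

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

CANDIDATE_TSV_COLUMNS = (
    "transcript_id",
    "cTIS",
    "iuTIS",
    "iuSTOP_end",
    "ntTIS",
    "class",
    "spacer_nt",
    "iuORF_len_codons",
    "iu_kozak",
    "nt_kozak",
    "init_score",
)

TIS_TABLE_COLUMNS = ("transcript_id", "pos", "codon", "init_score", "is_canonical")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def normalize_alphabet(raw: str) -> str:
    """Normalize a raw nucleotide string to the internal RNA alphabet.

    Uppercases, strips whitespace, converts T to U.  Any residue outside
    {A, C, G, U, N} is rejected with its 1-based offset.
    """
    cleaned = "".join(raw.split()).upper().replace("T", "U")
    if not cleaned:
        raise FormatError("sequence is empty after stripping whitespace")
    for i, ch in enumerate(cleaned, start=1):
        if ch not in RNA_ALPHABET:
            raise FormatError(f"illegal residue {ch!r} at offset {i}")
    return cleaned


@dataclass(frozen=True)
class SequenceRecord:
    """An mRNA sequence with identifier and free-text description."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)

    def codon_at(self, pos: int) -> str:
        """Trinucleotide starting at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.seq) - 2:
            raise IndexError(f"codon position {pos} out of bounds for {self.id!r}")
        return self.seq[pos - 1 : pos + 2]


@dataclass(frozen=True)
class TISCall:
    """An observed translation-initiation event on a transcript."""

    transcript_id: str
    pos: int
    codon: str
    init_score: float
    is_canonical: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"TIS position must be >= 1, got {self.pos}")
        if self.codon not in TIS_CODONS:
            raise ValueError(f"unknown start codon {self.codon!r}")
        if self.init_score < 0:
            raise ValueError(f"init_score must be non-negative, got {self.init_score}")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized :class:`SequenceRecord` objects.

    Duplicate ids are a hard error; an empty file yields an empty list
    with a warning.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            seq = normalize_alphabet(str(rec.seq))
        except FormatError as exc:
            raise FormatError(f"record {rec.id!r}: {exc}") from exc
        records.append(SequenceRecord(id=rec.id, seq=seq, description=rec.description))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description and rec.description != rec.id:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}


def read_tis_table(path: str | Path) -> list[TISCall]:
    """Parse the tab-separated TIS-call table (strict header required)."""
    calls: list[TISCall] = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            raise FormatError(f"{path}: empty file, expected a header row")
        header = tuple(h.strip() for h in header_line.rstrip("\n").split("\t"))
        missing = [c for c in TIS_TABLE_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        idx = {c: header.index(c) for c in TIS_TABLE_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                pos = int(fields[idx["pos"]])
                codon = fields[idx["codon"]].strip().upper().replace("T", "U")
                score = float(fields[idx["init_score"]])
                canon_raw = fields[idx["is_canonical"]].strip().lower()
                if canon_raw not in _BOOL:
                    raise ValueError(f"bad boolean {canon_raw!r}")
                call = TISCall(
                    transcript_id=fields[idx["transcript_id"]].strip(),
                    pos=pos,
                    codon=codon,
                    init_score=score,
                    is_canonical=_BOOL[canon_raw],
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            calls.append(call)
    return calls


def write_tis_table(calls: Iterable[TISCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TIS_TABLE_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.transcript_id}\t{c.pos}\t{c.codon}\t{c.init_score:g}\t"
                f"{'true' if c.is_canonical else 'false'}\n"
            )


def _fmt_score(score: float | None) -> str:
    return "." if score is None else f"{score:g}"


def _sorted_candidates(candidates: Sequence["IuOrfCandidate"]) -> list["IuOrfCandidate"]:
    return sorted(candidates, key=lambda c: (c.transcript_id, c.iuTIS, c.ntTIS))


def write_candidates(
    candidates: Sequence["IuOrfCandidate"], path: str | Path, format: str = "tsv"
) -> None:
    """Write screen candidates as TSV or GFF3.

    Output is byte-stable for a fixed input: rows are sorted by
    (transcript_id, iuTIS).  GFF3 emits one CDS-like feature for the
    iuORF and a 1-nt feature for the ntTIS, both 1-based inclusive.
    """
    ordered = _sorted_candidates(candidates)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(CANDIDATE_TSV_COLUMNS) + "\n")
            for c in ordered:
                fh.write(
                    "\t".join(
                        [
                            c.transcript_id,
                            str(c.cTIS),
                            str(c.iuTIS),
                            str(c.iuSTOP_end),
                            str(c.ntTIS),
                            c.klass,
                            str(c.spacer_nt),
                            str(c.iuORF_len_codons),
                            c.iu_kozak,
                            c.nt_kozak,
                            _fmt_score(c.init_score),
                        ]
                    )
                    + "\n"
                )
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, c in enumerate(ordered, start=1):
                attrs = (
                    f"ID=iuORF{i};class={c.klass};spacer_nt={c.spacer_nt};"
                    f"iu_kozak={c.iu_kozak};nt_kozak={c.nt_kozak};"
                    f"init_score={_fmt_score(c.init_score)}"
                )
                fh.write(
                    f"{c.transcript_id}\tiuorfkit\tCDS\t{c.iuTIS}\t{c.iuSTOP_end}\t"
                    f"{_fmt_score(c.init_score)}\t+\t0\t{attrs}\n"
                )
                fh.write(
                    f"{c.transcript_id}\tiuorfkit\tTIS\t{c.ntTIS}\t{c.ntTIS}\t.\t+\t.\t"
                    f"ID=ntTIS{i};Parent=iuORF{i}\n"
                )
    else:
        raise ValueError(f"unknown candidate format {format!r} (use 'tsv' or 'gff3')")


def read_candidates_tsv(path: str | Path) -> list["IuOrfCandidate"]:
    """Re-parse a candidate TSV written by :func:`write_candidates`."""
    from .screen import IuOrfCandidate

    out: list[IuOrfCandidate] = []
    with open(path) as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != CANDIDATE_TSV_COLUMNS:
            raise FormatError(f"{path}: unexpected candidate TSV header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != len(CANDIDATE_TSV_COLUMNS):
                raise FormatError(f"{path}: line {lineno}: wrong field count")
            out.append(
                IuOrfCandidate(
                    transcript_id=f[0],
                    cTIS=int(f[1]),
                    iuTIS=int(f[2]),
                    iuSTOP_end=int(f[3]),
                    ntTIS=int(f[4]),
                    klass=f[5],
                    spacer_nt=int(f[6]),
                    iuORF_len_codons=int(f[7]),
                    iu_kozak=f[8],
                    nt_kozak=f[9],
                    init_score=None if f[10] == "." else float(f[10]),
                )
            )
    return out
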