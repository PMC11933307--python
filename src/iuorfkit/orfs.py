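"""Frame arithmetic and ORF enumeration relative to a canonical TIS."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import STOP_CODONS, SequenceRecord, TISCall


@dataclass(frozen=True)
class CanonicalOrf:
    """The annotated main ORF: cTIS .. last nucleotide of the stop codon."""

    transcript_id: str
    cTIS: int
    cSTOP_end: int

    def __post_init__(self) -> None:
        if self.cSTOP_end <= self.cTIS:
            raise ValueError("cSTOP_end must be > cTIS")
        if (self.cSTOP_end - self.cTIS + 1) % 3 != 0:
            raise ValueError("canonical ORF length must be a multiple of 3")


@dataclass(frozen=True)
class OrfInterval:
    """An ORF from its start codon to the last nucleotide of its stop codon.

    ``len_codons`` counts coding codons and excludes the stop codon;
    ``frame`` is the offset relative to the canonical TIS (0 = in-frame).
    """

    transcript_id: str
    start: int
    stop_end: int
    len_codons: int
    frame: int
    start_codon: str
    init_score: float | None = None

    def __post_init__(self) -> None:
        if (self.stop_end - self.start + 1) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if self.len_codons != (self.stop_end - self.start + 1) // 3 - 1:
            raise ValueError("len_codons inconsistent with coordinates")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be in {0, 1, 2}")


def frame_offset(pos: int, ctis: int) -> int:
    """Reading-frame offset of ``pos`` relative to ``ctis``; 0 = in-frame."""
    if pos < 1 or ctis < 1:
        raise ValueError("positions are 1-based and must be >= 1")
    return (pos - ctis) % 3


def extend_orf(
    transcript: SequenceRecord, start: int, ctis: int | None = None
) -> OrfInterval | None:
    """Walk codon-by-codon from ``start`` to the first in-frame stop codon.

    Returns ``None`` when no stop codon occurs before the transcript end.
    ``frame`` is computed relative to ``ctis`` when given, else relative
    to position 1.  Codons containing N never count as stop codons.
    """
    n = len(transcript.seq)
    if not 1 <= start <= n - 2:
        raise IndexError(f"ORF start {start} out of bounds (transcript length {n})")
    start_codon = transcript.codon_at(start)
    pos = start + 3
    while pos + 2 <= n:
        codon = transcript.codon_at(pos)
        if codon in STOP_CODONS:
            stop_end = pos + 2
            return OrfInterval(
                transcript_id=transcript.id,
                start=start,
                stop_end=stop_end,
                len_codons=(stop_end - start + 1) // 3 - 1,
                frame=frame_offset(start, ctis) if ctis is not None else (start - 1) % 3,
                start_codon=start_codon,
            )
        pos += 3
    return None


def _denovo_aug_positions(transcript: SequenceRecord) -> Iterable[int]:
    seq = transcript.seq
    i = seq.find("AUG")
    while i != -1:
        yield i + 1
        i = seq.find("AUG", i + 1)


def enumerate_internal_out_of_frame_sorfs(
    transcript: SequenceRecord,
    canonical: CanonicalOrf,
    tis_calls: Sequence[TISCall] | str = "de-novo",
    max_codons: int = 100,
) -> list[OrfInterval]:
    """Enumerate short out-of-frame ORFs starting 3' of the canonical TIS.

    Candidate starts are the supplied TIS calls with frame != 0 and
    pos > cTIS, or — in de-novo mode — every out-of-frame AUG 3' of the
    cTIS.  Each start is extended to its first in-frame stop; ORFs longer
    than ``max_codons`` coding codons or lacking a stop are discarded.
    """
    if canonical is None:
        raise ValueError("canonical ORF is required")
    if max_codons < 1:
        raise ValueError("max_codons must be >= 1")
    n = len(transcript.seq)

    starts: list[tuple[int, float | None]] = []
    if isinstance(tis_calls, str):
        if tis_calls != "de-novo":
            raise ValueError(f"unknown mode {tis_calls!r}")
        for pos in _denovo_aug_positions(transcript):
            if pos > canonical.cTIS and frame_offset(pos, canonical.cTIS) != 0:
                starts.append((pos, None))
    else:
        for call in tis_calls:
            if call.transcript_id != transcript.id:
                continue
            if call.pos > canonical.cTIS and frame_offset(call.pos, canonical.cTIS) != 0:
                if call.pos + 2 <= n and transcript.codon_at(call.pos) == call.codon:
                    starts.append((call.pos, call.init_score))

    out: list[OrfInterval] = []
    for pos, score in sorted(starts):
        orf = extend_orf(transcript, pos, ctis=canonical.cTIS)
        if orf is None or orf.len_codons > max_codons:
            continue
        if score is not None:
            orf = OrfInterval(
                transcript_id=orf.transcript_id,
                start=orf.start,
                stop_end=orf.stop_end,
                len_codons=orf.len_codons,
                frame=orf.frame,
                start_codon=orf.start_codon,
                init_score=score,
            )
        out.append(orf)
    return out


def enumerate_internal_inframe_tis(
    transcript: SequenceRecord,
    canonical: CanonicalOrf,
    tis_calls: Sequence[TISCall],
) -> list[TISCall]:
    """Internal in-frame TIS calls: cTIS < pos < cSTOP_end - 2, frame 0.

    Near-cognate starts (CUG, ACG, ...) are admitted only through
    explicit TIS calls; this function never scans de novo.
    """
    out = []
    for call in tis_calls:
        if call.transcript_id != transcript.id:
            continue
        if not canonical.cTIS < call.pos < canonical.cSTOP_end - 2:
            continue
        if frame_offset(call.pos, canonical.cTIS) != 0:
            continue
        if call.pos + 2 <= len(transcript.seq) and transcript.codon_at(call.pos) != call.codon:
            continue
        out.append(call)
    return sorted(out, key=lambda c: c.pos)


def next_inframe_start(
    transcript: SequenceRecord,
    canonical: CanonicalOrf,
    from_pos: int,
    start_codons: frozenset[str] | set[str] = frozenset({"AUG"}),
) -> int | None:
    """Smallest in-frame start-codon position >= ``from_pos`` inside the CDS."""
    if from_pos < canonical.cTIS:
        raise ValueError("from_pos must be >= cTIS")
    # advance to the first in-frame position at or after from_pos
    pos = from_pos + (-(from_pos - canonical.cTIS)) % 3
    while pos < canonical.cSTOP_end - 2:
        if transcript.codon_at(pos) in start_codons:
            return pos
        pos += 3
    return None
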