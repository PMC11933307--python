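"""The iuORF candidate screen.

Pairs internal out-of-frame short ORFs with internal in-frame TISs,
applies the positional filters (ORF length <= 100 codons, upstream
spacer <= 30 nt or overlap), keeps at most one candidate per transcript
(highest initiation score) and classifies candidates as upstream or
overlapping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .io import SequenceRecord, TISCall
from .kozak import extract_context
from .orfs import (
    CanonicalOrf,
    OrfInterval,
    enumerate_internal_inframe_tis,
    enumerate_internal_out_of_frame_sorfs,
    extend_orf,
    frame_offset,
)

logger = logging.getLogger(__name__)

KLASS_UPSTREAM = "upstream"
KLASS_OVERLAPPING = "overlapping"


@dataclass(frozen=True)
class ScreenParams:
    """Filter parameters; defaults reproduce the published screen."""

    max_codons: int = 100
    max_upstream_spacer_nt: int = 30
    start_codons_denovo: frozenset[str] = frozenset({"AUG"})
    mode: str = "tis-calls"

    def __post_init__(self) -> None:
        if self.max_codons < 1:
            raise ValueError("max_codons must be >= 1")
        if self.max_upstream_spacer_nt < 0:
            raise ValueError("max_upstream_spacer_nt must be >= 0")
        if self.mode not in ("tis-calls", "de-novo"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class IuOrfCandidate:
    """A paired (short out-of-frame ORF, truncated-proteoform TIS)."""

    transcript_id: str
    cTIS: int
    iuTIS: int
    iuSTOP_end: int
    ntTIS: int
    klass: str
    spacer_nt: int
    iuORF_len_codons: int
    iu_kozak: str = "indeterminate"
    nt_kozak: str = "indeterminate"
    init_score: float | None = None

    def __post_init__(self) -> None:
        if self.iuTIS >= self.ntTIS:
            raise ValueError("iuTIS must be 5' of ntTIS")
        if frame_offset(self.iuTIS, self.cTIS) == 0:
            raise ValueError("iuORF must be out of frame")
        if frame_offset(self.ntTIS, self.cTIS) != 0:
            raise ValueError("ntTIS must be in frame")
        if self.spacer_nt != self.ntTIS - self.iuSTOP_end:
            raise ValueError("spacer_nt inconsistent with coordinates")
        if self.klass not in (KLASS_UPSTREAM, KLASS_OVERLAPPING):
            raise ValueError(f"unknown class {self.klass!r}")


@dataclass
class ScreenReport:
    """Aggregate result of screening a transcriptome."""

    n_transcripts_in: int = 0
    n_with_canonical_tis: int = 0
    candidates: list[IuOrfCandidate] = field(default_factory=list)

    @property
    def n_candidates(self) -> int:
        return len(self.candidates)

    @property
    def n_upstream(self) -> int:
        return sum(1 for c in self.candidates if c.klass == KLASS_UPSTREAM)

    @property
    def n_overlapping(self) -> int:
        return sum(1 for c in self.candidates if c.klass == KLASS_OVERLAPPING)


def spacer(iustop_end: int, nttis: int) -> int:
    """Signed intercistronic distance ntTIS - iuSTOP_end.

    Positive when the short-ORF stop lies strictly 5' of the ntTIS;
    negative/zero indicates overlap geometry.
    """
    if iustop_end < 1 or nttis < 1:
        raise ValueError("positions are 1-based and must be >= 1")
    return nttis - iustop_end


def pair_and_classify(
    sorf: OrfInterval,
    nttis_calls: Sequence[TISCall],
    params: ScreenParams = ScreenParams(),
    *,
    ctis: int,
) -> list[IuOrfCandidate]:
    """Pair one short ORF with the nearest qualifying downstream ntTIS.

    A ntTIS qualifies when sorf.start < ntTIS and either the sORF stop
    lies 3' of the ntTIS (overlapping) or 1 <= spacer <=
    ``max_upstream_spacer_nt`` (upstream).  Only the nearest qualifying
    ntTIS (smallest ntTIS - iuTIS) is kept.
    """
    hits: list[IuOrfCandidate] = []
    for call in nttis_calls:
        if sorf.start >= call.pos:
            continue
        sp = spacer(sorf.stop_end, call.pos)
        if sorf.stop_end > call.pos:
            klass = KLASS_OVERLAPPING
        elif 1 <= sp <= params.max_upstream_spacer_nt:
            klass = KLASS_UPSTREAM
        else:
            continue
        hits.append(
            IuOrfCandidate(
                transcript_id=sorf.transcript_id,
                cTIS=ctis,
                iuTIS=sorf.start,
                iuSTOP_end=sorf.stop_end,
                ntTIS=call.pos,
                klass=klass,
                spacer_nt=sp,
                iuORF_len_codons=sorf.len_codons,
                init_score=sorf.init_score,
            )
        )
    if not hits:
        return []
    nearest = min(hits, key=lambda c: c.ntTIS - c.iuTIS)
    return [nearest]


def _tiebreak_key(c: IuOrfCandidate) -> tuple:
    # highest init_score first; absent scores sort after any scored one
    score = c.init_score if c.init_score is not None else float("-inf")
    return (-score, abs(c.spacer_nt), c.iuTIS)


def _canonical_from_calls(
    transcript: SequenceRecord, tis_calls: Sequence[TISCall]
) -> CanonicalOrf | None:
    canon = [c for c in tis_calls if c.transcript_id == transcript.id and c.is_canonical]
    if len(canon) > 1:
        raise ValueError(f"transcript {transcript.id!r} has {len(canon)} canonical TIS calls")
    if not canon:
        return None
    ctis = canon[0].pos
    orf = extend_orf(transcript, ctis, ctis=ctis)
    if orf is None:
        logger.warning("canonical ORF of %s has no stop codon; transcript skipped", transcript.id)
        return None
    return CanonicalOrf(transcript_id=transcript.id, cTIS=ctis, cSTOP_end=orf.stop_end)


def _denovo_inframe_calls(
    transcript: SequenceRecord, canonical: CanonicalOrf, start_codons: frozenset[str]
) -> list[TISCall]:
    calls = []
    pos = canonical.cTIS + 3
    while pos < canonical.cSTOP_end - 2:
        codon = transcript.codon_at(pos)
        if codon in start_codons:
            calls.append(
                TISCall(
                    transcript_id=transcript.id,
                    pos=pos,
                    codon=codon,
                    init_score=0.0,
                )
            )
        pos += 3
    return calls


def screen_transcript(
    transcript: SequenceRecord,
    canonical: CanonicalOrf,
    tis_calls: Sequence[TISCall],
    params: ScreenParams = ScreenParams(),
) -> list[IuOrfCandidate]:
    """Screen one transcript; returns at most one candidate.

    When several short ORFs qualify, the one with the highest initiation
    score wins; ties break by smaller absolute spacer, then 5'-most
    iuTIS.  Kozak tiers are attached for both the iuTIS and the ntTIS.
    """
    if params.mode == "de-novo":
        sorfs = enumerate_internal_out_of_frame_sorfs(
            transcript, canonical, "de-novo", max_codons=params.max_codons
        )
        nttis = _denovo_inframe_calls(transcript, canonical, params.start_codons_denovo)
    else:
        sorfs = enumerate_internal_out_of_frame_sorfs(
            transcript, canonical, tis_calls, max_codons=params.max_codons
        )
        nttis = enumerate_internal_inframe_tis(transcript, canonical, tis_calls)

    candidates: list[IuOrfCandidate] = []
    for sorf in sorfs:
        candidates.extend(pair_and_classify(sorf, nttis, params, ctis=canonical.cTIS))
    if not candidates:
        return []
    best = min(candidates, key=_tiebreak_key)
    return [
        replace(
            best,
            iu_kozak=extract_context(transcript, best.iuTIS).tier,
            nt_kozak=extract_context(transcript, best.ntTIS).tier,
        )
    ]


def screen_transcriptome(
    transcripts: Sequence[SequenceRecord],
    tis_table: Sequence[TISCall],
    params: ScreenParams = ScreenParams(),
) -> ScreenReport:
    """Run the screen over a set of transcripts with their TIS calls.

    TIS calls referencing unknown transcripts are skipped with a
    warning.  Transcripts without a flagged canonical TIS are counted
    but produce no candidates.
    """
    by_id: dict[str, list[TISCall]] = {}
    known = {t.id for t in transcripts}
    n_unknown = 0
    for call in tis_table:
        if call.transcript_id not in known:
            n_unknown += 1
            continue
        by_id.setdefault(call.transcript_id, []).append(call)
    if n_unknown:
        logger.warning("skipped %d TIS calls referencing unknown transcripts", n_unknown)

    report = ScreenReport(n_transcripts_in=len(transcripts))
    for transcript in sorted(transcripts, key=lambda t: t.id):
        calls = by_id.get(transcript.id, [])
        canonical = _canonical_from_calls(transcript, calls)
        if canonical is None and params.mode == "tis-calls":
            continue
        if canonical is None:
            continue
        report.n_with_canonical_tis += 1
        report.candidates.extend(screen_transcript(transcript, canonical, calls, params))
    report.candidates.sort(key=lambda c: (c.transcript_id, c.iuTIS))
    return report


def candidate_passes_filters(
    cand: IuOrfCandidate,
    transcript: SequenceRecord,
    canonical: CanonicalOrf,
    params: ScreenParams = ScreenParams(),
) -> bool:
    """Independent predicate re-checking every screen filter.

    Used by tests and by the synthetic generator's certificate; kept
    deliberately free of the enumeration code paths above.
    """
    seq = transcript.seq
    if cand.cTIS != canonical.cTIS:
        return False
    if not canonical.cTIS < cand.iuTIS:
        return False
    if (cand.iuTIS - canonical.cTIS) % 3 == 0:
        return False
    if (cand.ntTIS - canonical.cTIS) % 3 != 0:
        return False
    if not canonical.cTIS < cand.ntTIS < canonical.cSTOP_end - 2:
        return False
    span = cand.iuSTOP_end - cand.iuTIS + 1
    if span % 3 != 0 or span // 3 - 1 != cand.iuORF_len_codons:
        return False
    if cand.iuORF_len_codons > params.max_codons:
        return False
    if seq[cand.iuSTOP_end - 3 : cand.iuSTOP_end] not in {"UAA", "UAG", "UGA"}:
        return False
    # stop must be the FIRST in-frame stop after iuTIS
    for p in range(cand.iuTIS, cand.iuSTOP_end - 3, 3):
        if seq[p - 1 : p + 2] in {"UAA", "UAG", "UGA"}:
            return False
    sp = cand.ntTIS - cand.iuSTOP_end
    if cand.klass == KLASS_UPSTREAM:
        return 1 <= sp <= params.max_upstream_spacer_nt
    if cand.klass == KLASS_OVERLAPPING:
        return cand.iuSTOP_end > cand.ntTIS and cand.iuTIS < cand.ntTIS
    return False
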