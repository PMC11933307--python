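"""Cross-species conservation of iuORF cis-element features.

Closest-ortholog selection uses global pairwise alignment identity
(match +1, mismatch -1, gap -2, linear) instead of tree construction;
the "multiple alignment" is reference-anchored pairwise alignment,
which suffices because every feature is defined relative to reference
anchors (cTIS, iuTIS, ntTIS).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .io import STOP_CODONS, SequenceRecord
from .kozak import extract_context
from .orfs import extend_orf
from .screen import IuOrfCandidate

GAP = "gap"
ABSENT = "absent"

MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_SCORE = -2.0

FEATURE_NAMES = (
    "cTIS_context_tier",
    "iu_start_codon",
    "iu_context_tier",
    "nt_start_codon",
    "nt_context_tier",
    "iuORF_len_codons",
    "spacer_nt",
    "dist_cTIS_to_iuTIS",
)


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Global alignment of two sequences; returns the gapped strings."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    alignment = _aligner().align(a, b)[0]
    gapped_a, gapped_b = str(alignment[0]), str(alignment[1])
    return gapped_a, gapped_b


def alignment_score(a: str, b: str) -> float:
    """Optimal global alignment score under the fixed scoring scheme."""
    return float(_aligner().score(a, b))


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical columns in one optimal global alignment."""
    ga, gb = align_pair(a, b)
    matches = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    return matches / len(ga)


def select_closest_ortholog(
    reference: SequenceRecord, candidates: Sequence[SequenceRecord]
) -> SequenceRecord:
    """Candidate with maximal alignment identity to the reference.

    Ties are broken by id order (lexicographically smallest id).
    """
    if not candidates:
        raise ValueError("no ortholog candidates given")
    scored = [(pairwise_identity(reference.seq, c.seq), c) for c in candidates]
    best_identity = max(s for s, _ in scored)
    ties = sorted((c for s, c in scored if s == best_identity), key=lambda c: c.id)
    return ties[0]


def project_position(
    alignment: Mapping[str, str], from_id: str, pos: int, to_id: str
) -> int | str:
    """Map a 1-based position through a gapped alignment.

    Returns the corresponding 1-based position in the target sequence,
    or ``"gap"`` when the column is a gap in the target.
    """
    if from_id not in alignment or to_id not in alignment:
        raise KeyError(f"ids {from_id!r}/{to_id!r} not both present in alignment")
    src, dst = alignment[from_id], alignment[to_id]
    if len(src) != len(dst):
        raise ValueError("aligned strings must have equal length")
    src_count = dst_count = 0
    for s_ch, d_ch in zip(src, dst):
        if d_ch != "-":
            dst_count += 1
        if s_ch != "-":
            src_count += 1
            if src_count == pos:
                return dst_count if d_ch != "-" else GAP
    raise IndexError(f"position {pos} beyond the end of sequence {from_id!r}")


@dataclass(frozen=True)
class FeatureVector:
    """Per-species values of the repression-relevant cis features."""

    species: str
    cTIS_context_tier: str = ABSENT
    iu_start_codon: str = ABSENT
    iu_context_tier: str = ABSENT
    nt_start_codon: str = ABSENT
    nt_context_tier: str = ABSENT
    iuORF_len_codons: int | None = None
    spacer_nt: int | None = None
    dist_cTIS_to_iuTIS: int | None = None
    sorf_peptide: str = ""


@dataclass(frozen=True)
class ConservationReport:
    """Per-feature conservation flags across species plus sORF peptide identity."""

    flags: Mapping[str, bool]
    sorf_peptide_identity: float
    n_species: int


def translate_sorf(transcript: SequenceRecord, start: int, stop_end: int) -> str:
    """Amino-acid string of an ORF, stop codon excluded."""
    cds = transcript.seq[start - 1 : stop_end - 3]
    return str(Seq(cds).translate())


def extract_feature_vector(
    transcript: SequenceRecord,
    species: str,
    ctis: int | str,
    iutis: int | str,
    nttis: int | str,
) -> FeatureVector:
    """Read the feature vector at (projected) anchor positions.

    Anchors projected to a gap yield ``absent`` features rather than an
    error.  The sORF is re-extended in this species to its own stop, so
    length and spacer are species-specific.
    """
    n = len(transcript.seq)

    def codon(pos: int | str) -> str:
        if isinstance(pos, str) or pos + 2 > n:
            return ABSENT
        return transcript.codon_at(pos)

    def tier(pos: int | str) -> str:
        if isinstance(pos, str) or pos + 2 > n:
            return ABSENT
        return extract_context(transcript, pos).tier

    iu_len: int | None = None
    spacer_nt: int | None = None
    peptide = ""
    if not isinstance(iutis, str) and iutis + 2 <= n:
        orf = extend_orf(transcript, iutis, ctis=None if isinstance(ctis, str) else ctis)
        if orf is not None:
            iu_len = orf.len_codons
            peptide = translate_sorf(transcript, orf.start, orf.stop_end)
            if not isinstance(nttis, str):
                spacer_nt = nttis - orf.stop_end

    dist = None
    if not isinstance(ctis, str) and not isinstance(iutis, str):
        dist = iutis - ctis

    return FeatureVector(
        species=species,
        cTIS_context_tier=tier(ctis),
        iu_start_codon=codon(iutis),
        iu_context_tier=tier(iutis),
        nt_start_codon=codon(nttis),
        nt_context_tier=tier(nttis),
        iuORF_len_codons=iu_len,
        spacer_nt=spacer_nt,
        dist_cTIS_to_iuTIS=dist,
        sorf_peptide=peptide,
    )


def feature_vector_from_candidate(
    transcript: SequenceRecord, candidate: IuOrfCandidate, species: str = "reference"
) -> FeatureVector:
    """Reference-species feature vector straight from a screen candidate."""
    return extract_feature_vector(
        transcript, species, candidate.cTIS, candidate.iuTIS, candidate.ntTIS
    )


def conservation_report(
    ref: FeatureVector,
    others: Sequence[FeatureVector],
    len_tol_codons: int = 2,
    dist_tol_nt: int = 6,
) -> ConservationReport:
    """Cross-species agreement of the feature vectors.

    Codon and tier features are conserved iff they match exactly in all
    species; lengths within ``len_tol_codons`` codons; distances within
    ``dist_tol_nt`` nucleotides.  sORF peptide identity is the mean
    alignment identity of each non-reference peptide to the reference.
    """
    flags: dict[str, bool] = {}
    for name in (
        "cTIS_context_tier",
        "iu_start_codon",
        "iu_context_tier",
        "nt_start_codon",
        "nt_context_tier",
    ):
        ref_val = getattr(ref, name)
        flags[name] = ref_val != ABSENT and all(
            getattr(o, name) == ref_val for o in others
        )

    def within(name: str, tol: int) -> bool:
        ref_val = getattr(ref, name)
        if ref_val is None:
            return False
        return all(
            getattr(o, name) is not None and abs(getattr(o, name) - ref_val) <= tol
            for o in others
        )

    flags["iuORF_len_codons"] = within("iuORF_len_codons", len_tol_codons)
    flags["spacer_nt"] = within("spacer_nt", dist_tol_nt)
    flags["dist_cTIS_to_iuTIS"] = within("dist_cTIS_to_iuTIS", dist_tol_nt)

    if ref.sorf_peptide and others and all(o.sorf_peptide for o in others):
        identity = sum(
            pairwise_identity(ref.sorf_peptide, o.sorf_peptide) for o in others
        ) / len(others)
    else:
        identity = 0.0

    return ConservationReport(
        flags=flags, sorf_peptide_identity=identity, n_species=len(others) + 1
    )


def analyze_orthologs(
    reference: SequenceRecord,
    candidate: IuOrfCandidate,
    orthologs: Sequence[SequenceRecord],
    len_tol_codons: int = 2,
    dist_tol_nt: int = 6,
) -> tuple[FeatureVector, list[FeatureVector], ConservationReport]:
    """Project candidate anchors into each ortholog and summarize conservation."""
    ref_vec = feature_vector_from_candidate(reference, candidate)
    other_vecs: list[FeatureVector] = []
    for ortho in orthologs:
        ga, gb = align_pair(reference.seq, ortho.seq)
        alignment = {reference.id: ga, ortho.id: gb}
        anchors = {
            name: project_position(alignment, reference.id, pos, ortho.id)
            for name, pos in (
                ("ctis", candidate.cTIS),
                ("iutis", candidate.iuTIS),
                ("nttis", candidate.ntTIS),
            )
        }
        other_vecs.append(
            extract_feature_vector(
                ortho, ortho.id, anchors["ctis"], anchors["iutis"], anchors["nttis"]
            )
        )
    report = conservation_report(ref_vec, other_vecs, len_tol_codons, dist_tol_nt)
    return ref_vec, other_vecs, report
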