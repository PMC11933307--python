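"""Synthetic inputs with planted ground truth.

Transcripts are built anchor-first: the canonical ORF, the out-of-frame
short ORF and the internal in-frame TIS are written at exact coordinates
with requested Kozak tiers, then a rejection-resampling fixer scrubs
accidental decoys (out-of-frame AUGs, premature stops) everywhere except
the protected anchor positions.  Every generated transcript carries a
certificate: an independent brute-force search confirms that no
unplanted qualifying (sORF, ntTIS) pair exists.

Frame arithmetic constrains realizable geometries: an upstream plant
with spacer s requires the iuORF frame f = (1 - s) mod 3, so s = 1 mod 3
is impossible (the "short ORF" would be in frame); likewise an overlap
of o nt requires o != 2 mod 3.  Unrealizable specs raise
:class:`GenerationError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import SequenceRecord, TISCall, write_fasta, write_tis_table
from .kozak import extract_context
from .screen import IuOrfCandidate, ScreenParams
from .stats import CtRecord, RatioTable

_BASES = ("A", "C", "G", "U")
_STOPS = ("UAA", "UAG", "UGA")
_PURINES = ("A", "G")
_PYRIMIDINES = ("C", "U")

_MAX_FIX_ITER = 500


class GenerationError(ValueError):
    """Raised when a plant spec is unrealizable or scrubbing fails."""


@dataclass(frozen=True)
class PlantSpec:
    """Requested geometry and contexts for one synthetic transcript."""

    klass: str = "upstream"  # upstream | overlapping | none
    iuORF_len_codons: int = 10
    spacer_nt: int = 14  # upstream class
    overlap_nt: int = 6  # overlapping class
    iu_kozak_tier: str = "adequate"
    c_kozak_tier: str = "weak"
    nt_kozak_tier: str = "adequate"
    init_scores: tuple[float, float, float] = (10.0, 3.0, 1.5)
    transcript_len: int | None = None

    def __post_init__(self) -> None:
        if self.klass not in ("upstream", "overlapping", "none"):
            raise ValueError(f"unknown plant class {self.klass!r}")
        if self.iuORF_len_codons < 1:
            raise ValueError("iuORF_len_codons must be >= 1")
        if self.klass == "upstream" and self.spacer_nt < 1:
            raise ValueError("upstream spacer must be >= 1")
        if self.klass == "overlapping" and self.overlap_nt < 1:
            raise ValueError("overlap must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated transcript."""

    transcript_id: str
    candidate: IuOrfCandidate | None
    certified: bool


def _required_frame(spec: PlantSpec) -> int:
    if spec.klass == "upstream":
        f = (1 - spec.spacer_nt) % 3
    elif spec.klass == "overlapping":
        f = (1 + spec.overlap_nt) % 3
    else:
        return 0
    if f == 0:
        raise GenerationError(
            f"{spec.klass} plant with distance {spec.spacer_nt if spec.klass == 'upstream' else spec.overlap_nt}"
            " nt puts the short ORF in frame 0 (unrealizable)"
        )
    return f


def _layout(spec: PlantSpec) -> dict[str, int]:
    """Anchor coordinates (1-based) for a plant spec."""
    ctis = 13  # leaves room for a -6..-1 context
    lay: dict[str, int] = {"ctis": ctis}
    if spec.klass == "none":
        cstop_start = ctis + 3 * 40
    else:
        f = _required_frame(spec)
        iutis = ctis + 9 + f
        iustop_end = iutis + 3 * (spec.iuORF_len_codons + 1) - 1
        if spec.klass == "upstream":
            nttis = iustop_end + spec.spacer_nt
        else:
            nttis = iustop_end - spec.overlap_nt
            if nttis <= iutis:
                raise GenerationError("overlap longer than the short ORF itself")
        cstop_start = nttis + 3 * max(8, spec.overlap_nt // 3 + 2)
        lay.update(iutis=iutis, iustop_end=iustop_end, nttis=nttis)
    lay["cstop_start"] = cstop_start
    min_len = cstop_start + 2 + 15
    if spec.transcript_len is None:
        lay["length"] = min_len
    else:
        if spec.transcript_len < min_len:
            raise GenerationError(
                f"transcript_len {spec.transcript_len} too short (need >= {min_len})"
            )
        lay["length"] = spec.transcript_len
    return lay


def _set_base(seq: list[str], idx: int, ch: str, protected: set[int]) -> None:
    """Write one anchor base; anchors may only overlap when they agree."""
    if idx in protected and seq[idx] != ch:
        raise GenerationError(
            f"conflicting anchors at position {idx + 1}: {seq[idx]} vs {ch}"
        )
    seq[idx] = ch
    protected.add(idx)


def _write_context(
    seq: list[str], pos: int, tier: str, rng: np.random.Generator, protected: set[int]
) -> None:
    """Write -3/+4 (and neighbours as needed) for a requested Kozak tier.

    ``pos`` is the 1-based start-codon position; ``seq`` is 0-based.
    """
    i3, i4 = pos - 4, pos + 2  # 0-based indexes of -3 and +4
    if tier == "optimal":
        for k, ch in enumerate("GCCACC"):
            _set_base(seq, pos - 7 + k, ch, protected)
        _set_base(seq, i4, "G", protected)
    elif tier == "strong":
        _set_base(seq, i3, str(rng.choice(_PURINES)), protected)
        _set_base(seq, i4, "G", protected)
        # forbid drifting into the optimal window
        _set_base(seq, pos - 7, "U", protected)
    elif tier == "adequate":
        if rng.random() < 0.5:
            _set_base(seq, i3, str(rng.choice(_PURINES)), protected)
            _set_base(seq, i4, str(rng.choice(("A", "C", "U"))), protected)
        else:
            _set_base(seq, i3, str(rng.choice(_PYRIMIDINES)), protected)
            _set_base(seq, i4, "G", protected)
    elif tier == "weak":
        _set_base(seq, i3, str(rng.choice(_PYRIMIDINES)), protected)
        _set_base(seq, i4, str(rng.choice(("A", "C", "U"))), protected)
    else:
        raise GenerationError(f"cannot construct requested tier {tier!r}")


def _write_codon(seq: list[str], pos: int, codon: str, protected: set[int]) -> None:
    for k, ch in enumerate(codon):
        _set_base(seq, pos - 1 + k, ch, protected)


def _violations(seq: list[str], lay: dict[str, int]) -> list[int]:
    """0-based start indexes of codons that must be rewritten."""
    s = "".join(seq)
    n = len(s)
    ctis = lay["ctis"]
    cstop_start = lay["cstop_start"]
    iutis = lay.get("iutis")
    nttis = lay.get("nttis")
    iustop_end = lay.get("iustop_end")
    bad: list[int] = []

    # premature stop in the canonical frame
    for p in range(ctis, cstop_start, 3):
        if s[p - 1 : p + 2] in _STOPS:
            bad.append(p - 1)
    # accidental out-of-frame AUG 3' of the cTIS
    i = s.find("AUG")
    while i != -1:
        pos = i + 1
        if pos > ctis and (pos - ctis) % 3 != 0 and pos != iutis:
            bad.append(i)
        i = s.find("AUG", i + 1)
    if iutis is not None:
        # accidental in-frame internal AUG (would steal the ntTIS pairing)
        for p in range(ctis + 3, cstop_start, 3):
            if p != nttis and s[p - 1 : p + 2] == "AUG":
                bad.append(p - 1)
        # premature stop inside the short ORF (its own frame)
        for p in range(iutis, iustop_end - 4, 3):
            if s[p - 1 : p + 2] in _STOPS:
                bad.append(p - 1)
    return bad


def _scrub(
    seq: list[str], lay: dict[str, int], protected: set[int], rng: np.random.Generator
) -> None:
    for _ in range(_MAX_FIX_ITER):
        bad = _violations(seq, lay)
        if not bad:
            return
        for start in bad:
            free = [k for k in (start, start + 1, start + 2) if k not in protected]
            if not free:
                raise GenerationError(
                    "conflicting anchors: violating codon is fully protected"
                )
            k = free[int(rng.integers(len(free)))]
            seq[k] = str(rng.choice([b for b in _BASES if b != seq[k]]))
    raise GenerationError(f"scrubbing did not converge in {_MAX_FIX_ITER} iterations")


def _build_planted(
    spec: PlantSpec, rng: np.random.Generator
) -> tuple[list[str], dict[str, int], set[int]]:
    lay = _layout(spec)  # deterministic geometry errors surface before retries
    last_err: GenerationError | None = None
    # random tier residues occasionally complete a stop/AUG entirely inside
    # protected anchors (e.g. iu-AUG with A at +4 spells a frame-0 UGA);
    # those draws are rejected and resampled wholesale
    for _ in range(50):
        seq = [str(b) for b in rng.choice(_BASES, size=lay["length"])]
        protected: set[int] = set()
        try:
            _write_codon(seq, lay["ctis"], "AUG", protected)
            _write_context(seq, lay["ctis"], spec.c_kozak_tier, rng, protected)
            _write_codon(seq, lay["cstop_start"], str(rng.choice(_STOPS)), protected)
            if spec.klass != "none":
                _write_codon(seq, lay["iutis"], "AUG", protected)
                _write_context(seq, lay["iutis"], spec.iu_kozak_tier, rng, protected)
                _write_codon(seq, lay["iustop_end"] - 2, str(rng.choice(_STOPS)), protected)
                _write_codon(seq, lay["nttis"], "AUG", protected)
                _write_context(seq, lay["nttis"], spec.nt_kozak_tier, rng, protected)
            _scrub(seq, lay, protected, rng)
        except GenerationError as err:
            last_err = err
            continue
        return seq, lay, protected
    raise GenerationError(f"could not realize plant spec after 50 attempts: {last_err}")


def _brute_force_pairs(
    seq: str, ctis: int, cstop_end: int, params: ScreenParams
) -> set[tuple[int, int]]:
    """Independent qualifying-(iuTIS, ntTIS) search by exhaustive scan."""
    n = len(seq)
    inframe_aug = [
        p
        for p in range(ctis + 3, cstop_end - 2, 3)
        if seq[p - 1 : p + 2] == "AUG"
    ]
    pairs: set[tuple[int, int]] = set()
    for p in range(ctis + 1, n - 1):
        if seq[p - 1 : p + 2] != "AUG" or (p - ctis) % 3 == 0:
            continue
        stop_end = None
        q = p + 3
        while q + 2 <= n:
            if seq[q - 1 : q + 2] in _STOPS:
                stop_end = q + 2
                break
            q += 3
        if stop_end is None:
            continue
        if (stop_end - p + 1) // 3 - 1 > params.max_codons:
            continue
        qualifying = []
        for nt in inframe_aug:
            if p >= nt:
                continue
            sp = nt - stop_end
            if stop_end > nt or 1 <= sp <= params.max_upstream_spacer_nt:
                qualifying.append(nt)
        if qualifying:
            nearest = min(qualifying, key=lambda nt: nt - p)
            pairs.add((p, nearest))
    return pairs


def _truth_candidate(
    transcript: SequenceRecord, spec: PlantSpec, lay: dict[str, int]
) -> IuOrfCandidate | None:
    if spec.klass == "none":
        return None
    return IuOrfCandidate(
        transcript_id=transcript.id,
        cTIS=lay["ctis"],
        iuTIS=lay["iutis"],
        iuSTOP_end=lay["iustop_end"],
        ntTIS=lay["nttis"],
        klass=spec.klass,
        spacer_nt=lay["nttis"] - lay["iustop_end"],
        iuORF_len_codons=spec.iuORF_len_codons,
        iu_kozak=extract_context(transcript, lay["iutis"]).tier,
        nt_kozak=extract_context(transcript, lay["nttis"]).tier,
        init_score=spec.init_scores[1],
    )


def _certify(
    seq: str, lay: dict[str, int], truth: IuOrfCandidate | None, params: ScreenParams
) -> bool:
    expected = set() if truth is None else {(truth.iuTIS, truth.ntTIS)}
    found = _brute_force_pairs(seq, lay["ctis"], lay["cstop_start"] + 2, params)
    return found == expected


def generate_transcript(
    spec: PlantSpec, seed: int, transcript_id: str = "synth1"
) -> tuple[SequenceRecord, list[TISCall], SyntheticTruth]:
    """Build one transcript with the requested plant, TIS calls and truth.

    Deterministic for a fixed (spec, seed).  Raises
    :class:`GenerationError` for unrealizable geometry or when decoy
    scrubbing cannot converge.
    """
    rng = np.random.default_rng(seed)
    seq, lay, _ = _build_planted(spec, rng)
    record = SequenceRecord(id=transcript_id, seq="".join(seq))

    calls = [
        TISCall(
            transcript_id=transcript_id,
            pos=lay["ctis"],
            codon="AUG",
            init_score=spec.init_scores[0],
            is_canonical=True,
        )
    ]
    if spec.klass != "none":
        calls.append(
            TISCall(
                transcript_id=transcript_id,
                pos=lay["iutis"],
                codon="AUG",
                init_score=spec.init_scores[1],
            )
        )
        calls.append(
            TISCall(
                transcript_id=transcript_id,
                pos=lay["nttis"],
                codon="AUG",
                init_score=spec.init_scores[2],
            )
        )

    truth_cand = _truth_candidate(record, spec, lay)
    certified = _certify(record.seq, lay, truth_cand, ScreenParams())
    if not certified:
        raise GenerationError("certificate failed: unplanted qualifying pair survived")
    return record, calls, SyntheticTruth(transcript_id, truth_cand, certified)


def _random_spec(klass: str, rng: np.random.Generator) -> PlantSpec:
    length = int(rng.integers(4, 30))
    tiers = ("strong", "adequate", "weak")
    if klass == "upstream":
        spacer = int(rng.choice([s for s in range(2, 31) if s % 3 != 1]))
        extra = {"spacer_nt": spacer}
    elif klass == "overlapping":
        max_ov = 3 * length + 1
        choices = [o for o in range(1, min(max_ov, 25) + 1) if o % 3 != 2]
        extra = {"overlap_nt": int(rng.choice(choices))}
    else:
        extra = {}
    return PlantSpec(
        klass=klass,
        iuORF_len_codons=length,
        iu_kozak_tier=str(rng.choice(tiers)),
        c_kozak_tier=str(rng.choice(tiers)),
        nt_kozak_tier=str(rng.choice(tiers)),
        init_scores=(
            float(rng.uniform(5, 15)),
            float(rng.uniform(0.5, 5)),
            float(rng.uniform(0.5, 5)),
        ),
        **extra,
    )


def generate_transcriptome(
    n: int,
    class_mix: dict[str, float],
    seed: int,
    outdir: str | Path | None = None,
) -> tuple[list[SequenceRecord], list[TISCall], list[SyntheticTruth]]:
    """Draw ``n`` transcripts from a class mix; optionally write scan inputs.

    ``class_mix`` maps upstream/overlapping/none to probabilities that
    must sum to 1.  With ``outdir`` set, writes ``transcripts.fasta``,
    ``tis_calls.tsv`` and ``truth.tsv``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    unknown = set(class_mix) - {"upstream", "overlapping", "none"}
    if unknown:
        raise ValueError(f"unknown classes in mix: {sorted(unknown)}")
    total = sum(class_mix.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"class mix must sum to 1, got {total}")

    rng = np.random.default_rng(seed)
    klasses = list(class_mix)
    probs = [class_mix[k] for k in klasses]
    records: list[SequenceRecord] = []
    calls: list[TISCall] = []
    truths: list[SyntheticTruth] = []
    for i in range(n):
        klass = str(rng.choice(klasses, p=probs))
        # retry with a fresh spec/seed on rare unrealizable anchor overlaps
        for attempt in range(20):
            spec = _random_spec(klass, rng)
            child_seed = int(rng.integers(0, 2**31 - 1))
            try:
                rec, c, truth = generate_transcript(
                    spec, child_seed, transcript_id=f"tx{i + 1:04d}"
                )
                break
            except GenerationError:
                if attempt == 19:
                    raise
        records.append(rec)
        calls.extend(c)
        truths.append(truth)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "transcripts.fasta")
        write_tis_table(calls, outdir / "tis_calls.tsv")
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(
                "transcript_id\tklass\tiuTIS\tiuSTOP_end\tntTIS\tspacer_nt\tiuORF_len_codons\n"
            )
            for t in truths:
                if t.candidate is None:
                    fh.write(f"{t.transcript_id}\tnone\t.\t.\t.\t.\t.\n")
                else:
                    c = t.candidate
                    fh.write(
                        f"{t.transcript_id}\t{c.klass}\t{c.iuTIS}\t{c.iuSTOP_end}\t"
                        f"{c.ntTIS}\t{c.spacer_nt}\t{c.iuORF_len_codons}\n"
                    )
    return records, calls, truths


@dataclass(frozen=True)
class OrthologSet:
    """A reference transcript plus species-tagged ortholog sequences."""

    reference: SequenceRecord
    others: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        ids = [self.reference.id] + [o.id for o in self.others]
        if len(set(ids)) != len(ids):
            raise ValueError("ortholog ids must be unique")
        if not self.others:
            raise ValueError("need at least one non-reference sequence")


def generate_ortholog_trio(
    spec: PlantSpec,
    divergence: float,
    seed: int,
    species: Sequence[str] = ("human", "rat"),
) -> tuple[OrthologSet, SyntheticTruth]:
    """Reference plus orthologs mutated outside the feature anchors.

    Substitution-only divergence: start codons, -3/+4 context residues
    and stop placements are preserved, so geometry is conserved while
    the sORF codons drift (nonsynonymous substitutions allowed).
    """
    if not 0 <= divergence < 0.5:
        raise ValueError("divergence must be in [0, 0.5)")
    if spec.klass == "none":
        raise GenerationError("ortholog trio requires a planted iuORF")
    rng = np.random.default_rng(seed)
    ref_seq, lay, protected = _build_planted(spec, rng)
    reference = SequenceRecord(id="mouse", seq="".join(ref_seq))
    truth_cand = _truth_candidate(reference, spec, lay)
    if not _certify(reference.seq, lay, truth_cand, ScreenParams()):
        raise GenerationError("certificate failed on reference")

    others = []
    for name in species:
        seq = list(ref_seq)
        for k in range(len(seq)):
            if k in protected:
                continue
            if rng.random() < divergence:
                seq[k] = str(rng.choice([b for b in _BASES if b != seq[k]]))
        _scrub(seq, lay, protected, rng)
        rec = SequenceRecord(id=name, seq="".join(seq))
        if not _certify(rec.seq, lay, truth_cand and _truth_candidate(rec, spec, lay), ScreenParams()):
            raise GenerationError(f"certificate failed on ortholog {name!r}")
        others.append(rec)

    return (
        OrthologSet(reference=reference, others=tuple(others)),
        SyntheticTruth(reference.id, truth_cand, True),
    )


def generate_screen_ratios(
    n: int,
    n_hits: int,
    effect_sd_units: float,
    seed: int,
    mu: float = 0.04,
    sigma: float = 0.015,
) -> tuple[RatioTable, list[str]]:
    """Normally distributed screen ratios with spiked hits.

    Baseline ratios ~ Normal(mu, sigma) truncated positive; hits are
    shifted upward by ``effect_sd_units * sigma``.  Returns the table
    and the sorted list of spiked labels.
    """
    if n_hits > n:
        raise ValueError("n_hits cannot exceed n")
    rng = np.random.default_rng(seed)
    ratios = rng.normal(mu, sigma, size=n)
    while np.any(ratios <= 0):
        mask = ratios <= 0
        ratios[mask] = rng.normal(mu, sigma, size=int(mask.sum()))
    hit_idx = rng.choice(n, size=n_hits, replace=False)
    ratios[hit_idx] += effect_sd_units * sigma
    labels = [f"kinase_{i + 1:03d}" for i in range(n)]
    entries = tuple((labels[i], float(ratios[i])) for i in range(n))
    return RatioTable(entries=entries), sorted(labels[i] for i in hit_idx)


def generate_ct_table(
    true_index: float, noise_sd_cycles: float, n_reps: int, seed: int
) -> tuple[list[CtRecord], float]:
    """Replicate Ct values whose noiseless ddCt recovers ``true_index``."""
    if true_index <= 0:
        raise ValueError("true_index must be positive")
    if n_reps < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_reps):
        ct_target_bg = float(rng.uniform(28, 32))
        ct_ref_bg = float(rng.uniform(28, 32))
        d_ref = float(rng.uniform(-6, -2))
        d_target = d_ref - math.log2(true_index)
        noise = rng.normal(0.0, noise_sd_cycles, size=4) if noise_sd_cycles > 0 else np.zeros(4)
        records.append(
            CtRecord(
                replicate=f"rep{i + 1}",
                ct_target_tis=ct_target_bg + d_target + float(noise[0]),
                ct_target_bg=ct_target_bg + float(noise[1]),
                ct_ref_tis=ct_ref_bg + d_ref + float(noise[2]),
                ct_ref_bg=ct_ref_bg + float(noise[3]),
            )
        )
    return records, true_index
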