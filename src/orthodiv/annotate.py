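"""Protein-guided CDS / 5'UTR / 3'UTR delineation on ortholog pairs.

For each member of a pair the shared reference protein anchors the reading
frame (best of the six translated frames); the start codon is the in-frame
ATG within +/-30 bp of the aligned protein start (nearest wins, ties go
upstream), the stop codon the in-frame TAA/TAG/TGA within +/-30 bp of the
aligned protein end.  When no ATG is found the CDS is anchored at the aligned
reference start and the pair is excluded from 5'UTR statistics; likewise a
missing stop excludes the pair from 3'UTR statistics.

Quality filters mirror the workflow this package models: CDS pairs with
unequal lengths (the substitution-only analogue of an indel/frameshift),
internal stop codons, or fewer than 150 bp are rejected; UTR alignments are
kept only above a high-stringency surrogate threshold (aligned length >= 40
and identity >= 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import (AlignmentParams, ProteinSearchParams, align_protein,
                    local_align, six_frame_translations)
from .genetics import has_internal_stop, is_stop, reverse_complement
from .io import as_seq_dict
from .orthologs import OrthologPair

START_WINDOW = 30   # bp on either side of the aligned reference protein start
STOP_WINDOW = 30
STOP_MOTIFS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class AnnotateParams:
    min_cds_length: int = 150
    start_window: int = START_WINDOW
    stop_window: int = STOP_WINDOW
    utr_min_aligned: int = 40        # surrogate for the high-stringency UTR E-value
    utr_min_identity: float = 0.90
    utr_align: AlignmentParams = field(
        default_factory=lambda: AlignmentParams(min_score=15))
    protein: ProteinSearchParams = field(default_factory=ProteinSearchParams)


@dataclass(frozen=True)
class CdsAnchor:
    """Best protein-guided frame for one transcript.

    Coordinates refer to the oriented sequence (reverse-complemented once if
    the best hit was on the minus strand).
    """
    strand: str
    frame: int
    tx_start: int     # first base of the first aligned codon
    tx_end: int       # one past the last base of the last aligned codon
    score: float


def protein_guided_cds(transcript: str, protein: str,
                       params: AnnotateParams = AnnotateParams()) -> CdsAnchor | None:
    """Locate the protein-homologous interval by six-frame translated alignment."""
    if not transcript or not protein:
        raise ValueError("transcript and protein must be non-empty")
    best: CdsAnchor | None = None
    for strand, f, aa in six_frame_translations(transcript):
        score, aln = align_protein(aa, protein, params.protein)
        if aln is None or score < params.protein.min_score:
            continue
        if best is not None and score <= best.score:
            continue
        blocks_q = aln.aligned[0]
        aa_start, aa_end = int(blocks_q[0][0]), int(blocks_q[-1][1])
        best = CdsAnchor(strand, f, f + 3 * aa_start, f + 3 * aa_end, score)
    return best


def _nearest_in_frame(seq: str, anchor: int, window: int,
                      motifs: tuple[str, ...]) -> int | None:
    """Nearest in-frame motif start within +/-window bp of anchor (tie: upstream)."""
    candidates = []
    lo = anchor - window
    hi = anchor + window
    for p in range(anchor % 3, len(seq) - 2, 3):
        if p < lo or p > hi:
            continue
        if seq[p:p + 3] in motifs:
            candidates.append(p)
    if not candidates:
        return None
    return min(candidates, key=lambda p: (abs(p - anchor), p))


def locate_start(seq: str, ref_start: int,
                 params: AnnotateParams = AnnotateParams()) -> int | None:
    """In-frame ATG within the start window around the aligned protein start."""
    return _nearest_in_frame(seq, ref_start, params.start_window, ("ATG",))


def locate_stop(seq: str, ref_stop: int,
                params: AnnotateParams = AnnotateParams()) -> int | None:
    """In-frame TAA/TAG/TGA within the stop window around the reference stop."""
    return _nearest_in_frame(seq, ref_stop, params.stop_window, STOP_MOTIFS)


@dataclass(frozen=True)
class MemberAnnotation:
    """Region coordinates on one oriented member sequence."""
    transcript_id: str
    sequence: str                     # oriented (+ strand w.r.t. the protein)
    strand: str
    cds: tuple[int, int]              # includes the terminal stop codon if found
    utr5: tuple[int, int] | None
    utr3: tuple[int, int] | None
    start_found: bool
    stop_found: bool


@dataclass(frozen=True)
class AlignedRegion:
    """Column-matched gap-free region of an annotated pair."""
    label: str                        # "utr5" | "cds" | "utr3"
    pos_a: np.ndarray                 # transcript coordinates, oriented, per column
    pos_b: np.ndarray

    def bases(self, seq_a: str, seq_b: str) -> tuple[str, str]:
        return ("".join(seq_a[p] for p in self.pos_a),
                "".join(seq_b[p] for p in self.pos_b))


@dataclass(frozen=True)
class AnnotatedOrtholog:
    pair: OrthologPair
    member_a: MemberAnnotation
    member_b: MemberAnnotation
    regions: tuple[AlignedRegion, ...]

    @property
    def aligned_cds(self) -> tuple[str, str]:
        region = next(r for r in self.regions if r.label == "cds")
        return region.bases(self.member_a.sequence, self.member_b.sequence)


@dataclass(frozen=True)
class Rejection:
    pair: OrthologPair
    reason: str


def _annotate_member(tid: str, seq: str, protein: str,
                     params: AnnotateParams) -> MemberAnnotation | str:
    anchor = protein_guided_cds(seq, protein, params)
    if anchor is None:
        return "no_cds_hit"
    if anchor.strand == "-":
        seq = reverse_complement(seq)
        # anchor coordinates already refer to the oriented sequence
    start = locate_start(seq, anchor.tx_start, params)
    stop = locate_stop(seq, anchor.tx_end, params)
    cds_start = start if start is not None else anchor.tx_start
    cds_end = stop + 3 if stop is not None else anchor.tx_end
    if cds_end <= cds_start:
        return "empty_cds"
    utr5 = (0, cds_start) if (start is not None and cds_start > 0) else None
    utr3 = (cds_end, len(seq)) if (stop is not None and cds_end < len(seq)) else None
    return MemberAnnotation(tid, seq, anchor.strand, (cds_start, cds_end),
                            utr5, utr3, start is not None, stop is not None)


def extract_regions(pair: OrthologPair, set_a, set_b, protein: str,
                    params: AnnotateParams = AnnotateParams()
                    ) -> AnnotatedOrtholog | Rejection:
    """Annotate both members against the shared protein and pair their regions.

    The CDS pairing is positional codon-by-codon (gap-free by construction;
    pairs whose located CDSs differ in length are rejected, mirroring the
    indel/frameshift filter).  UTR pairings come from a nucleotide local
    alignment and are attached only if both members have the region and the
    alignment passes the high-stringency surrogate threshold; gap columns in
    a UTR alignment are dropped from the comparison.
    """
    seqs_a, seqs_b = as_seq_dict(set_a), as_seq_dict(set_b)
    mem_a = _annotate_member(pair.id_a, seqs_a[pair.id_a], protein, params)
    if isinstance(mem_a, str):
        return Rejection(pair, f"{mem_a}_a")
    mem_b = _annotate_member(pair.id_b, seqs_b[pair.id_b], protein, params)
    if isinstance(mem_b, str):
        return Rejection(pair, f"{mem_b}_b")
    len_a = mem_a.cds[1] - mem_a.cds[0]
    len_b = mem_b.cds[1] - mem_b.cds[0]
    if len_a % 3 or len_b % 3:
        return Rejection(pair, "frame_mismatch")
    if len_a != len_b:
        return Rejection(pair, "cds_length_mismatch")
    if len_a < params.min_cds_length:
        return Rejection(pair, "cds_too_short")
    cds_a = mem_a.sequence[mem_a.cds[0]:mem_a.cds[1]]
    cds_b = mem_b.sequence[mem_b.cds[0]:mem_b.cds[1]]
    if has_internal_stop(cds_a) or has_internal_stop(cds_b):
        return Rejection(pair, "internal_stop")
    if not (mem_a.stop_found and mem_b.stop_found):
        # without a located stop the anchored CDS must itself be stop-free
        if any(is_stop(cds_a[i:i + 3]) for i in range(0, len_a, 3)) or \
           any(is_stop(cds_b[i:i + 3]) for i in range(0, len_b, 3)):
            return Rejection(pair, "internal_stop")
    regions = [AlignedRegion("cds",
                             np.arange(mem_a.cds[0], mem_a.cds[1]),
                             np.arange(mem_b.cds[0], mem_b.cds[1]))]
    for label in ("utr5", "utr3"):
        iv_a = getattr(mem_a, label)
        iv_b = getattr(mem_b, label)
        if iv_a is None or iv_b is None:
            continue
        ua = mem_a.sequence[iv_a[0]:iv_a[1]]
        ub = mem_b.sequence[iv_b[0]:iv_b[1]]
        if min(len(ua), len(ub)) < params.utr_min_aligned:
            continue
        hit_aln = _utr_alignment(ua, ub, params)
        if hit_aln is None:
            continue
        pos_a, pos_b = hit_aln
        regions.append(AlignedRegion(label, pos_a + iv_a[0], pos_b + iv_b[0]))
    return AnnotatedOrtholog(pair, mem_a, mem_b, tuple(regions))


def _utr_alignment(ua: str, ub: str, params: AnnotateParams):
    """Gap-free column lists of a passing UTR alignment, or None."""
    from .align import _nt_aligner  # same scoring machinery as local_align
    p = params.utr_align
    aligner = _nt_aligner(p.match, p.mismatch, p.open_gap, p.extend_gap)
    if aligner.score(ua, ub) < p.min_score:
        return None
    aln = next(iter(aligner.align(ua, ub)))
    blocks_a, blocks_b = aln.aligned
    pos_a, pos_b, matches, denom = [], [], 0, 0
    for (qs, qe), (ss, se) in zip(blocks_a, blocks_b):
        for i in range(qe - qs):
            a, b = ua[qs + i], ub[ss + i]
            if a == "N" or b == "N":
                continue
            pos_a.append(qs + i)
            pos_b.append(ss + i)
            denom += 1
            matches += a == b
    if denom < params.utr_min_aligned:
        return None
    if matches / denom < params.utr_min_identity:
        return None
    return np.array(pos_a), np.array(pos_b)
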