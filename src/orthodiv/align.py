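"""Pairwise local alignment primitives.

Nucleotide alignment is exact affine-gap local alignment (Smith-Waterman /
Gotoh) through Biopython's ``PairwiseAligner``; candidate pre-selection for
all-vs-all searches uses shared k-mer counts so that only plausible homologs
reach the DP.  Because MegaBLAST-style E-values depend on database statistics
this package does not reproduce, significance is expressed as raw-score and
score-per-column thresholds in the parameter objects; the mapping is
documented in docs/methods.md.

N is never a match: it scores as a mismatch and is excluded from the identity
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

from .genetics import reverse_complement


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring and search parameters for nucleotide local alignment.

    match/mismatch/open_gap/extend_gap follow the convention that the first
    residue of a gap costs ``open_gap`` and each further residue
    ``extend_gap``.  ``min_score`` plays the role of the BLAST significance
    threshold (a 40-score hit at +1/-2 scoring needs >=40 matched bases net).
    """
    match: int = 1
    mismatch: int = -2
    open_gap: int = -5
    extend_gap: int = -2
    word_size: int = 11
    min_score: int = 40
    max_candidates: int = 8       # k-mer prefilter shortlist per query
    min_shared_kmers: int = 2

    def __post_init__(self):
        if self.word_size <= 0:
            raise ValueError("word_size must be positive")
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be positive and mismatch negative")


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between a query and a subject sequence."""
    query_id: str
    subject_id: str
    score: float
    identity: float               # matches / non-gap non-N columns
    n_columns: int                # total alignment columns (incl. gap columns)
    aligned_span_query: tuple[int, int]    # 0-based half-open on the query
    aligned_span_subject: tuple[int, int]
    evalue_surrogate: float       # score per alignment column (higher = better)


_NT_ALPHABET = "ACGTN"


@lru_cache(maxsize=16)
def _nt_aligner(match: int, mismatch: int, open_gap: int, extend_gap: int) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array(_NT_ALPHABET, dims=2)
    for a in _NT_ALPHABET:
        for b in _NT_ALPHABET:
            # N vs anything (including N) is scored as a mismatch.
            mat[a, b] = match if (a == b and a != "N") else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def _validate_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    if set(seq) - set(_NT_ALPHABET):
        bad = sorted(set(seq) - set(_NT_ALPHABET))
        raise ValueError(f"{name} contains non-ACGTN characters: {bad}")


def local_align(query: str, subject: str, params: AlignmentParams = AlignmentParams(),
                query_id: str = "query", subject_id: str = "subject") -> AlignmentHit | None:
    """Best local alignment of two nucleotide sequences, or None below threshold.

    Deterministic: among co-optimal alignments Biopython's first enumerated
    alignment is used, which is a fixed traceback order.
    """
    _validate_sequence(query, "query")
    _validate_sequence(subject, "subject")
    aligner = _nt_aligner(params.match, params.mismatch, params.open_gap, params.extend_gap)
    score = aligner.score(query, subject)
    if score < params.min_score:
        return None
    aln = next(iter(aligner.align(query, subject)))
    blocks_q, blocks_s = aln.aligned
    matches = 0
    denom = 0
    for (qs, qe), (ss, se) in zip(blocks_q, blocks_s):
        for i in range(qe - qs):
            a, b = query[qs + i], subject[ss + i]
            if a == "N" or b == "N":
                continue
            denom += 1
            matches += a == b
    identity = matches / denom if denom else 0.0
    n_cols = aln.shape[1]
    span_q = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    span_s = (int(blocks_s[0][0]), int(blocks_s[-1][1]))
    return AlignmentHit(query_id, subject_id, float(score), identity, int(n_cols),
                        span_q, span_s, float(score) / max(n_cols, 1))


class KmerIndex:
    """Distinct-k-mer index over a set of sequences for candidate shortlisting."""

    def __init__(self, seqs: dict[str, str], k: int):
        self.k = k
        self.ids = sorted(seqs)
        self._kmer_sets = {i: self._kmers(seqs[i]) for i in self.ids}
        self._by_kmer: dict[str, list[str]] = {}
        for i in self.ids:
            for km in self._kmer_sets[i]:
                self._by_kmer.setdefault(km, []).append(i)

    def _kmers(self, seq: str) -> frozenset[str]:
        k = self.k
        return frozenset(seq[j:j + k] for j in range(len(seq) - k + 1)
                         if "N" not in seq[j:j + k])

    def candidates(self, query: str, n_best: int, min_shared: int) -> list[str]:
        """Subject ids ranked by shared distinct k-mers (ties: lexicographic id)."""
        counts: dict[str, int] = {}
        for km in self._kmers(query):
            for sid in self._by_kmer.get(km, ()):
                counts[sid] = counts.get(sid, 0) + 1
        ranked = sorted((sid for sid, c in counts.items() if c >= min_shared),
                        key=lambda sid: (-counts[sid], sid))
        return ranked[:n_best]


def best_hit(query_id: str, query: str, subjects: dict[str, str],
             index: KmerIndex, params: AlignmentParams) -> AlignmentHit | None:
    """Highest-scoring hit of one query into a subject set.

    Tie-breaking: highest score, then longest aligned subject span, then
    lexicographically smallest subject id.  Candidates are first ranked by a
    score-only DP pass; the full traceback runs only for the top scorers.
    """
    aligner = _nt_aligner(params.match, params.mismatch, params.open_gap,
                          params.extend_gap)
    scores: dict[str, float] = {}
    for sid in index.candidates(query, params.max_candidates, params.min_shared_kmers):
        if sid == query_id:
            continue
        scores[sid] = float(aligner.score(query, subjects[sid]))
    if not scores:
        return None
    top = max(scores.values())
    if top < params.min_score:
        return None
    best: AlignmentHit | None = None
    for sid in sorted(s for s, sc in scores.items() if sc == top):
        hit = local_align(query, subjects[sid], params, query_id, sid)
        if best is None:
            best = hit
            continue
        span = hit.aligned_span_subject[1] - hit.aligned_span_subject[0]
        bspan = best.aligned_span_subject[1] - best.aligned_span_subject[0]
        if span > bspan:
            best = hit
    return best


# ---------------------------------------------------------------------------
# Protein search (six-frame translated comparison against a reference set)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinSearchParams:
    """BLOSUM62 local alignment with BLAST-like gap costs.

    ``min_score`` is the significance surrogate for a BLAST-style E<1e-5
    protein threshold; ``tie_margin`` is the score gap below which two best
    protein hits are considered ambiguous (paralog filter).
    """
    open_gap: int = -11
    extend_gap: int = -1
    min_score: float = 60.0
    tie_margin: float = 5.0
    kmer: int = 4
    max_candidates: int = 6


@lru_cache(maxsize=4)
def _aa_aligner(open_gap: int, extend_gap: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


_BLOSUM_ALPHABET = None


def _sanitize_aa(seq: str) -> str:
    """Map residues outside the BLOSUM62 alphabet to X."""
    global _BLOSUM_ALPHABET
    if _BLOSUM_ALPHABET is None:
        _BLOSUM_ALPHABET = set(substitution_matrices.load("BLOSUM62").alphabet)
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in seq)


def six_frame_translations(seq: str) -> list[tuple[str, int, str]]:
    """All six reading-frame translations as (strand, frame_offset, protein)."""
    from .genetics import translate
    out = []
    rc = reverse_complement(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for f in range(3):
            out.append((strand, f, _sanitize_aa(translate(s[f:]))))
    return out


def align_protein(query_aa: str, subject_aa: str,
                  params: ProteinSearchParams = ProteinSearchParams()):
    """Local BLOSUM62 alignment; returns (score, alignment) or (0.0, None)."""
    if not query_aa or not subject_aa:
        return 0.0, None
    aligner = _aa_aligner(params.open_gap, params.extend_gap)
    score = aligner.score(query_aa, subject_aa)
    if score <= 0:
        return 0.0, None
    return float(score), next(iter(aligner.align(query_aa, subject_aa)))


class ProteinIndex:
    """Amino-acid k-mer shortlist index over a reference protein set."""

    def __init__(self, proteins: dict[str, str], k: int = 4):
        self.k = k
        self.proteins = {pid: _sanitize_aa(p) for pid, p in proteins.items()}
        self._by_kmer: dict[str, list[str]] = {}
        for pid in sorted(self.proteins):
            p = self.proteins[pid]
            for j in range(len(p) - k + 1):
                self._by_kmer.setdefault(p[j:j + k], []).append(pid)

    def candidates(self, aa: str, n_best: int, min_shared: int = 2) -> list[str]:
        counts: dict[str, int] = {}
        for j in range(len(aa) - self.k + 1):
            km = aa[j:j + self.k]
            for pid in self._by_kmer.get(km, ()):
                counts[pid] = counts.get(pid, 0) + 1
        ranked = sorted((pid for pid, c in counts.items() if c >= min_shared),
                        key=lambda pid: (-counts[pid], pid))
        return ranked[:n_best]


@dataclass(frozen=True)
class ProteinHit:
    protein_id: str
    score: float
    strand: str
    frame: int
    runner_up_score: float     # best score to any OTHER protein (0 if none)


def best_protein_hit(transcript: str, index: ProteinIndex,
                     params: ProteinSearchParams = ProteinSearchParams()) -> ProteinHit | None:
    """Best six-frame translated hit of a transcript into the protein set.

    Each translated frame is compared (score-only) against its own k-mer
    candidate shortlist; the per-protein score is the best over frames.  The
    returned hit records the runner-up protein's score so callers can test
    uniqueness.  Returns None when no protein reaches ``min_score``.
    """
    aligner = _aa_aligner(params.open_gap, params.extend_gap)
    per_protein: dict[str, tuple[float, str, int]] = {}
    for strand, f, aa in six_frame_translations(transcript):
        if len(aa) < index.k:
            continue
        for pid in index.candidates(aa, params.max_candidates):
            sc = float(aligner.score(aa, index.proteins[pid]))
            if pid not in per_protein or sc > per_protein[pid][0]:
                per_protein[pid] = (sc, strand, f)
    if not per_protein:
        return None
    ranked = sorted(per_protein, key=lambda pid: (-per_protein[pid][0], pid))
    top = ranked[0]
    score, strand, frame = per_protein[top]
    if score < params.min_score:
        return None
    runner = per_protein[ranked[1]][0] if len(ranked) > 1 else 0.0
    return ProteinHit(top, score, strand, frame, runner)
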