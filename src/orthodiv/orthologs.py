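"""Reciprocal-best-hit orthology with a shared-protein paralog filter.

Putative orthologs between the two transcript sets are pairs that are each
other's best local-alignment hit with an alignment longer than 200 bp.
Because de novo transcriptome assemblies confound gene-family members, a
second screen keeps only pairs whose two members map unambiguously (unique
best hit, no near-tie) to the same reference protein — the operational
stand-in for "same unique Swissprot hit".
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .align import (AlignmentHit, AlignmentParams, KmerIndex, ProteinIndex,
                    ProteinSearchParams, best_hit, best_protein_hit)
from .io import as_seq_dict


@dataclass(frozen=True)
class OrthologPair:
    """A reciprocal-best-hit transcript pair (A-side id first)."""
    id_a: str
    id_b: str
    hit_ab: AlignmentHit
    hit_ba: AlignmentHit
    pair_identity: float
    shared_protein_id: str | None = None


@dataclass(frozen=True)
class RbhParams:
    """Pair-level filters applied on top of the alignment parameters."""
    min_aligned_length: int = 201     # "longer than 200 bp"
    min_pair_identity: float = 0.80   # reporting floor


def reciprocal_best_hits(set_a, set_b,
                         align_params: AlignmentParams = AlignmentParams(),
                         rbh_params: RbhParams = RbhParams()) -> list[OrthologPair]:
    """Mutual-best pairs between two transcript sets.

    Each transcript appears in at most one pair (best hits are unique by the
    deterministic tie-break in :func:`orthodiv.align.best_hit`).  Pairs whose
    alignment is not longer than ``min_aligned_length - 1`` columns, or whose
    identity falls below the reporting floor, are dropped.
    """
    seqs_a, seqs_b = as_seq_dict(set_a), as_seq_dict(set_b)
    if not seqs_a or not seqs_b:
        raise ValueError("both transcript sets must be non-empty")
    idx_b = KmerIndex(seqs_b, align_params.word_size)
    idx_a = KmerIndex(seqs_a, align_params.word_size)
    best_ab = {qid: best_hit(qid, seqs_a[qid], seqs_b, idx_b, align_params)
               for qid in sorted(seqs_a)}
    best_ba = {qid: best_hit(qid, seqs_b[qid], seqs_a, idx_a, align_params)
               for qid in sorted(seqs_b)}
    pairs: list[OrthologPair] = []
    for qid in sorted(seqs_a):
        hit_ab = best_ab[qid]
        if hit_ab is None:
            continue
        hit_ba = best_ba.get(hit_ab.subject_id)
        if hit_ba is None or hit_ba.subject_id != qid:
            continue
        if hit_ab.n_columns < rbh_params.min_aligned_length:
            continue
        if hit_ab.identity < rbh_params.min_pair_identity:
            continue
        pairs.append(OrthologPair(qid, hit_ab.subject_id, hit_ab, hit_ba,
                                  hit_ab.identity))
    return pairs


def paralog_filter(pairs: list[OrthologPair], set_a, set_b,
                   proteins: dict[str, str],
                   params: ProteinSearchParams = ProteinSearchParams()
                   ) -> list[OrthologPair]:
    """Keep pairs whose members share a unique best reference-protein hit.

    Both members are compared against the protein set in all six reading
    frames; a pair survives iff both best hits pass ``min_score``, are unique
    (score lead over the runner-up of at least ``tie_margin``) and name the
    same protein.  Survivors get ``shared_protein_id`` populated.
    """
    if not proteins:
        raise ValueError("protein set must be non-empty")
    seqs_a, seqs_b = as_seq_dict(set_a), as_seq_dict(set_b)
    index = ProteinIndex(proteins, params.kmer)
    hit_cache: dict[str, object] = {}

    def _hit(tid: str, seq: str):
        if tid not in hit_cache:
            hit_cache[tid] = best_protein_hit(seq, index, params)
        return hit_cache[tid]

    out: list[OrthologPair] = []
    for pair in pairs:
        ha = _hit(pair.id_a, seqs_a[pair.id_a])
        hb = _hit(pair.id_b, seqs_b[pair.id_b])
        if ha is None or hb is None:
            continue
        if ha.protein_id != hb.protein_id:
            continue
        if ha.score - ha.runner_up_score < params.tie_margin:
            continue
        if hb.score - hb.runner_up_score < params.tie_margin:
            continue
        out.append(replace(pair, shared_protein_id=ha.protein_id))
    return out
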