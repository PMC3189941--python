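"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own code paths: the Smith-Waterman
oracle is a plain Gotoh dynamic program, the pathway oracle a recursive
enumeration, and the truth-side filter oracle applies the annotation rules
directly to ground-truth coordinates.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}
_PURINES = {"A", "G"}


def sw_score(a: str, b: str, match: int, mismatch: int,
             open_gap: int, extend_gap: int) -> float:
    """Affine-gap local alignment score by the full O(mn) Gotoh recursion.

    Gap convention: the first residue of a gap costs ``open_gap``, each
    further residue ``extend_gap``.  N scores as a mismatch.
    """
    m, n = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        ai = a[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Ei1 = E[i], E[i - 1]
        Fi = F[i]
        for j in range(1, n + 1):
            bj = b[j - 1]
            e = max(Hi1[j] + open_gap, Ei1[j] + extend_gap)
            f = max(Hi[j - 1] + open_gap, Fi[j - 1] + extend_gap)
            sub = match if (ai == bj and ai != "N") else mismatch
            h = Hi1[j - 1] + sub
            h = max(0.0, h, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best = h
    return best


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Equal-weight pathway-averaged (synonymous, nonsynonymous) differences.

    Recursively enumerates orderings of the differing positions, dropping
    orderings that pass through a stop codon; falls back to all orderings if
    every one is blocked.  Uses Biopython's translation, not the package's
    genetic-code tables.
    """
    diffs = [p for p in range(3) if c1[p] != c2[p]]
    if not diffs:
        return 0.0, 0.0

    def walk(order):
        cur = c1
        syn = non = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                return None
            if _aa(cur) == _aa(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non

    results = [r for r in (walk(o) for o in permutations(diffs)) if r is not None]
    if not results:
        def walk_any(order):
            cur = c1
            syn = non = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if _aa(cur) == _aa(nxt) and nxt not in _STOPS and cur not in _STOPS:
                    syn += 1
                else:
                    non += 1
                cur = nxt
            return syn, non
        results = [walk_any(o) for o in permutations(diffs)]
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def in_frame_motif(seq: str, anchor: int, window: int, motifs) -> int | None:
    """Truth-side re-statement of the +/-window in-frame motif rule."""
    cands = [p for p in range(anchor % 3, len(seq) - 2, 3)
             if anchor - window <= p <= anchor + window and seq[p:p + 3] in motifs]
    if not cands:
        return None
    return min(cands, key=lambda p: (abs(p - anchor), p))


def truth_accepted_pairs(world, min_cds: int = 150, window: int = 30,
                         min_rbh_columns: int = 201) -> set[tuple[str, str]]:
    """Apply the annotation filters directly to the ground-truth table.

    For each true ortholog pair: the RBH length rule (transcripts must admit
    an alignment longer than 200 bp — with substitution-only evolution the
    whole transcript aligns), then per member the located start (in-frame ATG
    within the window of the true CDS start, else anchored at the true
    start), the located stop (in-frame stop motif within the window of the
    true terminal-stop position, else anchored), equal CDS lengths, length >=
    min_cds and no internal stop.
    """
    accepted = set()
    seqs = {}
    for rec in (*world.records_a, *world.records_b):
        seqs[rec.id] = rec.sequence
    for ia, ib in sorted(world.truth.true_pairs()):
        ta = world.truth.transcripts[ia]
        tb = world.truth.transcripts[ib]
        if len(seqs[ia]) < min_rbh_columns:
            continue
        spans = []
        ok = True
        for tid, tt in ((ia, ta), (ib, tb)):
            seq = seqs[tid]
            start = in_frame_motif(seq, tt.cds_start, window, {"ATG"})
            cds_start = start if start is not None else tt.cds_start
            stop = in_frame_motif(seq, tt.cds_end - 3, window, _STOPS)
            cds_end = stop + 3 if stop is not None else tt.cds_end - 3
            if cds_end <= cds_start or (cds_end - cds_start) % 3:
                ok = False
                break
            cds = seq[cds_start:cds_end]
            body = cds[:-3] if cds[-3:] in _STOPS else cds
            if any(body[i:i + 3] in _STOPS for i in range(0, len(body) - 2, 3)):
                ok = False
                break
            spans.append((cds_start, cds_end))
        if not ok or len(spans) != 2:
            continue
        la = spans[0][1] - spans[0][0]
        lb = spans[1][1] - spans[1][0]
        if la != lb or la < min_cds:
            continue
        accepted.add((ia, ib))
    return accepted
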