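"""Pairwise Ka/Ks estimation (NG86 and a YN-style approximate method).

Two estimators over gap-free, in-frame CDS pairs:

* :func:`ng86` — Nei & Gojobori (1986) counting: per-codon synonymous-site
  fractions, multi-difference codons averaged over all minimal mutational
  pathways (stop-codon intermediates excluded) with equal weights, and a
  Jukes-Cantor correction applied separately to the synonymous and
  nonsynonymous proportions.  Serves as the transparent baseline and oracle
  partner for the YN estimator.

* :func:`yn` — an approximate method in the spirit of Yang & Nielsen (2000):
  transition/transversion rate ratio kappa estimated from fourfold-degenerate
  and nondegenerate sites (K80 formulas, site-count weighted), sites counted
  under mutation-rate weights kappa^ts x pi(target codon) with F3x4 codon
  frequencies, pathway weights additionally carrying omega on nonsynonymous
  steps, K80-type distance corrections per site class, and iteration until
  omega stabilizes.

Both estimators are symmetric in their two arguments and strip a terminal
stop-codon pair before counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd

from .genetics import (CODON_NEIGHBORS, CODON_TO_AA, DEGENERACY, FOURFOLD, ND,
                       NUCLEOTIDES, is_stop, is_transition)

_POS_WEIGHT_CACHE: dict[str, tuple[float, ...]] = {}


@dataclass(frozen=True)
class KaKsResult:
    pair_id: str
    method: str                  # "NG86" or "YN"
    n_codons: int
    s_sites: float               # effective synonymous sites
    n_sites: float
    s_sub: float                 # pathway-averaged synonymous differences
    n_sub: float
    ka: float | None             # None when the correction is undefined
    ks: float | None
    ka_ks: float | None          # None when Ks is 0 or undefined
    kappa_hat: float | None
    converged: bool = True

    @property
    def selection_class(self) -> str | None:
        """positive (Ka/Ks>1), relaxed (0.5<=Ka/Ks<=1), constrained (<0.5)."""
        if self.ka_ks is None:
            return None
        if self.ka_ks > 1.0:
            return "positive"
        if self.ka_ks >= 0.5:
            return "relaxed"
        return "constrained"


def _prepare(seq1: str, seq2: str) -> tuple[list[str], list[str]]:
    if len(seq1) != len(seq2):
        raise ValueError("CDS pair must be aligned to equal lengths")
    if len(seq1) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    c1 = [seq1[i:i + 3] for i in range(0, len(seq1), 3)]
    c2 = [seq2[i:i + 3] for i in range(0, len(seq2), 3)]
    if c1 and is_stop(c1[-1]) and is_stop(c2[-1]):
        c1, c2 = c1[:-1], c2[:-1]
    for cod in (*c1, *c2):
        if is_stop(cod):
            raise ValueError(f"internal stop codon {cod} in CDS pair")
        if cod not in CODON_TO_AA:
            raise ValueError(f"ambiguous codon {cod} in CDS pair")
    if not c1:
        raise ValueError("empty CDS pair")
    return c1, c2


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def _ng86_syn_fraction(codon: str) -> tuple[float, ...]:
    """Per-position synonymous fraction among non-stop single changes."""
    if codon not in _POS_WEIGHT_CACHE:
        fracs = []
        for pos in range(3):
            ch = [c for c in CODON_NEIGHBORS[codon] if c.pos == pos and not c.to_stop]
            fracs.append(sum(c.synonymous for c in ch) / len(ch) if ch else 0.0)
        _POS_WEIGHT_CACHE[codon] = tuple(fracs)
    return _POS_WEIGHT_CACHE[codon]


def count_pathways(codon1: str, codon2: str,
                   step_weight=None) -> tuple[float, float, float, float]:
    """Pathway-averaged (syn, nonsyn, syn_ts, nonsyn_ts) differences.

    Enumerates every ordering of the differing positions, discards orderings
    passing through a stop codon, and averages the per-step synonymous and
    transition tallies.  With ``step_weight`` (a function of
    (from_codon, to_codon, synonymous, transition) returning a rate factor)
    pathways are weighted by the product of their step factors instead of
    equally.  If every ordering passes through a stop, all orderings are used.
    """
    diffs = [p for p in range(3) if codon1[p] != codon2[p]]
    if not diffs:
        return 0.0, 0.0, 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = codon1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
            if is_stop(nxt):
                blocked = True
                break
            syn = (CODON_TO_AA[cur] == CODON_TO_AA[nxt])
            ts = is_transition(cur[pos], codon2[pos])
            steps.append((cur, nxt, syn, ts))
            cur = nxt
        if not blocked:
            paths.append(steps)
    if not paths:   # all orderings stop-blocked: fall back to unrestricted set
        for order in permutations(diffs):
            cur = codon1
            steps = []
            for pos in order:
                nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
                syn = (CODON_TO_AA.get(cur) == CODON_TO_AA.get(nxt)
                       and not is_stop(nxt) and not is_stop(cur))
                steps.append((cur, nxt, syn, is_transition(cur[pos], codon2[pos])))
                cur = nxt
            paths.append(steps)
    weights = []
    for steps in paths:
        if step_weight is None:
            weights.append(1.0)
        else:
            w = 1.0
            for cur, nxt, syn, ts in steps:
                w *= step_weight(cur, nxt, syn, ts)
            weights.append(w)
    total = sum(weights)
    if total <= 0:
        weights = [1.0] * len(paths)
        total = float(len(paths))
    sd = nd = sd_ts = nd_ts = 0.0
    for w, steps in zip(weights, paths):
        for cur, nxt, syn, ts in steps:
            share = w / total
            if syn:
                sd += share
                sd_ts += share * ts
            else:
                nd += share
                nd_ts += share * ts
    return sd, nd, sd_ts, nd_ts


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        return None
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return None
    return -0.75 * math.log(arg)


def ng86(seq1: str, seq2: str, pair_id: str = "pair") -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction."""
    c1, c2 = _prepare(seq1, seq2)
    s_sites = 0.0
    for codon in (*c1, *c2):
        s_sites += sum(_ng86_syn_fraction(codon))
    s_sites /= 2.0
    n_sites = 3.0 * len(c1) - s_sites
    s_sub = n_sub = 0.0
    for a, b in zip(c1, c2):
        sd, nd, _, _ = count_pathways(a, b)
        s_sub += sd
        n_sub += nd
    ps = s_sub / s_sites if s_sites > 0 else 0.0
    pn = n_sub / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    ka_ks = (ka / ks) if (ka is not None and ks is not None and ks > 0) else None
    return KaKsResult(pair_id, "NG86", len(c1), s_sites, n_sites, s_sub, n_sub,
                      ka, ks, ka_ks, kappa_hat=None)


# ---------------------------------------------------------------------------
# YN-style approximate method
# ---------------------------------------------------------------------------

def f3x4_frequencies(c1: list[str], c2: list[str]) -> dict[str, float]:
    """F3x4 codon frequencies from positional nucleotide counts of the pair."""
    counts = np.zeros((3, 4))
    for cod in (*c1, *c2):
        for p, b in enumerate(cod):
            counts[p, NUCLEOTIDES.index(b)] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = {}
    for cod in CODON_TO_AA:
        if is_stop(cod):
            continue
        pi[cod] = float(np.prod([freqs[p, NUCLEOTIDES.index(b)]
                                 for p, b in enumerate(cod)]))
    total = sum(pi.values())
    return {c: v / total for c, v in pi.items()}


def uniform_frequencies() -> dict[str, float]:
    sense = [c for c in CODON_TO_AA if not is_stop(c)]
    return {c: 1.0 / len(sense) for c in sense}


def _k80(p_ts: float, p_tv: float) -> tuple[float | None, float | None]:
    """K80 distance and kappa from transition/transversion proportions."""
    a1 = 1.0 - 2.0 * p_ts - p_tv
    a2 = 1.0 - 2.0 * p_tv
    if a1 <= 0 or a2 <= 0:
        return None, None
    at = -0.5 * math.log(a1) + 0.25 * math.log(a2)
    bt = -0.25 * math.log(a2)
    d = at + 2.0 * bt
    kappa = at / bt if bt > 0 else None
    return d, kappa


def estimate_kappa(c1: list[str], c2: list[str]) -> float:
    """kappa from 4-fold degenerate and nondegenerate columns (K80, weighted).

    Columns enter only when both codons agree on the degeneracy class.
    Falls back to 1.0 when neither class yields a valid estimate; the result
    is clamped to [0.05, 99].
    """
    tallies = {FOURFOLD: [0, 0, 0], ND: [0, 0, 0]}   # sites, ts, tv
    for a, b in zip(c1, c2):
        for p in range(3):
            da, db = DEGENERACY.get((a, p)), DEGENERACY.get((b, p))
            if da is None or da != db or da not in tallies:
                continue
            t = tallies[da]
            t[0] += 1
            if a[p] != b[p]:
                if is_transition(a[p], b[p]):
                    t[1] += 1
                else:
                    t[2] += 1
    estimates = []
    for cls, (n, ts, tv) in tallies.items():
        if n == 0 or (ts + tv) == 0:
            continue
        _, kap = _k80(ts / n, tv / n)
        if kap is not None and kap > 0:
            estimates.append((n, kap))
    if not estimates:
        return 1.0
    total = sum(n for n, _ in estimates)
    kappa = sum(n * k for n, k in estimates) / total
    return float(min(max(kappa, 0.05), 99.0))


def _yn_site_fractions(codon: str, kappa: float, pi: dict[str, float]) -> float:
    """Synonymous fraction of the mutational opportunity of one codon."""
    syn_w = tot_w = 0.0
    for ch in CODON_NEIGHBORS[codon]:
        if ch.to_stop:
            continue
        w = (kappa if ch.transition else 1.0) * pi.get(ch.new_codon, 0.0)
        tot_w += w
        if ch.synonymous:
            syn_w += w
    if tot_w == 0:
        return sum(_ng86_syn_fraction(codon))
    return 3.0 * syn_w / tot_w


def yn(seq1: str, seq2: str, pair_id: str = "pair",
       codon_frequencies: str | dict[str, float] = "f3x4",
       kappa: float | None = None, max_iter: int = 100,
       tol: float = 1e-6) -> KaKsResult:
    """YN-style approximate Ka/Ks (kappa- and frequency-weighted counting)."""
    c1, c2 = _prepare(seq1, seq2)
    if codon_frequencies == "f3x4":
        pi = f3x4_frequencies(c1, c2)
    elif codon_frequencies == "uniform":
        pi = uniform_frequencies()
    elif isinstance(codon_frequencies, dict):
        pi = codon_frequencies
    else:
        raise ValueError("codon_frequencies must be 'f3x4', 'uniform' or a dict")
    kap = estimate_kappa(c1, c2) if kappa is None else float(kappa)

    frac_cache = {}

    def syn_frac(codon):
        if codon not in frac_cache:
            frac_cache[codon] = _yn_site_fractions(codon, kap, pi)
        return frac_cache[codon]

    s_sites = sum(syn_frac(c) for c in c1) + sum(syn_frac(c) for c in c2)
    s_sites /= 2.0
    n_sites = 3.0 * len(c1) - s_sites

    omega = 0.5
    converged = False
    ka = ks = ka_ks = None
    s_sub = n_sub = 0.0
    for _ in range(max_iter):
        def step_weight(cur, nxt, syn, ts, _om=omega):
            w = (kap if ts else 1.0) * pi.get(nxt, 1e-12)
            if not syn:
                w *= _om
            return w

        s_sub = n_sub = s_ts = n_ts = 0.0
        for a, b in zip(c1, c2):
            sd, nd, sdt, ndt = count_pathways(a, b, step_weight)
            s_sub += sd
            n_sub += nd
            s_ts += sdt
            n_ts += ndt
        ks, _ = _k80(s_ts / s_sites, (s_sub - s_ts) / s_sites) \
            if s_sites > 0 else (None, None)
        ka, _ = _k80(n_ts / n_sites, (n_sub - n_ts) / n_sites) \
            if n_sites > 0 else (None, None)
        if ks is None or ka is None:
            break
        if ks <= 0:
            ka_ks = None
            converged = True
            break
        new_omega = ka / ks
        ka_ks = new_omega
        if abs(new_omega - omega) <= tol * max(omega, 1e-12):
            converged = True
            break
        # omega may be exactly 0 (no nonsynonymous differences): the pathway
        # weighting then falls back to equal weights where all paths vanish.
        omega = new_omega
    return KaKsResult(pair_id, "YN", len(c1), s_sites, n_sites, s_sub, n_sub,
                      ka, ks, ka_ks, kappa_hat=kap, converged=converged)


# ---------------------------------------------------------------------------
# Selection-band classification
# ---------------------------------------------------------------------------

@dataclass
class SelectionSummary:
    """Banded gene lists, a Ka/Ks table and Ka-vs-Ks scatter data."""
    bands: dict[str, list[str]]
    table: pd.DataFrame
    scatter: pd.DataFrame
    reference_lines: dict[str, float]
    n_with_both_rates: int
    n_total: int


def classify_selection(results: list[KaKsResult]) -> SelectionSummary:
    """Partition pairs into Ka/Ks > 1, [0.5, 1] and < 0.5 bands.

    Boundary convention: Ka/Ks exactly 1 or 0.5 falls in the middle band (a
    ratio must be strictly larger than one to count as positive selection).
    Pairs without a defined ratio are reported in the table with whichever
    rate is defined but excluded from the bands and the scatter.
    """
    bands = {"positive": [], "relaxed": [], "constrained": []}
    rows = []
    for r in results:
        rows.append({"pair_id": r.pair_id, "method": r.method,
                     "n_codons": r.n_codons,
                     "s_sites": r.s_sites, "n_sites": r.n_sites,
                     "s_sub": r.s_sub, "n_sub": r.n_sub,
                     "ka": r.ka, "ks": r.ks, "ka_ks": r.ka_ks,
                     "kappa_hat": r.kappa_hat,
                     "selection_class": r.selection_class})
        if r.selection_class is not None:
            bands[r.selection_class].append(r.pair_id)
    table = pd.DataFrame(rows, columns=["pair_id", "method", "n_codons",
                                        "s_sites", "n_sites", "s_sub", "n_sub",
                                        "ka", "ks", "ka_ks", "kappa_hat",
                                        "selection_class"])
    if not table.empty:
        table = table.sort_values("ka_ks", ascending=False,
                                  na_position="last").reset_index(drop=True)
    defined = table.dropna(subset=["ka_ks"]) if not table.empty else table
    scatter = defined[["pair_id", "ka", "ks"]].copy() if not defined.empty \
        else pd.DataFrame(columns=["pair_id", "ka", "ks"])
    return SelectionSummary(
        bands=bands, table=table, scatter=scatter,
        reference_lines={"ka_eq_ks_slope": 1.0, "ka_eq_half_ks_slope": 0.5},
        n_with_both_rates=len(defined), n_total=len(results))
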