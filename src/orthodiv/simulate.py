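"""Synthetic two-species transcriptome pairs with a full ground-truth channel.

The generator emulates pairs of orthologous transcripts descended from a
common ancestor: each ancestor has 5'UTR + CDS + 3'UTR structure, tunable GC
content and CpG dinucleotide enrichment, and the two descendant lineages
accumulate substitutions with CpG-elevated rates, transition bias kappa and
codon-level selection intensity omega.  Every realized substitution is logged
with its region, CpG context at draw time, transition status and synonymous
status, so downstream estimators can be tested by parameter recovery.

The substitution process is a per-site single-draw approximation rather than
a continuous-time chain: at the sub-5% divergences this emulates, multiple
hits at one site within one lineage are negligible (probability ~ d^2/4) and
a single draw keeps the truth log exact.  CpG status is evaluated against the
current sequence state at draw time, sweeping left to right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genetics import (CODON_NEIGHBORS, NUCLEOTIDES, STOP_CODONS, is_stop,
                       is_transition, translate)
from .io import (GroundTruth, SubstitutionTruth, TranscriptRecord,
                 TranscriptTruth, write_fasta, write_truth)

_NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic transcriptome pair.

    Defaults mirror the divergence regime of a closely related insect species
    pair: ~1% substitutions per non-CpG site between the lineages, strong CpG
    hypermutability, moderate transition bias and strong purifying selection
    on coding sequence.
    """
    n_transcripts: int = 100
    cds_length_range: tuple[int, int] = (300, 900)   # bp, multiples of 3 possible
    utr5_length_range: tuple[int, int] = (30, 120)
    utr3_length_range: tuple[int, int] = (60, 200)
    gc_content: float = 0.42
    cpg_enrichment: float = 0.7        # observed/expected CpG dinucleotide frequency
    branch_divergence: float = 0.01    # E[substitutions] per non-CpG site, both lineages summed
    cpg_rate_multiplier: float = 6.5   # fold rate elevation at CpG sites
    kappa: float = 3.0                 # transition/transversion rate ratio
    omega: float = 0.225               # nonsynonymous/synonymous rate ratio (CDS)
    paralog_fraction: float = 0.0      # fraction of transcripts given a within-genome duplicate
    paralog_extra_divergence: float = 0.03  # additional per-site divergence on duplicates
    seed: int = 0

    def __post_init__(self):
        for name in ("cds_length_range", "utr5_length_range", "utr3_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is inverted: {(lo, hi)}")
            if lo <= 0 and name == "cds_length_range":
                raise ValueError("cds lengths must be positive")
            if lo < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.cds_length_range
        if hi < 150:
            raise ValueError("cds_length_range must allow CDS >= 150 bp")
        if (hi // 3) * 3 < max(lo, 150):
            raise ValueError("cds_length_range contains no usable multiple of 3")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0,1)")
        if self.cpg_enrichment < 0:
            raise ValueError("cpg_enrichment must be >= 0")
        if not (0 <= self.branch_divergence <= 0.2):
            raise ValueError("branch_divergence must lie in [0, 0.2]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not (0 <= self.paralog_fraction < 1):
            raise ValueError("paralog_fraction must be in [0,1)")
        if self.cpg_rate_multiplier <= 0:
            raise ValueError("cpg_rate_multiplier must be positive")


# ---------------------------------------------------------------------------
# Ancestor generation: first-order Markov chain over nucleotides
# ---------------------------------------------------------------------------

def _transition_matrix(gc: float, cpg_enrichment: float) -> np.ndarray:
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    T = np.tile(base, (4, 1))
    crow = base.copy()
    crow[_NUC_INDEX["G"]] *= cpg_enrichment
    s = crow.sum()
    if s == 0:   # gc extremely small with enrichment 0: fall back to base sans G
        crow = base.copy()
        crow[_NUC_INDEX["G"]] = 0
        s = crow.sum()
    T[_NUC_INDEX["C"]] = crow / s
    return T


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _calibrated_chain(gc: float, cpg_enrichment: float) -> tuple[np.ndarray, np.ndarray]:
    """Markov chain whose stationary GC matches the target despite CpG skew."""
    gc_in = gc
    T = _transition_matrix(gc_in, cpg_enrichment)
    for _ in range(40):
        pi = _stationary(T)
        got = pi[_NUC_INDEX["C"]] + pi[_NUC_INDEX["G"]]
        if abs(got - gc) < 1e-6:
            break
        gc_in = min(0.999, max(1e-4, gc_in * gc / max(got, 1e-9)))
        T = _transition_matrix(gc_in, cpg_enrichment)
    return T, _stationary(T)


class _ChainSampler:
    def __init__(self, gc: float, cpg_enrichment: float, rng: np.random.Generator):
        self.T, self.pi = _calibrated_chain(gc, cpg_enrichment)
        self.rng = rng
        self._cum_T = np.cumsum(self.T, axis=1)
        self._cum_pi = np.cumsum(self.pi)

    def first(self) -> str:
        return NUCLEOTIDES[int(np.searchsorted(self._cum_pi, self.rng.random()))]

    def next(self, prev: str) -> str:
        row = self._cum_T[_NUC_INDEX[prev]]
        return NUCLEOTIDES[int(np.searchsorted(row, self.rng.random()))]

    def run(self, n: int, prev: str | None) -> list[str]:
        out = []
        for _ in range(n):
            prev = self.next(prev) if prev is not None else self.first()
            out.append(prev)
        return out


def _draw_cds(sampler: _ChainSampler, n_codons: int, prev: str | None,
              rng: np.random.Generator) -> str:
    """ATG + (n_codons-2) non-stop codons + stop, drawn through the chain."""
    parts = ["ATG"]
    prev = "G"
    for _ in range(n_codons - 2):
        for _attempt in range(200):
            codon = "".join(sampler.run(3, prev))
            if not is_stop(codon):
                break
        else:  # pragma: no cover - chain always admits non-stop codons
            codon = "AAA"
        parts.append(codon)
        prev = codon[-1]
    # Uniform stop choice; none of TAA/TAG/TGA contains a CG dinucleotide and
    # each starts with T, so CpG-free construction is preserved.
    stops = sorted(STOP_CODONS)
    parts.append(stops[int(rng.integers(len(stops)))])
    return "".join(parts)


def _length_choice(rng: np.random.Generator, lo: int, hi: int, multiple3: bool = False) -> int:
    if multiple3:
        lo3 = max((max(lo, 150) + 2) // 3, 1)
        hi3 = hi // 3
        return 3 * int(rng.integers(lo3, hi3 + 1))
    if hi == lo:
        return lo
    return int(rng.integers(lo, hi + 1))


def generate_ancestor_set(config: SimulationConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[list[TranscriptRecord], dict[str, str], GroundTruth]:
    """Ancestral transcripts with UTR5+CDS+UTR3 structure plus their proteins.

    The reference protein of each ancestor is the exact translation of its
    CDS (sans terminal stop); the truth channel records CDS coordinates and
    protein ids.  Paralogs and descendants are added by later stages.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0]) \
        if rng is None else rng
    sampler = _ChainSampler(config.gc_content, config.cpg_enrichment, rng)
    records: list[TranscriptRecord] = []
    proteins: dict[str, str] = {}
    truth = GroundTruth()
    for i in range(config.n_transcripts):
        u5 = _length_choice(rng, *config.utr5_length_range)
        u3 = _length_choice(rng, *config.utr3_length_range)
        cds_len = _length_choice(rng, *config.cds_length_range, multiple3=True)
        utr5 = "".join(sampler.run(u5, None))
        prev = utr5[-1] if utr5 else None
        cds = _draw_cds(sampler, cds_len // 3, prev, rng)
        utr3 = "".join(sampler.run(u3, cds[-1]))
        seq = utr5 + cds + utr3
        tid = f"anc{i:05d}"
        pid = f"P_{tid}"
        records.append(TranscriptRecord(tid, "ancestral", seq))
        proteins[pid] = translate(cds[:-3])
        truth.transcripts[tid] = TranscriptTruth(tid, "ancestral", None,
                                                 u5, u5 + cds_len, pid)
    return records, proteins, truth


# ---------------------------------------------------------------------------
# Divergence along two lineages
# ---------------------------------------------------------------------------

def _cpg_flag(seq: list[str], i: int) -> bool:
    if seq[i] == "C" and i + 1 < len(seq) and seq[i + 1] == "G":
        return True
    if seq[i] == "G" and i > 0 and seq[i - 1] == "C":
        return True
    return False


def _evolve_lineage(ancestor_seq: str, cds_start: int, cds_end: int,
                    config: SimulationConfig, rng: np.random.Generator,
                    pair_id: str, lineage: str, per_site_rate: float,
                    log: list[SubstitutionTruth] | None) -> str:
    """Apply the per-site substitution draw along one lineage, left to right."""
    seq = list(ancestor_seq)
    L = len(seq)
    kappa = config.kappa
    last_codon_start = cds_end - 3      # terminal stop codon: evolves neutrally
    for i in range(L):
        cur = seq[i]
        if cur not in _NUC_INDEX:
            continue
        in_cds = cds_start <= i < cds_end
        sense = in_cds and i < last_codon_start
        region = "cds" if in_cds else ("utr5" if i < cds_start else "utr3")
        cpg = _cpg_flag(seq, i)
        rate = per_site_rate * (config.cpg_rate_multiplier if cpg else 1.0)
        # Per-change weights: kappa structure, omega on nonsynonymous changes.
        alts, weights, syn_flags, valid = [], [], [], []
        if sense:
            cpos = (i - cds_start) % 3
            codon_start = i - cpos
            codon = "".join(seq[codon_start:codon_start + 3])
            changes = {(c.pos, c.alt): c for c in CODON_NEIGHBORS.get(codon, ())}
        for alt in NUCLEOTIDES:
            if alt == cur:
                continue
            w = kappa / (kappa + 2) if is_transition(cur, alt) else 1.0 / (kappa + 2)
            syn: bool | None = None
            ok = True
            if sense:
                ch = changes.get((cpos, alt))
                if ch is None:          # codon contains N; treat as neutral
                    syn = None
                else:
                    syn = ch.synonymous
                    if ch.to_stop:
                        # Stop-creating changes carry zero rate (standard
                        # codon-model convention), so descendants always
                        # survive the unexpected-stop filter.
                        ok = False
                        w = 0.0
                    elif not ch.synonymous:
                        w *= config.omega
            alts.append(alt)
            weights.append(w)
            syn_flags.append(syn)
            valid.append(ok)
        total = sum(w for w in weights)
        p_sub = min(rate * total, 0.999)
        if p_sub <= 0 or rng.random() >= p_sub:
            continue
        # Redraw stop-creating proposals: target chosen among valid changes
        # with unchanged relative weights.
        vw = [w if ok else 0.0 for w, ok in zip(weights, valid)]
        vt = sum(vw)
        if vt <= 0:
            continue
        r = rng.random() * vt
        acc = 0.0
        idx = 0
        for idx, w in enumerate(vw):
            acc += w
            if r < acc:
                break
        alt = alts[idx]
        if log is not None:
            log.append(SubstitutionTruth(pair_id, lineage, i, cur, alt, region,
                                         cpg, is_transition(cur, alt), syn_flags[idx]))
        seq[i] = alt
    return "".join(seq)


def evolve_pair(ancestor: TranscriptRecord, truth: GroundTruth,
                config: SimulationConfig, rng: np.random.Generator | None = None
                ) -> tuple[TranscriptRecord, TranscriptRecord, GroundTruth]:
    """Evolve one ancestor down two lineages; log every substitution.

    Returns descendants ``<id>_A`` / ``<id>_B`` (species tags A/B) and the
    updated truth: partner links, CDS coordinates (unchanged: substitution
    only) and the per-pair substitution list.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0]) \
        if rng is None else rng
    anc_truth = truth.transcripts[ancestor.id]
    pair_id = ancestor.id
    log: list[SubstitutionTruth] = truth.substitutions.setdefault(pair_id, [])
    per_lineage = config.branch_divergence / 2.0
    seq_a = _evolve_lineage(ancestor.sequence, anc_truth.cds_start, anc_truth.cds_end,
                            config, rng, pair_id, "A", per_lineage, log)
    seq_b = _evolve_lineage(ancestor.sequence, anc_truth.cds_start, anc_truth.cds_end,
                            config, rng, pair_id, "B", per_lineage, log)
    id_a, id_b = f"{ancestor.id}_A", f"{ancestor.id}_B"
    rec_a = TranscriptRecord(id_a, "A", seq_a)
    rec_b = TranscriptRecord(id_b, "B", seq_b)
    truth.transcripts[id_a] = TranscriptTruth(id_a, "A", id_b, anc_truth.cds_start,
                                              anc_truth.cds_end, anc_truth.protein_id)
    truth.transcripts[id_b] = TranscriptTruth(id_b, "B", id_a, anc_truth.cds_start,
                                              anc_truth.cds_end, anc_truth.protein_id)
    return rec_a, rec_b, truth


def add_paralogs(records_a: list[TranscriptRecord], ancestors: list[TranscriptRecord],
                 proteins: dict[str, str], truth: GroundTruth,
                 config: SimulationConfig, rng: np.random.Generator | None = None
                 ) -> list[TranscriptRecord]:
    """Spike within-genome duplicates into species A.

    Each duplicate descends from a chosen ancestor with extra divergence and
    carries its own reference protein (the translation of the diverged
    duplicate CDS), so a shared-unique-protein filter can reject any pair it
    contaminates.  Returns the augmented species-A record list.
    """
    if config.paralog_fraction == 0:
        return records_a
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0]) \
        if rng is None else rng
    n_dup = int(round(config.paralog_fraction * len(ancestors)))
    chosen = rng.choice(len(ancestors), size=n_dup, replace=False)
    out = list(records_a)
    for k in sorted(int(c) for c in chosen):
        anc = ancestors[k]
        anc_truth = truth.transcripts[anc.id]
        dup_id = f"{anc.id}_dupA"
        dup_seq = _evolve_lineage(anc.sequence, anc_truth.cds_start, anc_truth.cds_end,
                                  config, rng, dup_id, "A",
                                  config.paralog_extra_divergence +
                                  config.branch_divergence / 2.0, None)
        pid = f"P_{anc.id}_dup"
        cds = dup_seq[anc_truth.cds_start:anc_truth.cds_end - 3]
        proteins[pid] = translate(cds)
        out.append(TranscriptRecord(dup_id, "A", dup_seq))
        truth.transcripts[dup_id] = TranscriptTruth(dup_id, "A", None,
                                                    anc_truth.cds_start,
                                                    anc_truth.cds_end, pid,
                                                    is_paralog=True)
    return out


@dataclass
class SimulatedWorld:
    """Everything one simulation run produces."""
    records_a: list[TranscriptRecord]
    records_b: list[TranscriptRecord]
    proteins: dict[str, str]
    truth: GroundTruth
    config: SimulationConfig = field(repr=False, default=None)  # type: ignore[assignment]
    ancestors: list[TranscriptRecord] = field(default_factory=list, repr=False)


def realized_context_divergence(world: SimulatedWorld) -> dict[str, float]:
    """Realized CpG vs non-CpG divergence with truth-side context labels.

    Substitutions are classified by their CpG status at draw time (from the
    truth log) and site totals by the ancestral CpG content, so the ratio
    recovers the configured rate multiplier free of the creation/decay
    ascertainment that affects any two-sequence CpG classification (a
    substitution creating a CG cannot be told apart from one destroying it
    when only the two descendants are observed; see docs).
    """
    n_cpg_sites = n_sites = 0
    for anc in world.ancestors:
        seq = anc.sequence
        n_sites += len(seq)
        n_cpg_sites += sum(_cpg_flag(list(seq), i) for i in range(len(seq)))
    subs_cpg = subs_non = ts = tv = 0
    for pid, subs in world.truth.substitutions.items():
        for s in subs:
            if s.cpg:
                subs_cpg += 1
            else:
                subs_non += 1
            if s.transition:
                ts += 1
            else:
                tv += 1
    if min(n_cpg_sites, n_sites - n_cpg_sites) == 0:
        raise ValueError("need both CpG and non-CpG ancestral sites")
    cpg_div = subs_cpg / n_cpg_sites
    non_div = subs_non / (n_sites - n_cpg_sites)
    return {
        "cpg_divergence": cpg_div,
        "noncpg_divergence": non_div,
        "ratio": cpg_div / non_div if non_div > 0 else float("nan"),
        "ts_tv": ts / tv if tv else float("nan"),
        "n_cpg_sites": float(n_cpg_sites),
        "n_sites": float(n_sites),
    }


def simulate_transcriptomes(config: SimulationConfig) -> SimulatedWorld:
    """Full generator: ancestors -> two descendant species -> paralog spike.

    Seeding: a single master seed; each stochastic stage and each transcript
    receives a deterministically spawned child stream, so output is
    bit-reproducible for a given config.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_transcripts + 2)
    ancestors, proteins, truth = generate_ancestor_set(
        config, np.random.default_rng(children[0]))
    records_a, records_b = [], []
    for i, anc in enumerate(ancestors):
        a, b, truth = evolve_pair(anc, truth, config,
                                  np.random.default_rng(children[i + 1]))
        records_a.append(a)
        records_b.append(b)
    records_a = add_paralogs(records_a, ancestors, proteins, truth, config,
                             np.random.default_rng(children[-1]))
    return SimulatedWorld(records_a, records_b, proteins, truth, config, ancestors)


def write_fixture(world: SimulatedWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write speciesA.fasta, speciesB.fasta, proteins.fasta and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "speciesA": out / "speciesA.fasta",
        "speciesB": out / "speciesB.fasta",
        "proteins": out / "proteins.fasta",
    }
    write_fasta(world.records_a, paths["speciesA"])
    write_fasta(world.records_b, paths["speciesB"])
    write_fasta(world.proteins, paths["proteins"])
    write_truth(world.truth, out)
    paths["truth"] = out / "truth.tsv"
    return paths
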