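"""Generator contracts: structure, composition, substitution process, truth log."""

import numpy as np
import pytest

from orthodiv import (SimulationConfig, TranscriptRecord, evolve_pair,
                      generate_ancestor_set, read_fasta, read_truth,
                      simulate_transcriptomes, write_fixture)
from orthodiv.genetics import has_internal_stop, translate
from orthodiv.simulate import realized_context_divergence


def _cds(record, truth):
    t = truth.transcripts[record.id]
    return record.sequence[t.cds_start:t.cds_end]


class TestAncestors:
    def test_fixed_lengths_and_clean_translation(self):
        cfg = SimulationConfig(n_transcripts=10, cds_length_range=(300, 300),
                               utr5_length_range=(50, 50),
                               utr3_length_range=(80, 80), seed=1)
        ancestors, proteins, truth = generate_ancestor_set(cfg)
        assert len(ancestors) == 10
        for rec in ancestors:
            assert len(rec.sequence) == 430
            cds = _cds(rec, truth)
            assert cds[:3] == "ATG" and cds[-3:] in {"TAA", "TAG", "TGA"}
            assert not has_internal_stop(cds)
            # reference protein is the exact translation of the CDS
            pid = truth.transcripts[rec.id].protein_id
            assert proteins[pid] == translate(cds[:-3])

    def test_zero_cpg_enrichment_removes_all_cg(self):
        cfg = SimulationConfig(n_transcripts=10, cpg_enrichment=0.0, seed=2)
        ancestors, _, _ = generate_ancestor_set(cfg)
        assert all("CG" not in rec.sequence for rec in ancestors)

    def test_gc_content_concentrates_on_target(self):
        cfg = SimulationConfig(n_transcripts=60, gc_content=0.5,
                               cds_length_range=(900, 1200),
                               utr5_length_range=(100, 300),
                               utr3_length_range=(100, 300), seed=3)
        ancestors, _, _ = generate_ancestor_set(cfg)
        total = "".join(rec.sequence for rec in ancestors)
        assert len(total) >= 80_000
        gc = sum(b in "GC" for b in total) / len(total)
        assert 0.48 <= gc <= 0.52

    def test_cpg_frequency_monotone_in_enrichment(self):
        freqs = []
        for enrich in (0.3, 1.0, 2.0):
            cfg = SimulationConfig(n_transcripts=30, cpg_enrichment=enrich, seed=4)
            ancestors, _, _ = generate_ancestor_set(cfg)
            total = "".join(r.sequence for r in ancestors)
            freqs.append(total.count("CG") / len(total))
        assert freqs[0] < freqs[1] < freqs[2]

    def test_inverted_length_range_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            SimulationConfig(utr5_length_range=(100, 50))

    def test_unusable_cds_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(cds_length_range=(140, 149))


class TestEvolution:
    def test_zero_divergence_keeps_descendants_identical(self):
        cfg = SimulationConfig(n_transcripts=5, branch_divergence=0.0, seed=5)
        world = simulate_transcriptomes(cfg)
        for a, b, anc in zip(world.records_a, world.records_b, world.ancestors):
            assert a.sequence == anc.sequence == b.sequence
        assert all(not subs for subs in world.truth.substitutions.values())

    def test_omega_zero_forbids_nonsynonymous_changes(self):
        cfg = SimulationConfig(n_transcripts=20, omega=0.0,
                               branch_divergence=0.05, seed=6)
        world = simulate_transcriptomes(cfg)
        flags = [s.synonymous for subs in world.truth.substitutions.values()
                 for s in subs if s.region == "cds" and s.synonymous is not None]
        assert flags and all(flags)

    def test_large_kappa_makes_changes_transitions(self):
        cfg = SimulationConfig(n_transcripts=40, kappa=1000.0, omega=1.0,
                               branch_divergence=0.05, seed=7)
        world = simulate_transcriptomes(cfg)
        subs = [s for lst in world.truth.substitutions.values() for s in lst]
        assert len(subs) > 1000
        ts_frac = np.mean([s.transition for s in subs])
        assert ts_frac > 0.99

    def test_descendant_cds_never_gains_internal_stop(self, small_world):
        for rec in (*small_world.records_a, *small_world.records_b):
            t = small_world.truth.transcripts[rec.id]
            cds = rec.sequence[t.cds_start:t.cds_end]
            assert not has_internal_stop(cds)

    def test_truth_log_matches_hamming_differences(self, small_world):
        """At sites hit in exactly one lineage, descendants differ there and
        nowhere else except double-hit sites."""
        for a, b in zip(small_world.records_a[:60], small_world.records_b[:60]):
            pid = a.id.rsplit("_", 1)[0]
            subs = small_world.truth.substitutions[pid]
            by_pos = {}
            for s in subs:
                by_pos.setdefault(s.position, []).append(s)
            hamming = {i for i, (x, y) in enumerate(zip(a.sequence, b.sequence))
                       if x != y}
            single_hit = {p for p, lst in by_pos.items() if len(lst) == 1}
            assert single_hit <= hamming
            assert hamming <= set(by_pos)

    def test_cpg_rate_multiplier_recovered_from_truth(self):
        cfg = SimulationConfig(n_transcripts=60, cpg_rate_multiplier=4.0,
                               branch_divergence=0.04, seed=8)
        world = simulate_transcriptomes(cfg)
        r = realized_context_divergence(world)
        assert 3.2 <= r["ratio"] <= 4.8


class TestParalogs:
    def test_zero_fraction_is_identity(self, small_world):
        assert len(small_world.records_a) == len(small_world.records_b) == 60

    def test_forced_duplicate_count_and_truth_marking(self, paralog_world):
        dups = [t for t in paralog_world.truth.transcripts.values() if t.is_paralog]
        assert len(dups) == 6
        assert len(paralog_world.records_a) == 66
        originals = {t.protein_id for t in paralog_world.truth.transcripts.values()
                     if not t.is_paralog}
        for d in dups:
            assert d.partner_id is None
            assert d.protein_id not in originals  # points to its own protein


class TestFixtureRoundTrip:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_fasta_and_truth_round_trip(self, tmp_path, seed):
        cfg = SimulationConfig(n_transcripts=6, paralog_fraction=0.2, seed=seed)
        world = simulate_transcriptomes(cfg)
        out = tmp_path / f"fx{seed}"
        write_fixture(world, out)
        back_a = read_fasta(out / "speciesA.fasta", "A")
        assert back_a == [TranscriptRecord(r.id, "A", r.sequence)
                          for r in world.records_a]
        back_truth = read_truth(out)
        assert back_truth.transcripts == world.truth.transcripts
        assert back_truth.substitutions == world.truth.substitutions
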