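"""Ka/Ks estimators: pathway oracle equality, symmetry, YN/NG86 agreement."""

import warnings

import numpy as np
import pytest

from orthodiv import SimulationConfig, classify_selection, ng86, simulate_transcriptomes, yn
from orthodiv.genetics import SENSE_CODONS, is_stop
from orthodiv.selection import KaKsResult, count_pathways, estimate_kappa

from _oracles import pathway_counts


def _random_cds(rng, n_codons):
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    return "".join(codons)


def _mutate_cds(rng, cds, n_subs):
    """Scatter substitutions that never create a stop codon."""
    seq = list(cds)
    done = 0
    while done < n_subs:
        i = int(rng.integers(len(seq)))
        alt = "ACGT"[int(rng.integers(4))]
        if alt == seq[i]:
            continue
        old = seq[i]
        seq[i] = alt
        codon = "".join(seq[i - i % 3: i - i % 3 + 3])
        if is_stop(codon):
            seq[i] = old
            continue
        done += 1
    return "".join(seq)


class TestNg86:
    def test_identical_sequences_have_zero_rates(self):
        cds = "ATGCATGGA" * 40
        r = ng86(cds, cds)
        assert r.ka == r.ks == 0.0
        assert r.ka_ks is None          # Ks = 0: ratio undefined

    def test_single_synonymous_change_counts_one_s_sub(self):
        cds = "ATG" + "GGA" * 98 + "CAT"
        mutated = cds[:5] + "G" + cds[6:]     # GGA -> GGG, Gly, synonymous
        r = ng86(cds, mutated)
        assert r.s_sub == pytest.approx(1.0)
        assert r.n_sub == 0.0
        assert r.ks > 0 and r.ka == 0.0

    def test_site_counts_sum_to_three_per_codon(self, rng):
        cds = _random_cds(rng, 120)
        r = ng86(cds, cds)
        assert r.s_sites + r.n_sites == pytest.approx(3 * 120)

    def test_pathway_counts_match_enumeration_oracle_on_all_codon_pairs(self):
        """Exhaustive check of the per-codon-pair counting unit."""
        for c1 in SENSE_CODONS:
            for c2 in SENSE_CODONS:
                got = count_pathways(c1, c2)[:2]
                want = pathway_counts(c1, c2)
                assert got == pytest.approx(want), (c1, c2)

    def test_two_codon_inputs_match_oracle(self, rng):
        for _ in range(300):
            a = _random_cds(rng, 2)
            b = _mutate_cds(rng, a, int(rng.integers(0, 5)))
            r = ng86(a, b)
            want_s = want_n = 0.0
            for k in (0, 3):
                s, n = pathway_counts(a[k:k + 3], b[k:k + 3])
                want_s += s
                want_n += n
            assert r.s_sub == pytest.approx(want_s)
            assert r.n_sub == pytest.approx(want_n)

    def test_agrees_with_biopython_reference(self, rng):
        """Independent cross-check against Bio.codonalign's NG86 distances.

        Conventions differ on mutations toward stop codons (Biopython counts
        them as nonsynonymous sites; this package excludes them from the
        mutational opportunity), so agreement is asserted to within the few
        percent that convention difference produces.
        """
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(5):
                a = _random_cds(rng, 100)
                b = _mutate_cds(rng, a, 12)
                dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
                r = ng86(a, b)
                assert r.ka == pytest.approx(dn, rel=0.08, abs=2e-3)
                assert r.ks == pytest.approx(ds, rel=0.08, abs=2e-3)


class TestSymmetryAndAdditivity:
    def test_swapping_sequences_leaves_rates_unchanged(self, rng):
        for method in (ng86, yn):
            a = _random_cds(rng, 150)
            b = _mutate_cds(rng, a, 10)
            r1, r2 = method(a, b), method(b, a)
            assert r1.ka == pytest.approx(r2.ka)
            assert r1.ks == pytest.approx(r2.ks)

    def test_concatenation_adds_site_counts(self, rng):
        a1, a2 = _random_cds(rng, 60), _random_cds(rng, 80)
        r1, r2 = ng86(a1, a1), ng86(a2, a2)
        rc = ng86(a1 + a2, a1 + a2)
        assert rc.s_sites == pytest.approx(r1.s_sites + r2.s_sites)
        assert rc.n_sites == pytest.approx(r1.n_sites + r2.n_sites)


class TestYn:
    def test_identical_sequences_have_zero_rates(self):
        cds = "ATGCATGGATGC" * 30
        r = yn(cds, cds)
        assert r.ka == r.ks == 0.0
        assert r.ka_ks is None

    def test_matches_ng86_in_neutral_uniform_limit(self, rng):
        """kappa=1, uniform codon frequencies, divergence <= 5%."""
        for _ in range(10):
            a = _random_cds(rng, 400)
            b = _mutate_cds(rng, a, 30)       # 2.5% divergence
            r_ng = ng86(a, b)
            r_yn = yn(a, b, codon_frequencies="uniform", kappa=1.0)
            assert r_yn.converged
            assert r_yn.ka == pytest.approx(r_ng.ka, rel=0.05)
            assert r_yn.ks == pytest.approx(r_ng.ks, rel=0.05)

    def test_kappa_estimated_from_degenerate_sites(self):
        cfg = SimulationConfig(n_transcripts=20, cds_length_range=(1500, 1500),
                               utr5_length_range=(0, 0), utr3_length_range=(0, 0),
                               gc_content=0.5, cpg_enrichment=1.0,
                               cpg_rate_multiplier=1.0, branch_divergence=0.08,
                               kappa=4.0, omega=0.5, seed=31)
        world = simulate_transcriptomes(cfg)
        kappas = []
        for a, b in zip(world.records_a, world.records_b):
            t = world.truth.transcripts[a.id]
            ca = a.sequence[t.cds_start:t.cds_end - 3]
            cb = b.sequence[t.cds_start:t.cds_end - 3]
            kappas.append(estimate_kappa([ca[i:i + 3] for i in range(0, len(ca), 3)],
                                         [cb[i:i + 3] for i in range(0, len(cb), 3)]))
        assert 3.0 <= np.median(kappas) <= 5.5

    def test_omega_recovery_smoke(self):
        """Small-scale parameter recovery; the full-size check is in acceptance."""
        cfg = SimulationConfig(n_transcripts=40, cds_length_range=(1500, 1500),
                               utr5_length_range=(0, 0), utr3_length_range=(0, 0),
                               gc_content=0.5, cpg_enrichment=1.0,
                               cpg_rate_multiplier=1.0, branch_divergence=0.08,
                               kappa=2.0, omega=0.2, seed=32)
        world = simulate_transcriptomes(cfg)
        ratios = []
        for a, b in zip(world.records_a, world.records_b):
            t = world.truth.transcripts[a.id]
            r = yn(a.sequence[t.cds_start:t.cds_end - 3],
                   b.sequence[t.cds_start:t.cds_end - 3])
            if r.ka_ks is not None:
                ratios.append(r.ka_ks)
        assert 0.15 <= np.mean(ratios) <= 0.26


class TestClassifySelection:
    def _result(self, pid, ka_ks):
        ka = ka_ks * 0.01 if ka_ks is not None else None
        return KaKsResult(pid, "YN", 100, 75.0, 225.0, 1.0, 1.0,
                          ka, 0.01 if ka_ks is not None else None, ka_ks, 2.0)

    def test_three_way_banding(self):
        summary = classify_selection([self._result("a", 2.0),
                                      self._result("b", 0.7),
                                      self._result("c", 0.1)])
        assert [len(summary.bands[k]) for k in
                ("positive", "relaxed", "constrained")] == [1, 1, 1]
        assert summary.table["ka_ks"].tolist() == [2.0, 0.7, 0.1]  # sorted desc

    def test_boundaries_fall_in_middle_band(self):
        summary = classify_selection([self._result("a", 1.0),
                                      self._result("b", 0.5)])
        assert summary.bands["relaxed"] == ["a", "b"]
        assert summary.bands["positive"] == []

    def test_empty_input(self):
        summary = classify_selection([])
        assert all(not v for v in summary.bands.values())
        assert summary.n_total == 0

    def test_undefined_ratio_excluded_from_bands_and_scatter(self):
        summary = classify_selection([self._result("a", None),
                                      self._result("b", 0.3)])
        assert summary.n_with_both_rates == 1
        assert summary.scatter["pair_id"].tolist() == ["b"]

    def test_high_omega_genes_detected(self):
        """10 genes at omega=3 vs 90 at omega=0.1: most positives recovered."""
        high = SimulationConfig(n_transcripts=10, cds_length_range=(1500, 1500),
                                utr5_length_range=(0, 0), utr3_length_range=(0, 0),
                                gc_content=0.5, cpg_enrichment=1.0,
                                cpg_rate_multiplier=1.0, branch_divergence=0.04,
                                kappa=2.0, omega=3.0, seed=33)
        low = SimulationConfig(n_transcripts=90, cds_length_range=(1500, 1500),
                               utr5_length_range=(0, 0), utr3_length_range=(0, 0),
                               gc_content=0.5, cpg_enrichment=1.0,
                               cpg_rate_multiplier=1.0, branch_divergence=0.04,
                               kappa=2.0, omega=0.1, seed=34)
        results = []
        truth_high = set()
        for cfg, tag in ((high, "hi"), (low, "lo")):
            world = simulate_transcriptomes(cfg)
            for a, b in zip(world.records_a, world.records_b):
                t = world.truth.transcripts[a.id]
                pid = f"{tag}_{a.id}"
                if tag == "hi":
                    truth_high.add(pid)
                results.append(yn(a.sequence[t.cds_start:t.cds_end - 3],
                                  b.sequence[t.cds_start:t.cds_end - 3],
                                  pair_id=pid))
        summary = classify_selection(results)
        positives = set(summary.bands["positive"])
        assert len(positives & truth_high) >= 7
        false_pos = positives - truth_high
        assert len(false_pos) <= 5
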