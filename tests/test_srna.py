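"""Small-RNA processing: trimming, collapse, matching, exclusion,
normalization identities and locus summaries."""

import numpy as np
import pytest

from crpmeth import simulate as sim
from crpmeth import srna as sr
from crpmeth.reference import InputError, reverse_complement

ADAPTER = "TCGTATGCCGTCTTCTGCTTGT"  # DNA form of the 3' ligation adapter


def random_seq(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))


class TestTrimAdapter:
    def test_full_adapter_occurrence(self):
        assert sr.trim_adapter("ACGTACGT" + ADAPTER, ADAPTER) == "ACGTACGT"

    def test_read_equal_to_adapter_gives_empty_insert(self):
        assert sr.trim_adapter(ADAPTER, ADAPTER) == ""

    def test_partial_terminal_overlap(self):
        read = "ACGTACGTACGTACGTACGTACGT" + ADAPTER[:6]
        assert sr.trim_adapter(read, ADAPTER, min_overlap=5) == read[:-6]
        # below the overlap floor the occurrence does not count
        read4 = "ACGTACGTACGTACGTACGTACGT" + ADAPTER[:4]
        assert sr.trim_adapter(read4, ADAPTER, min_overlap=5) is None

    def test_mismatch_budget(self):
        insert = "ACGTACGTACGTACGTAACC"
        damaged = "X".join([ADAPTER[:10], ADAPTER[11:]])  # one substitution
        assert sr.trim_adapter(insert + damaged, ADAPTER, max_mismatch=0) is None
        assert sr.trim_adapter(insert + damaged, ADAPTER, max_mismatch=1) == insert

    def test_empty_adapter_rejected(self):
        with pytest.raises(InputError):
            sr.trim_adapter("ACGT", "")

    def test_trimming_is_idempotent_on_simulated_library(self):
        rng = np.random.default_rng(50)
        for _ in range(300):
            insert = random_seq(rng, int(rng.integers(18, 30)))
            read = insert + ADAPTER + random_seq(rng, 5)
            once = sr.trim_adapter(read, ADAPTER)
            assert once is not None
            again = sr.trim_adapter(once, ADAPTER)
            assert again is None or again == once

    def test_library_accounting_reconciles(self):
        rng = np.random.default_rng(51)
        reads = [random_seq(rng, 24) + ADAPTER for _ in range(40)]
        reads += [random_seq(rng, 10) + ADAPTER for _ in range(7)]  # too short
        reads += [random_seq(rng, 40) for _ in range(5)]  # no adapter
        inserts, acct = sr.trim_library(reads, ADAPTER)
        assert acct["input"] == 52
        assert acct["kept"] + acct["no_adapter"] + acct["too_short"] == acct["input"]
        assert len(inserts) == acct["kept"] == 40


class TestCollapse:
    def test_abundances_summed_lexicographic(self):
        sigs = sr.collapse_signatures(["AAA", "AAA", "CCC"])
        assert [(s.sequence, s.raw_abundance) for s in sigs] == [("AAA", 2), ("CCC", 1)]

    def test_empty_input_empty_output(self):
        assert sr.collapse_signatures([]) == []

    def test_precounted_pairs_and_conservation(self):
        rng = np.random.default_rng(52)
        reads = [random_seq(rng, 21) for _ in range(500)]
        sigs = sr.collapse_signatures(reads)
        assert sum(s.raw_abundance for s in sigs) == 500
        paired = sr.collapse_signatures([(r, 2) for r in reads])
        assert sum(s.raw_abundance for s in paired) == 1000

    def test_collapse_commutes_with_trimming(self):
        """Collapsing before vs after trimming yields identical tables."""
        rng = np.random.default_rng(53)
        inserts = [random_seq(rng, 24) for _ in range(50)] * 3
        reads = [i + ADAPTER for i in inserts]
        trimmed_then_collapsed = sr.collapse_signatures(
            sr.trim_library(reads, ADAPTER)[0])
        collapsed_reads = sr.collapse_signatures(reads)
        collapsed_then_trimmed = sr.collapse_signatures(
            (sr.trim_adapter(s.sequence, ADAPTER), s.raw_abundance)
            for s in collapsed_reads)
        assert trimmed_then_collapsed == collapsed_then_trimmed


class TestMatchReference:
    def test_single_plus_strand_hit_is_unique(self):
        sig = sr.collapse_signatures(["ACGTTTGACGTAACGTAGGCATCA"])
        refs = {"g": "CCC" + sig[0].sequence + "GGG"}
        (m,) = sr.match_reference(sig, refs)
        assert m.hits == 1 and m.klass == "unique"
        assert m.positions == (("g", 4, "+"),)

    def test_tandem_duplication_is_duplicated(self):
        seq = "ACGTTTGACGTAACGTAGGCATCA"
        refs = {"g": seq + "TTTT" + seq}
        (m,) = sr.match_reference(sr.collapse_signatures([seq]), refs)
        assert m.hits == 2 and m.klass == "duplicated"

    def test_minus_strand_hit_found(self):
        seq = "ACGTTTGACGTAACGTAGGCATCA"
        refs = {"g": "AA" + reverse_complement(seq) + "AA"}
        (m,) = sr.match_reference(sr.collapse_signatures([seq]), refs)
        assert m.hits == 1 and m.positions[0][2] == "-"

    def test_hits_cap_discards_hyperrepetitive(self):
        seq = "ACGTACGTACGTACGTACGTACGT"
        refs = {"g": seq * 5}
        out = sr.match_reference(sr.collapse_signatures([seq]), refs, max_hits_cap=3)
        assert out == []

    def test_positions_match_naive_substring_scan(self):
        rng = np.random.default_rng(54)
        refs = {f"r{i}": random_seq(rng, 300) for i in range(4)}
        # signatures: some sampled from references, some random
        sigs = []
        for i in range(30):
            if i % 2 == 0:
                ref = refs[f"r{i % 4}"]
                start = int(rng.integers(0, len(ref) - 24))
                sigs.append(ref[start : start + 24])
            else:
                sigs.append(random_seq(rng, 24))
        matched = sr.match_reference(sr.collapse_signatures(sigs), refs)
        for m in matched:
            expected = []
            for name, ref in refs.items():
                for j in range(len(ref) - m.length + 1):
                    if ref[j : j + m.length] == m.sequence:
                        expected.append((name, j + 1, "+"))
                    if ref[j : j + m.length] == reverse_complement(m.sequence):
                        expected.append((name, j + 1, "-"))
            assert sorted(m.positions) == sorted(expected)


class TestExcludeStructural:
    def test_structural_match_removed(self):
        seqs = ["ACGTTTGACGTAACGTAGGCATCA", "TTTTGGGGCCCCAAAATTTTGGGA"]
        sigs = sr.match_reference(sr.collapse_signatures(seqs),
                                  {"g": seqs[0] + "AT" + seqs[1]})
        retained, acct = sr.exclude_structural(sigs, {"rRNA": "GG" + seqs[1] + "CC"})
        assert [s.sequence for s in retained] == [seqs[0]]
        assert acct.structural_excluded == 1 and acct.genome_matched == 1

    def test_empty_exclusion_set_is_identity(self):
        sigs = sr.collapse_signatures(["AAAA", "CCCC"])
        retained, acct = sr.exclude_structural(sigs, {})
        assert retained == sigs

    def test_accounting_conserves_reads(self):
        rng = np.random.default_rng(55)
        genome = {"g": random_seq(rng, 500)}
        structural = {"t": random_seq(rng, 100)}
        reads = []
        for _ in range(50):
            src = rng.choice(["g", "t", "junk"])
            if src == "junk":
                reads.append(random_seq(rng, 24))
            else:
                ref = genome["g"] if src == "g" else structural["t"]
                start = int(rng.integers(0, len(ref) - 24))
                reads.append(ref[start : start + 24])
        sigs = sr.match_reference(sr.collapse_signatures(reads), genome)
        retained, acct = sr.exclude_structural(sigs, structural)
        assert (acct.structural_excluded + acct.genome_matched + acct.unmatched
                == acct.total_reads == 50)


class TestNormalization:
    def test_single_signature_full_scale(self):
        sigs = sr.match_reference(
            sr.collapse_signatures([("ACGTTTGACGTAACGTAGGCATCA", 7)]),
            {"g": "ACGTTTGACGTAACGTAGGCATCA"})
        (s,) = sr.normalize(sigs)
        assert s.tpm == pytest.approx(1e6)

    def test_proportional_split(self):
        a, b = "ACGTTTGACGTAACGTAGGCATCA", "TTTTGGGGCCCCAAAATTTTGGGA"
        sigs = sr.match_reference(
            sr.collapse_signatures([(a, 3), (b, 1)]), {"g": a + "AT" + b})
        out = {s.sequence: s.tpm for s in sr.normalize(sigs)}
        assert out[a] == pytest.approx(750_000)
        assert out[b] == pytest.approx(250_000)

    def test_tpm_sums_to_scale(self):
        rng = np.random.default_rng(56)
        ref = random_seq(rng, 1000)
        reads = [(ref[i : i + 24], int(rng.integers(1, 50)))
                 for i in rng.integers(0, 976, size=60)]
        sigs = sr.match_reference(sr.collapse_signatures(reads), {"g": ref})
        normalized = sr.normalize(sigs)
        assert sum(s.tpm for s in normalized) == pytest.approx(1e6)

    def test_zero_denominator_raises(self):
        sigs = sr.collapse_signatures(["AAAA"])  # unmatched, hits 0
        with pytest.raises(InputError):
            sr.normalize(sigs, denominator="matched")

    def test_hna_identities(self):
        """tpm 10 / hits 2 -> 5 per position; hits 1 -> hna = tpm;
        sum of positional HNA = sum of matched TPM."""
        rng = np.random.default_rng(57)
        ref = random_seq(rng, 400)
        dup = ref[50:74]
        refs = {"g": ref + "TTTT" + dup}  # duplicates one 24-mer
        reads = [(dup, 10), (ref[100:124], 7), (ref[200:224], 3)]
        sigs = sr.normalize(sr.match_reference(sr.collapse_signatures(reads), refs))
        matched = sr.hits_normalize(sigs)
        by_seq = {s.sequence: s for s in matched}
        assert by_seq[dup].hits == 2
        assert by_seq[dup].hna_per_hit == pytest.approx(by_seq[dup].tpm / 2)
        single = by_seq[ref[100:124]]
        assert single.hna_per_hit == pytest.approx(single.tpm)
        positional = sum(s.hna_per_hit * s.hits for s in matched)
        assert positional == pytest.approx(sum(s.tpm for s in matched))


class TestLocusSummary:
    def test_all_unique_inside_locus(self):
        rng = np.random.default_rng(58)
        ref = random_seq(rng, 300)
        reads = [(ref[i : i + 24], 5) for i in (10, 60, 110)]
        sigs = sr.normalize(sr.match_reference(
            sr.collapse_signatures(reads), {"g": ref}))
        summary = sr.summarize_locus("g", (1, 300), sr.hits_normalize(sigs))
        assert summary.hna_sum == pytest.approx(1e6)
        assert summary.abundance_24nt == pytest.approx(1e6)
        assert summary.unique_24nt_count == 3

    def test_no_positions_in_locus_zero_summary(self):
        rng = np.random.default_rng(59)
        ref = random_seq(rng, 300)
        sigs = sr.normalize(sr.match_reference(
            sr.collapse_signatures([(ref[10:34], 5)]), {"g": ref}))
        summary = sr.summarize_locus("g", (200, 300), sr.hits_normalize(sigs))
        assert (summary.hna_sum, summary.abundance_24nt,
                summary.unique_24nt_count) == (0.0, 0.0, 0)

    def test_track_totals_match_locus_aggregates(self):
        rng = np.random.default_rng(60)
        ref = random_seq(rng, 500)
        reads = [(ref[i : i + ln], int(rng.integers(1, 9)))
                 for i, ln in zip(rng.integers(0, 450, size=25),
                                  rng.choice([21, 22, 23, 24], size=25))]
        sigs = sr.normalize(sr.match_reference(
            sr.collapse_signatures(reads), {"g": ref}))
        matched = sr.hits_normalize(sigs)
        track = sr.length_profile(matched, "g")
        summary = sr.summarize_locus("g", (1, 500), matched)
        assert track["hna_per_hit"].sum() == pytest.approx(summary.hna_sum)

    def test_mutant_expression_ratio_recovered_end_to_end(self):
        """Pol IV-mutant factor 0.1 on one locus: mutant/wt hna_sum ratio
        ~ 0.1 within multinomial 3 sigma."""
        loci = [sim.make_locus(60, 150, 60, context_density_profile={},
                               seed=s, locus_id=f"L{s}") for s in (61, 62)]
        refs = {l.id: l.sequence for l in loci}
        intervals = {l.id: (1, len(l)) for l in loci}

        def run(factors, seed):
            lib = sim.simulate_srna_library(
                loci, {"L61": 1.0, "L62": 1.0}, {24: 1.0},
                total_reads=10_000, genotype_effect_factors=factors, seed=seed)
            sigs = sr.normalize(sr.match_reference(
                sr.collapse_signatures(lib), refs), denominator="matched")
            matched = sr.hits_normalize(sigs)
            return {lid: sr.summarize_locus(lid, intervals[lid], matched).hna_sum
                    for lid in refs}

        wt = run(None, 63)
        mut = run({"L61": 0.1}, 64)
        # within each library HNA sums to 1e6; compare L61's share
        share_wt = wt["L61"] / (wt["L61"] + wt["L62"])
        share_mut = mut["L61"] / (mut["L61"] + mut["L62"])
        expected_share = 0.1 / 1.1
        sigma = np.sqrt(expected_share * (1 - expected_share) / 10_000)
        assert abs(share_mut - expected_share) < 4 * sigma
        assert abs(share_wt - 0.5) < 4 * np.sqrt(0.25 / 10_000)

    def test_locus_ranking_tracks_true_expression(self):
        """Per-locus HNA rank order equals the simulated expression order."""
        from scipy.stats import spearmanr

        loci = [sim.make_locus(50, 120, 50, context_density_profile={},
                               seed=70 + i, locus_id=f"E{i}") for i in range(4)]
        expression = {"E0": 8.0, "E1": 4.0, "E2": 2.0, "E3": 1.0}
        lib = sim.simulate_srna_library(
            loci, expression, {23: 0.3, 24: 0.7}, total_reads=10_000, seed=71)
        refs = {l.id: l.sequence for l in loci}
        sigs = sr.normalize(sr.match_reference(
            sr.collapse_signatures(lib), refs))
        matched = sr.hits_normalize(sigs)
        hna = [sr.summarize_locus(l.id, (1, len(l)), matched).hna_sum
               for l in loci]
        rho = spearmanr(hna, [expression[l.id] for l in loci]).statistic
        assert rho >= 0.95
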