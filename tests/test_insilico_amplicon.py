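import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mockbias.insilico_amplicon import (
    AmpliconNotFoundError,
    FeatureRecord,
    PrimerPair,
    count_16s_features,
    find_amplicon,
    gc_percent,
    iupac_mismatches,
    load_primer_table,
    modal_amplicon_length,
    read_fasta,
    read_gff_features,
    region_primer_pairs,
    reverse_complement,
    write_fasta,
)

# independent IUPAC table for oracle checks (typed afresh, not imported)
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def oracle_mismatches(pattern, window):
    return sum(w not in ORACLE_IUPAC[p] for p, w in zip(pattern, window))


def oracle_find(template, fwd, rev, max_mm):
    """Exhaustive enumeration over all (forward, reverse) window pairs."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C", "W": "W", "S": "S",
            "M": "K", "K": "M", "R": "Y", "Y": "R", "N": "N", "B": "V",
            "V": "B", "D": "H", "H": "D"}
    rc = "".join(comp[b] for b in reversed(rev))
    f_scores = [
        (oracle_mismatches(fwd, template[i:i + len(fwd)]), i)
        for i in range(len(template) - len(fwd) + 1)
    ]
    best_mm = min(s for s, _ in f_scores)
    if best_mm > max_mm:
        return None
    f_pos = min(i for s, i in f_scores if s == best_mm)
    start = f_pos + len(fwd)
    for j in range(start, len(template) - len(rc) + 1):
        if oracle_mismatches(rc, template[j:j + len(rc)]) <= max_mm:
            return (start, j)
    return None


class TestIupacMismatches:
    def test_w_matches_a(self):
        assert iupac_mismatches("W", "A") == 0

    def test_exact(self):
        assert iupac_mismatches("AGCW", "AGCT") == 0

    def test_single_mismatch(self):
        assert iupac_mismatches("AGCW", "AGGT") == 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            iupac_mismatches("AG", "AGT")

    def test_invalid_symbols(self):
        with pytest.raises(ValueError):
            iupac_mismatches("AXC", "AGC")
        with pytest.raises(ValueError):
            iupac_mismatches("AGC", "ANC")

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_oracle(self, pattern):
        rng = random.Random(hash(pattern) & 0xFFFF)
        window = "".join(rng.choice("ACGT") for _ in pattern)
        assert iupac_mismatches(pattern, window) == oracle_mismatches(pattern, window)


class TestReverseComplement:
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_degenerate_pairs(self):
        assert reverse_complement("W") == "W"
        assert reverse_complement("M") == "K"
        assert reverse_complement("K") == "M"
        assert reverse_complement("ACGT") == "ACGT"

    def test_invalid(self):
        with pytest.raises(ValueError):
            reverse_complement("AXC")


class TestFindAmplicon:
    FWD = "GACTCCTACGGGAGGCWGCAG"
    REV = "CGTATTACCGCGGCTGCTGG"

    def pair(self, mm=0):
        return PrimerPair("V3", self.FWD, self.REV, max_mismatches=mm)

    def test_constructed_template(self):
        insert = "ACGTACGTAC"
        template = self.FWD.replace("W", "A") + insert + reverse_complement(self.REV)
        res = find_amplicon(template, self.pair())
        assert res.trimmed_length == 10
        assert res.gc_percent == pytest.approx(50.0)  # 5 G/C in 10
        assert res.insert_start == len(self.FWD)

    def test_missing_reverse_site(self):
        template = self.FWD.replace("W", "A") + "ACGT" * 30
        with pytest.raises(AmpliconNotFoundError, match="reverse"):
            find_amplicon(template, self.pair())

    def test_template_too_short(self):
        with pytest.raises(ValueError):
            find_amplicon("ACGT", self.pair())

    def test_one_mismatch_tolerated(self):
        fwd_site = self.FWD.replace("W", "A")
        fwd_site = "T" + fwd_site[1:]  # known 5'-end mismatch
        template = fwd_site + "ACGTACGTAC" + reverse_complement(self.REV)
        with pytest.raises(AmpliconNotFoundError):
            find_amplicon(template, self.pair(mm=0))
        assert find_amplicon(template, self.pair(mm=1)).trimmed_length == 10

    def test_brute_force_oracle_random_templates(self):
        rng = random.Random(7)
        pairs = region_primer_pairs(max_mismatches=1)
        n_found = 0
        for trial in range(40):
            region = rng.choice(list(pairs))
            pair = pairs[region]
            insert = "".join(rng.choice("ACGT") for _ in range(rng.randint(30, 400)))
            pad5 = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 60)))
            pad3 = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, 60)))
            fwd_site = "".join(
                rng.choice(sorted(ORACLE_IUPAC[b])) for b in pair.forward
            )
            rev_site = reverse_complement(pair.reverse).replace("Y", "C").replace("W", "A").replace("M", "A").replace("K", "G").replace("R", "A")
            template = pad5 + fwd_site + insert + rev_site + pad3
            expected = oracle_find(template, pair.forward, pair.reverse, 1)
            assert expected is not None
            res = find_amplicon(template, pair)
            assert (res.insert_start, res.insert_end) == expected
            n_found += 1
        assert n_found == 40

    def test_oracle_agreement_on_unstructured_random(self):
        # templates with no planted sites: both routes must agree on failure
        rng = random.Random(11)
        pair = self.pair(mm=1)
        for _ in range(20):
            template = "".join(rng.choice("ACGT") for _ in range(500))
            expected = oracle_find(template, pair.forward, pair.reverse, 1)
            if expected is None:
                with pytest.raises(AmpliconNotFoundError):
                    find_amplicon(template, pair)
            else:
                res = find_amplicon(template, pair)
                assert (res.insert_start, res.insert_end) == expected

    def test_v1v3_longer_than_v3(self):
        # same synthetic template containing 27F ... 337F ... 518R sites
        rng = random.Random(3)
        pairs = region_primer_pairs(max_mismatches=0)
        seg1 = "".join(rng.choice("ACGT") for _ in range(150))
        seg2 = "".join(rng.choice("ACGT") for _ in range(160))
        fwd27 = pairs["V1-V3"].forward.replace("M", "A")
        fwd337 = pairs["V3"].forward.replace("W", "A")
        rev518 = reverse_complement(pairs["V3"].reverse)
        template = "AC" + fwd27 + seg1 + fwd337 + seg2 + rev518 + "GT"
        v3 = find_amplicon(template, pairs["V3"])
        v13 = find_amplicon(template, pairs["V1-V3"])
        assert v13.trimmed_length > v3.trimmed_length

    def test_modal_length(self):
        template = self.FWD.replace("W", "A") + "ACGTACGTAC" + reverse_complement(self.REV)
        longer = self.FWD.replace("W", "A") + "ACGTACGTACGT" + reverse_complement(self.REV)
        assert modal_amplicon_length([template, template, longer], self.pair()) == 10
        with pytest.raises(AmpliconNotFoundError):
            modal_amplicon_length(["ACGT" * 30], self.pair())


class TestGcPercent:
    def test_all_gc(self):
        assert gc_percent("GGCC") == 100.0

    def test_no_gc(self):
        assert gc_percent("ATAT") == 0.0

    def test_s_counts_as_gc(self):
        assert gc_percent("ASAT") == pytest.approx(25.0)

    def test_other_ambiguity_excluded(self):
        assert gc_percent("GNNC") == 100.0

    def test_empty(self):
        with pytest.raises(ValueError):
            gc_percent("")


class TestFeatures:
    def make(self, type_, product):
        return FeatureRecord("chr", type_, 0, 10, "+", product)

    def test_empty(self):
        assert count_16s_features([]) == 0

    def test_mixed_rrna_types(self):
        feats = [
            self.make("rRNA", "23S ribosomal RNA"),
            self.make("rRNA", "16S ribosomal RNA"),
            self.make("gene", "16S ribosomal RNA"),  # gene row, not rRNA
        ]
        assert count_16s_features(feats) == 1

    def test_case_insensitive(self):
        assert count_16s_features([self.make("rRNA", "16s RIBOSOMAL rna")]) == 1

    def test_gff_roundtrip(self, tmp_path):
        gff = tmp_path / "x.gff"
        gff.write_text(
            "##gff-version 3\n"
            "c1\tsrc\trRNA\t11\t20\t.\t-\t.\tID=r1;product=16S ribosomal RNA\n"
            "c1\tsrc\tCDS\t30\t50\t.\t+\t.\tID=c1;product=thing\n"
        )
        feats = read_gff_features(gff)
        assert len(feats) == 2
        assert feats[0].start == 10 and feats[0].end == 20
        assert feats[0].strand == "-"
        assert count_16s_features(feats) == 1


class TestFastaIO:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "x.fa"
        write_fasta([("a", "ACGT" * 30), ("b", "GGCC")], path)
        recs = read_fasta(path)
        assert recs == [("a", "ACGT" * 30), ("b", "GGCC")]


class TestPrimerTable:
    def test_published_sequences(self):
        table = {(r["platform"], r["name"]): r["sequence"] for r in load_primer_table()}
        assert table[("QX200", "337F")] == "GACTCCTACGGGAGGCWGCAG"
        assert table[("IonTorrent", "bif27F")] == "GGGTTCGATTCTGGCTCAG"
        assert table[("SequelII/MinION", "1492R")] == "TACGGYTACCTTGTTACGACTT"

    def test_region_pairs(self):
        pairs = region_primer_pairs()
        assert set(pairs) == {"V1-V2", "V3", "V4", "V1-V3", "V1-V9"}
        assert pairs["V3"].forward == "GACTCCTACGGGAGGCWGCAG"
        assert pairs["V3"].reverse == "CGTATTACCGCGGCTGCTGG"
        bif = region_primer_pairs(bifido=True)
        assert bif["V1-V2"].forward == "GGGTTCGATTCTGGCTCAG"
        assert bif["V3"].forward == pairs["V3"].forward  # 337F unchanged
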