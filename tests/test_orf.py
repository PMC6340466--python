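import pytest

from opsinphylo import io, orf, simulate
from opsinphylo.io import CodonAlignment, SequenceRecord

# A 60-nt toy ORF (20 codons) with no internal stops.
REF = "ATGGCTGTTCTGACTGGTATCGCTAAAGATGAACCTCAGTCTGTTAGGTGGTATCACTAA"


def _aln(rows):
    return CodonAlignment([SequenceRecord(k, v) for k, v in rows.items()])


class TestScanOrf:
    def test_identical_to_reference_is_functional(self):
        calls = orf.scan_orf(_aln({"ref": REF, "x": REF}), "ref")
        x = next(c for c in calls if c.taxon == "x")
        assert x.status == "functional" and x.lesions == []

    def test_one_nt_deletion_frameshifts_and_finds_downstream_stop(self):
        # delete nt 10 (codon 4); downstream out-of-frame stops appear
        mutant = REF[:9] + "-" + REF[10:]
        calls = orf.scan_orf(_aln({"ref": REF, "x": mutant}), "ref")
        x = next(c for c in calls if c.taxon == "x")
        assert x.status == "pseudogene"
        dels = [l for l in x.lesions if l.kind == "deletion"]
        assert len(dels) == 1
        assert dels[0].codon_column == 4
        assert dels[0].length_nt == 1 and dels[0].causes_frameshift
        # the shifted frame must be scanned for stops: verify vs manual
        shifted_aa = io.translate(mutant.replace("-", ""))
        expect_stops = shifted_aa[:-1].count("*")
        stops = [l for l in x.lesions if l.kind == "premature_stop"]
        assert len(stops) == expect_stops and len(stops) >= 1

    def test_in_frame_deletion_stays_functional(self):
        mutant = REF[:9] + "---" + REF[12:]
        calls = orf.scan_orf(_aln({"ref": REF, "x": mutant}), "ref")
        x = next(c for c in calls if c.taxon == "x")
        assert x.status == "functional"
        (les,) = x.lesions
        assert les.kind == "deletion" and not les.causes_frameshift

    def test_terminal_stop_is_never_a_lesion(self):
        calls = orf.scan_orf(_aln({"ref": REF}), "ref")
        assert calls[0].lesions == []

    def test_three_prime_stop_within_leniency_window_reported_not_flipping(self):
        # stop at codon 19 of 20 (final 10% of the ORF)
        mutant = REF[:54] + "TAA" + REF[57:]
        calls = orf.scan_orf(_aln({"ref": REF, "x": mutant}), "ref")
        x = next(c for c in calls if c.taxon == "x")
        stops = [l for l in x.lesions if l.kind == "premature_stop"]
        assert len(stops) == 1 and "leniency" in stops[0].note
        assert x.status == "functional"
        strict = orf.scan_orf(
            _aln({"ref": REF, "x": mutant}), "ref", lenient_stop_flips_status=True
        )
        assert next(c for c in strict if c.taxon == "x").status == "pseudogene"

    def test_disrupted_reference_rejected(self):
        mutant = REF[:12] + "TGA" + REF[15:]
        with pytest.raises(ValueError, match="reference"):
            orf.scan_orf(_aln({"bad": mutant, "ok": REF}), "bad")

    def test_gap_accounting_conservation(self):
        mutant = REF[:9] + "--" + REF[11:57] + "---"
        aln = _aln({"ref": REF, "x": mutant})
        calls = orf.scan_orf(aln, "ref")
        x = next(c for c in calls if c.taxon == "x")
        net = sum(
            l.length_nt if l.kind == "insertion" else -l.length_nt
            for l in x.lesions
            if l.kind in {"insertion", "deletion"}
        )
        ref_len = len(REF)
        x_len = len(mutant) - mutant.count("-")
        assert net == x_len - ref_len

    def test_functional_call_implies_stop_free_frame(self, preset_tree):
        spec = simulate.SimulationSpec(tree=preset_tree, omega=0.2, n_codons=60, seed=5)
        aln, _ = simulate.simulate_codon_alignment(spec)
        for call in orf.scan_orf(aln):
            if call.status == "functional":
                aa = io.translate(aln.row(call.taxon).replace("-", ""))
                assert "*" not in aa[:-1]

    def test_recovers_injected_lesions_exactly(self, preset_tree):
        t = preset_tree.copy()
        for n in t.preorder():
            n.length *= 0.004
        t.units = "subs"
        spec = simulate.SimulationSpec(tree=t, omega=0.15, n_codons=100, seed=5)
        aln, _ = simulate.simulate_codon_alignment(spec)
        lesions = [
            simulate.LesionSpec("cave1", "deletion", 10, 1),
            simulate.LesionSpec("cave2", "deletion", 20, 3),
            simulate.LesionSpec("hdc1", "stop_substitution", 30),
            simulate.LesionSpec("cave3", "insertion", 40, 2, bases="CT"),
        ]
        mutated, truth = simulate.inject_lesions(aln, lesions)
        calls = {c.taxon: c for c in orf.scan_orf(mutated, "tree1")}
        kind_map = {"stop_substitution": "premature_stop"}
        for row in truth:
            want_kind = kind_map.get(row["kind"], row["kind"])
            hits = [
                l
                for l in calls[row["taxon"]].lesions
                if l.kind == want_kind
                and l.codon_column == row["codon_column"]
                and l.length_nt == row["length_nt"]
            ]
            assert hits, (row, calls[row["taxon"]].lesions)


class TestSpliceSites:
    GENOMIC = "ATGAAA" + "GTAAGTTTTCAG" + "GGGTTT" + "GCAAGTTTTCAG" + "TAA"

    def test_canonical_introns_pass(self):
        # exon1 1-6, intron GT..AG, exon2 19-24, intron GC..AG (violation), exon3
        violations = orf.check_splice_sites(self.GENOMIC, [(1, 6), (19, 24), (37, 39)])
        assert len(violations) == 1
        v = violations[0]
        assert v["intron_index"] == 2 and v["donor"] == "GC" and v["acceptor"] == "AG"

    def test_single_exon_no_introns(self):
        assert orf.check_splice_sites("ATGTAA", [(1, 6)]) == []

    def test_interval_outside_sequence(self):
        with pytest.raises(ValueError):
            orf.check_splice_sites("ATG", [(1, 10)])


class TestPlaceLesions:
    def _calls(self, carriers, lesion=("deletion", 5, 1)):
        kind, col, ln = lesion
        return [
            orf.FunctionalityCall(
                taxon=t,
                status="pseudogene",
                lesions=[
                    orf.Lesion(t, kind, col, ln, causes_frameshift=ln % 3 != 0)
                ],
            )
            for t in carriers
        ]

    def test_single_carrier_origin_is_terminal_branch(self, six_taxon_tree):
        (origin,) = orf.place_lesions(self._calls(["A"]), six_taxon_tree)
        assert origin.origin_branch == "A" and not origin.homoplastic

    def test_clean_clade_origin_is_stem(self, six_taxon_tree):
        (origin,) = orf.place_lesions(self._calls(["A", "B"]), six_taxon_tree)
        # brute force: the only branch whose descendant tips are exactly {A,B}
        expected = [
            n.name
            for n in six_taxon_tree.nodes
            if {t.name for t in six_taxon_tree.tips_below(n)} == {"A", "B"}
        ]
        assert [origin.origin_branch] == expected

    def test_paraphyletic_carriers_flagged_homoplastic(self, six_taxon_tree):
        origins = orf.place_lesions(self._calls(["A", "C"]), six_taxon_tree)
        assert all(o.homoplastic for o in origins)
        assert sorted(o.origin_branch for o in origins) == ["A", "C"]
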