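import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opsinphylo import io, selection, simulate
from opsinphylo.io import (
    CODON_INDEX,
    SENSE_CODONS,
    STANDARD_CODE,
    CodonAlignment,
    SequenceRecord,
)


class TestStripIndelCodons:
    def _aln(self, rows):
        return CodonAlignment([SequenceRecord(k, v) for k, v in rows.items()])

    def test_gap_free_alignment_unchanged(self):
        aln = self._aln({"a": "ATGAAA", "b": "ATGCCC"})
        out, log = selection.strip_indel_codons(aln)
        assert out.n_codon_columns == 2 and log == []

    def test_single_gapped_column_removed(self):
        aln = self._aln({"a": "ATG---CCC", "b": "ATGAAACCC"})
        out, log = selection.strip_indel_codons(aln)
        assert out.n_codon_columns == 2
        assert log == [(2, "gap")]

    def test_hand_counted_ten_codon_example(self):
        # gaps in codon columns 2 and 7 -> 8 columns remain
        a = "ATG" + "---" + "AAA" * 4 + "A--" + "CCC" * 3
        b = "ATG" + "GGG" + "AAA" * 4 + "AGG" + "CCC" * 3
        out, log = selection.strip_indel_codons(self._aln({"a": a, "b": b}))
        assert out.n_codon_columns == 8
        assert [c for c, _ in log] == [2, 7]

    def test_stop_columns_removed(self):
        aln = self._aln({"a": "ATGTAACCC", "b": "ATGAAACCC"})
        out, log = selection.strip_indel_codons(aln)
        assert out.n_codon_columns == 2 and log == [(2, "stop")]

    def test_all_columns_removed_is_error(self):
        with pytest.raises(ValueError, match="all codon columns"):
            selection.strip_indel_codons(self._aln({"a": "---", "b": "ATG"}))


def oracle_codon_pair(ca, cb):
    """Independent per-codon enumeration of NG86 sites and differences."""
    code = STANDARD_CODE

    def sites(codon):
        s = 0.0
        for pos in range(3):
            syn = valid = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if mut in code.stop_codons:
                    continue
                valid += 1
                syn += code.table[mut] == code.table[codon]
            s += syn / valid if valid else 0.0
        return s

    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diff_pos):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in code.stop_codons:
                ok = False
                break
            sd += code.table[cur] == code.table[nxt]
            nd += code.table[cur] != code.table[nxt]
            cur = nxt
        if ok:
            paths.append((sd, nd))
    S = (sites(ca) + sites(cb)) / 2
    sd = sum(p[0] for p in paths) / len(paths) if paths else None
    nd = sum(p[1] for p in paths) / len(paths) if paths else None
    return S, 3 - S, sd, nd


class TestCountDnds:
    def test_identical_sequences(self):
        res = selection.count_dnds("ATGAAA", "ATGAAA")
        assert res.Nd == res.Sd == 0 and res.dN == res.dS == 0.0

    @pytest.mark.parametrize(
        "ca,cb,nd,sd",
        [("TTT", "TTA", 1, 0), ("GGT", "GGC", 0, 1)],  # Phe→Leu; Gly→Gly
    )
    def test_single_difference_against_enumeration(self, ca, cb, nd, sd):
        res = selection.count_dnds(ca, cb)
        assert res.Nd == nd and res.Sd == sd
        _, _, osd, ond = oracle_codon_pair(ca, cb)
        assert res.Sd == osd and res.Nd == ond

    def test_sites_and_paths_match_oracle_on_random_codons(self):
        rng = np.random.default_rng(8)
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=40)]
        for ca, cb in zip(codons[::2], codons[1::2]):
            res = selection.count_dnds(ca, cb)
            S, N, osd, ond = oracle_codon_pair(ca, cb)
            assert res.S == pytest.approx(S)
            assert res.N == pytest.approx(N)
            if osd is not None:
                assert res.Sd == pytest.approx(osd)
                assert res.Nd == pytest.approx(ond)

    def test_site_counts_sum_to_three_per_codon(self):
        res = selection.count_dnds("ATGAAACCC", "ATGAAGCCA")
        assert res.N + res.S == pytest.approx(9.0)

    def test_ds_zero_gives_null_omega(self):
        res = selection.count_dnds("TTT", "GTT")  # single nonsyn change
        assert res.omega is None and "dS" in res.note

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            selection.count_dnds("ATGTAACCC", "ATGAAACCC")


class TestRateMatrix:
    def test_row_sums_zero(self):
        pi = selection.codon_frequencies(method="uniform")
        Q = selection.build_rate_matrix(2.0, 0.3, pi)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        pi = selection.codon_frequencies(method="uniform")
        Q = selection.build_rate_matrix(2.0, 0.0, pi)
        ala = [CODON_INDEX[c] for c in ("GCT", "GCC", "GCA", "GCG")]
        phe = CODON_INDEX["TTT"]
        assert Q[ala[0], phe] == 0.0
        assert Q[ala[0], ala[1]] > 0.0

    def test_unit_expected_rate(self):
        pi = selection.codon_frequencies(method="uniform")
        Q = selection.build_rate_matrix(3.0, 0.1, pi)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    @given(
        st.floats(min_value=0.3, max_value=10.0),
        st.floats(min_value=0.01, max_value=5.0),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_detailed_balance(self, kappa, omega):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.full(61, 5.0))
        Q = selection.build_rate_matrix(kappa, omega, pi)
        flux = pi[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            selection.build_rate_matrix(2.0, 0.5, np.ones(61))


class TestFitModel:
    def test_lnl_matches_exhaustive_summation(self):
        tree = simulate.name_nodes(io.read_newick("(A:0.3,B:0.2,C:0.4);"))
        spec = simulate.SimulationSpec(tree=tree, omega=0.5, n_codons=5, seed=3)
        aln, _ = simulate.simulate_codon_alignment(spec)
        fit = selection.fit_model(
            aln,
            tree,
            selection.CodonModelSpec(
                "M0", codon_freqs="uniform", kappa=1.7,
                fix_branch_lengths=True, n_starts=1,
            ),
        )
        pi = selection.codon_frequencies(method="uniform")
        Q = selection.build_rate_matrix(1.7, fit.estimates["omega"], pi)
        prop = selection._Propagator(Q, pi)
        P = {
            n.name: prop.probability_matrix(n.length)
            for n in tree.preorder()
            if n.parent
        }
        lnL = 0.0
        for col in range(5):
            obs = {t: CODON_INDEX[aln.codon(t, col + 1)] for t in aln.ids}
            total = sum(
                pi[r] * np.prod([P[t][r, s] for t, s in obs.items()])
                for r in range(61)
            )
            lnL += np.log(total)
        assert fit.lnL == pytest.approx(lnL, abs=1e-8)

    def test_two_ratio_constrained_equal_reproduces_m0(self, small_alignment,
                                                       six_taxon_tree):
        tree = six_taxon_tree.copy()
        for name in ("A", "B"):
            tree.find(name).tags.add("fg")
        m0 = selection.fit_model(
            small_alignment, six_taxon_tree,
            selection.CodonModelSpec("M0", n_starts=1),
        )
        two = selection.fit_model(
            small_alignment, tree,
            selection.CodonModelSpec("two-ratio", foreground_tag="fg", n_starts=1),
        )
        # nested: the two-ratio optimum can only match or beat M0
        assert two.lnL >= m0.lnL - 1e-4

    def test_likelihood_invariant_under_reordering(self, small_alignment,
                                                   six_taxon_tree):
        spec = selection.CodonModelSpec(
            "M0", kappa=2.0, fix_branch_lengths=True, n_starts=1
        )
        fit1 = selection.fit_model(small_alignment, six_taxon_tree, spec)
        recs = list(small_alignment.records)[::-1]
        rng = np.random.default_rng(1)
        cols = rng.permutation(small_alignment.n_codon_columns)
        shuffled = CodonAlignment(
            [
                SequenceRecord(
                    r.id,
                    "".join(r.seq[3 * c : 3 * c + 3] for c in cols),
                )
                for r in recs
            ]
        )
        fit2 = selection.fit_model(shuffled, six_taxon_tree, spec)
        assert fit1.lnL == pytest.approx(fit2.lnL, abs=1e-6)
        assert fit1.estimates["omega"] == pytest.approx(
            fit2.estimates["omega"], abs=1e-4
        )

    def test_free_ratio_beats_m0_on_heterogeneous_data(self, six_taxon_tree):
        omega_by_branch = {"A": 0.8, "B": 0.8}
        spec = simulate.SimulationSpec(
            tree=six_taxon_tree, omega=0.1, omega_by_branch=omega_by_branch,
            n_codons=200, seed=23,
        )
        aln, _ = simulate.simulate_codon_alignment(spec)
        m0 = selection.fit_model(
            aln, six_taxon_tree,
            selection.CodonModelSpec("M0", kappa=2.0, fix_branch_lengths=True,
                                     n_starts=1),
        )
        free = selection.fit_model(
            aln, six_taxon_tree,
            selection.CodonModelSpec("free-ratio", kappa=2.0,
                                     fix_branch_lengths=True, n_starts=1),
        )
        assert free.lnL >= m0.lnL - 1e-4
        assert free.np > m0.np

    def test_taxon_mismatch_rejected(self, small_alignment):
        other = simulate.name_nodes(io.read_newick("(X:1,Y:1);"))
        with pytest.raises(ValueError, match="mismatch"):
            selection.fit_model(
                small_alignment, other, selection.CodonModelSpec("M0")
            )

    def test_stop_codon_in_data_rejected(self, six_taxon_tree):
        rows = {t: "ATGTAACCC" for t in "ABCDEF"}
        aln = CodonAlignment(
            [SequenceRecord(k, v) for k, v in rows.items()]
        )
        with pytest.raises(ValueError, match="strip"):
            selection.fit_model(aln, six_taxon_tree, selection.CodonModelSpec("M0"))


class TestLRT:
    def test_identical_fits_give_p_one(self, small_alignment, six_taxon_tree):
        fit = selection.fit_model(
            small_alignment, six_taxon_tree,
            selection.CodonModelSpec("M0", n_starts=1),
        )
        fake_general = selection.FitResult(
            model_id="two-ratio", lnL=fit.lnL, np=fit.np + 1,
            estimates={}, tree=fit.tree, converged=True,
        )
        res = selection.lrt(fake_general, fit)
        assert res.twice_delta == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_chi_square_tail_example(self):
        from scipy.stats import chi2

        general = selection.FitResult("M8", -100.0, 5, {}, None, True)
        restricted = selection.FitResult("M7", -111.55, 3, {}, None, True)
        res = selection.lrt(general, restricted)
        assert res.twice_delta == pytest.approx(23.1)
        assert res.df == 2
        assert res.p_value == pytest.approx(chi2.sf(23.1, 2), rel=1e-12)
        assert res.p_value == pytest.approx(9.65e-6, rel=5e-3)

    def test_negative_delta_warns(self):
        general = selection.FitResult("two-ratio", -105.0, 5, {}, None, True)
        restricted = selection.FitResult("M0", -100.0, 4, {}, None, True)
        with pytest.warns(UserWarning, match="non-convergence"):
            res = selection.lrt(general, restricted)
        assert res.warning


class TestLabelBranches:
    TIP_TAGS = {
        "A": {"HDC"}, "B": {"HDC"}, "C": {"cave"}, "D": set(),
        "E": {"HDC"}, "F": set(),
    }

    def test_all_tips_tagged_tags_every_branch(self, six_taxon_tree):
        tags = {t: {"x"} for t in "ABCDEF"}
        out = selection.label_branches(six_taxon_tree, "x", tags)
        assert all(
            "x" in n.tags for n in out.preorder() if n is not out.root
        )

    def test_single_tip_only_terminal_branch(self, six_taxon_tree):
        out = selection.label_branches(six_taxon_tree, "cave", self.TIP_TAGS)
        tagged = [n.name for n in out.preorder() if "cave" in n.tags]
        assert tagged == ["C"]

    def test_paraphyletic_tag_hand_enumeration(self, six_taxon_tree):
        # HDC tips: A, B, E -> tagged branches: A, B, stem(A,B), E
        out = selection.label_branches(six_taxon_tree, "HDC", self.TIP_TAGS)
        stem_ab = out.mrca(["A", "B"]).name
        tagged = {n.name for n in out.preorder() if "HDC" in n.tags}
        assert tagged == {"A", "B", "E", stem_ab}

    def test_stem_exclusion(self, six_taxon_tree):
        out = selection.label_branches(
            six_taxon_tree, "HDC", self.TIP_TAGS, include_stem=False
        )
        tagged = {n.name for n in out.preorder() if "HDC" in n.tags}
        assert tagged == {"A", "B"}  # stem(A,B) and isolated E dropped

    def test_absent_tag_rejected(self, six_taxon_tree):
        with pytest.raises(ValueError, match="absent"):
            selection.label_branches(six_taxon_tree, "nope", self.TIP_TAGS)
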