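"""Allele-specific primer design, Tm models, in-silico PCR, genotyping."""

from __future__ import annotations

import numpy as np
import pytest

from dystmap.primers import (
    DesignConfig,
    DesignError,
    Primer,
    design_as_primers,
    genotype_call,
    genotype_mouse,
    in_silico_pcr,
    tm,
)
from dystmap.reference import revcomp

from .oracles import tm_nn_oracle


def _random_template(rng, n=500, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), p=p, size=n))


class TestTm:
    def test_wallace_examples(self):
        assert tm("ACGT", model="wallace") == 12.0
        assert tm("A" * 20, model="wallace") == 40.0

    def test_auto_switches_at_14_nt(self):
        assert tm("ACGTACGTACGTA") == tm("ACGTACGTACGTA", model="wallace")
        s = "ACGTACGTACGTAC"
        assert tm(s) == tm(s, model="nn")

    def test_nn_matches_independent_reimplementation(self):
        """NN Tm (monovalent conditions) within 0.1 degC of a literal
        re-implementation of the same parameter table."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=20))
            ours = tm(seq, model="nn", mg_mM=0.0)
            assert abs(ours - tm_nn_oracle(seq)) < 0.1

    def test_rejects_bad_sequence(self):
        with pytest.raises(ValueError):
            tm("")
        with pytest.raises(ValueError):
            tm("ACGN")


class TestDesign:
    def test_allele_specific_primers_end_on_the_allele_base(self):
        rng = np.random.default_rng(1)
        template = _random_template(rng)
        pos = 250
        pset = design_as_primers(template, pos, template[pos], "A"
                                 if template[pos] != "A" else "G")
        mut = "A" if template[pos] != "A" else "G"
        assert pset.as_forward_wt.sequence[-1] == template[pos]
        assert pset.as_forward_mut.sequence[-1] == mut
        assert pset.as_reverse_wt.sequence[-1] == revcomp(template[pos])
        assert pset.as_reverse_mut.sequence[-1] == revcomp(mut)

    def test_at_rich_upstream_flank_gives_longer_forward_primers(self):
        """AT-rich sequence needs more bases to reach the Tm window, as in
        the published design."""
        for seed in range(40):
            rng = np.random.default_rng(seed)
            pos = 300
            template = (_random_template(rng, pos, gc=0.34)
                        + _random_template(rng, 300, gc=0.62))
            try:
                pset = design_as_primers(template, pos, template[pos],
                                         "A" if template[pos] != "A" else "G")
            except DesignError:
                continue
            assert len(pset.as_forward_wt.sequence) > len(
                pset.as_reverse_wt.sequence
            )
            return
        raise AssertionError("no feasible AT-rich/GC-rich template found")

    def test_mutation_at_template_edge_is_infeasible(self):
        rng = np.random.default_rng(2)
        template = _random_template(rng, 200)
        with pytest.raises(DesignError):
            design_as_primers(template, 5, template[5], "A"
                              if template[5] != "A" else "G")

    def test_wt_reverse_destabilizing_substitution(self):
        rng = np.random.default_rng(11)
        # ensure a C at the -2 position of the WT reverse primer by trying seeds
        for seed in range(30):
            rng = np.random.default_rng(seed)
            template = _random_template(rng)
            pos = 250
            mut = "A" if template[pos] != "A" else "G"
            try:
                base = design_as_primers(template, pos, template[pos], mut)
            except DesignError:
                continue
            if base.as_reverse_wt.sequence[-2] == "C":
                cfg = DesignConfig(destabilize_wt_reverse=True)
                pset = design_as_primers(template, pos, template[pos], mut, cfg=cfg)
                assert pset.as_reverse_wt.sequence[-2] == "G"
                assert pset.as_reverse_wt.extra_mismatch_offset == -2
                return
        raise AssertionError("no template produced a C at -2")

    @pytest.mark.parametrize("seed", range(25))
    def test_designed_primers_revalidate_against_template(self, seed):
        """Independent scan: footprint slice matches the primer (up to the
        allele base), 3' base equals the allele, Tm inside the window."""
        rng = np.random.default_rng(seed + 100)
        template = _random_template(rng, 600)
        pos = 300
        wt = template[pos]
        mut = str(rng.choice([b for b in "ACGT" if b != wt]))
        try:
            pset = design_as_primers(template, pos, wt, mut)
        except DesignError:
            pytest.skip("no feasible design for this random template")
        cfg = DesignConfig()
        for p in pset.all_primers():
            s, e = p.footprint.start, p.footprint.end
            window = template[s:e]
            if p.orientation == "forward":
                onto = window
            else:
                onto = revcomp(window)
            mism = sum(a != b for a, b in zip(onto, p.sequence))
            if p.allele == "mutant":
                assert mism == 1 and p.sequence[-1] != onto[-1]
            else:
                assert mism == 0
            assert cfg.min_len <= len(p.sequence) <= cfg.max_len
            if p.allele == "none":
                inner = (pset.as_forward_wt.tm + pset.as_reverse_wt.tm) / 2
                assert abs(p.tm - inner) <= cfg.tm_tolerance
            else:
                assert abs(p.tm - cfg.tm_target) <= cfg.tm_tolerance


class TestInSilicoPcr:
    @pytest.fixture()
    def designed(self):
        rng = np.random.default_rng(5)
        template = _random_template(rng, 600)
        pos = 300
        wt = template[pos]
        mut = "A" if wt != "A" else "G"
        pset = design_as_primers(template, pos, wt, mut)
        mut_template = template[:pos] + mut + template[pos + 1 :]
        return template, mut_template, pset

    def test_mutant_reaction_amplifies_only_mutant_allele(self, designed):
        wt_t, mut_t, pset = designed
        prods = in_silico_pcr(mut_t, pset.outside_forward, pset.as_reverse_mut)
        assert len(prods) == 1
        assert prods[0].length == pset.product_lengths["fout_rmut"]
        assert in_silico_pcr(wt_t, pset.outside_forward, pset.as_reverse_mut) == []

    def test_control_reaction_amplifies_both_alleles(self, designed):
        wt_t, mut_t, pset = designed
        for t in (wt_t, mut_t):
            prods = in_silico_pcr(t, pset.outside_forward, pset.outside_reverse)
            assert [p.length for p in prods] == [pset.product_lengths["control"]]

    def test_products_match_brute_force_strand_scan(self):
        """Product coordinates equal an exhaustive scan over both strands
        using a vectorized character-comparison oracle."""
        rng = np.random.default_rng(9)
        template = _random_template(rng, 300)
        arr = np.frombuffer(template.encode(), dtype="S1")

        def sites(primer, reverse):
            target = revcomp(primer) if reverse else primer
            tarr = np.frombuffer(target.encode(), dtype="S1")
            n = len(target)
            hits = []
            for i in range(len(template) - n + 1):
                mm = np.sum(arr[i : i + n] != tarr)
                three_prime_ok = (
                    arr[i] == tarr[0] if reverse else arr[i + n - 1] == tarr[-1]
                )
                internal = mm - (0 if three_prime_ok else 1)
                if three_prime_ok and internal <= 1:
                    hits.append(i)
            return hits

        for _ in range(15):
            i = int(rng.integers(0, 250))
            fwd = template[i : i + 20]
            j = int(rng.integers(i + 30, 280))
            rev = revcomp(template[j : j + 20])
            # corrupt one internal base sometimes
            if rng.random() < 0.5:
                k = int(rng.integers(0, 18))
                fwd = fwd[:k] + ("A" if fwd[k] != "A" else "C") + fwd[k + 1 :]
            prods = in_silico_pcr(template, fwd, rev)
            expected = set()
            for pf, pr in [(fwd, rev), (rev, fwd), (fwd, fwd), (rev, rev)]:
                for s in sites(pf, reverse=False):
                    for r in sites(pr, reverse=True):
                        e = r + len(pr)
                        if e - s >= len(pf) + len(pr) and e - s <= 5000:
                            expected.add((s, e))
            assert {(p.start, p.end) for p in prods} == expected


class TestGenotyping:
    def test_call_table(self):
        assert genotype_call(True, True) == "carrier"
        assert genotype_call(True, False) == "non-carrier"
        assert genotype_call(False, True) == "fail"
        assert genotype_call(False, False) == "fail"
        assert genotype_call(True, True, wt_product=False) == "carrier_homozygous"

    def test_het_template_pair_called_carrier(self):
        rng = np.random.default_rng(21)
        template = _random_template(rng, 600)
        pos = 300
        wt = template[pos]
        mut = "A" if wt != "A" else "G"
        pset = design_as_primers(template, pos, wt, mut)
        mut_t = template[:pos] + mut + template[pos + 1 :]
        assert genotype_mouse((template, mut_t), pset) == "carrier"
        assert genotype_mouse((template, template), pset) == "non-carrier"

    def test_simulated_litter_of_40_genotypes_perfectly(self, default_gene):
        region, _, planted = default_gene
        pad = 350
        start = planted.pos - pad
        template = region.slice(start, planted.pos + pad)
        pset = design_as_primers(template, pad, planted.ref, planted.alt)
        mut_t = template[:pad] + planted.alt + template[pad + 1 :]
        rng = np.random.default_rng(33)
        truth = rng.random(40) < 0.5
        for carrier in truth:
            alleles = (template, mut_t) if carrier else (template, template)
            call = genotype_mouse(alleles, pset)
            assert call == ("carrier" if carrier else "non-carrier")


@pytest.mark.parametrize("seed", range(20))
def test_control_and_discrimination_properties_hold_across_designs(seed):
    """Across random designed fixtures: the control pair amplifies both
    alleles; the mutant-specific pair amplifies only the mutant allele."""
    rng = np.random.default_rng(seed + 1000)
    template = _random_template(rng, 520)
    pos = 260
    wt = template[pos]
    mut = str(rng.choice([b for b in "ACGT" if b != wt]))
    try:
        pset = design_as_primers(template, pos, wt, mut)
    except DesignError:
        pytest.skip("infeasible random template")
    mut_t = template[:pos] + mut + template[pos + 1 :]
    assert in_silico_pcr(template, pset.outside_forward, pset.outside_reverse)
    assert in_silico_pcr(mut_t, pset.outside_forward, pset.outside_reverse)
    assert in_silico_pcr(mut_t, pset.outside_forward, pset.as_reverse_mut)
    assert not in_silico_pcr(template, pset.outside_forward, pset.as_reverse_mut)
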