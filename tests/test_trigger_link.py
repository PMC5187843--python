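"""miRNA complementarity scoring, binding-site scanning, and the
cleavage-proximity linkage rule."""

import numpy as np
import pytest

from phaswindow import (link_triggers, scan_targets, target_score)
from phaswindow.phasirna_extract import PhasiRNA, _revcomp
from phaswindow.trigger_link import TargetSite, five_prime_end

MIRNA = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt


def perfect_site(mirna=MIRNA):
    """Target strand read 3'->5' that pairs every miRNA base."""
    comp = str.maketrans("ACGU", "UGCA")
    return mirna.translate(comp)


def site_with(mirna_pos, base):
    """Perfect site with the base opposite ``mirna_pos`` (1-based)
    replaced."""
    s = list(perfect_site())
    s[mirna_pos - 1] = base
    return "".join(s)


class TestTargetScore:
    def test_perfect_complement_scores_zero(self):
        assert target_score(MIRNA, perfect_site()) == 0.0

    def test_wobble_outside_core(self):
        # miRNA position 15 is U; opposite G forms a U:G wobble
        assert MIRNA[14] == "U"
        assert target_score(MIRNA, site_with(15, "G")) == 0.5

    def test_mismatch_in_core_doubles(self):
        assert target_score(MIRNA, site_with(5, "A")) == 2.0

    def test_exhaustive_single_edit_enumeration(self):
        # every single-base substitution scores exactly per the rule table
        pair = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        wobble = {("G", "U"), ("U", "G")}
        for pos in range(1, 22):
            for base in "ACGU":
                duplex = (MIRNA[pos - 1], base)
                if duplex in pair:
                    want = 0.0
                elif duplex in wobble:
                    want = 0.5
                else:
                    want = 1.0
                if 2 <= pos <= 13:
                    want *= 2
                assert target_score(MIRNA, site_with(pos, base)) == want

    def test_single_bulge_costs(self):
        # extra target nucleotide far from the core: bulge cost 1.0
        bulged = perfect_site()[:17] + "A" + perfect_site()[17:]
        assert target_score(MIRNA, bulged) == 1.0
        # unpaired miRNA nucleotide: best gap placement chosen
        shorter = perfect_site()[:16] + perfect_site()[17:]
        assert target_score(MIRNA, shorter) == 1.0

    def test_reversal_symmetry_without_positional_weights(self):
        site = site_with(17, "U")
        fwd = target_score(MIRNA, site, core_multiplier=1.0)
        rev = target_score(MIRNA[::-1], site[::-1], core_multiplier=1.0)
        assert fwd == rev

    def test_alphabet_violation_raises(self):
        with pytest.raises(ValueError):
            target_score(MIRNA, "X" * 21)


class TestScanTargets:
    def test_planted_reverse_complement_found(self):
        rng = np.random.default_rng(5)
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))
        planted_at = 137
        dna = (flank[:planted_at]
               + _revcomp(MIRNA.replace("U", "T"))
               + flank[planted_at:])
        sites = scan_targets({"mir": MIRNA}, {"L": dna}, max_penalty=0.0)
        assert any(s.strand == "+" and s.penalty == 0.0
                   and s.site_start == planted_at
                   and s.cleavage == planted_at + 21 - 10
                   for s in sites)

    @pytest.mark.parametrize("extra,kept", [(0.0, True), (0.5, False)])
    def test_penalty_threshold_inclusive(self, extra, kept):
        # a site of penalty exactly 3.0 (three non-core mismatches),
        # optionally worsened by a non-core wobble to 3.5
        site = perfect_site()
        site = site[:13] + "CCC" + site[16:]  # positions 14-16 mismatched
        assert target_score(MIRNA, site) == 3.0
        if extra:
            site = site[:20] + "G"  # U:G wobble at miRNA position 21
            assert target_score(MIRNA, site) == 3.5
        # the scanned plus strand reads the site back 3'->5'
        dna = site[::-1].replace("U", "T")
        found = scan_targets({"mir": MIRNA}, {"L": dna}, max_penalty=3.0,
                             allow_bulge=False)
        assert bool(found) is kept

    def test_scrambled_mirna_no_sites_in_random_sequence(self):
        rng = np.random.default_rng(11)
        dna = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        scrambled = "".join(rng.permutation(list(MIRNA)))
        assert scan_targets({"m": scrambled}, {"L": dna},
                            max_penalty=3.0) == []

    def test_flank_extension_never_removes_sites(self):
        rng = np.random.default_rng(13)
        dna = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        dna = dna[:100] + _revcomp(MIRNA.replace("U", "T")) + dna[100:]
        flank = "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        base = scan_targets({"m": MIRNA}, {"L": dna}, max_penalty=3.0)
        ext = scan_targets({"m": MIRNA}, {"L": flank + dna + flank},
                           max_penalty=3.0)
        base_keys = {(s.mirna_id, s.strand, s.site_start, s.penalty)
                     for s in base}
        ext_keys = {(s.mirna_id, s.strand, s.site_start - 50, s.penalty)
                    for s in ext}
        assert base_keys <= ext_keys


def _site(cleavage, chrom="Chr01"):
    return TargetSite("mir", MIRNA, "L", chrom, "+", cleavage - 11,
                      cleavage + 10, cleavage, 0.0)


def _phasirna(start, strand="+", chrom="Chr01"):
    return PhasiRNA("L", chrom, start, strand, None, {"s1": 5000})


class TestLinkTriggers:
    @pytest.mark.parametrize("distance,kept", [(0, True), (420, True),
                                               (421, False)])
    def test_distance_rule_inclusive(self, distance, kept):
        links = link_triggers([_site(1000)], [_phasirna(1000 + distance)])
        assert (len(links) == 1) is kept
        if kept:
            assert links[0].distance == distance
            assert links[0].in_register is (distance % 21 == 0)

    def test_minus_strand_five_prime_end(self):
        p = _phasirna(1000, strand="-")
        assert five_prime_end(p) == 1020
        (link,) = link_triggers([_site(1440)], [p])
        assert link.distance == 420

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(17)
        sites = [_site(int(c)) for c in rng.integers(0, 3000, 15)]
        phas = [_phasirna(int(p), strand=("+", "-")[int(s)])
                for p, s in zip(rng.integers(0, 3000, 25),
                                rng.integers(0, 2, 25))]
        got = {(id(l.site), id(l.phasirna)) for l in link_triggers(sites, phas)}
        want = {(id(s), id(p)) for s in sites for p in phas
                if abs(s.cleavage - five_prime_end(p)) <= 420}
        assert got == want

    def test_different_chromosome_never_links(self):
        assert link_triggers([_site(1000, chrom="Chr01")],
                             [_phasirna(1000, chrom="Chr02")]) == []

    def test_planted_triggers_link_in_simulation(self, sim7, phasing_set7,
                                                 regions7):
        from phaswindow import extract_phasirnas, scaled_min_total, \
            extract_locus_sequences
        threshold = scaled_min_total(3000, sim7.config.n_samples)
        phas = []
        for reg in regions7:
            phas += extract_phasirnas(reg, phasing_set7, min_total=threshold)
        seqs, origins = extract_locus_sequences(sim7.genome, regions7)
        sites = scan_targets(sim7.truth.mirnas, seqs, max_penalty=3.0,
                             origins=origins)
        links = link_triggers(sites, phas)
        # every truth locus has its planted miRNA linked at the planted
        # cleavage position
        linked = {(l.site.mirna_id, l.site.cleavage) for l in links}
        for t in sim7.truth.loci:
            assert (t.mirna_id, t.cleavage) in linked
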