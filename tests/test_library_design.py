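import itertools
import random
import re

import pytest

from adscreen.library_design import (DEFAULT_CODON_USAGE, DnaDesignConstraints,
                                     design_mutant_panels,
                                     enforce_edit_distance, reverse_translate,
                                     tile_protein, tiles_for_protein,
                                     translate, validate_constraints,
                                     verify_paired_end_distance)
from adscreen.seq_features import AMINO_ACIDS


class TestTiling:
    def test_single_tile_protein(self):
        assert tile_protein("A" * 53).positions == (0,)

    def test_79_residue_protein(self):
        # n = 1 + ceil(26/13) = 3 tiles, evenly spaced by 13
        assert tile_protein("A" * 79).positions == (0, 13, 26)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            tile_protein("A" * 52)

    @pytest.mark.parametrize("length", [53, 54, 66, 79, 100, 153, 500, 999])
    def test_step_bound_and_exact_coverage(self, length):
        scheme = tile_protein("A" * length)
        starts = scheme.positions
        steps = [b - a for a, b in zip(starts, starts[1:])]
        assert all(1 <= s <= 13 for s in steps)
        assert starts[0] == 0
        assert starts[-1] + 53 == length  # last tile ends at protein end
        covered = set()
        for s in starts:
            covered.update(range(s, s + 53))
        assert covered == set(range(length))

    def test_tiles_for_protein_sequences(self):
        seq = "".join(random.Random(0).choices(AMINO_ACIDS, k=100))
        tiles = tiles_for_protein("p", seq)
        for t in tiles:
            assert t.sequence == seq[t.start:t.stop]


# independent naive scanners for every DNA constraint rule
def naive_violation_kinds(dna, c: DnaDesignConstraints):
    kinds = set()
    gc = lambda s: (s.count("G") + s.count("C")) / len(s)
    if abs(gc(dna) - c.gc_target) > c.gc_tolerance:
        kinds.add(("gc_global", 0))
    for i in range(len(dna) - c.gc_window + 1):
        if abs(gc(dna[i:i + c.gc_window]) - c.gc_target) > c.gc_tolerance:
            kinds.add(("gc_window", i))
    k = c.max_repeat_len
    for i in range(len(dna) - k + 1):
        for j in range(i):
            if dna[j:j + k] == dna[i:i + k]:
                kinds.add(("repeat", i))
                break
    for base, limit in c.homopolymer_limits:
        for m in re.finditer(f"{base}{{{limit},}}", dna):
            kinds.add(("homopolymer", m.start()))
    for km, npeat in c.kmer_repeat_rules:
        for i in range(len(dna) - km * npeat + 1):
            unit = dna[i:i + km]
            if dna[i:i + km * npeat] == unit * npeat:
                kinds.add(("kmer_repeat", i))
    return kinds


class TestValidateConstraints:
    def test_homopolymer_flagged(self):
        dna = "ACGT" * 5 + "A" * 8 + "CGT" * 4
        kinds = {v.kind for v in validate_constraints(dna)}
        assert "homopolymer" in kinds

    def test_kmer_repeat_flagged(self):
        v = validate_constraints("ATCGATCG" + "ACGACGACG" + "TTAAGGCC")
        assert any(x.kind == "kmer_repeat" and x.detail == "ACGx3" for x in v)

    def test_agrees_with_naive_scanners(self):
        r = random.Random(5)
        c = DnaDesignConstraints()
        for _ in range(60):
            # biased alphabets provoke homopolymers and repeats
            alphabet = r.choice(["ACGT", "AACGT", "AAACCGT", "ACG"])
            dna = "".join(r.choices(alphabet, k=150))
            got = {(v.kind, v.position) for v in validate_constraints(dna, c)}
            assert got == naive_violation_kinds(dna, c)


class TestReverseTranslate:
    def test_round_trip(self, random_peptides):
        for i, pep in enumerate(random_peptides(30, 25)):
            dna = reverse_translate(pep, rng_seed=i)
            assert translate(dna) == pep

    def test_deterministic(self):
        pep = "MKDLLEEFWA"
        assert reverse_translate(pep, rng_seed=3) == reverse_translate(pep, rng_seed=3)

    def test_polylysine_avoids_homopolymer_run(self):
        # AAA-codon runs must be broken by AAG to respect the 8-A limit
        dna = reverse_translate("KKKKKKKK", rng_seed=0)
        assert "A" * 8 not in dna
        assert translate(dna) == "KKKKKKKK"


class TestEnforceEditDistance:
    def test_identical_pair_repaired(self):
        pep = "".join(random.Random(1).choices(AMINO_ACIDS, k=53))
        dna = reverse_translate(pep, rng_seed=0)
        rep = enforce_edit_distance([dna, dna], rng_seed=0)
        assert rep.converged
        assert rep.min_head >= 6 and rep.min_tail >= 6
        assert all(translate(d) == pep for d in rep.dnas)

    def test_satisfying_set_is_fixed_point(self):
        r = random.Random(2)
        peps = ["".join(r.choices(AMINO_ACIDS, k=53)) for _ in range(5)]
        dnas = [reverse_translate(p, rng_seed=i) for i, p in enumerate(peps)]
        rep1 = enforce_edit_distance(dnas, rng_seed=0)
        assert rep1.converged
        rep2 = enforce_edit_distance(rep1.dnas, rng_seed=99)
        assert rep2.dnas == rep1.dnas

    def test_paired_end_distance_reporting(self):
        dna = reverse_translate("M" + "K" * 20, rng_seed=0)
        minimum, offenders = verify_paired_end_distance([dna, dna], read_len=50)
        assert minimum == 0 and offenders == [(0, 1)]
        assert verify_paired_end_distance([dna], read_len=50) == (100, [])


class TestMutantPanels:
    CAD = "DDLFDYDFLLDYE"  # 13-aa core AD-like sequence

    def test_acidic_swaps(self):
        d2e = design_mutant_panels("DED", "d2e")[0].sequence
        e2d = design_mutant_panels("DED", "e2d")[0].sequence
        assert d2e == "EEE" and e2d == "DDD"
        neutral = design_mutant_panels("DED", "d2n_e2q")[0].sequence
        assert neutral == "NQN"

    def test_scrambles_preserve_multiset(self):
        for m in design_mutant_panels(self.CAD, "scramble", n_scrambles=8):
            assert sorted(m.sequence) == sorted(self.CAD)

    def test_alapro_scan_count(self):
        # positions 4-10 (1-based) of the cAD: indices 3..9 =
        # F D Y D F L L -> non-WFYILM residues are the two D's -> 2 x {A, P}
        mutants = design_mutant_panels(self.CAD, "alapro_scan")
        assert len(mutants) == 4
        for m in mutants:
            assert len(m.sequence) == 13
            assert sum(a != b for a, b in zip(m.sequence, self.CAD)) == 1

    def test_aromatic_subsets_mutate_to_alanine(self):
        for m in design_mutant_panels(self.CAD, "aromatic_subsets", n_aromatic_subsets=2):
            for a, b in zip(self.CAD, m.sequence):
                if a != b:
                    assert a in "WFY" and b == "A"

    def test_tandem_cads_preserve_spacing(self):
        res = design_mutant_panels(self.CAD, "tandem_cads", second_cad="DLDLDLDLD",
                                   cad_gap=5)
        tandem = next(m for m in res if m.provenance == "tandem")
        assert tandem.sequence.startswith(self.CAD)
        assert tandem.sequence.endswith("DLDLDLDLD")
        assert len(tandem.sequence) == 13 + 5 + 9
        alone = next(m for m in res if m.provenance == "second_alone")
        assert alone.sequence.index("DLDLDLDLD") == 13 + 5  # distance maintained

    def test_hydrophobic_matrix_layout(self):
        res = design_mutant_panels(self.CAD, "hydrophobic_matrix", n_matrix_regions=4)
        for m in res:
            assert len(m.sequence) == 53
            assert m.sequence[25:38] == self.CAD  # 20 variable + 5 neutral + cAD

    def test_systematic_9mers_context(self):
        res = design_mutant_panels("A", "systematic_9mers")
        assert len(res) == 1534
        for m in res[:20]:
            assert len(m.sequence) == 30
            assert m.sequence.startswith("ASAVGQQGAN")
            assert m.sequence.endswith("NSSATQSQSNT")

    def test_inapplicable_panel_empty(self):
        assert design_mutant_panels("GGGG", "aromatic_subsets") == []
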