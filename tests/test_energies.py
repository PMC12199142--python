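"""Nearest-neighbor energy evaluation: table handling, component rules, and
equivalence with an independent reference evaluator (ViennaRNA, dangling
ends disabled, same published Turner 2004 tables)."""

import math
import random
import shutil

import pytest

import RNA

from rnalsc.energies import (
    DATA_DIR,
    ParameterError,
    annotate_structure_energies,
    bulge_dg,
    hairpin_dg,
    internal_dg,
    load_turner_params,
    stem_dg,
    total_single_branch_dg,
)
from rnalsc.structures import decompose, parse_dotbracket
from rnalsc.synthetic_data import random_single_branch_structure

_PAIR_ORDER = ["CG", "GC", "GU", "UG", "AU", "UA"]


def reference_energy(seq: str, db: str) -> float:
    md = RNA.md()
    md.dangles = 0
    return RNA.fold_compound(seq, md).eval_structure(db)


def kcal(e):
    assert e.scorable, e.reason
    return e.dg


class TestLoadParams:
    def test_stack_table_complete_for_canonical_pairs(self, params):
        for i in range(6):
            for j in range(6):
                assert abs(params.stack[i, j]) < 1000  # finite, tabulated

    def test_stack_symmetric_under_duo_rotation(self, params):
        # rotating a stacked duo 180 degrees swaps the roles of the outer
        # and (reversed) inner pair: the table must be symmetric
        for i in range(6):
            for j in range(6):
                assert params.stack[i, j] == params.stack[j, i]

    def test_initiation_tables_monotone(self, params):
        # the published small-size entries dip (e.g. hairpin 6 < hairpin 5);
        # entropic growth makes the tables monotone beyond those specials
        for table, start in (
            (params.hairpin_init, 9),
            (params.bulge_init, 2),
            (params.internal_init, 4),
        ):
            vals = table[start:31]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_missing_table_raises(self, tmp_path):
        for f in DATA_DIR.iterdir():
            if f.name != "loop_init.txt":
                shutil.copy(f, tmp_path / f.name)
        with pytest.raises(ParameterError, match="loop initiation"):
            load_turner_params(tmp_path)

    def test_malformed_table_raises(self, tmp_path):
        for f in DATA_DIR.iterdir():
            shutil.copy(f, tmp_path / f.name)
        (tmp_path / "stack.txt").write_text("# stack\n1 2 3\n")
        with pytest.raises(ParameterError, match="stack"):
            load_turner_params(tmp_path)


def _stem_of(db_id, seq, db, index=0):
    s = parse_dotbracket(db_id, seq, db)
    return decompose(s).stems[index], s.sequence


class TestStemEnergy:
    def test_length_one_stem_is_zero(self, params):
        stem, seq = _stem_of("s", "GAAAC", "(...)")
        assert kcal(stem_dg(stem, seq, params)) == 0.0

    def test_length_two_gc_stem_equals_stack_entry(self, params):
        # 5'GG3'/3'CC5' duo; reference total minus hairpin term isolates it
        seq, db = "GGAAAACC", "((....))"
        stem, _ = _stem_of("s", seq, db)
        e = kcal(stem_dg(stem, seq, params))
        s = parse_dotbracket("s", seq, db)
        hp = decompose(s).hairpins[0]
        assert e + kcal(hairpin_dg(hp, seq, params)) == pytest.approx(
            reference_energy(seq, db), abs=0.005
        )
        # the duo 5'-GG-3'/3'-CC-5' is keyed (GC, CG) in the table encoding
        assert e == params.stack[1, 0] / 100.0

    def test_au_helix_end_penalties(self, params):
        # all-AU helix: two stacks; penalties only where configured
        stem, seq = _stem_of("s", "AAAGAAACUUU", "(((.....)))")
        bare = kcal(stem_dg(stem, seq, params))
        both = kcal(stem_dg(stem, seq, params, end_penalties=(True, True)))
        assert both - bare == pytest.approx(2 * params.au_end_penalty / 100.0)

    def test_non_canonical_pair_unscorable(self, params):
        stem, seq = _stem_of("s", "GAAAA", "(...)")
        e = stem_dg(stem, seq, params)
        assert not e.scorable and "non-canonical" in e.reason


class TestHairpinEnergy:
    def test_size_three_is_initiation_only_for_gc_closing(self, params):
        s = parse_dotbracket("h", "GAAAC", "(...)")
        hp = decompose(s).hairpins[0]
        assert kcal(hairpin_dg(hp, s.sequence, params)) == params.hairpin_init[3] / 100.0

    def test_special_tetraloop_lookup(self, params):
        # CAACGG: closing C-G with an AACG tetraloop, a tabulated special case
        assert "CAACGG" in params.special_hairpins
        s = parse_dotbracket("h", "CAACGG", "(....)")
        hp = decompose(s).hairpins[0]
        e = hairpin_dg(hp, s.sequence, params)
        assert e.dg == params.special_hairpins["CAACGG"] / 100.0
        assert e.terms == {"special": e.dg}

    def test_jacobson_stockmayer_extrapolation_step(self, params):
        e30 = hairpin_dg(
            decompose(parse_dotbracket("a", "G" + "A" * 30 + "C", "(" + "." * 30 + ")")).hairpins[0],
            "G" + "A" * 30 + "C", params,
        )
        e31 = hairpin_dg(
            decompose(parse_dotbracket("b", "G" + "A" * 31 + "C", "(" + "." * 31 + ")")).hairpins[0],
            "G" + "A" * 31 + "C", params,
        )
        expected_step = int(params.jacobson_coeff * math.log(31 / 30)) / 100.0
        assert e31.dg - e30.dg == pytest.approx(expected_step, abs=1e-9)

    def test_extrapolation_continuous_at_thirty(self, params):
        # the extrapolation formula evaluated AT size 30 equals the table
        extrapolated = params.hairpin_init[30] + int(
            params.jacobson_coeff * math.log(30 / 30)
        )
        assert extrapolated == params.hairpin_init[30]

    def test_too_small_hairpin_unscorable(self, params):
        s = parse_dotbracket("h", "GAAC", "(..)")
        e = hairpin_dg(decompose(s).hairpins[0], s.sequence, params)
        assert not e.scorable and "size 2" in e.reason


class TestBulgeEnergy:
    def test_size_one_bulge_stacks_through(self, params):
        # C bulge between two G-C pairs keeps the helix stack
        s = parse_dotbracket("b", "GCGGAAACCC", "(.((...)))")
        b = decompose(s).bulges[0]
        e = bulge_dg(b, s.sequence, params)
        assert e.terms["initiation"] == params.bulge_init[1] / 100.0
        assert "through_stack" in e.terms
        assert "end_penalty" not in e.terms

    def test_larger_bulge_charges_weak_closing_pairs(self, params):
        # size-3 bulge closed by G-C (outer) and A-U (inner): one AU penalty
        s = parse_dotbracket("b", "GAAAAAAAUC", "(...(...))")
        b = decompose(s).bulges[0]
        e = bulge_dg(b, s.sequence, params)
        assert e.terms["initiation"] == params.bulge_init[3] / 100.0
        assert e.terms["end_penalty"] == params.au_end_penalty / 100.0

    def test_bulge_insertion_changes_total_consistently(self, params):
        """Inserting a 1-nt bulge into a helix shifts the reference total by
        bulge_dg minus the replaced stack; verified against reference totals."""
        rng = random.Random(5)
        for _ in range(20):
            pairs = [rng.choice([("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")]) for _ in range(4)]
            loop = "GAAAC"
            helix5 = "".join(p[0] for p in pairs)
            helix3 = "".join(p[1] for p in reversed(pairs))
            seq0 = helix5 + loop + helix3
            db0 = "(" * 4 + "." * len(loop) + ")" * 4
            seq1 = helix5[:2] + "C" + helix5[2:] + loop + helix3
            db1 = "((.((" + "." * len(loop) + "))))"
            delta_ref = reference_energy(seq1, db1) - reference_energy(seq0, db0)
            s1 = parse_dotbracket("with", seq1, db1)
            b = decompose(s1).bulges[0]
            e_bulge = kcal(bulge_dg(b, s1.sequence, params))
            t2 = _PAIR_ORDER.index(pairs[1][0] + pairs[1][1])
            t2r = _PAIR_ORDER.index(pairs[2][1] + pairs[2][0])
            replaced_stack = params.stack[t2, t2r] / 100.0
            assert delta_ref == pytest.approx(e_bulge - replaced_stack, abs=0.005)


class TestInternalLoopEnergy:
    def test_one_by_one_uses_int11_table(self, params):
        # 1x1 G.A mismatch between C-G and G-C closing pairs
        s = parse_dotbracket("i", "CGGGAAACCAG", "(.((...)).)")
        il = decompose(s).internal_loops[0]
        e = internal_dg(il, s.sequence, params)
        assert e.scorable and list(e.terms) == ["int11"]
        assert e.dg == pytest.approx(reference_energy(s.sequence, "(.((...)).)")
                                     - total_without(s, il.label, params), abs=0.005)

    def test_symmetric_loop_has_no_asymmetry_term(self, params):
        seq = "G" + "AAAA" + "GGAAACC" + "ACAA" + "C"
        db = "(" + "...." + "((...))" + "...." + ")"
        s = parse_dotbracket("i", seq, db)
        il = decompose(s).internal_loops[0]
        e = internal_dg(il, s.sequence, params)
        assert il.sizes == (4, 4)
        assert "asymmetry" not in e.terms

    def test_two_by_three_uses_dedicated_mismatches(self, params):
        seq = "G" + "AA" + "GGAAACC" + "ACA" + "C"
        db = "(" + ".." + "((...))" + "..." + ")"
        s = parse_dotbracket("i", seq, db)
        il = decompose(s).internal_loops[0]
        e = internal_dg(il, s.sequence, params)
        assert e.terms["initiation"] == params.internal_init[5] / 100.0
        assert e.terms["asymmetry"] == min(params.ninio_max, params.ninio_m) / 100.0


def total_without(struct, label, params):
    sset = decompose(struct)
    energies = annotate_structure_energies(struct, params, sset)
    return sum(e.dg for e in energies if e.scorable and e.label != label)


class TestAnnotateStructure:
    def test_toy_hairpin_has_two_records(self, params):
        s = parse_dotbracket("h", "GGGAAACCC", "(((...)))")
        energies = annotate_structure_energies(s, params)
        assert sorted(e.label for e in energies) == ["H1", "S1"]

    def test_ambiguous_base_flags_only_its_component(self, params):
        s = parse_dotbracket("n", "GGGANACCC", "(((...)))")
        energies = {e.label: e for e in annotate_structure_energies(s, params)}
        assert not energies["H1"].scorable
        assert energies["S1"].scorable

    def test_terms_sum_to_dg(self, params):
        rng = random.Random(77)
        for trial in range(50):
            seq, db = random_single_branch_structure(rng)
            s = parse_dotbracket(f"t{trial}", seq, db)
            for e in annotate_structure_energies(s, params):
                if e.scorable:
                    assert e.dg == pytest.approx(sum(e.terms.values()), abs=1e-9)


class TestReferenceEquivalence:
    def test_component_sums_match_reference_totals(self, params):
        """Independent-evaluator oracle: on random single-branch structures,
        the sum of per-component energies equals the full nearest-neighbor
        total (dangles disabled) within 0.01 kcal/mol."""
        rng = random.Random(2024)
        for trial in range(150):
            seq, db = random_single_branch_structure(rng, big_loops=True)
            s = parse_dotbracket(f"t{trial}", seq, db)
            mine = total_single_branch_dg(s, params)
            ref = reference_energy(seq, db)
            assert mine == pytest.approx(ref, abs=0.01), (seq, db)

    def test_palindromic_mirror_symmetry(self, params):
        """A structure and its reverse-complement mirror score identically:
        the nearest-neighbor model is strand-symmetric for such pairs."""
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        rng = random.Random(9)

        def wc_single_branch():
            # Watson-Crick pairs only: G:U maps to the non-canonical A:C
            # under reverse complementation, so wobble pairs are excluded
            seq = [rng.choice("ACGU") for _ in range(rng.randint(3, 6))]
            db = ["."] * len(seq)
            while len(seq) < 40:
                b5, b3 = rng.choice([("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")])
                gap5 = rng.randint(0, 3)
                gap3 = rng.randint(0, 3)
                seq = [b5] + [rng.choice("ACGU") for _ in range(gap5)] + seq \
                    + [rng.choice("ACGU") for _ in range(gap3)] + [b3]
                db = ["("] + ["."] * gap5 + db + ["."] * gap3 + [")"]
            return "".join(seq), "".join(db)

        for trial in range(30):
            seq, db = wc_single_branch()
            mirror_seq = "".join(comp[b] for b in reversed(seq))
            mirror_db = "".join(
                {"(": ")", ")": "(", ".": "."}[c] for c in reversed(db)
            )
            a = total_single_branch_dg(parse_dotbracket("a", seq, db), params)
            b = total_single_branch_dg(parse_dotbracket("b", mirror_seq, mirror_db), params)
            ref_a = reference_energy(seq, db)
            ref_b = reference_energy(mirror_seq, mirror_db)
            assert a == pytest.approx(ref_a, abs=0.01)
            assert b == pytest.approx(ref_b, abs=0.01)
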