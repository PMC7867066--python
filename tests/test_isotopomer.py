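import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracnmr import isotopomer as iso
from fracnmr.errors import (
    ExcludedResidueError,
    UndefinedProbabilityError,
    UnknownBondError,
    UnknownResidueError,
)
from fracnmr.isotopomer import (
    DEFAULT_ATTENUATION,
    STANDARD_RESIDUES,
    LabelingScheme,
    PathwayMap,
    classify_group,
    conditional_partner_label,
    enumerate_isotopomers,
    methyl_multiplet,
    p_joint_label,
    predict_cbca_ratio,
)

NON_GLYPRO = [aa for aa in STANDARD_RESIDUES if aa not in ("GLY", "PRO")]


def mc_bond_probability(aa, atom_a, atom_b, scheme, n=200_000, seed=0):
    """Monte-Carlo oracle: simulate per-molecule labeling directly.

    Independent of the analytic enumeration: draws molecule label states
    with a PRNG and counts coincidences.
    """
    rng = np.random.default_rng(seed)
    sites = PathwayMap.default().sites(aa)
    mols = sorted({s.molecule for s in sites})
    fam = {s.molecule: s.family for s in sites}
    ia = next(i for i, s in enumerate(sites) if s.atom == atom_a)
    ib = next(i for i, s in enumerate(sites) if s.atom == atom_b)

    q, a, p = scheme.p_full, scheme.nat_abund, scheme.p_site
    labels = np.zeros((n, len(sites)), dtype=bool)
    for m in mols:
        cols = [i for i, s in enumerate(sites) if s.molecule == m]
        full = rng.random(n) < q
        per_site = rng.random((n, len(cols))) < a
        state = full[:, None] | per_site
        if fam[m] in iso.TCA_FAMILIES:
            scrambled = rng.random(n) < scheme.scramble
            indep = rng.random((n, len(cols))) < p
            state = np.where(scrambled[:, None], indep, state)
        labels[:, cols] = state
    both = labels[:, ia] & labels[:, ib]
    joint = both.mean()
    cond = both.sum() / max(labels[:, ia].sum(), 1)
    return joint, cond


class TestEnumerate:
    def test_uniform_labeling_all_13c(self):
        s = LabelingScheme(1.0, nat_abund=0.0, isotopic_purity=1.0)
        d = enumerate_isotopomers("ALA", s)
        all_on = tuple([1] * len(d.atoms))
        assert d.probs[all_on] == pytest.approx(1.0)

    def test_unlabeled_limit(self):
        s = LabelingScheme(0.0, nat_abund=0.0)
        d = enumerate_isotopomers("ALA", s)
        assert d.probs[tuple([0] * len(d.atoms))] == pytest.approx(1.0)

    def test_val_joint_4_percent(self, scheme_clean):
        # Val Calpha and Cbeta come from two different pyruvates
        d = enumerate_isotopomers("VAL", scheme_clean)
        assert d.joint("CA", "CB") == pytest.approx(0.04)

    def test_unknown_residue(self, scheme_clean):
        with pytest.raises(UnknownResidueError):
            enumerate_isotopomers("XYZ", scheme_clean)

    @pytest.mark.parametrize("aa", STANDARD_RESIDUES)
    def test_normalization_all_residues(self, aa, scheme_default):
        d = enumerate_isotopomers(aa, scheme_default)
        assert sum(d.probs.values()) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(
        aa=st.sampled_from(STANDARD_RESIDUES),
        f=st.floats(0.0, 1.0),
        a=st.floats(0.0, 0.05),
        s=st.floats(0.0, 1.0),
    )
    def test_normalization_property(self, aa, f, a, s):
        d = enumerate_isotopomers(aa, LabelingScheme(f, a, s))
        assert sum(d.probs.values()) == pytest.approx(1.0, abs=1e-12)


class TestJointAndConditional:
    def test_ala_intact_carries_fraction(self, scheme_clean):
        assert p_joint_label("ALA", ("CA", "CB"), scheme_clean) == pytest.approx(0.2)

    def test_val_broken_squares_fraction(self, scheme_clean):
        assert p_joint_label("VAL", ("CA", "CB"), scheme_clean) == pytest.approx(0.04)

    @pytest.mark.parametrize("aa,bond", [("ALA", ("CA", "CB")),
                                         ("VAL", ("CB", "CG1")),
                                         ("GLU", ("CG", "CD"))])
    def test_uniform_limit_is_one(self, aa, bond):
        s = LabelingScheme(1.0, nat_abund=0.0, isotopic_purity=1.0)
        assert p_joint_label(aa, bond, s) == pytest.approx(1.0)

    def test_invalid_bond_lists_valid_ones(self, scheme_clean):
        with pytest.raises(UnknownBondError) as exc:
            p_joint_label("ALA", ("CA", "CG"), scheme_clean)
        assert ("CA", "CB") in exc.value.valid

    def test_conditional_intact_is_one(self, scheme_clean):
        assert conditional_partner_label("ALA", "CA", "CB", scheme_clean) == \
            pytest.approx(1.0)

    def test_conditional_across_precursors_is_f(self, scheme_clean):
        assert conditional_partner_label("VAL", "CA", "CB", scheme_clean) == \
            pytest.approx(0.2)

    def test_conditional_natural_abundance_independence(self):
        s = LabelingScheme(0.0, nat_abund=0.011)
        # at f=0 all carbons are independent natural-abundance draws
        assert conditional_partner_label("VAL", "CA", "CB", s) == pytest.approx(0.011)

    def test_conditional_undefined_at_zero_marginal(self):
        s = LabelingScheme(0.0, nat_abund=0.0)
        with pytest.raises(UndefinedProbabilityError):
            conditional_partner_label("ALA", "CA", "CB", s)

    @pytest.mark.parametrize("aa", STANDARD_RESIDUES)
    def test_oracle_equivalence_all_bonds(self, aa, scheme_default):
        # p_joint/conditional must agree with direct summation over the
        # enumerated distribution, bond by bond
        d = enumerate_isotopomers(aa, scheme_default)
        for bond in iso.CARBON_SKELETON[aa]:
            a, b = bond
            assert p_joint_label(aa, bond, scheme_default) == \
                pytest.approx(d.joint(a, b), abs=1e-12)
            assert conditional_partner_label(aa, a, b, scheme_default) == \
                pytest.approx(d.joint(a, b) / d.marginal(a), abs=1e-12)

    def test_joint_bounded_by_marginals(self, scheme_default):
        for aa in STANDARD_RESIDUES:
            d = enumerate_isotopomers(aa, scheme_default)
            for a, b in iso.CARBON_SKELETON[aa]:
                assert d.joint(a, b) <= min(d.marginal(a), d.marginal(b)) + 1e-12

    @pytest.mark.parametrize("aa,bond", [("VAL", ("CA", "CB")),
                                         ("ALA", ("CA", "CB")),
                                         ("GLU", ("CA", "CB")),
                                         ("ILE", ("CA", "CB"))])
    def test_monte_carlo_oracle(self, aa, bond, scheme_default):
        joint_mc, cond_mc = mc_bond_probability(aa, *bond, scheme_default)
        assert p_joint_label(aa, bond, scheme_default) == pytest.approx(
            joint_mc, abs=5e-3
        )
        assert conditional_partner_label(aa, bond[0], bond[1], scheme_default) == \
            pytest.approx(cond_mc, abs=2e-2)

    @settings(max_examples=20, deadline=None)
    @given(
        aa=st.sampled_from(["ALA", "VAL", "GLU", "ILE", "PHE"]),
        f1=st.floats(0.0, 1.0),
        f2=st.floats(0.0, 1.0),
    )
    def test_monotone_in_fraction(self, aa, f1, f2):
        lo, hi = sorted((f1, f2))
        bond = ("CA", "CB")
        p_lo = p_joint_label(aa, bond, LabelingScheme(lo))
        p_hi = p_joint_label(aa, bond, LabelingScheme(hi))
        assert p_hi >= p_lo - 1e-12


class TestPathwayMap:
    INTACT_CACB = ("ALA", "PHE", "TYR", "HIS", "SER", "CYS")
    BROKEN_CACB = ("VAL", "LEU", "ILE")

    def test_gly_has_no_cb(self):
        assert "CB" not in PathwayMap.default().carbons("GLY")

    @pytest.mark.parametrize("aa", INTACT_CACB)
    def test_cacb_intact(self, aa):
        assert frozenset(("CA", "CB")) in PathwayMap.default().intact_bonds(aa)

    @pytest.mark.parametrize("aa", BROKEN_CACB)
    def test_cacb_broken(self, aa):
        assert frozenset(("CA", "CB")) not in PathwayMap.default().intact_bonds(aa)

    def test_intact_bonds_subset_of_skeleton(self):
        pmap = PathwayMap.default()
        for aa in STANDARD_RESIDUES:
            skel = {frozenset(b) for b in iso.CARBON_SKELETON[aa]}
            assert pmap.intact_bonds(aa) <= skel

    def test_every_carbon_has_one_origin(self):
        pmap = PathwayMap.default()
        for aa in STANDARD_RESIDUES:
            atoms = pmap.carbons(aa)
            assert len(atoms) == len(set(atoms))


class TestRatioAndGroups:
    def test_val_over_ala_equals_fraction(self, scheme_clean):
        r_val = predict_cbca_ratio("VAL", scheme_clean, attenuation=1.0)
        r_ala = predict_cbca_ratio("ALA", scheme_clean, attenuation=1.0)
        assert r_val / r_ala == pytest.approx(0.2)

    def test_natural_abundance_floor(self):
        s = LabelingScheme(0.0, nat_abund=0.011)
        assert predict_cbca_ratio("ALA", s, attenuation=1.0) == pytest.approx(0.011)

    def test_gly_pro_raise(self, scheme_default):
        for aa in ("GLY", "PRO"):
            with pytest.raises(ExcludedResidueError):
                predict_cbca_ratio(aa, scheme_default)

    def test_group_ordering(self, scheme_default):
        high = [predict_cbca_ratio(aa, scheme_default)
                for aa in ("PHE", "TYR", "ALA", "HIS")]
        mid = [predict_cbca_ratio(aa, scheme_default) for aa in NON_GLYPRO
               if classify_group(aa) == iso.GROUP_TCA]
        low = [predict_cbca_ratio(aa, scheme_default)
               for aa in ("VAL", "LEU", "ILE")]
        assert min(high) > max(mid) > max(low)

    def test_default_calibration_bands(self, scheme_default):
        for aa in ("PHE", "TYR", "ALA", "HIS"):
            assert 0.75 <= predict_cbca_ratio(aa, scheme_default) <= 0.9
        for aa in ("VAL", "LEU", "ILE"):
            assert predict_cbca_ratio(aa, scheme_default) == pytest.approx(0.1, abs=0.05)

    @pytest.mark.parametrize("aa,expected", [
        ("PHE", "intact-high"), ("TYR", "intact-high"), ("ALA", "intact-high"),
        ("HIS", "intact-high"), ("VAL", "broken-low"), ("LEU", "broken-low"),
        ("ILE", "broken-low"), ("GLY", "excluded"), ("PRO", "excluded"),
        ("GLU", "intermediate-TCA"), ("MET", "intermediate-TCA"),
        ("LYS", "intermediate-TCA"),
    ])
    def test_classify_group(self, aa, expected):
        assert classify_group(aa) == expected

    def test_classify_group_covers_everything(self):
        for aa in STANDARD_RESIDUES:
            assert classify_group(aa) in (
                iso.GROUP_INTACT, iso.GROUP_TCA, iso.GROUP_BROKEN, iso.GROUP_EXCLUDED
            )


class TestMethylMultiplet:
    def test_val_pro_r_doublet(self, scheme_clean):
        m = methyl_multiplet("VAL", "pro-R", scheme_clean)
        assert m["doublet"] == pytest.approx(1.0)

    def test_val_pro_s_mostly_singlet(self, scheme_clean):
        m = methyl_multiplet("VAL", "pro-S", scheme_clean)
        assert m["doublet"] == pytest.approx(0.2)
        assert m["singlet"] + m["doublet"] == pytest.approx(1.0)

    def test_leu_uniform_all_doublet(self):
        s = LabelingScheme(1.0, nat_abund=0.0, isotopic_purity=1.0)
        for methyl in ("pro-R", "pro-S"):
            assert methyl_multiplet("LEU", methyl, s)["doublet"] == pytest.approx(1.0)

    def test_leu_pro_s_tracks_fraction(self, scheme_clean):
        assert methyl_multiplet("LEU", "pro-S", scheme_clean)["doublet"] == \
            pytest.approx(0.2)

    def test_other_residues_rejected(self, scheme_clean):
        with pytest.raises(ExcludedResidueError):
            methyl_multiplet("ILE", "pro-R", scheme_clean)


class TestScheme:
    @pytest.mark.parametrize("field,value", [
        ("f_labeled", -0.1), ("f_labeled", 1.1), ("nat_abund", 2.0),
        ("scramble", -1.0), ("isotopic_purity", 1.5),
    ])
    def test_out_of_range_rejected(self, field, value):
        kwargs = {"f_labeled": 0.2, field: value}
        with pytest.raises(ValueError):
            LabelingScheme(**kwargs)

    def test_limits(self):
        up = LabelingScheme(1.0, nat_abund=0.0, isotopic_purity=1.0)
        down = LabelingScheme(0.0, nat_abund=0.0)
        for aa in ("ALA", "VAL", "TRP"):
            d_up = enumerate_isotopomers(aa, up)
            d_down = enumerate_isotopomers(aa, down)
            for atom in d_up.atoms:
                assert d_up.marginal(atom) == pytest.approx(1.0)
                assert d_down.marginal(atom) == pytest.approx(0.0)

    def test_scramble_zero_keeps_tca_bonds(self):
        s = LabelingScheme(0.2, nat_abund=0.0, scramble=0.0, isotopic_purity=1.0)
        assert conditional_partner_label("GLU", "CA", "CB", s) == pytest.approx(1.0)

    def test_scramble_one_breaks_tca_bonds(self):
        s = LabelingScheme(0.2, nat_abund=0.0, scramble=1.0, isotopic_purity=1.0)
        assert conditional_partner_label("GLU", "CA", "CB", s) == pytest.approx(0.2)
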