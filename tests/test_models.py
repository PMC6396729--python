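"""Genotypes, fitness tables, and Mendelian inheritance with viability."""

from __future__ import annotations

import math
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitobarrier import (
    Genotype,
    Model,
    ModelParams,
    Sex,
    fitness,
    migrant_genotype,
    offspring_distribution,
    resident_genotype,
)
from conftest import all_genotypes

UNIT = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def geno(model, label_args):
    """Terse genotype constructor: geno("A", (1, 2, "F")) -> mt1 N2 female."""
    model = Model(model)
    if model is Model.A:
        cyto, n, sex = label_args
        return Genotype(model=model, sex=Sex(sex), cyto=cyto, alleles=((n,),))
    if model is Model.B:
        a, b = label_args
        return Genotype(model=model, sex=None, cyto=None, alleles=((a,), (b,)))
    if model is Model.C:
        cyto, nn, sex = label_args
        return Genotype(model=model, sex=Sex(sex), cyto=cyto, alleles=(tuple(sorted(nn)),))
    aa, bb = label_args
    return Genotype(
        model=model, sex=None, cyto=None,
        alleles=(tuple(sorted(aa)), tuple(sorted(bb))),
    )


class TestEndpoints:
    @pytest.mark.parametrize(
        "model,sex,expected_label",
        [
            (Model.A, Sex.FEMALE, "mt1 N1 F"),
            (Model.B, None, "A1 B1"),
            (Model.C, Sex.MALE, "mt1 N1N1 M"),
            (Model.D, None, "A1A1 B1B1"),
        ],
    )
    def test_resident_is_pure_index1_strain(self, model, sex, expected_label):
        assert resident_genotype(model, sex).label == expected_label

    @pytest.mark.parametrize(
        "model,sex,expected_label",
        [
            (Model.A, Sex.MALE, "mt2 N2 M"),
            (Model.B, None, "A2 B2"),
            (Model.C, Sex.FEMALE, "mt2 N2N2 F"),
            (Model.D, None, "A2A2 B2B2"),
        ],
    )
    def test_migrant_is_pure_index2_strain(self, model, sex, expected_label):
        assert migrant_genotype(model, sex).label == expected_label

    def test_sexed_request_for_unsexed_model_rejected(self):
        with pytest.raises(ValueError):
            resident_genotype(Model.B, Sex.FEMALE)
        with pytest.raises(ValueError):
            migrant_genotype(Model.A)  # sex required


class TestFitnessTables:
    """Cell-by-cell checks of the four models' viability tables."""

    @pytest.mark.parametrize(
        "params,g,expected",
        [
            # haploid MtNI: hybrids mt1N2 -> 1-s1, mt2N1 -> 1-s2
            (ModelParams(model="A", s1=0.3, s2=0.9), ("A", (1, 2, "F")), 0.7),
            (ModelParams(model="A", s1=0.3, s2=0.9), ("A", (2, 1, "M")), 0.1),
            (ModelParams(model="A", s1=1.0, s2=1.0), ("A", (1, 1, "F")), 1.0),
            (ModelParams(model="A", s1=1.0, s2=1.0), ("A", (2, 2, "M")), 1.0),
            # haploid NNI: A2B1 -> 1-sA, A1B2 -> 1-sB
            (ModelParams(model="B", sA=0.25, sB=0.5), ("B", (2, 1)), 0.75),
            (ModelParams(model="B", sA=0.25, sB=0.5), ("B", (1, 2)), 0.5),
            (ModelParams(model="B", sA=1.0, sB=1.0), ("B", (2, 2)), 1.0),
            # diploid MtNI: heterozygotes 1-h1*s1 / 1-h2*s2, homozygotes 1-s
            (ModelParams(model="C", h1=0.0, s1=0.9), ("C", (1, (1, 2), "F")), 1.0),
            (ModelParams(model="C", h1=0.5, s1=0.8), ("C", (1, (1, 2), "M")), 0.6),
            (ModelParams(model="C", s1=0.9), ("C", (1, (2, 2), "F")), 0.1),
            (ModelParams(model="C", h2=1.0, s2=0.4), ("C", (2, (1, 2), "F")), 0.6),
            (ModelParams(model="C", s2=0.4), ("C", (2, (1, 1), "M")), 0.6),
            (ModelParams(model="C", s1=1.0, s2=1.0), ("C", (2, (2, 2), "F")), 1.0),
            # diploid NNI asymmetric: A1A1 row all fit, double het 1-hA*sA,
            # A2A2B1B1 -> 1-sA, A1A2B2B2 fit
            (ModelParams(model="D", hA=0.5, sA=0.8), ("D", ((1, 1), (2, 2))), 1.0),
            (ModelParams(model="D", hA=0.5, sA=0.8), ("D", ((1, 2), (1, 2))), 0.6),
            (ModelParams(model="D", hA=0.5, sA=0.8), ("D", ((1, 2), (2, 2))), 1.0),
            (ModelParams(model="D", hA=0.5, sA=0.8), ("D", ((2, 2), (1, 1))), 0.2),
            (ModelParams(model="D", hA=0.5, sA=0.8), ("D", ((2, 2), (1, 2))), 0.6),
            # diploid NNI symmetric: double het 1-h*s, double homozygous
            # hybrids 1-s, single het 1-h*s
            (
                ModelParams(model="D", d_variant="symmetric", h=0.5, s=0.8),
                ("D", ((1, 2), (1, 2))),
                0.6,
            ),
            (
                ModelParams(model="D", d_variant="symmetric", h=0.5, s=0.8),
                ("D", ((1, 1), (2, 2))),
                0.2,
            ),
            (
                ModelParams(model="D", d_variant="symmetric", h=0.5, s=0.8),
                ("D", ((1, 1), (1, 2))),
                0.6,
            ),
            (
                ModelParams(model="D", d_variant="symmetric", h=1.0, s=1.0),
                ("D", ((2, 2), (2, 2))),
                1.0,
            ),
        ],
    )
    def test_table_cells(self, params, g, expected):
        assert fitness(params, geno(*g)) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("model", list(Model))
    def test_no_selection_means_uniform_fitness(self, model):
        params = ModelParams(model=model)
        for g in all_genotypes(model):
            assert fitness(params, g) == 1.0

    @pytest.mark.parametrize("model", [Model.A, Model.C])
    def test_fitness_is_sex_independent(self, model):
        params = ModelParams(model=model, s1=0.37, s2=0.81, h1=0.2, h2=0.9)
        by_class = {}
        for g in all_genotypes(model):
            key = (g.cyto, g.alleles)
            by_class.setdefault(key, set()).add(fitness(params, g))
        assert all(len(vals) == 1 for vals in by_class.values())

    def test_genotype_model_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fitness(ModelParams(model="A"), resident_genotype(Model.B))


class TestOffspringDistribution:
    def test_migrant_mother_backcross_haploid_mtni(self):
        # mother mt2 N2 x resident father: half the offspring keep N2, all
        # keep the maternal mt2; the mt2 N1 class pays viability 1-s2
        params = ModelParams(model="A", s1=0.3, s2=0.4)
        mother = geno("A", (2, 2, "F"))
        father = geno("A", (1, 1, "M"))
        dist = offspring_distribution(params, mother, father)
        expected = {
            "mt2 N1 M": 0.25 * (1 - 0.4),
            "mt2 N2 M": 0.25,
            "mt2 N1 F": 0.25 * (1 - 0.4),
            "mt2 N2 F": 0.25,
        }
        assert {g.label: w for g, w in dist.items()} == pytest.approx(expected)

    def test_migrant_backcross_haploid_nni(self):
        params = ModelParams(model="B", sA=0.6, sB=0.2)
        dist = offspring_distribution(params, geno("B", (2, 2)), geno("B", (1, 1)))
        expected = {
            "A1 B1": 0.25,
            "A1 B2": 0.25 * (1 - 0.2),
            "A2 B1": 0.25 * (1 - 0.6),
            "A2 B2": 0.25,
        }
        assert {g.label: w for g, w in dist.items()} == pytest.approx(expected)

    def test_male_passes_no_mitochondria(self):
        # father mt2 N1 x resident mother: all offspring carry the maternal
        # mt1 and, having lost N2 already, are pure residents
        params = ModelParams(model="A", s1=0.3, s2=0.4)
        dist = offspring_distribution(
            params, geno("A", (2, 1, "M")), geno("A", (1, 1, "F"))
        )
        assert {g.label: w for g, w in dist.items()} == pytest.approx(
            {"mt1 N1 M": 0.5, "mt1 N1 F": 0.5}
        )

    def test_diploid_f1_backcross_segregates_all_four_classes(self):
        params = ModelParams(model="D", hA=0.5, sA=0.8)
        f1 = geno("D", ((1, 2), (1, 2)))
        dist = offspring_distribution(params, f1, geno("D", ((1, 1), (1, 1))))
        expected = {
            "A1A1 B1B1": 0.25,
            "A1A1 B1B2": 0.25,
            "A1A2 B1B1": 0.25 * (1 - 0.4),
            "A1A2 B1B2": 0.25 * (1 - 0.4),
        }
        assert {g.label: w for g, w in dist.items()} == pytest.approx(expected)

    def test_same_sex_cross_rejected(self):
        params = ModelParams(model="A")
        with pytest.raises(ValueError):
            offspring_distribution(params, geno("A", (1, 1, "F")), geno("A", (2, 2, "F")))

    @pytest.mark.parametrize("model", list(Model))
    def test_mendelian_weights_sum_to_one_without_selection(self, model):
        params = ModelParams(model=model)  # all s = 0: pure Mendelian shares
        genos = all_genotypes(model)
        for parent, mate in product(genos, genos):
            if model.sexed and parent.sex == mate.sex:
                continue
            total = sum(offspring_distribution(params, parent, mate).values())
            assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("model", [Model.A, Model.C])
    def test_cytotype_is_strictly_maternal(self, model):
        params = ModelParams(model=model, s1=0.5, s2=0.5, h1=0.5, h2=0.5)
        genos = all_genotypes(model)
        for parent, mate in product(genos, genos):
            if parent.sex == mate.sex:
                continue
            mother = parent if parent.sex is Sex.FEMALE else mate
            for child in offspring_distribution(params, parent, mate):
                assert child.cyto == mother.cyto

    @pytest.mark.parametrize("model", [Model.A, Model.C])
    def test_offspring_sex_ratio_is_even(self, model):
        params = ModelParams(model=model, s1=0.3, s2=0.7, h1=0.4, h2=0.6)
        mother = migrant_genotype(model, Sex.FEMALE)
        father = resident_genotype(model, Sex.MALE)
        dist = offspring_distribution(params, mother, father)
        by_sex = {Sex.FEMALE: 0.0, Sex.MALE: 0.0}
        for child, w in dist.items():
            by_sex[child.sex] += w
        assert by_sex[Sex.FEMALE] == pytest.approx(by_sex[Sex.MALE], abs=1e-15)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(sA=UNIT, sB=UNIT)
    def test_two_locus_gametes_equiprobable(self, sA, sB):
        # free recombination: the F1 backcross produces all four haplotypes
        # in equal Mendelian shares regardless of selection strength
        params = ModelParams(model="B", sA=sA, sB=sB)
        dist = offspring_distribution(
            params, migrant_genotype(Model.B), resident_genotype(Model.B)
        )
        shares = {
            g.label: w / fitness(params, g) for g, w in dist.items() if fitness(params, g) > 0
        }
        for share in shares.values():
            assert math.isclose(share, 0.25, abs_tol=1e-12)


class TestParamValidation:
    def test_out_of_range_coefficients_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(model="A", s1=1.5)
        with pytest.raises(ValueError):
            ModelParams(model="C", h2=-0.1)
        with pytest.raises(ValueError):
            ModelParams(model="D", d_variant="bogus")

    def test_unordered_diploid_alleles_rejected(self):
        with pytest.raises(ValueError):
            Genotype(model=Model.C, sex=Sex.FEMALE, cyto=1, alleles=((2, 1),))
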