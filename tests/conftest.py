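"""Shared helpers: genotype enumeration and random parameter draws."""

from __future__ import annotations

from itertools import combinations_with_replacement, product

import numpy as np
import pytest

from mitobarrier import Genotype, Model, ModelParams, Sex


def all_genotypes(model: Model) -> list[Genotype]:
    """Every genetic class of a model (8 for A, 4 for B, 12 for C, 9 for D)."""
    model = Model(model)
    per_locus = list(
        combinations_with_replacement((1, 2), model.ploidy)
    )  # sorted tuples
    allele_sets = list(product(per_locus, repeat=len(model.loci)))
    out = []
    if model.sexed:
        for cyto, alleles, sex in product((1, 2), allele_sets, (Sex.FEMALE, Sex.MALE)):
            out.append(Genotype(model=model, sex=sex, cyto=cyto, alleles=alleles))
    else:
        for alleles in allele_sets:
            out.append(Genotype(model=model, sex=None, cyto=None, alleles=alleles))
    return out


def random_params(model: Model, rng: np.random.Generator) -> ModelParams:
    """Uniform random draw of the coefficients that belong to one model."""
    u = rng.uniform
    model = Model(model)
    if model is Model.A:
        return ModelParams(model=model, s1=u(), s2=u(), mf=u())
    if model is Model.B:
        return ModelParams(model=model, sA=u(), sB=u())
    if model is Model.C:
        return ModelParams(model=model, s1=u(), s2=u(), h1=u(), h2=u(), mf=u())
    if rng.integers(2) == 0:
        return ModelParams(model=model, sA=u(), hA=u(), d_variant="asymmetric")
    return ModelParams(model=model, s=u(), h=u(), d_variant="symmetric")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20190213)
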