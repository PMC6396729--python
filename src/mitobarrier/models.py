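"""Genetic model definitions: genotypes, fitness tables, and inheritance.

Four mainland-island incompatibility models are supported, differing in
ploidy and in whether the incompatibility involves the maternally inherited
cytotype (mitochondrial haplotype) or two nuclear loci:

* ``Model.A`` — haploid mito-nuclear incompatibility (MtNI).  One nuclear
  locus N with alleles N1/N2 and a cytotype mt1/mt2.  Sexed, because
  mitochondria pass only through the maternal line.
* ``Model.B`` — haploid nuclear-nuclear incompatibility (NNI).  Two
  unlinked nuclear loci A and B.  Unsexed: both sexes have identical
  fitness and inheritance, so they need not be distinguished.
* ``Model.C`` — diploid MtNI (one nuclear locus, cytotype, sexed).
* ``Model.D`` — diploid NNI (two nuclear loci, unsexed), in an
  *asymmetric* variant (only A2-carrying combinations with B1 suffer;
  the classic Dobzhansky-Muller configuration) or a *symmetric* variant
  (both mixed combinations suffer equally).

Island residents carry only index-1 alleles (and mt1); mainland migrants
carry only index-2 alleles (and mt2).  Pure strains are equally fit
(relative fitness 1); hybrid genotypes lose viability according to the
model's fitness table.

The one-generation kernel :func:`offspring_distribution` returns, for a
given cross, each offspring class together with its *fitness component*:
the Mendelian probability of the class multiplied by the viability of its
genotype.  This is the quantity the fitness-graph method places on its
edges, and it is also the building block of the forward recursion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from itertools import product
from typing import Iterator

__all__ = [
    "Model",
    "Sex",
    "Genotype",
    "ModelParams",
    "resident_genotype",
    "migrant_genotype",
    "fitness",
    "offspring_distribution",
]


class Model(str, Enum):
    """The four incompatibility models."""

    A = "A"  #: haploid mito-nuclear
    B = "B"  #: haploid nuclear-nuclear
    C = "C"  #: diploid mito-nuclear
    D = "D"  #: diploid nuclear-nuclear

    @property
    def sexed(self) -> bool:
        """Whether males and females must be distinguished (MtNI models)."""
        return self in (Model.A, Model.C)

    @property
    def ploidy(self) -> int:
        return 1 if self in (Model.A, Model.B) else 2

    @property
    def loci(self) -> tuple[str, ...]:
        """Names of the nuclear incompatibility loci."""
        return ("N",) if self in (Model.A, Model.C) else ("A", "B")


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"

    @property
    def other(self) -> "Sex":
        return Sex.MALE if self is Sex.FEMALE else Sex.FEMALE


@dataclass(frozen=True, order=True)
class Genotype:
    """A genetic class: sex, cytotype and nuclear alleles of one model.

    ``alleles`` holds one sorted tuple of allele indices (1 or 2) per
    nuclear locus, in the order of ``model.loci``; diploid genotypes are
    unordered (N1N2 and N2N1 are the same class) and parental origin is
    not tracked.  ``cyto`` is the mitochondrial haplotype index for the
    MtNI models and ``None`` for the NNI models; ``sex`` is ``None`` for
    the unsexed models.
    """

    model: Model
    sex: Sex | None
    cyto: int | None
    alleles: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        m = self.model
        if m.sexed:
            if self.sex is None:
                raise ValueError(f"model {m.value} genotypes are sexed")
            if self.cyto not in (1, 2):
                raise ValueError(f"model {m.value} genotypes carry a cytotype")
        else:
            if self.sex is not None:
                raise ValueError(f"model {m.value} does not distinguish sexes")
            if self.cyto is not None:
                raise ValueError(f"model {m.value} has no cytotype")
        if len(self.alleles) != len(m.loci):
            raise ValueError(f"model {m.value} has {len(m.loci)} nuclear loci")
        for locus, a in zip(m.loci, self.alleles):
            if len(a) != m.ploidy:
                raise ValueError(f"locus {locus}: expected {m.ploidy} allele(s)")
            if tuple(sorted(a)) != a:
                raise ValueError(f"locus {locus}: alleles must be sorted")
            if not all(x in (1, 2) for x in a):
                raise ValueError(f"locus {locus}: alleles are indexed 1 or 2")

    def count(self, locus_index: int, allele: int) -> int:
        """Dosage of ``allele`` at the given nuclear locus."""
        return self.alleles[locus_index].count(allele)

    @property
    def label(self) -> str:
        """Canonical string, e.g. ``"mt2 N1N2 F"`` or ``"A1A2 B1B1"``."""
        parts = []
        if self.cyto is not None:
            parts.append(f"mt{self.cyto}")
        for locus, a in zip(self.model.loci, self.alleles):
            parts.append("".join(f"{locus}{x}" for x in a))
        if self.sex is not None:
            parts.append(self.sex.value)
        return " ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def _uniform_genotype(model: Model, index: int, sex: Sex | None) -> Genotype:
    if model.sexed:
        if sex is None:
            raise ValueError(f"model {model.value} requires a sex")
        sex = Sex(sex)
        cyto: int | None = index
    else:
        if sex is not None:
            raise ValueError(f"model {model.value} genotypes are unsexed")
        cyto = None
    alleles = tuple((index,) * model.ploidy for _ in model.loci)
    return Genotype(model=model, sex=sex, cyto=cyto, alleles=alleles)


def resident_genotype(model: Model, sex: Sex | None = None) -> Genotype:
    """Pure island strain: all index-1 alleles (mt1 N1…, A1…B1…)."""
    return _uniform_genotype(Model(model), 1, sex)


def migrant_genotype(model: Model, sex: Sex | None = None) -> Genotype:
    """Pure mainland strain: all index-2 alleles (mt2 N2…, A2…B2…)."""
    return _uniform_genotype(Model(model), 2, sex)


_D_VARIANTS = ("asymmetric", "symmetric")


@dataclass(frozen=True)
class ModelParams:
    """Selection, dominance and migrant-sex-ratio parameters of one model.

    Only the coefficients belonging to ``model`` are consulted:

    ======= =====================================================
    Model A ``s1`` (mt1 with N2), ``s2`` (mt2 with N1), ``mf``
    Model B ``sA`` (A2 with B1), ``sB`` (A1 with B2)
    Model C ``s1, s2`` and heterozygote dominance ``h1, h2``, ``mf``
    Model D ``d_variant``; asymmetric: ``sA, hA``; symmetric: ``s, h``
    ======= =====================================================

    ``mf`` is the fraction of females among migrants; it matters only for
    the sexed MtNI models A and C.  All coefficients must lie in [0, 1].
    """

    model: Model
    s1: float = 0.0
    s2: float = 0.0
    h1: float = 0.0
    h2: float = 0.0
    sA: float = 0.0
    sB: float = 0.0
    hA: float = 0.0
    s: float = 0.0
    h: float = 0.0
    mf: float = 0.5
    d_variant: str = "asymmetric"

    def __post_init__(self) -> None:
        object.__setattr__(self, "model", Model(self.model))
        for name in ("s1", "s2", "h1", "h2", "sA", "sB", "hA", "s", "h", "mf"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val!r} outside [0, 1]")
        if self.d_variant not in _D_VARIANTS:
            raise ValueError(f"d_variant must be one of {_D_VARIANTS}")


def fitness(params: ModelParams, g: Genotype) -> float:
    """Relative viability of genotype ``g`` under the model's fitness table.

    Fitness is sex-independent; residents and pure migrants have fitness 1.
    """
    if g.model is not params.model:
        raise ValueError(
            f"genotype of model {g.model.value} passed to model "
            f"{params.model.value} parameters"
        )
    m = params.model
    if m is Model.A:
        n = g.alleles[0][0]
        if g.cyto == 1 and n == 2:
            return 1.0 - params.s1
        if g.cyto == 2 and n == 1:
            return 1.0 - params.s2
        return 1.0
    if m is Model.B:
        a, b = g.alleles[0][0], g.alleles[1][0]
        if a == 2 and b == 1:
            return 1.0 - params.sA
        if a == 1 and b == 2:
            return 1.0 - params.sB
        return 1.0
    if m is Model.C:
        n2 = g.count(0, 2)  # dosage of N2
        if g.cyto == 1:
            return (1.0, 1.0 - params.h1 * params.s1, 1.0 - params.s1)[n2]
        return (1.0 - params.s2, 1.0 - params.h2 * params.s2, 1.0)[n2]
    # Model D
    a2, b2 = g.count(0, 2), g.count(1, 2)
    if params.d_variant == "asymmetric":
        if a2 == 0:
            return 1.0
        if a2 == 1:
            return 1.0 if b2 == 2 else 1.0 - params.hA * params.sA
        return (1.0 - params.sA, 1.0 - params.hA * params.sA, 1.0)[b2]
    # symmetric: pure strains fit, double homozygous hybrids 1-s,
    # everything carrying a heterozygous locus 1-h*s
    if (a2, b2) in ((0, 0), (2, 2)):
        return 1.0
    if (a2, b2) in ((0, 2), (2, 0)):
        return 1.0 - params.s
    return 1.0 - params.h * params.s


def _gametes(g: Genotype) -> Iterator[tuple[tuple[int, ...], float]]:
    """Haplotypes produced by ``g`` with probabilities (free recombination).

    Yields ``(alleles_per_locus, prob)``; cytotype transmission is handled
    by the caller (strictly maternal).  Haploid parents produce their own
    haplotype with probability 1; diploids segregate each locus
    independently.
    """
    per_locus = []
    for a in g.alleles:
        opts = sorted(set(a))
        per_locus.append([(x, a.count(x) / len(a)) for x in opts])
    for combo in product(*per_locus):
        p = 1.0
        for _, pr in combo:
            p *= pr
        yield tuple(x for x, _ in combo), p


def offspring_distribution(
    params: ModelParams, parent: Genotype, mate: Genotype
) -> dict[Genotype, float]:
    """Offspring classes of a cross, weighted by Mendelian share × viability.

    The returned weights are *fitness components*: the probability of each
    offspring class (cytotype strictly maternal, free recombination among
    all nuclear loci, and — in sexed models — a 1:1 sex ratio splitting
    each Mendelian class equally into sons and daughters) multiplied by
    the viability of the offspring genotype.  They therefore sum to the
    mean offspring viability of the cross, which is 1 only when no
    selected genotype is produced.

    In the haploid models the (transient diploid) zygote undergoes meiosis,
    so each offspring locus carries either parent's allele with equal
    probability; in the diploid models each parent contributes one allele
    per locus.
    """
    model = params.model
    for g in (parent, mate):
        if g.model is not model:
            raise ValueError("parent genotypes must belong to params.model")
    if model.sexed:
        if parent.sex == mate.sex:
            raise ValueError("sexed models require an opposite-sex cross")
        mother, father = (parent, mate) if parent.sex is Sex.FEMALE else (mate, parent)
    else:
        mother, father = parent, mate  # cytotype irrelevant

    dist: dict[Genotype, float] = {}
    for egg, p_egg in _gametes(mother):
        for sperm, p_sperm in _gametes(father):
            p = p_egg * p_sperm
            if model.ploidy == 1:
                # meiosis of the zygote: each locus from either gamete
                locus_opts = [sorted({(e,), (s,)}) for e, s in zip(egg, sperm)]
                for combo in product(*locus_opts):
                    pr = p
                    for opt, (e, s) in zip(combo, zip(egg, sperm)):
                        if (e,) != (s,):
                            pr *= 0.5
                    _accumulate(dist, params, model, mother, tuple(combo), pr)
            else:
                alleles = tuple(
                    tuple(sorted((e, s))) for e, s in zip(egg, sperm)
                )
                _accumulate(dist, params, model, mother, alleles, p)
    return dist


def _accumulate(
    dist: dict[Genotype, float],
    params: ModelParams,
    model: Model,
    mother: Genotype,
    alleles: tuple[tuple[int, ...], ...],
    prob: float,
) -> None:
    cyto = mother.cyto if model.sexed else None
    if model.sexed:
        sexes: tuple[Sex | None, ...] = (Sex.FEMALE, Sex.MALE)
        prob *= 0.5
    else:
        sexes = (None,)
    for sex in sexes:
        child = Genotype(model=model, sex=sex, cyto=cyto, alleles=alleles)
        w = prob * fitness(params, child)
        if w or child not in dist:
            dist[child] = dist.get(child, 0.0) + w
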