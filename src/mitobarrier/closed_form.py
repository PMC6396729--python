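"""Closed-form migrant reproductive values for the four models.

These are the analytic solutions of the fitness-graph linear systems,
implemented independently of the graph solver so they can serve as an
oracle for it (and for the forward recursion's weak-migration limit).

Notation: v is normalised so residents have v = 1; the gene flow factor
equals the (sex-weighted) migrant v.  For the diploid NNI model the
*asymmetric* variant is the classic Dobzhansky-Muller configuration in
which only A2 combined with B1 is deleterious; the *symmetric* variant
penalises both mixed combinations.  The two variants give

    asymmetric:  v = (1 - hA sA) / (1 + hA sA)
    symmetric:   v = (1 - h s)(3 - h s) / ((1 + h s)(3 + h s))

(the asymmetric value coincides with the male-migrant value of the
diploid MtNI model, with hA sA in place of h1 s1).
"""

from __future__ import annotations

from .models import Model, ModelParams

__all__ = [
    "v_model_a",
    "v_model_b",
    "v_model_c",
    "v_model_d",
    "migrant_average",
]


def _check_unit(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name}={val!r} outside [0, 1]")


def v_model_a(s1: float, s2: float) -> tuple[float, float]:
    """Haploid MtNI migrant reproductive values ``(v_male, v_female)``.

    v_male = 1/(1+s1);
    v_female = (3 + 2 s1 - s2 - 2 s1 s2) / (3 (1+s1)(1+s2)).
    """
    _check_unit(s1=s1, s2=s2)
    v_male = 1.0 / (1.0 + s1)
    v_female = (3.0 + 2.0 * s1 - s2 - 2.0 * s1 * s2) / (3.0 * (1.0 + s1) * (1.0 + s2))
    return v_male, v_female


def v_model_b(sA: float, sB: float) -> tuple[float, float, float]:
    """Haploid NNI reproductive values ``(v_A1B2, v_A2B1, v_A2B2)``."""
    _check_unit(sA=sA, sB=sB)
    v_a1b2 = 1.0 / (1.0 + sB)
    v_a2b1 = 1.0 / (1.0 + sA)
    v_a2b2 = (3.0 + sA + sB - sA * sB) / (3.0 * (1.0 + sA + sB + sA * sB))
    return v_a1b2, v_a2b1, v_a2b2


def v_model_c(s1: float, s2: float, h1: float, h2: float) -> tuple[float, float]:
    """Diploid MtNI migrant reproductive values ``(v_male, v_female)``.

    v_male = (1 - h1 s1)/(1 + h1 s1);
    v_female = (1 - h2 s2)(3 + s2 + h1 s1 (1 - s2))
               / ((1 + h1 s1)(1 + s2)(3 + h2 s2)).
    """
    _check_unit(s1=s1, s2=s2, h1=h1, h2=h2)
    x = h1 * s1
    v_male = (1.0 - x) / (1.0 + x)
    v_female = ((1.0 - h2 * s2) * (3.0 + s2 + x * (1.0 - s2))) / (
        (1.0 + x) * (1.0 + s2) * (3.0 + h2 * s2)
    )
    return v_male, v_female


def v_model_d(variant: str, s: float, h: float) -> float:
    """Diploid NNI migrant reproductive value for the chosen variant.

    ``variant`` is ``"asymmetric"`` (coefficients sA, hA) or
    ``"symmetric"`` (coefficients s, h); either way the value depends on
    the parameters only through the product h*s.
    """
    _check_unit(s=s, h=h)
    y = h * s
    if variant == "asymmetric":
        return (1.0 - y) / (1.0 + y)
    if variant == "symmetric":
        return ((1.0 - y) * (3.0 - y)) / ((1.0 + y) * (3.0 + y))
    raise ValueError(f"unknown Model D variant {variant!r}")


def migrant_average(params: ModelParams) -> float:
    """Sex-weighted average migrant reproductive value (gene flow factor).

    (1 - mf) v_male + mf v_female for the sexed MtNI models; the single
    migrant value for the unsexed NNI models.
    """
    m = params.model
    if m is Model.A:
        vm, vf = v_model_a(params.s1, params.s2)
        return (1.0 - params.mf) * vm + params.mf * vf
    if m is Model.B:
        return v_model_b(params.sA, params.sB)[2]
    if m is Model.C:
        vm, vf = v_model_c(params.s1, params.s2, params.h1, params.h2)
        return (1.0 - params.mf) * vm + params.mf * vf
    if params.d_variant == "asymmetric":
        return v_model_d("asymmetric", params.sA, params.hA)
    return v_model_d("symmetric", params.s, params.h)
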