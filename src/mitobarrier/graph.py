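"""Fitness graph construction and reproductive values of migrant classes.

Under weak migration, a migrant lineage backcrosses exclusively into the
resident population.  The genetic classes it can pass through then form a
directed graph — the *fitness graph* — whose edge from class X to class Y
carries the expected relative number of adult Y offspring per X parent
when X mates with a resident (Mendelian share × offspring viability).

A neutral allele carried by a migrant moves through these classes like an
allele through age or sex classes, so each class has a *reproductive
value* v: its long-term contribution to the island gene pool at the
neutral marker, normalised so that residents have v = 1.  The values
satisfy the linear system

    v(X) = sum_Y  w(X -> Y) v(Y),        v(resident) = 1,

whose unique solution is obtained here by a dense direct solve (the
systems have at most ten unknowns).  The sex-weighted average migrant
reproductive value equals the gene flow factor m_e / m in the weak-
migration limit.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .models import (
    Genotype,
    Model,
    ModelParams,
    Sex,
    migrant_genotype,
    offspring_distribution,
    resident_genotype,
)

__all__ = [
    "FitnessGraph",
    "GraphSolveError",
    "build_graph",
    "reproductive_values",
    "gene_flow_factor",
    "to_dot",
]


class GraphSolveError(RuntimeError):
    """The reproductive-value system is singular for these parameters."""


@dataclass(frozen=True)
class FitnessGraph:
    """Directed weighted graph over the migrant lineage's genetic classes.

    ``edges[src]`` maps each target class to the aggregated fitness
    component of ``src``'s offspring in that class when ``src`` is crossed
    to the opposite-sex resident.  Resident classes carry no out-edges;
    their reproductive value is fixed to 1 as a boundary condition.
    """

    params: ModelParams
    nodes: tuple[Genotype, ...]
    edges: dict[Genotype, dict[Genotype, float]]
    residents: tuple[Genotype, ...]
    migrants: tuple[Genotype, ...]


def _residents(model: Model) -> tuple[Genotype, ...]:
    if model.sexed:
        return (resident_genotype(model, Sex.FEMALE), resident_genotype(model, Sex.MALE))
    return (resident_genotype(model),)


def _migrants(model: Model) -> tuple[Genotype, ...]:
    if model.sexed:
        return (migrant_genotype(model, Sex.FEMALE), migrant_genotype(model, Sex.MALE))
    return (migrant_genotype(model),)


def build_graph(params: ModelParams) -> FitnessGraph:
    """Breadth-first closure of the migrant classes under backcrossing.

    Nodes are discovered through Mendelian-possible offspring, ignoring
    the viability weights, so classes that become unreachable only because
    a fitness hits zero at a parameter corner are retained (their solved
    reproductive value simply stops contributing to upstream classes).
    """
    model = params.model
    residents = _residents(model)
    migrants = _migrants(model)
    edges: dict[Genotype, dict[Genotype, float]] = {}
    seen: set[Genotype] = set(residents)
    queue = deque(migrants)
    seen.update(migrants)
    while queue:
        g = queue.popleft()
        if g in residents:
            continue
        if model.sexed:
            mate = resident_genotype(model, g.sex.other)
        else:
            mate = resident_genotype(model)
        out = offspring_distribution(params, g, mate)
        edges[g] = dict(out)
        for child in out:
            if child not in seen:
                seen.add(child)
                queue.append(child)
    nodes = tuple(sorted(seen, key=lambda g: (g.label)))
    return FitnessGraph(
        params=params, nodes=nodes, edges=edges, residents=residents, migrants=migrants
    )


def reproductive_values(graph: FitnessGraph) -> dict[Genotype, float]:
    """Solve the linear reproductive-value system of a fitness graph.

    Residents are the boundary (v = 1); the system restricted to the
    remaining classes is square and, for all parameters in [0, 1], has a
    dominant diagonal that keeps it nonsingular.
    """
    resident_set = set(graph.residents)
    unknowns = [g for g in graph.nodes if g not in resident_set]
    index = {g: i for i, g in enumerate(unknowns)}
    n = len(unknowns)
    A = np.eye(n)
    b = np.zeros(n)
    for g in unknowns:
        i = index[g]
        for child, w in graph.edges[g].items():
            if child in resident_set:
                b[i] += w  # v(resident) = 1
            else:
                A[i, index[child]] -= w
    try:
        v = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate corners
        raise GraphSolveError(
            f"singular reproductive-value system for {graph.params!r}"
        ) from exc
    values = {g: 1.0 for g in graph.residents}
    values.update({g: float(v[i]) for g, i in index.items()})
    return values


def gene_flow_factor(params: ModelParams) -> float:
    """Average migrant reproductive value = gene flow factor m_e/m as m -> 0.

    For the sexed MtNI models the male and female migrant values are
    weighted by the migrant sex ratio, (1 - mf) v(male) + mf v(female);
    the unsexed NNI models have a single migrant class.
    """
    graph = build_graph(params)
    v = reproductive_values(graph)
    if params.model.sexed:
        vf = v[migrant_genotype(params.model, Sex.FEMALE)]
        vm = v[migrant_genotype(params.model, Sex.MALE)]
        return (1.0 - params.mf) * vm + params.mf * vf
    return v[migrant_genotype(params.model)]


def to_dot(graph: FitnessGraph, values: dict[Genotype, float] | None = None) -> str:
    """Render the fitness graph in DOT format.

    Edge labels carry the numeric fitness components at the graph's
    parameters; node labels optionally include reproductive values.
    """
    lines = ["digraph fitness_graph {", "  rankdir=LR;"]
    resident_set = set(graph.residents)
    migrant_set = set(graph.migrants)
    for g in graph.nodes:
        label = g.label
        if values is not None:
            label += f"\\nv={values[g]:.6g}"
        style = ""
        if g in migrant_set:
            style = ', style=filled, fillcolor="lightblue"'
        elif g in resident_set:
            style = ', style=filled, fillcolor="white"'
        else:
            style = ', style=filled, fillcolor="lightgray"'
        lines.append(f'  "{g.label}" [label="{label}"{style}];')
    for src, out in sorted(graph.edges.items(), key=lambda kv: kv[0].label):
        for child, w in sorted(out.items(), key=lambda kv: kv[0].label):
            lines.append(f'  "{src.label}" -> "{child.label}" [label="{w:.6g}"];')
    lines.append("}")
    return "\n".join(lines)
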