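"""Enumeration of candidate model structures.

An incomplete model leaves design choices open wherever a process
instance references an inner node of the template taxonomy (each
alternative child is a choice) or an optional node (absent/present).  A
leaf with nested template references opens the Cartesian product of its
nested choices.  Exhaustive expansion of these choices yields the finite
space of candidate structures; each candidate is a list of fully bound
reaction-carrying leaves plus the free parameters referenced by their
rate laws.

Complexity of a structure is its flattened reaction-equation count (a
reversible interaction counts as two reactions); combinations are kept
purely combinatorial — a choice that yields a reaction over a species
never produced is retained and counted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .formalism import (
    ConstSpec,
    IncompleteModel,
    KnowledgeLibrary,
    ProcessInstance,
    TemplateProcess,
)

__all__ = [
    "ResolvedLeaf",
    "CandidateStructure",
    "enumerate_candidates",
    "count_alternatives",
    "structure_complexity",
]


@dataclass(frozen=True)
class ResolvedLeaf:
    """A reaction-carrying taxonomy leaf with its entity bindings.

    ``path`` is the instance-scoped route to the leaf (used to scope
    parameter symbols); ``binding`` maps the leaf's slot names to entity
    instance names.
    """

    path: str
    template: str
    binding: tuple[tuple[str, str], ...]

    def binding_dict(self) -> dict[str, str]:
        return dict(self.binding)


@dataclass
class CandidateStructure:
    id: str
    model_name: str
    decisions: tuple[tuple[str, str], ...]  # (choice point, chosen child)
    resolved: list[ResolvedLeaf] = field(default_factory=list)
    free_parameters: list[tuple[str, tuple[float, float]]] = field(default_factory=list)
    complexity: int = 0


class EnumerationError(ValueError):
    pass


# ---------------------------------------------------------------------------


def _expand_node(
    lib: KnowledgeLibrary,
    tmpl: TemplateProcess,
    binding: dict[str, str],
    path: str,
):
    """Yield ``(decisions, leaves)`` for every resolution of ``tmpl``.

    ``decisions`` is a tuple of (choice-point path, chosen child short
    name); ``leaves`` the resolved reaction-carrying leaves.
    """
    children = sorted(lib.children(tmpl.name), key=lambda p: p.name)
    if children:
        for child in children:
            short = child.name.rsplit(".", 1)[-1] if child.generated else child.name
            for decisions, leaves in _expand_node(lib, child, binding, path):
                yield ((path, short),) + decisions, leaves
        return

    # leaf: cartesian product over nested template references
    own_leaves: list[ResolvedLeaf] = []
    if tmpl.reactions:
        slots = [s for s, _ in lib.all_slots(tmpl.name)]
        own_leaves.append(
            ResolvedLeaf(path, tmpl.name, tuple((s, binding[s]) for s in slots))
        )
    nested = lib.all_nested(tmpl.name)
    if not nested:
        yield (), own_leaves
        return
    sub_expansions = []
    for ref in nested:
        sub_tmpl = lib.processes[ref.template]
        sub_slots = lib.all_slots(ref.template)
        sub_binding = {
            sname: binding[arg] for (sname, _), arg in zip(sub_slots, ref.args)
        }
        sub_path = f"{path}.{ref.template}"
        sub_expansions.append(
            list(_expand_node(lib, sub_tmpl, sub_binding, sub_path))
        )
    for combo in itertools.product(*sub_expansions):
        decisions = tuple(d for sub_dec, _ in combo for d in sub_dec)
        leaves = list(own_leaves)
        for _, sub_leaves in combo:
            leaves.extend(sub_leaves)
        yield decisions, leaves


def _instance_expansions(lib: KnowledgeLibrary, inst: ProcessInstance):
    tmpl = lib.processes[inst.template]
    slots = lib.all_slots(inst.template)
    binding = {sname: arg for (sname, _), arg in zip(slots, inst.args)}
    return list(_expand_node(lib, tmpl, binding, inst.name))


def enumerate_candidates(
    model: IncompleteModel, lib: KnowledgeLibrary
) -> list[CandidateStructure]:
    """Expand all unresolved choices into the full candidate space.

    The result is deterministic: the per-instance expansions follow the
    taxonomy in lexicographic child order, and the final list is sorted
    lexicographically by candidate id.
    """
    per_instance = [_instance_expansions(lib, inst) for inst in model.processes]
    for inst, exps in zip(model.processes, per_instance):
        if not exps:
            raise EnumerationError(f"process instance {inst.name} has no resolution")

    candidates = []
    for combo in itertools.product(*per_instance):
        decisions = tuple(d for dec, _ in combo for d in dec)
        leaves = [leaf for _, lvs in combo for leaf in lvs]
        cid = "/".join(f"{point}:{choice}" for point, choice in decisions) or "complete"
        cand = CandidateStructure(cid, model.name, decisions, leaves)
        cand.complexity = sum(
            len(lib.processes[leaf.template].reactions) for leaf in leaves
        )
        cand.free_parameters = _collect_free_parameters(model, lib, leaves)
        candidates.append(cand)
    candidates.sort(key=lambda c: c.id)
    ids = [c.id for c in candidates]
    if len(set(ids)) != len(ids):
        raise EnumerationError("candidate ids are not unique")
    return candidates


def _collect_free_parameters(model, lib, leaves):
    """Ranged constants actually referenced by the resolved reactions.

    Local process constants are scoped by the leaf's instance path;
    entity constants by the entity instance name.  Fixed constants are
    excluded — they carry no parametric uncertainty.
    """
    out: dict[str, tuple[float, float]] = {}
    for leaf in leaves:
        tmpl = lib.processes[leaf.template]
        binding = leaf.binding_dict()
        inst_name = leaf.path.split(".", 1)[0]
        inst = next(p for p in model.processes if p.name == inst_name)
        for rx in tmpl.reactions:
            for sym in rx.rate.symbols():
                name, spec = _resolve_param(model, lib, leaf, inst, binding, sym)
                if not spec.is_fixed:
                    out.setdefault(name, (spec.low, spec.high))
    return sorted(out.items())


def _resolve_param(model, lib, leaf, inst, binding, sym) -> tuple[str, ConstSpec]:
    if "." in sym:
        slot, cname = sym.split(".", 1)
        ent_inst = model.entities[binding[slot]]
        return f"{ent_inst.name}.{cname}", ent_inst.constants[cname]
    decl = lib.resolve_symbol(leaf.template, sym)
    if decl is None:
        raise EnumerationError(f"unresolved rate symbol {sym!r} in {leaf.template}")
    spec = inst.const_overrides.get(sym, ConstSpec.from_decl(decl))
    return f"{leaf.path}.{sym}", spec


def count_alternatives(
    instance: ProcessInstance | str, lib: KnowledgeLibrary
) -> int:
    """Number of structural alternatives a process instance (or template
    node name) contributes to the enumeration.

    Equals the product, over the instance's choice tree, of leaf counts:
    an inner node contributes the sum over its children, a leaf the
    product over its nested references.
    """
    name = instance.template if isinstance(instance, ProcessInstance) else instance
    if name not in lib.processes:
        raise EnumerationError(f"unknown template process {name!r}")
    return _count_node(lib, name)


def _count_node(lib: KnowledgeLibrary, name: str) -> int:
    children = lib.children(name)
    if children:
        return sum(_count_node(lib, c.name) for c in children)
    total = 1
    for ref in lib.all_nested(name):
        total *= _count_node(lib, ref.template)
    return total


def structure_complexity(c: CandidateStructure) -> int:
    """Number of flattened reaction equations of a fully resolved
    candidate (reversibles already expanded at parse time)."""
    return c.complexity
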