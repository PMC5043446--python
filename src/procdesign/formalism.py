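"""Process-based knowledge representation.

A knowledge library formalizes how dynamical systems in a domain may be
modelled: *template entities* declare the constituents (with variable
properties such as molecule counts or concentrations, and constant
properties such as kinetic rates with admissible ranges), and *template
processes* declare the interactions between entities as parameterized
reaction equations.  Processes are organized in a taxonomy (a forest):
inner nodes represent abstract interactions, leaves carry concrete
reaction templates, and children inherit their parent's entity slots and
constants.  An *optional* process is sugar for a two-level hierarchy with
an empty (absent) child and a present child.

An *incomplete model* instantiates templates for a concrete system.  A
process instance that references an inner taxonomy node (or an optional
node) leaves a design choice open; the set of such choices defines a
finite space of candidate model structures (structural uncertainty),
while the declared constant ranges define the parametric uncertainty.

Both objects have a line-oriented text syntax (see :func:`parse_library`
and :func:`parse_incomplete_model`) designed to be written by hand and
diffed.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

__all__ = [
    "ConstDecl",
    "SpeciesRef",
    "Term",
    "RateLawTemplate",
    "ReactionTemplate",
    "TemplateEntity",
    "NestedRef",
    "TemplateProcess",
    "KnowledgeLibrary",
    "ConstSpec",
    "EntityInstance",
    "ProcessInstance",
    "IncompleteModel",
    "DslError",
    "parse_library",
    "serialize_library",
    "validate_library",
    "parse_incomplete_model",
    "serialize_incomplete_model",
]

MASS_ACTION = "mass-action"
MM_COOPERATIVE = "mm-cooperative"

DEFAULT_RANGE = (0.0, 10.0)


class DslError(ValueError):
    """Syntax or reference error in a library/model document."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# declarations


@dataclass(frozen=True)
class ConstDecl:
    """A constant property: either a fixed value or an admissible range."""

    name: str
    low: float = DEFAULT_RANGE[0]
    high: float = DEFAULT_RANGE[1]
    fixed: float | None = None
    units: str = ""

    @property
    def is_fixed(self) -> bool:
        return self.fixed is not None

    def fmt(self) -> str:
        if self.is_fixed:
            return f"const {self.name} = {_num(self.fixed)}"
        return f"const {self.name} in [{_num(self.low)}, {_num(self.high)}]"


@dataclass(frozen=True)
class SpeciesRef:
    """Reference to an entity slot's variable, e.g. ``p`` or ``p.active``.

    ``var`` is ``None`` for single-variable entities (resolved at
    flattening time).
    """

    slot: str
    var: str | None = None

    def fmt(self) -> str:
        return self.slot if self.var is None else f"{self.slot}.{self.var}"


@dataclass(frozen=True)
class Term:
    ref: SpeciesRef
    stoich: int = 1

    def fmt(self) -> str:
        return self.ref.fmt() if self.stoich == 1 else f"{self.stoich} {self.ref.fmt()}"


@dataclass(frozen=True)
class RateLawTemplate:
    """Symbolic rate law.

    Symbols (``k``, ``K``, ``n``) are either local constant names,
    resolved against the owning process or its ancestors, or dotted
    ``slot.const`` references into a bound entity's constants.
    """

    kind: str  # MASS_ACTION | MM_COOPERATIVE
    k: str
    K: str | None = None
    n: str | None = None
    catalyst: SpeciesRef | None = None

    def symbols(self) -> list[str]:
        out = [self.k]
        if self.kind == MM_COOPERATIVE:
            out += [self.K, self.n]
        return out

    def fmt(self) -> str:
        if self.kind == MASS_ACTION:
            return self.k
        return f"hill({self.k}, {self.K}, {self.n}; cat={self.catalyst.fmt()})"


@dataclass(frozen=True)
class ReactionTemplate:
    reactants: tuple[Term, ...]
    products: tuple[Term, ...]
    rate: RateLawTemplate

    def fmt(self) -> str:
        lhs = " + ".join(t.fmt() for t in self.reactants) or "0"
        rhs = " + ".join(t.fmt() for t in self.products) or "0"
        return f"reaction {lhs} -> {rhs} [{self.rate.fmt()}]"

    def species_refs(self) -> list[SpeciesRef]:
        refs = [t.ref for t in self.reactants] + [t.ref for t in self.products]
        if self.rate.catalyst is not None:
            refs.append(self.rate.catalyst)
        return refs


@dataclass
class TemplateEntity:
    name: str
    variables: list[str] = field(default_factory=list)
    constants: list[ConstDecl] = field(default_factory=list)

    def const(self, name: str) -> ConstDecl | None:
        for c in self.constants:
            if c.name == name:
                return c
        return None


@dataclass(frozen=True)
class NestedRef:
    """Reference from a leaf process to a nested template process.

    ``args`` are slot names of the *enclosing* process, bound
    positionally to the nested template's slots.
    """

    template: str
    args: tuple[str, ...]

    def fmt(self) -> str:
        return f"nested {self.template}({', '.join(self.args)})"


@dataclass
class TemplateProcess:
    name: str
    parent: str | None = None
    slots: list[tuple[str, str]] | None = None  # None => inherited
    constants: list[ConstDecl] = field(default_factory=list)
    nested: list[NestedRef] = field(default_factory=list)
    reactions: list[ReactionTemplate] = field(default_factory=list)
    modifier: str = "mandatory"  # mandatory | optional | alternative-leaf
    generated: bool = False  # created by the `optional` sugar


@dataclass
class KnowledgeLibrary:
    name: str
    entities: dict[str, TemplateEntity] = field(default_factory=dict)
    processes: dict[str, TemplateProcess] = field(default_factory=dict)

    # -- taxonomy navigation ------------------------------------------------

    def children(self, name: str) -> list[TemplateProcess]:
        return [p for p in self.processes.values() if p.parent == name]

    def roots(self) -> list[TemplateProcess]:
        return [p for p in self.processes.values() if p.parent is None]

    def is_leaf(self, name: str) -> bool:
        return not self.children(name)

    def ancestors(self, name: str) -> list[TemplateProcess]:
        """Chain from the node itself up to its root (cycle-safe)."""
        out, seen = [], set()
        cur: str | None = name
        while cur is not None and cur in self.processes and cur not in seen:
            seen.add(cur)
            node = self.processes[cur]
            out.append(node)
            cur = node.parent
        return out

    def all_slots(self, name: str) -> list[tuple[str, str]]:
        """Entity slots of a process, inherited from the nearest declaring
        ancestor."""
        for node in self.ancestors(name):
            if node.slots is not None:
                return list(node.slots)
        return []

    def all_constants(self, name: str) -> list[ConstDecl]:
        """Union of the node's own and all ancestors' constants
        (child declarations shadow the parent's)."""
        out: dict[str, ConstDecl] = {}
        for node in self.ancestors(name):  # node first, then ancestors
            for c in node.constants:
                out.setdefault(c.name, c)
        return list(out.values())

    def all_nested(self, name: str) -> list[NestedRef]:
        out: list[NestedRef] = []
        for node in reversed(self.ancestors(name)):
            out.extend(node.nested)
        return out

    def resolve_symbol(self, proc: str, sym: str) -> ConstDecl | None:
        """Resolve a local rate-law symbol against the process chain."""
        for c in self.all_constants(proc):
            if c.name == sym:
                return c
        return None

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self, default=_jsonable))

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


# ---------------------------------------------------------------------------
# incomplete models


@dataclass(frozen=True)
class ConstSpec:
    """Instance-level constant: fixed value or range."""

    low: float = DEFAULT_RANGE[0]
    high: float = DEFAULT_RANGE[1]
    fixed: float | None = None

    @property
    def is_fixed(self) -> bool:
        return self.fixed is not None

    @classmethod
    def from_decl(cls, d: ConstDecl) -> "ConstSpec":
        return cls(low=d.low, high=d.high, fixed=d.fixed)


@dataclass
class EntityInstance:
    name: str
    template: str
    var_init: dict[str, float] = field(default_factory=dict)
    constants: dict[str, ConstSpec] = field(default_factory=dict)


@dataclass
class ProcessInstance:
    name: str
    template: str
    args: tuple[str, ...] = ()
    const_overrides: dict[str, ConstSpec] = field(default_factory=dict)


@dataclass
class IncompleteModel:
    name: str
    entities: dict[str, EntityInstance] = field(default_factory=dict)
    processes: list[ProcessInstance] = field(default_factory=list)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self, default=_jsonable))

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _jsonable(obj):
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(type(obj))


# ---------------------------------------------------------------------------
# parsing


def _num(x: float) -> str:
    xf = float(x)
    return str(int(xf)) if xf == int(xf) else repr(xf)


_IDENT = r"[A-Za-z_][A-Za-z0-9_]*"
_DOTTED = rf"{_IDENT}(?:\.{_IDENT})?"

_RE_CONST_RANGE = re.compile(
    rf"^const\s+({_IDENT})\s+in\s+\[\s*([^\s,\]]+)\s*,\s*([^\s,\]]+)\s*\]$"
)
_RE_CONST_FIXED = re.compile(rf"^const\s+({_IDENT})\s*=\s*(\S+)$")
_RE_VAR = re.compile(rf"^var\s+({_IDENT})$")
_RE_ENTITY = re.compile(rf"^entity\s+({_IDENT})\s*{{$")
_RE_PROCESS = re.compile(
    rf"^process\s+({_IDENT})\s*(\(([^)]*)\))?\s*(?::\s*({_IDENT}))?\s*(optional)?\s*{{$"
)
_RE_NESTED = re.compile(rf"^nested\s+({_IDENT})\s*\(([^)]*)\)$")
_RE_REACTION = re.compile(r"^reaction\s+(.*?)\s*(<->|->)\s*(.*?)\s*\[(.*)\]$")
_RE_HILL = re.compile(
    rf"^hill\(\s*({_DOTTED})\s*,\s*({_DOTTED})\s*,\s*({_DOTTED})\s*;\s*cat\s*=\s*({_DOTTED})\s*\)$"
)
_RE_ENT_INST = re.compile(rf"^entity\s+({_IDENT})\s*:\s*({_IDENT})\s*(?:{{(.*)}})?\s*$")
_RE_PROC_INST = re.compile(
    rf"^process\s+({_IDENT})\s*:\s*({_IDENT})\s*\(([^)]*)\)\s*(?:{{(.*)}})?\s*$"
)


def _parse_float(tok: str, lineno: int) -> float:
    try:
        return float(tok)
    except ValueError:
        raise DslError(f"expected a number, got {tok!r}", lineno)


def _parse_species_ref(tok: str, lineno: int) -> SpeciesRef:
    if not re.fullmatch(_DOTTED, tok):
        raise DslError(f"bad species reference {tok!r}", lineno)
    if "." in tok:
        slot, var = tok.split(".", 1)
        return SpeciesRef(slot, var)
    return SpeciesRef(tok)


def _parse_side(text: str, lineno: int) -> tuple[Term, ...]:
    text = text.strip()
    if text in ("0", ""):
        return ()
    terms = []
    for part in text.split("+"):
        part = part.strip()
        m = re.fullmatch(rf"(?:(\d+)\s+)?({_DOTTED})", part)
        if not m:
            raise DslError(f"bad reaction term {part!r}", lineno)
        stoich = int(m.group(1) or 1)
        if stoich < 1:
            raise DslError(f"stoichiometry must be positive in {part!r}", lineno)
        terms.append(Term(_parse_species_ref(m.group(2), lineno), stoich))
    return tuple(terms)


def _parse_rate(text: str, lineno: int, reversible: bool) -> list[RateLawTemplate]:
    text = text.strip()
    m = _RE_HILL.match(text)
    if m:
        if reversible:
            raise DslError("reversible arrow is not allowed with a hill rate law", lineno)
        return [
            RateLawTemplate(
                MM_COOPERATIVE,
                k=m.group(1),
                K=m.group(2),
                n=m.group(3),
                catalyst=_parse_species_ref(m.group(4), lineno),
            )
        ]
    syms = [s.strip() for s in text.split(",")]
    if reversible:
        if len(syms) != 2:
            raise DslError("reversible reaction needs two rate symbols [kf, kb]", lineno)
    elif len(syms) != 1:
        raise DslError("irreversible reaction takes a single rate symbol", lineno)
    for s in syms:
        if not re.fullmatch(_DOTTED, s):
            raise DslError(f"bad rate symbol {s!r}", lineno)
    return [RateLawTemplate(MASS_ACTION, k=s) for s in syms]


def _parse_reaction(line: str, lineno: int) -> list[ReactionTemplate]:
    m = _RE_REACTION.match(line)
    if not m:
        raise DslError(f"bad reaction syntax: {line!r}", lineno)
    lhs, arrow, rhs, rate_txt = m.group(1), m.group(2), m.group(3), m.group(4)
    reactants = _parse_side(lhs, lineno)
    products = _parse_side(rhs, lineno)
    rates = _parse_rate(rate_txt, lineno, reversible=(arrow == "<->"))
    out = [ReactionTemplate(reactants, products, rates[0])]
    if arrow == "<->":
        out.append(ReactionTemplate(products, reactants, rates[1]))
    return out


def _iter_lines(text: str):
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield i, line


def parse_library(text: str) -> KnowledgeLibrary:
    """Parse a library document; returns a validated :class:`KnowledgeLibrary`.

    Raises :class:`DslError` on syntax errors, duplicate names or
    unresolved references.
    """
    lib: KnowledgeLibrary | None = None
    block: str | None = None  # "entity" | "process"
    cur_ent: TemplateEntity | None = None
    cur_proc: TemplateProcess | None = None
    pending_optional = False

    def close_block(lineno):
        nonlocal block, cur_ent, cur_proc, pending_optional
        if block == "process" and pending_optional:
            _expand_optional(lib, cur_proc, lineno)
        block, cur_ent, cur_proc, pending_optional = None, None, None, False

    for lineno, line in _iter_lines(text):
        if lib is None:
            m = re.fullmatch(rf"library\s+({_IDENT})", line)
            if not m:
                raise DslError("document must start with 'library <name>'", lineno)
            lib = KnowledgeLibrary(m.group(1))
            continue
        if block is None:
            m = _RE_ENTITY.match(line)
            if m:
                name = m.group(1)
                if name in lib.entities:
                    raise DslError(f"duplicate entity {name!r}", lineno)
                cur_ent = TemplateEntity(name)
                lib.entities[name] = cur_ent
                block = "entity"
                continue
            m = _RE_PROCESS.match(line)
            if m:
                name, _, slot_txt, parent, opt = m.groups()
                if name in lib.processes:
                    raise DslError(f"duplicate process {name!r}", lineno)
                slots = None
                if slot_txt is not None:
                    slots = []
                    for part in [p for p in slot_txt.split(",") if p.strip()]:
                        sm = re.fullmatch(rf"\s*({_IDENT})\s*:\s*({_IDENT})\s*", part)
                        if not sm:
                            raise DslError(f"bad slot declaration {part!r}", lineno)
                        slots.append((sm.group(1), sm.group(2)))
                cur_proc = TemplateProcess(name, parent=parent, slots=slots)
                lib.processes[name] = cur_proc
                block = "process"
                pending_optional = opt is not None
                continue
            raise DslError(f"expected an entity or process block, got {line!r}", lineno)
        if line == "}":
            close_block(lineno)
            continue
        if block == "entity":
            m = _RE_VAR.match(line)
            if m:
                if m.group(1) in cur_ent.variables:
                    raise DslError(f"duplicate variable {m.group(1)!r}", lineno)
                cur_ent.variables.append(m.group(1))
                continue
            decl = _parse_const_line(line, lineno)
            if decl is not None:
                if cur_ent.const(decl.name) is not None:
                    raise DslError(f"duplicate constant {decl.name!r}", lineno)
                cur_ent.constants.append(decl)
                continue
            raise DslError(f"bad entity body line {line!r}", lineno)
        # process body
        decl = _parse_const_line(line, lineno)
        if decl is not None:
            cur_proc.constants.append(decl)
            continue
        m = _RE_NESTED.match(line)
        if m:
            args = tuple(a.strip() for a in m.group(2).split(",") if a.strip())
            cur_proc.nested.append(NestedRef(m.group(1), args))
            continue
        if line.startswith("reaction"):
            cur_proc.reactions.extend(_parse_reaction(line, lineno))
            continue
        raise DslError(f"bad process body line {line!r}", lineno)

    if lib is None:
        raise DslError("empty document", 1)
    if block is not None:
        raise DslError("unterminated block at end of document", 0)

    findings = validate_library(lib)
    errors = [f for f in findings if f[0] in ("unresolved", "cycle", "type", "duplicate")]
    if errors:
        kind, msg = errors[0]
        raise DslError(f"{kind}: {msg}")
    return lib


def _parse_const_line(line: str, lineno: int) -> ConstDecl | None:
    m = _RE_CONST_RANGE.match(line)
    if m:
        lo = _parse_float(m.group(2), lineno)
        hi = _parse_float(m.group(3), lineno)
        if not (lo <= hi):
            raise DslError(f"empty range for constant {m.group(1)!r}", lineno)
        return ConstDecl(m.group(1), low=lo, high=hi)
    m = _RE_CONST_FIXED.match(line)
    if m:
        v = _parse_float(m.group(2), lineno)
        return ConstDecl(m.group(1), low=v, high=v, fixed=v)
    return None


def _expand_optional(lib: KnowledgeLibrary, proc: TemplateProcess, lineno: int) -> None:
    """Rewrite ``process X(...) optional { body }`` into a parent X with an
    empty ``X.absent`` child and an ``X.present`` child carrying the body."""
    if proc.parent is not None:
        raise DslError("an optional process cannot also declare a parent", lineno)
    present = TemplateProcess(
        f"{proc.name}.present",
        parent=proc.name,
        slots=None,
        constants=proc.constants,
        nested=proc.nested,
        reactions=proc.reactions,
        modifier="alternative-leaf",
        generated=True,
    )
    absent = TemplateProcess(
        f"{proc.name}.absent",
        parent=proc.name,
        slots=None,
        modifier="alternative-leaf",
        generated=True,
    )
    proc.constants, proc.nested, proc.reactions = [], [], []
    proc.modifier = "optional"
    # dotted names cannot clash with _IDENT-named user processes
    lib.processes[absent.name] = absent
    lib.processes[present.name] = present


# ---------------------------------------------------------------------------
# validation


def validate_library(lib: KnowledgeLibrary) -> list[tuple[str, str]]:
    """Check library invariants; returns ``(kind, message)`` findings.

    An empty report means the library is usable for enumeration.
    Kinds: ``unresolved``, ``cycle``, ``type``, ``duplicate``, ``invariant``.
    """
    findings: list[tuple[str, str]] = []

    for ent in lib.entities.values():
        seen = set()
        for c in ent.constants:
            if c.name in seen:
                findings.append(("duplicate", f"entity {ent.name}: constant {c.name}"))
            seen.add(c.name)
            if not (c.low <= c.high) or c.low != c.low or abs(c.high) == float("inf"):
                findings.append(("invariant", f"entity {ent.name}: constant {c.name} range not finite"))

    # parent resolution and cycles
    for proc in lib.processes.values():
        if proc.parent is not None and proc.parent not in lib.processes:
            findings.append(("unresolved", f"process {proc.name}: parent {proc.parent!r} undeclared"))
    for proc in lib.processes.values():
        seen, cur = set(), proc.name
        while cur is not None and cur in lib.processes:
            if cur in seen:
                findings.append(("cycle", f"taxonomy cycle through {cur!r}"))
                break
            seen.add(cur)
            cur = lib.processes[cur].parent

    cyclic = {m for k, m in findings if k == "cycle"}
    if cyclic:
        return findings  # everything below assumes an acyclic forest

    for proc in lib.processes.values():
        slots = dict(lib.all_slots(proc.name))
        for sname, stype in slots.items():
            if stype not in lib.entities:
                findings.append(("unresolved", f"process {proc.name}: slot type {stype!r} undeclared"))
        if not lib.is_leaf(proc.name) and proc.reactions:
            findings.append(("invariant", f"process {proc.name}: inner taxonomy node carries reactions"))
        for ref in proc.nested:
            if ref.template not in lib.processes:
                findings.append(("unresolved", f"process {proc.name}: nested template {ref.template!r} undeclared"))
                continue
            tslots = lib.all_slots(ref.template)
            if len(ref.args) != len(tslots):
                findings.append(("type", f"process {proc.name}: nested {ref.template} expects {len(tslots)} slots, got {len(ref.args)}"))
                continue
            for arg, (tname, ttype) in zip(ref.args, tslots):
                if arg not in slots:
                    findings.append(("unresolved", f"process {proc.name}: nested argument {arg!r} is not a slot"))
                elif slots[arg] != ttype:
                    findings.append(("type", f"process {proc.name}: slot {arg} has type {slots[arg]}, nested {ref.template}.{tname} needs {ttype}"))
        for rx in proc.reactions:
            for ref in rx.species_refs():
                if ref.slot not in slots:
                    findings.append(("unresolved", f"process {proc.name}: species slot {ref.slot!r} undeclared"))
                    continue
                ent = lib.entities.get(slots[ref.slot])
                if ent is None:
                    continue
                if ref.var is None:
                    if len(ent.variables) != 1:
                        findings.append(("type", f"process {proc.name}: slot {ref.slot} of entity {ent.name} needs an explicit variable"))
                elif ref.var not in ent.variables:
                    findings.append(("unresolved", f"process {proc.name}: entity {ent.name} has no variable {ref.var!r}"))
            for sym in rx.rate.symbols():
                if _resolve_rate_symbol(lib, proc.name, slots, sym) is None:
                    findings.append(("unresolved", f"process {proc.name}: rate symbol {sym!r} not housed in any constant declaration"))
        if proc.modifier == "optional":
            kids = lib.children(proc.name)
            empties = [k for k in kids if not k.reactions and not k.nested]
            if len(kids) != 2 or not empties:
                findings.append(("invariant", f"process {proc.name}: optional node must have exactly two children, one empty"))
    return findings


def _resolve_rate_symbol(
    lib: KnowledgeLibrary, proc: str, slots: dict[str, str], sym: str
) -> ConstDecl | None:
    if "." in sym:
        slot, cname = sym.split(".", 1)
        stype = slots.get(slot)
        if stype is None:
            return None
        ent = lib.entities.get(stype)
        return ent.const(cname) if ent is not None else None
    return lib.resolve_symbol(proc, sym)


# ---------------------------------------------------------------------------
# serialization


def serialize_library(lib: KnowledgeLibrary) -> str:
    """Render a library back to its canonical DSL text.

    ``parse_library(serialize_library(lib))`` is structurally the identity;
    on documents already in canonical form the text round-trips byte-for-byte.
    """
    out = [f"library {lib.name}", ""]
    for ent in lib.entities.values():
        out.append(f"entity {ent.name} {{")
        for v in ent.variables:
            out.append(f"  var {v}")
        for c in ent.constants:
            out.append(f"  {c.fmt()}")
        out.append("}")
        out.append("")
    for proc in lib.processes.values():
        if proc.generated:
            continue
        head = f"process {proc.name}"
        if proc.slots is not None:
            head += "(" + ", ".join(f"{n}: {t}" for n, t in proc.slots) + ")"
        if proc.parent is not None:
            head += f" : {proc.parent}"
        if proc.modifier == "optional":
            head += " optional"
        body_src = proc
        if proc.modifier == "optional":
            body_src = lib.processes[f"{proc.name}.present"]
        out.append(head + " {")
        for c in body_src.constants:
            out.append(f"  {c.fmt()}")
        for ref in body_src.nested:
            out.append(f"  {ref.fmt()}")
        for rx in _merge_reversible(body_src.reactions):
            out.append(f"  {rx}")
        out.append("}")
        out.append("")
    return "\n".join(out)


def _merge_reversible(reactions: list[ReactionTemplate]) -> list[str]:
    """Re-fold forward/backward mass-action pairs into ``<->`` sugar."""
    out, skip = [], set()
    for i, rx in enumerate(reactions):
        if i in skip:
            continue
        if i + 1 < len(reactions):
            nxt = reactions[i + 1]
            if (
                rx.rate.kind == MASS_ACTION
                and nxt.rate.kind == MASS_ACTION
                and nxt.reactants == rx.products
                and nxt.products == rx.reactants
            ):
                lhs = " + ".join(t.fmt() for t in rx.reactants) or "0"
                rhs = " + ".join(t.fmt() for t in rx.products) or "0"
                out.append(f"reaction {lhs} <-> {rhs} [{rx.rate.k}, {nxt.rate.k}]")
                skip.add(i + 1)
                continue
        out.append(rx.fmt())
    return out


# ---------------------------------------------------------------------------
# incomplete-model parsing


def parse_incomplete_model(text: str, lib: KnowledgeLibrary) -> IncompleteModel:
    """Parse a model document against a validated library.

    Inner-node process references are preserved (they signal structural
    uncertainty and are resolved by the enumerator, not here).
    """
    model: IncompleteModel | None = None
    for lineno, line in _iter_lines(text):
        if model is None:
            m = re.fullmatch(rf"model\s+({_IDENT})", line)
            if not m:
                raise DslError("document must start with 'model <name>'", lineno)
            model = IncompleteModel(m.group(1))
            continue
        m = _RE_ENT_INST.match(line)
        if m:
            name, tmpl, body = m.groups()
            if tmpl not in lib.entities:
                raise DslError(f"unknown template entity {tmpl!r}", lineno)
            if name in model.entities:
                raise DslError(f"duplicate entity instance {name!r}", lineno)
            ent = lib.entities[tmpl]
            inst = EntityInstance(name, tmpl)
            for v in ent.variables:
                inst.var_init[v] = 0.0
            for c in ent.constants:
                inst.constants[c.name] = ConstSpec.from_decl(c)
            for stmt in _split_stmts(body):
                _apply_instance_stmt(inst, ent, stmt, lineno)
            model.entities[name] = inst
            continue
        m = _RE_PROC_INST.match(line)
        if m:
            name, tmpl, arg_txt, body = m.groups()
            if tmpl not in lib.processes:
                raise DslError(f"unknown template process {tmpl!r}", lineno)
            args = tuple(a.strip() for a in arg_txt.split(",") if a.strip())
            slots = lib.all_slots(tmpl)
            if len(args) != len(slots):
                raise DslError(
                    f"process {name}: template {tmpl} expects {len(slots)} entity arguments, got {len(args)}",
                    lineno,
                )
            for arg, (sname, stype) in zip(args, slots):
                if arg not in model.entities:
                    raise DslError(f"process {name}: unknown entity instance {arg!r}", lineno)
                bound = model.entities[arg]
                if bound.template != stype:
                    raise DslError(
                        f"process {name}: slot {sname} needs entity of type {stype}, "
                        f"but {arg} is a {bound.template}",
                        lineno,
                    )
            inst = ProcessInstance(name, tmpl, args)
            for stmt in _split_stmts(body):
                inst.const_overrides.update(_parse_override(stmt, lineno))
            model.processes.append(inst)
            continue
        raise DslError(f"bad model line {line!r}", lineno)
    if model is None:
        raise DslError("empty document", 1)
    return model


def _split_stmts(body: str | None) -> list[str]:
    if not body:
        return []
    return [s.strip() for s in body.split(";") if s.strip()]


def _apply_instance_stmt(inst: EntityInstance, ent: TemplateEntity, stmt: str, lineno: int):
    m = re.fullmatch(rf"({_IDENT})\s*=\s*(\S+)", stmt)
    if m:
        name, val = m.group(1), _parse_float(m.group(2), lineno)
        if name in ent.variables:
            inst.var_init[name] = val
            return
        if ent.const(name) is not None:
            inst.constants[name] = ConstSpec(low=val, high=val, fixed=val)
            return
        raise DslError(f"entity {inst.name}: no variable or constant {name!r}", lineno)
    ov = _parse_override(stmt, lineno)
    for name, spec in ov.items():
        if ent.const(name) is None:
            raise DslError(f"entity {inst.name}: no constant {name!r}", lineno)
        inst.constants[name] = spec


def _parse_override(stmt: str, lineno: int) -> dict[str, ConstSpec]:
    m = re.fullmatch(rf"({_IDENT})\s+in\s+\[\s*([^\s,\]]+)\s*,\s*([^\s,\]]+)\s*\]", stmt)
    if m:
        lo, hi = _parse_float(m.group(2), lineno), _parse_float(m.group(3), lineno)
        if not lo <= hi:
            raise DslError(f"empty range for {m.group(1)!r}", lineno)
        return {m.group(1): ConstSpec(low=lo, high=hi)}
    m = re.fullmatch(rf"({_IDENT})\s*=\s*(\S+)", stmt)
    if m:
        v = _parse_float(m.group(2), lineno)
        return {m.group(1): ConstSpec(low=v, high=v, fixed=v)}
    raise DslError(f"bad override {stmt!r}", lineno)


def serialize_incomplete_model(model: IncompleteModel) -> str:
    out = [f"model {model.name}", ""]
    for inst in model.entities.values():
        stmts = [f"{v} = {_num(x)}" for v, x in inst.var_init.items()]
        for cname, spec in inst.constants.items():
            if spec.is_fixed:
                stmts.append(f"{cname} = {_num(spec.fixed)}")
            else:
                stmts.append(f"{cname} in [{_num(spec.low)}, {_num(spec.high)}]")
        body = f" {{ {'; '.join(stmts)} }}" if stmts else ""
        out.append(f"entity {inst.name} : {inst.template}{body}")
    out.append("")
    for p in model.processes:
        body = ""
        if p.const_overrides:
            stmts = []
            for cname, spec in p.const_overrides.items():
                if spec.is_fixed:
                    stmts.append(f"{cname} = {_num(spec.fixed)}")
                else:
                    stmts.append(f"{cname} in [{_num(spec.low)}, {_num(spec.high)}]")
            body = f" {{ {'; '.join(stmts)} }}"
        out.append(f"process {p.name} : {p.template}({', '.join(p.args)}){body}")
    out.append("")
    return "\n".join(out)
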