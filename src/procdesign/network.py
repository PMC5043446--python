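"""Concrete reaction networks.

Flattening substitutes the entity bindings of a resolved candidate
structure into its reaction templates, yielding an ordered species list,
a reaction list with rate-law descriptors, and a parameter table with
instance-scoped symbol names.  The same network supports a deterministic
reading (mass-action / Michaelis–Menten-with-cooperation rate equations)
and a stochastic one (mass-action propensities of the underlying
continuous-time Markov chain); Hill-type laws are deterministic-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enumerator import CandidateStructure
from .formalism import (
    MASS_ACTION,
    MM_COOPERATIVE,
    ConstSpec,
    IncompleteModel,
    KnowledgeLibrary,
)

__all__ = [
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "NetworkError",
    "UnsupportedRateLaw",
    "flatten",
    "ode_rhs",
    "propensities",
    "export_sbml",
    "import_sbml",
]


class NetworkError(ValueError):
    pass


class UnsupportedRateLaw(NetworkError):
    pass


@dataclass(frozen=True)
class RateLaw:
    """Concrete rate law over flattened species/parameter names.

    mass-action: rate = k * prod(conc_i ** stoich_i).
    mm-cooperative: rate = k * [substrate] * [catalyst]**n / (K**n + [catalyst]**n).
    """

    kind: str
    k: str
    K: str | None = None
    n: str | None = None
    substrate: str | None = None
    catalyst: str | None = None


@dataclass(frozen=True)
class Reaction:
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate: RateLaw
    origin: str = ""  # leaf path, for provenance


@dataclass
class ReactionNetwork:
    name: str
    species: list[str] = field(default_factory=list)
    initial: dict[str, float] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    parameters: dict[str, ConstSpec] = field(default_factory=dict)

    @property
    def free_parameters(self) -> list[tuple[str, tuple[float, float]]]:
        return [
            (name, (s.low, s.high))
            for name, s in sorted(self.parameters.items())
            if not s.is_fixed
        ]

    def species_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.species)}

    def initial_vector(self) -> np.ndarray:
        return np.array([self.initial[s] for s in self.species], dtype=float)

    def is_stochastic_compatible(self) -> bool:
        return all(r.rate.kind == MASS_ACTION for r in self.reactions)

    def compile(self, dtype=np.float64) -> "CompiledNetwork":
        return CompiledNetwork(self, dtype)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": list(self.species),
            "initial": dict(self.initial),
            "reactions": [
                {
                    "reactants": [list(t) for t in r.reactants],
                    "products": [list(t) for t in r.products],
                    "rate": {k: v for k, v in r.rate.__dict__.items() if v is not None},
                    "origin": r.origin,
                }
                for r in self.reactions
            ],
            "parameters": {
                name: ({"fixed": s.fixed} if s.is_fixed else {"low": s.low, "high": s.high})
                for name, s in self.parameters.items()
            },
        }

    def to_json(self, **kw) -> str:
        import json

        return json.dumps(self.to_dict(), indent=2, **kw)


# ---------------------------------------------------------------------------
# flattening


def _species_name(model: IncompleteModel, lib: KnowledgeLibrary, inst: str, var: str | None) -> str:
    ent = model.entities[inst]
    variables = lib.entities[ent.template].variables
    if var is None:
        if len(variables) != 1:
            raise NetworkError(f"entity {inst} has {len(variables)} variables; reference is ambiguous")
        return inst
    if var not in variables:
        raise NetworkError(f"entity {inst} has no variable {var!r}")
    return f"{inst}.{var}"


def flatten(
    c: CandidateStructure, lib: KnowledgeLibrary, model: IncompleteModel
) -> ReactionNetwork:
    """Instantiate a fully resolved candidate into a reaction network.

    Species are ordered by model entity-instance declaration (one per
    entity variable); parameter symbols are scoped by instance path so
    they are globally unique after flattening.
    """
    net = ReactionNetwork(name=f"{model.name}::{c.id}")
    for inst in model.entities.values():
        variables = lib.entities[inst.template].variables
        for v in variables:
            sname = inst.name if len(variables) == 1 else f"{inst.name}.{v}"
            if sname in net.initial:
                raise NetworkError(f"duplicate species {sname!r}")
            net.species.append(sname)
            net.initial[sname] = inst.var_init.get(v, 0.0)

    from .enumerator import _resolve_param  # shared scoping rules

    for leaf in c.resolved:
        tmpl = lib.processes[leaf.template]
        binding = leaf.binding_dict()
        inst_name = leaf.path.split(".", 1)[0]
        pinst = next(p for p in model.processes if p.name == inst_name)
        missing = [s for s, _ in lib.all_slots(leaf.template) if s not in binding]
        if missing:
            raise NetworkError(f"unbound slot(s) {missing} in {leaf.path}")
        for rx in tmpl.reactions:
            def _side(terms):
                return tuple(
                    (_species_name(model, lib, binding[t.ref.slot], t.ref.var), t.stoich)
                    for t in terms
                )

            syms = {}
            for sym in rx.rate.symbols():
                pname, spec = _resolve_param(model, lib, leaf, pinst, binding, sym)
                prev = net.parameters.get(pname)
                if prev is not None and prev != spec:
                    raise NetworkError(f"conflicting declarations for parameter {pname}")
                net.parameters[pname] = spec
                syms[sym] = pname

            if rx.rate.kind == MASS_ACTION:
                law = RateLaw(MASS_ACTION, k=syms[rx.rate.k])
            else:
                if len(rx.reactants) != 1 or rx.reactants[0].stoich != 1:
                    raise NetworkError("mm-cooperative law needs a single unit-stoichiometry substrate")
                law = RateLaw(
                    MM_COOPERATIVE,
                    k=syms[rx.rate.k],
                    K=syms[rx.rate.K],
                    n=syms[rx.rate.n],
                    substrate=_species_name(
                        model, lib, binding[rx.reactants[0].ref.slot], rx.reactants[0].ref.var
                    ),
                    catalyst=_species_name(
                        model, lib, binding[rx.rate.catalyst.slot], rx.rate.catalyst.var
                    ),
                )
            net.reactions.append(Reaction(_side(rx.reactants), _side(rx.products), law, origin=leaf.path))
    if len(net.reactions) != c.complexity:
        raise NetworkError(
            f"flattened reaction count {len(net.reactions)} != structure complexity {c.complexity}"
        )
    return net


# ---------------------------------------------------------------------------
# compiled array form (shared by the deterministic and stochastic kernels)


class CompiledNetwork:
    """Dense array encoding of a network for the simulation kernels."""

    def __init__(self, net: ReactionNetwork, dtype=np.float64):
        self.net = net
        idx = net.species_index()
        n_r, n_s = len(net.reactions), len(net.species)
        # reactant index/stoich in CSR layout
        ptr, sp, st = [0], [], []
        self.kind = np.zeros(n_r, dtype=np.int8)
        self.stoich = np.zeros((n_r, n_s), dtype=np.float64)

        pnames = sorted(net.parameters)
        self.param_names = pnames
        pidx = {p: i for i, p in enumerate(pnames)}
        self.k_idx = np.zeros(n_r, dtype=np.int64)
        self.K_idx = np.full(n_r, -1, dtype=np.int64)
        self.n_idx = np.full(n_r, -1, dtype=np.int64)
        self.sub_idx = np.full(n_r, -1, dtype=np.int64)
        self.cat_idx = np.full(n_r, -1, dtype=np.int64)

        for j, rx in enumerate(net.reactions):
            for name, s in rx.reactants:
                sp.append(idx[name])
                st.append(s)
                self.stoich[j, idx[name]] -= s
            ptr.append(len(sp))
            for name, s in rx.products:
                self.stoich[j, idx[name]] += s
            self.k_idx[j] = pidx[rx.rate.k]
            if rx.rate.kind == MM_COOPERATIVE:
                self.kind[j] = 1
                self.K_idx[j] = pidx[rx.rate.K]
                self.n_idx[j] = pidx[rx.rate.n]
                self.sub_idx[j] = idx[rx.rate.substrate]
                self.cat_idx[j] = idx[rx.rate.catalyst]
        self.in_ptr = np.array(ptr, dtype=np.int64)
        self.in_sp = np.array(sp, dtype=np.int64)
        self.in_st = np.array(st, dtype=np.int64)
        self.n_species = n_s
        self.n_reactions = n_r

    def param_vector(self, params: dict[str, float]) -> np.ndarray:
        out = np.empty(len(self.param_names))
        for i, name in enumerate(self.param_names):
            spec = self.net.parameters[name]
            if name in params:
                out[i] = params[name]
            elif spec.is_fixed:
                out[i] = spec.fixed
            else:
                raise NetworkError(f"missing value for free parameter {name!r}")
        return out


def _rates(cn: CompiledNetwork, state: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Deterministic reaction rates (concentration units)."""
    x = np.maximum(state, 0.0)
    v = np.empty(cn.n_reactions)
    for j in range(cn.n_reactions):
        if cn.kind[j] == 0:
            r = p[cn.k_idx[j]]
            for m in range(cn.in_ptr[j], cn.in_ptr[j + 1]):
                r *= x[cn.in_sp[m]] ** cn.in_st[m]
        else:
            cat = x[cn.cat_idx[j]]
            n = p[cn.n_idx[j]]
            K = p[cn.K_idx[j]]
            cn_pow = cat**n
            r = p[cn.k_idx[j]] * x[cn.sub_idx[j]] * cn_pow / (K**n + cn_pow)
        v[j] = r
    return v


def ode_rhs(
    net: ReactionNetwork | CompiledNetwork,
    state: np.ndarray,
    params: dict[str, float] | np.ndarray,
) -> np.ndarray:
    """Time derivative of the species vector under mass-action /
    MM-cooperative kinetics.  Negative states are rejected."""
    cn = net if isinstance(net, CompiledNetwork) else net.compile()
    state = np.asarray(state, dtype=float)
    if np.any(state < 0):
        raise NetworkError("negative state")
    p = cn.param_vector(params) if isinstance(params, dict) else np.asarray(params, float)
    return _rates(cn, state, p) @ cn.stoich


def propensities(
    net: ReactionNetwork | CompiledNetwork,
    counts: np.ndarray,
    params: dict[str, float] | np.ndarray,
) -> np.ndarray:
    """Stochastic mass-action propensities at integer molecule counts.

    a_j = c * prod over reactants of C(n_i, s_i) * s_i!  (falling
    factorials: c*n_A*n_B for A+B, c*n_A*(n_A-1)/2 for 2A, ...).
    """
    cn = net if isinstance(net, CompiledNetwork) else net.compile()
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.all(np.equal(np.mod(counts, 1), 0)):
        raise NetworkError("counts must be non-negative integers")
    if np.any(cn.kind != 0):
        raise UnsupportedRateLaw(
            "mm-cooperative rate laws have no stochastic interpretation here"
        )
    p = cn.param_vector(params) if isinstance(params, dict) else np.asarray(params, float)
    a = np.empty(cn.n_reactions)
    for j in range(cn.n_reactions):
        v = p[cn.k_idx[j]]
        for m in range(cn.in_ptr[j], cn.in_ptr[j + 1]):
            n, s = counts[cn.in_sp[m]], cn.in_st[m]
            for q in range(s):
                v *= (n - q) / (q + 1)
        a[j] = v
    return a


# ---------------------------------------------------------------------------
# SBML level 3 export / import

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_ANNOT_NS = "urn:procdesign:network"


def export_sbml(net: ReactionNetwork, params: dict[str, float] | None = None) -> str:
    """Serialize a network to an SBML Level 3 Version 2 document.

    Kinetic laws are written as MathML; a small annotation block records
    the rate-law descriptor so that :func:`import_sbml` round-trips the
    network semantics exactly.  Free parameters without a supplied value
    are exported at the midpoint of their range.
    """
    from lxml import etree

    E = lambda tag, **kw: etree.SubElement(kw.pop("parent"), f"{{{_SBML_NS}}}{tag}", **kw)
    root = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap={None: _SBML_NS}, level="3", version="2")
    mdl = E("model", parent=root, id=_sbml_id(net.name))
    comps = E("listOfCompartments", parent=mdl)
    E("compartment", parent=comps, id="cell", constant="true", spatialDimensions="3", size="1")
    if net.species:
        los = E("listOfSpecies", parent=mdl)
        for s in net.species:
            E(
                "species",
                parent=los,
                id=_sbml_id(s),
                name=s,
                compartment="cell",
                initialAmount=repr(float(net.initial[s])),
                hasOnlySubstanceUnits="true",
                boundaryCondition="false",
                constant="false",
            )
    if net.parameters:
        lop = E("listOfParameters", parent=mdl)
        for name in sorted(net.parameters):
            spec = net.parameters[name]
            if params and name in params:
                val = params[name]
            elif spec.is_fixed:
                val = spec.fixed
            else:
                val = 0.5 * (spec.low + spec.high)
            E("parameter", parent=lop, id=_sbml_id(name), name=name, value=repr(float(val)), constant="true")
    lor = E("listOfReactions", parent=mdl)
    for j, rx in enumerate(net.reactions):
        r = E("reaction", parent=lor, id=f"r{j}", reversible="false")
        ann = etree.SubElement(r, f"{{{_SBML_NS}}}annotation")
        etree.SubElement(ann, f"{{{_ANNOT_NS}}}rateLaw", nsmap={"pd": _ANNOT_NS}).text = _rate_json(rx.rate)
        if rx.reactants:
            lo = E("listOfReactants", parent=r)
            for name, s in rx.reactants:
                E("speciesReference", parent=lo, species=_sbml_id(name), stoichiometry=str(s), constant="true")
        if rx.products:
            lo = E("listOfProducts", parent=r)
            for name, s in rx.products:
                E("speciesReference", parent=lo, species=_sbml_id(name), stoichiometry=str(s), constant="true")
        kl = E("kineticLaw", parent=r)
        math = etree.SubElement(kl, f"{{{_MATHML_NS}}}math", nsmap={None: _MATHML_NS})
        math.append(_rate_mathml(rx))
    return etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8").decode()


def _sbml_id(name: str) -> str:
    return name.replace(".", "__").replace(":", "_").replace("/", "_").replace("=", "_")


def _rate_json(rate: RateLaw) -> str:
    import json

    return json.dumps(rate.__dict__)


def _rate_mathml(rx: Reaction):
    from lxml import etree

    M = lambda tag: etree.Element(f"{{{_MATHML_NS}}}{tag}")

    def ci(name):
        el = M("ci")
        el.text = f" {_sbml_id(name)} "
        return el

    def cn(val):
        el = M("cn")
        el.text = f" {val} "
        return el

    def apply(op, *args):
        el = M("apply")
        el.append(M(op))
        for a in args:
            el.append(a)
        return el

    law = rx.rate
    if law.kind == MASS_ACTION:
        factors = [ci(law.k)]
        for name, s in rx.reactants:
            factors.append(ci(name) if s == 1 else apply("power", ci(name), cn(s)))
        return factors[0] if len(factors) == 1 else apply("times", *factors)
    catn = apply("power", ci(law.catalyst), ci(law.n))
    Kn = apply("power", ci(law.K), ci(law.n))
    return apply(
        "divide",
        apply("times", ci(law.k), ci(law.substrate), apply("power", ci(law.catalyst), ci(law.n))),
        apply("plus", Kn, catn),
    )


def import_sbml(text: str) -> ReactionNetwork:
    """Re-import a document produced by :func:`export_sbml`."""
    import json

    from lxml import etree

    root = etree.fromstring(text.encode() if isinstance(text, str) else text)
    mdl = root.find(f"{{{_SBML_NS}}}model")
    net = ReactionNetwork(name=mdl.get("id"))
    for sp in mdl.findall(f".//{{{_SBML_NS}}}species"):
        name = sp.get("name") or sp.get("id")
        net.species.append(name)
        net.initial[name] = float(sp.get("initialAmount", "0"))
    for par in mdl.findall(f".//{{{_SBML_NS}}}parameter"):
        v = float(par.get("value"))
        net.parameters[par.get("name") or par.get("id")] = ConstSpec(low=v, high=v, fixed=v)
    for rx in mdl.findall(f".//{{{_SBML_NS}}}reaction"):
        ann = rx.find(f"{{{_SBML_NS}}}annotation/{{{_ANNOT_NS}}}rateLaw")
        law = RateLaw(**json.loads(ann.text))

        def side(tag):
            lo = rx.find(f"{{{_SBML_NS}}}{tag}")
            if lo is None:
                return ()
            out = []
            for ref in lo.findall(f"{{{_SBML_NS}}}speciesReference"):
                sid = ref.get("species")
                name = next(s for s in net.species if _sbml_id(s) == sid)
                out.append((name, int(float(ref.get("stoichiometry", "1")))))
            return tuple(out)

        net.reactions.append(Reaction(side("listOfReactants"), side("listOfProducts"), law))
    return net
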