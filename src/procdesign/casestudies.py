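"""Built-in design tasks: the stochastic toggle switch without
cooperativity and the deterministic negative-feedback oscillator.

Both knowledge libraries and incomplete models are encoded as DSL
documents in this module, so the whole pipeline (enumerate -> flatten ->
simulate -> objectives -> optimize -> rank) runs end-to-end with no
external inputs.  Kinetic ranges, initial conditions and the inducer
schedule are fixture defaults documented in docs/methods.md; they are
declared explicitly in the DSL texts, which are the single source of
truth pinned by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enumerator import CandidateStructure
from .formalism import (
    IncompleteModel,
    KnowledgeLibrary,
    parse_incomplete_model,
    parse_library,
)
from .objectives import OscillatorSpec, SwitchSpec
from .simulate import SamplingGrid, Trajectory

__all__ = [
    "DesignTask",
    "TOGGLE_LIBRARY",
    "TOGGLE_MODEL",
    "OSCILLATOR_LIBRARY",
    "OSCILLATOR_MODEL",
    "build_toggle_task",
    "build_oscillator_tasks",
    "expected_switch_profile",
    "oscillator_structure_label",
    "toggle_classic_structures",
]


# ---------------------------------------------------------------------------
# toggle switch: two genes whose products mutually repress each other's
# expression by promoter binding, controlled by two inducers that
# sequester the free repressors.  The inhibition family offers a simple
# per-gene binding mechanism (each binding optional, plus optional
# degradation of the bound repressors) or an exclusive shared-operator
# mechanism in which at most one repressor can be bound at a time;
# repressor heterodimerization is a separate optional mechanism.

TOGGLE_LIBRARY = """\
library toggle_switch

entity gene {
  var mol
  const k_p in [0, 10]
  const k_d in [0, 1]
}

entity protein {
  var mol
}

entity bound_factor {
  var mol
}

entity inducer {
  var mol
}

entity complex {
  var mol
}

# constitutive expression of a gene product and its first-order decay
process basic(g: gene, p: protein) {
  nested expression(g, p)
  nested degradation(g, p)
}

process expression(g: gene, p: protein) {
  reaction g -> g + p [g.k_p]
}

process degradation(g: gene, p: protein) {
  reaction p -> 0 [g.k_d]
}

# irreversible sequestration of a free repressor by its inducer
process inducer_binding(i: inducer, p: protein, c: complex) {
  const k_i in [0, 10]
  reaction i + p -> c [k_i]
}

# the mutual-inhibition family: how the two repressors silence each
# other's gene
process inhibition(pa: protein, pb: protein, ga: gene, gb: gene, ba: bound_factor, bb: bound_factor) {
}

process simple_inhibition : inhibition {
  nested binding_a(pa, gb, ba)
  nested binding_b(pb, ga, bb)
  nested bound_degradation(ba, gb, bb, ga)
}

# shared operator: a repressor can bind only while both promoter sites
# are free, so co-occupancy (the deadlock state) is impossible
process exclusive_inhibition : inhibition {
  const k_xa in [0, 10]
  const k_ya in [0, 10]
  const k_xb in [0, 10]
  const k_yb in [0, 10]
  reaction pa + ga + gb -> ba + ga [k_xa]
  reaction ba -> pa + gb [k_ya]
  reaction pb + ga + gb -> bb + gb [k_xb]
  reaction bb -> pb + ga [k_yb]
  nested bound_degradation(ba, gb, bb, ga)
}

process binding_a(p: protein, g: gene, b: bound_factor) optional {
  const k_on in [0, 10]
  const k_off in [0, 10]
  reaction p + g <-> b [k_on, k_off]
}

process binding_b(p: protein, g: gene, b: bound_factor) optional {
  const k_on in [0, 10]
  const k_off in [0, 10]
  reaction p + g <-> b [k_on, k_off]
}

# degradation of a repressor while bound to the promoter, freeing the
# gene; the two bound factors toggle as a single linked choice
process bound_degradation(b1: bound_factor, g1: gene, b2: bound_factor, g2: gene) optional {
  const k_bd in [0, 1]
  reaction b1 -> g1 [k_bd]
  reaction b2 -> g2 [k_bd]
}

process dimerization(p1: protein, p2: protein, c: complex) optional {
  const k_f in [0, 10]
  const k_r in [0, 10]
  reaction p1 + p2 <-> c [k_f, k_r]
}
"""

TOGGLE_MODEL = """\
model toggle_switch_incomplete

entity gA : gene { mol = 1 }
entity gB : gene { mol = 1 }
entity A : protein { mol = 0 }
entity B : protein { mol = 0 }
entity S : inducer { mol = 0 }
entity R : inducer { mol = 0 }
entity AgB : bound_factor { mol = 0 }
entity BgA : bound_factor { mol = 0 }
entity SA : complex { mol = 0 }
entity RB : complex { mol = 0 }
entity AB : complex { mol = 0 }

process basic_a : basic(gA, A)
process basic_b : basic(gB, B)
process ind_a : inducer_binding(S, A, SA)
process ind_b : inducer_binding(R, B, RB)
process inh : inhibition(A, B, gA, gB, AgB, BgA)
process dim : dimerization(A, B, AB)
"""


# ---------------------------------------------------------------------------
# negative-feedback oscillator: three proteins, each switching between a
# passive and an active form (total concentration 1 per protein), with a
# ring of cooperative (Hill) inhibitions A -| B -| C -| A.  The open
# design choice is a single auto-interaction on protein A: none, weak or
# strong auto-activation, weak or strong auto-inhibition (weak/strong
# are disjoint rate-constant regimes on the same loop template).

OSCILLATOR_LIBRARY = """\
library nf_oscillator

entity protein {
  var active
  var passive
}

# basal interconversion between passive and active form
process turnover(p: protein) {
  const k_act in [0.5, 5]
  const k_inact in [0, 2]
  reaction p.passive -> p.active [k_act]
  reaction p.active -> p.passive [k_inact]
}

# directed protein-protein interaction, inactivating the target,
# catalysed by the active form of the source (Hill kinetics)
process interaction(src: protein, dst: protein) {
  const k in [5, 60]
  const K in [0.3, 0.7]
  const n = 8
}

process inhibits : interaction {
  reaction dst.active -> dst.passive [hill(k, K, n; cat=src.active)]
}

process auto_interaction(p: protein) {
  const K in [0.3, 0.7]
  const n = 8
}

process auto_none : auto_interaction {
}

process auto_weak : auto_interaction {
  const k in [0, 5]
}

process auto_strong : auto_interaction {
  const k in [5, 50]
}

process auto_weak_activation : auto_weak {
  reaction p.passive -> p.active [hill(k, K, n; cat=p.active)]
}

process auto_weak_inhibition : auto_weak {
  reaction p.active -> p.passive [hill(k, K, n; cat=p.active)]
}

process auto_strong_activation : auto_strong {
  reaction p.passive -> p.active [hill(k, K, n; cat=p.active)]
}

process auto_strong_inhibition : auto_strong {
  reaction p.active -> p.passive [hill(k, K, n; cat=p.active)]
}
"""

OSCILLATOR_MODEL = """\
model nf_oscillator_incomplete

entity A : protein { active = 1; passive = 0 }
entity B : protein { active = 0; passive = 1 }
entity C : protein { active = 0; passive = 1 }

process turn_a : turnover(A)
process turn_b : turnover(B)
process turn_c : turnover(C)
process inh_ab : inhibits(A, B)
process inh_bc : inhibits(B, C)
process inh_ca : inhibits(C, A)
process auto_a : auto_interaction(A)
"""


@dataclass
class DesignTask:
    """One fully specified design problem: fixtures, interpretation,
    sampling, objective spec and optimizer defaults."""

    name: str
    library: KnowledgeLibrary
    model: IncompleteModel
    interpretation: str  # stochastic | deterministic
    grid: SamplingGrid
    objective: SwitchSpec | OscillatorSpec
    n_realizations: int = 1
    alpha: float = 0.5
    events: list[tuple[float, str, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.interpretation not in ("stochastic", "deterministic"):
            raise ValueError("interpretation must be stochastic or deterministic")


def build_toggle_task(
    high_level: float = 20.0,
    n_realizations: int = 100,
    alpha: float = 0.5,
) -> DesignTask:
    """The stochastic toggle-switch design task.

    Interpretation: continuous-time Markov chain, 100 realizations,
    integer sampling on 0..100.  Inducer schedule: a transient pulse of
    S at t=0 sequesters repressor A, flipping the system towards the
    B-high state, which must then *hold* (level H on alpha=[10, 45])
    after the pulse ends — the memory requirement that separates the
    switch mechanisms; a pulse of R at t=50 flips it back (B expected 0
    on beta=[60, 95]).  The inducers are prescribed inputs: each pulse
    clamps the inducer count to 50 molecules for 10 time units and back
    to 0 afterwards, so induction is strictly transient and the
    expected-behaviour windows begin only after their pulse ends.
    """
    lib = parse_library(TOGGLE_LIBRARY)
    model = parse_incomplete_model(TOGGLE_MODEL, lib)
    schedule = (
        (0.0, "S", 50.0, "set"),
        (10.0, "S", 0.0, "set"),
        (50.0, "R", 50.0, "set"),
        (60.0, "R", 0.0, "set"),
    )
    spec = SwitchSpec(
        species="B",
        high_level=high_level,
        alpha=(10.0, 45.0),
        beta=(60.0, 95.0),
        schedule=schedule,
    )
    return DesignTask(
        name="toggle_switch",
        library=lib,
        model=model,
        interpretation="stochastic",
        grid=SamplingGrid.integers(0, 100),
        objective=spec,
        n_realizations=n_realizations,
        alpha=alpha,
        events=[list(e) for e in schedule],
    )


def build_oscillator_tasks(
    frequencies: tuple[float, ...] = (0.1, 1.0, 10.0),
    amplitudes: tuple[float, ...] = (0.01, 0.1, 1.0),
    species: tuple[str, ...] = ("A.active", "C.active"),
    t0: float = 2.0,
) -> list[DesignTask]:
    """The oscillator design-task grid: per observed species (active A,
    active C), the Cartesian product of target frequencies {0.1, 1, 10}
    Hz and amplitudes {0.01, 0.1, 1}; deterministic interpretation,
    simulation window 0..28 sampled at 40 Hz, transient cutoff 2 s.

    Complexity is structurally uninformative here (all candidates share
    the ring and turnover reactions), so ranking uses HVUPF alone
    (alpha = 1).
    """
    lib = parse_library(OSCILLATOR_LIBRARY)
    model = parse_incomplete_model(OSCILLATOR_MODEL, lib)
    grid = SamplingGrid.regular(0.0, 28.0, 40.0)
    tasks = []
    for sp in species:
        for f_t in frequencies:
            for a_t in amplitudes:
                tasks.append(
                    DesignTask(
                        name=f"oscillator[{sp}|f={f_t}|A={a_t}]",
                        library=lib,
                        model=model,
                        interpretation="deterministic",
                        grid=grid,
                        objective=OscillatorSpec(species=sp, f_target=f_t, a_target=a_t, t0=t0),
                        alpha=1.0,
                    )
                )
    return tasks


def expected_switch_profile(spec: SwitchSpec, grid: SamplingGrid) -> Trajectory:
    """Ideal observed-protein trajectory: H on alpha, 0 elsewhere
    (piecewise-constant with exactly two levels)."""
    t = grid.times
    in_alpha = (t >= spec.alpha[0]) & (t <= spec.alpha[1])
    in_beta = (t >= spec.beta[0]) & (t <= spec.beta[1])
    if not in_alpha.any():
        raise ValueError("alpha window contains no sample points")
    if not in_beta.any():
        raise ValueError("beta window contains no sample points")
    values = np.where(in_alpha, spec.high_level, 0.0)[None, :]
    return Trajectory(grid, [spec.species], values, kind="single")


def oscillator_structure_label(c: CandidateStructure) -> str:
    """Map an oscillator candidate to its conventional name M1..M5
    (M1 no auto-interaction, M2/M3 weak/strong auto-activation,
    M4/M5 weak/strong auto-inhibition)."""
    leaves = {leaf.template for leaf in c.resolved}
    mapping = {
        "auto_weak_activation": "M2",
        "auto_strong_activation": "M3",
        "auto_weak_inhibition": "M4",
        "auto_strong_inhibition": "M5",
    }
    for tmpl, label in mapping.items():
        if tmpl in leaves:
            return label
    return "M1"


def toggle_classic_structures(
    candidates: list[CandidateStructure],
) -> dict[str, CandidateStructure]:
    """The four toggle-switch variants studied before this design space
    was enumerated: basic switch (mutual promoter binding only), bound
    repressor degradation, exclusive switch, and the protein-protein
    interaction switch (repressor heterodimerization)."""

    def decisions(c):
        return dict(c.decisions)

    out = {}
    for c in candidates:
        d = decisions(c)
        simple_both = (
            d.get("inh") == "simple_inhibition"
            and d.get("inh.binding_a") == "present"
            and d.get("inh.binding_b") == "present"
        )
        no_bdeg = d.get("inh.bound_degradation") == "absent"
        no_dim = d.get("dim") == "absent"
        if simple_both and no_bdeg and no_dim:
            out["basic"] = c
        elif simple_both and d.get("inh.bound_degradation") == "present" and no_dim:
            out["bound_degradation"] = c
        elif (
            d.get("inh") == "exclusive_inhibition" and no_bdeg and no_dim
        ):
            out["exclusive"] = c
        elif simple_both and no_bdeg and d.get("dim") == "present":
            out["protein_protein"] = c
    return out
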