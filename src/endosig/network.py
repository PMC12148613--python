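"""Reaction-network representation of the coupled VEGF / Ang-Tie signaling model.

The model is a coarse-grained, rule-derived ODE network of the endothelial
signaling layer formed by the VEGF axis (VEGF, VEGFR1/2, NRP1, TSP1/CD47),
the Ang-Tie axis (Ang1, Ang2 multimers, Tie1/Tie2, VE-PTP, ectodomain
shedding), their crosstalk (VEGF-enhanced Tie2 shedding, S1P-driven Ang2
release from Weibel-Palade bodies, Tie2-driven Src sequestration through
RhoA-GTP/mDia) and the shared downstream network (Src, Axl, PI3K/Akt,
PLCgamma/Ca, Raf/MEK/Erk, eNOS, VE-cadherin).

Species live in named compartments and carry an explicit monomer
composition; every rule that is not flagged ``non_conserving`` must balance
monomer counts, which is what the conservation tests lean on.

Rate-law vocabulary (documented forms; v is the reaction rate):

``mass_action``
    v = k * prod([reactant]) with at most two reactants.  Reversible rules
    add a second, reverse mass-action reaction with its own constant.
``michaelis_menten``
    v = kcat * [modifier] * [S] / (Km + [S]) for an enzymatic rule with one
    substrate; with no modifier the form degenerates to Vmax * [S]/(Km+[S])
    (used for the SERCA-style Ca reuptake flux).
``saturating_hill``
    v = k * [S] * [M] / (K + [M]) -- first order in the (optional)
    substrate, saturating in the modifier M.  With no substrate the rule is
    a zero-order synthesis gated by M (used for S1P production).

Any rule may additionally carry multiplicative *gates*
g = [G]/(Kg+[G]) (activating) or Kg/(Kg+[G]) (inhibitory); gates encode
coarse requirements such as the joint S1P-and-Ca dependence of Raf
activation, or the stabilisation of junctional pTie2 by Tie1.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
import hashlib

import numpy as np

COMPARTMENTS = (
    "extracellular",
    "surface",
    "junctional",
    "cytosol",
    "ER",
    "internalized",
    "WPB",
)

RATE_LAWS = ("mass_action", "michaelis_menten", "saturating_hill")

#: catalytic nodes recognised by :class:`InhibitorSpec`
INHIBITOR_TARGETS = ("Src", "Axl", "Akt", "VEGFR2")


class ModelError(ValueError):
    """Raised for structurally invalid model definitions."""


@dataclass(frozen=True)
class SpeciesDef:
    """A model species: where it lives, what it is made of, how it starts.

    ``composition`` maps monomer names to positive copy counts (an Ang1
    tetramer bound to four Tie2 receptors is ``{"Ang1": 4, "Tie2": 4}``).
    Messenger species with an empty composition (Ca, S1P, IP3) are exempt
    from monomer-balance checking.  ``initial_value_key`` names the
    ParameterSet entry holding the initial abundance; ``None`` means the
    species starts at zero and is filled by the dynamics.
    """

    name: str
    compartment: str
    composition: dict = field(default_factory=dict)
    phospho: tuple = ()
    initial_value_key: str | None = None

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ModelError(f"unknown compartment {self.compartment!r} for species {self.name}")
        for m, n in self.composition.items():
            if not (isinstance(n, int) and n > 0):
                raise ModelError(f"composition count for {m} in {self.name} must be a positive integer")


@dataclass(frozen=True)
class Gate:
    """Multiplicative saturation factor on a rule rate."""

    species: str
    k_key: str
    sign: int = 1  # +1 activating, -1 inhibitory


@dataclass(frozen=True)
class ReactionRule:
    name: str
    reactants: tuple
    products: tuple
    rate_law: str
    rate_constant_key: str
    km_key: str | None = None
    modifier: str | None = None
    reversible: bool = False
    reverse_key: str | None = None
    gates: tuple = ()
    non_conserving: bool = False
    #: explicit stoichiometry override {species: signed int}; used by the
    #: lumped Ang2-tetramer clustering step which consumes 3 Tie2 in one rule
    stoich_override: dict | None = None
    subsystems: frozenset = frozenset({"core"})
    #: catalytic node(s) whose pharmacological inhibition scales this rule
    inhibitor_target: tuple = ()

    def __post_init__(self):
        if self.rate_law not in RATE_LAWS:
            raise ModelError(f"rule {self.name}: unknown rate law {self.rate_law!r}")
        if self.rate_law == "mass_action" and len(self.reactants) > 2:
            raise ModelError(f"rule {self.name}: mass_action rules take at most 2 reactants")
        if self.rate_law == "michaelis_menten" and len(self.reactants) != 1:
            raise ModelError(f"rule {self.name}: enzymatic rules take exactly one substrate")
        if self.reversible and not self.reverse_key:
            raise ModelError(f"rule {self.name}: reversible rule needs a reverse constant key")
        if isinstance(self.inhibitor_target, str):
            object.__setattr__(self, "inhibitor_target", (self.inhibitor_target,))
        for t in self.inhibitor_target:
            if t not in INHIBITOR_TARGETS:
                raise ModelError(f"rule {self.name}: unknown inhibitor target {t!r}")

    def stoichiometry(self) -> dict:
        """Net stoichiometry {species: coefficient} of the forward reaction."""
        if self.stoich_override is not None:
            return dict(self.stoich_override)
        st = Counter()
        for r in self.reactants:
            st[r] -= 1
        for p in self.products:
            st[p] += 1
        return {s: c for s, c in st.items() if c != 0}

    def parameter_keys(self) -> list:
        keys = [self.rate_constant_key]
        if self.km_key:
            keys.append(self.km_key)
        if self.reverse_key:
            keys.append(self.reverse_key)
        keys.extend(g.k_key for g in self.gates)
        return keys


@dataclass(frozen=True)
class InhibitorSpec:
    """Instantaneous fractional inhibition of a catalytic node.

    The inhibitor scales the target node's activation rate constant by
    (1 - fraction) from ``apply_time`` (minutes) onward.  Inhibitors are
    activity scalings, not binding species.
    """

    target: str
    fraction: float
    apply_time: float = 0.0

    def __post_init__(self):
        if self.target not in INHIBITOR_TARGETS:
            raise ModelError(f"unknown inhibitor target {self.target!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ModelError("inhibitor fraction must lie in [0, 1]")


class ParameterSet:
    """Named positive parameters with optional bounds and source metadata.

    Values are rate constants (per-min, per-nM-per-min), abundances (nM) or
    dimensionless factors.  Keys referenced by any rule or species initial
    condition must be present.
    """

    def __init__(self, values, bounds=None, metadata=None):
        self.values = dict(values)
        self.bounds = dict(bounds or {})
        self.metadata = dict(metadata or {})
        for k, v in self.values.items():
            if not v > 0:
                raise ModelError(f"parameter {k} must be strictly positive (got {v})")
        for k, (lo, hi) in self.bounds.items():
            v = self.values.get(k)
            if v is not None and not (lo <= v <= hi):
                raise ModelError(f"parameter {k}={v} outside bounds ({lo}, {hi})")
        self._order = list(self.values)
        self._index = {k: i for i, k in enumerate(self._order)}

    def __contains__(self, key):
        return key in self.values

    def __getitem__(self, key):
        return self.values[key]

    def __len__(self):
        return len(self.values)

    def keys(self):
        return list(self._order)

    def index(self, key) -> int:
        try:
            return self._index[key]
        except KeyError:
            raise ModelError(f"parameter key {key!r} not found in ParameterSet") from None

    def vector(self) -> np.ndarray:
        return np.array([self.values[k] for k in self._order], dtype=float)

    def with_updates(self, updates) -> "ParameterSet":
        vals = dict(self.values)
        for k, v in updates.items():
            if k not in vals:
                raise ModelError(f"unknown parameter key {k!r}")
            vals[k] = float(v)
        return ParameterSet(vals, self.bounds, self.metadata)

    def from_vector(self, vec) -> "ParameterSet":
        vals = {k: float(v) for k, v in zip(self._order, vec)}
        return ParameterSet(vals, self.bounds, self.metadata)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for k in self._order:
            h.update(k.encode())
            h.update(np.float64(self.values[k]).tobytes())
        return h.hexdigest()[:16]


@dataclass
class NetworkModel:
    """Species + rules + observables; compiled by :mod:`endosig.compile`."""

    species: list
    rules: list
    observables: dict
    config: "object" = None
    inhibitors: list = field(default_factory=list)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(names) != len(set(names)):
            dup = [n for n, c in Counter(names).items() if c > 1]
            raise ModelError(f"duplicate species names: {dup}")
        self._sindex = {n: i for i, n in enumerate(names)}
        known = set(names)
        for r in self.rules:
            for s in list(r.reactants) + list(r.products) + list(r.stoichiometry()):
                if s not in known:
                    raise ModelError(f"rule {r.name} references unknown species {s!r}")
            if r.modifier is not None and r.modifier not in known:
                raise ModelError(f"rule {r.name} has unknown modifier {r.modifier!r}")
            for g in r.gates:
                if g.species not in known:
                    raise ModelError(f"rule {r.name} has unknown gate species {g.species!r}")
        for obs, weights in self.observables.items():
            for s in weights:
                if s not in known:
                    raise ModelError(f"observable {obs} references unknown species {s!r}")

    # -- lookups -----------------------------------------------------------
    @property
    def species_names(self):
        return [s.name for s in self.species]

    def species_index(self, name) -> int:
        return self._sindex[name]

    def rule(self, name) -> ReactionRule:
        for r in self.rules:
            if r.name == name:
                return r
        raise ModelError(f"no rule named {name!r}")

    def parameter_keys(self) -> set:
        keys = set()
        for r in self.rules:
            keys.update(r.parameter_keys())
        for s in self.species:
            if s.initial_value_key:
                keys.add(s.initial_value_key)
        return keys

    def validate_parameters(self, params: ParameterSet):
        missing = sorted(k for k in self.parameter_keys() if k not in params)
        if missing:
            raise ModelError(f"missing parameter keys: {missing}")

    # -- stoichiometry -----------------------------------------------------
    def expanded_reactions(self):
        """One entry per compiled reaction column (reversible rules give 2)."""
        out = []
        for r in self.rules:
            out.append((r, +1))
            if r.reversible:
                out.append((r, -1))
        return out

    def stoichiometry_matrix(self) -> np.ndarray:
        cols = self.expanded_reactions()
        S = np.zeros((len(self.species), len(cols)))
        for j, (r, direction) in enumerate(cols):
            for s, c in r.stoichiometry().items():
                S[self._sindex[s], j] = direction * c
        return S

    # -- conservation ------------------------------------------------------
    def monomers(self) -> list:
        mons = set()
        for s in self.species:
            mons.update(s.composition)
        return sorted(mons)

    def monomer_matrix(self) -> np.ndarray:
        """(n_monomers x n_species) copy-count matrix."""
        mons = self.monomers()
        M = np.zeros((len(mons), len(self.species)))
        for j, s in enumerate(self.species):
            for m, c in s.composition.items():
                M[mons.index(m), j] = c
        return M

    def check_monomer_balance(self) -> list:
        """Return names of non-flagged rules violating monomer conservation."""
        comp = {s.name: s.composition for s in self.species}
        bad = []
        for r in self.rules:
            if r.non_conserving:
                continue
            net = Counter()
            for sp, c in r.stoichiometry().items():
                for m, n in comp[sp].items():
                    net[m] += c * n
            if any(v != 0 for v in net.values()):
                bad.append(r.name)
        return bad

    def conserved_pools(self) -> dict:
        """monomer -> [(species, multiplicity), ...] over all members."""
        pools = {}
        for m in self.monomers():
            members = [(s.name, s.composition[m]) for s in self.species if m in s.composition]
            pools[m] = members
        return pools

    def with_inhibitor(self, spec: InhibitorSpec) -> "NetworkModel":
        m = replace(self)
        m.inhibitors = list(self.inhibitors) + [spec]
        return m


def apply_inhibitor(model: NetworkModel, spec: InhibitorSpec) -> NetworkModel:
    """Return a model with ``spec`` attached; the compiled simulator scales
    the target node's activation rate constant by (1 - fraction) from
    ``spec.apply_time`` onward, leaving every other rule untouched."""
    return model.with_inhibitor(spec)
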