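"""Mass-action network of higher-order GL3-centred complexes.

GL3 is a scaffold with two independent ligand sites per molecule: a MYB site
(bound by GL1 or, in the extended network, by the R3MYB inhibitor TRY) and a
WD40 site (bound by TTG1).  GL3 additionally homodimerizes, which lifts the
largest complex to a hexamer (two GL3, two MYB-site ligands, two TTG1).

Species bookkeeping is *positional*: the two subunits of a GL3 dimer are
tracked as distinguishable, which is the enumeration under which the
canonical network (GL1 + TTG1 + GL3 with dimerization) has 22 species and 92
mass-action reactions (46 reversible pairs).  Reporting aggregates positional
microstates into structurally distinct (unordered) complexes - 13 without
the inhibitor, 26 with TRY.

Reaction rules
--------------
* Ligand binding is per subunit and independent between subunits.
* Negative cooperativity couples GL1 and TTG1 on the *same* subunit: once one
  is bound, the dissociation constant of the other is divided by ``alpha``
  (alpha < 1 weakens the second event).  TRY binds independently of TTG1 by
  default; ``try_cooperativity=True`` applies the same coupling to TRY as a
  sensitivity analysis.
* GL3 dimerization is independent of ligand occupancy on either subunit.
* Dimer association is written once per unordered pair of subunit states,
  producing the canonically ordered dimer; the mirrored ordering is reached
  through ligand events.  Thermodynamic cycle closure (checked at build time)
  makes the equilibrium independent of this bookkeeping choice.

Rate constants are scale-free for a closed system at equilibrium: each
reversible pair gets forward rate 1 and backward rate equal to the effective
relative dissociation constant, so only K ratios matter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .binding_models import RelativeKD

__all__ = [
    "Subunit",
    "Species",
    "Reaction",
    "ReactionNetwork",
    "EquilibriumState",
    "FractionReport",
    "NetworkConstructionError",
    "PAPER_KDS",
    "PAPER_ALPHA",
    "build_network",
    "enumerate_complexes",
    "solve_equilibrium",
    "fraction_report",
    "ratio_scan",
    "mass_action_rhs",
    "export_sbml",
    "import_sbml",
]

#: Relative dissociation constants estimated from the pull-down titrations
#: (dimensionless, relative to total GL3).
PAPER_KDS = {
    "GL3-GL1": 0.5,
    "GL3-TTG1": 1.0,
    "GL3-GL3": 0.5,
    "GL3-TRY": 2.7,
    "GL3-CPC": 2.3,
}

#: Cooperativity between GL1 and TTG1 on the same GL3 subunit, estimated with
#: GL3 homodimerization included.
PAPER_ALPHA = 0.4

_MYB_CODE = {"": "0", "GL1": "G", "TRY": "Y"}
_WD_CODE = {"": "0", "TTG1": "T"}
_MYB_DECODE = {v: k for k, v in _MYB_CODE.items()}
_WD_DECODE = {v: k for k, v in _WD_CODE.items()}


class NetworkConstructionError(RuntimeError):
    """Raised when the network cannot be built consistently."""


@dataclass(frozen=True, order=True)
class Subunit:
    """Occupancy of one GL3 molecule's two ligand sites."""

    myb: str = ""  # "", "GL1" or "TRY"
    wd: str = ""  # "" or "TTG1"

    @property
    def code(self) -> str:
        return _MYB_CODE[self.myb] + _WD_CODE[self.wd]

    @property
    def n_ligands(self) -> int:
        return (self.myb != "") + (self.wd != "")

    @property
    def label(self) -> str:
        bound = [p for p in (self.myb, self.wd) if p]
        return "GL3(" + ",".join(bound) + ")" if bound else "GL3"

    @classmethod
    def from_code(cls, code: str) -> "Subunit":
        return cls(myb=_MYB_DECODE[code[0]], wd=_WD_DECODE[code[1]])


@dataclass(frozen=True)
class Species:
    """A chemical species: a free ligand or a GL3 scaffold with occupancy."""

    kind: str  # "ligand" or "scaffold"
    name: str = ""  # ligand protein name
    subunits: tuple[Subunit, ...] = ()

    def __post_init__(self):
        if self.kind not in ("ligand", "scaffold"):
            raise ValueError(f"unknown species kind {self.kind!r}")
        if self.kind == "scaffold" and len(self.subunits) not in (1, 2):
            raise ValueError("scaffold species carry one or two GL3 subunits")

    @property
    def n_gl3(self) -> int:
        return len(self.subunits) if self.kind == "scaffold" else 0

    @property
    def composition(self) -> dict[str, int]:
        if self.kind == "ligand":
            return {self.name: 1}
        comp: dict[str, int] = {"GL3": self.n_gl3}
        for sub in self.subunits:
            for p in (sub.myb, sub.wd):
                if p:
                    comp[p] = comp.get(p, 0) + 1
        return comp

    @property
    def n_proteins(self) -> int:
        return sum(self.composition.values())

    def count(self, protein: str) -> int:
        return self.composition.get(protein, 0)

    @property
    def contains_try(self) -> bool:
        return self.count("TRY") > 0

    @property
    def ordered_id(self) -> str:
        if self.kind == "ligand":
            return self.name
        return "GL3_" + "__GL3_".join(s.code for s in self.subunits)

    @property
    def unordered_id(self) -> str:
        if self.kind == "ligand":
            return self.name
        return "GL3_" + "__GL3_".join(sorted(s.code for s in self.subunits))

    @property
    def label(self) -> str:
        if self.kind == "ligand":
            return self.name
        return "·".join(s.label for s in self.subunits)

    @classmethod
    def from_ordered_id(cls, sid: str) -> "Species":
        if not sid.startswith("GL3_"):
            return cls(kind="ligand", name=sid)
        codes = [part for part in sid.split("__")]
        subs = tuple(Subunit.from_code(c.removeprefix("GL3_")) for c in codes)
        return cls(kind="scaffold", subunits=subs)


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction (indices into the species list)."""

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: float

    def reversed_against(self, other: "Reaction") -> bool:
        return sorted(self.reactants) == sorted(other.products) and sorted(
            self.products
        ) == sorted(other.reactants)


@dataclass
class ReactionNetwork:
    """Species list, reactions, and derived stoichiometric structure."""

    species: list[Species]
    reactions: list[Reaction]
    reversible_pairs: list[tuple[int, int]]
    kds: dict[str, float] = field(default_factory=dict)
    alpha: float = 1.0
    include_try: bool = False
    include_gl3_dimer: bool = True
    try_cooperativity: bool = False

    # derived (filled in __post_init__)
    proteins: list[str] = field(default_factory=list)
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        prots: list[str] = []
        for sp in self.species:
            for p in sp.composition:
                if p not in prots:
                    prots.append(p)
        self.proteins = prots
        self.index = {sp.ordered_id: i for i, sp in enumerate(self.species)}
        self._free_index = {
            p: self.index["GL3_00" if p == "GL3" else p] for p in prots
        }
        self._comp = np.array(
            [[sp.count(p) for p in prots] for sp in self.species], dtype=float
        )
        self._weights = self._thermodynamic_weights()

    # -- structure ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def composition_matrix(self) -> np.ndarray:
        """(N x P) protein content of every species."""
        return self._comp.copy()

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """(N x R) net stoichiometry of every reaction."""
        S = np.zeros((self.n_species, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for i in rxn.reactants:
                S[i, j] -= 1
            for i in rxn.products:
                S[i, j] += 1
        return S

    @property
    def molecularity_matrix(self) -> np.ndarray:
        """(N x R) reactant molecularities beta_ij."""
        B = np.zeros((self.n_species, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for i in rxn.reactants:
                B[i, j] += 1
        return B

    @property
    def rate_constants(self) -> np.ndarray:
        return np.array([r.rate for r in self.reactions])

    def equilibrium_constant(self, pair: tuple[int, int]) -> float:
        """Association equilibrium constant (k_f / k_b) of a reversible pair."""
        f, b = pair
        return self.reactions[f].rate / self.reactions[b].rate

    # -- thermodynamics ----------------------------------------------------

    def _thermodynamic_weights(self) -> np.ndarray:
        """Weight g_s such that c_s = g_s * prod_p m_p^{n_ps} at equilibrium.

        Assigned by walking association reactions outward from the free
        monomers; revisits must agree to 1e-10 relative (cycle closure),
        otherwise the rate assignment violates detailed balance.
        """
        g = np.full(self.n_species, np.nan)
        for p, i in self._free_index.items():
            g[i] = 1.0
        changed = True
        while changed:
            changed = False
            for f, b in self.reversible_pairs:
                rxn = self.reactions[f]
                if len(rxn.products) != 1:
                    raise NetworkConstructionError(
                        "association reactions must have a single product"
                    )
                prod = rxn.products[0]
                if any(np.isnan(g[i]) for i in rxn.reactants):
                    continue
                K = self.equilibrium_constant((f, b))
                val = np.prod([g[i] for i in rxn.reactants]) * K
                if np.isnan(g[prod]):
                    g[prod] = val
                    changed = True
                elif abs(g[prod] - val) > 1e-10 * max(abs(val), abs(g[prod])):
                    raise NetworkConstructionError(
                        "thermodynamic cycle closure violated at species "
                        f"{self.species[prod].ordered_id}: {g[prod]!r} vs {val!r}"
                    )
        if np.any(np.isnan(g)):
            if self.alpha == 0:
                # alpha = 0 forbids the cooperative second binding event, so
                # doubly-occupied subunit states are thermodynamically absent
                g = np.where(np.isnan(g), 0.0, g)
            else:
                missing = [
                    self.species[i].ordered_id for i in np.flatnonzero(np.isnan(g))
                ]
                raise NetworkConstructionError(f"unreachable species: {missing}")
        return g

    def species_concentrations(self, free: np.ndarray) -> np.ndarray:
        """Concentrations of all species given free-monomer concentrations.

        ``free`` has shape (..., P) ordered like ``self.proteins``; returns
        shape (..., N).
        """
        free = np.asarray(free, dtype=float)
        # exp(-1e4) underflows to exactly 0, so species containing an absent
        # monomer come out at 0 while others are untouched
        logm = np.where(free > 0, np.log(np.where(free > 0, free, 1.0)), -1e4)
        expo = logm @ self._comp.T  # (..., N)
        with np.errstate(over="ignore"):
            return self._weights * np.exp(expo)


@dataclass
class EquilibriumState:
    """Solved steady state of a closed network (normalized concentrations)."""

    network: ReactionNetwork
    concentrations: np.ndarray  # (..., N)
    free_monomers: np.ndarray  # (..., P)
    totals: dict[str, float | np.ndarray]

    def concentration(self, species_id: str) -> float | np.ndarray:
        """Concentration of one ordered species id (or free ligand name)."""
        return self.concentrations[..., self.network.index[species_id]]

    def unordered_concentrations(self) -> dict[str, float | np.ndarray]:
        """Aggregate positional microstates into unordered complexes."""
        agg: dict[str, float | np.ndarray] = {}
        for i, sp in enumerate(self.network.species):
            agg[sp.unordered_id] = agg.get(sp.unordered_id, 0.0) + self.concentrations[
                ..., i
            ]
        return agg

    def species_table(self) -> pd.DataFrame:
        """Per-species table (scalar states only)."""
        conc = np.atleast_2d(self.concentrations)
        if conc.shape[0] != 1:
            raise ValueError("species_table is defined for scalar states")
        rows = []
        for sp, c in zip(self.network.species, conc[0]):
            rows.append(
                {
                    "ordered_id": sp.ordered_id,
                    "unordered_id": sp.unordered_id,
                    "label": sp.label,
                    "n_proteins": sp.n_proteins,
                    "n_gl3": sp.n_gl3,
                    "contains_try": sp.contains_try,
                    "concentration": float(c),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class FractionReport:
    """Percentages of complex groupings against an explicit denominator."""

    denominator: str
    denominator_total: float
    table: pd.DataFrame  # unordered complexes with percent column
    groupings: dict[str, float]
    alternatives: dict[str, float]

    def percent(self, grouping: str) -> float:
        return self.groupings[grouping]


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _as_kd_value(v) -> float:
    if isinstance(v, RelativeKD):
        return float(v.value)
    return float(v)


def _subunit_states(include_try: bool) -> list[Subunit]:
    mybs = ["", "GL1"] + (["TRY"] if include_try else [])
    return [Subunit(myb=m, wd=w) for m in mybs for w in ["", "TTG1"]]


def build_network(
    include_try: bool = False,
    include_gl3_dimer: bool = True,
    kds: Mapping[str, float | RelativeKD] | None = None,
    alpha: float = PAPER_ALPHA,
    try_cooperativity: bool = False,
) -> ReactionNetwork:
    """Enumerate species and single-binding-step reactions.

    Parameters
    ----------
    include_try
        Add the R3MYB inhibitor TRY, competing with GL1 for the MYB site of
        each GL3 subunit.
    include_gl3_dimer
        Add GL3 homodimerization and all positional dimer states.
    kds
        Relative dissociation constants keyed ``"GL3-GL1"``, ``"GL3-TTG1"``,
        ``"GL3-GL3"`` (if dimerization) and ``"GL3-TRY"`` (if TRY).  Defaults
        to the estimates in :data:`PAPER_KDS`.
    alpha
        Cooperativity between GL1 and TTG1 on the same GL3 subunit: the
        second of the two binding events sees its K divided by ``alpha``.
    try_cooperativity
        Apply the same coupling between TRY and TTG1 (sensitivity analysis;
        off by default - the estimated cooperativity concerns GL1 and TTG1).
    """
    if kds is None:
        kds = PAPER_KDS
    kmap = {k: _as_kd_value(v) for k, v in kds.items()}
    required = ["GL3-GL1", "GL3-TTG1"]
    if include_gl3_dimer:
        required.append("GL3-GL3")
    if include_try:
        required.append("GL3-TRY")
    for key in required:
        if key not in kmap:
            raise NetworkConstructionError(f"missing relative K_D for {key}")
        if not kmap[key] > 0:
            raise NetworkConstructionError(f"relative K_D for {key} must be > 0")
    if alpha < 0:
        raise NetworkConstructionError("cooperativity alpha must be >= 0")

    states = _subunit_states(include_try)
    ligands = ["GL1", "TTG1"] + (["TRY"] if include_try else [])

    species: list[Species] = [Species(kind="ligand", name=p) for p in ligands]
    mono = {s: Species(kind="scaffold", subunits=(s,)) for s in states}
    species.extend(mono.values())
    dimer: dict[tuple[Subunit, Subunit], Species] = {}
    if include_gl3_dimer:
        for s1, s2 in itertools.product(states, repeat=2):
            dimer[(s1, s2)] = Species(kind="scaffold", subunits=(s1, s2))
        species.extend(dimer.values())

    idx = {sp.ordered_id: i for i, sp in enumerate(species)}

    def effective_kd(sub: Subunit, ligand: str) -> float:
        if ligand == "TTG1":
            k = kmap["GL3-TTG1"]
            if sub.myb == "GL1" or (try_cooperativity and sub.myb == "TRY"):
                k = k / alpha if alpha > 0 else np.inf
            return k
        k = kmap[f"GL3-{ligand}"]
        if sub.wd == "TTG1" and (ligand == "GL1" or try_cooperativity):
            k = k / alpha if alpha > 0 else np.inf
        return k

    def binding_events(sub: Subunit):
        """(ligand, new subunit, effective K) for every open site."""
        events = []
        if sub.myb == "":
            for lig in ["GL1"] + (["TRY"] if include_try else []):
                events.append(
                    (lig, Subunit(myb=lig, wd=sub.wd), effective_kd(sub, lig))
                )
        if sub.wd == "":
            events.append(
                ("TTG1", Subunit(myb=sub.myb, wd="TTG1"), effective_kd(sub, "TTG1"))
            )
        return events

    reactions: list[Reaction] = []
    pairs: list[tuple[int, int]] = []

    def add_pair(reactants: tuple[int, ...], product: int, K: float):
        # alpha = 0 forbids the cooperative event entirely (backward rate
        # would be infinite); the species stays in the network but the
        # doubly-occupied state is unreachable, matching the competitive limit
        if not np.isfinite(K):
            return
        f = Reaction(reactants=reactants, products=(product,), rate=1.0)
        b = Reaction(reactants=(product,), products=reactants, rate=K)
        reactions.append(f)
        reactions.append(b)
        pairs.append((len(reactions) - 2, len(reactions) - 1))

    # ligand binding on the monomeric scaffold
    for s in states:
        for lig, s_new, K in binding_events(s):
            add_pair((idx[mono[s].ordered_id], idx[lig]), idx[mono[s_new].ordered_id], K)

    # ligand binding on either dimer subunit (positional)
    if include_gl3_dimer:
        for s1, s2 in itertools.product(states, repeat=2):
            here = idx[dimer[(s1, s2)].ordered_id]
            for lig, s_new, K in binding_events(s1):
                add_pair((here, idx[lig]), idx[dimer[(s_new, s2)].ordered_id], K)
            for lig, s_new, K in binding_events(s2):
                add_pair((here, idx[lig]), idx[dimer[(s1, s_new)].ordered_id], K)

        # dimerization: one reaction per unordered pair of subunit states,
        # producing the canonically ordered dimer
        for i, s1 in enumerate(states):
            for s2 in states[i:]:
                add_pair(
                    (idx[mono[s1].ordered_id], idx[mono[s2].ordered_id]),
                    idx[dimer[(s1, s2)].ordered_id],
                    kmap["GL3-GL3"],
                )

    net = ReactionNetwork(
        species=species,
        reactions=reactions,
        reversible_pairs=pairs,
        kds=kmap,
        alpha=alpha,
        include_try=include_try,
        include_gl3_dimer=include_gl3_dimer,
        try_cooperativity=try_cooperativity,
    )
    _check_reaction_conservation(net)
    return net


def _check_reaction_conservation(net: ReactionNetwork) -> None:
    """Every reaction must conserve each protein's total count."""
    comp = net.composition_matrix  # N x P
    S = net.stoichiometric_matrix  # N x R
    drift = comp.T @ S  # P x R
    if np.any(np.abs(drift) > 0):
        raise NetworkConstructionError("a reaction violates protein conservation")


def enumerate_complexes(network: ReactionNetwork) -> list[str]:
    """Structurally distinct complexes (>= 2 proteins, dimers unordered)."""
    seen = sorted(
        {sp.unordered_id for sp in network.species if sp.n_proteins >= 2}
    )
    return seen


# ---------------------------------------------------------------------------
# equilibrium solving
# ---------------------------------------------------------------------------

def solve_equilibrium(
    network: ReactionNetwork,
    totals: Mapping[str, float | Sequence[float]],
    rtol: float = 1e-12,
    max_iter: int = 200,
) -> EquilibriumState:
    """Solve the closed system for its equilibrium speciation.

    Works in the free-monomer representation: at equilibrium every species
    concentration is a product of free-monomer concentrations and equilibrium
    constants (detailed balance), so conservation of each protein gives one
    equation per free monomer.  Solved by damped Newton iteration in
    log-concentration space; conservation is verified to 1e-9 relative and
    detailed balance of every reversible pair to 1e-8 relative.

    ``totals`` maps protein name to total amount (scalar or array; arrays
    broadcast to batched solves).  A protein absent from the mapping, or with
    total 0, is held at zero.
    """
    prots = network.proteins
    tot_list = [np.asarray(totals.get(p, 0.0), dtype=float) for p in prots]
    if any(np.any(t < 0) for t in tot_list):
        raise ValueError("totals must be non-negative")
    T = np.stack(np.broadcast_arrays(*tot_list), axis=-1)  # (..., P)
    batch_shape = T.shape[:-1]
    Tf = T.reshape(-1, len(prots))

    free = solve_conservation(
        network._comp, network._weights, Tf, rtol=rtol, max_iter=max_iter
    )
    conc = network.species_concentrations(free)

    # conservation check
    recovered = conc @ network._comp  # (B, P)
    err = np.abs(recovered - Tf) / np.maximum(1.0, Tf)
    if np.max(err) > 1e-9:
        raise RuntimeError(
            f"conservation residual {np.max(err):.3e} exceeds 1e-9 after solve"
        )
    _check_detailed_balance(network, conc)

    return EquilibriumState(
        network=network,
        concentrations=conc.reshape(*batch_shape, network.n_species),
        free_monomers=free.reshape(*batch_shape, len(prots)),
        totals={p: totals.get(p, 0.0) for p in prots},
    )


def solve_conservation(
    comp: np.ndarray,
    weights: np.ndarray,
    T: np.ndarray,
    rtol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Batched damped Newton for detailed-balanced speciation problems.

    Solves the per-protein conservation equations of a closed equilibrium
    system whose species concentrations are monomials in the free-monomer
    concentrations: ``c_s = weights[s] * prod_p m_p^{comp[s, p]}``.

    Parameters
    ----------
    comp : (N, P) protein content of every species.
    weights : (N,) thermodynamic weight of every species.
    T : (B, P) totals per batch element; zero totals are held at zero.

    Returns the free-monomer concentrations, shape (B, P).
    """
    comp = np.asarray(comp, dtype=float)
    weights = np.asarray(weights, dtype=float)
    T = np.asarray(T, dtype=float)
    B, P = T.shape
    active = T > 0
    scale = np.maximum(1.0, T)
    diag = np.arange(P)

    # The conservation residual is the gradient of the strictly convex
    # potential Phi(logm) = sum_s c_s(logm) - sum_p T_p logm_p, whose Hessian
    # is the Gram matrix J[p,q] = sum_s n_ps n_qs c_s; damped Newton with an
    # Armijo backtracking line search on Phi is therefore globally convergent.
    logm = np.where(active, np.log(np.where(active, T, 1.0)) - 2.0, -1e4)

    def evaluate(logm):
        with np.errstate(over="ignore"):
            conc = weights * np.exp(logm @ comp.T)
        rec = conc @ comp
        r = np.where(active, rec - T, 0.0)
        phi = np.sum(conc, axis=1) - np.sum(
            np.where(active, T * logm, 0.0), axis=1
        )
        return conc, r, phi

    conc, r, phi = evaluate(logm)
    stall = 0
    prev_res = np.inf
    for _ in range(max_iter):
        res = np.max(np.abs(r) / scale, axis=1)
        worst_res = float(np.max(res))
        if worst_res <= rtol:
            break
        # rounding plateau: residual no longer improves
        stall = stall + 1 if worst_res >= prev_res * 0.9 else 0
        prev_res = min(prev_res, worst_res)
        if stall >= 5:
            break
        J = np.einsum("bs,sp,sq->bpq", conc, comp, comp)
        inact = ~active
        J[inact[:, :, None] | inact[:, None, :]] = 0.0
        J[:, diag, diag] = np.where(active, J[:, diag, diag], 1.0)
        # Levenberg-style floor keeps J invertible when concentrations vanish
        J[:, diag, diag] += 1e-14 * scale
        try:
            step = np.linalg.solve(J, -r[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = (-np.linalg.pinv(J) @ r[..., None])[..., 0]
        step = np.clip(step, -50.0, 50.0)
        slope = np.sum(r * step, axis=1)  # directional derivative of Phi
        lam = np.ones(B)
        # in the quadratic-convergence basin the line search cannot resolve
        # the (rounding-level) Phi decrease; take the pure Newton step there
        accept = res < 1e-4
        trial = np.where(accept[:, None], logm + step, logm)
        for _ls in range(60):
            cand = np.where(accept[:, None], trial, logm + lam[:, None] * step)
            conc_t, r_t, phi_t = evaluate(cand)
            ok = phi_t <= phi + 1e-4 * lam * slope
            trial = np.where((ok & ~accept)[:, None], cand, trial)
            accept = accept | ok
            if np.all(accept):
                break
            lam = np.where(accept, lam, lam * 0.5)
        if not np.all(accept):
            # a zero step is always Armijo-admissible up to rounding; treat
            # remaining elements as converged-at-machine-precision
            trial = np.where(accept[:, None], trial, logm)
        logm = trial
        conc, r, phi = evaluate(logm)
    res = np.max(np.abs(r) / scale, axis=1)
    if np.any(res > 1e-9):
        worst = int(np.argmax(res))
        raise RuntimeError(
            "equilibrium solve did not converge "
            f"(relative residual {res[worst]:.3e} at totals {T[worst]})"
        )
    return np.where(active, np.exp(logm), 0.0)


def _check_detailed_balance(network: ReactionNetwork, conc: np.ndarray) -> None:
    """Forward and backward fluxes of every reversible pair must match."""
    c = np.atleast_2d(conc)
    for f, b in network.reversible_pairs:
        vf = network.reactions[f].rate * np.prod(
            c[:, list(network.reactions[f].reactants)], axis=1
        )
        vb = network.reactions[b].rate * np.prod(
            c[:, list(network.reactions[b].reactants)], axis=1
        )
        denom = np.maximum(np.maximum(vf, vb), 1e-300)
        rel = np.abs(vf - vb) / denom
        # fluxes that are both essentially zero are balanced
        rel[np.maximum(vf, vb) < 1e-250] = 0.0
        if np.max(rel) > 1e-8:
            raise RuntimeError(
                f"detailed balance violated (relative flux residual {np.max(rel):.3e})"
            )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

_DENOMINATORS = ("all_complexes", "single_gl3_complexes", "dimer_gl3_complexes")


def fraction_report(
    state: EquilibriumState, denominator: str = "all_complexes"
) -> FractionReport:
    """Percentages of complex classes against an explicit denominator.

    A *complex* is any species containing at least two proteins; positional
    dimer microstates are aggregated into unordered complexes and weighted by
    concentration.  ``denominator`` selects the reference set:
    ``all_complexes``, ``single_gl3_complexes`` (exactly one GL3) or
    ``dimer_gl3_complexes`` (two GL3).

    Besides the primary convention, ``alternatives`` reports the readings the
    printed percentages do not disambiguate: percentages with the bare GL3
    homodimer excluded from the complex denominator, and the TRY share among
    single-GL3 complexes restricted to those without TTG1.
    """
    if denominator not in _DENOMINATORS:
        raise ValueError(f"denominator must be one of {_DENOMINATORS}")
    net = state.network
    conc = np.asarray(state.concentrations)
    if conc.ndim != 1:
        raise ValueError("fraction_report expects a scalar (non-batched) state")

    by_unordered: dict[str, dict] = {}
    for i, sp in enumerate(net.species):
        if sp.n_proteins < 2:
            continue
        entry = by_unordered.setdefault(
            sp.unordered_id,
            {
                "unordered_id": sp.unordered_id,
                "label": sp.label,
                "n_proteins": sp.n_proteins,
                "n_gl3": sp.n_gl3,
                "contains_try": sp.contains_try,
                "concentration": 0.0,
            },
        )
        entry["concentration"] += float(conc[i])
    table = pd.DataFrame(sorted(by_unordered.values(), key=lambda e: e["unordered_id"]))

    def total(mask) -> float:
        return float(table.loc[mask, "concentration"].sum())

    all_total = total(slice(None))
    single_total = total(table.n_gl3 == 1)
    dimer_total = total(table.n_gl3 == 2)
    denom_total = {
        "all_complexes": all_total,
        "single_gl3_complexes": single_total,
        "dimer_gl3_complexes": dimer_total,
    }[denominator]
    if denom_total <= 0:
        raise ValueError(f"denominator group {denominator!r} has zero concentration")

    table = table.assign(percent=100.0 * table.concentration / denom_total)

    trimer_id = "GL3_GT"  # single GL3 with GL1 and TTG1
    bare_dimer_id = "GL3_00__GL3_00"
    bare = float(
        table.loc[table.unordered_id == bare_dimer_id, "concentration"].sum()
    )
    groupings = {
        "single_gl3": 100.0 * single_total / denom_total,
        "dimer_gl3": 100.0 * dimer_total / denom_total,
        "hexamer": 100.0 * total(table.n_proteins == 6) / denom_total,
        "try_containing": 100.0 * total(table.contains_try) / denom_total,
        "try_in_single_gl3": (
            100.0 * total(table.contains_try & (table.n_gl3 == 1)) / single_total
            if single_total > 0
            else 0.0
        ),
        "try_in_dimer_gl3": (
            100.0 * total(table.contains_try & (table.n_gl3 == 2)) / dimer_total
            if dimer_total > 0
            else 0.0
        ),
        "gl1_gl3_ttg1_trimer": 100.0
        * total(table.unordered_id == trimer_id)
        / denom_total,
    }
    alt_denom = denom_total - (bare if denominator == "all_complexes" else 0.0)
    alternatives = {}
    if alt_denom > 0:
        alternatives["single_gl3_excl_bare_dimer"] = 100.0 * single_total / alt_denom
        alternatives["gl1_gl3_ttg1_trimer_excl_bare_dimer"] = (
            100.0 * total(table.unordered_id == trimer_id) / alt_denom
        )
    # TRY-containing single-GL3 complexes that do NOT also carry TTG1
    if single_total > 0:
        sole = total(table.contains_try & (table.n_gl3 == 1) & (table.n_proteins == 2))
        alternatives["try_only_in_single_gl3"] = 100.0 * sole / single_total

    return FractionReport(
        denominator=denominator,
        denominator_total=denom_total,
        table=table,
        groupings=groupings,
        alternatives=alternatives,
    )


def ratio_scan(
    network: ReactionNetwork,
    base_totals: Mapping[str, float],
    folds: Mapping[str, Iterable[float]] | None = None,
    fold_values: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
) -> pd.DataFrame:
    """Fraction reports over a grid of per-protein fold changes.

    Each scanned protein's total is ``base_totals[p] * fold``; GL3 stays at
    its base amount (fold changes are expressed relative to GL3).  Returns a
    long-format table with one row per (grid point, grouping).
    """
    if folds is None:
        folds = {
            p: fold_values for p in network.proteins if p != "GL3"
        }
    scan_prots = list(folds)
    rows = []
    for combo in itertools.product(*(folds[p] for p in scan_prots)):
        totals = dict(base_totals)
        for p, f in zip(scan_prots, combo):
            if f <= 0:
                raise ValueError("fold factors must be positive")
            totals[p] = base_totals.get(p, 0.0) * f
        state = solve_equilibrium(network, totals)
        rep = fraction_report(state)
        point = {f"{p.lower()}_fold": f for p, f in zip(scan_prots, combo)}
        for grouping, pct in rep.groupings.items():
            rows.append({**point, "grouping": grouping, "percent": pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# kinetics (ODE right-hand side, used as an independent solver path)
# ---------------------------------------------------------------------------

def mass_action_rhs(network: ReactionNetwork):
    """Return f(t, c) = S v(c, k) with mass-action rates v_j = k_j prod c^beta."""
    S = network.stoichiometric_matrix
    Bmat = network.molecularity_matrix
    k = network.rate_constants

    def rhs(_t, c):
        cc = np.maximum(np.asarray(c, dtype=float), 0.0)
        logs = np.where(cc > 0, np.log(np.where(cc > 0, cc, 1.0)), -1e4)
        v = k * np.exp(Bmat.T @ logs)
        return S @ v

    return rhs


def initial_concentrations(
    network: ReactionNetwork, totals: Mapping[str, float]
) -> np.ndarray:
    """All-free initial condition for kinetic integration."""
    c0 = np.zeros(network.n_species)
    for p, i in network._free_index.items():
        c0[i] = float(totals.get(p, 0.0))
    return c0


# ---------------------------------------------------------------------------
# SBML round trip
# ---------------------------------------------------------------------------

def export_sbml(network: ReactionNetwork, path: str) -> None:
    """Write the network as an SBML Level 3 core document.

    Each irreversible mass-action reaction becomes one SBML reaction with a
    kinetic law k * prod(reactants); species ids encode the scaffold
    occupancy so the document can be re-imported losslessly.
    """
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel("mbw_network")
    comp = model.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    for sp in network.species:
        s = model.createSpecies()
        s.setId(sp.ordered_id)
        s.setName(sp.label)
        s.setCompartment("cell")
        s.setInitialConcentration(0.0)
        s.setConstant(False)
        s.setBoundaryCondition(False)
        s.setHasOnlySubstanceUnits(False)

    for j, rxn in enumerate(network.reactions):
        r = model.createReaction()
        r.setId(f"r{j}")
        r.setReversible(False)
        for i in rxn.reactants:
            ref = r.createReactant()
            ref.setSpecies(network.species[i].ordered_id)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        for i in rxn.products:
            ref = r.createProduct()
            ref.setSpecies(network.species[i].ordered_id)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        law = r.createKineticLaw()
        param = law.createLocalParameter()
        param.setId("k")
        param.setValue(rxn.rate)
        formula = " * ".join(
            ["k"] + [network.species[i].ordered_id for i in rxn.reactants]
        )
        law.setMath(libsbml.parseL3Formula(formula))

    if doc.checkConsistency() > 0:
        errors = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        if errors:
            raise RuntimeError("SBML consistency check failed: " + "; ".join(errors))
    libsbml.writeSBMLToFile(doc, str(path))


def import_sbml(path: str) -> ReactionNetwork:
    """Re-import a document written by :func:`export_sbml`.

    The structural content (species, reactions, rate constants, reversible
    pairing) is reconstructed exactly; flags and the K_D map are inferred
    from the species set and rates where possible.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise RuntimeError(doc.getErrorLog().toString())
    model = doc.getModel()

    species = [
        Species.from_ordered_id(model.getSpecies(i).getId())
        for i in range(model.getNumSpecies())
    ]
    index = {sp.ordered_id: i for i, sp in enumerate(species)}

    reactions: list[Reaction] = []
    for j in range(model.getNumReactions()):
        r = model.getReaction(j)
        reactants = tuple(
            index[r.getReactant(i).getSpecies()] for i in range(r.getNumReactants())
        )
        products = tuple(
            index[r.getProduct(i).getSpecies()] for i in range(r.getNumProducts())
        )
        k = r.getKineticLaw().getLocalParameter("k").getValue()
        reactions.append(Reaction(reactants=reactants, products=products, rate=k))

    pairs = []
    used = set()
    for j, rxn in enumerate(reactions):
        if j in used or len(rxn.reactants) != 2:
            continue
        for jj, other in enumerate(reactions):
            if jj in used or jj == j:
                continue
            if rxn.reversed_against(other):
                pairs.append((j, jj))
                used.update((j, jj))
                break

    include_try = any(sp.ordered_id == "TRY" for sp in species)
    include_dimer = any(sp.n_gl3 == 2 for sp in species)
    return ReactionNetwork(
        species=species,
        reactions=reactions,
        reversible_pairs=pairs,
        include_try=include_try,
        include_gl3_dimer=include_dimer,
    )
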