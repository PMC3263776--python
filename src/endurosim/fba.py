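"""Stoichiometric model construction and flux-balance analysis (FBA).

A metabolic network is a list of reactions over compartment-tagged
metabolites (``_c`` cytosol, ``_m`` mitochondrion, ``_e`` extracellular).
At steady state every internal metabolite X obeys a Kirchhoff-type balance
— the fluxes producing X equal the fluxes consuming it — which yields one
equality row per internal metabolite of the stoichiometric matrix S, so
S v = 0.  Extracellular species are boundary pools and are excluded from
the balances.  Irreversible reactions contribute lower bounds v >= 0, and
measured uptake/release rates enter as bounds on exchange fluxes
(convention: positive exchange flux = release, negative = uptake).  FBA
maximizes or minimizes a linear objective over this polytope with an exact
LP solver.

The packaged application is cerebral carbon metabolism: glycolysis,
pentose phosphate pathway, TCA cycle, oxidative phosphorylation with an
explicit proton-motive pseudo-metabolite, malate-aspartate and
glycerol-3-phosphate shuttles, palmitate synthesis with its 14-NADPH
demand, alanine synthesis and glutamate/GABA cycling.  Whole-organ units
(mmol/min) are used throughout.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "Reaction",
    "FluxSystem",
    "FluxResult",
    "NetworkError",
    "parse_equation",
    "read_reaction_table",
    "load_brain_network",
    "load_formulas",
    "check_elemental_balance",
    "build_system",
    "solve_fba",
    "flux_ranges",
    "sample_flux_space",
    "brain_scenario",
    "carbon_report",
    "export_graph",
    "write_sbml",
    "read_sbml",
]

_ARROWS = ("<->", "<=>", "-->", "->")
_BIG = 1e4  # default box for otherwise unbounded fluxes


class NetworkError(ValueError):
    """Raised for malformed reactions, duplicate ids or unknown metabolites."""


@dataclass(frozen=True)
class Reaction:
    """One reaction: id, signed stoichiometry, reversibility, annotation."""

    id: str
    stoichiometry: dict  # metabolite -> signed coefficient (products positive)
    reversible: bool
    subsystem: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkError(f"{self.id}: empty stoichiometry")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise NetworkError(f"{self.id}: zero stoichiometric coefficient")

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions have an implicit empty side (pure source/sink)."""
        signs = {c > 0 for c in self.stoichiometry.values()}
        return len(signs) == 1

    def equation(self) -> str:
        def side(sign):
            parts = []
            for m, c in self.stoichiometry.items():
                if (c > 0) == (sign > 0):
                    a = abs(c)
                    parts.append(f"{a:g} {m}" if a != 1 else m)
            return " + ".join(parts)

        arrow = "<->" if self.reversible else "-->"
        return f"{side(-1)} {arrow} {side(+1)}".strip()


def parse_equation(reaction_id: str, text: str) -> tuple[dict, bool]:
    """Parse 'a + 2 b --> c' into signed stoichiometry and reversibility."""
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise NetworkError(f"{reaction_id}: no reaction arrow in '{text}'")
    lhs, rhs = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add(side: str, sign: float):
        for term in filter(None, (t.strip() for t in side.split("+"))):
            m = re.match(r"^(?:(\d+(?:\.\d+)?)\s+)?(\S+)$", term)
            if m is None:
                raise NetworkError(f"{reaction_id}: cannot parse term '{term}'")
            coef = float(m.group(1) or 1.0) * sign
            met = m.group(2)
            stoich[met] = stoich.get(met, 0.0) + coef

    add(lhs, -1.0)
    add(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    return stoich, arrow in ("<->", "<=>")


def read_reaction_table(path: str | Path) -> list[Reaction]:
    """Read a TSV of (reaction_id, equation, reversible, subsystem)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"reaction_id", "equation", "reversible"}
    if not needed.issubset(df.columns):
        raise NetworkError(f"{path}: needs columns {sorted(needed)}")
    seen = set()
    out = []
    for _, row in df.iterrows():
        rid = str(row["reaction_id"])
        if rid in seen:
            raise NetworkError(f"{path}: duplicate reaction id '{rid}'")
        seen.add(rid)
        stoich, rev_arrow = parse_equation(rid, str(row["equation"]))
        rev = bool(row["reversible"]) if "reversible" in row else rev_arrow
        out.append(Reaction(rid, stoich, rev, str(row.get("subsystem", "") or "")))
    return out


def _data(name: str) -> Path:
    return Path(importlib.resources.files("endurosim") / "data" / name)


def load_brain_network() -> list[Reaction]:
    """The packaged ~65-reaction network of cerebral carbon metabolism."""
    return read_reaction_table(_data("brain_reactions.tsv"))


def load_formulas() -> dict:
    """Per-metabolite C/N/P atom counts (compartment-agnostic)."""
    df = pd.read_csv(_data("metabolite_formulas.tsv"), sep="\t")
    return {r["metabolite"]: {"C": int(r["C"]), "N": int(r["N"]), "P": int(r["P"])}
            for _, r in df.iterrows()}


def _strip_compartment(met: str) -> str:
    return re.sub(r"_(c|m|e)$", "", met)


def check_elemental_balance(r: Reaction, formulas: dict | None = None) -> dict:
    """Signed element totals of a reaction; zero means balanced.

    Exchange reactions are boundary flows and are exempt.  If any
    participant lacks a formula the reaction is reported as unchecked
    rather than failed.
    """
    formulas = formulas if formulas is not None else load_formulas()
    if r.is_exchange:
        return {"exempt": True}
    residual = {"C": 0.0, "N": 0.0, "P": 0.0}
    for met, coef in r.stoichiometry.items():
        f = formulas.get(_strip_compartment(met))
        if f is None:
            return {"unchecked": True, "missing": _strip_compartment(met)}
        for el in residual:
            residual[el] += coef * f[el]
    return residual


@dataclass
class FluxSystem:
    """Equality matrix, bounds and objective of one FBA problem."""

    S: np.ndarray  # (n_internal_metabolites, n_reactions)
    metabolites: list
    reactions: list  # Reaction objects, column order
    lower: np.ndarray
    upper: np.ndarray
    objective: str

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    def column(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise NetworkError(f"unknown reaction '{reaction_id}'") from None


@dataclass
class FluxResult:
    """Flux vector (mmol/min whole organ) with solver status."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: pd.Series | None
    ranges: pd.DataFrame | None = None

    def __getitem__(self, reaction_id: str) -> float:
        if self.fluxes is None:
            raise KeyError("no flux vector (status %s)" % self.status)
        return float(self.fluxes[reaction_id])


def build_system(
    reactions: list,
    bounds: dict | None = None,
    objective: str = "",
) -> FluxSystem:
    """Assemble the steady-state system from a reaction list.

    One balance row per explicit metabolite (production positive); the
    boundary pool on the implicit empty side of an exchange reaction is the
    only thing excluded, so uptake bounds on exchanges propagate through
    the transporters.  ``bounds`` maps reaction ids to (lower, upper) flux
    bounds in mmol/min; irreversible reactions get a lower bound of 0,
    reversible ones are boxed at +/- a large default.
    """
    ids = [r.id for r in reactions]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise NetworkError(f"duplicate reaction identifiers {dup}")
    if objective and objective not in ids:
        raise NetworkError(f"objective reaction '{objective}' not in the model")
    internal = sorted({m for r in reactions for m in r.stoichiometry})
    index = {m: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), len(reactions)))
    for j, r in enumerate(reactions):
        for met, coef in r.stoichiometry.items():
            if met in index:
                S[index[met], j] = coef
    lower = np.array([-_BIG if r.reversible else 0.0 for r in reactions])
    upper = np.full(len(reactions), _BIG)
    for rid, (lo, hi) in (bounds or {}).items():
        if rid not in ids:
            raise NetworkError(f"bound refers to unknown reaction '{rid}'")
        j = ids.index(rid)
        if hi < lo:
            raise NetworkError(f"bound for {rid} has upper < lower")
        lower[j], upper[j] = lo, hi
    return FluxSystem(S, internal, list(reactions), lower, upper, objective)


def solve_fba(system: FluxSystem, direction: str = "maximize",
              compute_ranges: bool = False) -> FluxResult:
    """Solve the linear program; statuses are reported faithfully.

    With ``compute_ranges`` the objective is fixed at its optimum and each
    flux is minimized and maximized in turn (flux variability), exposing
    alternative optima instead of pretending the vector is unique.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError("direction must be 'maximize' or 'minimize'")
    c = np.zeros(len(system.reactions))
    c[system.column(system.objective)] = -1.0 if direction == "maximize" else 1.0
    res = linprog(c, A_eq=system.S, b_eq=np.zeros(system.S.shape[0]),
                  bounds=list(zip(system.lower, system.upper)), method="highs")
    if res.status == 2:
        return FluxResult("infeasible", None, None)
    if res.status == 3:
        return FluxResult("unbounded", None, None)
    if not res.success:
        return FluxResult(f"solver-failure: {res.message}", None, None)
    fluxes = pd.Series(res.x, index=system.reaction_ids)
    obj = float(fluxes[system.objective]) if system.objective else 0.0
    ranges = None
    if compute_ranges:
        ranges = flux_ranges(system, obj, direction)
    return FluxResult("optimal", obj, fluxes, ranges)


def flux_ranges(system: FluxSystem, objective_value: float,
                direction: str = "maximize") -> pd.DataFrame:
    """Feasible [min, max] of every flux with the objective held optimal."""
    j_obj = system.column(system.objective)
    lower = system.lower.copy()
    upper = system.upper.copy()
    lower[j_obj] = upper[j_obj] = objective_value
    rows = []
    for j, rid in enumerate(system.reaction_ids):
        vals = []
        for sign in (1.0, -1.0):
            c = np.zeros(len(system.reactions))
            c[j] = sign
            r = linprog(c, A_eq=system.S, b_eq=np.zeros(system.S.shape[0]),
                        bounds=list(zip(lower, upper)), method="highs")
            vals.append(float(r.x[j]) if r.success else np.nan)
        rows.append((rid, vals[0], vals[1]))
    return pd.DataFrame(rows, columns=["reaction", "min", "max"]).set_index("reaction")


def sample_flux_space(system: FluxSystem, n: int, seed: int = 0,
                      thin: int = 10, box: float = _BIG) -> pd.DataFrame:
    """Uniform hit-and-run samples of the feasible flux polytope.

    The walk moves in null-space coordinates of S, so every sample
    satisfies the balances to solver precision; inequality feasibility is
    maintained by sampling uniformly on the feasible chord through the
    current point.  Unbounded directions are clipped at ``+/- box``
    (documented auto-bounding).  A fixed seed makes the sample
    deterministic.
    """
    rng = np.random.default_rng(seed)
    lower = np.maximum(system.lower, -box)
    upper = np.minimum(system.upper, box)
    # interior start: maximize the smallest slack to the box faces
    nr = len(system.reactions)
    c = np.zeros(nr + 1)
    c[-1] = -1.0
    A_ub = np.vstack([
        np.hstack([-np.eye(nr), np.ones((nr, 1))]),
        np.hstack([np.eye(nr), np.ones((nr, 1))]),
    ])
    b_ub = np.concatenate([-lower, upper])
    A_eq = np.hstack([system.S, np.zeros((system.S.shape[0], 1))])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq,
                  b_eq=np.zeros(system.S.shape[0]),
                  bounds=[(None, None)] * nr + [(0, None)], method="highs")
    if not res.success or res.x[-1] <= 1e-12:
        return pd.DataFrame(columns=system.reaction_ids)  # empty/degenerate region
    v = res.x[:nr]
    # null-space basis of S
    _, s, vt = np.linalg.svd(system.S, full_matrices=True)
    rank = int(np.sum(s > 1e-10 * (s[0] if len(s) else 1.0)))
    N = vt[rank:].T
    if N.shape[1] == 0:
        return pd.DataFrame([v], columns=system.reaction_ids)
    samples = []
    while len(samples) < n:
        for _ in range(thin):
            d = N @ rng.standard_normal(N.shape[1])
            nrm = np.linalg.norm(d)
            if nrm < 1e-12:
                continue
            d /= nrm
            # feasible interval for v + t d within [lower, upper]
            t_lo, t_hi = -np.inf, np.inf
            for j in range(nr):
                if abs(d[j]) < 1e-13:
                    continue
                a = (lower[j] - v[j]) / d[j]
                b = (upper[j] - v[j]) / d[j]
                lo, hi = min(a, b), max(a, b)
                t_lo, t_hi = max(t_lo, lo), min(t_hi, hi)
            if not np.isfinite(t_lo) or not np.isfinite(t_hi) or t_hi <= t_lo:
                continue
            v = v + rng.uniform(t_lo, t_hi) * d
        samples.append(v.copy())
    return pd.DataFrame(samples, columns=system.reaction_ids)


# ---------------------------------------------------------------------------
# Brain rest/exercise case studies
# ---------------------------------------------------------------------------

#: measured whole-brain uptakes, mmol/min (negative exchange flux = uptake)
BRAIN_UPTAKES = {
    "rest": {"glc": 0.4, "lac": 0.0, "o2": 2.4},  # O2 = 6 x glucose
    "exercise": {"glc": 0.8, "lac": 0.53, "o2": 3.2},
}


def brain_scenario(state: str = "rest", compute_ranges: bool = False,
                   objective: str = "ATPS4m") -> tuple[FluxResult, dict]:
    """Maximal-ATP flux distribution of the brain network, plus carbon report.

    At rest 0.4 mmol/min glucose is taken up with oxygen fixed by the
    O2:glucose ratio of 6; during exercise glucose doubles and lactate and
    oxygen uptakes are fixed at their measured values, with palmitate
    synthesis enabled as the carbon sink under investigation.  The
    objective is the mitochondrial ATP synthase flux.
    """
    if state not in BRAIN_UPTAKES:
        raise ValueError("state must be 'rest' or 'exercise'")
    u = BRAIN_UPTAKES[state]
    reactions = load_brain_network()
    _validate_network(reactions)
    bounds = {
        "EX_glc": (-u["glc"], -u["glc"]),
        "EX_lac": (-u["lac"], -u["lac"]),
        "EX_o2": (-u["o2"], -u["o2"]),
        "EX_co2": (0.0, _BIG),
        "EX_hdca": (0.0, _BIG if state == "exercise" else 0.0),
        "EX_ala": (0.0, 0.0),
    }
    system = build_system(reactions, bounds, objective=objective)
    result = solve_fba(system, "maximize", compute_ranges=compute_ranges)
    report = carbon_report(system, result) if result.status == "optimal" else {}
    return result, report


def _validate_network(reactions: list) -> None:
    formulas = load_formulas()
    bad = []
    for r in reactions:
        res = check_elemental_balance(r, formulas)
        if res.get("exempt") or res.get("unchecked"):
            continue
        if any(abs(v) > 1e-9 for v in res.values()):
            bad.append((r.id, res))
    if bad:
        raise NetworkError(f"elementally unbalanced internal reactions: {bad}")


def carbon_report(system: FluxSystem, result: FluxResult) -> dict:
    """Carbon bookkeeping of a solved network (mmol C/min).

    Carbon entering via exchange uptakes must leave as CO2, as fatty acid
    or as other sinks; the residual closes to solver precision for a
    balanced network.
    """
    formulas = load_formulas()
    c_in = c_co2 = c_fat = c_other = 0.0
    for r in system.reactions:
        if not r.is_exchange:
            continue
        flux = result[r.id]
        for met, coef in r.stoichiometry.items():
            name = _strip_compartment(met)
            carbons = formulas.get(name, {}).get("C", 0)
            # exchange stoichiometry is negative (species consumed toward the
            # boundary), so positive flux exports carbon, negative imports it
            rate = flux * (-coef) * carbons
            if rate < 0:
                c_in += -rate
            elif name == "co2":
                c_co2 += rate
            elif name == "hdca":
                c_fat += rate
            else:
                c_other += rate
    return {
        "carbon_in": c_in,
        "carbon_to_co2": c_co2,
        "carbon_to_fatty_acid": c_fat,
        "carbon_to_other": c_other,
        "closure_residual": c_in - c_co2 - c_fat - c_other,
    }


# ---------------------------------------------------------------------------
# Graph and SBML interchange
# ---------------------------------------------------------------------------

def export_graph(system: FluxSystem, result: FluxResult | None = None,
                 path: str | Path | None = None) -> nx.DiGraph:
    """Bipartite metabolite-reaction graph, optionally annotated with fluxes.

    Written as GraphML when ``path`` is given; no layout is computed.
    """
    g = nx.DiGraph()
    for m in system.metabolites:
        g.add_node(m, kind="metabolite")
    for r in system.reactions:
        flux = float(result[r.id]) if result is not None and result.fluxes is not None else 0.0
        g.add_node(r.id, kind="reaction", subsystem=r.subsystem,
                   flux=flux, zero_flux=bool(abs(flux) < 1e-9))
        for met, coef in r.stoichiometry.items():
            if met not in g:
                continue
            if coef < 0:
                g.add_edge(met, r.id, coefficient=float(-coef))
            else:
                g.add_edge(r.id, met, coefficient=float(coef))
    if path is not None:
        nx.write_graphml(g, str(path))
    return g


def write_sbml(reactions: list, path: str | Path, model_id: str = "endurosim_model") -> None:
    """Export a reaction list as SBML Level 3 (requires python-libsbml)."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    model = doc.createModel()
    model.setId(model_id)
    comps = {}
    mets = sorted({m for r in reactions for m in r.stoichiometry})
    for met in mets:
        comp = met.rsplit("_", 1)[-1]
        if comp not in comps:
            c = model.createCompartment()
            c.setId(comp)
            c.setConstant(True)
            comps[comp] = c
        s = model.createSpecies()
        s.setId("M_" + met)  # SBML SIds may not start with a digit
        s.setCompartment(comp)
        s.setConstant(False)
        s.setBoundaryCondition(met.endswith("_e"))
        s.setHasOnlySubstanceUnits(False)
    for r in reactions:
        rx = model.createReaction()
        rx.setId("R_" + r.id)
        rx.setReversible(r.reversible)
        for met, coef in r.stoichiometry.items():
            ref = rx.createReactant() if coef < 0 else rx.createProduct()
            ref.setSpecies("M_" + met)
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
    libsbml.writeSBMLToFile(doc, str(path))


def read_sbml(path: str | Path) -> list:
    """Import reactions from an SBML file (requires python-libsbml)."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise NetworkError(f"{path}: SBML parse errors")
    model = doc.getModel()

    def unprefix(sid: str, prefix: str) -> str:
        return sid[len(prefix):] if sid.startswith(prefix) else sid

    out = []
    for rx in model.getListOfReactions():
        stoich = {}
        for ref in rx.getListOfReactants():
            met = unprefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            met = unprefix(ref.getSpecies(), "M_")
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        out.append(Reaction(unprefix(rx.getId(), "R_"), stoich, rx.getReversible()))
    return out
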