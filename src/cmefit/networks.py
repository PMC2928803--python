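"""Stochastic reaction networks: species, stoichiometry, propensities, parameters.

A :class:`ReactionNetwork` is the static description of a chemical master
equation model: ``N`` species, ``M`` reactions with integer stoichiometric
change vectors, and a propensity function ``a_j(x, k)`` per reaction.  The
built-in case-study models (gene activation/transcription in *E. coli*,
the yEGFP galactose-uptake cascade in yeast, and the genetic toggle
switch) ship as editable YAML files next to this module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import yaml

from ._expr import parse_expression

logger = logging.getLogger(__name__)

BUILTIN_MODELS = (
    "ecoli_rna",
    "yegfp_reduced",
    "yegfp_full",
    "toggle_switch",
    "birth_death_test",
)


class NetworkError(ValueError):
    """Malformed network definition or mismatched input."""


class PropensityEvaluationError(RuntimeError):
    """A propensity evaluated to a non-finite value."""


# --------------------------------------------------------------------------
# Propensity specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MassAction:
    """Elementary mass-action propensity ``c * h(x)``.

    The stochastic rate constant is ``rate_const`` times the product of
    the named ``rate_params`` (a product is allowed so that e.g. a binding
    constant and an active fraction stay separate parameters; a purely
    numeric rate models a fixed, non-estimated constant).  ``reactants``
    is the reactant multiset; an empty tuple is a zeroth-order (constant)
    propensity and a doubly listed species yields the dimerisation factor
    ``x(x-1)/2``.
    """

    rate_params: tuple[str, ...]
    reactants: tuple[str, ...] = ()
    rate_const: float = 1.0

    def __post_init__(self) -> None:
        if len(self.reactants) > 2:
            raise NetworkError("mass_action supports at most bimolecular reactions")
        if self.rate_const < 0:
            raise NetworkError("rate_const must be non-negative")


@dataclass(frozen=True)
class HillRepression:
    """Repressive Hill propensity ``A / (1 + (x_reg / s)^h)``.

    ``numerator`` and ``exponent`` name parameters; the half-saturation
    scale ``s`` is 1 unless ``induction`` is given, in which case
    ``s = (1 + [I]/K)^eta`` — an inducer at concentration ``[I]`` that
    sequesters the regulator (the IPTG/LacI mechanism of the toggle
    switch), with ``K`` and ``eta`` free parameters.
    """

    numerator: str
    regulator: str
    exponent: str
    induction: tuple[str, str] | None = None  # (K_param, eta_param)
    inducer_conc: float = 0.0

    def scale(self, params: Mapping[str, float]) -> float:
        if self.induction is None:
            return 1.0
        k_name, eta_name = self.induction
        k = params[k_name]
        if k <= 0.0:
            # K -> 0 means total sequestration of the regulator
            return math.inf
        return (1.0 + self.inducer_conc / k) ** params[eta_name]


@dataclass(frozen=True)
class ExpressionPropensity:
    """Arbitrary arithmetic formula over species counts and parameters."""

    formula: str

    def __post_init__(self) -> None:
        fn, names = parse_expression(self.formula)
        object.__setattr__(self, "_fn", fn)
        object.__setattr__(self, "_names", names)

    @property
    def names(self) -> frozenset[str]:
        return self._names  # type: ignore[attr-defined]

    def __call__(self, env: Mapping[str, float]) -> float:
        return self._fn(env)  # type: ignore[attr-defined]


PropensitySpec = Union[MassAction, HillRepression, ExpressionPropensity]


@dataclass(frozen=True)
class Reaction:
    name: str
    changes: Mapping[str, int]  # species -> stoichiometric change
    propensity: PropensitySpec


# --------------------------------------------------------------------------
# The network
# --------------------------------------------------------------------------

@dataclass
class ReactionNetwork:
    """Immutable-ish container for an M-reaction, N-species CME model."""

    species_names: list[str]
    reactions: list[Reaction]
    parameter_names: list[str]
    parameter_bounds: list[tuple[float, float]]
    volume_label: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.species_names) < 1 or len(self.reactions) < 1:
            raise NetworkError("need at least one species and one reaction")
        if len(self.parameter_bounds) != len(self.parameter_names):
            raise NetworkError("one bounds pair per parameter required")
        for lo, hi in self.parameter_bounds:
            if not lo <= hi:
                raise NetworkError(f"invalid bounds ({lo}, {hi})")
        sp = set(self.species_names)
        pars = set(self.parameter_names)
        for rxn in self.reactions:
            unknown = set(rxn.changes) - sp
            if unknown:
                raise NetworkError(f"reaction {rxn.name!r} changes unknown species {unknown}")
            self._check_refs(rxn, sp, pars)
        self._species_index = {s: i for i, s in enumerate(self.species_names)}
        self._param_index = {p: i for i, p in enumerate(self.parameter_names)}

    @staticmethod
    def _check_refs(rxn: Reaction, sp: set[str], pars: set[str]) -> None:
        p = rxn.propensity
        if isinstance(p, MassAction):
            bad = (set(p.rate_params) - pars) | (set(p.reactants) - sp)
        elif isinstance(p, HillRepression):
            bad = {p.numerator, p.exponent} - pars
            if p.regulator not in sp:
                bad.add(p.regulator)
            if p.induction is not None:
                bad |= set(p.induction) - pars
        else:
            bad = p.names - sp - pars
        if bad:
            raise NetworkError(f"reaction {rxn.name!r} references undeclared names {bad}")

    # -- basic views --------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names)

    @property
    def stoichiometry(self) -> np.ndarray:
        """M x N integer matrix of state changes."""
        nu = np.zeros((self.n_reactions, self.n_species), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for s, c in rxn.changes.items():
                nu[j, self._species_index[s]] = c
        return nu

    def species_index(self, name: str) -> int:
        return self._species_index[name]

    @property
    def bounds_array(self) -> np.ndarray:
        return np.asarray(self.parameter_bounds, dtype=float)

    @property
    def true_values(self) -> np.ndarray | None:
        tv = self.metadata.get("true_values")
        if tv is None:
            return None
        return self.params_array(tv)

    @property
    def initial_state(self) -> np.ndarray:
        x0 = np.zeros(self.n_species, dtype=np.int64)
        for s, c in self.metadata.get("initial_state", {}).items():
            x0[self._species_index[s]] = int(c)
        return x0

    def params_array(self, values) -> np.ndarray:
        """Canonicalise a parameter mapping/sequence into an aligned array."""
        if isinstance(values, Mapping):
            missing = set(self.parameter_names) - set(values)
            if missing:
                raise NetworkError(f"missing parameter values for {sorted(missing)}")
            arr = np.array([float(values[p]) for p in self.parameter_names])
        else:
            arr = np.asarray(values, dtype=float)
            if arr.shape != (self.n_parameters,):
                raise NetworkError(
                    f"expected {self.n_parameters} parameters, got shape {arr.shape}"
                )
        return arr

    def params_dict(self, values) -> dict[str, float]:
        arr = self.params_array(values)
        return dict(zip(self.parameter_names, arr))

    # -- propensity evaluation ----------------------------------------------

    def evaluate_propensities(self, state, params) -> np.ndarray:
        """Evaluate ``a_j(x, k)`` for every reaction at one state.

        Negative evaluations are clamped to zero (with a logged warning);
        non-finite evaluations raise :class:`PropensityEvaluationError`
        naming the reaction.
        """
        state = np.asarray(state)
        if state.shape != (self.n_species,):
            raise NetworkError(
                f"state has shape {state.shape}, expected ({self.n_species},)"
            )
        if np.any(state < 0):
            raise NetworkError("state entries must be non-negative")
        pd = self.params_dict(params)
        env = {**pd, **{s: float(state[i]) for s, i in self._species_index.items()}}
        out = np.empty(self.n_reactions)
        for j, rxn in enumerate(self.reactions):
            p = rxn.propensity
            if isinstance(p, MassAction):
                a = p.rate_const * math.prod(pd[r] for r in p.rate_params)
                if len(p.reactants) == 2 and p.reactants[0] == p.reactants[1]:
                    x = float(state[self._species_index[p.reactants[0]]])
                    a *= x * (x - 1.0) / 2.0
                else:
                    for r in p.reactants:
                        a *= float(state[self._species_index[r]])
            elif isinstance(p, HillRepression):
                x = float(state[self._species_index[p.regulator]])
                s = p.scale(pd)
                z = 0.0 if s == math.inf else x / s
                a = pd[p.numerator] / (1.0 + z ** pd[p.exponent])
            else:
                try:
                    a = p(env)
                except ZeroDivisionError as exc:
                    raise PropensityEvaluationError(
                        f"division by zero in reaction {rxn.name!r} at state "
                        f"{state.tolist()}"
                    ) from exc
            if not math.isfinite(a):
                raise PropensityEvaluationError(
                    f"propensity of reaction {rxn.name!r} is {a!r} at state {state.tolist()}"
                )
            if a < 0.0:
                logger.warning(
                    "negative propensity %.3g for reaction %r clamped to 0", a, rxn.name
                )
                a = 0.0
            out[j] = a
        return out

    # -- compiled form for the SSA kernel -----------------------------------

    @property
    def kernel_compatible(self) -> bool:
        """True when every propensity is mass-action or Hill (numba path)."""
        return all(
            isinstance(r.propensity, (MassAction, HillRepression)) for r in self.reactions
        )

    def kernel_tables(self, params) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten propensities into per-reaction code tables.

        Returns ``(kinds, coefs, sp)`` with kinds 0 = mass action and
        1 = Hill repression.  Coefficients already have the numeric
        parameter values folded in, so the SSA kernel stays branch-light.
        """
        if not self.kernel_compatible:
            raise NetworkError("network contains expression propensities; use the generic engine")
        pd = self.params_dict(params)
        m = self.n_reactions
        kinds = np.zeros(m, dtype=np.int64)
        coefs = np.zeros((m, 3))
        sp = np.full((m, 2), -1, dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            p = rxn.propensity
            if isinstance(p, MassAction):
                kinds[j] = 0
                coefs[j, 0] = p.rate_const * math.prod(pd[r] for r in p.rate_params)
                for q, r in enumerate(p.reactants):
                    sp[j, q] = self._species_index[r]
            else:
                kinds[j] = 1
                s = p.scale(pd)
                coefs[j] = (pd[p.numerator], s if math.isfinite(s) else 0.0, pd[p.exponent])
                # scale 0 encodes "regulator fully sequestered" (a == numerator)
                sp[j, 0] = self._species_index[p.regulator]
        return kinds, coefs, sp


# --------------------------------------------------------------------------
# (De)serialisation
# --------------------------------------------------------------------------

def _propensity_to_dict(p: PropensitySpec) -> dict:
    if isinstance(p, MassAction):
        d: dict = {"kind": "mass_action", "rate": list(p.rate_params)}
        if p.rate_const != 1.0:
            d["rate_const"] = p.rate_const
        if p.reactants:
            d["reactants"] = list(p.reactants)
        return d
    if isinstance(p, HillRepression):
        d = {
            "kind": "hill",
            "numerator": p.numerator,
            "regulator": p.regulator,
            "exponent": p.exponent,
        }
        if p.induction is not None:
            d["induction"] = {
                "K": p.induction[0],
                "eta": p.induction[1],
                "inducer_conc": p.inducer_conc,
            }
        return d
    return {"kind": "expression", "formula": p.formula}


def _propensity_from_dict(d: Mapping) -> PropensitySpec:
    kind = d.get("kind")
    if kind == "mass_action":
        rate = d["rate"]
        if isinstance(rate, str):
            rate = [rate]
        return MassAction(
            tuple(rate),
            tuple(d.get("reactants", ())),
            rate_const=float(d.get("rate_const", 1.0)),
        )
    if kind == "hill":
        ind = d.get("induction")
        return HillRepression(
            numerator=d["numerator"],
            regulator=d["regulator"],
            exponent=d["exponent"],
            induction=(ind["K"], ind["eta"]) if ind else None,
            inducer_conc=float(ind.get("inducer_conc", 0.0)) if ind else 0.0,
        )
    if kind == "expression":
        return ExpressionPropensity(d["formula"])
    raise NetworkError(f"unknown propensity kind {kind!r}")


def network_to_dict(net: ReactionNetwork) -> dict:
    return {
        "species": list(net.species_names),
        "parameters": [
            {
                "name": p,
                "bounds": [float(lo), float(hi)],
                **(
                    {"true_value": float(net.metadata["true_values"][p])}
                    if p in net.metadata.get("true_values", {})
                    else {}
                ),
            }
            for p, (lo, hi) in zip(net.parameter_names, net.parameter_bounds)
        ],
        "reactions": [
            {
                "name": r.name,
                "stoichiometry": dict(r.changes),
                "propensity": _propensity_to_dict(r.propensity),
            }
            for r in net.reactions
        ],
        **({"volume_label": net.volume_label} if net.volume_label else {}),
        "metadata": {
            k: v for k, v in net.metadata.items() if k != "true_values"
        },
    }


def network_from_dict(d: Mapping) -> ReactionNetwork:
    params = d["parameters"]
    truths = {p["name"]: float(p["true_value"]) for p in params if "true_value" in p}
    metadata = dict(d.get("metadata", {}))
    if truths:
        metadata["true_values"] = truths
    return ReactionNetwork(
        species_names=list(d["species"]),
        reactions=[
            Reaction(
                name=r["name"],
                changes={s: int(c) for s, c in r["stoichiometry"].items()},
                propensity=_propensity_from_dict(r["propensity"]),
            )
            for r in d["reactions"]
        ],
        parameter_names=[p["name"] for p in params],
        parameter_bounds=[(float(p["bounds"][0]), float(p["bounds"][1])) for p in params],
        volume_label=d.get("volume_label"),
        metadata=metadata,
    )


def load_network(path: str | Path) -> ReactionNetwork:
    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh))


def save_network(net: ReactionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


def builtin_model(name: str) -> ReactionNetwork:
    """Load one of the shipped case-study models by name."""
    if name not in BUILTIN_MODELS:
        raise LookupError(
            f"unknown model {name!r}; available: {', '.join(BUILTIN_MODELS)}"
        )
    ref = resources.files(__package__) / "models" / f"{name}.yaml"
    return network_from_dict(yaml.safe_load(ref.read_text()))
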