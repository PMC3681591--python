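"""Stoichiometric reaction networks for metabolite balancing.

A network is a list of metabolites (each either *balanced*, i.e. subject to
the pseudo-steady-state constraint, or *unbalanced*, e.g. extracellular
species and biomass) and a list of reactions with signed stoichiometric
coefficients (negative = consumed).  The balanced-metabolite x reaction
matrix ``A`` encodes the constraint ``A @ r = 0`` on the flux vector ``r``.

Three on-disk dialects are supported and round-trip exactly:

* *reaction-text* -- one ``metabolite`` declaration or one reaction per
  line, human-editable (see ``data/pichia_ccm.txt``);
* *tsv* -- long-form tables (metabolite table, reaction table, stoichiometry
  triples) in a single tab-separated file with a leading ``table`` column;
* *json* -- a direct mirror of the in-memory types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "NetworkParseError",
    "load_network",
    "write_network",
    "load_pichia_network",
    "degrees_of_freedom",
    "partition",
]

COMPARTMENTS = ("cytosol", "mitochondria", "extracellular")
_FLAGS = ("rev", "measured", "inactive")


class NetworkParseError(ValueError):
    """Raised when a network file violates the format or its invariants."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    balanced: bool = True

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkParseError(
                f"metabolite {self.id!r}: unknown compartment {self.compartment!r}"
            )
        if self.compartment == "extracellular" and self.balanced:
            raise NetworkParseError(
                f"metabolite {self.id!r}: extracellular species cannot be balanced"
            )


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    measured: bool = False
    inactive: bool = False

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise NetworkParseError(f"reaction {self.id!r}: empty stoichiometry")


@dataclass
class StoichiometricModel:
    """A validated network with its balance matrix.

    ``A`` has one row per balanced metabolite (in declaration order) and one
    column per active reaction (in declaration order).  Inactive reactions
    (e.g. the glyoxylate shunt on glycerol) are kept for provenance in
    ``inactive_reactions`` but excluded from ``A``.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    inactive_reactions: list[Reaction] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_reactions(
        cls,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
    ) -> "StoichiometricModel":
        """Build a model, separating out inactive reactions."""
        reactions = list(reactions)
        return cls(
            metabolites=list(metabolites),
            reactions=[r for r in reactions if not r.inactive],
            inactive_reactions=[r for r in reactions if r.inactive],
        )

    def _validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = {m for m in met_ids if met_ids.count(m) > 1}
            raise NetworkParseError(f"duplicate metabolite ids: {sorted(dupes)}")
        rxn_ids = [r.id for r in self.reactions + self.inactive_reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = {r for r in rxn_ids if rxn_ids.count(r) > 1}
            raise NetworkParseError(f"duplicate reaction ids: {sorted(dupes)}")
        known = set(met_ids)
        for rxn in self.reactions + self.inactive_reactions:
            for mid in rxn.stoichiometry:
                if mid not in known:
                    raise NetworkParseError(
                        f"reaction {rxn.id!r} references undeclared metabolite {mid!r}"
                    )
        row_nnz = (np.abs(self.A) > 0).sum(axis=1)
        orphans = [m.id for m, n in zip(self.balanced_metabolites, row_nnz) if n < 2]
        if orphans:
            raise NetworkParseError(
                "balanced metabolites must be both produced and consumed; "
                f"fewer than 2 reactions touch: {orphans}"
            )

    # -- derived views --------------------------------------------------------

    @property
    def balanced_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.balanced]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def measured_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.measured]

    @property
    def A(self) -> np.ndarray:
        rows = {m.id: i for i, m in enumerate(self.balanced_metabolites)}
        A = np.zeros((len(rows), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                i = rows.get(mid)
                if i is not None:
                    A[i, j] = coef
        return A

    def partition(
        self, measured_ids: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Split ``A`` into unknown (``An``) and measured (``Ab``) columns.

        ``Ab`` columns follow ``measured_ids`` order; ``An`` keeps network
        order.  Defaults to the reactions flagged ``measured`` in the file.
        """
        if measured_ids is None:
            measured_ids = self.measured_ids
        ids = self.reaction_ids
        unknown_idx, measured_idx = _partition_indices(ids, measured_ids)
        A = self.A
        return A[:, unknown_idx], A[:, measured_idx]

    def unknown_ids(self, measured_ids: Sequence[str] | None = None) -> list[str]:
        if measured_ids is None:
            measured_ids = self.measured_ids
        return [rid for rid in self.reaction_ids if rid not in set(measured_ids)]

    def with_biomass(
        self, coefficients: Mapping[str, float], biomass_id: str = "r44"
    ) -> "StoichiometricModel":
        """Return a copy with the biomass reaction's stoichiometry replaced."""
        if biomass_id not in self.reaction_ids:
            raise KeyError(f"no reaction {biomass_id!r} in model")
        reactions = [
            replace(r, stoichiometry=dict(coefficients)) if r.id == biomass_id else r
            for r in self.reactions
        ]
        return StoichiometricModel(
            metabolites=self.metabolites,
            reactions=reactions,
            inactive_reactions=self.inactive_reactions,
        )


def _partition_indices(
    ids: Sequence[str], measured_ids: Sequence[str]
) -> tuple[list[int], list[int]]:
    index = {rid: j for j, rid in enumerate(ids)}
    unknown = [rid for rid in measured_ids if rid not in index]
    if unknown:
        raise KeyError(f"unknown reaction ids in measured set: {unknown}")
    if len(set(measured_ids)) != len(measured_ids):
        raise KeyError("duplicate ids in measured set")
    measured_idx = [index[rid] for rid in measured_ids]
    chosen = set(measured_idx)
    unknown_idx = [j for j in range(len(ids)) if j not in chosen]
    return unknown_idx, measured_idx


# -- free-function operation surface -----------------------------------------


def degrees_of_freedom(model: StoichiometricModel) -> int:
    """Number of flux directions not fixed by the balances: cols - rank(A).

    Coincides with ``n_reactions - n_balanced`` when ``A`` has full row rank.
    """
    A = model.A
    return A.shape[1] - int(np.linalg.matrix_rank(A))


def partition(
    model: StoichiometricModel, measured_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    return model.partition(measured_ids)


# -- parsing / writing --------------------------------------------------------


def load_network(
    path: str | Path,
    dialect: str | None = None,
    biomass_coefficients: Mapping[str, float] | None = None,
    biomass_id: str = "r44",
) -> StoichiometricModel:
    """Read a network file; ``dialect`` is inferred from the suffix if omitted."""
    path = Path(path)
    if dialect is None:
        dialect = {".json": "json", ".tsv": "tsv"}.get(path.suffix.lower(), "reaction-text")
    if dialect == "reaction-text":
        model = _parse_reaction_text(path.read_text().splitlines())
    elif dialect == "tsv":
        model = _parse_tsv(path)
    elif dialect == "json":
        model = _parse_json(json.loads(path.read_text()))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if biomass_coefficients is not None:
        model = model.with_biomass(biomass_coefficients, biomass_id)
    return model


def load_pichia_network(
    biomass_coefficients: Mapping[str, float] | None = None,
) -> StoichiometricModel:
    """The packaged P. pastoris central-carbon network (36 x 44 active)."""
    here = Path(__file__).parent / "data" / "pichia_ccm.txt"
    return load_network(here, "reaction-text", biomass_coefficients)


def _parse_reaction_text(lines: Iterable[str]) -> StoichiometricModel:
    metabolites: list[Metabolite] = []
    reactions: list[Reaction] = []
    seen_rxn: set[str] = set()
    met_ids: set[str] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            if line.startswith("metabolite"):
                metabolites.append(_parse_metabolite_line(line))
                met_ids.add(metabolites[-1].id)
                continue
            if ":" not in line:
                raise NetworkParseError(f"expected 'rid: ...' reaction syntax: {line!r}")
            rid, body = (s.strip() for s in line.split(":", 1))
            if rid in seen_rxn:
                raise NetworkParseError(f"duplicate reaction id {rid!r}")
            seen_rxn.add(rid)
            stoich, flags = _parse_reaction_body(body)
            for mid in stoich:
                if mid not in met_ids:
                    raise NetworkParseError(
                        f"reaction {rid!r} references undeclared metabolite {mid!r}"
                    )
            reactions.append(
                Reaction(
                    id=rid,
                    stoichiometry=stoich,
                    reversible="rev" in flags,
                    measured="measured" in flags,
                    inactive="inactive" in flags,
                )
            )
        except NetworkParseError as exc:
            raise NetworkParseError(f"line {lineno}: {exc}") from None
    return StoichiometricModel.from_reactions(metabolites, reactions)


def _parse_metabolite_line(line: str) -> Metabolite:
    # metabolite <id> "<name>" <compartment> <balanced|unbalanced>
    rest = line[len("metabolite"):].strip()
    name = ""
    if '"' in rest:
        pre, _, tail = rest.partition('"')
        name, _, post = tail.partition('"')
        tokens = pre.split() + post.split()
    else:
        tokens = rest.split()
    if len(tokens) != 3:
        raise NetworkParseError(f"malformed metabolite declaration: {line!r}")
    mid, compartment, flag = tokens
    if flag not in ("balanced", "unbalanced"):
        raise NetworkParseError(f"metabolite {mid!r}: expected balanced|unbalanced, got {flag!r}")
    return Metabolite(id=mid, name=name or mid, compartment=compartment,
                      balanced=flag == "balanced")


def _parse_reaction_body(body: str) -> tuple[dict[str, float], set[str]]:
    tokens = body.split()
    flags: set[str] = set()
    while tokens and tokens[-1] in _FLAGS:
        flags.add(tokens.pop())
    body = " ".join(tokens)
    if "->" not in body:
        raise NetworkParseError(f"missing '->' in reaction body: {body!r}")
    lhs, rhs = body.split("->", 1)
    stoich: dict[str, float] = {}
    for side, sign in ((lhs, -1.0), (rhs, 1.0)):
        side = side.strip()
        if not side:
            continue
        for term in side.split("+"):
            parts = term.split()
            if len(parts) == 1:
                coef, mid = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError:
                    raise NetworkParseError(f"bad coefficient in term {term.strip()!r}")
                mid = parts[1]
            else:
                raise NetworkParseError(f"malformed term {term.strip()!r}")
            stoich[mid] = stoich.get(mid, 0.0) + sign * coef
    if not stoich:
        raise NetworkParseError("empty stoichiometry")
    return stoich, flags


def _parse_tsv(path: Path) -> StoichiometricModel:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "table" not in df.columns:
        raise NetworkParseError("tsv dialect requires a 'table' column")
    mets = [
        Metabolite(
            id=row["id"], name=row["name"], compartment=row["compartment"],
            balanced=row["balanced"] == "true",
        )
        for _, row in df[df["table"] == "metabolite"].iterrows()
    ]
    rxn_rows = df[df["table"] == "reaction"]
    triples = df[df["table"] == "stoichiometry"]
    reactions = []
    for _, row in rxn_rows.iterrows():
        rid = row["id"]
        sub = triples[triples["reaction_id"] == rid]
        stoich = {r["metabolite_id"]: float(r["coefficient"]) for _, r in sub.iterrows()}
        if not stoich:
            raise NetworkParseError(f"reaction {rid!r}: empty stoichiometry")
        reactions.append(
            Reaction(
                id=rid, stoichiometry=stoich,
                reversible=row["reversible"] == "true",
                measured=row["measured"] == "true",
                inactive=row["inactive"] == "true",
            )
        )
    return StoichiometricModel.from_reactions(mets, reactions)


def _parse_json(doc: dict) -> StoichiometricModel:
    mets = [Metabolite(**m) for m in doc["metabolites"]]
    reactions = [Reaction(**r) for r in doc["reactions"]]
    return StoichiometricModel.from_reactions(mets, reactions)


def write_network(model: StoichiometricModel, path: str | Path,
                  dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = {".json": "json", ".tsv": "tsv"}.get(path.suffix.lower(), "reaction-text")
    all_rxns = model.reactions + model.inactive_reactions
    if dialect == "reaction-text":
        lines = []
        for m in model.metabolites:
            flag = "balanced" if m.balanced else "unbalanced"
            lines.append(f'metabolite {m.id} "{m.name}" {m.compartment} {flag}')
        for r in all_rxns:
            lines.append(_format_reaction(r))
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "tsv":
        import pandas as pd

        rows = []
        for m in model.metabolites:
            rows.append({"table": "metabolite", "id": m.id, "name": m.name,
                         "compartment": m.compartment,
                         "balanced": "true" if m.balanced else "false"})
        for r in all_rxns:
            rows.append({"table": "reaction", "id": r.id,
                         "reversible": "true" if r.reversible else "false",
                         "measured": "true" if r.measured else "false",
                         "inactive": "true" if r.inactive else "false"})
        for r in all_rxns:
            for mid, coef in r.stoichiometry.items():
                rows.append({"table": "stoichiometry", "reaction_id": r.id,
                             "metabolite_id": mid, "coefficient": repr(coef)})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif dialect == "json":
        doc = {
            "metabolites": [
                {"id": m.id, "name": m.name, "compartment": m.compartment,
                 "balanced": m.balanced}
                for m in model.metabolites
            ],
            "reactions": [
                {"id": r.id, "stoichiometry": dict(r.stoichiometry),
                 "reversible": r.reversible, "measured": r.measured,
                 "inactive": r.inactive}
                for r in all_rxns
            ],
        }
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _format_reaction(r: Reaction) -> str:
    def side(items):
        terms = []
        for mid, coef in items:
            coef = abs(coef)
            terms.append(mid if coef == 1 else f"{coef:g} {mid}")
        return " + ".join(terms)

    lhs = side((m, c) for m, c in r.stoichiometry.items() if c < 0)
    rhs = side((m, c) for m, c in r.stoichiometry.items() if c > 0)
    flags = "".join(
        f" {f}" for f, on in (("rev", r.reversible), ("measured", r.measured),
                              ("inactive", r.inactive)) if on
    )
    return f"{r.id}: {lhs} -> {rhs}{flags}"
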