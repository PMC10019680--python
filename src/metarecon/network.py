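"""Metabolic network model: metabolites, reactions, stoichiometry and elasticity sparsity.

The network fixes the structural side of the inverse problem.  Each reaction
rate :math:`r_i` is a function of the metabolite concentrations it depends on
(its substrates and modifiers).  Concentration dynamics follow
:math:`dC/dt = N \\cdot r(C)` with :math:`N` the stoichiometric matrix
(metabolites x reactions).  Linearizing around steady state gives the
biochemical Jacobian

.. math:: J = N \\cdot \\frac{\\partial r}{\\partial C},

so the sparsity of the stoichiometric matrix and of the elasticity matrix
:math:`\\partial r/\\partial C` together determine which Jacobian entries may
be nonzero.  That structural mask is what makes the covariance-based inverse
problem identifiable with far fewer unknowns than Jacobian entries.

Networks are described in a small plain-text reaction-list format, one
reaction per line::

    # comment
    cofactors: NAD, NADH
    PHGDH : 3PG + NAD -> 3PHP + NADH
    PSAT1 : 3PHP + Glu -> PSer + KGA | modifiers: Ca

Stoichiometric coefficients prefix the metabolite token (``2 ATP``).  Either
side of ``->`` may be empty (pure source or sink/exchange reactions).
Metabolite order is first appearance in the file; all matrices are indexed in
that order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "NetworkParseError",
    "FreeParameterReport",
    "load_network",
    "save_network",
    "jacobian_sparsity",
    "count_free_parameters",
]


class NetworkParseError(ValueError):
    """Raised when a reaction-list file cannot be parsed or validated."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species tracked by the model.

    ``is_cofactor`` is a reporting flag only (e.g. NAD/NADH, Glu/KGA pairs);
    cofactors participate in all matrices like any other metabolite.
    """

    id: str
    name: str = ""
    is_cofactor: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A reaction with mass-changing substrates/products and rate modifiers.

    Modifiers affect the rate (hence the elasticity pattern) without
    appearing in the stoichiometry.
    """

    id: str
    substrates: tuple[tuple[str, int], ...] = ()
    products: tuple[tuple[str, int], ...] = ()
    modifiers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not self.substrates and not self.products:
            raise ValueError(f"reaction {self.id!r}: substrates and products both empty")
        sub_ids = {m for m, _ in self.substrates}
        prod_ids = {m for m, _ in self.products}
        overlap = sub_ids & prod_ids
        if overlap:
            raise ValueError(
                f"reaction {self.id!r}: metabolite(s) {sorted(overlap)} appear on both sides"
            )
        for side in (self.substrates, self.products):
            for met, coef in side:
                if coef <= 0:
                    raise ValueError(
                        f"reaction {self.id!r}: non-positive stoichiometry {coef} for {met!r}"
                    )


@dataclass
class MetabolicNetwork:
    """Ordered metabolites + reactions with derived structural matrices.

    Parameters
    ----------
    include_product_elasticities:
        When False (default) only substrates and modifiers contribute to the
        elasticity pattern — the irreversible-kinetics assumption, which keeps
        the inverse problem better determined.  Set True to also allow product
        (reverse-rate) elasticities.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    include_product_elasticities: bool = False
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkParseError(f"duplicate metabolite id(s): {dup}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise NetworkParseError(f"duplicate reaction id(s): {dup}")
        self._index = {m: i for i, m in enumerate(ids)}
        for r in self.reactions:
            for met in [m for m, _ in r.substrates] + [m for m, _ in r.products] + list(r.modifiers):
                if met not in self._index:
                    raise NetworkParseError(
                        f"reaction {r.id!r} references unknown metabolite {met!r}"
                    )

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite_index(self, met_id: str) -> int:
        return self._index[met_id]

    @property
    def stoichiometry(self) -> np.ndarray:
        """Integer matrix (metabolites x reactions): product minus substrate coefficients."""
        s = np.zeros((self.n_metabolites, self.n_reactions), dtype=int)
        for k, r in enumerate(self.reactions):
            for met, coef in r.substrates:
                s[self._index[met], k] -= coef
            for met, coef in r.products:
                s[self._index[met], k] += coef
        return s

    @property
    def elasticity_pattern(self) -> np.ndarray:
        """Boolean matrix (reactions x metabolites): where dr_i/dC_j may be nonzero."""
        pat = np.zeros((self.n_reactions, self.n_metabolites), dtype=bool)
        for k, r in enumerate(self.reactions):
            for met, _ in r.substrates:
                pat[k, self._index[met]] = True
            for met in r.modifiers:
                pat[k, self._index[met]] = True
            if self.include_product_elasticities:
                for met, _ in r.products:
                    pat[k, self._index[met]] = True
        return pat

    def free_elasticity_index(self) -> list[tuple[int, int]]:
        """Positions (reaction row, metabolite column) of free elasticity parameters."""
        pat = self.elasticity_pattern
        return [(int(p), int(q)) for p, q in zip(*np.nonzero(pat))]

    # ---- tabular export -------------------------------------------------

    def stoichiometry_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stoichiometry, index=self.metabolite_ids, columns=self.reaction_ids)

    def elasticity_pattern_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.elasticity_pattern, index=self.reaction_ids, columns=self.metabolite_ids
        )

    def write_matrices(self, stoich_path: str | Path, pattern_path: str | Path) -> None:
        self.stoichiometry_frame().to_csv(stoich_path, sep="\t")
        self.elasticity_pattern_frame().astype(int).to_csv(pattern_path, sep="\t")


# ---------------------------------------------------------------------------
# reaction-list text format
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(\d+)\s+)?(\S+)$")


def _parse_side(text: str, line_no: int) -> tuple[tuple[str, int], ...]:
    text = text.strip()
    if not text:
        return ()
    terms = []
    for raw in text.split("+"):
        raw = raw.strip()
        m = _TERM_RE.match(raw)
        if m is None:
            raise NetworkParseError(f"line {line_no}: cannot parse term {raw!r}")
        coef = int(m.group(1)) if m.group(1) else 1
        terms.append((m.group(2), coef))
    return tuple(terms)


def _parse_reaction_line(line: str, line_no: int) -> Reaction:
    modifiers: tuple[str, ...] = ()
    if "|" in line:
        line, mod_part = line.split("|", 1)
        mod_part = mod_part.strip()
        if not mod_part.lower().startswith("modifiers:"):
            raise NetworkParseError(f"line {line_no}: expected 'modifiers:' after '|'")
        mod_text = mod_part.split(":", 1)[1]
        modifiers = tuple(m.strip() for m in mod_text.split(",") if m.strip())
    if ":" not in line:
        raise NetworkParseError(f"line {line_no}: missing ':' between reaction id and equation")
    rid, eqn = line.split(":", 1)
    if "->" not in eqn:
        raise NetworkParseError(f"line {line_no}: missing '->' in reaction equation")
    lhs, rhs = eqn.split("->", 1)
    try:
        return Reaction(
            id=rid.strip(),
            substrates=_parse_side(lhs, line_no),
            products=_parse_side(rhs, line_no),
            modifiers=modifiers,
        )
    except ValueError as exc:
        raise NetworkParseError(f"line {line_no}: {exc}") from exc


def parse_network(text: str, include_product_elasticities: bool = False) -> MetabolicNetwork:
    """Parse reaction-list text into a validated :class:`MetabolicNetwork`."""
    reactions: list[Reaction] = []
    cofactors: set[str] = set()
    order: list[str] = []
    seen: set[str] = set()

    def note(met: str) -> None:
        if met not in seen:
            seen.add(met)
            order.append(met)

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("cofactors:"):
            for tok in line.split(":", 1)[1].split(","):
                if tok.strip():
                    cofactors.add(tok.strip())
            continue
        rxn = _parse_reaction_line(line, line_no)
        reactions.append(rxn)
        for met, _ in rxn.substrates:
            note(met)
        for met, _ in rxn.products:
            note(met)
        for met in rxn.modifiers:
            note(met)

    if not reactions:
        raise NetworkParseError("no reactions found in network definition")
    unknown_cof = cofactors - seen
    if unknown_cof:
        raise NetworkParseError(
            f"cofactors directive references unknown metabolite(s): {sorted(unknown_cof)}"
        )
    metabolites = [Metabolite(id=m, is_cofactor=(m in cofactors)) for m in order]
    return MetabolicNetwork(metabolites, reactions, include_product_elasticities)


def load_network(path: str | Path, include_product_elasticities: bool = False) -> MetabolicNetwork:
    """Load a network from a reaction-list text file (see module docstring for format)."""
    path = Path(path)
    return parse_network(path.read_text(), include_product_elasticities)


def format_network(net: MetabolicNetwork) -> str:
    """Serialize a network back to reaction-list text (round-trips through :func:`parse_network`)."""
    lines = []
    cof = [m.id for m in net.metabolites if m.is_cofactor]
    if cof:
        lines.append("cofactors: " + ", ".join(cof))

    def side(terms: Iterable[tuple[str, int]]) -> str:
        return " + ".join(f"{c} {m}" if c != 1 else m for m, c in terms)

    for r in net.reactions:
        line = f"{r.id} : {side(r.substrates)} -> {side(r.products)}"
        if r.modifiers:
            line += " | modifiers: " + ", ".join(r.modifiers)
        lines.append(line)
    return "\n".join(lines) + "\n"


def save_network(net: MetabolicNetwork, path: str | Path) -> None:
    Path(path).write_text(format_network(net))


# ---------------------------------------------------------------------------
# structural analysis
# ---------------------------------------------------------------------------


def jacobian_sparsity(net: MetabolicNetwork) -> np.ndarray:
    """Allowed-nonzero mask of the Jacobian J = N * (dr/dC).

    Entry (i, j) is True iff some reaction k both changes metabolite i
    (stoichiometry nonzero) and may depend on metabolite j (elasticity
    pattern).  Equivalent to the boolean product of |N| and the pattern.
    """
    s = net.stoichiometry != 0
    return (s.astype(int) @ net.elasticity_pattern.astype(int)) > 0


@dataclass(frozen=True)
class FreeParameterReport:
    """Determinacy accounting: free elasticities vs. independent covariance equations."""

    free: int
    equations: int

    @property
    def determinacy(self) -> str:
        if self.free < self.equations:
            return "over-determined"
        if self.free == self.equations:
            return "exactly-determined"
        return "under-determined"


def count_free_parameters(net: MetabolicNetwork) -> FreeParameterReport:
    """Count free elasticity parameters against the n(n+1)/2 independent
    scalar equations supplied by a symmetric n x n covariance matrix."""
    n = net.n_metabolites
    return FreeParameterReport(
        free=int(net.elasticity_pattern.sum()), equations=n * (n + 1) // 2
    )
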