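"""Reading and writing stoichiometric models and solutions.

Supported formats:

- SBML level 2 versions 1–4 (read; level 3 accepted leniently with a
  warning) and level 2 version 4 (write), via libsbml.  Flux bounds use
  the COBRA kinetic-law convention (parameters named LOWER_BOUND /
  UPPER_BOUND), falling back to reversibility defaults.
- a plain-text flat dialect, one reaction per line:
  ``<id>: <coeff> <met> [+ <coeff> <met>…] (->|<=>) … [lb, ub] {w=…}``
  with ``#`` comments, ``-boundary <met>`` declarations, and an optional
  trailing ``{exchange}``/``{internal}`` marker overriding the
  boundary-crossing heuristic.
- val files: one ``<reaction-id><TAB><flux>`` line per reaction, the
  table consumed by network visualization tools.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path
from typing import Optional

import libsbml

from .model import (
    INF_BOUND,
    FluxDistribution,
    Metabolite,
    Network,
    Reaction,
)

logger = logging.getLogger(__name__)


class ModelSyntaxError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SBML


def _default_bounds(reversible: bool) -> tuple[float, float]:
    return (-INF_BOUND, INF_BOUND) if reversible else (0.0, INF_BOUND)


def read_sbml(path: str | Path) -> Network:
    """Parse an SBML stoichiometric model into a Network.

    Species become metabolites (``boundaryCondition`` honored); reactions
    take their net stoichiometry from reactants and products, their
    bounds from LOWER_BOUND/UPPER_BOUND kinetic-law parameters or, when
    absent, from the reversibility flag.  Missing bounds are replaced by
    the finite surrogate ±1e5.  ``stoichiometryMath`` is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        msgs = [
            doc.getError(i).getMessage()
            for i in range(doc.getNumErrors())
            if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        ]
        raise ModelSyntaxError(f"SBML parse failure in {path}: {msgs[:3]}")
    model = doc.getModel()
    if model is None:
        raise ModelSyntaxError(f"{path}: no model element")
    level, version = doc.getLevel(), doc.getVersion()
    if level == 2 and not 1 <= version <= 4:
        raise ModelSyntaxError(
            f"{path}: SBML level 2 version {version} is outside 1-4"
        )
    if level == 3:
        warnings.warn(
            f"{path}: SBML level 3 read leniently (bounds from kinetic "
            "laws or reversibility defaults)"
        )
    elif level != 2:
        raise ModelSyntaxError(f"{path}: unsupported SBML level {level}")
    net = Network(name=model.getId() or path.stem)
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        net.add_metabolite(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                is_boundary=bool(sp.getBoundaryCondition()),
            )
        )
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        stoich: dict[str, float] = {}
        for refs, sign in (
            ([rxn.getReactant(j) for j in range(rxn.getNumReactants())], -1.0),
            ([rxn.getProduct(j) for j in range(rxn.getNumProducts())], 1.0),
        ):
            for ref in refs:
                if ref.isSetStoichiometryMath():
                    raise ModelSyntaxError(
                        f"reaction {rxn.getId()!r} uses stoichiometryMath, "
                        "which is not supported"
                    )
                mid = ref.getSpecies()
                stoich[mid] = stoich.get(mid, 0.0) + sign * ref.getStoichiometry()
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        reversible = bool(rxn.getReversible())
        lb, ub = _default_bounds(reversible)
        kl = rxn.getKineticLaw()
        if kl is not None:
            for pname, setter in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                par = kl.getParameter(pname) or kl.getLocalParameter(pname)
                if par is not None and par.isSetValue():
                    val = par.getValue()
                    if abs(val) > INF_BOUND or val != val:
                        val = INF_BOUND if val > 0 else -INF_BOUND
                    if setter == "lb":
                        lb = val
                    else:
                        ub = val
        is_exchange = None
        if rxn.isSetNotes():
            m = re.search(r"EXCHANGE:\s*(true|false)", rxn.getNotesString())
            if m:
                is_exchange = m.group(1) == "true"
        net.add_reaction(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                reversible=reversible or lb < 0,
                is_exchange=is_exchange,
            )
        )
    logger.info(
        "read %s: %d species, %d reactions (SBML L%dV%d)",
        path, len(net.metabolites), len(net.reactions), level, version,
    )
    if len(net.reactions) != model.getNumReactions():  # pragma: no cover
        raise ModelSyntaxError("reaction count mismatch after parsing")
    return net


def write_sbml(
    net: Network,
    path: str | Path,
    solution: Optional[FluxDistribution] = None,
) -> None:
    """Write SBML level 2 version 4; solution fluxes go into reaction
    notes and a FLUX_VALUE kinetic-law parameter.  Deterministic output.
    """
    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId(re.sub(r"[^A-Za-z0-9_]", "_", net.name) or "model")
    compartments: list[str] = []
    for met in net.metabolites.values():
        if met.compartment not in compartments:
            compartments.append(met.compartment)
    for cid in compartments:
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setSize(1.0)
    for met in net.metabolites.values():
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setBoundaryCondition(met.is_boundary)
        sp.setInitialConcentration(0.0)
    for rxn in net.reactions.values():
        r = model.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name)
        r.setReversible(rxn.lower_bound < 0)
        for mid, coeff in rxn.stoichiometry.items():
            ref = r.createReactant() if coeff < 0 else r.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coeff))
        kl = r.createKineticLaw()
        kl.setFormula("FLUX_VALUE")
        for pname, val in (
            ("LOWER_BOUND", rxn.lower_bound),
            ("UPPER_BOUND", rxn.upper_bound),
            (
                "FLUX_VALUE",
                solution.fluxes.get(rxn.id, 0.0)
                if solution is not None and solution.optimal
                else 0.0,
            ),
        ):
            par = kl.createParameter()
            par.setId(pname)
            par.setValue(val)
        notes: list[str] = []
        if solution is not None and solution.optimal:
            notes.append(f"<p>FLUX: {solution.fluxes.get(rxn.id, 0.0):.6g}</p>")
        if rxn.is_exchange is not None:
            # an explicit boundary-crossing flag overrides the one-sided
            # stoichiometry heuristic and must survive the round trip
            notes.append(f"<p>EXCHANGE: {str(rxn.is_exchange).lower()}</p>")
        if notes:
            r.setNotes(
                '<body xmlns="http://www.w3.org/1999/xhtml">'
                + "".join(notes)
                + "</body>"
            )
    ok = libsbml.writeSBMLToFile(doc, str(path))
    if not ok:
        raise OSError(f"cannot write SBML to {path}")


# ---------------------------------------------------------------------------
# flat text dialect

_ARROW_RE = re.compile(r"(->|<=>)")
_BOUNDS_RE = re.compile(r"\[\s*([-+0-9.eE]+)\s*,\s*([-+0-9.eE]+)\s*\]")
_WEIGHT_RE = re.compile(r"\{\s*w\s*=\s*([-+0-9.eE]+)\s*\}")
_EXCHANGE_RE = re.compile(r"\{\s*(exchange|internal)\s*\}")


def _parse_side(text: str, line_no: int) -> dict[str, float]:
    text = text.strip()
    if not text:
        return {}
    stoich: dict[str, float] = {}
    for chunk in text.split("+"):
        parts = chunk.split()
        if len(parts) == 1:
            coeff, mid = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coeff = float(parts[0])
            except ValueError:
                raise ModelSyntaxError(
                    f"line {line_no}: bad coefficient {parts[0]!r}"
                )
            mid = parts[1]
        else:
            raise ModelSyntaxError(f"line {line_no}: bad term {chunk.strip()!r}")
        stoich[mid] = stoich.get(mid, 0.0) + coeff
    return stoich


def read_flat(path: str | Path) -> Network:
    """Parse the plain-text flat model dialect (see module docstring)."""
    net = Network(name=Path(path).stem)
    boundary: set[str] = set()
    reactions: list[Reaction] = []
    met_order: list[str] = []
    for line_no, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("-boundary"):
            parts = line.split()
            if len(parts) != 2:
                raise ModelSyntaxError(
                    f"line {line_no}: -boundary takes one metabolite"
                )
            boundary.add(parts[1])
            if parts[1] not in met_order:
                met_order.append(parts[1])
            continue
        if ":" not in line:
            raise ModelSyntaxError(
                f"line {line_no}: expected '<id>: <reaction>' in {line!r}"
            )
        rid, _, body = line.partition(":")
        rid = rid.strip()
        if not rid:
            raise ModelSyntaxError(f"line {line_no}: empty reaction id")
        weight = 1.0
        wm = _WEIGHT_RE.search(body)
        if wm:
            weight = float(wm.group(1))
            body = _WEIGHT_RE.sub("", body)
        is_exchange = None
        xm = _EXCHANGE_RE.search(body)
        if xm:
            is_exchange = xm.group(1) == "exchange"
            body = _EXCHANGE_RE.sub("", body)
        bounds: Optional[tuple[float, float]] = None
        bm = _BOUNDS_RE.search(body)
        if bm:
            bounds = (float(bm.group(1)), float(bm.group(2)))
            body = _BOUNDS_RE.sub("", body)
        arrow = _ARROW_RE.search(body)
        if not arrow:
            raise ModelSyntaxError(
                f"line {line_no}: no '->' or '<=>' in {line!r}"
            )
        reversible = arrow.group(1) == "<=>"
        left, right = body[: arrow.start()], body[arrow.end() :]
        stoich: dict[str, float] = {}
        for mid, coeff in _parse_side(left, line_no).items():
            stoich[mid] = stoich.get(mid, 0.0) - coeff
        for mid, coeff in _parse_side(right, line_no).items():
            stoich[mid] = stoich.get(mid, 0.0) + coeff
        stoich = {m: c for m, c in stoich.items() if c != 0.0}
        if not stoich:
            raise ModelSyntaxError(f"line {line_no}: empty stoichiometry")
        lb, ub = bounds if bounds is not None else _default_bounds(reversible)
        for mid in stoich:
            if mid not in met_order:
                met_order.append(mid)
        reactions.append(
            Reaction(
                id=rid,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                reversible=reversible,
                weight=weight,
                is_exchange=is_exchange,
            )
        )
    for mid in met_order:
        net.add_metabolite(Metabolite(mid, is_boundary=mid in boundary))
    for rxn in reactions:
        net.add_reaction(rxn)
    return net


def _fmt_num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.10g}"


def write_flat(net: Network, path: str | Path) -> None:
    """Serialize to the flat dialect; read_flat round-trips exactly."""
    lines: list[str] = []
    for mid, met in net.metabolites.items():
        if met.is_boundary:
            lines.append(f"-boundary {mid}")
    for rid, rxn in net.reactions.items():
        subs = [
            f"{_fmt_num(-c)} {m}" for m, c in rxn.stoichiometry.items() if c < 0
        ]
        prods = [
            f"{_fmt_num(c)} {m}" for m, c in rxn.stoichiometry.items() if c > 0
        ]
        arrow = "<=>" if rxn.reversible else "->"
        line = (
            f"{rid}: {' + '.join(subs)} {arrow} {' + '.join(prods)}".rstrip()
            + f" [{_fmt_num(rxn.lower_bound)}, {_fmt_num(rxn.upper_bound)}]"
        )
        if rxn.weight != 1.0:
            line += f" {{w={_fmt_num(rxn.weight)}}}"
        if rxn.is_exchange is not None:
            line += " {exchange}" if rxn.is_exchange else " {internal}"
        lines.append(line)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# val files


def write_val(
    solution: FluxDistribution,
    net: Network,
    path: str | Path,
    header: bool = False,
) -> None:
    """One ``<reaction-id><TAB><flux>`` line per reaction, network order,
    6 significant digits; zero printed as ``0``, never ``-0``."""
    if not solution.optimal:
        raise ValueError("val files require an OPTIMAL solution")
    lines: list[str] = []
    if header:
        lines.append("# reaction\tflux")
    for rid in net.reactions:
        flux = solution.fluxes.get(rid, 0.0)
        if flux == 0.0:
            flux = 0.0  # normalize -0.0
        lines.append(f"{rid}\t{flux:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
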