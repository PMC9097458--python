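"""Serialization of the reaction network: SBML Level 3, CSV tables, and a
BioNetGen-flavoured plain-text rule listing.

The CSV pair (``species.csv`` + ``reactions.csv``) round-trips losslessly:
re-importing reproduces the identical stoichiometry matrix and rate values,
so simulation derivatives are bit-identical before and after export.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import pandas as pd

from .params import ParameterSet
from .network import Reaction, ReactionNetwork, Species, SpeciesKind
from .rules import RuleSet
from .states import enumerate_states

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sbml_id(i: int) -> str:
    return f"s{i}"


def to_sbml(network: ReactionNetwork) -> str:
    """Render the network as an SBML Level 3 Version 2 document string."""
    ET.register_namespace("", SBML_NS)
    sbml = ET.Element(f"{{{SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(sbml, f"{{{SBML_NS}}}model", {"id": "plcg1_activation"})

    comps = ET.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    ET.SubElement(
        comps,
        f"{{{SBML_NS}}}compartment",
        {"id": "cell", "constant": "true", "spatialDimensions": "3", "size": "1"},
    )

    los = ET.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sp in network.species:
        ET.SubElement(
            los,
            f"{{{SBML_NS}}}species",
            {
                "id": _sbml_id(sp.id),
                "name": sp.label,
                "compartment": "cell",
                "hasOnlySubstanceUnits": "false",
                "boundaryCondition": "false",
                "constant": "false",
            },
        )

    lop = ET.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for name, value in network.params.rate_values().items():
        ET.SubElement(
            lop,
            f"{{{SBML_NS}}}parameter",
            {"id": name, "value": repr(value), "constant": "true"},
        )

    lor = ET.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rxn in network.reactions:
        r = ET.SubElement(
            lor,
            f"{{{SBML_NS}}}reaction",
            {"id": f"r{rxn.id}", "name": rxn.source_rule, "reversible": "false"},
        )
        lre = ET.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
        for i in rxn.reactant_ids:
            ET.SubElement(
                lre,
                f"{{{SBML_NS}}}speciesReference",
                {"species": _sbml_id(i), "stoichiometry": "1", "constant": "true"},
            )
        lpr = ET.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
        for i in rxn.product_ids:
            ET.SubElement(
                lpr,
                f"{{{SBML_NS}}}speciesReference",
                {"species": _sbml_id(i), "stoichiometry": "1", "constant": "true"},
            )
        kl = ET.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        math = ET.SubElement(kl, f"{{{MATHML_NS}}}math")
        times = ET.SubElement(math, f"{{{MATHML_NS}}}apply")
        ET.SubElement(times, f"{{{MATHML_NS}}}times")
        ET.SubElement(times, f"{{{MATHML_NS}}}ci").text = rxn.rate_constant
        for i in rxn.reactant_ids:
            ET.SubElement(times, f"{{{MATHML_NS}}}ci").text = _sbml_id(i)

    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)


def to_bngl(ruleset: RuleSet, params: ParameterSet) -> str:
    """Plain-text, BioNetGen-flavoured listing of the 12 rules."""
    rates = params.rate_values()
    lines = ["begin reaction rules"]
    for rule in ruleset:
        pat = ",".join(
            f"{site}~{{{'|'.join(sorted(v.value for v in vals))}}}"
            for site, vals in sorted(rule.reactant_pattern.items())
        )
        change = f"{rule.product_site}~{rule.product_value.value}"
        partner = " + RTK(pY~free)" if rule.bimolecular else ""
        lines.append(
            f"  {rule.name}: PLC({pat}){partner} -> PLC({change})"
            f"  {rule.rate_constant}={rates[rule.rate_constant]:g}"
        )
    lines.append("end reaction rules")
    return "\n".join(lines) + "\n"


def species_table(network: ReactionNetwork) -> pd.DataFrame:
    rows = []
    for sp in network.species:
        st = sp.plc_state
        rows.append(
            {
                "id": sp.id,
                "label": sp.label,
                "kind": sp.kind.value,
                "rtk_bound": bool(st.rtk_bound) if st else False,
                "active": bool(st.active) if st else False,
                "cytosolic": bool(st.cytosolic) if st else False,
            }
        )
    return pd.DataFrame(rows)


def reaction_table(network: ReactionNetwork) -> pd.DataFrame:
    rows = []
    for r in network.reactions:
        rows.append(
            {
                "id": r.id,
                "rule": r.source_rule,
                "rate_constant": r.rate_constant,
                "rate_value": r.rate_value,
                "reactants": "+".join(map(str, r.reactant_ids)),
                "products": "+".join(map(str, r.product_ids)),
            }
        )
    return pd.DataFrame(rows)


def to_csv(network: ReactionNetwork, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    species_table(network).to_csv(directory / "species.csv", index=False)
    reaction_table(network).to_csv(directory / "reactions.csv", index=False)


def from_csv(directory: str | Path, params: ParameterSet) -> ReactionNetwork:
    """Rebuild a network from the CSV pair written by :func:`to_csv`."""
    directory = Path(directory)
    sdf = pd.read_csv(directory / "species.csv")
    rdf = pd.read_csv(directory / "reactions.csv")
    by_label = {st.label(): st for st in enumerate_states()}
    species = []
    for row in sdf.itertuples():
        kind = SpeciesKind(row.kind)
        state = None
        if kind is not SpeciesKind.RTK_FREE:
            state = by_label[row.label.removesuffix(".RTK")]
        species.append(Species(int(row.id), kind, state, row.label))
    reactions = []
    for row in rdf.itertuples():
        reactions.append(
            Reaction(
                id=int(row.id),
                reactant_ids=tuple(int(x) for x in str(row.reactants).split("+")),
                product_ids=tuple(int(x) for x in str(row.products).split("+")),
                rate_constant=row.rate_constant,
                rate_value=float(row.rate_value),
                source_rule=row.rule,
            )
        )
    return ReactionNetwork(species, reactions, params)


def export_network(
    network: ReactionNetwork,
    fmt: str,
    path: str | Path,
    ruleset: RuleSet | None = None,
) -> Path:
    """Write the network in one of ``sbml``, ``csv`` or ``bngl`` formats.

    For ``csv`` the path is a directory receiving ``species.csv`` and
    ``reactions.csv``; otherwise it is the output file.
    """
    path = Path(path)
    if fmt == "sbml":
        path.write_text(to_sbml(network))
    elif fmt == "csv":
        to_csv(network, path)
    elif fmt == "bngl":
        if ruleset is None:
            raise ValueError("bngl export requires the rule set")
        path.write_text(to_bngl(ruleset, network.params))
    else:
        raise ValueError(f"unknown export format: {fmt!r}")
    return path
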