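"""SBML Level 3 Version 2 export/import for reaction networks.

The writer emits one compartment, species with initial amounts, global
parameters, and one reaction element per network reaction with a
MathML kinetic law (product of the rate constant, reactant and modifier
amounts, and any saturating inhibition divisors).  The reader inverts
exactly this dialect; it is a round-trip companion for the writer, not
a general SBML importer.
"""

from __future__ import annotations

from lxml import etree

from .network import MASS_ACTION, ReactionNetwork

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_KIND_ANNOT = "{%s}reactionKind" % SBML_NS


def _math_ci(parent, name):
    etree.SubElement(parent, "{%s}ci" % MATHML_NS).text = f" {name} "


def export_sbml(network: ReactionNetwork, path=None) -> bytes:
    """Serialize the network to SBML L3V2; returns the XML bytes."""
    nsmap = {None: SBML_NS}
    root = etree.Element("{%s}sbml" % SBML_NS, nsmap=nsmap,
                         level="3", version="2")
    model = etree.SubElement(root, "{%s}model" % SBML_NS, id=network.name)
    comps = etree.SubElement(model, "{%s}listOfCompartments" % SBML_NS)
    for tag in sorted({s.compartment_tag for s in network.species.values()}):
        etree.SubElement(comps, "{%s}compartment" % SBML_NS, id=tag,
                         constant="true", spatialDimensions="3", size="1")
    sp_list = etree.SubElement(model, "{%s}listOfSpecies" % SBML_NS)
    for s in network.species.values():
        etree.SubElement(
            sp_list, "{%s}species" % SBML_NS, id=s.name,
            compartment=s.compartment_tag,
            initialAmount=repr(s.initial_amount),
            hasOnlySubstanceUnits="true", boundaryCondition="false",
            constant="false",
        )
    par_list = etree.SubElement(model, "{%s}listOfParameters" % SBML_NS)
    for name, value in network.parameters.items():
        etree.SubElement(par_list, "{%s}parameter" % SBML_NS, id=name,
                         value=repr(value), constant="true")
    rxn_list = etree.SubElement(model, "{%s}listOfReactions" % SBML_NS)
    for r in network.reactions:
        rx = etree.SubElement(rxn_list, "{%s}reaction" % SBML_NS, id=r.name,
                              reversible="false")
        rx.set("metaid", f"kind.{r.kind}")
        if r.reactants:
            lst = etree.SubElement(rx, "{%s}listOfReactants" % SBML_NS)
            for sp in r.reactants:
                etree.SubElement(lst, "{%s}speciesReference" % SBML_NS,
                                 species=sp, stoichiometry="1", constant="true")
        if r.products:
            lst = etree.SubElement(rx, "{%s}listOfProducts" % SBML_NS)
            for sp in r.products:
                etree.SubElement(lst, "{%s}speciesReference" % SBML_NS,
                                 species=sp, stoichiometry="1", constant="true")
        if r.modifiers or r.inhibitors:
            lst = etree.SubElement(rx, "{%s}listOfModifiers" % SBML_NS)
            for sp in r.modifiers:
                etree.SubElement(lst, "{%s}modifierSpeciesReference" % SBML_NS,
                                 species=sp)
            for sp, kp in r.inhibitors:
                el = etree.SubElement(lst,
                                      "{%s}modifierSpeciesReference" % SBML_NS,
                                      species=sp)
                el.set("metaid", f"inhibitor.{kp}")
        law = etree.SubElement(rx, "{%s}kineticLaw" % SBML_NS)
        math = etree.SubElement(law, "{%s}math" % MATHML_NS)
        apply_el = etree.SubElement(math, "{%s}apply" % MATHML_NS)
        etree.SubElement(apply_el, "{%s}times" % MATHML_NS)
        _math_ci(apply_el, r.rate_param)
        for sp in list(r.reactants) + list(r.modifiers):
            _math_ci(apply_el, sp)
        for sp, kp in r.inhibitors:
            div = etree.SubElement(apply_el, "{%s}apply" % MATHML_NS)
            etree.SubElement(div, "{%s}divide" % MATHML_NS)
            etree.SubElement(div, "{%s}cn" % MATHML_NS).text = " 1 "
            plus = etree.SubElement(div, "{%s}apply" % MATHML_NS)
            etree.SubElement(plus, "{%s}plus" % MATHML_NS)
            etree.SubElement(plus, "{%s}cn" % MATHML_NS).text = " 1 "
            ratio = etree.SubElement(plus, "{%s}apply" % MATHML_NS)
            etree.SubElement(ratio, "{%s}divide" % MATHML_NS)
            _math_ci(ratio, sp)
            _math_ci(ratio, kp)
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(data)
    return data


def import_sbml(source) -> ReactionNetwork:
    """Parse a network from SBML produced by :func:`export_sbml`.

    ``source`` is a path or XML bytes.  Raises ``ValueError`` with line
    context on malformed input.
    """
    try:
        if isinstance(source, (bytes, bytearray)):
            root = etree.fromstring(bytes(source))
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed SBML: {exc}") from exc
    if root.tag != "{%s}sbml" % SBML_NS:
        raise ValueError(f"not an SBML L3 document (root {root.tag})")
    model = root.find("{%s}model" % SBML_NS)
    net = ReactionNetwork(model.get("id", "network"))
    for sp in model.findall(".//{%s}species" % SBML_NS):
        net.add_species(sp.get("id"), float(sp.get("initialAmount", "0")),
                        compartment_tag=sp.get("compartment", "cytosol"))
    for par in model.findall(".//{%s}parameter" % SBML_NS):
        net.set_parameter(par.get("id"), float(par.get("value")))
    for rx in model.findall(".//{%s}reaction" % SBML_NS):
        kind_annot = rx.get("metaid", "")
        if not kind_annot.startswith("kind."):
            raise ValueError(
                f"reaction {rx.get('id')!r} (line {rx.sourceline}): "
                "missing reaction-kind annotation"
            )
        kind = kind_annot[len("kind."):]
        reactants = [e.get("species") for e in
                     rx.findall(".//{%s}listOfReactants/{%s}speciesReference"
                                % (SBML_NS, SBML_NS))]
        products = [e.get("species") for e in
                    rx.findall(".//{%s}listOfProducts/{%s}speciesReference"
                               % (SBML_NS, SBML_NS))]
        modifiers, inhibitors = [], []
        for e in rx.findall(".//{%s}modifierSpeciesReference" % SBML_NS):
            meta = e.get("metaid", "")
            if meta.startswith("inhibitor."):
                inhibitors.append((e.get("species"), meta[len("inhibitor."):]))
            else:
                modifiers.append(e.get("species"))
        ci = rx.find(".//{%s}kineticLaw//{%s}ci" % (SBML_NS, MATHML_NS))
        if ci is None:
            raise ValueError(
                f"reaction {rx.get('id')!r} (line {rx.sourceline}): "
                "missing kinetic law"
            )
        rate_param = ci.text.strip()
        net.add_reaction(rx.get("id"), reactants, products,
                         modifiers=modifiers, rate_param=rate_param,
                         kind=kind or MASS_ACTION, inhibitors=inhibitors)
    return net
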