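"""Reading and writing SBML Level 3 qual documents.

Supports the logical-model profile of the qual package: qualitative species
with ``maxLevel``/``initialLevel``, transitions whose inputs have
``transitionEffect="none"`` and outputs ``transitionEffect="assignmentLevel"``,
ordered function terms with MathML boolean conditions, and a mandatory default
term. Petri-net style transition effects (consumption/production) are rejected
with an explicit unsupported-profile error rather than silently misread.

Output is canonical: species and transitions are emitted in lexicographic id
order with a fixed attribute order, so equal models serialise to identical
bytes. Annotation and notes elements are carried through opaquely.
"""

from __future__ import annotations

import io as _io
from typing import Optional, Union

from lxml import etree

from .errors import ParseError, ValidationError
from .model import (
    And,
    Cmp,
    FALSE,
    FunctionTerm,
    LogicalModel,
    LogicExpression,
    Not,
    Or,
    QualitativeSpecies,
    TRUE,
    Transition,
    TransitionInput,
    TransitionOutput,
    validate_model,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
QUAL_NS = "http://www.sbml.org/sbml/level3/version1/qual/version1"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

NSMAP = {None: SBML_NS, "qual": QUAL_NS}


def _q(tag: str) -> str:
    return f"{{{QUAL_NS}}}{tag}"


def _s(tag: str) -> str:
    return f"{{{SBML_NS}}}{tag}"


def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


# ---------------------------------------------------------------------------
# MathML conditions
# ---------------------------------------------------------------------------

_RELOPS = {"eq": "eq", "neq": "neq", "lt": "lt", "leq": "leq", "gt": "gt", "geq": "geq"}
_FLIP = {"lt": "gt", "gt": "lt", "leq": "geq", "geq": "leq", "eq": "eq", "neq": "neq"}


def parse_condition(fragment: Union[str, bytes, etree._Element]) -> LogicExpression:
    """Parse a MathML ``<math>`` fragment into a LogicExpression.

    Supported: ``apply`` with and/or/xor/not and the relational operators
    eq/neq/lt/leq/gt/geq comparing one species symbol (``ci``) with one
    integer constant (``cn``), plus the boolean constants. ``xor`` is
    normalised into and/or/not form. Anything else is rejected.
    """
    if isinstance(fragment, (str, bytes)):
        root = etree.fromstring(fragment)
    else:
        root = fragment
    if etree.QName(root).localname != "math":
        raise ParseError("bad-math", "condition is not rooted at a math element")
    children = [c for c in root if isinstance(c.tag, str)]
    if len(children) != 1:
        raise ParseError("bad-math", "math element must have exactly one child")
    return _parse_node(children[0])


def _parse_node(el: etree._Element) -> LogicExpression:
    name = etree.QName(el).localname
    if name == "true":
        return TRUE
    if name == "false":
        return FALSE
    if name != "apply":
        raise ParseError("unsupported-mathml", f"unexpected MathML element <{name}>")
    kids = [c for c in el if isinstance(c.tag, str)]
    if not kids:
        raise ParseError("unsupported-mathml", "empty apply")
    op = etree.QName(kids[0]).localname
    args = kids[1:]
    if op in ("and", "or", "xor"):
        if len(args) < 2:
            raise ParseError("unsupported-mathml", f"<{op}> needs at least two operands")
        parsed = [_parse_node(a) for a in args]
        if op == "and":
            return And(tuple(parsed))
        if op == "or":
            return Or(tuple(parsed))
        # fold xor pairwise into and/or/not form
        acc = parsed[0]
        for nxt in parsed[1:]:
            acc = Or((And((acc, Not(nxt))), And((Not(acc), nxt))))
        return acc
    if op == "not":
        if len(args) != 1:
            raise ParseError("unsupported-mathml", "<not> needs exactly one operand")
        return Not(_parse_node(args[0]))
    if op in _RELOPS:
        if len(args) != 2:
            raise ParseError("unsupported-mathml", f"<{op}> needs exactly two operands")
        names = [etree.QName(a).localname for a in args]
        if names == ["ci", "cn"]:
            ci, cn = args
            flip = False
        elif names == ["cn", "ci"]:
            cn, ci = args
            flip = True
        else:
            raise ParseError(
                "unsupported-mathml",
                f"<{op}> must compare one species symbol with one constant, got {names}",
            )
        species = (ci.text or "").strip()
        if not species:
            raise ParseError("unsupported-mathml", "empty species symbol in comparison")
        cn_type = cn.get("type", "integer")
        txt = (cn.text or "").strip()
        try:
            if cn_type not in ("integer", "real"):
                raise ValueError
            value = float(txt)
            const = int(value)
            if const != value:
                raise ValueError
        except ValueError:
            raise ParseError("non-integer-constant", f"constant {txt!r} is not an integer")
        return Cmp(_FLIP[op] if flip else op, species, const)
    raise ParseError("unsupported-mathml", f"unsupported MathML operator <{op}>")


def condition_to_mathml(expr: LogicExpression) -> etree._Element:
    """Serialise a LogicExpression into a MathML ``<math>`` element."""
    math = etree.Element(_m("math"), nsmap={None: MATHML_NS})
    math.append(_emit_node(expr))
    return math


def _emit_node(expr: LogicExpression) -> etree._Element:
    from .model import And as _And, Or as _Or, Not as _Not, Cmp as _Cmp
    from .model import TrueExpr, FalseExpr

    if isinstance(expr, TrueExpr):
        return etree.Element(_m("true"))
    if isinstance(expr, FalseExpr):
        return etree.Element(_m("false"))
    apply = etree.Element(_m("apply"))
    if isinstance(expr, _Cmp):
        apply.append(etree.Element(_m(expr.op)))
        ci = etree.SubElement(apply, _m("ci"))
        ci.text = f" {expr.species} "
        cn = etree.SubElement(apply, _m("cn"))
        cn.set("type", "integer")
        cn.text = f" {expr.const} "
        return apply
    if isinstance(expr, _Not):
        apply.append(etree.Element(_m("not")))
        apply.append(_emit_node(expr.child))
        return apply
    if isinstance(expr, (_And, _Or)):
        apply.append(etree.Element(_m("and" if isinstance(expr, _And) else "or")))
        for c in expr.children:
            apply.append(_emit_node(c))
        return apply
    raise TypeError(f"cannot serialise {expr!r}")


# ---------------------------------------------------------------------------
# Reader
# ---------------------------------------------------------------------------

_KNOWN_SPECIES_ATTRS = {"id", "name", "compartment", "constant", "maxLevel", "initialLevel"}
_KNOWN_INPUT_ATTRS = {"id", "name", "qualitativeSpecies", "transitionEffect", "sign", "thresholdLevel"}
_KNOWN_OUTPUT_ATTRS = {"id", "name", "qualitativeSpecies", "transitionEffect", "outputLevel"}


def _opaque(el: etree._Element) -> list[bytes]:
    """Annotation/notes payloads preserved verbatim for round-trips."""
    out = []
    for child in el:
        if isinstance(child.tag, str) and etree.QName(child).localname in ("annotation", "notes"):
            out.append(etree.tostring(child))
    return out


def read(
    source, strict: bool = False
) -> tuple[LogicalModel, list[str]]:
    """Read an SBML qual document into a LogicalModel.

    `source` is a path, file object, or bytes. Returns the model and a list
    of warnings for ignorable oddities (unknown annotations, core reaction
    lists, zero transitions). Under `strict`, unknown qual attributes are
    errors instead of warnings. Structural problems raise ParseError with the
    offending element path.
    """
    if isinstance(source, bytes):
        source = _io.BytesIO(source)
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise ParseError("xml-syntax", str(exc)) from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise ParseError("not-sbml", f"root element is <{etree.QName(root).localname}>, not <sbml>")
    if QUAL_NS not in root.nsmap.values():
        raise ParseError("no-qual-namespace", "document does not declare the qual version-1 namespace")
    warnings: list[str] = []
    if root.get(_q("required")) is None:
        warnings.append("qual:required flag missing on the sbml element")

    model_el = root.find(_s("model"))
    if model_el is None:
        raise ParseError("no-model", "document has no <model> element")
    name = model_el.get("id") or model_el.get("name")

    if model_el.find(_s("listOfReactions")) is not None:
        warnings.append("core listOfReactions present; ignored")

    annotations: dict = {}
    payload = _opaque(model_el)
    if payload:
        annotations[("model",)] = payload

    species: list[QualitativeSpecies] = []
    los = model_el.find(_q("listOfQualitativeSpecies"))
    if los is not None:
        for el in los.findall(_q("qualitativeSpecies")):
            sid = el.get(_q("id"))
            path = f"qualitativeSpecies[{sid}]"
            if sid is None:
                raise ParseError("missing-id", "qualitativeSpecies without qual:id", path)
            unknown = [
                etree.QName(k).localname
                for k in el.keys()
                if k.startswith(f"{{{QUAL_NS}}}")
                and etree.QName(k).localname not in _KNOWN_SPECIES_ATTRS
            ]
            if unknown:
                msg = f"unknown qual attributes on {path}: {unknown}"
                if strict:
                    raise ParseError("unknown-attribute", msg, path)
                warnings.append(msg)
            max_level = el.get(_q("maxLevel"))
            init = el.get(_q("initialLevel"))
            species.append(
                QualitativeSpecies(
                    id=sid,
                    name=el.get(_q("name")),
                    compartment=el.get(_q("compartment")) or "default",
                    constant=(el.get(_q("constant")) == "true"),
                    max_level=int(max_level) if max_level is not None else 1,
                    initial_level=int(init) if init is not None else None,
                )
            )
            payload = _opaque(el)
            if payload:
                annotations[("species", sid)] = payload

    transitions: list[Transition] = []
    lot = model_el.find(_q("listOfTransitions"))
    if lot is not None:
        for el in lot.findall(_q("transition")):
            transitions.append(_read_transition(el, annotations))
    if not transitions:
        warnings.append("document declares no transitions; all species are constants")

    model = LogicalModel(species, transitions, name=name)
    model.annotations = annotations
    diags = [d for d in validate_model(model) if d.severity == "error"]
    if diags:
        d = diags[0]
        raise ParseError(d.code, d.message, d.location)
    return model, warnings


def _read_transition(el: etree._Element, annotations: dict) -> Transition:
    tid = el.get(_q("id")) or "(anonymous)"
    path = f"transition[{tid}]"

    inputs = []
    loi = el.find(_q("listOfInputs"))
    if loi is not None:
        for inp in loi.findall(_q("input")):
            ref = inp.get(_q("qualitativeSpecies"))
            if ref is None:
                raise ParseError("missing-ref", "input without qualitativeSpecies", path)
            effect = inp.get(_q("transitionEffect"), "none")
            if effect != "none":
                raise ParseError(
                    "unsupported-profile",
                    f"input transitionEffect {effect!r} (Petri-net profile) is not supported",
                    path,
                )
            thr = inp.get(_q("thresholdLevel"))
            inputs.append(
                TransitionInput(
                    species=ref,
                    sign=inp.get(_q("sign")),
                    threshold_level=int(thr) if thr is not None else None,
                )
            )

    outputs = []
    loo = el.find(_q("listOfOutputs"))
    if loo is not None:
        for out in loo.findall(_q("output")):
            ref = out.get(_q("qualitativeSpecies"))
            if ref is None:
                raise ParseError("missing-ref", "output without qualitativeSpecies", path)
            effect = out.get(_q("transitionEffect"), "assignmentLevel")
            if effect != "assignmentLevel":
                raise ParseError(
                    "unsupported-profile",
                    f"output transitionEffect {effect!r} (Petri-net profile) is not supported",
                    path,
                )
            outputs.append(TransitionOutput(species=ref))

    terms: list[FunctionTerm] = []
    default: Optional[FunctionTerm] = None
    loft = el.find(_q("listOfFunctionTerms"))
    if loft is not None:
        for child in loft:
            if not isinstance(child.tag, str):
                continue
            local = etree.QName(child).localname
            if local == "defaultTerm":
                lvl = child.get(_q("resultLevel"))
                if lvl is None:
                    raise ParseError("missing-result", "defaultTerm without resultLevel", path)
                default = FunctionTerm(result_level=int(lvl))
            elif local == "functionTerm":
                lvl = child.get(_q("resultLevel"))
                if lvl is None:
                    raise ParseError("missing-result", "functionTerm without resultLevel", path)
                math = child.find(_m("math"))
                if math is None:
                    raise ParseError("missing-condition", "functionTerm without math condition", path)
                terms.append(
                    FunctionTerm(result_level=int(lvl), condition=parse_condition(math))
                )
    if default is None:
        raise ParseError("missing-default", f"transition {tid!r} has no defaultTerm", path)

    payload = _opaque(el)
    if payload:
        annotations[("transition", tid)] = payload
    return Transition(
        id=tid,
        inputs=tuple(inputs),
        outputs=tuple(outputs),
        function_terms=tuple(terms),
        default_term=default,
    )


# ---------------------------------------------------------------------------
# Writer
# ---------------------------------------------------------------------------


def write(model: LogicalModel, strict_validation: bool = True) -> bytes:
    """Serialise a LogicalModel to canonical SBML qual bytes.

    Refuses invalid models with their diagnostics. Equal models produce
    byte-identical documents (lexicographic element order, fixed attributes,
    UTF-8).
    """
    if strict_validation:
        diags = [d for d in validate_model(model) if d.severity == "error"]
        if diags:
            raise ValidationError(diags)

    annotations = getattr(model, "annotations", {}) or {}

    root = etree.Element(_s("sbml"), nsmap=NSMAP)
    root.set("level", "3")
    root.set("version", "1")
    root.set(_q("required"), "false")

    model_el = etree.SubElement(root, _s("model"))
    model_el.set("id", model.name or "model")
    for blob in annotations.get(("model",), ()):
        model_el.append(etree.fromstring(blob))

    compartments = sorted({s.compartment for s in model.species} or {"default"})
    loc = etree.SubElement(model_el, _s("listOfCompartments"))
    for comp in compartments:
        c = etree.SubElement(loc, _s("compartment"))
        c.set("id", comp)
        c.set("constant", "true")

    los = etree.SubElement(model_el, _q("listOfQualitativeSpecies"))
    for sp in sorted(model.species, key=lambda s: s.id):
        el = etree.SubElement(los, _q("qualitativeSpecies"))
        el.set(_q("id"), sp.id)
        if sp.name is not None:
            el.set(_q("name"), sp.name)
        el.set(_q("compartment"), sp.compartment)
        el.set(_q("constant"), "true" if sp.constant else "false")
        el.set(_q("maxLevel"), str(sp.max_level))
        if sp.initial_level is not None:
            el.set(_q("initialLevel"), str(sp.initial_level))
        for blob in annotations.get(("species", sp.id), ()):
            el.append(etree.fromstring(blob))

    if model.transitions:
        lot = etree.SubElement(model_el, _q("listOfTransitions"))
        for tr in sorted(model.transitions, key=lambda t: t.id):
            _write_transition(lot, tr, annotations)

    return etree.tostring(
        etree.ElementTree(root),
        xml_declaration=True,
        encoding="UTF-8",
        pretty_print=True,
    )


def _write_transition(parent, tr: Transition, annotations: dict) -> None:
    el = etree.SubElement(parent, _q("transition"))
    el.set(_q("id"), tr.id)
    for blob in annotations.get(("transition", tr.id), ()):
        el.append(etree.fromstring(blob))
    if tr.inputs:
        loi = etree.SubElement(el, _q("listOfInputs"))
        for inp in sorted(tr.inputs, key=lambda i: i.species):
            iel = etree.SubElement(loi, _q("input"))
            iel.set(_q("id"), f"{tr.id}_in_{inp.species}")
            iel.set(_q("qualitativeSpecies"), inp.species)
            iel.set(_q("transitionEffect"), "none")
            if inp.sign is not None:
                iel.set(_q("sign"), inp.sign)
            if inp.threshold_level is not None:
                iel.set(_q("thresholdLevel"), str(inp.threshold_level))
    loo = etree.SubElement(el, _q("listOfOutputs"))
    for out in sorted(tr.outputs, key=lambda o: o.species):
        oel = etree.SubElement(loo, _q("output"))
        oel.set(_q("id"), f"{tr.id}_out_{out.species}")
        oel.set(_q("qualitativeSpecies"), out.species)
        oel.set(_q("transitionEffect"), "assignmentLevel")
    loft = etree.SubElement(el, _q("listOfFunctionTerms"))
    dt = etree.SubElement(loft, _q("defaultTerm"))
    dt.set(_q("resultLevel"), str(tr.default_term.result_level))
    for term in tr.function_terms:
        ft = etree.SubElement(loft, _q("functionTerm"))
        ft.set(_q("resultLevel"), str(term.result_level))
        ft.append(condition_to_mathml(term.condition))
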