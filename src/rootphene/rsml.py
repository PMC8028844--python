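"""Root System Markup Language (RSML) reader and writer.

Writes one scene/plant per root system with axial roots as top-level
<root> elements and their laterals nested inside, polyline geometry in cm
(y = depth, positive down), per-root diameter, emergence day and class
label (stored both as the ``label`` attribute and an ``accession``
property, following RSML practice).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .simulate import Root, RootSystem


class RSMLError(ValueError):
    pass


def write_rsml(system: RootSystem, path) -> None:
    rsml = ET.Element("rsml")
    meta = ET.SubElement(rsml, "metadata")
    ET.SubElement(meta, "version").text = "1"
    ET.SubElement(meta, "unit").text = "cm"
    ET.SubElement(meta, "resolution").text = "1"
    ET.SubElement(meta, "software").text = "rootphene"
    prop = ET.SubElement(meta, "property-definitions")
    for name, unit in (("diameter", "cm"), ("born_day", "day"),
                       ("branch_arc", "cm")):
        pd_ = ET.SubElement(prop, "property-definition")
        ET.SubElement(pd_, "label").text = name
        ET.SubElement(pd_, "type").text = "float"
        ET.SubElement(pd_, "unit").text = unit
    scene = ET.SubElement(rsml, "scene")
    plant = ET.SubElement(scene, "plant", id="1", label=system.species)
    plant.set("day", repr(float(system.day)))

    laterals: dict = {}
    for r in system.roots:
        if r.class_id == "lateral":
            laterals.setdefault(r.parent_root_id, []).append(r)
    for r in system.roots:
        if r.class_id == "lateral":
            continue
        el = _root_element(r)
        for lat in laterals.get(r.root_id, []):
            el.append(_root_element(lat))
        plant.append(el)
    # orphan laterals (e.g. external data): write at plant level
    axial_ids = {r.root_id for r in system.roots if r.class_id != "lateral"}
    for pid, lats in laterals.items():
        if pid not in axial_ids:
            for lat in lats:
                plant.append(_root_element(lat))
    tree = ET.ElementTree(rsml)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def _root_element(r: Root) -> ET.Element:
    el = ET.Element("root", ID=str(r.root_id), label=r.class_id)
    props = ET.SubElement(el, "properties")
    ET.SubElement(props, "accession", value=r.class_id)
    ET.SubElement(props, "diameter", value=repr(2.0 * r.radius))
    ET.SubElement(props, "born_day", value=repr(float(r.born_day)))
    if r.branch_arc is not None:
        ET.SubElement(props, "branch_arc", value=repr(float(r.branch_arc)))
    geom = ET.SubElement(el, "geometry")
    poly = ET.SubElement(geom, "polyline")
    for (x, y, z) in r.points:
        ET.SubElement(poly, "point", x=repr(x), y=repr(y), z=repr(z))
    return el


DEFAULT_DIAMETER = 0.05  # cm, used when an external file omits diameter


def read_rsml(path) -> RootSystem:
    try:
        tree = ET.parse(path)
    except ET.ParseError as e:
        raise RSMLError(f"malformed RSML {path}: {e}") from e
    rsml = tree.getroot()
    plant = rsml.find("./scene/plant")
    if plant is None:
        raise RSMLError(f"{path}: missing scene/plant element")
    species = plant.get("label", "unknown")
    day = float(plant.get("day", "0"))
    roots: list[Root] = []
    for el in plant.findall("root"):
        roots.extend(_parse_root(el, parent=None, path=path))
    if not roots:
        raise RSMLError(f"{path}: no root elements")
    return RootSystem(species, day, roots)


def _parse_root(el: ET.Element, parent: Root | None, path) -> list[Root]:
    poly = el.find("./geometry/polyline")
    if poly is None:
        raise RSMLError(f"{path}: root {el.get('ID')} lacks "
                        "geometry/polyline")
    pts = []
    for p in poly.findall("point"):
        try:
            pts.append((float(p.get("x")), float(p.get("y")),
                        float(p.get("z", "0"))))
        except (TypeError, ValueError) as e:
            raise RSMLError(
                f"{path}: bad point in root {el.get('ID')}") from e
    if len(pts) < 2:
        raise RSMLError(f"{path}: root {el.get('ID')} has <2 points")
    label = el.get("label")
    acc = el.find("./properties/accession")
    class_id = (acc.get("value") if acc is not None else label) or "unknown"
    dia_el = el.find("./properties/diameter")
    if dia_el is not None:
        diameter = float(dia_el.get("value"))
    else:
        diameter = DEFAULT_DIAMETER
        import warnings
        warnings.warn(f"{path}: root {el.get('ID')} has no diameter; "
                      f"defaulting to {DEFAULT_DIAMETER} cm")
    born_el = el.find("./properties/born_day")
    born = float(born_el.get("value")) if born_el is not None else 0.0
    arc_el = el.find("./properties/branch_arc")
    arc = float(arc_el.get("value")) if arc_el is not None else None

    rid = el.get("ID")
    try:
        rid = int(rid)
    except (TypeError, ValueError):
        pass
    import math as _m
    r = Root(root_id=rid, class_id=class_id, radius=diameter / 2.0,
             born_day=born, origin=pts[0], direction=(0.0, 1.0, 0.0),
             growth_rate=0.0, gravitropism=0.0, jitter_sd=0.0,
             parent_class=parent.class_id if parent else None,
             parent_root_id=parent.root_id if parent else None,
             branch_arc=arc)
    r.points = pts
    r.seg_days = [born] * (len(pts) - 1)
    r.length = sum(_m.dist(a, b) for a, b in zip(pts[:-1], pts[1:]))
    out = [r]
    for sub in el.findall("root"):
        out.extend(_parse_root(sub, parent=r, path=path))
    return out


def rsml_roundtrip(system: RootSystem, path=None) -> RootSystem:
    """Write a system to RSML and read it back (round-trip check)."""
    import tempfile
    if path is None:
        with tempfile.NamedTemporaryFile("w", suffix=".rsml",
                                         delete=False) as fh:
            path = fh.name
    write_rsml(system, path)
    return read_rsml(path)
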