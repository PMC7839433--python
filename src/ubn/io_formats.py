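"""Readers and writers: XMLBIF 0.3, the UBN-YAML dialect, CSV case files,
and a seeded random-fixture generator.

XMLBIF carries plain discrete networks only.  UBN-YAML extends the network
description with the uncertainty payloads this package adds: per-row
Dirichlet models (``enhanced:``, fields ``t`` and ``s``), per-row interval
bounds (``credal:``), a caveat ledger (``caveats:``) and the network's
uncertainty-type tag (``type:``).  A node may carry an enhanced or a credal
payload, never both.

Probabilities are serialized as decimal strings with 17 significant digits
so that write -> read round-trips bit-faithfully.

XMLBIF table-entry order: parent configurations iterate in declared parent
order with the last parent varying fastest; within a configuration the
child's states follow their declared order.
"""

from __future__ import annotations

import io
import itertools
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from lxml import etree

from .bn_core import BnModel, Cpt, InputError, NodeSpec, SchemaError, build_network
from .credal import CredalBn, CredalRow
from .param_uncertainty import (
    SENTINEL,
    DirichletRow,
    EnhancedBn,
    EnhancedCpt,
    collapse_to_aleatory,
)

UBN_FORMAT_VERSION = 1


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


# ---------------------------------------------------------------------------
# XMLBIF
# ---------------------------------------------------------------------------


def write_xmlbif(model: BnModel | EnhancedBn, path: str | Path) -> None:
    """Write a plain BN as XMLBIF 0.3.

    An :class:`EnhancedBn` is collapsed to its posterior-mean tables first,
    with a warning — XMLBIF has no slot for parameter uncertainty, so the
    export is lossy and must be explicit.
    """
    if isinstance(model, EnhancedBn):
        warnings.warn(
            "XMLBIF cannot carry Dirichlet payloads; exporting the collapsed "
            "posterior-mean tables (lossy)"
        )
        model = collapse_to_aleatory(model)
    root = etree.Element("BIF", VERSION="0.3")
    net = etree.SubElement(root, "NETWORK")
    etree.SubElement(net, "NAME").text = "ubn-network"
    node_map = model.node_map
    for spec in model.nodes:
        var = etree.SubElement(net, "VARIABLE", TYPE="nature")
        etree.SubElement(var, "NAME").text = spec.name
        for st in spec.states:
            etree.SubElement(var, "OUTCOME").text = st
        if spec.meaning:
            etree.SubElement(var, "PROPERTY").text = f"meaning = {spec.meaning}"
    for spec in model.nodes:
        d = etree.SubElement(net, "DEFINITION")
        etree.SubElement(d, "FOR").text = spec.name
        for p in spec.parents:
            etree.SubElement(d, "GIVEN").text = p
        cpt = model.cpts[spec.name]
        entries: list[str] = []
        configs = (
            itertools.product(*(node_map[p].states for p in spec.parents))
            if spec.parents
            else [()]
        )
        for key in configs:
            entries.extend(_fmt(v) for v in cpt.rows[tuple(key)])
        etree.SubElement(d, "TABLE").text = " ".join(entries)
    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8")


def read_xmlbif(path: str | Path) -> BnModel:
    """Parse an XMLBIF 0.3 document into a validated plain BN."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise SchemaError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    net = root.find("NETWORK")
    if net is None:
        raise SchemaError(f"{path}: no NETWORK element")
    states: dict[str, tuple[str, ...]] = {}
    meanings: dict[str, str] = {}
    order: list[str] = []
    for var in net.findall("VARIABLE"):
        name_el = var.find("NAME")
        if name_el is None or not name_el.text:
            raise SchemaError(f"{path}: VARIABLE without NAME")
        name = name_el.text.strip()
        outcomes = tuple(o.text.strip() for o in var.findall("OUTCOME"))
        states[name] = outcomes
        order.append(name)
        for prop in var.findall("PROPERTY"):
            if prop.text and prop.text.strip().startswith("meaning ="):
                meanings[name] = prop.text.split("=", 1)[1].strip()
    parents: dict[str, tuple[str, ...]] = {}
    tables: dict[str, list[float]] = {}
    for d in net.findall("DEFINITION"):
        for_el = d.find("FOR")
        if for_el is None or not for_el.text:
            raise SchemaError(f"{path}: DEFINITION without FOR")
        name = for_el.text.strip()
        if name not in states:
            raise SchemaError(f"{path}: DEFINITION/FOR names undeclared variable {name!r}")
        given = tuple(g.text.strip() for g in d.findall("GIVEN"))
        for g in given:
            if g not in states:
                raise SchemaError(
                    f"{path}: DEFINITION for {name!r} GIVEN undeclared parent {g!r}"
                )
        table_el = d.find("TABLE")
        if table_el is None or not table_el.text:
            raise SchemaError(f"{path}: DEFINITION for {name!r} lacks TABLE")
        parents[name] = given
        tables[name] = [float(x) for x in table_el.text.split()]
    nodes = []
    cpts = []
    for name in order:
        if name not in parents:
            raise SchemaError(f"{path}: variable {name!r} has no DEFINITION")
        spec = NodeSpec(
            name=name,
            states=states[name],
            parents=parents[name],
            meaning=meanings.get(name, ""),
        )
        nodes.append(spec)
        k = len(states[name])
        configs = (
            list(itertools.product(*(states[p] for p in parents[name])))
            if parents[name]
            else [()]
        )
        flat = tables[name]
        if len(flat) != k * len(configs):
            raise SchemaError(
                f"{path}: TABLE for {name!r} has {len(flat)} entries, "
                f"expected {k * len(configs)}"
            )
        rows = {
            tuple(cfg): tuple(flat[i * k : (i + 1) * k])
            for i, cfg in enumerate(configs)
        }
        cpts.append(Cpt(node=name, rows=rows))
    return build_network(nodes, cpts, bn_type="aleatory",
                         provenance=f"read from XMLBIF {path}")


# ---------------------------------------------------------------------------
# UBN-YAML
# ---------------------------------------------------------------------------


def _row_key_to_yaml(key: tuple[str, ...]) -> list[str]:
    return list(key)


def _serialize_model(model: BnModel) -> dict:
    nodes = []
    for spec in model.nodes:
        cpt = model.cpts[spec.name]
        table = [
            {"parents": _row_key_to_yaml(k), "p": [_fmt(v) for v in row]}
            for k, row in sorted(cpt.rows.items())
        ]
        nodes.append(
            {
                "name": spec.name,
                "states": list(spec.states),
                "parents": list(spec.parents),
                "meaning": spec.meaning,
                "table": table,
            }
        )
    return {
        "ubn": UBN_FORMAT_VERSION,
        "type": model.bn_type,
        "provenance": model.provenance,
        "network": {"nodes": nodes},
    }


def write_ubn(obj: BnModel | EnhancedBn | CredalBn, path: str | Path) -> None:
    """Write a plain, enhanced, or credal network as UBN-YAML."""
    if isinstance(obj, EnhancedBn):
        doc = _serialize_model(obj.base)
        enhanced = {}
        for name, ecpt in obj.enhanced_cpts.items():
            enhanced[name] = [
                {
                    "parents": _row_key_to_yaml(k),
                    "t": [_fmt(v) for v in r.mean],
                    "s": "inf" if r.is_sentinel else _fmt(r.equivalent_sample_size),
                }
                for k, r in sorted(ecpt.rows.items())
            ]
        doc["enhanced"] = enhanced
    elif isinstance(obj, CredalBn):
        nodes = []
        for spec in obj.nodes:
            nodes.append(
                {
                    "name": spec.name,
                    "states": list(spec.states),
                    "parents": list(spec.parents),
                    "meaning": spec.meaning,
                }
            )
        doc = {
            "ubn": UBN_FORMAT_VERSION,
            "credal_flavor": obj.flavor,
            "network": {"nodes": nodes},
            "credal": {
                name: [
                    {
                        "parents": _row_key_to_yaml(k),
                        "lower": [_fmt(v) for v in r.lower],
                        "upper": [_fmt(v) for v in r.upper],
                    }
                    for k, r in sorted(rows.items())
                ]
                for name, rows in obj.credal_cpts.items()
            },
        }
    elif isinstance(obj, BnModel):
        doc = _serialize_model(obj)
    else:
        raise InputError(f"cannot serialize {type(obj).__name__}")
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, default_flow_style=None), encoding="utf-8"
    )


def _parse_nodes(doc: dict, path: str | Path) -> list[NodeSpec]:
    try:
        raw_nodes = doc["network"]["nodes"]
    except (KeyError, TypeError):
        raise SchemaError(f"{path}: missing network.nodes") from None
    specs = []
    for nd in raw_nodes:
        try:
            specs.append(
                NodeSpec(
                    name=str(nd["name"]),
                    states=tuple(str(s) for s in nd["states"]),
                    parents=tuple(str(p) for p in nd.get("parents", [])),
                    meaning=str(nd.get("meaning", "")),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: node entry missing field {exc}") from None
    return specs


def read_ubn(path: str | Path) -> BnModel | EnhancedBn | CredalBn:
    """Parse a UBN-YAML document; the payloads decide the return type."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(doc, dict) or "ubn" not in doc:
        raise SchemaError(f"{path}: not a UBN-YAML document (missing 'ubn' key)")
    has_enhanced = "enhanced" in doc
    has_credal = "credal" in doc
    if has_enhanced and has_credal:
        both = set(doc["enhanced"]) & set(doc["credal"])
        raise SchemaError(
            f"{path}: nodes {sorted(both) or '(document level)'} carry both "
            "enhanced and credal payloads; exactly one payload kind per node"
        )
    specs = _parse_nodes(doc, path)

    if has_credal:
        node_map = {s.name: s for s in specs}
        credal_cpts: dict[str, dict[tuple[str, ...], CredalRow]] = {}
        for name, rows in doc["credal"].items():
            if name not in node_map:
                raise SchemaError(f"{path}: credal payload for undeclared node {name!r}")
            credal_cpts[name] = {}
            for r in rows:
                key = tuple(str(x) for x in r.get("parents", []))
                try:
                    credal_cpts[name][key] = CredalRow(
                        lower=tuple(float(x) for x in r["lower"]),
                        upper=tuple(float(x) for x in r["upper"]),
                    )
                except KeyError as exc:
                    raise SchemaError(
                        f"{path}: credal row {name!r}{key} missing field {exc}"
                    ) from None
        return CredalBn(
            nodes=tuple(specs),
            credal_cpts=credal_cpts,
            flavor=doc.get("credal_flavor", "aleatory_credal"),
        )

    nodes = []
    cpts = []
    for nd, spec in zip(doc["network"]["nodes"], specs):
        if "table" not in nd:
            raise SchemaError(f"{path}: node {spec.name!r} has no table")
        rows = {}
        for r in nd["table"]:
            key = tuple(str(x) for x in r.get("parents", []))
            rows[key] = tuple(float(x) for x in r["p"])
        nodes.append(spec)
        cpts.append(Cpt(node=spec.name, rows=rows))
    model = build_network(
        nodes,
        cpts,
        bn_type=doc.get("type", "aleatory"),
        provenance=str(doc.get("provenance", "")),
    )
    if not has_enhanced:
        return model
    ecpts = {}
    for spec in model.nodes:
        if spec.name not in doc["enhanced"]:
            raise SchemaError(
                f"{path}: enhanced payload missing for node {spec.name!r}"
            )
        rows = {}
        for r in doc["enhanced"][spec.name]:
            key = tuple(str(x) for x in r.get("parents", []))
            if "s" not in r:
                raise SchemaError(
                    f"{path}: enhanced row {spec.name!r}{key} missing required field 's'"
                )
            if "t" not in r:
                raise SchemaError(
                    f"{path}: enhanced row {spec.name!r}{key} missing required field 't'"
                )
            s_raw = r["s"]
            s = SENTINEL if str(s_raw).lower() in ("inf", ".inf", "infinity") else float(s_raw)
            rows[key] = DirichletRow(
                mean=tuple(float(x) for x in r["t"]), equivalent_sample_size=s
            )
        ecpts[spec.name] = EnhancedCpt(node=spec.name, rows=rows)
    return EnhancedBn(base=model, enhanced_cpts=ecpts)


# ---------------------------------------------------------------------------
# Case tables and caveats
# ---------------------------------------------------------------------------


def read_cases(path: str | Path, model: BnModel | None = None) -> pd.DataFrame:
    """Load a complete-case CSV (header = node names, cells = state labels).

    With a model given, every column must be a node and every label a
    declared state — labels are never coerced.
    """
    cases = pd.read_csv(path, dtype=str)
    if cases.isna().any().any():
        raise InputError(f"{path}: case file contains missing values")
    if model is not None:
        for col in cases.columns:
            if col not in model.node_map:
                raise InputError(f"{path}: column {col!r} is not a model node")
            bad = set(cases[col]) - set(model.node(col).states)
            if bad:
                raise InputError(
                    f"{path}: column {col!r} has labels {sorted(bad)} not in the model"
                )
    return cases


def write_cases(cases: pd.DataFrame, path: str | Path) -> None:
    cases.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Fixture generator
# ---------------------------------------------------------------------------


def generate_fixture(
    n_nodes: int,
    max_states: int = 3,
    density: float = 0.4,
    seed: int = 0,
    enhanced_s_range: tuple[float, float] | None = None,
    credal_width: float | None = None,
    n_cases: int = 0,
) -> tuple[BnModel | EnhancedBn | CredalBn, pd.DataFrame | None]:
    """Seeded random network (and optionally forward-sampled cases).

    The DAG comes from edge sampling over a fixed topological order (node i
    may parent node j only for i < j, each edge present with probability
    ``density``); tables are Dirichlet(1, ..., 1) draws.  With
    ``enhanced_s_range`` each row additionally gets an equivalent sample
    size drawn uniformly from the range; with ``credal_width`` the point
    tables are widened into intervals of that half-width (clipped to
    [0, 1]).  Fully reproducible under the seed.
    """
    if n_nodes < 1:
        raise InputError("n_nodes must be >= 1")
    if not 0 <= density <= 1:
        raise InputError("density must be in [0, 1]")
    if enhanced_s_range is not None and credal_width is not None:
        raise InputError("choose at most one of enhanced_s_range / credal_width")
    rng = np.random.default_rng(seed)
    names = [f"N{i}" for i in range(n_nodes)]
    card = rng.integers(2, max_states + 1, size=n_nodes)
    parents: dict[str, tuple[str, ...]] = {}
    for j in range(n_nodes):
        ps = [names[i] for i in range(j) if rng.random() < density]
        parents[names[j]] = tuple(ps)
    specs = [
        NodeSpec(
            name=names[j],
            states=tuple(f"s{k}" for k in range(card[j])),
            parents=parents[names[j]],
        )
        for j in range(n_nodes)
    ]
    node_map = {s.name: s for s in specs}
    cpts = []
    for spec in specs:
        configs = (
            list(itertools.product(*(node_map[p].states for p in spec.parents)))
            if spec.parents
            else [()]
        )
        rows = {
            tuple(cfg): tuple(rng.dirichlet(np.ones(len(spec.states))))
            for cfg in configs
        }
        cpts.append(Cpt(node=spec.name, rows=rows))
    model = build_network(specs, cpts, bn_type="aleatory",
                          provenance=f"seeded fixture (seed={seed})")

    result: BnModel | EnhancedBn | CredalBn = model
    if enhanced_s_range is not None:
        lo, hi = enhanced_s_range
        ecpts = {}
        for spec in specs:
            rows = {
                k: DirichletRow(mean=v, equivalent_sample_size=float(rng.uniform(lo, hi)))
                for k, v in model.cpts[spec.name].rows.items()
            }
            ecpts[spec.name] = EnhancedCpt(node=spec.name, rows=rows)
        result = EnhancedBn(base=model, enhanced_cpts=ecpts)
    elif credal_width is not None:
        credal_cpts = {}
        for spec in specs:
            rows = {}
            for k, v in model.cpts[spec.name].rows.items():
                arr = np.asarray(v)
                rows[k] = CredalRow(
                    lower=tuple(np.clip(arr - credal_width, 0, 1)),
                    upper=tuple(np.clip(arr + credal_width, 0, 1)),
                )
            credal_cpts[spec.name] = rows
        result = CredalBn(nodes=tuple(specs), credal_cpts=credal_cpts)

    cases = forward_sample(model, n_cases, rng) if n_cases else None
    return result, cases


def forward_sample(
    model: BnModel, n: int, rng: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Forward-sample n complete cases (ancestral order) from a plain BN."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(model.node_names())
    for spec in model.nodes:
        for p in spec.parents:
            g.add_edge(p, spec.name)
    topo = list(nx.lexicographical_topological_sort(g))
    data: dict[str, list[str]] = {name: [] for name in model.node_names()}
    for _ in range(n):
        assignment: dict[str, str] = {}
        for name in topo:
            spec = model.node(name)
            key = tuple(assignment[p] for p in spec.parents)
            probs = np.asarray(model.cpts[name].rows[key])
            idx = rng.choice(len(spec.states), p=probs / probs.sum())
            assignment[name] = spec.states[idx]
        for name, st in assignment.items():
            data[name].append(st)
    return pd.DataFrame(data, columns=list(model.node_names()))
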