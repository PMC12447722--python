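"""Reading and writing Boolean networks and analysis results.

Networks are exchanged in the plain-text BoolNet rule format::

    targets, factors
    A, B & !C
    B, A | C
    C, !A

One line per node: the target name, a comma, and a Boolean expression
over node names with ``!`` (not), ``&`` (and), ``|`` (or), parentheses
and the constants ``0``/``1``.  Node indices follow the order of the
target lines; each node's input order follows the first appearance of
names in its expression.  Update mode is always synchronous.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import IO

import numpy as np

from .attractors import AttractorLandscape
from .metrics import StabilityReport
from .network import BooleanNetwork
from .transition import TransitionMatrix

__all__ = [
    "read_bnet",
    "write_bnet",
    "BnetParseError",
    "write_landscape_json",
    "write_matrix_csv",
    "write_matrix_json",
    "write_report_json",
    "write_attractor_table_csv",
]

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_TOKEN_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*|[()!&|]|[01])")


class BnetParseError(ValueError):
    """A rule file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


def _tokenize(expr: str, lineno: int) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip():
                raise BnetParseError(
                    f"unexpected character {expr[pos:].strip()[0]!r} in expression",
                    lineno,
                )
            break
        tokens.append(m.group(1))
        pos = m.end()
    if not tokens:
        raise BnetParseError("empty expression", lineno)
    return tokens


def _compile_rule(
    tokens: list[str], name_to_idx: dict[str, int], lineno: int
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Turn a token list into (input indices, truth table)."""
    inputs: list[str] = []
    py_parts: list[str] = []
    for t in tokens:
        if t == "!":
            py_parts.append(" not ")
        elif t == "&":
            py_parts.append(" and ")
        elif t == "|":
            py_parts.append(" or ")
        elif t in "()01":
            py_parts.append(t)
        else:
            if t not in name_to_idx:
                raise BnetParseError(f"unknown node name {t!r}", lineno)
            if t not in inputs:
                inputs.append(t)
            py_parts.append(t)
    try:
        code = compile("".join(py_parts).strip(), "<bnet>", "eval")
    except SyntaxError as exc:
        raise BnetParseError(f"syntax error in expression: {exc.msg}", lineno)
    table = []
    for combo in range(1 << len(inputs)):
        env = {nm: bool((combo >> j) & 1) for j, nm in enumerate(inputs)}
        try:
            value = eval(code, {"__builtins__": {}}, env)  # tokens pre-validated
        except Exception as exc:
            raise BnetParseError(f"cannot evaluate expression: {exc}", lineno)
        table.append(1 if value else 0)
    return tuple(name_to_idx[nm] for nm in inputs), tuple(table)


def read_bnet(path: str | Path | IO[str]) -> BooleanNetwork:
    """Parse a BoolNet rule file into a :class:`BooleanNetwork`.

    Node order follows the order of target lines; names are kept in
    ``meta['names']`` and reused by :func:`write_bnet`.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
        source = getattr(path, "name", "<stream>")
    else:
        lines = Path(path).read_text().splitlines()
        source = str(path)

    rules: list[tuple[str, str, int]] = []
    header_seen = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            if re.fullmatch(r"targets\s*,\s*factors", line, re.IGNORECASE):
                header_seen = True
                continue
            raise BnetParseError("expected header 'targets, factors'", lineno)
        if "," not in line:
            raise BnetParseError("expected 'target, expression'", lineno)
        target, expr = line.split(",", 1)
        target = target.strip()
        if not _NAME_RE.fullmatch(target):
            raise BnetParseError(f"invalid target name {target!r}", lineno)
        rules.append((target, expr.strip(), lineno))
    if not header_seen:
        raise BnetParseError("missing header 'targets, factors'")
    if not rules:
        raise BnetParseError("no rules found")

    name_to_idx: dict[str, int] = {}
    for target, _, lineno in rules:
        if target in name_to_idx:
            raise BnetParseError(f"duplicate target {target!r}", lineno)
        name_to_idx[target] = len(name_to_idx)

    inputs, tables = [], []
    for target, expr, lineno in rules:
        inp, tab = _compile_rule(_tokenize(expr, lineno), name_to_idx, lineno)
        inputs.append(inp)
        tables.append(tab)

    names = [t for t, _, _ in rules]
    return BooleanNetwork(
        n_nodes=len(rules),
        inputs=tuple(inputs),
        tables=tuple(tables),
        meta={"names": names, "source": source},
    )


def _dnf(name_of: list[str], inputs: tuple[int, ...], table: tuple[int, ...]) -> str:
    """Full disjunctive normal form of one node's truth table."""
    if all(v == 0 for v in table):
        return "0"
    if all(v == 1 for v in table):
        return "1"
    terms = []
    for combo, v in enumerate(table):
        if not v:
            continue
        lits = [
            (name_of[src] if (combo >> j) & 1 else "!" + name_of[src])
            for j, src in enumerate(inputs)
        ]
        terms.append("(" + " & ".join(lits) + ")" if len(lits) > 1 else lits[0])
    return " | ".join(terms)


def write_bnet(net: BooleanNetwork, path: str | Path | IO[str]) -> None:
    """Write a network as BoolNet rules (full DNF per node).

    Reading the file back yields a network with an identical update map.
    """
    names = net.meta.get("names") or [f"x{i}" for i in range(net.n_nodes)]
    lines = ["targets, factors"]
    for i in range(net.n_nodes):
        lines.append(f"{names[i]}, {_dnf(names, net.inputs[i], net.tables[i])}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def _round12(x):
    """Serialise floats with 12 significant digits."""
    if isinstance(x, float):
        return float(f"{x:.12g}")
    if isinstance(x, dict):
        return {k: _round12(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round12(v) for v in x]
    if isinstance(x, (np.floating,)):
        return float(f"{float(x):.12g}")
    if isinstance(x, (np.integer,)):
        return int(x)
    return x


def _dump_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_round12(obj), indent=2) + "\n")


def write_landscape_json(landscape: AttractorLandscape, path: str | Path) -> None:
    _dump_json(landscape.to_dict(), path)


def write_matrix_json(matrix: TransitionMatrix, path: str | Path) -> None:
    _dump_json(matrix.to_dict(), path)


def write_matrix_csv(matrix: TransitionMatrix, path: str | Path) -> None:
    """Dense CSV with attractor-index headers."""
    labels = [f"att{i}" for i in range(matrix.n_att)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["from\\to"] + labels)
        for i, row in enumerate(matrix.m):
            w.writerow([labels[i]] + [f"{x:.12g}" for x in row])


def write_report_json(report: StabilityReport, path: str | Path) -> None:
    _dump_json(report.to_dict(), path)


def write_attractor_table_csv(
    landscape: AttractorLandscape,
    matrix: TransitionMatrix,
    report: StabilityReport,
    path: str | Path,
) -> None:
    """Per-attractor summary: length, basin size, self-return, occupancy, similarity."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["attractor", "length", "basin_size", "self_return", "stationary",
             "similarity_exact"]
        )
        for i, a in enumerate(landscape.attractors):
            w.writerow(
                [
                    i,
                    a.length,
                    f"{landscape.basin_sizes[i]:.12g}",
                    f"{matrix.m[i, i]:.12g}",
                    f"{report.stationary[i]:.12g}",
                    f"{report.similarity_exact_per[i]:.12g}",
                ]
            )
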