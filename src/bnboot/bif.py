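"""Reader/writer for a BIF-subset network file format.

The dialect covers the blocks needed to exchange discrete Bayesian networks:

.. code-block:: text

    network example { }
    variable A {
      type discrete [ 2 ] { yes, no };
    }
    probability ( A ) {
      table 0.3, 0.7;
    }
    probability ( B | A ) {
      (yes) 0.2, 0.8;
      (no)  0.5, 0.5;
    }

Whitespace is free-form and ``//`` comments run to end of line.  Rows of a
conditional block list P(child = level | configuration) in the child's level
order; every parent configuration must appear exactly once.
"""

from __future__ import annotations

import itertools
import os
import re

import numpy as np

from .bn_model import CPT, CategoricalVariable, DiscreteBayesianNetwork, validate_network

__all__ = [
    "read_network",
    "write_network",
    "BifError",
    "BifParseError",
    "BifUndeclaredVariableError",
    "BifArityError",
]


class BifError(ValueError):
    """Base class for network-file errors; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class BifParseError(BifError):
    """Malformed syntax."""


class BifUndeclaredVariableError(BifError):
    """A probability block references a variable with no declaration."""


class BifArityError(BifError):
    """A CPT's configurations or row lengths do not match the declared levels."""


_TOKEN_RE = re.compile(r"//[^\n]*|[A-Za-z0-9_.+\-]+|[{}()\[\];,|]|\S")


def _tokenize(text: str) -> list[tuple[str, int]]:
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for m in _TOKEN_RE.finditer(line):
            tok = m.group(0)
            if tok.startswith("//"):
                break
            out.append((tok, lineno))
    return out


class _Cursor:
    def __init__(self, tokens: list[tuple[str, int]]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    @property
    def line(self) -> int:
        if self.i < len(self.tokens):
            return self.tokens[self.i][1]
        return self.tokens[-1][1] if self.tokens else 0

    def next(self, what: str = "token") -> str:
        if self.i >= len(self.tokens):
            raise BifParseError(f"unexpected end of file, expected {what}",
                                self.tokens[-1][1] if self.tokens else 0)
        tok, _ = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, literal: str) -> None:
        line = self.line
        tok = self.next(repr(literal))
        if tok != literal:
            raise BifParseError(f"expected {literal!r}, found {tok!r}", line)


def _parse_values(cur: _Cursor, terminator: str) -> list[str]:
    """Comma-separated identifiers up to (and consuming) the terminator."""
    vals: list[str] = []
    while True:
        tok = cur.next("value")
        if tok == terminator:
            break
        if tok == ",":
            continue
        vals.append(tok)
    return vals


def read_network(path: str | os.PathLike) -> DiscreteBayesianNetwork:
    """Parse a BIF-subset file into a validated network."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    tokens = _tokenize(text)
    if not tokens:
        raise BifParseError("empty file: no network definition", 1)
    cur = _Cursor(tokens)

    variables: list[CategoricalVariable] = []
    by_name: dict[str, CategoricalVariable] = {}
    cpts: dict[str, CPT] = {}

    while cur.peek() is not None:
        line = cur.line
        kw = cur.next("block keyword")
        if kw == "network":
            cur.next("network name")
            cur.expect("{")
            depth = 1
            while depth:
                tok = cur.next("'}'")
                depth += {"{": 1, "}": -1}.get(tok, 0)
        elif kw == "variable":
            name = cur.next("variable name")
            if name in by_name:
                raise BifParseError(f"duplicate variable {name!r}", line)
            cur.expect("{")
            cur.expect("type")
            cur.expect("discrete")
            cur.expect("[")
            k_line = cur.line
            k_tok = cur.next("level count")
            try:
                k = int(k_tok)
            except ValueError:
                raise BifParseError(f"level count must be an integer, got {k_tok!r}", k_line)
            cur.expect("]")
            cur.expect("{")
            levels = _parse_values(cur, "}")
            cur.expect(";")
            cur.expect("}")
            if len(levels) != k:
                raise BifArityError(
                    f"variable {name!r} declares {k} levels but lists {len(levels)}", line)
            var = CategoricalVariable(name, tuple(levels))
            variables.append(var)
            by_name[name] = var
        elif kw == "probability":
            cur.expect("(")
            child = cur.next("child variable")
            if child not in by_name:
                raise BifUndeclaredVariableError(f"undeclared variable {child!r}", line)
            parents: list[str] = []
            tok = cur.next("')' or '|'")
            if tok == "|":
                parents = _parse_values(cur, ")")
            elif tok != ")":
                raise BifParseError(f"expected '|' or ')', found {tok!r}", line)
            for p in parents:
                if p not in by_name:
                    raise BifUndeclaredVariableError(
                        f"undeclared parent {p!r} of {child!r}", line)
            cpts[child] = _parse_probability_body(cur, by_name[child],
                                                  [by_name[p] for p in parents])
        else:
            raise BifParseError(f"unexpected token {kw!r}", line)

    if not variables:
        raise BifParseError("file declares no variables", 1)
    net = DiscreteBayesianNetwork(variables=variables, cpts=cpts)
    problems = validate_network(net)
    if problems:
        raise BifArityError("; ".join(problems))
    return net


def _parse_probability_body(
    cur: _Cursor, child: CategoricalVariable, parents: list[CategoricalVariable]
) -> CPT:
    r = child.cardinality
    dims = [p.cardinality for p in parents]
    q = int(np.prod(dims, dtype=np.int64)) if parents else 1
    table = np.full((q, r), np.nan)
    cur.expect("{")
    start_line = cur.line
    while cur.peek() != "}":
        line = cur.line
        tok = cur.next("'table', '(' or '}'")
        if tok == "table":
            if parents:
                raise BifArityError(
                    f"'table' row in conditional block for {child.name!r}", line)
            row = _parse_values(cur, ";")
            _fill_row(table, 0, row, child, line)
        elif tok == "(":
            if not parents:
                raise BifArityError(
                    f"parenthesised configuration for parentless {child.name!r}", line)
            cfg = _parse_values(cur, ")")
            if len(cfg) != len(parents):
                raise BifArityError(
                    f"configuration {tuple(cfg)} has {len(cfg)} values for "
                    f"{len(parents)} parents of {child.name!r}", line)
            idx = []
            for val, p in zip(cfg, parents):
                if val not in p.levels:
                    raise BifArityError(
                        f"{val!r} is not a level of parent {p.name!r}", line)
                idx.append(p.levels.index(val))
            j = int(np.ravel_multi_index(tuple(idx), dims))
            if not np.isnan(table[j]).all():
                raise BifArityError(
                    f"duplicate configuration {tuple(cfg)} for {child.name!r}", line)
            row = _parse_values(cur, ";")
            _fill_row(table, j, row, child, line)
        else:
            raise BifParseError(f"expected 'table' or '(', found {tok!r}", line)
    cur.expect("}")
    if np.isnan(table).any():
        raise BifArityError(
            f"probability block for {child.name!r} is missing configurations",
            start_line)
    return CPT(parents=tuple(p.name for p in parents), table=table)


def _fill_row(table, j, row, child, line):
    if len(row) != child.cardinality:
        raise BifArityError(
            f"row for {child.name!r} lists {len(row)} probabilities, "
            f"expected {child.cardinality}", line)
    try:
        table[j] = [float(x) for x in row]
    except ValueError:
        raise BifParseError(f"non-numeric probability in row for {child.name!r}", line)


def write_network(net: DiscreteBayesianNetwork, path: str | os.PathLike,
                  name: str = "unknown") -> None:
    """Serialise a network; ``read_network`` recovers it up to 1e-9 round-off."""
    problems = validate_network(net)
    if problems:
        raise ValueError("refusing to write invalid network: " + "; ".join(problems))
    lines = [f"network {name} {{", "}"]
    for v in net.variables:
        lines.append(f"variable {v.name} {{")
        lines.append(f"  type discrete [ {v.cardinality} ] "
                     f"{{ {', '.join(v.levels)} }};")
        lines.append("}")
    by_name = {v.name: v for v in net.variables}
    for v in net.variables:
        cpt = net.cpts[v.name]
        if not cpt.parents:
            lines.append(f"probability ( {v.name} ) {{")
            lines.append("  table " + ", ".join(f"{p:.12g}" for p in cpt.table[0]) + ";")
        else:
            lines.append(f"probability ( {v.name} | {', '.join(cpt.parents)} ) {{")
            dims = [by_name[p].cardinality for p in cpt.parents]
            for j, combo in enumerate(itertools.product(*(range(d) for d in dims))):
                labels = ", ".join(by_name[p].levels[i]
                                   for p, i in zip(cpt.parents, combo))
                row = ", ".join(f"{p:.12g}" for p in cpt.table[j])
                lines.append(f"  ({labels}) {row};")
        lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
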