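"""Minimal s-expression reader/writer shared by the CLIF module and the rule
engine's rule files.

Supported syntax: parenthesised lists, bare symbols, double-quoted strings
with backslash escapes, and ``;`` line comments.  A parsed tree is nested
Python lists of strings; quoted strings are represented as ``QuotedString``
so rendering round-trips.
"""

from __future__ import annotations

from .errors import ParseError


class QuotedString(str):
    """A string that was written with double quotes in the source."""


Node = "Union[str, QuotedString, list]"


def tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c in " \t\r\n":
            i += 1
        elif c == ";":
            while i < n and text[i] != "\n":
                i += 1
        elif c in "()":
            tokens.append((c, i))
            i += 1
        elif c == '"':
            start = i
            i += 1
            buf = []
            while i < n and text[i] != '"':
                if text[i] == "\\" and i + 1 < n:
                    i += 1
                buf.append(text[i])
                i += 1
            if i >= n:
                raise ParseError("unterminated string", pos=start)
            tokens.append(('"' + "".join(buf), start))
            i += 1
        else:
            start = i
            while i < n and text[i] not in ' \t\r\n();"':
                i += 1
            tokens.append((text[start:i], start))
    return tokens


def parse(text: str) -> list:
    """Parse all top-level s-expressions in ``text``."""
    tokens = tokenize(text)
    pos = 0

    def read() -> object:
        nonlocal pos
        if pos >= len(tokens):
            raise ParseError("unexpected end of input", pos=len(text))
        tok, at = tokens[pos]
        pos += 1
        if tok == "(":
            items = []
            while True:
                if pos >= len(tokens):
                    raise ParseError("unbalanced parenthesis", pos=at)
                if tokens[pos][0] == ")":
                    pos += 1
                    return items
                items.append(read())
        if tok == ")":
            raise ParseError("unexpected ')'", pos=at)
        if tok.startswith('"'):
            return QuotedString(tok[1:])
        return tok

    out = []
    while pos < len(tokens):
        out.append(read())
    return out


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def render(node: object) -> str:
    """Single-line rendering of one node."""
    if isinstance(node, QuotedString):
        return f'"{_escape(node)}"'
    if isinstance(node, str):
        return node
    return "(" + " ".join(render(x) for x in node) + ")"
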