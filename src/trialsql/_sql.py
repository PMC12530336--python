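"""Minimal SQL lexer and structural checks used by the schema validator and auditor.

This is deliberately not a full SQL grammar: the toolkit only needs to
(1) decide whether candidate text is structurally plausible SQL,
(2) locate table/column identifiers, and
(3) locate literals compared against concept-ID columns — including the
placeholder tokens (``?``, ``:name``, ``<ANGLE>``, ``{curly}``) that broken
generators emit, which real SQL parsers reject outright.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import SqlParseError

# Token kinds
IDENT = "ident"
QIDENT = "qident"  # quoted identifier, unquoted text kept in .value
NUMBER = "number"
STRING = "string"  # single-quoted, verbatim including quotes
PLACEHOLDER = "placeholder"
PUNCT = "punct"

KEYWORDS = frozenset(
    """select from where and or not in on join inner left right outer full cross
    as distinct group by order having limit offset union intersect except all
    between like is null case when then else end exists with asc desc cast
    values insert into update set delete using""".split()
)

FUNCTIONS = frozenset("count sum avg min max abs coalesce date strftime lower upper".split())

_ANGLE_PLACEHOLDER = re.compile(r"<[A-Za-z_][\w ]*>")
_CURLY_PLACEHOLDER = re.compile(r"\{[\w ]*\}")
_NAMED_PARAM = re.compile(r":[A-Za-z_]\w*")
_NUMBER = re.compile(r"\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")
_WORD = re.compile(r"[A-Za-z_][\w$]*")
_MULTI_PUNCT = ("<>", "<=", ">=", "!=", "==", "||")


@dataclass(frozen=True)
class Token:
    kind: str
    text: str  # verbatim source slice
    pos: int  # character offset in the input

    @property
    def value(self) -> str:
        """Identifier value with quoting stripped, lowercased for idents."""
        if self.kind == QIDENT:
            return self.text[1:-1]
        if self.kind == IDENT:
            return self.text.lower()
        return self.text


def tokenize(sql: str) -> list[Token]:
    """Lex *sql* into tokens with character offsets.

    Raises :class:`SqlParseError` on unterminated strings/comments.
    """
    tokens: list[Token] = []
    i, n = 0, len(sql)
    while i < n:
        ch = sql[i]
        if ch.isspace():
            i += 1
            continue
        if sql.startswith("--", i):
            j = sql.find("\n", i)
            i = n if j < 0 else j + 1
            continue
        if sql.startswith("/*", i):
            j = sql.find("*/", i + 2)
            if j < 0:
                raise SqlParseError(f"unterminated block comment at offset {i}")
            i = j + 2
            continue
        if ch == "'":
            j = i + 1
            while j < n:
                if sql[j] == "'":
                    if j + 1 < n and sql[j + 1] == "'":
                        j += 2
                        continue
                    break
                j += 1
            else:
                raise SqlParseError(f"unterminated string literal at offset {i}")
            if j >= n:
                raise SqlParseError(f"unterminated string literal at offset {i}")
            tokens.append(Token(STRING, sql[i : j + 1], i))
            i = j + 1
            continue
        if ch in '"`':
            j = sql.find(ch, i + 1)
            if j < 0:
                raise SqlParseError(f"unterminated quoted identifier at offset {i}")
            tokens.append(Token(QIDENT, sql[i : j + 1], i))
            i = j + 1
            continue
        if ch == "?":
            tokens.append(Token(PLACEHOLDER, "?", i))
            i += 1
            continue
        if ch == ":":
            m = _NAMED_PARAM.match(sql, i)
            if m:
                tokens.append(Token(PLACEHOLDER, m.group(), i))
                i = m.end()
                continue
            tokens.append(Token(PUNCT, ch, i))
            i += 1
            continue
        if ch == "<":
            m = _ANGLE_PLACEHOLDER.match(sql, i)
            if m:
                tokens.append(Token(PLACEHOLDER, m.group(), i))
                i = m.end()
                continue
        if ch == "{":
            m = _CURLY_PLACEHOLDER.match(sql, i)
            if m:
                tokens.append(Token(PLACEHOLDER, m.group(), i))
                i = m.end()
                continue
            raise SqlParseError(f"stray '{{' at offset {i}")
        if ch.isdigit():
            m = _NUMBER.match(sql, i)
            tokens.append(Token(NUMBER, m.group(), i))
            i = m.end()
            continue
        if ch.isalpha() or ch == "_":
            m = _WORD.match(sql, i)
            tokens.append(Token(IDENT, m.group(), i))
            i = m.end()
            continue
        two = sql[i : i + 2]
        if two in _MULTI_PUNCT:
            tokens.append(Token(PUNCT, two, i))
            i += 2
            continue
        if ch in "(),.;=<>!+-*/%":
            tokens.append(Token(PUNCT, ch, i))
            i += 1
            continue
        raise SqlParseError(f"unexpected character {ch!r} at offset {i}")
    return tokens


def parse_check(sql: str) -> tuple[bool, str]:
    """Structural plausibility check.

    Returns ``(ok, reason)``. This is a lexical/shape check, not a grammar:
    it verifies lexability, a SELECT/WITH head, balanced parentheses and
    FROM/JOIN targets. Sufficient to separate "generated SQL" from prose
    or truncated output, which is the distinction the evaluation needs.
    """
    if not sql or not sql.strip():
        return False, "empty input"
    try:
        tokens = tokenize(sql)
    except SqlParseError as exc:
        return False, str(exc)
    if not tokens:
        return False, "no tokens"
    head = tokens[0]
    if head.kind != IDENT or head.value not in ("select", "with"):
        return False, "statement does not start with SELECT or WITH"
    depth = 0
    for idx, tok in enumerate(tokens):
        if tok.kind == PUNCT and tok.text == "(":
            depth += 1
        elif tok.kind == PUNCT and tok.text == ")":
            depth -= 1
            if depth < 0:
                return False, "unbalanced parentheses"
        if tok.kind == IDENT and tok.value in ("from", "join"):
            nxt = tokens[idx + 1] if idx + 1 < len(tokens) else None
            if nxt is None or not (nxt.kind in (IDENT, QIDENT) or nxt.text == "("):
                return False, "FROM/JOIN not followed by a table or subquery"
        if tok.kind == PUNCT and tok.text == "," and idx + 1 < len(tokens):
            if tokens[idx + 1].text == ",":
                return False, "empty select-list element"
    if depth != 0:
        return False, "unbalanced parentheses"
    last = tokens[-1]
    if last.text == ";":
        last = tokens[-2] if len(tokens) > 1 else last
    if last.kind == IDENT and last.value in ("from", "where", "and", "or", "select", "in", "join", "on"):
        return False, "statement ends mid-clause"
    if last.kind == PUNCT and last.text in (",", "=", "(", "<", ">", "<=", ">=", "<>", "!="):
        return False, "statement ends mid-expression"
    return True, "ok"


def table_references(tokens: list[Token]) -> tuple[list[Token], dict[str, str]]:
    """Return FROM/JOIN table tokens and an alias→table map.

    Subqueries (``FROM (``) contribute no table token; their aliases are
    recorded as unresolvable and skipped by callers.
    """
    tables: list[Token] = []
    aliases: dict[str, str] = {}
    for idx, tok in enumerate(tokens):
        if tok.kind == IDENT and tok.value in ("from", "join"):
            if idx + 1 >= len(tokens):
                continue
            nxt = tokens[idx + 1]
            if nxt.kind in (IDENT, QIDENT) and nxt.value not in KEYWORDS:
                tables.append(nxt)
                # optional alias: "t AS a" or "t a"
                j = idx + 2
                if j < len(tokens) and tokens[j].kind == IDENT and tokens[j].value == "as":
                    j += 1
                if j < len(tokens) and tokens[j].kind in (IDENT, QIDENT) and tokens[j].value not in KEYWORDS:
                    # avoid swallowing the next clause keyword / punctuation
                    aliases[tokens[j].value.lower()] = nxt.value.lower()
    return tables, aliases
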