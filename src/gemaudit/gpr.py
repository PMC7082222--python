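"""Gene–protein–reaction (GPR) boolean expressions.

Grammar (keywords case-insensitive)::

    expr   := term (OR term)*
    term   := factor (AND factor)*
    factor := gene | "(" expr ")"

The AST is a nested tuple: ``("gene", id)``, ``("and", [...])`` or
``("or", [...])``.  A malformed rule raises :class:`GPRError`; callers in
the test battery record that as a failed basic test rather than aborting.
"""

from __future__ import annotations

import re
from typing import FrozenSet, List, Tuple

__all__ = ["GPRError", "parse_gpr", "eval_gpr", "gpr_genes"]

_TOKEN = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.\-]+)")


class GPRError(ValueError):
    pass


def _tokenize(text: str) -> List[str]:
    tokens, pos = [], 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None:
            if text[pos:].strip() == "":
                break
            raise GPRError(f"unexpected character {text[pos]!r} in GPR rule")
        tokens.append(match.group(1))
        pos = match.end()
    return tokens


class _Parser:
    def __init__(self, tokens: List[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expr(self):
        terms = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def term(self):
        factors = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else ("and", factors)

    def factor(self):
        tok = self.next()
        if tok is None:
            raise GPRError("unexpected end of GPR rule")
        if tok == "(":
            inner = self.expr()
            if self.next() != ")":
                raise GPRError("unbalanced parenthesis in GPR rule")
            return inner
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRError(f"unexpected token {tok!r} in GPR rule")
        return ("gene", tok)


def parse_gpr(text: str) -> Tuple:
    """Parse a GPR rule into an AST; raise :class:`GPRError` if malformed."""
    tokens = _tokenize(text)
    if not tokens:
        raise GPRError("empty GPR rule")
    parser = _Parser(tokens)
    tree = parser.expr()
    if parser.peek() is not None:
        raise GPRError(f"trailing token {parser.peek()!r} in GPR rule")
    return tree


def eval_gpr(tree: Tuple, knocked_out: FrozenSet[str] | set) -> bool:
    """Evaluate the rule with the given genes switched off."""
    kind = tree[0]
    if kind == "gene":
        return tree[1] not in knocked_out
    if kind == "and":
        return all(eval_gpr(t, knocked_out) for t in tree[1])
    if kind == "or":
        return any(eval_gpr(t, knocked_out) for t in tree[1])
    raise GPRError(f"invalid AST node {kind!r}")


def gpr_genes(tree: Tuple) -> set:
    if tree[0] == "gene":
        return {tree[1]}
    genes = set()
    for sub in tree[1]:
        genes |= gpr_genes(sub)
    return genes
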