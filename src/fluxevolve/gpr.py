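"""Transcript–reaction association trees (GPR-style boolean expressions).

The association grammar is transcript ids combined with ``AND`` / ``OR`` and
parentheses.  Evaluation against an expression profile follows the standard
capacity reading: an ``OR`` of isoenzymes sums their expression, an ``AND`` of
complex subunits takes the minimum.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping

logger = logging.getLogger(__name__)

__all__ = ["Association", "AssociationParseError", "parse_association", "evaluate_association"]


class AssociationParseError(ValueError):
    pass


class Association:
    """A node in an AND/OR tree.  ``op`` is 'leaf', 'and' or 'or'."""

    __slots__ = ("op", "transcript", "children")

    def __init__(self, op: str, transcript: str | None = None, children=None) -> None:
        self.op = op
        self.transcript = transcript
        self.children: list[Association] = children or []

    @classmethod
    def leaf(cls, transcript: str) -> "Association":
        return cls("leaf", transcript=transcript)

    def transcripts(self) -> set[str]:
        if self.op == "leaf":
            return {self.transcript}
        out: set[str] = set()
        for child in self.children:
            out |= child.transcripts()
        return out

    def __str__(self) -> str:
        if self.op == "leaf":
            return self.transcript
        joiner = f" {self.op.upper()} "
        parts = []
        for child in self.children:
            text = str(child)
            if child.op != "leaf" and child.op != self.op:
                text = f"({text})"
            parts.append(text)
        return joiner.join(parts)

    def __repr__(self) -> str:
        return f"Association({str(self)!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, Association) and str(self) == str(other)

    def __hash__(self) -> int:
        return hash(str(self))


_TOKEN_RE = re.compile(r"\(|\)|\bAND\b|\bOR\b|[^\s()]+", re.IGNORECASE)


def parse_association(text: str) -> Association:
    """Parse ``tA AND (tB OR tC)`` into a tree.  OR binds looser than AND."""
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        raise AssociationParseError(f"empty association: {text!r}")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> Association:
        node = parse_and()
        children = [node]
        while peek() is not None and peek().upper() == "OR":
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else Association("or", children=children)

    def parse_and() -> Association:
        node = parse_atom()
        children = [node]
        while peek() is not None and peek().upper() == "AND":
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else Association("and", children=children)

    def parse_atom() -> Association:
        tok = peek()
        if tok is None:
            raise AssociationParseError(f"unexpected end of association: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise AssociationParseError(f"unbalanced parentheses in {text!r}")
            take()
            return node
        if tok == ")" or tok.upper() in ("AND", "OR"):
            raise AssociationParseError(f"unexpected token {tok!r} in {text!r}")
        return Association.leaf(take())

    tree = parse_or()
    if pos != len(tokens):
        raise AssociationParseError(f"trailing tokens in association {text!r}")
    return tree


def evaluate_association(tree: Association, tpm: Mapping[str, float]) -> float:
    """Reaction-level expression: OR -> sum of children, AND -> min of children.

    A transcript absent from the profile contributes 0 (with a warning); this
    is the conservative choice matching the switch-off behaviour for
    unobserved transcripts.
    """
    if tree.op == "leaf":
        try:
            return float(tpm[tree.transcript])
        except KeyError:
            logger.warning("transcript %s absent from profile; treating TPM as 0", tree.transcript)
            return 0.0
    values = [evaluate_association(child, tpm) for child in tree.children]
    return sum(values) if tree.op == "or" else min(values)
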