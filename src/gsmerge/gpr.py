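"""Boolean gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers: AND nodes encode enzyme
complexes (all subunits required), OR nodes encode isozymes (alternatives).
An empty tree means the reaction is spontaneous or its genetics are unknown,
and it evaluates to True under every knockout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass(frozen=True)
class GprTree:
    """Immutable GPR expression tree.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"`` or ``"empty"``; leaves
    carry the gene id in ``gene``.
    """

    op: str = "empty"
    gene: str | None = None
    children: tuple["GprTree", ...] = field(default_factory=tuple)

    # -- constructors --------------------------------------------------------

    @staticmethod
    def empty() -> "GprTree":
        return GprTree()

    @staticmethod
    def leaf(gene: str) -> "GprTree":
        if not gene:
            raise ValueError("empty gene id in GPR leaf")
        return GprTree(op="gene", gene=gene)

    @staticmethod
    def all_of(parts: list["GprTree"]) -> "GprTree":
        return GprTree._nary("and", parts)

    @staticmethod
    def any_of(parts: list["GprTree"]) -> "GprTree":
        return GprTree._nary("or", parts)

    @staticmethod
    def _nary(op: str, parts: list["GprTree"]) -> "GprTree":
        parts = [p for p in parts if not p.is_empty()]
        if not parts:
            return GprTree.empty()
        if len(parts) == 1:
            return parts[0]
        flat: list[GprTree] = []
        for p in parts:
            flat.extend(p.children if p.op == op else (p,))
        return GprTree(op=op, children=tuple(flat))

    # -- queries -------------------------------------------------------------

    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> set[str]:
        if self.op == "empty":
            return set()
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, present: set[str] | frozenset[str]) -> bool:
        """Truth value under a gene-presence assignment.

        Empty rules evaluate True: a spontaneous reaction is never knocked
        out.
        """
        if self.op == "empty":
            return True
        if self.op == "gene":
            return self.gene in present
        if self.op == "and":
            return all(c.evaluate(present) for c in self.children)
        return any(c.evaluate(present) for c in self.children)

    def canonical_string(self) -> str:
        """Deterministic rendering; sorted operands, explicit parentheses."""
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = " and " if self.op == "and" else " or "
        parts = sorted(
            c.canonical_string() if c.op == "gene"
            else "(" + c.canonical_string() + ")"
            for c in self.children
        )
        return sep.join(parts)

    def copy(self) -> "GprTree":
        return self  # immutable

    def __bool__(self) -> bool:
        return not self.is_empty()


# ---------------------------------------------------------------------------
# Parsing ("gene1 and (gene2 or gene3)"; '&'/'|' accepted as synonyms)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(\(|\)|&&?|\|\|?|\band\b|\bor\b|\bAND\b|\bOR\b|[^\s()&|]+)")


def parse_gpr(text: str) -> GprTree:
    """Parse a GPR rule string into a tree.

    Accepts ``and``/``or`` (case-insensitive) and ``&``/``|`` operators and
    arbitrary parenthesisation.  OR binds looser than AND.
    """
    if text is None or not text.strip():
        return GprTree.empty()
    tokens = _TOKEN.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprTree:
        parts = [parse_and()]
        while peek() is not None and peek().lower() in ("or", "|", "||"):
            take()
            parts.append(parse_and())
        return GprTree.any_of(parts)

    def parse_and() -> GprTree:
        parts = [parse_atom()]
        while peek() is not None and peek().lower() in ("and", "&", "&&"):
            take()
            parts.append(parse_atom())
        return GprTree.all_of(parts)

    def parse_atom() -> GprTree:
        tok = peek()
        if tok is None:
            raise ValueError(f"truncated GPR rule: {text!r}")
        if tok == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return inner
        if tok == ")":
            raise ValueError(f"unexpected ')' in GPR: {text!r}")
        return GprTree.leaf(take())

    tree = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR: {text!r}")
    return tree
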