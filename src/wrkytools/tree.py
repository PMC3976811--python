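"""A minimal rooted-representation phylogenetic tree with Newick I/O.

Unrooted trees are stored with a trifurcating root, the convention NJ
produces.  Branch lengths are optional; internal node ``name`` doubles as
the bootstrap-support label (written after the closing parenthesis, the
usual Newick convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class TreeNode:
    name: Optional[str] = None
    length: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    # -- traversal ---------------------------------------------------------
    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    # -- analysis ----------------------------------------------------------
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalised to its smaller side.

        A split is represented by the leaf set under an internal edge; the
        side not containing the alphabetically first leaf is used so the
        representation is rooting-independent.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            below = frozenset(node.leaf_names())
            side = all_leaves - below if anchor in below else below
            if len(side) >= 2 and len(all_leaves) - len(side) >= 2:
                splits.add(side)
        return splits

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.walk() if n is not self)

    def find(self, name: str) -> Optional["TreeNode"]:
        for node in self.walk():
            if node.name == name:
                return node
        return None

    # -- serialisation -----------------------------------------------------
    def to_newick(self) -> str:
        return _write_node(self) + ";"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_newick()


def _fmt_length(x: float) -> str:
    return f"{x:.6g}"


def _write_node(node: TreeNode) -> str:
    if node.is_leaf:
        out = node.name or ""
    else:
        out = "(" + ",".join(_write_node(c) for c in node.children) + ")"
        if node.name:
            out += node.name
    if node.length is not None:
        out += f":{_fmt_length(node.length)}"
    return out


class NewickError(ValueError):
    pass


def parse_newick(text: str) -> TreeNode:
    """Parse one Newick tree; raises :class:`NewickError` with the offending
    position on malformed input."""
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(f"{msg} at position {pos}")

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(text):
                    raise error("unbalanced parentheses: unexpected end")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise error(f"unexpected character {text[pos]!r}")
        # label (leaf name or internal support label)
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        label = text[start:pos]
        if label:
            node.name = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            try:
                node.length = float(text[start:pos])
            except ValueError:
                raise error(f"bad branch length {text[start:pos]!r}")
        return node

    root = parse_node()
    if pos >= len(text) or text[pos] != ";":
        raise error("expected ';'")
    if pos != len(text) - 1:
        raise error("trailing characters after ';'")
    return root
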