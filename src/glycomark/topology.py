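"""Rooted-tree model and linear string grammar for glycan structures.

A structure is written non-reducing end first, reducing end (the tree root)
last. Each residue token is

    Identity + ring letter + optional methyl list + linkage

e.g. ``Manp(3Me)(a1-3)`` — an alpha-mannopyranose carrying a natural
3-O-methyl group, attached to carbon 3 of the residue written to its right.
Branches are bracketed and immediately precede the residue they attach to.
The root's "linkage" records the reducing-end state instead of a carbon:
``r`` for a free reducing end (anomeric mixture), ``ol`` for a borohydride-
reduced alditol.

The two elucidated microalgal structures and the pineapple bromelain MUXF3
glycan ship as built-in fixtures::

    Araf(b1-4)Manp(3Me)(a1-3)Manp(b1-4)[Araf(a1-3)]GlcNAcp(b1-4)GlcNAcp(b1-ol)   # "Raa"
    Xylp(3Me)(b1-2)[Manp(a1-6)]Manp(b1-4)[Xylp(b1-3)]GlcNAcp(b1-4)GlcNAcp(b1-r)  # "Now"
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .glycomath import MASSES, Composition, ParseError, exact_mass_sum, neutral_mass

__all__ = [
    "StructureError",
    "Residue",
    "GlycanTopology",
    "parse_structure",
    "format_structure",
    "to_composition",
    "builtin_structure",
    "builtin_structures",
    "with_reducing_end",
    "RAA_STRING",
    "NOW_STRING",
    "MUXF3_STRING",
]


class StructureError(ValueError):
    """A structurally invalid topology (duplicate linkage, bad methyl site, ...)."""


#: residue identity -> composition class
_CLASS_OF = {
    "Man": "hex",
    "Glc": "hex",
    "Hex": "hex",
    "GlcNAc": "hexnac",
    "Ara": "pent",
    "Xyl": "pent",
    "Fuc": "dhex",
}

#: residue identity -> monoisotopic residue-mass attribute on the mass table
_MASS_ATTR = _CLASS_OF


@dataclass(frozen=True)
class Residue:
    """One monosaccharide residue in a glycan tree.

    ``link_to_parent`` is the carbon of the *parent* residue to which this
    residue's anomeric carbon is attached; it is None only for the root.
    ``o_methyl`` holds natural O-methylation sites (carbon numbers).
    """

    identity: str
    ring: str  # 'p' pyranose | 'f' furanose
    anomeric: str  # 'a' | 'b'
    o_methyl: frozenset[int] = frozenset()
    link_to_parent: int | None = None
    children: tuple["Residue", ...] = ()

    def __post_init__(self) -> None:
        if self.identity not in _CLASS_OF:
            raise StructureError(f"unknown residue identity {self.identity!r}")
        if self.ring not in ("p", "f"):
            raise StructureError(f"ring form must be 'p' or 'f', got {self.ring!r}")
        if self.anomeric not in ("a", "b"):
            raise StructureError(f"anomeric must be 'a' or 'b', got {self.anomeric!r}")
        child_pos = [c.link_to_parent for c in self.children]
        if len(child_pos) != len(set(child_pos)):
            raise StructureError(
                f"duplicate linkage position on {self.identity}: {sorted(child_pos)}"
            )
        for pos in child_pos:
            if pos is None or not 1 <= pos <= 6:
                raise StructureError(f"child linkage position out of range: {pos}")
        for pos in self.o_methyl:
            if not 1 <= pos <= 6:
                raise StructureError(f"O-methyl position out of range: {pos}")
            if pos in child_pos:
                raise StructureError(
                    f"O-methyl at carbon {pos} of {self.identity} clashes with a glycosidic bond"
                )
            if pos == 1:
                raise StructureError("carbon 1 is the anomeric centre and cannot be O-methylated")

    @property
    def residue_class(self) -> str:
        return _CLASS_OF[self.identity]

    def mass(self, table=MASSES) -> float:
        """Dehydrated residue mass including natural O-methyl increments."""
        return exact_mass_sum(self.mass_terms(table))

    def mass_terms(self, table=MASSES) -> list[float]:
        """The constituent mass constants (class mass + one term per O-methyl)."""
        return [getattr(table, _MASS_ATTR[self.identity])] + [table.methyl] * len(self.o_methyl)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(frozen=True)
class GlycanTopology:
    """A rooted glycan tree; the root is the reducing-end residue.

    ``reduced=True`` marks an alditol (borohydride-reduced) reducing end.
    """

    root: Residue
    reduced: bool = False
    name: str | None = None

    def residues(self) -> list[Residue]:
        return list(self.root.walk())

    def __len__(self) -> int:
        return len(self.residues())


_RESIDUE_RE = re.compile(
    r"(?P<ident>GlcNAc|Man|Ara|Xyl|Fuc|Glc|Hex)"
    r"(?P<ring>[pf])"
    r"(?:\((?P<me>\d+Me(?:,\d+Me)*)\))?"
    r"\((?P<ano>[ab])1-(?P<pos>\d+|r|ol)\)"
)


@dataclass
class _Node:
    identity: str
    ring: str
    anomeric: str
    o_methyl: frozenset
    pos_token: str  # digits, 'r' or 'ol'
    children: list = field(default_factory=list)

    def freeze(self, is_root: bool) -> Residue:
        return Residue(
            identity=self.identity,
            ring=self.ring,
            anomeric=self.anomeric,
            o_methyl=self.o_methyl,
            link_to_parent=None if is_root else int(self.pos_token),
            children=tuple(c.freeze(False) for c in self.children),
        )


def _parse_chain(text: str, base: int) -> _Node:
    """Parse one chain (no enclosing brackets); returns its last residue."""
    pending: list[_Node] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            depth, j = 1, i + 1
            while j < len(text) and depth:
                if text[j] == "[":
                    depth += 1
                elif text[j] == "]":
                    depth -= 1
                j += 1
            if depth:
                raise ParseError(f"unbalanced '[' at offset {base + i}")
            child = _parse_chain(text[i + 1 : j - 1], base + i + 1)
            if child.pos_token in ("r", "ol"):
                raise ParseError(
                    f"branch ending at offset {base + j - 1} must attach at a carbon position"
                )
            pending.append(child)
            i = j
        else:
            m = _RESIDUE_RE.match(text, i)
            if not m:
                raise ParseError(
                    f"unrecognized residue token at offset {base + i}: {text[i:i + 16]!r}"
                )
            methyls = frozenset(
                int(tok[:-2]) for tok in (m.group("me") or "").split(",") if tok
            )
            node = _Node(
                identity=m.group("ident"),
                ring=m.group("ring"),
                anomeric=m.group("ano"),
                o_methyl=methyls,
                pos_token=m.group("pos"),
            )
            node.children = pending
            pending = [node]
            i = m.end()
    if len(pending) != 1 or pending[0].pos_token is None:
        raise ParseError(f"empty or dangling chain at offset {base}")
    return pending[0]


def parse_structure(text: str, name: str | None = None) -> GlycanTopology:
    """Parse the linear structure grammar into a :class:`GlycanTopology`."""
    s = text.strip()
    if not s:
        raise ParseError("empty structure string")
    last = _parse_chain(s, 0)
    if last.pos_token not in ("r", "ol"):
        raise ParseError(
            "root residue must end with (x1-r) [free reducing end] or (x1-ol) [alditol], "
            f"got position {last.pos_token!r}"
        )
    try:
        root = last.freeze(is_root=True)
    except StructureError:
        raise
    return GlycanTopology(root=root, reduced=(last.pos_token == "ol"), name=name)


def _depth(r: Residue) -> int:
    return 1 + max((_depth(c) for c in r.children), default=0)


def _format_residue_token(r: Residue, tail: str) -> str:
    me = ""
    if r.o_methyl:
        me = "(" + ",".join(f"{p}Me" for p in sorted(r.o_methyl)) + ")"
    return f"{r.identity}{r.ring}{me}({r.anomeric}1-{tail})"


def _format_chain(r: Residue, tail: str) -> str:
    parts = []
    if r.children:
        # main chain = deepest subtree; ties broken toward the lowest position
        main = min(r.children, key=lambda c: (-_depth(c), c.link_to_parent))
        branches = sorted(
            (c for c in r.children if c is not main), key=lambda c: c.link_to_parent
        )
        parts.append(_format_chain(main, str(main.link_to_parent)))
        for b in branches:
            parts.append("[" + _format_chain(b, str(b.link_to_parent)) + "]")
    parts.append(_format_residue_token(r, tail))
    return "".join(parts)


def format_structure(t: GlycanTopology) -> str:
    """Canonical linear string: deepest branch inline, others bracketed by position."""
    return _format_chain(t.root, "ol" if t.reduced else "r")


def to_composition(t: GlycanTopology) -> Composition:
    """Project a topology onto residue-class counts (the os-code view)."""
    counts = {"hex": 0, "hexnac": 0, "pent": 0, "dhex": 0}
    methyl = 0
    for r in t.root.walk():
        counts[r.residue_class] += 1
        methyl += len(r.o_methyl)
    return Composition(methyl=methyl, reduced=t.reduced, **counts)


def topology_mass(t: GlycanTopology, table=MASSES) -> float:
    """Neutral mass summed residue-by-residue (independent of the composition path)."""
    terms: list[float] = [table.water]
    for r in t.root.walk():
        terms.extend(r.mass_terms(table))
    if t.reduced:
        terms.append(table.alditol)
    return exact_mass_sum(terms)


def with_reducing_end(t: GlycanTopology, reduced: bool) -> GlycanTopology:
    """Same tree with the reducing-end state switched (alditol <-> free)."""
    return replace(t, reduced=reduced)


# -- built-in fixtures -------------------------------------------------------

#: "Raa"-type major glycan (os2221): Araf-4(3-O-Me)Man-a3-Man-b4-GlcNAc-b4-GlcNAc-ol,
#: with a second Araf a1-3 on the inner GlcNAc. NMR preparation = alditol.
RAA_STRING = "Araf(b1-4)Manp(3Me)(a1-3)Manp(b1-4)[Araf(a1-3)]GlcNAcp(b1-4)GlcNAcp(b1-ol)"

#: "Now"-type major glycan (os2221): (3-O-Me)Xyl-b2-[Man-a6]Man-b4-GlcNAc-b4-GlcNAc,
#: with Xyl b1-3 on the inner GlcNAc. Free reducing end.
NOW_STRING = "Xylp(3Me)(b1-2)[Manp(a1-6)]Manp(b1-4)[Xylp(b1-3)]GlcNAcp(b1-4)GlcNAcp(b1-r)"

#: Pineapple stem bromelain MUXF3 (Man2 GlcNAc2 Xyl Fuc), the plant glycan
#: isobaric with os2221.
MUXF3_STRING = "Xylp(b1-2)[Manp(a1-6)]Manp(b1-4)GlcNAcp(b1-4)[Fucp(a1-3)]GlcNAcp(b1-r)"

_BUILTINS = {
    "raa": ("Raa", RAA_STRING),
    "now": ("Now", NOW_STRING),
    "muxf3": ("MUXF3", MUXF3_STRING),
}


def builtin_structure(name: str, reduced: bool | None = None) -> GlycanTopology:
    """A built-in fixture by (case-insensitive) name: "Raa", "Now" or "MUXF3".

    ``reduced`` overrides the reducing-end state; the default is the state of
    the original preparation ("Raa" was analyzed as the alditol, the others
    with a free reducing end). MALDI work on non-reduced pools uses
    ``reduced=False``.
    """
    key = name.strip().lower()
    if key not in _BUILTINS:
        raise KeyError(f"no built-in structure {name!r}; have {sorted(_BUILTINS)}")
    label, s = _BUILTINS[key]
    t = parse_structure(s, name=label)
    if reduced is not None:
        t = with_reducing_end(t, reduced)
    return t


def builtin_structures() -> dict[str, GlycanTopology]:
    return {label: builtin_structure(label) for label, _ in _BUILTINS.values()}


def resolve_structure(spec: str) -> GlycanTopology:
    """A fixture name or a structure string, whichever parses."""
    try:
        return builtin_structure(spec)
    except KeyError:
        return parse_structure(spec)


def verify_mass_consistency(t: GlycanTopology, table=MASSES, atol: float = 1e-9) -> bool:
    """Composition-path and residue-sum masses must agree to float noise."""
    return abs(neutral_mass(to_composition(t), table) - topology_mass(t, table)) <= atol
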