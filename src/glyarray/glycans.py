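"""Glycan probes, CFG-IUPAC condensed parsing, compositions, motif matching.

An arrayed *glycan probe* is a glycan moiety plus an optional tag (the
lipid or linker used for immobilization, e.g. Cer32 = ceramide with 32
carbon atoms).  Tag information is stored and compared separately from the
glycan sequence, so probes carrying the same glycan on different tags
compare equal on the glycan and different as probes.

Sequences may be recorded in several text formats (2D-TEXT, CFG-IUPAC, GWS,
WURCS, GlycoCT); only CFG-IUPAC condensed is parsed into a tree — the others
are stored verbatim.  The condensed grammar used here:

* residues are written nonreducing→reducing; the rightmost residue is the
  reducing end (tree root);
* each non-root residue carries its linkage to the parent written directly
  after the symbol: optional anomer (``a``/``b``/``α``/``β``/``ß``/``?``),
  optional anomeric (child) position, ``-``, parent position (digit or
  ``?``), e.g. ``Galß-4``, ``NeuAcα2-3``;
* a parenthesized group forms a branch on the residue written immediately
  after the closing parenthesis, e.g. ``Galß-4(Fucα-3)GlcNAc``;
* unwritten anomeric positions default to 1 for aldoses and to unknown for
  ulosonic acids / ketoses (NeuAc, Kdn, Kdo, Fru, ...), whose anomeric
  carbon is not C1.

Greek anomer letters are normalized to ASCII ``a``/``b`` internally.

Monosaccharide symbols are constrained by the shipped dictionary (69
entries adapted from the SNFG symbol table); the shipped motif dictionary
holds 60 curated substructures (blood groups, Lewis and sialyl antigens,
O-glycan cores, common disaccharide units, ...) expressed in the same
grammar with wildcards.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import permutations
from typing import Callable, Iterable

__all__ = [
    "GlycanError", "VocabularyError", "GrammarError",
    "GlycanNode", "GlycanTree", "Composition", "MotifPattern", "GlycanProbe",
    "MatchResult", "monosaccharide_dictionary", "motif_dictionary",
    "parse_iupac", "composition", "match_motif", "filter_probes",
    "ProbeQuery", "read_probe_csv", "write_probe_csv",
]

SEQUENCE_FORMATS = ("2D-TEXT", "CFG-IUPAC", "GWS", "WURCS", "GlycoCT")
PROBE_CLASSES = ("defined-glycan", "undefined-or-fraction", "other-conjugate")


class GlycanError(Exception):
    pass


class VocabularyError(GlycanError):
    """Unknown monosaccharide token."""


class GrammarError(GlycanError):
    """Structural error in a condensed sequence (with position)."""


# ---------------------------------------------------------------------------
# dictionaries

@lru_cache(maxsize=1)
def monosaccharide_dictionary() -> dict[str, dict]:
    """The shipped monosaccharide symbol table (symbol → entry)."""
    with resources.files("glyarray").joinpath("data", "monosaccharides.json").open(
            encoding="utf-8") as fh:
        return json.load(fh)["entries"]


@lru_cache(maxsize=1)
def _symbol_lookup() -> dict[str, str]:
    """All accepted spellings (symbols + synonyms) → canonical symbol."""
    table = {}
    for sym, entry in monosaccharide_dictionary().items():
        table[sym] = sym
        for syn in entry.get("synonyms", []):
            table[syn] = sym
    return table


@lru_cache(maxsize=1)
def motif_dictionary() -> list["MotifPattern"]:
    """The shipped motif dictionary, parsed into :class:`MotifPattern`."""
    with resources.files("glyarray").joinpath("data", "motifs.json").open(
            encoding="utf-8") as fh:
        raw = json.load(fh)["motifs"]
    return [MotifPattern.from_sequence(m["pattern"], anchor=m["anchor"],
                                       motif_name=m["name"]) for m in raw]


# ---------------------------------------------------------------------------
# tree model

@dataclass
class GlycanNode:
    """One residue.  Linkage to the parent lives on the child node:
    ``child_pos`` is the anomeric position of this residue, ``parent_pos``
    the attachment position on the parent; ``None`` means unknown (``?``)."""

    id: int
    symbol: str
    anomer: str = "?"  # 'a' | 'b' | '?' | 'open'
    substituents: list[str] = field(default_factory=list)
    parent: int | None = None
    child_pos: int | None = None
    parent_pos: int | None = None


@dataclass
class GlycanTree:
    """Rooted glycan: nodes indexed by id, root = reducing-end residue."""

    nodes: dict[int, GlycanNode]
    root: int

    def __len__(self) -> int:
        return len(self.nodes)

    def children(self, node_id: int) -> list[int]:
        return [n.id for n in self.nodes.values() if n.parent == node_id]

    def leaves(self) -> list[int]:
        have_child = {n.parent for n in self.nodes.values() if n.parent is not None}
        return [i for i in self.nodes if i not in have_child]

    def validate(self) -> None:
        if self.root not in self.nodes:
            raise GlycanError("root id not among nodes")
        seen = set()
        stack = [self.root]
        while stack:
            i = stack.pop()
            if i in seen:
                raise GlycanError("cycle detected")
            seen.add(i)
            stack.extend(self.children(i))
        if seen != set(self.nodes):
            raise GlycanError("tree is not connected")
        vocab = monosaccharide_dictionary()
        for n in self.nodes.values():
            if n.symbol not in vocab:
                raise VocabularyError(f"unknown monosaccharide symbol {n.symbol!r}")


@dataclass(frozen=True)
class Composition:
    """Monosaccharide multiset of a tree (symbol → count ≥ 1)."""

    counts: tuple[tuple[str, int], ...]

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "Composition":
        return cls(tuple(sorted(d.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def total(self) -> int:
        return sum(c for _, c in self.counts)

    def get(self, symbol: str) -> int:
        return self.as_dict().get(symbol, 0)


# ---------------------------------------------------------------------------
# CFG-IUPAC condensed parser

_ANOMER_MAP = {"a": "a", "b": "b", "α": "a", "β": "b", "ß": "b", "?": "?"}


def _normalize(seq: str) -> str:
    return seq.replace("α", "a").replace("β", "b").replace("ß", "b").strip()


@lru_cache(maxsize=1)
def _symbol_regex() -> re.Pattern:
    # longest-first so GlcNAc wins over Glc, Neu5Ac over Neu
    spellings = sorted(_symbol_lookup(), key=len, reverse=True)
    return re.compile("|".join(re.escape(s) for s in spellings))


@dataclass
class _ResidueTok:
    symbol: str
    anomer: str
    child_pos: int | None
    child_pos_written: bool
    parent_pos: int | None
    has_linkage: bool  # a "-pos" linkage followed the symbol
    pos: int  # character offset, for error messages


def _default_child_pos(symbol: str) -> int | None:
    return monosaccharide_dictionary()[symbol].get("anomeric_position")


def _tokenize(seq: str) -> list:
    """Split a normalized sequence into '(' / ')' / residue tokens."""
    toks: list = []
    i = 0
    sym_re = _symbol_regex()
    while i < len(seq):
        ch = seq[i]
        if ch in "()":
            toks.append(ch)
            i += 1
            continue
        if ch.isspace():
            i += 1
            continue
        m = sym_re.match(seq, i)
        if not m:
            frag = seq[i:i + 12]
            raise VocabularyError(
                f"unknown monosaccharide token at position {i}: {frag!r}...")
        symbol = _symbol_lookup()[m.group(0)]
        j = m.end()
        anomer = "?"
        anomer_written = False
        if j < len(seq) and seq[j] in _ANOMER_MAP:
            anomer = _ANOMER_MAP[seq[j]]
            anomer_written = True
            j += 1
        child_pos: int | None = None
        child_written = False
        if j < len(seq) and seq[j].isdigit():
            child_pos = int(seq[j])
            child_written = True
            j += 1
        has_linkage = False
        parent_pos: int | None = None
        if j < len(seq) and seq[j] == "-":
            has_linkage = True
            j += 1
            if j < len(seq) and seq[j].isdigit():
                parent_pos = int(seq[j])
                j += 1
            elif j < len(seq) and seq[j] == "?":
                parent_pos = None
                j += 1
            else:
                # trailing "-Cer32" style tags must be split off beforehand
                raise GrammarError(
                    f"expected linkage position at position {j} in {seq!r}")
        if not child_written:
            child_pos = _default_child_pos(symbol)
        toks.append(_ResidueTok(symbol, anomer, child_pos, child_written,
                                parent_pos, has_linkage, i))
        i = j
    return toks


def parse_iupac(seq: str) -> GlycanTree:
    """Parse a CFG-IUPAC condensed sequence into a :class:`GlycanTree`.

    ``"NeuAcα-3Galß-4Glcß"`` yields a 3-node linear tree rooted at Glc with
    edges NeuAc→(?,3)Gal and Gal→(1,4)Glc.  Unknown tokens raise
    :class:`VocabularyError`; unbalanced parentheses raise
    :class:`GrammarError` with the character position.
    """
    norm = _normalize(seq)
    if not norm:
        raise GrammarError("empty sequence")
    depth = 0
    for i, ch in enumerate(norm):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise GrammarError(f"unbalanced ')' at position {i} in {seq!r}")
    if depth != 0:
        raise GrammarError(f"unbalanced '(' in {seq!r}")

    toks = _tokenize(norm)
    nodes: dict[int, GlycanNode] = {}
    counter = [0]

    def new_node(tok: _ResidueTok) -> GlycanNode:
        counter[0] += 1
        n = GlycanNode(id=counter[0], symbol=tok.symbol, anomer=tok.anomer,
                       child_pos=tok.child_pos, parent_pos=tok.parent_pos)
        nodes[n.id] = n
        return n

    def parse_chain(i: int, inner: bool) -> tuple[GlycanNode, int]:
        """Parse until end (or ')' when inner); return last residue and index."""
        pending: list[GlycanNode] = []  # subtrees awaiting their parent
        last: GlycanNode | None = None
        while i < len(toks):
            t = toks[i]
            if t == ")":
                if not inner:
                    raise GrammarError("unbalanced ')'")
                break
            if t == "(":
                sub, i = parse_chain(i + 1, True)
                if i >= len(toks) or toks[i] != ")":
                    raise GrammarError("unbalanced '('")
                i += 1
                pending.append(sub)
                continue
            node = new_node(t)
            for child in pending:
                child.parent = node.id
            pending = [node]
            last = node
            i += 1
        if last is None:
            raise GrammarError("empty residue chain (check parentheses)")
        return last, i

    root, i = parse_chain(0, False)
    if i != len(toks):
        raise GrammarError("trailing tokens after reducing end")
    tree = GlycanTree(nodes=nodes, root=root.id)
    tree.validate()
    return tree


def composition(tree: GlycanTree) -> Composition:
    """Monosaccharide multiset of ``tree`` (sum of counts == node count)."""
    counts: dict[str, int] = {}
    for n in tree.nodes.values():
        counts[n.symbol] = counts.get(n.symbol, 0) + 1
    return Composition.from_dict(counts)


# ---------------------------------------------------------------------------
# motif matching

ANCHORS = ("anywhere", "reducing_end", "nonreducing_terminal")


@dataclass
class MotifPattern:
    """A structural query: a small tree with wildcards on anomer ('?') and
    on linkage positions (None), plus an anchoring rule."""

    pattern_tree: GlycanTree
    anchor: str = "anywhere"
    motif_name: str = ""

    @classmethod
    def from_sequence(cls, seq: str, anchor: str = "anywhere",
                      motif_name: str = "") -> "MotifPattern":
        if anchor not in ANCHORS:
            raise ValueError(f"anchor must be one of {ANCHORS}, got {anchor!r}")
        return cls(pattern_tree=parse_iupac(seq), anchor=anchor,
                   motif_name=motif_name or seq)


@dataclass
class MatchResult:
    matched: bool
    n_sites: int
    sites: list[frozenset[int]]  # tree-node id sets, one per embedding


def _edge_compatible(p: GlycanNode, t: GlycanNode) -> bool:
    """Pattern node vs tree node: symbol exact; '?' anomer and None positions
    in the *pattern* are wildcards."""
    if p.symbol != t.symbol:
        return False
    if p.anomer != "?" and p.anomer != t.anomer:
        return False
    if p.child_pos is not None and p.child_pos != t.child_pos:
        return False
    if p.parent_pos is not None and p.parent_pos != t.parent_pos:
        return False
    return True


def _node_compatible(p: GlycanNode, t: GlycanNode) -> bool:
    if p.symbol != t.symbol:
        return False
    if p.anomer != "?" and p.anomer != t.anomer:
        return False
    return True


def match_motif(tree: GlycanTree, motif: MotifPattern) -> MatchResult:
    """Count rooted-pattern embeddings of ``motif`` in ``tree``.

    An embedding maps pattern nodes injectively onto tree nodes preserving
    parent/child relations, monosaccharide symbols and every non-wildcard
    anomer / linkage position.  ``anchor="reducing_end"`` pins the pattern
    root to the tree root; ``anchor="nonreducing_terminal"`` requires every
    pattern leaf to land on a tree leaf.
    """
    ptree = motif.pattern_tree
    tree_leaves = set(tree.leaves())
    pattern_leaves = set(ptree.leaves())
    require_leaf = motif.anchor == "nonreducing_terminal"

    def embed(p_id: int, t_id: int, check_edge: bool) -> list[dict[int, int]]:
        """All mappings of the pattern subtree at p_id onto tree subtree at t_id."""
        p = ptree.nodes[p_id]
        t = tree.nodes[t_id]
        ok = _edge_compatible(p, t) if check_edge else _node_compatible(p, t)
        if not ok:
            return []
        if require_leaf and p_id in pattern_leaves and t_id not in tree_leaves:
            return []
        p_kids = ptree.children(p_id)
        if not p_kids:
            return [{p_id: t_id}]
        t_kids = tree.children(t_id)
        if len(t_kids) < len(p_kids):
            return []
        out: list[dict[int, int]] = []
        # child subtrees are injectively assigned to distinct tree children
        per_child = {pk: {tk: embed(pk, tk, True) for tk in t_kids} for pk in p_kids}
        for assignment in permutations(t_kids, len(p_kids)):
            partials: list[dict[int, int]] = [{p_id: t_id}]
            for pk, tk in zip(p_kids, assignment):
                subs = per_child[pk][tk]
                if not subs:
                    partials = []
                    break
                partials = [{**base, **s} for base in partials for s in subs]
            out.extend(partials)
        return out

    roots = [tree.root] if motif.anchor == "reducing_end" else list(tree.nodes)
    embeddings: list[dict[int, int]] = []
    for t_id in roots:
        embeddings.extend(embed(ptree.root, t_id, False))
    # distinct embeddings = distinct pattern→tree mappings
    uniq = {tuple(sorted(e.items())) for e in embeddings}
    sites = sorted({frozenset(dict(e).values()) for e in uniq},
                   key=lambda s: sorted(s))
    return MatchResult(matched=bool(uniq), n_sites=len(uniq), sites=sites)


# ---------------------------------------------------------------------------
# probes and filtering

@dataclass
class GlycanProbe:
    """An arrayed entity: glycan sequence(s) plus a separately stored tag."""

    probe_key: str
    display_name: str = ""
    sequences: dict[str, str] = field(default_factory=dict)  # format → verbatim text
    glytoucan_id: str | None = None
    tag: dict[str, str] | None = None  # {"tag_name": ..., "description": ...}
    probe_class: str = "defined-glycan"

    def __post_init__(self) -> None:
        if self.probe_class not in PROBE_CLASSES:
            raise ValueError(f"probe_class must be one of {PROBE_CLASSES}")
        bad = set(self.sequences) - set(SEQUENCE_FORMATS)
        if bad:
            raise ValueError(f"unknown sequence formats: {sorted(bad)}")
        if not self.sequences and not self.display_name:
            raise ValueError("probe needs at least a sequence or a display name")

    def iupac(self) -> str | None:
        return self.sequences.get("CFG-IUPAC")

    def tree(self) -> GlycanTree | None:
        """Parsed CFG-IUPAC tree, or None when absent/unparseable."""
        seq = self.iupac()
        if not seq:
            return None
        try:
            return parse_iupac(seq)
        except GlycanError:
            return None

    def same_glycan(self, other: "GlycanProbe") -> bool:
        """Glycan-moiety equality, ignoring tags (compared via CFG-IUPAC)."""
        a, b = self.iupac(), other.iupac()
        if a is None or b is None:
            return False
        return _normalize(a) == _normalize(b)


@dataclass
class ProbeQuery:
    """Conjunctive structural/annotation query over probes.

    Clauses (all optional, ANDed): ``monosaccharide`` — composition must
    contain the symbol (at least ``min_count``); ``motif`` — sequence or
    :class:`MotifPattern` that must embed; ``tag_name`` — exact tag match;
    ``custom`` — arbitrary predicate on the probe.
    """

    monosaccharide: str | None = None
    min_count: int = 1
    motif: "MotifPattern | str | None" = None
    tag_name: str | None = None
    custom: Callable[["GlycanProbe"], bool] | None = None

    def needs_structure(self) -> bool:
        return self.monosaccharide is not None or self.motif is not None

    def pattern(self) -> "MotifPattern | None":
        if self.motif is None:
            return None
        if isinstance(self.motif, MotifPattern):
            return self.motif
        return MotifPattern.from_sequence(self.motif)


def filter_probes(probes: Iterable[GlycanProbe], query: ProbeQuery
                  ) -> tuple[list[GlycanProbe], dict[str, str]]:
    """Select probes satisfying ``query``, preserving input order.

    Returns (subset, explanations).  ``explanations`` maps every probe key
    to the clause that decided its fate; probes whose structure a clause
    needs but cannot be parsed are excluded with reason ``"unparsed"``,
    never via an exception.
    """
    pattern = query.pattern()
    selected: list[GlycanProbe] = []
    explain: dict[str, str] = {}
    for probe in probes:
        reasons: list[str] = []
        tree = probe.tree() if query.needs_structure() else None
        if query.needs_structure() and tree is None:
            explain[probe.probe_key] = "unparsed"
            continue
        if query.monosaccharide is not None:
            n = composition(tree).get(query.monosaccharide)
            if n < query.min_count:
                explain[probe.probe_key] = (
                    f"composition lacks {query.monosaccharide}"
                    f" x{query.min_count} (has {n})")
                continue
            reasons.append(f"contains {query.monosaccharide} x{n}")
        if pattern is not None:
            res = match_motif(tree, pattern)
            if not res.matched:
                explain[probe.probe_key] = f"motif {pattern.motif_name!r} absent"
                continue
            reasons.append(f"motif {pattern.motif_name!r} at {res.n_sites} site(s)")
        if query.tag_name is not None:
            tag = (probe.tag or {}).get("tag_name")
            if tag != query.tag_name:
                explain[probe.probe_key] = f"tag {tag!r} != {query.tag_name!r}"
                continue
            reasons.append(f"tag {tag!r}")
        if query.custom is not None:
            if not query.custom(probe):
                explain[probe.probe_key] = "custom predicate false"
                continue
            reasons.append("custom predicate")
        selected.append(probe)
        explain[probe.probe_key] = "; ".join(reasons) if reasons else "no constraints"
    return selected, explain


# ---------------------------------------------------------------------------
# probe list I/O (CSV template)

_PROBE_COLUMNS = ["probe_key", "name", "sequence_cfg_iupac", "sequence_2d_text",
                  "sequence_gws", "sequence_wurcs", "sequence_glycoct",
                  "glytoucan_id", "tag_name", "tag_description", "probe_class"]

_FMT_BY_COL = {"sequence_cfg_iupac": "CFG-IUPAC", "sequence_2d_text": "2D-TEXT",
               "sequence_gws": "GWS", "sequence_wurcs": "WURCS",
               "sequence_glycoct": "GlycoCT"}


def read_probe_csv(path) -> list[GlycanProbe]:
    """Read a probe list from the shipped CSV template dialect."""
    import csv as _csv
    from pathlib import Path as _Path
    with open(_Path(path), newline="", encoding="utf-8") as fh:
        reader = _csv.DictReader(fh)
        probes = []
        for row in reader:
            sequences = {fmt: row[col].strip() for col, fmt in _FMT_BY_COL.items()
                         if row.get(col, "").strip()}
            tag = None
            if row.get("tag_name", "").strip():
                tag = {"tag_name": row["tag_name"].strip(),
                       "description": row.get("tag_description", "").strip()}
            probes.append(GlycanProbe(
                probe_key=row["probe_key"].strip(),
                display_name=row.get("name", "").strip(),
                sequences=sequences,
                glytoucan_id=row.get("glytoucan_id", "").strip() or None,
                tag=tag,
                probe_class=row.get("probe_class", "").strip() or "defined-glycan"))
    return probes


def write_probe_csv(probes: Iterable[GlycanProbe], path) -> None:
    import csv as _csv
    from pathlib import Path as _Path
    rev = {v: k for k, v in _FMT_BY_COL.items()}
    with open(_Path(path), "w", newline="", encoding="utf-8") as fh:
        w = _csv.DictWriter(fh, fieldnames=_PROBE_COLUMNS)
        w.writeheader()
        for p in probes:
            row = {"probe_key": p.probe_key, "name": p.display_name,
                   "glytoucan_id": p.glytoucan_id or "",
                   "tag_name": (p.tag or {}).get("tag_name", ""),
                   "tag_description": (p.tag or {}).get("description", ""),
                   "probe_class": p.probe_class}
            for fmt, text in p.sequences.items():
                row[rev[fmt]] = text
            w.writerow(row)
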