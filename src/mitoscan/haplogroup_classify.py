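"""Haplogroup assignment from a user-supplied definition tree.

Each haplogroup is a node in a rooted tree; its defining variants are
cumulative along the path from the root.  A sample is assigned to the node
maximizing the unweighted fraction of path-defining variants it carries
(ties go to the deeper, then alphabetically first node).  Haplogroup names
collapse to simplified macro-lineages (L0–L3, M, N, R, H, ...) by
longest-prefix matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("mitoscan")

Variant = tuple[int, str]  # (1-based position, derived allele)


class TreeError(ValueError):
    """The haplogroup definitions do not form a single rooted tree."""


@dataclass
class HaplogroupDef:
    name: str
    parent: str | None  # None at the root
    defining_variants: frozenset[Variant]


@dataclass
class HaplogroupCall:
    sample_id: str
    haplogroup: str
    score: float
    matched: int
    expected: int
    private_variants: int


class HaplogroupTree:
    """Validated rooted tree of :class:`HaplogroupDef` nodes."""

    def __init__(self, defs: Iterable[HaplogroupDef]):
        self.nodes: dict[str, HaplogroupDef] = {}
        for d in defs:
            if d.name in self.nodes:
                raise TreeError(f"duplicate haplogroup name {d.name!r}")
            self.nodes[d.name] = d
        roots = [d.name for d in self.nodes.values() if d.parent is None]
        if len(roots) != 1:
            raise TreeError(f"expected exactly one root, got {roots}")
        self.root = roots[0]
        self._path_cache: dict[str, frozenset[Variant]] = {}
        for name in self.nodes:
            self.path_variants(name)  # validates parent links / cycles

    def path_variants(self, name: str) -> frozenset[Variant]:
        """Cumulative defining variants on the root -> ``name`` path."""
        if name not in self.nodes:
            raise KeyError(f"haplogroup {name!r} not in tree")
        if name in self._path_cache:
            return self._path_cache[name]
        chain: list[str] = []
        seen: set[str] = set()
        cur: str | None = name
        while cur is not None:
            if cur in seen:
                raise TreeError(f"cycle in parent links at {cur!r}")
            seen.add(cur)
            chain.append(cur)
            parent = self.nodes[cur].parent
            if parent is not None and parent not in self.nodes:
                raise TreeError(f"parent {parent!r} of {cur!r} is not defined")
            cur = parent
        acc: set[Variant] = set()
        for node in reversed(chain):
            acc |= self.nodes[node].defining_variants
            self._path_cache.setdefault(node, frozenset(acc))
        return self._path_cache[name]

    def depth(self, name: str) -> int:
        d = 0
        cur = self.nodes[name].parent
        while cur is not None:
            d += 1
            cur = self.nodes[cur].parent
        return d


def parse_variant_token(token: str) -> Variant:
    """Parse ``<pos><allele>`` tokens like ``11914A``."""
    token = token.strip()
    if len(token) < 2 or not token[:-1].isdigit() or token[-1] not in "ACGT-":
        raise ValueError(f"malformed variant token {token!r}")
    return int(token[:-1]), token[-1]


def read_haplogroup_tree_tsv(path) -> HaplogroupTree:
    """Read a ``name<TAB>parent<TAB>variants`` definition table.

    ``parent`` empty or ``-`` marks the root; ``variants`` is a
    comma-separated list of ``<pos><allele>`` tokens (may be empty).
    """
    defs: list[HaplogroupDef] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = line.split("\t")
            name = parts[0].strip()
            parent = parts[1].strip() if len(parts) > 1 else ""
            var_field = parts[2].strip() if len(parts) > 2 else ""
            variants = frozenset(
                parse_variant_token(t) for t in var_field.split(",") if t.strip()
            )
            defs.append(
                HaplogroupDef(
                    name=name,
                    parent=None if parent in ("", "-") else parent,
                    defining_variants=variants,
                )
            )
    return HaplogroupTree(defs)


def score_against_definition(
    sample_variants: Iterable[Variant], name: str, tree: HaplogroupTree
) -> tuple[int, int, float]:
    """(matched, expected, score) for one sample against one node.

    ``expected`` is the number of defining variants on the root -> node
    path, ``matched`` the intersection with the sample's variant set, and
    ``score = matched/expected`` (the root scores 1 with expected 0 by
    convention).
    """
    path = tree.path_variants(name)
    expected = len(path)
    matched = len(path & set(sample_variants))
    score = 1.0 if expected == 0 else matched / expected
    return matched, expected, score


def classify_sample(
    sample_id: str, sample_variants: Iterable[Variant], tree: HaplogroupTree
) -> HaplogroupCall:
    """Assign the best-scoring haplogroup.

    Ties are broken toward the larger ``expected`` (the deeper, more
    specific node), then alphabetically.  An empty variant set returns the
    root with a warning.
    """
    variants = set(sample_variants)
    if not variants:
        logger.warning("sample %s has no variants; returning root", sample_id)
        m, e, s = score_against_definition(variants, tree.root, tree)
        return HaplogroupCall(sample_id, tree.root, s, m, e, 0)
    best: tuple[float, int, str] | None = None  # (score, expected, name)
    best_stats = (0, 0)
    for name in tree.nodes:
        m, e, s = score_against_definition(variants, name, tree)
        key = (s, e, name)
        if best is None or (s, e) > (best[0], best[1]) or (
            (s, e) == (best[0], best[1]) and name < best[2]
        ):
            best = key
            best_stats = (m, e)
    assert best is not None
    winner = best[2]
    private = len(variants - tree.path_variants(winner))
    return HaplogroupCall(
        sample_id=sample_id,
        haplogroup=winner,
        score=best[0],
        matched=best_stats[0],
        expected=best_stats[1],
        private_variants=private,
    )


def classify_cohort(
    variants_by_sample: Mapping[str, Iterable[Variant]], tree: HaplogroupTree
) -> list[HaplogroupCall]:
    return [
        classify_sample(sid, v, tree) for sid, v in variants_by_sample.items()
    ]


def read_lineage_map_tsv(path) -> list[tuple[str, str]]:
    """Read a ``prefix<TAB>lineage`` table, kept in file order."""
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("prefix\t"):
                continue
            prefix, lineage = line.split("\t")[:2]
            out.append((prefix.strip(), lineage.strip()))
    return out


def simplify_lineage(
    haplogroup_name: str, lineage_map: Sequence[tuple[str, str]]
) -> str:
    """Collapse a haplogroup name to its macro-lineage by longest prefix.

    ``lineage_map`` is an ordered (prefix, lineage) table; the longest
    matching prefix wins.  Unmatched names map to ``"OTHER"`` with a warning.
    """
    if not haplogroup_name:
        raise ValueError("empty haplogroup name")
    best: tuple[int, str] | None = None
    for prefix, lineage in lineage_map:
        if haplogroup_name.startswith(prefix):
            if best is None or len(prefix) > best[0]:
                best = (len(prefix), lineage)
    if best is None:
        logger.warning("haplogroup %r matches no lineage prefix; OTHER", haplogroup_name)
        return "OTHER"
    return best[1]
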