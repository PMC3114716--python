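"""Functional-category definitions, identifier mapping, and reference sets.

A *category* is a named gene set (a GO term, a MapMan bin, or a custom list
such as a hand-curated "metal homeostasis" collection).  Categories live in a
:class:`CategoryCollection` whose members all use one identifier namespace —
either microarray probe-set IDs or genomic locus codes (e.g. AGI codes like
``AT1G49910``).  An :class:`IdentifierMap` translates collections between
namespaces; a :class:`ReferenceSet` (typically "all probe sets on the chip")
defines the gene universe against which category sizes are measured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = [
    "GeneCategory",
    "CategoryCollection",
    "IdentifierMap",
    "ReferenceSet",
    "MappingReport",
    "CategoryParseError",
    "parse_gmt",
    "write_gmt",
    "parse_two_column",
    "write_two_column",
    "read_reference",
    "write_reference",
    "map_identifiers",
    "restrict_to_reference",
]


class CategoryParseError(ValueError):
    """Raised when a category file is malformed; carries the line number."""


@dataclass(frozen=True)
class GeneCategory:
    """A named, non-empty set of gene identifiers with a provenance label."""

    name: str
    members: frozenset[str]
    source: str = "custom"

    def __post_init__(self) -> None:
        if not self.name or not self.name.strip():
            raise ValueError("category name must be non-empty")
        if not self.members:
            raise ValueError(f"category {self.name!r} has no members")
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CategoryCollection:
    """Mapping of category name -> :class:`GeneCategory`, one namespace.

    ``namespace`` records the identifier kind of every member ("gene" for
    locus codes, "probe" for array probe-set IDs); all categories in one
    collection share it, which is what makes restriction to a reference set
    and downstream statistics well defined.
    """

    categories: dict[str, GeneCategory] = field(default_factory=dict)
    namespace: str = "gene"

    def __post_init__(self) -> None:
        for name, cat in self.categories.items():
            if name != cat.name:
                raise ValueError(f"key {name!r} does not match category name {cat.name!r}")

    def add(self, cat: GeneCategory) -> None:
        if cat.name in self.categories:
            raise ValueError(f"duplicate category name {cat.name!r}")
        self.categories[cat.name] = cat

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories.values())

    def __getitem__(self, name: str) -> GeneCategory:
        return self.categories[name]

    def __contains__(self, name: str) -> bool:
        return name in self.categories

    def names(self) -> list[str]:
        return list(self.categories)

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for cat in self:
            out |= cat.members
        return frozenset(out)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CategoryCollection):
            return NotImplemented
        return self.namespace == other.namespace and self.categories == other.categories


@dataclass(frozen=True)
class ReferenceSet:
    """The gene universe (e.g. every probe set present on the array)."""

    members: frozenset[str]
    label: str = "reference"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("reference set must be non-empty")
        if not isinstance(self.members, frozenset):
            object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)


class IdentifierMap:
    """Many-to-many relation between two identifier namespaces.

    Built from (left, right) pairs, e.g. (probe-set ID, locus code).  Array
    annotations are genuinely many-to-many: one probe set can interrogate
    several loci and one locus can be covered by several probe sets, so both
    directions map an identifier to a *set* of images.
    """

    def __init__(
        self,
        pairs: list[tuple[str, str]] | set[tuple[str, str]],
        left_namespace: str = "probe",
        right_namespace: str = "gene",
    ) -> None:
        if left_namespace == right_namespace:
            raise ValueError("the two namespaces must differ")
        self.left_namespace = left_namespace
        self.right_namespace = right_namespace
        self._fwd: dict[str, set[str]] = {}
        self._rev: dict[str, set[str]] = {}
        seen: set[tuple[str, str]] = set()
        for left, right in pairs:
            left, right = left.strip(), right.strip()
            if not left or not right:
                raise ValueError("identifier map entries must be non-empty strings")
            if (left, right) in seen:
                continue
            seen.add((left, right))
            self._fwd.setdefault(left, set()).add(right)
            self._rev.setdefault(right, set()).add(left)

    @classmethod
    def from_tsv(cls, path: str | Path, left_namespace: str = "probe",
                 right_namespace: str = "gene") -> "IdentifierMap":
        pairs = []
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise CategoryParseError(
                        f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
                    )
                pairs.append((fields[0], fields[1]))
        return cls(pairs, left_namespace, right_namespace)

    def images(self, ident: str, target_namespace: str) -> set[str]:
        """All images of ``ident`` when translating toward ``target_namespace``."""
        if target_namespace == self.right_namespace:
            return set(self._fwd.get(ident, ()))
        if target_namespace == self.left_namespace:
            return set(self._rev.get(ident, ()))
        raise ValueError(f"unknown namespace {target_namespace!r}")

    def __len__(self) -> int:
        return sum(len(v) for v in self._fwd.values())


@dataclass
class MappingReport:
    """What was lost while mapping or restricting a collection."""

    dropped_members: dict[str, set[str]] = field(default_factory=dict)
    removed_categories: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.dropped_members and not self.removed_categories


# ---------------------------------------------------------------------------
# parsing / writing


def parse_gmt(path: str | Path, namespace: str = "gene") -> CategoryCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>member...`` per line.

    The description field is kept as the category's source annotation.
    Repeated member tokens on one line are collapsed (set semantics).
    """
    coll = CategoryCollection(namespace=namespace)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CategoryParseError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            if not members:
                raise CategoryParseError(f"{path}:{lineno}: category {name!r} has no members")
            try:
                coll.add(GeneCategory(name=name, members=members, source=fields[1].strip()))
            except ValueError as exc:
                raise CategoryParseError(f"{path}:{lineno}: {exc}") from exc
    return coll


def write_gmt(coll: CategoryCollection, path: str | Path) -> None:
    """Write a collection in GMT format with sorted members (deterministic)."""
    with open(path, "w") as fh:
        for name in sorted(coll.names()):
            cat = coll[name]
            fh.write("\t".join([cat.name, cat.source, *sorted(cat.members)]) + "\n")


def parse_two_column(path: str | Path, namespace: str = "gene",
                     source: str = "two-column") -> CategoryCollection:
    """Parse a ``gene<TAB>category`` file (the MapMan-bin dialect).

    Lines starting with ``#`` are comments.  Categories are assembled by
    grouping on the second column; a gene may appear under several
    categories.
    """
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise CategoryParseError(
                    f"{path}:{lineno}: expected 'gene<TAB>category', got {len(fields)} fields"
                )
            gene, cat = fields[0].strip(), fields[1].strip()
            if not gene or not cat:
                raise CategoryParseError(f"{path}:{lineno}: empty field")
            groups.setdefault(cat, set()).add(gene)
    coll = CategoryCollection(namespace=namespace)
    for name in sorted(groups):
        coll.add(GeneCategory(name=name, members=frozenset(groups[name]), source=source))
    return coll


def write_two_column(coll: CategoryCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.names()):
            for gene in sorted(coll[name].members):
                fh.write(f"{gene}\t{name}\n")


def read_reference(path: str | Path, label: str | None = None) -> ReferenceSet:
    """Read a reference set: one identifier per line, ``#`` comments allowed."""
    members = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                members.add(line)
    return ReferenceSet(frozenset(members), label=label or str(path))


def write_reference(ref: ReferenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ident in sorted(ref.members):
            fh.write(ident + "\n")


# ---------------------------------------------------------------------------
# transformations


def map_identifiers(
    coll: CategoryCollection,
    idmap: IdentifierMap,
    target_namespace: str,
) -> tuple[CategoryCollection, MappingReport]:
    """Translate a collection into ``target_namespace`` via ``idmap``.

    Each member is replaced by *all* of its images (union semantics for
    one-to-many relations, so a locus' category membership propagates to every
    probe set interrogating it).  Members without an image are dropped and
    listed in the report; categories that end up empty are removed and listed
    in the report rather than raising.
    """
    if coll.namespace == target_namespace:
        raise ValueError("collection is already in the target namespace")
    if target_namespace not in (idmap.left_namespace, idmap.right_namespace):
        raise ValueError(
            f"identifier map does not cover namespace {target_namespace!r}"
        )
    report = MappingReport()
    out = CategoryCollection(namespace=target_namespace)
    for cat in coll:
        mapped: set[str] = set()
        dropped: set[str] = set()
        for member in cat.members:
            images = idmap.images(member, target_namespace)
            if images:
                mapped |= images
            else:
                dropped.add(member)
        if dropped:
            report.dropped_members[cat.name] = dropped
        if mapped:
            out.add(GeneCategory(cat.name, frozenset(mapped), cat.source))
        else:
            report.removed_categories.append(cat.name)
    if not report.clean:
        logger.info(
            "identifier mapping dropped %d members across %d categories; removed %d empty categories",
            sum(len(v) for v in report.dropped_members.values()),
            len(report.dropped_members),
            len(report.removed_categories),
        )
    return out, report


def restrict_to_reference(
    coll: CategoryCollection,
    ref: ReferenceSet,
) -> tuple[CategoryCollection, MappingReport]:
    """Intersect every category with the reference set.

    The effective category size k used by all downstream statistics is
    defined on this restricted collection.  Categories disjoint from the
    reference are removed and recorded in the report.
    """
    report = MappingReport()
    out = CategoryCollection(namespace=coll.namespace)
    for cat in coll:
        kept = cat.members & ref.members
        lost = cat.members - ref.members
        if lost:
            report.dropped_members[cat.name] = lost
        if kept:
            out.add(GeneCategory(cat.name, frozenset(kept), cat.source))
        else:
            report.removed_categories.append(cat.name)
    return out, report
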