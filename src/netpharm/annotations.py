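"""Named many-to-many identifier maps (target→pathway, pathway→disease, ...).

All annotation layers in the pipeline are set-valued maps between opaque
identifier namespaces: a target belongs to a set of pathways, a pathway is
annotated to a set of diseases, a disease presents a set of symptoms or
belongs to a set of categories.  One container serves all of them.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping

__all__ = ["AnnotationMap"]


class AnnotationMap:
    """Immutable many-to-many mapping ``key id -> set of value ids``.

    Keys with empty value sets are not stored: a key is either annotated
    (to a nonempty set) or absent.  The reverse view is derived lazily and
    is always consistent with the forward view.
    """

    __slots__ = ("name", "_forward", "_reverse")

    def __init__(self, name: str, forward: Mapping[str, Iterable[str]]):
        if not name:
            raise ValueError("annotation map needs a nonempty name")
        clean: dict[str, frozenset[str]] = {}
        for key, values in forward.items():
            if not key:
                raise ValueError("empty key id in annotation map %r" % name)
            vset = frozenset(values)
            if not vset:
                raise ValueError(
                    "key %r in annotation map %r has an empty value set" % (key, name)
                )
            if any(not v for v in vset):
                raise ValueError("empty value id under key %r in map %r" % (key, name))
            clean[key] = vset
        self.name = name
        self._forward = clean
        self._reverse: AnnotationMap | None = None

    # -- mapping protocol -------------------------------------------------
    def __contains__(self, key: str) -> bool:
        return key in self._forward

    def __len__(self) -> int:
        return len(self._forward)

    def __iter__(self) -> Iterator[str]:
        return iter(self._forward)

    def __getitem__(self, key: str) -> frozenset[str]:
        return self._forward[key]

    def get(self, key: str, default: frozenset[str] = frozenset()) -> frozenset[str]:
        """Value set for *key*, or ``default`` (empty set) if unannotated."""
        return self._forward.get(key, default)

    def keys(self):
        return self._forward.keys()

    def items(self):
        return self._forward.items()

    def values(self):
        return self._forward.values()

    # -- derived views ----------------------------------------------------
    @property
    def all_values(self) -> frozenset[str]:
        return frozenset(v for vs in self._forward.values() for v in vs)

    def reverse(self) -> "AnnotationMap":
        """The inverted map (value id -> set of key ids), cached."""
        if self._reverse is None:
            rev: dict[str, set[str]] = {}
            for key, values in self._forward.items():
                for v in values:
                    rev.setdefault(v, set()).add(key)
            inv = AnnotationMap(self.name + ":reverse", rev)
            inv._reverse = self
            self._reverse = inv
        return self._reverse

    def n_pairs(self) -> int:
        """Total number of (key, value) annotation pairs."""
        return sum(len(v) for v in self._forward.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationMap):
            return NotImplemented
        return self._forward == other._forward

    def __repr__(self) -> str:
        return "AnnotationMap(%r, %d keys, %d pairs)" % (
            self.name,
            len(self._forward),
            self.n_pairs(),
        )
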