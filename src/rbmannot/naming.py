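"""Deterministic prefixed names for model entities.

Sites, states and subrules are not top-level entities in rule-based
languages, so annotations cannot point at them directly.  The convention
implemented here constructs a Turtle prefixed name for any model entity by
joining the symbolic names along its declaration path with ``:`` and
prepending the empty prefix — e.g. the ``y`` state of site ``site2`` of
agent ``A`` becomes ``:A:site2:y``.  With the empty prefix bound to a base
URI for the model file, these render as globally unique URIs.

Subrules, which have no symbolic name of their own, are addressed by
appending their 1-based position index to the parent rule's label
(``:Phos:1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union
from urllib.parse import quote


class UndefinedPrefixError(KeyError):
    """The prefix of a prefixed name is not bound in the prefix table."""


@dataclass(frozen=True)
class PrefixedName:
    """A Turtle prefixed name ``prefix:local``.

    The empty prefix is legal (and is the one used for model entities), so
    the rendering of ``PrefixedName("", "A:site2:y")`` is ``:A:site2:y``.
    The local part may itself contain ``:`` (valid in Turtle PN_LOCAL).
    """
    prefix: str
    local: str

    def render(self) -> str:
        return f"{self.prefix}:{self.local}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def _escape_component(component: str) -> str:
    # Percent-encode anything outside the always-safe PN_LOCAL repertoire;
    # keeps the joiner ':' unambiguous (':' itself is encoded) so distinct
    # paths can never collide.
    return quote(component, safe="")


def entity_name(path: Sequence[str]) -> PrefixedName:
    """Empty-prefix name for the entity at ``path``.

    ``["A", "site2", "y"]`` -> ``:A:site2:y``.  Deterministic and injective:
    components are percent-escaped so the ``:`` separator cannot be forged
    by a component.
    """
    if not path:
        raise ValueError("entity path must be non-empty")
    for c in path:
        if not c:
            raise ValueError("entity path components must be non-empty")
    return PrefixedName("", ":".join(_escape_component(c) for c in path))


def subrule_name(rule_label: str, index: int) -> PrefixedName:
    """Name of the ``index``-th (1-based) subrule of the labeled rule."""
    if index < 1:
        raise ValueError("subrule indices are 1-based")
    return entity_name([rule_label, str(index)])


def resolve(name: Union[PrefixedName, str],
            prefix_table: Mapping[str, str]) -> str:
    """Expand a prefixed name to an absolute URI via ``prefix_table``.

    Accepts either a :class:`PrefixedName` or its rendered text (split at
    the first ``:``).  Raises :class:`UndefinedPrefixError` when the prefix
    is not bound.
    """
    if isinstance(name, str):
        if ":" not in name:
            raise ValueError(f"{name!r} is not a prefixed name")
        prefix, local = name.split(":", 1)
        name = PrefixedName(prefix, local)
    if name.prefix not in prefix_table:
        raise UndefinedPrefixError(name.prefix)
    return prefix_table[name.prefix] + name.local
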