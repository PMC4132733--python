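"""Ribonucleoside registry: canonical and modified residue definitions.

All downstream mass arithmetic resolves residue codes through a
:class:`Registry`. Built-in residues ship as package data
(``data/residues.yaml``); user files may extend the registry but cannot
silently redefine a built-in.
"""

from __future__ import annotations

import importlib.resources
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterator, Mapping

import yaml

from .elements import (
    format_formula,
    formula_mass,
    formula_sub,
    parse_formula,
)

__all__ = [
    "RegistryError",
    "ResidueDefinition",
    "ModificationDelta",
    "Registry",
    "default_registry",
    "load_registry",
    "CANONICAL_CODES",
]

CANONICAL_CODES = ("A", "C", "G", "U")

# ribose moiety contributed by the nucleoside beyond the free base
# (ribose - H2O lost in the glycosidic bond); 2'-O-methyl adds one CH2
_SUGAR = parse_formula("C5H8O4")
_SUGAR_2OME = parse_formula("C6H10O4")


class RegistryError(KeyError):
    """Unknown residue code, or an invalid registry file/entry."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep messages readable
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class ResidueDefinition:
    """One canonical or modified ribonucleoside (as the free nucleoside)."""

    code: str
    formula: str
    base_class: str  # purine | pyrimidine
    name: str = ""
    parent_code: str | None = None
    ribose_2prime_methyl: bool = False
    t1_cleavable: bool = False
    rnaseA_cleavable: bool = False
    aliases: tuple[str, ...] = field(default_factory=tuple)

    @cached_property
    def mono_mass(self) -> float:
        return formula_mass(self.formula, "mono")

    @cached_property
    def avg_mass(self) -> float:
        return formula_mass(self.formula, "avg")

    def mass(self, kind: str = "mono") -> float:
        if kind == "mono":
            return self.mono_mass
        if kind == "avg":
            return self.avg_mass
        raise ValueError(f"kind must be 'mono' or 'avg', got {kind!r}")

    @cached_property
    def base_formula(self) -> Counter:
        """Formula of the free nucleobase (nucleoside minus its ribose)."""
        sugar = _SUGAR_2OME if self.ribose_2prime_methyl else _SUGAR
        return formula_sub(self.formula, sugar)


@dataclass(frozen=True)
class ModificationDelta:
    """Mass/formula difference between two registered residues."""

    from_code: str
    to_code: str
    delta_mono: float
    delta_formula: str


class Registry:
    """Mapping of residue codes (and aliases) to definitions."""

    def __init__(self, residues: Mapping[str, ResidueDefinition] | None = None):
        self._residues: dict[str, ResidueDefinition] = {}
        self._aliases: dict[str, str] = {}
        self._builtin: set[str] = set()
        if residues:
            for res in residues.values():
                self.add(res)

    # -- construction ------------------------------------------------------

    def add(self, residue: ResidueDefinition, override: bool = False) -> None:
        code = residue.code
        existing = self._aliases.get(code, code) in self._residues or any(
            alias in self._aliases or alias in self._residues
            for alias in residue.aliases
        )
        if code in self._residues and not override:
            raise RegistryError(
                f"residue {code!r} is already defined; pass override=True "
                "to redefine it"
            )
        if existing and code not in self._residues and not override:
            raise RegistryError(
                f"an alias of residue {code!r} is already defined; pass "
                "override=True to redefine it"
            )
        self._residues[code] = residue
        for alias in residue.aliases:
            self._aliases[alias] = code
        if residue.parent_code is not None and residue.parent_code not in self:
            raise RegistryError(
                f"residue {code!r} names unknown parent {residue.parent_code!r}"
            )

    def _mark_builtin(self) -> None:
        self._builtin = set(self._residues)

    # -- lookup ------------------------------------------------------------

    def resolve(self, code: str) -> str:
        return self._aliases.get(code, code)

    def get(self, code: str) -> ResidueDefinition:
        key = self.resolve(code)
        try:
            return self._residues[key]
        except KeyError:
            raise RegistryError(f"unknown residue code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return self.resolve(code) in self._residues

    def __iter__(self) -> Iterator[ResidueDefinition]:
        return iter(self._residues.values())

    def codes(self) -> list[str]:
        return list(self._residues)

    def canonical_parent(self, code: str) -> str:
        """Follow the parent chain down to one of A/C/G/U."""
        res = self.get(code)
        seen = {res.code}
        while res.parent_code is not None:
            res = self.get(res.parent_code)
            if res.code in seen:
                raise RegistryError(f"parent cycle at residue {res.code!r}")
            seen.add(res.code)
        if res.code not in CANONICAL_CODES:
            raise RegistryError(
                f"residue {code!r} does not resolve to a canonical base"
            )
        return res.code

    # -- mass arithmetic ---------------------------------------------------

    def residue_mass(self, code: str, kind: str = "mono") -> float:
        """Monoisotopic (default) or average mass of the free nucleoside."""
        return self.get(code).mass(kind)

    def modification_delta(self, from_code: str, to_code: str) -> ModificationDelta:
        a, b = self.get(from_code), self.get(to_code)
        delta = formula_sub(b.formula, a.formula)
        return ModificationDelta(
            from_code=a.code,
            to_code=b.code,
            delta_mono=b.mono_mass - a.mono_mass,
            delta_formula=format_formula(delta),
        )


def _residue_from_entry(entry: Mapping) -> ResidueDefinition:
    if not isinstance(entry, Mapping) or "code" not in entry or "formula" not in entry:
        raise RegistryError(f"malformed registry entry: {entry!r}")
    parse_formula(str(entry["formula"]))  # validate elements early
    return ResidueDefinition(
        code=str(entry["code"]),
        formula=str(entry["formula"]),
        base_class=str(entry.get("base_class", "")),
        name=str(entry.get("name", "")),
        parent_code=entry.get("parent"),
        ribose_2prime_methyl=bool(entry.get("ribose_2prime_methyl", False)),
        t1_cleavable=bool(entry.get("t1_cleavable", False)),
        rnaseA_cleavable=bool(entry.get("rnaseA_cleavable", False)),
        aliases=tuple(entry.get("aliases", ())),
    )


def _load_yaml(source) -> list[Mapping]:
    data = yaml.safe_load(source)
    if data is None:
        return []
    if not isinstance(data, Mapping) or "residues" not in data:
        raise RegistryError("registry file must contain a top-level 'residues' list")
    residues = data["residues"]
    if residues is None:
        return []
    if not isinstance(residues, list):
        raise RegistryError("'residues' must be a list of entries")
    return residues


def _builtin_registry() -> Registry:
    registry = Registry()
    text = (
        importlib.resources.files("trnamass")
        .joinpath("data/residues.yaml")
        .read_text(encoding="utf-8")
    )
    for entry in _load_yaml(text):
        registry.add(_residue_from_entry(entry))
    registry._mark_builtin()
    return registry


_DEFAULT: Registry | None = None


def default_registry() -> Registry:
    """The shared built-in registry (loaded once per process)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _builtin_registry()
    return _DEFAULT


def load_registry(path: str | Path | None = None, override: bool = False) -> Registry:
    """Built-in registry merged with an optional user YAML/JSON file.

    User entries may add residues; redefining a built-in raises unless
    ``override=True`` (or the entry carries ``override: true``).
    """
    registry = _builtin_registry()
    if path is None:
        return registry
    with open(path, encoding="utf-8") as handle:
        entries = _load_yaml(handle)
    for entry in entries:
        allow = override or bool(entry.get("override", False))
        residue = _residue_from_entry(entry)
        if residue.code in registry and not allow:
            raise RegistryError(
                f"registry file redefines built-in residue {residue.code!r} "
                "without override"
            )
        registry.add(residue, override=allow)
    return registry
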