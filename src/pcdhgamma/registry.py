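"""Isoform registries for the clustered protocadherin gamma (Pcdhg) locus.

The mouse Pcdhg cluster encodes 19 "variable" isoforms (12 gamma-A plus
7 gamma-B family members; Pcdhgb3 does not exist in mouse) and 3 "C-type"
isoforms (C3, C4, C5). Each isoform is defined by its own variable first
exon. The registry fixes the isoform identities and column order used by
every count matrix and similarity computation in this package; it is
configurable for non-default naming schemes or other species.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class IsoformRegistry:
    """Ordered sets of variable and C-type isoform identifiers.

    Parameters
    ----------
    variable_names
        Ordered identifiers of the variable isoforms (gamma-A and gamma-B
        families). The default has 19 entries.
    ctype_names
        Ordered identifiers of the C-type isoforms (C3, C4, C5).
    """

    variable_names: tuple[str, ...]
    ctype_names: tuple[str, ...]

    def __post_init__(self) -> None:
        var = tuple(self.variable_names)
        cty = tuple(self.ctype_names)
        object.__setattr__(self, "variable_names", var)
        object.__setattr__(self, "ctype_names", cty)
        all_names = var + cty
        if len(set(all_names)) != len(all_names):
            raise ValueError("registry names must be unique and the variable "
                             "and C-type sets disjoint")
        if not all_names:
            raise ValueError("registry cannot be empty")

    @property
    def all_names(self) -> tuple[str, ...]:
        """Variable isoforms followed by C-type isoforms (column order)."""
        return self.variable_names + self.ctype_names

    @property
    def n_variable(self) -> int:
        return len(self.variable_names)

    @property
    def n_ctype(self) -> int:
        return len(self.ctype_names)

    @property
    def n_isoforms(self) -> int:
        return len(self.variable_names) + len(self.ctype_names)

    def is_ctype(self, name: str) -> bool:
        return name in self.ctype_names

    def index(self, name: str) -> int:
        """Column index of ``name`` in the full (variable + C-type) order."""
        try:
            return self.all_names.index(name)
        except ValueError:
            raise KeyError(f"unknown isoform identifier: {name!r}") from None

    def __contains__(self, name: object) -> bool:
        return name in self.all_names


def default_registry() -> IsoformRegistry:
    """The 22-isoform mouse Pcdhg registry (19 variable + C3/C4/C5)."""
    return IsoformRegistry(
        variable_names=tuple(f"Pcdhga{i}" for i in range(1, 13))
        + tuple(f"Pcdhgb{i}" for i in (1, 2, 4, 5, 6, 7, 8)),
        ctype_names=("Pcdhgc3", "Pcdhgc4", "Pcdhgc5"),
    )


DEFAULT_REGISTRY = default_registry()
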