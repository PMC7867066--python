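"""Isotope cost arithmetic for labeling media recipes.

Costs are per litre of medium; the effective 13C molar fraction of a
glucose mix is corrected for the molar-mass difference between U-13C6 and
natural-abundance glucose (186.11 vs 180.16 g/mol), which is what brings a
0.42 g + 1.6 g mass recipe to ~20 mol%.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError, NumericalError

__all__ = [
    "Component",
    "MediaRecipe",
    "scheme_cost",
    "cost_ratio",
    "effective_13c_fraction",
    "MW_GLUCOSE_13C",
    "MW_GLUCOSE_12C",
]

MW_GLUCOSE_13C = 186.11  # g/mol, U-13C6 D-glucose
MW_GLUCOSE_12C = 180.16  # g/mol, natural-abundance D-glucose

TAGS = ("13C-glucose", "12C-glucose", "15N-ammonium", "other")


@dataclass(frozen=True)
class Component:
    name: str
    grams_per_l: float
    price_per_g: float = 0.0
    tag: str = "other"
    molar_mass: float | None = None

    def __post_init__(self):
        if self.grams_per_l < 0 or self.price_per_g < 0:
            raise InputError(f"{self.name}: negative grams or price")
        if self.tag not in TAGS:
            raise InputError(f"{self.name}: unknown isotope tag {self.tag!r}")

    @property
    def moles_per_l(self) -> float:
        mm = self.molar_mass
        if mm is None:
            mm = {"13C-glucose": MW_GLUCOSE_13C,
                  "12C-glucose": MW_GLUCOSE_12C}.get(self.tag)
        if mm is None or mm <= 0:
            raise InputError(f"{self.name}: molar mass required")
        return self.grams_per_l / mm


@dataclass(frozen=True)
class MediaRecipe:
    name: str
    components: tuple[Component, ...]

    def __post_init__(self):
        object.__setattr__(self, "components", tuple(self.components))

    def by_tag(self, tag: str) -> list[Component]:
        return [c for c in self.components if c.tag == tag]


def scheme_cost(recipe: MediaRecipe) -> float:
    """Total isotope cost per litre: sum of grams x price over components."""
    return sum(c.grams_per_l * c.price_per_g for c in recipe.components)


def cost_ratio(recipe_a: MediaRecipe, recipe_b: MediaRecipe) -> float:
    """cost(A) / cost(B)."""
    cb = scheme_cost(recipe_b)
    if cb == 0:
        raise NumericalError(f"recipe {recipe_b.name!r} has zero cost")
    return scheme_cost(recipe_a) / cb


def effective_13c_fraction(
    recipe: MediaRecipe,
    include_natural_abundance: bool = False,
    nat_abund: float = 0.011,
    isotopic_purity: float = 0.99,
) -> float:
    """Molar fraction of labeled glucose in the carbon source.

    With ``include_natural_abundance`` the result is instead the per-carbon
    13C probability: labeled molecules contribute at their isotopic purity,
    unlabeled ones at natural abundance.
    """
    labeled = sum(c.moles_per_l for c in recipe.by_tag("13C-glucose"))
    unlabeled = sum(c.moles_per_l for c in recipe.by_tag("12C-glucose"))
    total = labeled + unlabeled
    if total == 0:
        raise InputError(f"recipe {recipe.name!r} has no glucose component")
    frac = labeled / total
    if include_natural_abundance:
        return frac * isotopic_purity + (1.0 - frac) * nat_abund
    return frac
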