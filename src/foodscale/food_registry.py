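"""Label-to-trait lookup for the 51 dishes the shipped calibration
covers.

Trait assignment is a lookup on the recognised food label, never
inferred from pixels: the morphology category determines which linear
area-to-weight model applies.
"""

from __future__ import annotations

from typing import Optional

from .area_weight import TraitClass
from .errors import ModelError

__all__ = ["DISH_TRAITS", "trait_for_label", "known_labels"]

_BLOCK = [
    "Roasted meat",
    "Stir-fried pork with bamboo shoots",
    "Chicken thigh block",
    "Sweet and sour pork ribs",
    "Braised beans with potatoes",
    "Potato grilled pork ribs",
    "Eggplant chunks",
    "Pork meatballs",
    "Mushroom and chicken",
    "Halogen pig's feet",
    "Radish flank",
    "Fried yam block",
    "Fried chicken wings",
    "Tomato scrambled eggs",
    "Konjac roast duck",
    "Steak",
    "French fries",
]

_SLICE = [
    "Vinegar cabbage",
    "Shredded pork with Beijing sauce",
    "Bean sprouts salad",
    "Fried lettuce silk",
    "Green pepper shredded pork",
    "Fried pork with garlic sprouts",
    "Stir-fried pork with mushrooms",
    "Shredded onion",
    "Sausage slices",
    "Sliced ham",
    "Shredded chicken",
    "Vegetable salad",
    "Cold noodles",
    "Needle mushroom with sauce",
    "Dried fish fillet",
    "Sliced carrot",
    "Potato silk",
]

_GRAIN = [
    "Cucumber salad",
    "Chicken diced",
    "Stir-fried lotus root diced",
    "Stir-fried pork with lettuce diced",
    "Shrimp corn",
    "Cowpea fleshy foam",
    "Fried diced chicken",
    "Spicy chicken",
    "Bean curd butyl",
    "Beef granules",
    "Ham fried rice",
    "Carrot dices",
    "Mushroom butyl",
    "Green pepper corn",
    "Groundnut kernels",
    "Pea",
    "Bamboo butyl",
]

#: All 51 registered dishes and their morphology trait.
DISH_TRAITS: dict[str, TraitClass] = {
    **{name: TraitClass.BLOCK_THICK_BAR for name in _BLOCK},
    **{name: TraitClass.SLICE_SILK for name in _SLICE},
    **{name: TraitClass.GRAIN_GRANULE for name in _GRAIN},
}

_LOWER = {k.lower(): v for k, v in DISH_TRAITS.items()}


def known_labels() -> list[str]:
    return sorted(DISH_TRAITS)


def trait_for_label(label: str, strict: bool = True) -> Optional[TraitClass]:
    """Trait class for a recognised dish label (case-insensitive).

    Unknown labels raise when ``strict`` (the caller must then supply a
    trait explicitly) or return None otherwise.
    """
    trait = _LOWER.get(label.strip().lower())
    if trait is None and strict:
        raise ModelError(
            f"label {label!r} is not in the registered dish vocabulary; "
            "supply a trait class explicitly"
        )
    return trait
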