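"""Canonical food-group vocabulary for the dietary-network pipeline.

The pipeline operates on 39 food groups aggregated from a semi-quantitative
FFQ, with intakes in grams/day.  ``CANONICAL_GROUPS`` fixes both the set and
the column order used everywhere downstream (precision matrices, network
exports, scores), so results are reproducible across runs and machines.

``DEFAULT_MARGINALS`` carries a realistic (mean, SD) pair in g/day per group,
matching the intake scale of an adult urban Iranian cohort; the synthetic
cohort generator uses them as its default marginal targets.
"""

from __future__ import annotations

# Order is canonical: every matrix/table indexed by food group uses this order.
CANONICAL_GROUPS: tuple[str, ...] = (
    "cookies_cakes",
    "chips_puffs",
    "sauce",
    "processed_meat",
    "meat",
    "carbonated_drinks",
    "sweets",
    "spices",
    "dessert",
    "fish",
    "organ_meats",
    "french_fries",
    "fresh_fruits",
    "canned_fruits",
    "fruit_juice",
    "dried_fruits",
    "cabbage",
    "garlic",
    "mushroom",
    "cooked_vegetables",
    "green_leafy_vegetables",
    "other_vegetables",
    "nuts",
    "legumes",
    "high_fat_dairy",
    "low_fat_dairy",
    "low_fat_cheese",
    "high_fat_cheese",
    "grains",
    "breads",
    "rice_pasta_noodles",
    "butter",
    "margarine",
    "animal_fat",
    "vegetable_oils_olive",
    "cooked_potatoes",
    "egg",
    "tea",
    "coffee",
)

#: (mean g/day, SD g/day) defaults per food group.
DEFAULT_MARGINALS: dict[str, tuple[float, float]] = {
    "cookies_cakes": (24.8, 42.8),
    "chips_puffs": (9.44, 30.3),
    "sauce": (2.6, 3.89),
    "processed_meat": (3.23, 7.77),
    "meat": (65.3, 75.4),
    "carbonated_drinks": (42.7, 120.0),
    "sweets": (32.5, 41.5),
    "spices": (38.8, 33.7),
    "dessert": (1.01, 2.57),
    "fish": (12.2, 21.6),
    "organ_meats": (4.97, 15.0),
    "french_fries": (11.6, 36.3),
    "fresh_fruits": (345.0, 405.0),
    "canned_fruits": (5.07, 27.1),
    "fruit_juice": (28.2, 82.8),
    "dried_fruits": (16.1, 74.0),
    "cabbage": (7.66, 23.8),
    "garlic": (1.15, 3.25),
    "mushroom": (5.15, 11.7),
    "cooked_vegetables": (99.2, 85.2),
    "green_leafy_vegetables": (31.3, 41.1),
    "other_vegetables": (270.0, 250.0),
    "nuts": (15.7, 33.9),
    "legumes": (34.3, 46.0),
    "high_fat_dairy": (116.0, 202.0),
    "low_fat_dairy": (354.0, 405.0),
    "low_fat_cheese": (6.24, 1.16),
    "high_fat_cheese": (6.5, 14.3),
    "grains": (18.0, 36.0),
    "breads": (144.0, 13.8),
    "rice_pasta_noodles": (273.0, 231.0),
    "butter": (3.50, 11.5),
    "margarine": (2.82, 3.11),
    "animal_fat": (2.32, 8.17),
    "vegetable_oils_olive": (15.0, 24.3),
    "cooked_potatoes": (26.7, 31.4),
    "egg": (21.2, 25.1),
    "tea": (574.0, 707.0),
    "coffee": (26.5, 56.7),
}

assert set(DEFAULT_MARGINALS) == set(CANONICAL_GROUPS)
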