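"""Reference vocabulary of the 15 European fly-pollinator families.

The published corpus composition (image counts per family, plus the number
of distinct species and genera represented) is embedded here so that the
stratified-split arithmetic can be verified without access to the images
themselves. The counts sum to 29,275 images.
"""

from __future__ import annotations

# family -> (n_images, n_species, n_genera)
FAMILY_COMPOSITION: dict[str, tuple[int, int, int]] = {
    "Anthomyiidae": (1488, 132, 31),
    "Bombyliidae": (2239, 151, 40),
    "Calliphoridae": (1840, 37, 13),
    "Conopidae": (2356, 57, 10),
    "Empididae": (1632, 144, 14),
    "Fanniidae": (521, 36, 2),
    "Hybotidae": (1739, 93, 17),
    "Muscidae": (2163, 212, 41),
    "Sarcophagidae": (1346, 77, 22),
    "Scathophagidae": (2044, 64, 24),
    "Sepsidae": (2363, 32, 10),
    "Stratiomyidae": (2538, 115, 29),
    "Syrphidae": (2321, 485, 82),
    "Tabanidae": (2360, 97, 12),
    "Tachinidae": (2325, 370, 190),
}

DEFAULT_FAMILIES: tuple[str, ...] = tuple(FAMILY_COMPOSITION)

FAMILY_IMAGE_COUNTS: dict[str, int] = {
    f: c[0] for f, c in FAMILY_COMPOSITION.items()
}

TOTAL_IMAGES: int = sum(FAMILY_IMAGE_COUNTS.values())  # 29275
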