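"""Integer label vocabulary for phantom anatomy.

One integer per voxel/pixel; labels are mutually exclusive.  Semantic
groupings (which labels are endolymph, which are perilymph, which belong
to a given cochlear turn) are expressed as frozensets over this
vocabulary rather than as additional per-voxel channels.
"""

from __future__ import annotations

BACKGROUND = 0
MODIOLUS = 1

# cochlea: three turns, each split into a perilymphatic part and the
# endolymphatic scala media
COCHLEA_PERI_BASAL = 10
COCHLEA_PERI_MIDDLE = 11
COCHLEA_PERI_APICAL = 12
SCALA_MEDIA_BASAL = 13
SCALA_MEDIA_MIDDLE = 14
SCALA_MEDIA_APICAL = 15

# vestibule and otolithic organs
VESTIBULE_PERI = 20
SACCULE = 21
UTRICLE = 22

# lateral semicircular canal as seen on the axial MR grid
LSCC_RING = 30
LSCC_AMPULLA = 31
CANAL_TERRITORY = 32  # LSCC lumen outside the vestibule boundary

# 2D canal cross-sections (histology sites); per canal: lumen + duct
CANAL_CROSS_ANTERIOR = 40
CANAL_CROSS_LATERAL = 41
CANAL_CROSS_POSTERIOR = 42
CANAL_DUCT_ANTERIOR = 43
CANAL_DUCT_LATERAL = 44
CANAL_DUCT_POSTERIOR = 45

CANALS = ("anterior", "lateral", "posterior")
CANAL_CROSS = {
    "anterior": CANAL_CROSS_ANTERIOR,
    "lateral": CANAL_CROSS_LATERAL,
    "posterior": CANAL_CROSS_POSTERIOR,
}
CANAL_DUCT = {
    "anterior": CANAL_DUCT_ANTERIOR,
    "lateral": CANAL_DUCT_LATERAL,
    "posterior": CANAL_DUCT_POSTERIOR,
}

TURNS = ("basal", "middle", "apical")
SCALA_MEDIA = {
    "basal": SCALA_MEDIA_BASAL,
    "middle": SCALA_MEDIA_MIDDLE,
    "apical": SCALA_MEDIA_APICAL,
}
COCHLEA_PERI = {
    "basal": COCHLEA_PERI_BASAL,
    "middle": COCHLEA_PERI_MIDDLE,
    "apical": COCHLEA_PERI_APICAL,
}

ENDOLYMPH_LABELS = frozenset(
    {SCALA_MEDIA_BASAL, SCALA_MEDIA_MIDDLE, SCALA_MEDIA_APICAL, SACCULE, UTRICLE}
    | set(CANAL_DUCT.values())
)
PERILYMPH_LABELS = frozenset(
    {
        COCHLEA_PERI_BASAL,
        COCHLEA_PERI_MIDDLE,
        COCHLEA_PERI_APICAL,
        VESTIBULE_PERI,
        LSCC_RING,
        LSCC_AMPULLA,
        CANAL_TERRITORY,
    }
    | set(CANAL_CROSS.values())
)
FLUID_LABELS = ENDOLYMPH_LABELS | PERILYMPH_LABELS

# tissue classes driving the MR signal model
CLASS_BONE = "bone"
CLASS_PERILYMPH = "perilymph"
CLASS_ENDOLYMPH = "endolymph"

NAMES = {
    BACKGROUND: "background",
    MODIOLUS: "modiolus",
    COCHLEA_PERI_BASAL: "cochlea_peri_basal",
    COCHLEA_PERI_MIDDLE: "cochlea_peri_middle",
    COCHLEA_PERI_APICAL: "cochlea_peri_apical",
    SCALA_MEDIA_BASAL: "scala_media_basal",
    SCALA_MEDIA_MIDDLE: "scala_media_middle",
    SCALA_MEDIA_APICAL: "scala_media_apical",
    VESTIBULE_PERI: "vestibule_peri",
    SACCULE: "saccule",
    UTRICLE: "utricle",
    LSCC_RING: "lscc_ring",
    LSCC_AMPULLA: "lscc_ampulla",
    CANAL_TERRITORY: "canal_territory",
    CANAL_CROSS_ANTERIOR: "canal_cross_anterior",
    CANAL_CROSS_LATERAL: "canal_cross_lateral",
    CANAL_CROSS_POSTERIOR: "canal_cross_posterior",
    CANAL_DUCT_ANTERIOR: "canal_duct_anterior",
    CANAL_DUCT_LATERAL: "canal_duct_lateral",
    CANAL_DUCT_POSTERIOR: "canal_duct_posterior",
}


def tissue_class(label: int) -> str:
    """Map an anatomy label to the MR tissue class driving its signal."""
    if label in ENDOLYMPH_LABELS:
        return CLASS_ENDOLYMPH
    if label in PERILYMPH_LABELS:
        return CLASS_PERILYMPH
    return CLASS_BONE
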