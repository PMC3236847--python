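"""Default organ vocabulary.

The 52 canonical human organ names used as the default vocabulary, with
their organ systems.  Any other vocabulary is accepted throughout the
package; this list only supplies defaults (e.g. organ names for the
synthetic-data generator and canonical spellings for mapping tables).

Organ names are canonicalized everywhere as: lowercase, stripped,
internal whitespace collapsed to single spaces.
"""

import re

__all__ = ["ORGANS_52", "ORGAN_SYSTEMS", "canonical_organ"]

_WS = re.compile(r"\s+")


def canonical_organ(name: str) -> str:
    """Canonicalize a free-text organ (or tissue) label."""
    return _WS.sub(" ", name.strip().lower())


#: organ -> organ system ("" where the tissue does not belong to a
#: classical organ system and is kept as an organ of its own, e.g.
#: adipose, leiomios, peritoneum)
ORGAN_SYSTEMS: dict[str, str] = {
    "brain": "nervous system",
    "testis": "reproductive system",
    "lung": "respiratory system",
    "liver": "digestive system",
    "eye": "nervous system",
    "uterus": "reproductive system",
    "kidney": "excretory system",
    "placenta": "embryonic system",
    "embryo": "embryonic system",
    "spleen": "immune system",
    "colon": "digestive system",
    "breast": "reproductive system",
    "skin": "integumentary system",
    "prostate": "reproductive system",
    "pancreas": "digestive system",
    "bone": "skeletal system",
    "heart": "circulatory system",
    "muscle": "muscular system",
    "stomach": "digestive system",
    "ovary": "reproductive system",
    "blood": "circulatory system",
    "lymph node": "lymphatic system",
    "blood vessel": "circulatory system",
    "thymus": "immune system",
    "bone marrow": "immune system",
    "nerve": "nervous system",
    "mouth": "digestive system",
    "thyroid": "endocrine system",
    "small intestine": "digestive system",
    "cervix": "reproductive system",
    "adrenal gland": "endocrine system",
    "trachea": "respiratory system",
    "pharynx": "respiratory system",
    "bladder": "excretory system",
    "lymph": "lymphatic system",
    "larynx": "respiratory system",
    "parathyroid gland": "endocrine system",
    "pituitary": "endocrine system",
    "esophagus": "digestive system",
    "adipose": "",
    "ear": "nervous system",
    "salivary gland": "digestive system",
    "ganglia": "nervous system",
    "tonsil": "immune system",
    "umbilical cord": "embryonic system",
    "ureter": "excretory system",
    "amnion": "embryonic system",
    "rectum": "digestive system",
    "leiomios": "",
    "gallbladder": "digestive system",
    "spinal cord": "nervous system",
    "peritoneum": "",
}

#: the 52 default organ names, in a fixed order
ORGANS_52: tuple[str, ...] = tuple(ORGAN_SYSTEMS)

assert len(ORGANS_52) == 52
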