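"""Bundled example annotations.

Two freshwater-crab mitogenome annotation tables (genus *Sinopotamon*)
ship with the package as worked examples and test fixtures: the complete
17,311 bp *S. chishuiense* genome (38 features) and the nearly complete
16,785 bp *S. wushanense* genome (37 features; trnI not recovered).
Coordinates only — the tables carry no nucleotide sequence.
"""

from __future__ import annotations

from importlib import resources

from .model_io import MitogenomeAnnotation, read_annotation_table

_FILES = {
    "chishuiense": "sinopotamon_chishuiense.tsv",
    "wushanense": "sinopotamon_wushanense.tsv",
}


def available() -> list[str]:
    return sorted(_FILES)


def load_annotation(name: str) -> MitogenomeAnnotation:
    """Load a bundled annotation by short name (see :func:`available`)."""
    key = name.lower().replace("sinopotamon_", "").replace("s_", "")
    if key not in _FILES:
        raise KeyError(f"unknown dataset {name!r}; available: {available()}")
    ref = resources.files("mitorder.data") / _FILES[key]
    with resources.as_file(ref) as path:
        return read_annotation_table(path)
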