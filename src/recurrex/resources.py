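"""Paths to the packaged fixture files.

All fixtures are synthetic reconstructions: the original supplementary
tables of the source cohort are not redistributable, so the shipped positive
concept set, development partial sentences, and lexicon were hand-built to
the published counts and worked examples from recurrence vocabulary.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path


def _data(name: str) -> Path:
    return Path(str(resources.files("recurrex").joinpath("data", name)))


def lexicon_path() -> Path:
    """Synthetic dictionary lexicon covering the fixture vocabulary."""
    return _data("lexicon_synthetic.tsv")


def positive_set_path() -> Path:
    """Synthetic 48-CUI positive concept set."""
    return _data("positive_set_synthetic.tsv")


def partial_sentences_path() -> Path:
    """Synthetic 93 development partial sentences."""
    return _data("partial_sentences_synthetic.txt")


def exclusion_path() -> Path:
    """Function-word CUIs excluded when re-deriving the positive set."""
    return _data("exclusion_default.tsv")


def triggers_path() -> Path:
    """Default NegEx trigger + contextual-cue lexicon."""
    return _data("triggers_default.yaml")


def positive_templates_path() -> Path:
    return _data("templates_positive.txt")


def negative_templates_path() -> Path:
    return _data("templates_negative.txt")


def confound_templates_path() -> Path:
    return _data("templates_confound.txt")


def filler_templates_path() -> Path:
    return _data("templates_filler.txt")
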