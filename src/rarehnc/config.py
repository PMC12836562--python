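"""Loading of the YAML configuration resources.

Every classification rule in the package — ICD-10 code sets, the ADICAP
decoding dictionary, the text-mining lexicon and the qualifier triggers —
lives in data files, never in code.  The package ships documented defaults
under ``rarehnc/resources``; each loader accepts an explicit path so
deployments can swap in local rule sets.
"""

from __future__ import annotations

from importlib import resources as _res
from pathlib import Path
from typing import Any, Optional, Union

import yaml

PathLike = Union[str, Path]


def _load_yaml(name: str, path: Optional[PathLike]) -> dict[str, Any]:
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    text = _res.files("rarehnc").joinpath("resources", name).read_text(encoding="utf-8")
    return yaml.safe_load(text)


def load_codesets(path: Optional[PathLike] = None):
    from .icd10 import CodesetConfig

    raw = _load_yaml("codesets.yaml", path)
    return CodesetConfig.from_dict(raw)


def load_adicap_dictionary(path: Optional[PathLike] = None):
    from .adicap import AdicapDictionary

    raw = _load_yaml("adicap_dictionary.yaml", path)
    return AdicapDictionary.from_dict(raw)


def load_lexicon(path: Optional[PathLike] = None):
    from .textmine import Lexicon

    raw = _load_yaml("lexicon.yaml", path)
    return Lexicon.from_dict(raw)


def load_triggers(path: Optional[PathLike] = None):
    from .textmine import TriggerConfig

    raw = _load_yaml("triggers.yaml", path)
    return TriggerConfig.from_dict(raw)
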