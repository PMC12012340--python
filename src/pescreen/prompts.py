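"""Prompt template loading and LLM dialect wrapping.

Model families disagree about chat delimiters: Phi-3 brackets turns with
``<|im_start|>``/``<|im_end|>``, Mistral wraps instructions in
``[INST]`` tags, Llama-3 and Gemma use their own role markers.  A
:class:`PromptDialect` is a reversible prefix/suffix pair, so the user
payload can always be recovered from a wrapped prompt.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml


@dataclass(frozen=True)
class PromptDialect:
    name: str
    prefix: str
    suffix: str

    def wrap(self, payload: str) -> str:
        return self.prefix + payload + self.suffix

    def unwrap(self, prompt: str) -> str:
        out = prompt
        if self.prefix and out.startswith(self.prefix):
            out = out[len(self.prefix):]
        if self.suffix and out.endswith(self.suffix):
            out = out[: -len(self.suffix)]
        return out


DIALECTS: dict[str, PromptDialect] = {
    "plain": PromptDialect("plain", "", ""),
    "llama3": PromptDialect(
        "llama3",
        "<|begin_of_text|><|start_header_id|>user<|end_header_id|>\n\n",
        "<|eot_id|><|start_header_id|>assistant<|end_header_id|>\n\n",
    ),
    "mistral": PromptDialect("mistral", "[INST] ", " [/INST]"),
    "gemma": PromptDialect(
        "gemma", "<start_of_turn>user\n", "<end_of_turn>\n<start_of_turn>model\n"
    ),
    "phi3": PromptDialect(
        "phi3", "<|im_start|>user\n", "<|im_end|>\n<|im_start|>assistant\n"
    ),
}


def get_dialect(name: str) -> PromptDialect:
    try:
        return DIALECTS[name]
    except KeyError:
        raise ValueError(f"unknown prompt dialect {name!r}; know {sorted(DIALECTS)}")


def unwrap_any(prompt: str) -> str:
    """Strip whichever known dialect wrapping is present, if any."""
    for dialect in DIALECTS.values():
        if dialect.prefix and prompt.startswith(dialect.prefix):
            return dialect.unwrap(prompt)
    return prompt


@lru_cache(maxsize=4)
def load_prompts(path: Optional[str] = None) -> dict:
    """Load prompt templates from YAML (packaged default or a user file)."""
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = (resources.files("pescreen") / "data" / "prompts.yaml").read_text(
            encoding="utf-8"
        )
    return yaml.safe_load(text)
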