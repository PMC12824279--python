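"""Prompt construction for the benchmarking protocol.

The word-list task, its control, the strategy variants and the creative
writing tasks each have a fixed prompt; scores are only comparable across
groups when every group saw exactly the same instruction, so the texts
live here as frozen constants rather than user configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DAT_PROMPT",
    "CONTROL_PROMPT",
    "STRATEGY_CLAUSES",
    "CREATIVE_PROMPTS",
    "TEMPERATURES",
    "PromptSpec",
    "build_prompt",
]

DAT_PROMPT = (
    "Please enter 10 words that are as different from each other as possible, "
    "in all meanings and uses of the words. Rules: Only single words in English. "
    "Only nouns (e.g., things, objects, concepts). No proper nouns (e.g., no "
    "specific people or places). No specialized vocabulary (e.g., no technical "
    "terms). Think of the words on your own (e.g., do not just look at objects "
    "in your surroundings). Make a list of these 10 words, a single word in "
    "each entry of the list."
)

CONTROL_PROMPT = "make a list of 10 words"

# Appended to the task instructions as "... using a strategy that relies on X."
STRATEGY_CLAUSES = {
    "opposition": "meaning opposition",
    "thesaurus": "a thesaurus",
    "etymology": "varying etymology",
}

CREATIVE_PROMPTS = {
    "haiku": "Invent a haiku.",
    "synopsis": "Invent the synopsis of a movie, with a strict word limit of 50 words.",
    "flash_fiction": "Invent a flash fiction, with a strict word limit of 200 words.",
}

TEMPERATURES = {"low": 0.5, "mid": 1.0, "high": 1.5, "default": None}

_TASKS = ("dat", "control", "haiku", "synopsis", "flash_fiction")


@dataclass
class PromptSpec:
    """Task, optional strategy, and temperature level for one condition."""

    task: str
    strategy: str = "none"
    temperature_label: str = "default"

    def __post_init__(self):
        if self.task not in _TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.strategy != "none":
            if self.task != "dat":
                raise ValueError("strategies apply only to the word-list task")
            if self.strategy not in STRATEGY_CLAUSES:
                raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.temperature_label not in TEMPERATURES:
            raise ValueError(f"unknown temperature label {self.temperature_label!r}")

    @property
    def temperature(self) -> float | None:
        return TEMPERATURES[self.temperature_label]


def build_prompt(spec: PromptSpec) -> str:
    """Return the verbatim prompt text for a condition."""
    if spec.task == "dat":
        prompt = DAT_PROMPT
        if spec.strategy != "none":
            prompt += (
                " Answer using a strategy that relies on "
                f"{STRATEGY_CLAUSES[spec.strategy]}."
            )
        return prompt
    if spec.task == "control":
        return CONTROL_PROMPT
    return CREATIVE_PROMPTS[spec.task]
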