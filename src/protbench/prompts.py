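"""Prompt-string construction for protein question-answering LLMs.

This module only renders strings (property name + instruction + sequence
into a chat-delimited or plain template); sending prompts to any model is
out of scope.  The per-dataset property/instruction registry mirrors the
benchmark's task set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple, Union

from .errors import UnknownDataset

_FLOAT = "You should return a floating-point number."

#: dataset -> (instruction, property name)
PROMPT_REGISTRY: Dict[str, Tuple[str, str]] = {
    "Fluorescence": (_FLOAT, "Fluorescence intensity"),
    "Beta": (_FLOAT, "Increased activity"),
    "Stability": (_FLOAT, "Protein stability"),
    "Solubility": ("You should return an integer (0 or 1) where 0 is not "
                   "soluble and 1 is soluble.", "Protein solubility"),
    "Subcellular": ("You should choose an integer within the range [0, 9] "
                    "to indicate the protein's location.", "Location"),
    "Subcellular_Binary": ("You should return an integer (0 or 1) where 0 is "
                           "membrane-bound and 1 is soluble.", "Location"),
    "Tap": (_FLOAT, "Developability"),
    "SAbDab_Chen": (_FLOAT, "Developability"),
    "CRISPR": (_FLOAT, "Repair outcome"),
    "PPI-Affinity": (_FLOAT, "Activity of PPI"),
    "Yeast-PPI": ("You should return an integer (0 or 1) where 0 is weak "
                  "and 1 is strong.", "Activity of PPI"),
    "Human-PPI": ("You should return an integer (0 or 1) where 0 is weak "
                  "and 1 is strong.", "Activity of PPI"),
    "Fold": ("You should return an integer within the range [0, 1194].",
             "Global structural topology of a protein on the fold level"),
    "Secondary": ("You should return an integer within the range [0, 2].",
                  "Local structures of protein residues in their natural state"),
}

QUESTION = "What is the {prop} of the given protein sequence {seq}? {instr}"


@dataclass(frozen=True)
class PromptTemplate:
    """Rendering style for one prompt; the rendered prompt contains the
    sequence exactly once."""

    style: str = "plain"  # plain | chat_delimited
    sequence_delimiters: Optional[Tuple[str, str]] = ("<PROTEIN>", "</PROTEIN>")
    system_instruction: str = ("You are an AI assistant specializing in "
                               "protein property prediction. Follow the "
                               "given instruction format.")

    def __post_init__(self) -> None:
        if self.style not in ("plain", "chat_delimited"):
            raise ValueError(f"unknown prompt style {self.style!r}")


def format_llm_prompt(dataset_name: str, sequence: str,
                      template: Union[str, PromptTemplate] = "plain") -> str:
    """Render the question prompt for a registered dataset.

    ``plain`` wraps the sequence in the protein delimiter tokens;
    ``chat_delimited`` uses chat-turn markers around the same question.
    """
    if isinstance(template, str):
        template = PromptTemplate(style=template)
    if dataset_name not in PROMPT_REGISTRY:
        raise UnknownDataset(
            f"{dataset_name!r} has no registered prompt; known: "
            f"{sorted(PROMPT_REGISTRY)}")
    instr, prop = PROMPT_REGISTRY[dataset_name]
    if template.style == "plain" and template.sequence_delimiters:
        opn, close = template.sequence_delimiters
        seq = f"{opn} {sequence} {close}"
    else:
        seq = sequence
    question = QUESTION.format(prop=prop, seq=seq, instr=instr)
    if template.style == "chat_delimited":
        return (f"<|im_start|>user\n{question}\n<|im_end|>\n"
                f"<|im_start|>assistant\n")
    return question
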