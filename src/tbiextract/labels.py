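"""Annotation labels and modifier directionality rules.

Every lexical target in a structured summary carries exactly one
:class:`AnnotationLabel`.  ``NOT_SPECIFIED`` survives only for reading
legacy annotator tables; the extractor itself never emits it.
"""

from __future__ import annotations

import enum


class AnnotationLabel(enum.Enum):
    """The annotation vocabulary shared by annotators and the extractor.

    PRESENT        the report explicitly denotes the finding.
    SUSPECTED      the report indicates a potential finding.
    INDETERMINATE  the finding is mentioned as one of multiple etiologies.
    NOT_SPECIFIED  legacy option, accepted on input only.
    ABSENT         the report explicitly denies the finding, or it is unmentioned.
    NORMAL         the structure is stated or assumed normal.
    ABNORMAL       the structure is stated or inferred abnormal.
    """

    PRESENT = "PRESENT"
    SUSPECTED = "SUSPECTED"
    INDETERMINATE = "INDETERMINATE"
    NOT_SPECIFIED = "NOT_SPECIFIED"
    ABSENT = "ABSENT"
    NORMAL = "NORMAL"
    ABNORMAL = "ABNORMAL"

    def __str__(self) -> str:  # CSV-friendly
        return self.value

    @classmethod
    def parse(cls, token: str) -> "AnnotationLabel":
        """Parse a label token, tolerating case and space/underscore variants."""
        norm = token.strip().upper().replace(" ", "_")
        try:
            return cls(norm)
        except ValueError:
            raise ValueError(f"unknown annotation label: {token!r}") from None


class DirectionRule(enum.Enum):
    """Scope of a lexical modifier within its sentence.

    forward        modifies targets after it, to the sentence end.
    backward       modifies targets before it, from the sentence start.
    bidirectional  both.
    """

    FORWARD = "forward"
    BACKWARD = "backward"
    BIDIRECTIONAL = "bidirectional"

    def __str__(self) -> str:
        return self.value

    @classmethod
    def parse(cls, token: str) -> "DirectionRule":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValueError(f"unknown direction rule: {token!r}") from None
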