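"""Reading and writing i2b2-2010 style ``.con`` annotation files.

One annotation per line::

    c="<text>" <line>:<token> <line>:<token>||t="<category>"

Lines are 1-based, token offsets 0-based, spans inclusive. Categories are
``problem``, ``treatment`` and ``test``.
"""

from __future__ import annotations

import re
from typing import Sequence, Union

from .types import ConceptAnnotation, GoldAnnotation

_CON_LINE = re.compile(
    r'^c="(?P<text>[^"]*)"\s+'
    r'(?P<l1>\d+):(?P<t1>\d+)\s+'
    r'(?P<l2>\d+):(?P<t2>\d+)'
    r'\|\|t="(?P<category>[^"]+)"\s*$')


class ConParseError(ValueError):
    """A malformed ``.con`` line, reported with its line number."""


def parse_con_line(line: str, lineno: int = 0) -> GoldAnnotation:
    m = _CON_LINE.match(line)
    if m is None:
        raise ConParseError(f"line {lineno}: cannot parse .con line: {line!r}")
    l1, t1, l2, t2 = (int(m.group(k)) for k in ("l1", "t1", "l2", "t2"))
    if l1 != l2:
        raise ConParseError(f"line {lineno}: multi-line spans are not supported")
    if t2 < t1:
        raise ConParseError(f"line {lineno}: span end before start")
    return GoldAnnotation(text=m.group("text"), location=(l1, t1, t2),
                          category=m.group("category"))


def read_i2b2_con(path: str, doc_id: str = "") -> list[GoldAnnotation]:
    """Parse a ``.con`` file into gold annotations (empty file -> [])."""
    out: list[GoldAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            ann = parse_con_line(line.rstrip("\n"), lineno)
            if doc_id:
                ann = GoldAnnotation(text=ann.text, location=ann.location,
                                     category=ann.category, doc_id=doc_id)
            out.append(ann)
    return out


def format_con_line(ann: Union[ConceptAnnotation, GoldAnnotation]) -> str:
    line, start, end = ann.location
    return f'c="{ann.text}" {line}:{start} {line}:{end}||t="{ann.category}"'


def write_i2b2_con(annotations: Sequence[Union[ConceptAnnotation, GoldAnnotation]],
                   path: str) -> None:
    """Write annotations as a ``.con`` file (one line per annotation)."""
    with open(path, "w", encoding="utf-8") as fh:
        for ann in annotations:
            fh.write(format_con_line(ann) + "\n")
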